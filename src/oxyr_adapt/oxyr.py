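"""Curated OxyR domain knowledge.

OxyR is the LysR-family peroxide-sensing transcription factor of enteric
bacteria. Oxidation of the redox-active Cys-199 (disulfide with Cys-208)
switches the protein between two conformers; structural regions governing the
switch and the stability of each conformer are well characterized:

* the redox loop, residues 199-208, required for tetramerization of the
  reduced form;
* the flexible loop, residues 205-216, which allows Cys-199 to swing between
  its inward (reduced) and outward (oxidized) conformations;
* a unique proline arrangement (Pro-99, 103, 107, 111) forming the flat helix
  surface needed to dimerize the oxidized form;
* the Asp-172 / His-114 salt bridge stabilizing the reduced dimer;
* the hydrophobic core around Leu-200 stabilizing the reduced monomer;
* the peroxide-binding environment (Cys-199, Thr-129, Ala-147, Pro-99,
  Thr-100) whose chemistry biases the monomeric redox transition state.

Substitutions observed to activate OxyR constitutively in adaptive laboratory
evolution of E. coli and V. natriegens cluster in exactly these regions, and
similar substitutions recur in natural E. coli isolates.
"""

from __future__ import annotations

import numpy as np

from .mutations import MutationRecord
from .structure_proximity import FeatureAnnotation

#: Protein length of E. coli OxyR (residues).
OXYR_LENGTH = 305

#: Residues with a defined wild-type identity in E. coli OxyR numbering.
#: Used both for feature annotation and to pin the synthetic stand-in
#: reference sequence at the positions the analyses interrogate.
KEY_RESIDUES: dict[int, str] = {
    99: "P",
    100: "T",
    103: "P",
    107: "P",
    111: "P",
    113: "L",
    114: "H",
    129: "T",
    147: "A",
    172: "D",
    199: "C",
    200: "L",
    201: "R",
    208: "C",
    213: "A",
}


def feature_annotation() -> FeatureAnnotation:
    """Stability features and sequence regions of E. coli OxyR."""
    return FeatureAnnotation(
        features={
            199: "redox_center",
            208: "stabilizes_reduced",   # redox-loop cysteine; tetramer of reduced form
            200: "stabilizes_reduced",   # hydrophobic core of the reduced monomer
            172: "stabilizes_reduced",   # salt bridge with His-114
            114: "stabilizes_reduced",
            129: "transition_state",     # peroxide-binding environment
            147: "transition_state",
            100: "transition_state",
            99: "proline_arrangement",
            103: "proline_arrangement",
            107: "proline_arrangement",
            111: "proline_arrangement",
        },
        regions={
            "flexible_loop": (205, 216),
            "redox_loop": (199, 208),
        },
    )


def ale_mutations() -> list[MutationRecord]:
    """OxyR substitutions observed during laboratory evolution.

    Origins: ``E. coli`` (iron-replete evolution), ``V. natriegens``
    (fast-growth evolution) or ``both``.
    """
    raw = [
        ("A213P", "E. coli"),
        ("A213E", "V. natriegens"),
        ("A147E", "V. natriegens"),
        ("T100A", "E. coli"),
        ("P99T", "V. natriegens"),
        ("P107L", "E. coli"),
        ("L200I", "V. natriegens"),
        ("L113Q", "V. natriegens"),
        ("C208Y", "E. coli"),
        ("C208G", "V. natriegens"),
    ]
    return [MutationRecord.parse(s, origin=o) for s, o in raw]


def constitutive_reference_positions() -> list[dict]:
    """Reference set of positions whose substitution activates OxyR.

    Drawn from the laboratory-evolution substitutions plus the mutagenesis
    literature on constitutively active alleles (R201 class). Entries are
    dicts of ``{"position", "var_aa", "source"}``; ``var_aa`` None means any
    nonsynonymous change at the position qualifies under the position rule.
    """
    entries = [
        {"position": m.position, "var_aa": m.var_aa,
         "source": "ALE_Ecoli" if m.origin == "E. coli" else "ALE_Vnatriegens"}
        for m in ale_mutations()
    ]
    entries.append({"position": 201, "var_aa": None, "source": "literature"})
    return entries


def natural_isolate_substitutions() -> list[str]:
    """Substitutions reported in natural E. coli isolates carrying
    constitutive-class OxyR changes (seven genomes; R201C appears twice)."""
    return ["R201C", "R201C", "R201S", "A213T", "P107T", "A147V", "L200V"]


def synthetic_oxyr_protein(seed: int = 7) -> str:
    """Synthetic stand-in for the E. coli OxyR protein sequence.

    A random 305-residue sequence with the functionally annotated residues
    pinned to their true identities (see :data:`KEY_RESIDUES`), so that every
    positional analysis (allele screen, structure mapping) operates on the
    real coordinate system. It is NOT the real OxyR sequence and no sequence-
    identity claims are made from it.
    """
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    seq = rng.choice(alphabet, size=OXYR_LENGTH)
    # Met start for a plausible CDS
    seq[0] = "M"
    for pos, aa in KEY_RESIDUES.items():
        seq[pos - 1] = aa
    return "".join(seq)
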