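"""Screen coding-sequence collections for constitutive-activation OxyR alleles.

The screen deduplicates a CDS collection at the DNA and protein level, calls
amino-acid substitutions of each unique protein against the reference OxyR,
flags genomes whose substitutions fall at positions known to activate OxyR
constitutively, and maps positions between species through a global protein
alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .mutations import MutationRecord
from .synthetic_data import AlleleCollection

_DNA = set("ACGT")


@dataclass
class ConstitutiveReferenceSet:
    """Positions (and optionally variant residues) whose substitution is
    recognized to activate OxyR constitutively."""

    entries: list[dict]

    def __post_init__(self) -> None:
        for e in self.entries:
            if e["position"] < 1:
                raise ValueError("positions are 1-based")

    @property
    def positions(self) -> set[int]:
        return {e["position"] for e in self.entries}

    def exact_pairs(self) -> set[tuple[int, str]]:
        return {
            (e["position"], e["var_aa"]) for e in self.entries if e.get("var_aa")
        }


@dataclass
class DedupResult:
    dna_groups: dict[str, list[str]]        # representative genome id -> members
    protein_groups: dict[str, list[str]]
    proteins: dict[str, str]                # genome id -> protein (callable records)
    flagged: dict[str, str]                 # genome id -> reason excluded
    counts: dict[str, int] = field(default_factory=dict)


@dataclass
class ScreenResult:
    rows: pd.DataFrame                      # genome_id, sequence_change, metadata
    counts: dict[str, int]
    evidence: dict[str, list[str]]          # genome id -> matched substitutions
    shared_substitutions: dict[str, int]    # substitution -> genomes carrying it


def translate_and_dedup(collection: AlleleCollection) -> DedupResult:
    """Group a CDS collection into unique DNA and unique protein sequences.

    Records with ambiguity codes, length not divisible by 3 (after trimming a
    terminal stop) or internal stop codons are flagged and excluded from
    protein grouping; internal-stop records still count at the DNA level.
    """
    dna_groups: dict[str, list[str]] = {}
    dna_rep: dict[str, str] = {}
    protein_groups: dict[str, list[str]] = {}
    prot_rep: dict[str, str] = {}
    proteins: dict[str, str] = {}
    flagged: dict[str, str] = {}

    for gid, dna in collection.records:
        dna = dna.upper()
        if set(dna) - _DNA:
            flagged[gid] = "ambiguity codes"
            continue
        if dna not in dna_rep:
            dna_rep[dna] = gid
            dna_groups[gid] = []
        dna_groups[dna_rep[dna]].append(gid)

        if len(dna) % 3 != 0:
            flagged[gid] = "length not divisible by 3"
            continue
        aa = str(Seq(dna).translate(table=11))
        if aa.endswith("*"):
            aa = aa[:-1]
        if "*" in aa:
            flagged[gid] = "internal stop codon (pseudogene)"
            continue
        proteins[gid] = aa
        if aa not in prot_rep:
            prot_rep[aa] = gid
            protein_groups[gid] = []
        protein_groups[prot_rep[aa]].append(gid)

    counts = {
        "n_genomes": len(collection.records),
        "n_unique_dna": len(dna_groups),
        "n_unique_protein": len(protein_groups),
        "n_flagged": len(flagged),
    }
    return DedupResult(
        dna_groups=dna_groups,
        protein_groups=protein_groups,
        proteins=proteins,
        flagged=flagged,
        counts=counts,
    )


def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def pairwise_align(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
):
    """Global protein alignment with percent identity and similarity.

    Identity = identical aligned pairs / alignment length; similarity = pairs
    with a positive substitution score / alignment length (gap columns count
    toward the length of both).
    """
    if not a or not b:
        raise ValueError("empty sequence")
    subst = substitution_matrices.load(matrix)
    alphabet = set(str(subst.alphabet))
    for name, seq in (("a", a), ("b", b)):
        bad = set(seq) - alphabet
        if bad:
            raise ValueError(f"sequence {name}: non-amino-acid symbols {sorted(bad)}")
    aligner = _aligner(matrix, gap_open, gap_extend)
    alignment = aligner.align(a, b)[0]
    ga, gb = str(alignment[0]), str(alignment[1])
    length = len(ga)
    ident = sum(x == y and x != "-" for x, y in zip(ga, gb))
    similar = sum(
        x != "-" and y != "-" and subst[x, y] > 0 for x, y in zip(ga, gb)
    )
    return alignment, 100.0 * ident / length, 100.0 * similar / length


@dataclass
class CallResult:
    """Substitutions (reference numbering) plus indel records; iterates over
    the substitutions."""

    substitutions: list[MutationRecord]
    indels: list[dict]
    identity: float

    def __iter__(self):
        return iter(self.substitutions)

    def __len__(self) -> int:
        return len(self.substitutions)

    def __getitem__(self, i):
        return self.substitutions[i]


def call_substitutions(
    variant_protein: str,
    reference_protein: str,
    min_identity: float = 50.0,
    **align_kwargs,
) -> CallResult:
    """Substitutions of a variant protein relative to the reference.

    Positions are 1-based in reference numbering; aligned gaps are reported
    as indels and never as substitutions. Alignments below ``min_identity``
    percent identity are rejected (likely the wrong gene).
    """
    alignment, identity, _ = pairwise_align(
        variant_protein, reference_protein, **align_kwargs
    )
    if identity < min_identity:
        raise ValueError(
            f"alignment identity {identity:.1f}% below {min_identity:.0f}%: "
            "probably not the same gene"
        )
    gv, gr = str(alignment[0]), str(alignment[1])
    subs: list[MutationRecord] = []
    indels: list[dict] = []
    ref_pos = 0
    for x, y in zip(gv, gr):  # x = variant, y = reference
        if y != "-":
            ref_pos += 1
        if x == "-" and y != "-":
            indels.append({"type": "del", "ref_position": ref_pos, "ref_aa": y})
        elif y == "-" and x != "-":
            indels.append({"type": "ins", "after_ref_position": ref_pos, "var_aa": x})
        elif x != y:
            subs.append(MutationRecord(wt_aa=y, position=ref_pos, var_aa=x))
    subs.sort(key=lambda m: m.position)
    return CallResult(substitutions=subs, indels=indels, identity=identity)


def screen_constitutive(
    calls: dict[str, list[MutationRecord]],
    refset: ConstitutiveReferenceSet,
    rule: str = "position_match",
    metadata: dict[str, str] | None = None,
) -> ScreenResult:
    """Flag genomes whose substitutions match the constitutive reference set.

    ``position_match`` flags any nonsynonymous change at a reference
    position; ``exact_match`` additionally requires the variant residue.
    """
    if not refset.entries:
        raise ValueError("empty constitutive reference set")
    if rule not in ("position_match", "exact_match"):
        raise ValueError(f"unknown rule {rule!r}")
    metadata = metadata or {}
    positions = refset.positions
    exact = refset.exact_pairs()

    evidence: dict[str, list[str]] = {}
    for gid, subs in calls.items():
        hits = []
        for m in subs:
            if rule == "position_match":
                ok = m.position in positions
            else:
                ok = (m.position, m.var_aa) in exact
            if ok:
                hits.append(str(m))
        if hits:
            evidence[gid] = hits

    rows = pd.DataFrame(
        [
            {
                "genome_id": gid,
                "sequence_change": ";".join(hits),
                "metadata": metadata.get(gid, "N.A."),
            }
            for gid, hits in sorted(evidence.items())
        ],
        columns=["genome_id", "sequence_change", "metadata"],
    )
    tally: dict[str, int] = {}
    for hits in evidence.values():
        for h in set(hits):
            tally[h] = tally.get(h, 0) + 1
    shared = {s: n for s, n in tally.items() if n >= 2}
    counts = {
        "n_genomes": len(calls),
        "n_flagged": len(evidence),
        "n_sharing_substitution": sum(shared.values()),
    }
    return ScreenResult(rows=rows, counts=counts, evidence=evidence,
                        shared_substitutions=shared)


def map_position(
    ref_a: str,
    ref_b: str,
    position_in_a: int,
    **align_kwargs,
) -> int | None:
    """Map a 1-based position in protein A to its aligned position in
    protein B; returns None when the column is a gap in B."""
    if not (1 <= position_in_a <= len(ref_a)):
        raise ValueError(f"position {position_in_a} out of range for sequence A")
    alignment, _, _ = pairwise_align(ref_a, ref_b, **align_kwargs)
    ga, gb = str(alignment[0]), str(alignment[1])
    pos_a = pos_b = 0
    for x, y in zip(ga, gb):
        if x != "-":
            pos_a += 1
        if y != "-":
            pos_b += 1
        if x != "-" and pos_a == position_in_a:
            return pos_b if y != "-" else None
    return None
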