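"""Generators for every input the pipeline consumes, with known ground truth.

Four generators emulate the study's data modalities:

* expression matrices with planted independently modulated gene groups whose
  condition-dependent activities are mixed with i.i.d. Gaussian noise on the
  log scale (X = S_true @ A_true + eps);
* coding-sequence collections with planted amino-acid substitutions,
  synonymous changes and exact duplicates, under the bacterial genetic code;
* two-conformer toy structures related by known per-residue rigid
  displacements, so that every pairwise distance has a closed form;
* lagged-logistic growth curves with dose-dependent lag extension and
  optional "no growth" doses.

Every generator is deterministic given its seed and returns a truth object
alongside the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .expression import ExpressionMatrix
from .mutations import MutationRecord
from .structure_proximity import StructureModel

_BACTERIAL_TABLE = CodonTable.unambiguous_dna_by_id[11]

# one representative codon per amino acid (alphabetically first), table 11
_CODON_FOR_AA: dict[str, str] = {}
for codon, aa in sorted(_BACTERIAL_TABLE.forward_table.items()):
    _CODON_FOR_AA.setdefault(aa, codon)

_SYNONYMS: dict[str, list[str]] = {}
for codon, aa in _BACTERIAL_TABLE.forward_table.items():
    _SYNONYMS.setdefault(aa, []).append(codon)
for aa in _SYNONYMS:
    _SYNONYMS[aa].sort()


# --------------------------------------------------------------------------
# expression
# --------------------------------------------------------------------------

@dataclass
class ModulonSpec:
    """Ground-truth independently modulated gene group.

    ``weights`` gives the signed source weight of each member gene (non-zero);
    ``activity_by_condition`` the planted activity level per condition.
    """

    name: str
    weights: dict[str, float]
    activity_by_condition: dict[str, float]

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValueError(f"modulon {self.name}: no member genes")
        zeros = [g for g, w in self.weights.items() if w == 0]
        if zeros:
            raise ValueError(f"modulon {self.name}: zero weights for {zeros}")

    @property
    def member_genes(self) -> set[str]:
        return set(self.weights)


def simulate_expression(
    modulons: list[ModulonSpec],
    conditions: list[tuple[str, int]],
    noise_sd: float,
    seed: int,
    n_genes: int = 1000,
    reference_condition: str | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Plant modulated gene groups into a noisy log-expression matrix.

    Returns (ExpressionMatrix, S_true, A_true) with X = S_true @ A_true + eps,
    eps ~ N(0, noise_sd^2) i.i.d.; replicate columns of a condition share the
    same planted activities.
    """
    if not conditions:
        raise ValueError("empty condition list")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    seen: dict[str, tuple[str, float]] = {}
    for mod in modulons:
        for g, w in mod.weights.items():
            if g in seen and seen[g][1] != w:
                raise ValueError(
                    f"gene {g} appears in modulons {seen[g][0]!r} and "
                    f"{mod.name!r} with conflicting weights"
                )
            seen[g] = (mod.name, w)

    members = sorted({g for mod in modulons for g in mod.member_genes})
    if len(members) > n_genes:
        raise ValueError("gene universe smaller than union of member genes")
    n_bg = n_genes - len(members)
    genes = members + [f"bg{i:04d}" for i in range(1, n_bg + 1)]

    samples, cond_of, rep_of = [], [], []
    for cond, n_rep in conditions:
        for r in range(1, n_rep + 1):
            samples.append(f"{cond}__r{r}")
            cond_of.append(cond)
            rep_of.append(r)

    S_true = pd.DataFrame(0.0, index=genes, columns=[m.name for m in modulons])
    for mod in modulons:
        for g, w in mod.weights.items():
            S_true.loc[g, mod.name] = w
    A_true = pd.DataFrame(0.0, index=[m.name for m in modulons], columns=samples)
    for mod in modulons:
        for s, c in zip(samples, cond_of):
            A_true.loc[mod.name, s] = mod.activity_by_condition.get(c, 0.0)

    rng = np.random.default_rng(seed)
    X = S_true.values @ A_true.values
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, size=X.shape)
    values = pd.DataFrame(X, index=genes, columns=samples)

    ref = reference_condition if reference_condition is not None else conditions[0][0]
    em = ExpressionMatrix(
        values=values,
        sample_conditions=pd.Series(cond_of, index=samples),
        sample_replicates=pd.Series(rep_of, index=samples),
        reference_condition=ref,
    )
    return em, S_true, A_true


# --------------------------------------------------------------------------
# alleles
# --------------------------------------------------------------------------

@dataclass
class PlantedVariant:
    """A genome with one planted nonsynonymous change plus optional
    synonymous extras."""

    genome_id: str
    substitution: MutationRecord
    synonymous_extras: int = 0


@dataclass
class AlleleCollection:
    """Named DNA coding sequences (genome id -> CDS)."""

    records: list[tuple[str, str]]
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        ids = [g for g, _ in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("genome ids are not unique")

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for gid, seq in self.records:
                fh.write(f">{gid}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")

    @classmethod
    def from_fasta(cls, path: str | Path, provenance: str | None = None) -> "AlleleCollection":
        from Bio import SeqIO

        records = [
            (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
        ]
        return cls(records=records, provenance=provenance or str(path))


def back_translate(protein: str) -> str:
    """Deterministic CDS for a protein (one fixed codon per residue, table 11,
    TAA stop appended)."""
    return "".join(_CODON_FOR_AA[aa] for aa in protein) + "TAA"


def _synonymous_codon(codon: str, rng: np.random.Generator) -> str | None:
    aa = _BACTERIAL_TABLE.forward_table.get(codon)
    if aa is None:
        return None
    alts = [c for c in _SYNONYMS[aa] if c != codon]
    if not alts:
        return None
    return alts[rng.integers(len(alts))]


def _apply_synonymous(
    cds: str, n: int, rng: np.random.Generator, protect: set[int]
) -> str:
    """Apply n synonymous codon swaps, avoiding protected codon indices."""
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    candidates = [
        i
        for i in range(len(codons) - 1)  # leave the stop codon alone
        if i not in protect and _synonymous_codon(codons[i], rng) is not None
    ]
    if n > len(candidates):
        raise ValueError("not enough synonymously mutable codons")
    for i in rng.choice(len(candidates), size=n, replace=False):
        idx = candidates[int(i)]
        codons[idx] = _synonymous_codon(codons[idx], rng)
    return "".join(codons)


def simulate_alleles(
    reference_protein: str,
    reference_cds: str,
    n_background: int,
    planted: list[PlantedVariant],
    duplicate_rate: float,
    seed: int,
) -> tuple[AlleleCollection, pd.DataFrame]:
    """Plant substitutions into a CDS collection with background genomes.

    Background genomes are exact duplicates of the reference with probability
    ``duplicate_rate``, otherwise they carry 1-2 synonymous changes. Each
    planted genome differs from the reference by exactly its nonsynonymous
    substitution plus the requested synonymous extras. The truth table lists
    every genome with its substitution string and candidate flag.
    """
    if str(Seq(reference_cds).translate(table=11)).rstrip("*") != reference_protein:
        raise ValueError("reference CDS does not translate to reference protein")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    truth_rows = []

    for pv in planted:
        sub = pv.substitution
        if sub.position > len(reference_protein):
            raise ValueError(
                f"{pv.genome_id}: position {sub.position} beyond reference length"
            )
        ref_aa = reference_protein[sub.position - 1]
        if ref_aa != sub.wt_aa:
            raise ValueError(
                f"{pv.genome_id}: reference has {ref_aa} at position "
                f"{sub.position}, not {sub.wt_aa}"
            )
        codons = [reference_cds[i : i + 3] for i in range(0, len(reference_cds), 3)]
        idx = sub.position - 1
        var_codons = [c for c in _SYNONYMS[sub.var_aa] if c != codons[idx]]
        codons[idx] = var_codons[0]
        cds = "".join(codons)
        if pv.synonymous_extras:
            cds = _apply_synonymous(cds, pv.synonymous_extras, rng, protect={idx})
        records.append((pv.genome_id, cds))
        truth_rows.append(
            {
                "genome_id": pv.genome_id,
                "substitutions": str(sub),
                "n_synonymous": pv.synonymous_extras,
                "constitutive_candidate": True,
            }
        )

    for i in range(1, n_background + 1):
        gid = f"bg-{i:04d}"
        if rng.random() < duplicate_rate:
            cds, n_syn = reference_cds, 0
        else:
            n_syn = int(rng.integers(1, 3))
            cds = _apply_synonymous(reference_cds, n_syn, rng, protect=set())
        records.append((gid, cds))
        truth_rows.append(
            {
                "genome_id": gid,
                "substitutions": "",
                "n_synonymous": n_syn,
                "constitutive_candidate": False,
            }
        )

    truth = pd.DataFrame(
        truth_rows,
        columns=["genome_id", "substitutions", "n_synonymous", "constitutive_candidate"],
    )
    return AlleleCollection(records=records), truth


# --------------------------------------------------------------------------
# structures
# --------------------------------------------------------------------------

def simulate_structure(
    n_residues: int,
    feature_map: dict[int, str] | None = None,
    displacement: dict[int, np.ndarray] | None = None,
    seed: int = 0,
    conformer_labels: tuple[str, str] = ("reduced", "oxidized"),
    atoms_per_residue: int = 3,
    residue_ids: list[int] | None = None,
) -> tuple[StructureModel, StructureModel, dict[int, str]]:
    """Two toy conformers related by known per-residue rigid displacements.

    Conformer A lays residues along a jittered extended chain; conformer B is
    conformer A with each residue's atoms rigidly shifted by the supplied
    3-vector (default zero). All pairwise distances therefore follow in
    closed form from the generated coordinates.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if residue_ids is None:
        residue_ids = list(range(1, n_residues + 1))
    if len(residue_ids) != n_residues:
        raise ValueError("residue_ids length must equal n_residues")
    if len(set(residue_ids)) != len(residue_ids):
        raise ValueError("duplicate residue ids")
    displacement = displacement or {}
    feature_map = feature_map or {}
    outside = [p for p in feature_map if p not in set(residue_ids)]
    if outside:
        raise ValueError(f"feature positions outside structure: {outside}")
    rng = np.random.default_rng(seed)

    residues_a: dict[int, dict[str, np.ndarray]] = {}
    residues_b: dict[int, dict[str, np.ndarray]] = {}
    atom_names = ["CA", "CB", "CG", "CD", "CE"]
    for res in residue_ids:
        base = np.array([3.8 * res, 0.0, 0.0]) + rng.normal(0, 1.0, 3)
        n_atoms = 1 + int(rng.integers(atoms_per_residue))
        atoms = {}
        for k in range(n_atoms):
            offset = np.zeros(3) if k == 0 else rng.normal(0, 1.2, 3)
            atoms[atom_names[k]] = base + offset
        residues_a[res] = atoms
        shift = np.asarray(displacement.get(res, np.zeros(3)), dtype=float)
        residues_b[res] = {n: xyz + shift for n, xyz in atoms.items()}

    a = StructureModel(conformer=conformer_labels[0], source="synthetic", residues=residues_a)
    b = StructureModel(conformer=conformer_labels[1], source="synthetic", residues=residues_b)
    return a, b, dict(feature_map)


# --------------------------------------------------------------------------
# growth curves
# --------------------------------------------------------------------------

@dataclass
class GrowthCurveSet:
    """Tidy growth-curve table plus the planted lag per dose.

    ``data`` columns: time_h, od, dose_mM, strain, replicate.
    ``true_lag_by_dose``: dose -> planted lag in hours (NaN for "no growth").
    """

    data: pd.DataFrame
    true_lag_by_dose: dict[float, float]

    def to_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def lagged_logistic(
    t: np.ndarray, lag: float, mu_max: float, n0: float, capacity: float
) -> np.ndarray:
    """OD(t): flat at n0 until the lag ends, then logistic growth at rate
    mu_max toward the carrying capacity."""
    t = np.asarray(t, dtype=float)
    dt = np.clip(t - lag, 0.0, None)
    e = np.exp(mu_max * dt)
    return capacity * n0 * e / (capacity + n0 * (e - 1.0))


def simulate_growth_curves(
    mu_max: float,
    lag_by_dose: dict[float, float | None],
    carrying_capacity: float = 1.0,
    sampling_interval: float = 0.25,
    noise_sd: float = 0.005,
    seed: int = 0,
    baseline_od: float = 0.05,
    t_max: float = 24.0,
    n_replicates: int = 3,
    strain: str = "WT",
) -> GrowthCurveSet:
    """Lagged-logistic growth curves per dose; a dose with lag None produces
    a flat no-growth baseline."""
    if sampling_interval <= 0:
        raise ValueError("sampling_interval must be > 0")
    if mu_max <= 0:
        raise ValueError("mu_max must be > 0")
    for dose, lag in lag_by_dose.items():
        if lag is not None and lag < 0:
            raise ValueError(f"dose {dose}: negative lag")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_max + 1e-9, sampling_interval)
    rows = []
    truth: dict[float, float] = {}
    for dose in sorted(lag_by_dose):
        lag = lag_by_dose[dose]
        truth[dose] = np.nan if lag is None else float(lag)
        for rep in range(1, n_replicates + 1):
            if lag is None:
                od = np.full_like(t, baseline_od)
            else:
                od = lagged_logistic(t, lag, mu_max, baseline_od, carrying_capacity)
            if noise_sd > 0:
                od = np.clip(od + rng.normal(0, noise_sd, size=od.shape), 1e-4, None)
            rows.append(
                pd.DataFrame(
                    {
                        "time_h": t,
                        "od": od,
                        "dose_mM": dose,
                        "strain": strain,
                        "replicate": rep,
                    }
                )
            )
    return GrowthCurveSet(
        data=pd.concat(rows, ignore_index=True), true_lag_by_dose=truth
    )
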