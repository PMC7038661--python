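"""Distances between mutated residues and annotated stability features on the
oxidized and reduced OxyR conformers, and rule-based classification of each
mutation's predicted conformational bias.

The distance between two residues is the minimum Euclidean distance over all
heavy-atom pairs by default (switchable to CA-only). Residues unresolved in a
conformer produce flagged missing cells, never fabricated values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .mutations import MutationRecord

FEATURE_CATEGORIES = {
    "stabilizes_reduced",
    "stabilizes_oxidized",
    "transition_state",
    "proline_arrangement",
    "redox_center",
}


@dataclass
class StructureModel:
    """Residue-indexed heavy-atom coordinates for one conformer.

    ``residues`` maps a 1-based residue number to ``{atom_name: xyz}`` with
    coordinates in Angstrom.
    """

    conformer: str
    source: str
    residues: dict[int, dict[str, np.ndarray]]
    chain: str = "A"

    def __post_init__(self) -> None:
        for res, atoms in self.residues.items():
            if not atoms:
                raise ValueError(f"residue {res} has no heavy atoms")
            for name, xyz in atoms.items():
                arr = np.asarray(xyz, dtype=float)
                if arr.shape != (3,) or not np.all(np.isfinite(arr)):
                    raise ValueError(
                        f"residue {res} atom {name}: non-finite or malformed coordinates"
                    )
                atoms[name] = arr

    def coords(self, residue: int, metric: str = "min-heavy") -> np.ndarray:
        atoms = self.residues[residue]
        if metric == "ca":
            if "CA" not in atoms:
                raise KeyError(f"residue {residue} has no CA atom")
            return np.asarray([atoms["CA"]])
        return np.asarray(list(atoms.values()))

    def __contains__(self, residue: int) -> bool:
        return residue in self.residues


@dataclass
class FeatureAnnotation:
    """Categorized stability residues plus named sequence regions.

    ``features``: residue position -> category (fixed vocabulary).
    ``regions``: region name -> inclusive 1-based (start, end).
    """

    features: dict[int, str]
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {c for c in self.features.values()} - FEATURE_CATEGORIES
        if bad:
            raise ValueError(f"unknown feature categories: {sorted(bad)}")
        for name, (lo, hi) in self.regions.items():
            if lo > hi:
                raise ValueError(f"region {name}: start {lo} > end {hi}")


def read_structure(
    path: str | Path,
    conformer: str,
    chain: str | None = None,
    model_index: int = 0,
) -> StructureModel:
    """Read one chain of a PDB file into a StructureModel.

    Hydrogens are dropped; for alternate locations the highest-occupancy
    conformation is retained. Residue numbering is taken from the file.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = PDBParser(QUIET=True).get_structure("s", str(path))
    models = list(structure)
    if not models:
        raise ValueError(f"{path}: no ATOM records")
    model = models[model_index]
    chains = list(model)
    if chain is not None:
        chains = [c for c in chains if c.id == chain]
        if not chains:
            raise ValueError(f"{path}: chain {chain!r} not found")
    pdb_chain = chains[0]

    residues: dict[int, dict[str, np.ndarray]] = {}
    for res in pdb_chain:
        hetflag, resseq, _icode = res.get_id()
        if hetflag.strip():
            continue  # skip HETATM / waters
        atoms: dict[str, np.ndarray] = {}
        for atom in res:
            if atom.is_disordered():
                children = atom.disordered_get_list()
                atom = max(children, key=lambda a: a.get_occupancy() or 0.0)
            element = (atom.element or "").strip().upper()
            if element in ("H", "D"):
                continue
            atoms[atom.get_name()] = np.asarray(atom.get_coord(), dtype=float)
        if atoms:
            residues[int(resseq)] = atoms
    if not residues:
        raise ValueError(f"{path}: no ATOM records")
    return StructureModel(
        conformer=conformer, source=str(path), residues=residues, chain=pdb_chain.id
    )


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel as minimal single-chain ATOM records."""
    lines = []
    serial = 1
    for res in sorted(model.residues):
        for name, xyz in model.residues[res].items():
            elem = name[0]
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} GLY {model.chain}{res:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
                f"          {elem:>2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def residue_min_distance(
    model: StructureModel, res_a: int, res_b: int, metric: str = "min-heavy"
) -> float:
    """Minimum distance (A) over all heavy-atom pairs of two residues."""
    for r in (res_a, res_b):
        if r not in model:
            raise KeyError(f"residue {r} not resolved in {model.conformer} conformer")
    a = model.coords(res_a, metric)
    b = model.coords(res_b, metric)
    return float(cdist(a, b).min())


def proximity_matrix(
    oxidized: StructureModel,
    reduced: StructureModel,
    mutations: list[MutationRecord],
    features: FeatureAnnotation,
    metric: str = "min-heavy",
) -> pd.DataFrame:
    """Long-format distance table: one row per (feature residue, mutation,
    conformer). Unresolved residues yield NaN with ``missing=True``."""
    rows = []
    conformers = [(oxidized.conformer, oxidized), (reduced.conformer, reduced)]
    for mut in mutations:
        if all(mut.position not in m for _, m in conformers):
            warnings.warn(
                f"mutation {mut} unresolved in both conformers", stacklevel=2
            )
        for feat_pos, category in sorted(features.features.items()):
            for label, model in conformers:
                if mut.position in model and feat_pos in model:
                    d = residue_min_distance(model, feat_pos, mut.position, metric)
                    missing = False
                else:
                    d = np.nan
                    missing = True
                rows.append(
                    {
                        "feature_residue": feat_pos,
                        "category": category,
                        "mutation": str(mut),
                        "conformer": label,
                        "distance_A": d,
                        "missing": missing,
                    }
                )
    return pd.DataFrame(rows)


def region_membership(position: int, features: FeatureAnnotation) -> set[str]:
    """Names of annotated regions whose inclusive bounds contain ``position``."""
    if position < 1:
        raise ValueError("positions are 1-based")
    return {
        name
        for name, (lo, hi) in features.regions.items()
        if lo <= position <= hi
    }


#: category of the nearest feature -> predicted conformational bias
_CATEGORY_LABEL = {
    "redox_center": "favors_oxidized",
    "stabilizes_oxidized": "favors_oxidized",
    "transition_state": "favors_oxidized",
    "stabilizes_reduced": "destabilizes_reduced",
    "proline_arrangement": "proline_interface",
}


def classify_mutation(
    mutation: MutationRecord,
    matrix_row: pd.DataFrame,
    features: FeatureAnnotation,
    contact_cutoff: float = 8.0,
) -> tuple[str, list[dict]]:
    """Rule-based impact label for one mutation.

    Precedence: membership in the redox loop (tetramerization of the reduced
    form) beats the broader flexible loop (Cys-199 relaxation), which beats
    the proline arrangement; a mutation in none of the regions is labelled by
    the category of its nearest feature within ``contact_cutoff``, else
    ``ambiguous``. Pure function of (row, regions, cutoff).
    """
    if matrix_row.empty:
        raise ValueError(f"no distance row computed for {mutation}")
    pos = mutation.position
    regions = region_membership(pos, features)
    evidence: list[dict] = []
    if "redox_loop" in regions:
        lo, hi = features.regions["redox_loop"]
        evidence.append({"trigger": "redox_loop", "detail": f"position {pos} in [{lo},{hi}]"})
        return "destabilizes_reduced", evidence
    if "flexible_loop" in regions:
        lo, hi = features.regions["flexible_loop"]
        evidence.append({"trigger": "flexible_loop", "detail": f"position {pos} in [{lo},{hi}]"})
        return "redox_loop_flexibility", evidence
    proline_set = {
        p for p, c in features.features.items() if c == "proline_arrangement"
    }
    if pos in proline_set:
        evidence.append({"trigger": "proline_arrangement", "detail": f"position {pos}"})
        return "proline_interface", evidence

    valid = matrix_row.loc[~matrix_row["missing"]]
    if not valid.empty:
        nearest = valid.iloc[int(np.argmin(valid["distance_A"].to_numpy()))]
        if nearest["distance_A"] <= contact_cutoff:
            evidence.append(
                {
                    "trigger": "nearest_feature",
                    "feature_residue": int(nearest["feature_residue"]),
                    "category": nearest["category"],
                    "conformer": nearest["conformer"],
                    "distance_A": float(nearest["distance_A"]),
                }
            )
            return _CATEGORY_LABEL[nearest["category"]], evidence
    evidence.append({"trigger": "none", "detail": f"no feature within {contact_cutoff} A"})
    return "ambiguous", evidence
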