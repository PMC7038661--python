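"""Gene-by-sample log-expression container with condition/replicate labels.

The matrix is stored genes x samples (log scale, e.g. log-TPM). Every sample
carries a condition id and a replicate id, and one condition is designated the
reference (typically the wild-type strain) against which i-modulon activities
are interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """Log-expression values (genes x samples) plus sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    sample_conditions
        Series mapping sample id -> condition id (same order as columns).
    sample_replicates
        Series mapping sample id -> replicate id.
    reference_condition
        Condition id used as the baseline for centering.
    """

    values: pd.DataFrame
    sample_conditions: pd.Series
    sample_replicates: pd.Series
    reference_condition: str

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.values.shape[1] < 2:
            raise ValueError("need at least 2 samples")
        missing = set(self.values.columns) - set(self.sample_conditions.index)
        if missing:
            raise ValueError(f"samples without condition labels: {sorted(missing)}")
        self.sample_conditions = self.sample_conditions.reindex(self.values.columns)
        self.sample_replicates = self.sample_replicates.reindex(self.values.columns)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_of(self, condition: str) -> list[str]:
        mask = self.sample_conditions == condition
        return list(self.sample_conditions.index[mask])

    # -- on-disk format: expression TSV + sidecar metadata TSV ---------------

    def to_tsv(self, path: str | Path, meta_path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")
        meta = pd.DataFrame(
            {
                "sample_id": self.values.columns,
                "condition": self.sample_conditions.values,
                "replicate": self.sample_replicates.values,
                "is_reference": [
                    c == self.reference_condition for c in self.sample_conditions
                ],
            }
        )
        meta.to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, meta_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col="gene_id")
        meta = pd.read_csv(meta_path, sep="\t", dtype={"sample_id": str})
        meta = meta.set_index("sample_id")
        ref = meta.loc[meta["is_reference"], "condition"]
        if ref.empty:
            raise ValueError("metadata designates no reference condition")
        return cls(
            values=values,
            sample_conditions=meta["condition"],
            sample_replicates=meta["replicate"],
            reference_condition=str(ref.iloc[0]),
        )


def center_to_reference(X: ExpressionMatrix) -> pd.DataFrame:
    """Subtract each gene's mean over reference-condition samples.

    After centering, the reference samples of every gene average to zero, so
    downstream component activities read as deviations from the baseline
    (wild-type) state.
    """
    ref_samples = X.samples_of(X.reference_condition)
    if not ref_samples:
        raise ValueError(
            f"reference condition {X.reference_condition!r} has no samples"
        )
    ref_mean = X.values[ref_samples].mean(axis=1)
    return X.values.sub(ref_mean, axis=0)
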