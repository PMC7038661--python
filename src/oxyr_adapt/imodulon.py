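"""Robust independent component analysis of expression matrices.

ICA decomposes the reference-centered matrix Xc (genes x samples) as
Xc ~ S A: columns of S are gene-weight vectors of independently modulated
gene groups (i-modulons) and rows of A are their condition-dependent
activities. Robustness is assessed by re-running FastICA from multiple random
initializations and clustering components across restarts by absolute weight
correlation; only clusters recurring in a minimum fraction of restarts are
retained. Each retained component is reported as the cluster centroid with a
fixed convention (unit L2 norm, largest-magnitude weight positive) and A is
the least-squares projection of Xc onto S.

Membership of an i-modulon is defined by a robust k-MAD cutoff on the
absolute weights; regulator linkage uses hypergeometric enrichment against
known regulons with Bonferroni correction; condition effects on activities
use Welch's t-test on replicate activities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .expression import ExpressionMatrix, center_to_reference  # noqa: F401  (re-export)


@dataclass
class ICAModel:
    """Robust ICA decomposition: S (genes x components), A (components x
    samples), and the fraction of restarts in which each component recurred."""

    S: pd.DataFrame
    A: pd.DataFrame
    robustness: pd.Series
    flags: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.S.shape[1]


@dataclass
class IModulon:
    component: str
    members: set[str]
    threshold: float
    regulator: str | None = None
    p_value: float | None = None


@dataclass
class RegulonMatch:
    regulator: str | None
    p_value: float
    overlap: int
    all_p_values: dict[str, float]


def _fix_convention(s: np.ndarray) -> np.ndarray:
    """Unit L2 norm; sign such that the largest-magnitude weight is positive."""
    norm = np.linalg.norm(s)
    if norm > 0:
        s = s / norm
    peak = np.argmax(np.abs(s))
    if s[peak] < 0:
        s = -s
    return s


def robust_ica(
    Xc: pd.DataFrame,
    n_components: int,
    n_restarts: int = 10,
    min_recurrence: float = 0.5,
    seed: int = 0,
    cluster_threshold: float = 0.2,
    max_iter: int = 1000,
    tol: float = 1e-6,
) -> ICAModel:
    """FastICA from multiple restarts with recurrence-based component filtering.

    Components from all restarts are clustered on (1 - |Pearson r|) distance
    (average linkage, cut at ``cluster_threshold``); clusters present in at
    least ``min_recurrence`` of restarts survive. If fewer than
    ``n_components`` clusters are robust, the robust subset is returned with a
    flag (not an error).
    """
    genes = Xc.index
    samples = Xc.columns
    n_genes, n_samples = Xc.shape
    if n_components >= min(n_genes, n_samples):
        raise ValueError("n_components must be < min(genes, samples)")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")

    X = Xc.to_numpy(dtype=float)
    norm = np.linalg.norm(X)
    if norm < 1e-12:
        empty_S = pd.DataFrame(index=genes)
        empty_A = pd.DataFrame(columns=samples)
        return ICAModel(S=empty_S, A=empty_A, robustness=pd.Series(dtype=float),
                        flags=["degenerate: input matrix is all-zero"])

    # Noise-free matrices can have exactly-zero sample columns (reference
    # replicates), and FastICA's deterministic sign convention zeroes out a
    # whitening component whenever the first sample's loading is exactly 0.
    # A vanishing seeded jitter breaks those exact ties without measurably
    # perturbing the decomposition.
    jitter_rng = np.random.default_rng(int(seed))
    X_ica = X + jitter_rng.normal(0.0, 1e-9 * norm / np.sqrt(X.size), size=X.shape)

    comps: list[np.ndarray] = []
    restart_of: list[int] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        for r in range(n_restarts):
            ica = FastICA(
                n_components=n_components,
                random_state=int(seed) + r,
                whiten="unit-variance",
                max_iter=max_iter,
                tol=tol,
            )
            sources = ica.fit_transform(X_ica)  # genes x components
            for j in range(sources.shape[1]):
                s = sources[:, j]
                if np.linalg.norm(s) < 1e-12:
                    continue
                comps.append(_fix_convention(s))
                restart_of.append(r)

    M = np.column_stack(comps)  # genes x (restarts * components)
    corr = np.corrcoef(M.T)
    dist = np.clip(1.0 - np.abs(corr), 0.0, None)
    np.fill_diagonal(dist, 0.0)
    if M.shape[1] > 1:
        labels = fcluster(
            linkage(squareform(dist, checks=False), method="average"),
            t=cluster_threshold,
            criterion="distance",
        )
    else:
        labels = np.array([1])

    clusters: list[tuple[float, np.ndarray]] = []
    for lab in np.unique(labels):
        idx = np.where(labels == lab)[0]
        recurrence = len({restart_of[i] for i in idx}) / n_restarts
        if recurrence < min_recurrence:
            continue
        ref = M[:, idx[0]]
        aligned = [
            M[:, i] * (1.0 if np.dot(M[:, i], ref) >= 0 else -1.0) for i in idx
        ]
        centroid = _fix_convention(np.mean(aligned, axis=0))
        clusters.append((recurrence, centroid))

    clusters.sort(key=lambda rc: -rc[0])
    clusters = clusters[:n_components]
    flags = []
    if len(clusters) < n_components:
        flags.append(
            f"only {len(clusters)} of {n_components} components were robust"
        )
    if not clusters:
        return ICAModel(S=pd.DataFrame(index=genes), A=pd.DataFrame(columns=samples),
                        robustness=pd.Series(dtype=float), flags=flags or ["degenerate"])

    names = [f"ic{j + 1}" for j in range(len(clusters))]
    S0 = np.column_stack([c for _, c in clusters])
    # FastICA sources are gene-centered; refine the weight vectors against the
    # un-centered (reference-centered) matrix so S·A reconstructs Xc itself:
    # activities from the centered sources, then weights by regressing Xc on
    # those activities, then final activities by least squares on the result.
    Xcc = X - X.mean(axis=0, keepdims=True)
    A0, *_ = np.linalg.lstsq(S0, Xcc, rcond=None)
    S_ref = X @ np.linalg.pinv(A0)
    S_ref = np.column_stack([_fix_convention(S_ref[:, j]) for j in range(S_ref.shape[1])])
    S = pd.DataFrame(S_ref, index=genes, columns=names)
    A_vals, *_ = np.linalg.lstsq(S_ref, X, rcond=None)
    A = pd.DataFrame(A_vals, index=names, columns=samples)
    robustness = pd.Series([r for r, _ in clusters], index=names)
    return ICAModel(S=S, A=A, robustness=robustness, flags=flags)


def define_membership(weights: pd.Series, k: float = 5.0) -> IModulon:
    """Members are genes whose weight deviates from the median weight by more
    than k robust spreads (MAD x 1.4826) of the weight distribution.

    Component weight vectors have their bulk (non-member background) near the
    median, so the deviation form is equivalent to thresholding |weight| when
    the background sits at zero, but stays correct when the sign/offset
    convention shifts the background.
    """
    w = weights.to_numpy(dtype=float)
    if np.ptp(w) == 0:
        raise ValueError("constant weight vector has no members to define")
    med = np.median(w)
    dev = np.abs(w - med)
    # On noiseless data the MAD collapses to zero while tiny cross-component
    # leakage (a few % of the peak weight) remains; a relative floor keeps the
    # rule meaningful there without affecting noisy weight vectors.
    threshold = max(k * 1.4826 * np.median(dev), 0.1 * dev.max())
    members = set(weights.index[dev > threshold])
    return IModulon(component=str(weights.name), members=members, threshold=threshold)


def match_regulon(
    members: set[str],
    known_regulons: dict[str, set[str]],
    universe_size: int,
) -> RegulonMatch:
    """Hypergeometric enrichment of the member set against each known
    regulon; best hit after Bonferroni correction over regulons tested."""
    if not members:
        return RegulonMatch(regulator=None, p_value=float("nan"), overlap=0,
                            all_p_values={})
    n_tests = len(known_regulons)
    all_p: dict[str, float] = {}
    best: tuple[float, str, int] | None = None
    for reg, genes in known_regulons.items():
        k = len(members & genes)
        p = float(stats.hypergeom.sf(k - 1, universe_size, len(genes), len(members)))
        all_p[reg] = p
        if best is None or p < best[0]:
            best = (p, reg, k)
    p_adj = min(1.0, best[0] * n_tests)
    return RegulonMatch(regulator=best[1], p_value=p_adj, overlap=best[2],
                        all_p_values=all_p)


def activity_summary(
    A: pd.DataFrame, component: str, grouping: pd.Series
) -> pd.DataFrame:
    """Per-condition mean, SD (only with >= 2 replicates) and n of one
    component's activity row."""
    if component not in A.index:
        raise KeyError(f"unknown component {component!r}")
    row = A.loc[component]
    out = []
    for cond, samples in grouping.groupby(grouping):
        vals = row[samples.index].to_numpy(dtype=float)
        out.append(
            {
                "condition": cond,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) >= 2 else np.nan,
                "n": len(vals),
            }
        )
    return pd.DataFrame(out).set_index("condition")


def differential_activity(
    A: pd.DataFrame,
    component: str,
    group1: set[str],
    group2: set[str],
    grouping: pd.Series,
) -> tuple[float, float]:
    """Welch two-sample t-test between two condition groups on one
    component's activities. Returns (mean1 - mean2, two-sided p)."""
    if component not in A.index:
        raise KeyError(f"unknown component {component!r}")
    row = A.loc[component]
    v1 = row[grouping.index[grouping.isin(group1)]].to_numpy(dtype=float)
    v2 = row[grouping.index[grouping.isin(group2)]].to_numpy(dtype=float)
    if len(v1) < 2 or len(v2) < 2:
        raise ValueError(
            f"each group needs >= 2 samples (got {len(v1)} and {len(v2)}); "
            f"descriptive difference: {v1.mean() - v2.mean():.4g}"
        )
    diff = float(v1.mean() - v2.mean())
    pooled = np.concatenate([v1, v2])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0  # all activities identical: no evidence of change
    res = stats.ttest_ind(v1, v2, equal_var=False)
    return diff, float(res.pvalue)
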