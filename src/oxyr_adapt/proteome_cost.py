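"""Reduced proteome-allocation model of the fear-greed trade-off.

Over-expressing a stress-defense gene diverts a share of the finite proteome
budget Phi away from growth-promoting functions. The reduced model captures
the two scaling laws that a full metabolism-and-expression simulation
produces for the OxyR regulon:

1. relative growth rate falls linearly as any single gene's expression
   fold-change f rises:  mu/mu0 = 1 - alpha * phi_ref * (f - 1) / Phi;
2. the cost slope k_i = alpha * phi_ref(i) / Phi grows with the gene's
   reference abundance, so abundant defense genes (ahpC, ahpF, katG) dominate
   the growth cost.

Multi-gene costs compose additively and the rate is floored at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ProteomeCostModel:
    """Linear allocation model: reference growth rate ``mu0`` (1/h), proteome
    budget ``Phi``, per-gene reference abundance ``phi_ref`` (dimensionless
    fractions) and shared cost coefficient ``alpha``."""

    mu0: float
    Phi: float
    phi_ref: dict[str, float]
    alpha: float = 1.0
    cap_at_one: bool = True  # no reallocation gains below reference expression

    def __post_init__(self) -> None:
        if self.mu0 <= 0 or self.Phi <= 0:
            raise ValueError("mu0 and Phi must be positive")
        if any(v < 0 for v in self.phi_ref.values()):
            raise ValueError("reference abundances must be >= 0")
        if sum(self.phi_ref.values()) > 1 + 1e-9:
            raise ValueError("reference abundances sum above 1")


@dataclass
class CostReport:
    per_gene: pd.DataFrame          # gene, fold_change, slope, contribution
    relative_growth_rate: float
    ranking: list[str]              # genes by |contribution|, ties by gene id


def cost_slope(model: ProteomeCostModel, gene: str) -> float:
    """k_i = alpha * phi_ref(i) / Phi (per unit fold change)."""
    if gene not in model.phi_ref:
        raise KeyError(f"unknown gene {gene!r}")
    return model.alpha * model.phi_ref[gene] / model.Phi


def growth_at_expression(model: ProteomeCostModel, gene: str, fold_change: float) -> float:
    """Relative growth rate mu/mu0 at one gene's expression fold-change."""
    if fold_change < 0:
        raise ValueError("fold change must be >= 0")
    k = cost_slope(model, gene)
    mu = 1.0 - k * (fold_change - 1.0)
    if model.cap_at_one:
        mu = min(mu, 1.0)
    return max(mu, 0.0)


def regulon_cost(model: ProteomeCostModel, fold_changes: dict[str, float]) -> CostReport:
    """Additive multi-gene cost with contributions ranked; ties broken by
    gene id."""
    rows = []
    for gene, f in fold_changes.items():
        if f < 0:
            raise ValueError(f"{gene}: fold change must be >= 0")
        k = cost_slope(model, gene)
        rows.append(
            {"gene": gene, "fold_change": f, "slope": k, "contribution": k * (f - 1.0)}
        )
    per_gene = pd.DataFrame(rows, columns=["gene", "fold_change", "slope", "contribution"])
    mu = 1.0 - per_gene["contribution"].sum()
    if model.cap_at_one:
        mu = min(mu, 1.0)
    mu = max(mu, 0.0)
    ranking = list(
        per_gene.assign(absc=per_gene["contribution"].abs())
        .sort_values(["absc", "gene"], ascending=[False, True])["gene"]
    )
    return CostReport(per_gene=per_gene, relative_growth_rate=float(mu), ranking=ranking)


@dataclass
class FitDiagnostics:
    residual_rms: float
    per_gene_ratio: dict[str, float]   # per-gene fitted alpha/Phi
    misfit: bool
    misfit_genes: list[str] = field(default_factory=list)


def fit_cost_model(
    simulation_points: list[tuple[str, float, float]],
    phi_ref: dict[str, float],
    mu0: float = 1.0,
    Phi: float = 1.0,
    misfit_rtol: float = 0.05,
) -> tuple[ProteomeCostModel, FitDiagnostics]:
    """Least-squares recovery of the shared coefficient alpha/Phi.

    ``simulation_points`` are (gene, fold_change, mu/mu0) triples, at least
    two distinct fold changes per gene and at least two genes. Points at the
    zero-growth floor are excluded (the floor is a cap, not data). A misfit
    flag is raised when per-gene slopes imply materially different
    coefficients for genes of equal abundance.
    """
    pts = pd.DataFrame(simulation_points, columns=["gene", "f", "mu_rel"])
    genes = pts["gene"].unique()
    if len(genes) < 2:
        raise ValueError("need points for at least 2 genes")
    for g in genes:
        if pts.loc[pts["gene"] == g, "f"].nunique() < 2:
            raise ValueError(f"gene {g}: need >= 2 distinct fold changes")
        if g not in phi_ref:
            raise KeyError(f"unknown gene {g!r}")
    if pts["f"].nunique() < 2:
        raise ValueError("degenerate design: all fold changes equal")

    fit_pts = pts.loc[pts["mu_rel"] > 0]
    x = fit_pts["gene"].map(phi_ref).to_numpy() * (fit_pts["f"].to_numpy() - 1.0)
    y = 1.0 - fit_pts["mu_rel"].to_numpy()
    denom = float(x @ x)
    if denom == 0:
        raise ValueError("degenerate design: no abundance-weighted variation in f")
    ratio = float(x @ y) / denom  # alpha / Phi
    resid = y - ratio * x
    rms = float(np.sqrt(np.mean(resid**2)))

    per_gene_ratio: dict[str, float] = {}
    for g in genes:
        sub = fit_pts[fit_pts["gene"] == g]
        if phi_ref[g] == 0 or len(sub) < 2:
            continue
        slope = np.polyfit(sub["f"], 1.0 - sub["mu_rel"], 1)[0]
        per_gene_ratio[g] = float(slope / phi_ref[g])
    misfit_genes = []
    if per_gene_ratio and ratio != 0:
        for g, r in per_gene_ratio.items():
            if abs(r - ratio) > misfit_rtol * abs(ratio):
                misfit_genes.append(g)
    diagnostics = FitDiagnostics(
        residual_rms=rms,
        per_gene_ratio=per_gene_ratio,
        misfit=bool(misfit_genes),
        misfit_genes=sorted(misfit_genes),
    )
    model = ProteomeCostModel(mu0=mu0, Phi=Phi, phi_ref=dict(phi_ref),
                              alpha=ratio * Phi)
    return model, diagnostics
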