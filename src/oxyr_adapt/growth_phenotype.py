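"""Lag-phase estimation from microbial growth curves and the relative lag
increase under peroxide doses.

The default "tangent" estimator works on the log-OD curve: the tangent at
the maximum specific growth rate is extended back to the pre-growth baseline
level, and the crossing time is the lag. It is equivariant under time
translation and invariant under multiplicative OD rescaling. Curves that
never rise meaningfully above baseline are flagged "no growth" and carry no
lag value, mirroring the missing-bar semantics of dose-response summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GrowthCurve:
    time: np.ndarray   # hours, strictly increasing
    od: np.ndarray
    dose: float = 0.0
    strain: str = ""
    replicate: int | str = 0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if len(self.time) < 5:
            raise ValueError("need at least 5 time points")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.od < 0):
            raise ValueError("OD must be >= 0")


@dataclass
class LagEstimate:
    lag: float | None
    mu_max: float | None
    max_od: float
    no_growth: bool
    method: str


def estimate_lag(
    curve: GrowthCurve,
    method: str = "tangent",
    baseline_points: int = 3,
    delta: float = 0.02,
    delta_min: float = 0.05,
    window: int = 5,
) -> LagEstimate:
    """Estimate the lag phase of one growth curve.

    tangent: lag is where the steepest log-OD tangent (fitted over a sliding
    ``window`` of points) crosses the baseline log-OD level. threshold: first
    sampled time at which OD exceeds baseline + ``delta``. A curve whose rise
    above baseline stays below ``delta_min`` is a no-growth call.
    """
    t, od = curve.time, curve.od
    baseline = float(np.median(od[:baseline_points]))
    max_od = float(od.max())
    if max_od - baseline < delta_min:
        return LagEstimate(lag=None, mu_max=None, max_od=max_od,
                           no_growth=True, method=method)

    if method == "threshold":
        above = np.nonzero(od > baseline + delta)[0]
        lag = float(t[above[0]])
        return LagEstimate(lag=max(lag, 0.0), mu_max=None, max_od=max_od,
                           no_growth=False, method=method)
    if method != "tangent":
        raise ValueError(f"unknown method {method!r}")

    log_od = np.log(np.clip(od, 1e-6, None))
    base_log = float(np.median(log_od[:baseline_points]))
    best = None  # (slope, intercept)
    for i in range(len(t) - window + 1):
        ts = t[i : i + window]
        ys = log_od[i : i + window]
        if od[i + window - 1] <= baseline + delta:
            continue  # window still at baseline: slope is noise
        slope, intercept = np.polyfit(ts, ys, 1)
        if best is None or slope > best[0]:
            best = (slope, intercept)
    if best is None or best[0] <= 0:
        return LagEstimate(lag=None, mu_max=None, max_od=max_od,
                           no_growth=True, method=method)
    mu_max, intercept = float(best[0]), float(best[1])
    lag = (base_log - intercept) / mu_max
    return LagEstimate(lag=float(lag), mu_max=mu_max, max_od=max_od,
                       no_growth=False, method=method)


def relative_lag_increase(treated: LagEstimate, control: LagEstimate) -> float | None:
    """(lag_treated - lag_control) / lag_control; None when the treated
    culture never grew (the "missing bar")."""
    if control.no_growth:
        raise ValueError("control culture shows no growth; no baseline lag")
    if control.lag is None or control.lag <= 0:
        raise ValueError("control lag must be positive")
    if treated.no_growth:
        return None
    return (treated.lag - control.lag) / control.lag


def dose_response_table(
    data: pd.DataFrame,
    method: str = "tangent",
    **lag_kwargs,
) -> pd.DataFrame:
    """Per strain x dose summary of the relative lag increase.

    ``data`` columns: time_h, od, dose_mM, strain, replicate. Each replicate
    is estimated separately; the relative increase is computed against the
    mean 0-dose lag of the same strain. Strains without a 0-dose control are
    skipped with a warning. Output columns: strain, dose_mM,
    mean_rel_increase, sd_rel_increase, n, no_growth_fraction.
    """
    required = {"time_h", "od", "dose_mM", "strain", "replicate"}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")

    estimates = []
    for (strain, dose, rep), grp in data.groupby(["strain", "dose_mM", "replicate"]):
        grp = grp.sort_values("time_h")
        curve = GrowthCurve(time=grp["time_h"].to_numpy(), od=grp["od"].to_numpy(),
                            dose=float(dose), strain=str(strain), replicate=rep)
        est = estimate_lag(curve, method=method, **lag_kwargs)
        estimates.append({"strain": strain, "dose_mM": float(dose),
                          "replicate": rep, "lag": est.lag,
                          "no_growth": est.no_growth})
    est_df = pd.DataFrame(estimates)

    out = []
    for strain, grp in est_df.groupby("strain"):
        controls = grp[(grp["dose_mM"] == 0.0) & ~grp["no_growth"]]
        if controls.empty:
            warnings.warn(
                f"strain {strain!r}: no growing 0-dose control; skipped",
                stacklevel=2,
            )
            continue
        control_lag = float(controls["lag"].mean())
        for dose, sub in grp.groupby("dose_mM"):
            grew = sub[~sub["no_growth"]]
            rel = (grew["lag"] - control_lag) / control_lag
            out.append(
                {
                    "strain": strain,
                    "dose_mM": float(dose),
                    "mean_rel_increase": float(rel.mean()) if len(rel) else np.nan,
                    "sd_rel_increase": float(rel.std(ddof=1)) if len(rel) >= 2 else np.nan,
                    "n": int(len(sub)),
                    "no_growth_fraction": float(sub["no_growth"].mean()),
                }
            )
    return pd.DataFrame(
        out,
        columns=["strain", "dose_mM", "mean_rel_increase", "sd_rel_increase",
                 "n", "no_growth_fraction"],
    )
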