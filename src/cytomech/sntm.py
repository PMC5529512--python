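"""Spontaneous nanoscale tracer motion (SNTM) rheology.

Trajectories of cytoskeleton-anchored beads are reduced to an ensemble
mean-squared displacement curve MSD(τ) in nm², a power law
MSD(τ) = D*·τ^α is fitted by least squares in log-log space over a lag
window (default 10–300 s), and the fitted exponent classifies the motion
regime: α ≈ 1 is Brownian, α > 1 indicates a super-diffusive, actively
remodeling cytoskeleton.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .piv import TrajectoryEnsemble
from . import stats_report

__all__ = [
    "MSDCurve",
    "PowerLawFit",
    "compute_msd",
    "fit_power_law",
    "classify_motion",
    "group_alpha_summary",
]


@dataclass
class MSDCurve:
    """Ensemble mean-squared displacement vs lag time."""

    lag_s: np.ndarray
    msd_nm2: np.ndarray
    n_pairs: np.ndarray

    def __post_init__(self) -> None:
        self.lag_s = np.asarray(self.lag_s, dtype=float)
        self.msd_nm2 = np.asarray(self.msd_nm2, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if np.any(np.diff(self.lag_s) <= 0):
            raise ValueError("lag_s must be strictly increasing")
        if np.any(self.msd_nm2 < 0):
            raise ValueError("msd_nm2 must be non-negative")


@dataclass(frozen=True)
class PowerLawFit:
    """Least-squares power-law fit MSD(τ) = D*·τ^α."""

    dstar: float  # nm²/s^α
    alpha: float
    fit_window_s: tuple[float, float]
    r_squared: float
    alpha_se: float
    n_lags: int

    def to_dict(self) -> dict:
        return {
            "dstar": self.dstar,
            "alpha": self.alpha,
            "alpha_se": self.alpha_se,
            "window": list(self.fit_window_s),
            "r2": self.r_squared,
            "n_lags": self.n_lags,
        }


def compute_msd(
    trajectories: TrajectoryEnsemble,
    max_lag_s: float | None = None,
    averaging: str = "ensemble_time",
) -> MSDCurve:
    """Ensemble MSD of 2D bead trajectories.

    For each lag τ = m·Δt ≤ ``max_lag_s``, MSD(τ) is the mean of
    |r(t+τ) − r(t)|² over beads — and, in ``ensemble_time`` mode, over
    all overlapping time origins t; ``ensemble_only`` uses only the first
    frame of each track as origin.
    """
    dt = trajectories.frame_interval_s
    if max_lag_s is None:
        max_lag_s = trajectories.frames["t_s"].max()
    if max_lag_s < dt:
        raise ValueError("max_lag_s must be at least one frame interval")
    if averaging not in ("ensemble_time", "ensemble_only"):
        raise ValueError("averaging must be 'ensemble_time' or 'ensemble_only'")

    max_m = int(np.floor(max_lag_s / dt + 1e-9))
    sums = np.zeros(max_m)
    counts = np.zeros(max_m, dtype=int)
    tracks = list(trajectories.iter_tracks())
    lengths = {len(xy) for _, _, xy in tracks}
    if len(lengths) == 1:
        # equal-length ensemble: vectorize the bead loop per lag
        xyz = np.stack([xy for _, _, xy in tracks])  # (beads, frames, 2)
        n = xyz.shape[1]
        for m in range(1, min(max_m, n - 1) + 1):
            d = xyz[:, m:, :] - xyz[:, :-m, :]
            sq = (d**2).sum(axis=2)
            if averaging == "ensemble_time":
                sums[m - 1] = sq.sum()
                counts[m - 1] = sq.size
            else:
                sums[m - 1] = sq[:, 0].sum()
                counts[m - 1] = sq.shape[0]
    else:
        for _, _, xy in tracks:
            n = len(xy)
            for m in range(1, min(max_m, n - 1) + 1):
                d = xy[m:] - xy[:-m]
                sq = (d**2).sum(axis=1)
                if averaging == "ensemble_time":
                    sums[m - 1] += sq.sum()
                    counts[m - 1] += len(sq)
                else:
                    sums[m - 1] += sq[0]
                    counts[m - 1] += 1
    keep = counts > 0
    lags = np.arange(1, max_m + 1)[keep] * dt
    with np.errstate(invalid="ignore"):
        msd = sums[keep] / counts[keep]
    return MSDCurve(lag_s=lags, msd_nm2=msd, n_pairs=counts[keep])


def fit_power_law(msd: MSDCurve, window_s: tuple[float, float] = (10.0, 300.0)) -> PowerLawFit:
    """Fit log(MSD) = log(D*) + α·log(τ) by OLS over lags in (min, max].

    The default window matches the analysis range of 10–300 s. Non-positive
    MSD values inside the window are dropped with a warning; at least three
    surviving lags are required.
    """
    lo, hi = window_s
    in_win = (msd.lag_s > lo) & (msd.lag_s <= hi)
    pos = msd.msd_nm2 > 0
    if np.any(in_win & ~pos):
        warnings.warn("non-positive MSD values in window dropped", stacklevel=2)
    sel = in_win & pos
    if sel.sum() < 3:
        raise ValueError("need at least 3 positive MSD lags inside the fit window")
    x = np.log(msd.lag_s[sel])
    y = np.log(msd.msd_nm2[sel])
    n = len(x)
    xm, ym = x.mean(), y.mean()
    sxx = ((x - xm) ** 2).sum()
    slope = ((x - xm) * (y - ym)).sum() / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * x)
    ss_res = (resid**2).sum()
    ss_tot = ((y - ym) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    se = np.sqrt(ss_res / (n - 2) / sxx) if n > 2 else np.nan
    return PowerLawFit(
        dstar=float(np.exp(intercept)),
        alpha=float(slope),
        fit_window_s=(lo, hi),
        r_squared=float(r2),
        alpha_se=float(se),
        n_lags=int(n),
    )


def classify_motion(fit: PowerLawFit, tolerance: float = 0.05) -> str:
    """Label the regime: 'superdiffusive' (α > 1 + tol, active remodeling),
    'subdiffusive' (α < 1 − tol), else 'diffusive' (Brownian-like)."""
    if fit.alpha > 1.0 + tolerance:
        return "superdiffusive"
    if fit.alpha < 1.0 - tolerance:
        return "subdiffusive"
    return "diffusive"


def group_alpha_summary(fits: dict[str, list[PowerLawFit]]) -> dict:
    """Per-group mean ± SD of α and an unpaired two-sample t comparison.

    ``fits`` maps group label -> list of per-replicate fits (each group
    needs at least 2). With exactly two groups, a pooled-variance unpaired
    t-test on the α values is included.
    """
    summary: dict = {"groups": {}}
    for label, group_fits in fits.items():
        alphas = np.array([f.alpha for f in group_fits], dtype=float)
        if len(alphas) < 2:
            raise ValueError(f"group '{label}' has fewer than 2 fits")
        summary["groups"][label] = {
            "n": int(len(alphas)),
            "alpha_mean": float(alphas.mean()),
            "alpha_sd": float(alphas.std(ddof=1)),
        }
    if len(fits) == 2:
        (la, fa), (lb, fb) = fits.items()
        cmp = stats_report.two_sample_t(
            [f.alpha for f in fa], [f.alpha for f in fb], paired=False
        )
        summary["comparison"] = {
            "test": cmp.test_name,
            "groups": [la, lb],
            "t": cmp.statistic,
            "p_value": cmp.p_value,
        }
    return summary
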