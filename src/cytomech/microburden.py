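"""Alu-qPCR micrometastatic burden quantification.

Human-specific Alu repeats are absent from the mouse genome, so a
Taqman qPCR against a dilution series of known human-cell equivalents
turns Ct values measured in mouse tissues into human (tumor) cell
equivalents. A log-linear standard curve Ct = slope·log10(N) + intercept
is fitted by OLS; amplification efficiency is 10^(−1/slope) − 1. Burden
is summarized as per-tissue fold changes of knockdown over control, with
the median and range across all per-sample folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StandardCurve",
    "BurdenResult",
    "fit_standard_curve",
    "cell_equivalents",
    "fold_change_summary",
]


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of Ct on log10(cell equivalents)."""

    slope: float  # cycles per log10(equivalents); negative
    intercept: float  # cycles at 1 equivalent
    r_squared: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("standard-curve slope must be negative")
        if not 0 < self.efficiency <= 1.1:
            warnings.warn(
                f"amplification efficiency {self.efficiency:.3f} outside (0, 1.1]",
                stacklevel=2,
            )

    @property
    def efficiency(self) -> float:
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass
class BurdenResult:
    """Per-sample cell equivalents and per-tissue fold-change summaries."""

    per_sample: pd.DataFrame  # sample, tissue, group, ct, cell_equivalents, fold
    per_tissue: pd.DataFrame  # tissue, group medians, fold summaries
    median_fold: float
    fold_range: tuple[float, float]
    comparison: dict = field(default_factory=dict)


def fit_standard_curve(known_equivalents, ct) -> StandardCurve:
    """Fit the standard curve from >= 3 dilution points spanning >= 2 log10.

    Replicate Ct values should be averaged per dilution before the fit.
    """
    n_arr = np.asarray(known_equivalents, dtype=float)
    ct_arr = np.asarray(ct, dtype=float)
    if len(n_arr) != len(ct_arr):
        raise ValueError("known_equivalents and ct must have equal lengths")
    if np.any(n_arr <= 0):
        raise ValueError("cell equivalents must be positive")
    log_n = np.log10(n_arr)
    if len(np.unique(log_n)) < 3:
        raise ValueError("need >= 3 distinct dilution points")
    if log_n.max() - log_n.min() < 2.0:
        raise ValueError("dilution series must span >= 2 log10")
    xm, ym = log_n.mean(), ct_arr.mean()
    sxx = ((log_n - xm) ** 2).sum()
    slope = ((log_n - xm) * (ct_arr - ym)).sum() / sxx
    intercept = ym - slope * xm
    resid = ct_arr - (intercept + slope * log_n)
    ss_tot = ((ct_arr - ym) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else 1.0
    return StandardCurve(slope=float(slope), intercept=float(intercept), r_squared=float(r2))


def cell_equivalents(
    ct,
    curve: StandardCurve,
    nondetect_floor: float | None = None,
) -> np.ndarray:
    """Invert the standard curve: N = 10^((Ct − intercept)/slope).

    Non-detects (NaN Ct) map to ``nondetect_floor`` cell equivalents
    (callers typically pass 0.5x the lowest standard); NaN if no floor is
    given.
    """
    ct_arr = np.atleast_1d(np.asarray(ct, dtype=float))
    out = np.full(ct_arr.shape, np.nan)
    finite = np.isfinite(ct_arr)
    out[finite] = 10.0 ** ((ct_arr[finite] - curve.intercept) / curve.slope)
    if nondetect_floor is not None:
        out[~finite] = nondetect_floor
    return out if np.ndim(ct) else float(out[0])


def burden_from_table(
    table: pd.DataFrame,
    nondetect_floor_factor: float = 0.5,
) -> tuple[StandardCurve, pd.DataFrame]:
    """Fit the curve from a tidy Ct table's standards and quantify unknowns.

    The table needs columns ``sample, tissue, group, ct, is_standard,
    known_equivalents``; replicate Cts (standard and unknown alike) are
    averaged per sample before use. Returns the curve and the per-sample
    unknown table with a ``cell_equivalents`` column.
    """
    std = table[table["is_standard"].astype(bool)]
    if std.empty:
        raise ValueError("table contains no standards")
    per_dilution = std.groupby("known_equivalents")["ct"].mean()
    curve = fit_standard_curve(per_dilution.index.to_numpy(), per_dilution.to_numpy())
    floor = nondetect_floor_factor * float(std["known_equivalents"].min())
    unknown_rows = table[~table["is_standard"].astype(bool)]
    agg = {"tissue": "first", "group": "first", "ct": "mean"}
    if "true_equivalents" in unknown_rows.columns:
        agg["true_equivalents"] = "first"
    unknowns = unknown_rows.groupby("sample", sort=False).agg(agg).reset_index()
    unknowns["cell_equivalents"] = cell_equivalents(
        unknowns["ct"].to_numpy(), curve, nondetect_floor=floor
    )
    return curve, unknowns


def fold_change_summary(
    burden: pd.DataFrame,
    control_group: str,
    case_group: str,
    pairing: str = "per_tissue_median",
) -> BurdenResult:
    """Summarize per-tissue fold changes of case over control burden.

    ``pairing='per_tissue_median'`` (default): each case sample's
    equivalents divided by the median of control equivalents in the same
    tissue; the overall median and (min, max) range are taken over all
    per-sample folds across tissues. ``pairing='ratio_of_medians'``
    reports one fold per tissue (case median / control median) instead.
    Tissues whose control median is zero are skipped with a warning. The
    group comparison (Mann–Whitney on equivalents) is attached.
    """
    from . import stats_report

    required = {"tissue", "group", "cell_equivalents"}
    if not required.issubset(burden.columns):
        raise ValueError(f"burden table needs columns {sorted(required)}")
    if pairing not in ("per_tissue_median", "ratio_of_medians"):
        raise ValueError("pairing must be 'per_tissue_median' or 'ratio_of_medians'")

    per_sample = burden.copy()
    per_sample["fold"] = np.nan
    folds = []
    tissue_rows = []
    for tissue, grp in burden.groupby("tissue"):
        ctrl = grp.loc[grp["group"] == control_group, "cell_equivalents"].to_numpy()
        case = grp.loc[grp["group"] == case_group, "cell_equivalents"].to_numpy()
        if len(ctrl) == 0 or len(case) == 0:
            continue
        ctrl_med = float(np.median(ctrl))
        case_med = float(np.median(case))
        if ctrl_med == 0:
            warnings.warn(f"tissue '{tissue}': control median is 0, skipped", stacklevel=2)
            continue
        if pairing == "per_tissue_median":
            f = case / ctrl_med
            sel = (per_sample["tissue"] == tissue) & (per_sample["group"] == case_group)
            per_sample.loc[sel, "fold"] = f
            folds.extend(f.tolist())
            tissue_fold = float(np.median(f))
        else:
            tissue_fold = case_med / ctrl_med
            folds.append(tissue_fold)
        tissue_rows.append(
            {
                "tissue": tissue,
                "control_median": ctrl_med,
                "case_median": case_med,
                "fold": tissue_fold,
                "n_control": len(ctrl),
                "n_case": len(case),
            }
        )
    if not folds:
        raise ValueError("no tissue had both groups with a nonzero control median")
    folds_arr = np.asarray(folds, dtype=float)

    ctrl_all = burden.loc[burden["group"] == control_group, "cell_equivalents"].to_numpy()
    case_all = burden.loc[burden["group"] == case_group, "cell_equivalents"].to_numpy()
    cmp = stats_report.mann_whitney(case_all, ctrl_all)
    return BurdenResult(
        per_sample=per_sample,
        per_tissue=pd.DataFrame(tissue_rows),
        median_fold=float(np.median(folds_arr)),
        fold_range=(float(folds_arr.min()), float(folds_arr.max())),
        comparison={"test": cmp.test_name, "U": cmp.statistic, "p_value": cmp.p_value},
    )
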