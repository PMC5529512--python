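"""Tissue and cell image quantification.

Co-localization coefficients (Manders M1/M2, Pearson above Costes
thresholds), area-normalized proximity-ligation (PLA) spot density,
positive-cell fractions (e.g. Ki67), wound-closure time series, H-score
aggregation of pathologist intensity bins, and densitometric F/G-actin
ratios from biochemical fractionation blots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .piv import detect_spots
from .synthgen import ChannelPair

__all__ = [
    "ChannelPair",
    "ColocResult",
    "SpotDensityResult",
    "HScoreRecord",
    "WoundSeries",
    "DensitometryRecord",
    "coloc_coefficient",
    "spot_density",
    "positive_fraction",
    "wound_closure",
    "h_score",
    "f_over_g_ratio",
]


@dataclass(frozen=True)
class ColocResult:
    coefficient: float
    method: str
    threshold_a: float
    threshold_b: float

    def __post_init__(self) -> None:
        if self.method.startswith("manders") and not 0 <= self.coefficient <= 1:
            raise ValueError("Manders coefficients must lie in [0, 1]")


@dataclass(frozen=True)
class SpotDensityResult:
    n_spots: int
    roi_area_mm2: float
    density_per_mm2: float


@dataclass(frozen=True)
class HScoreRecord:
    """H-score from percentages of cells at staining intensity 0–3+.

    hscore = 1·pct1 + 2·pct2 + 3·pct3, range 0–300; scored separately per
    compartment (membranous vs cytoplasmic).
    """

    pct_level0: float
    pct_level1: float
    pct_level2: float
    pct_level3: float
    compartment: str = "membranous"

    def __post_init__(self) -> None:
        total = self.pct_level0 + self.pct_level1 + self.pct_level2 + self.pct_level3
        if abs(total - 100.0) > 0.01:
            raise ValueError(f"percentages must sum to 100 +/- 0.01 (got {total})")
        if any(p < 0 for p in (self.pct_level0, self.pct_level1, self.pct_level2, self.pct_level3)):
            raise ValueError("percentages must be non-negative")

    @property
    def hscore(self) -> float:
        return 1.0 * self.pct_level1 + 2.0 * self.pct_level2 + 3.0 * self.pct_level3


@dataclass
class WoundSeries:
    """Wound closure over time, as a fraction of the initial wound area."""

    times_h: np.ndarray
    area_fraction: np.ndarray

    @property
    def closure(self) -> np.ndarray:
        return 1.0 - self.area_fraction


@dataclass(frozen=True)
class DensitometryRecord:
    """Band intensities from F/G-actin fractionation (PEL = F pool,
    SUP = G pool, TCL = total cell lysate)."""

    pel: float
    sup: float
    tcl: float | None = None

    def __post_init__(self) -> None:
        if self.pel < 0 or self.sup < 0 or (self.tcl is not None and self.tcl < 0):
            raise ValueError("band intensities must be non-negative")


def _costes_thresholds(a, b):
    """Costes automatic joint thresholds.

    Walk the threshold on channel A downward (B tied through the
    orthogonal regression b = slope·a + icept) until the Pearson
    correlation of the below-threshold pixels drops to <= 0.
    """
    af, bf = a.ravel(), b.ravel()
    ca, cb = af - af.mean(), bf - bf.mean()
    # orthogonal (Deming) regression slope via principal axis
    cov = (ca * cb).mean()
    va, vb = (ca**2).mean(), (cb**2).mean()
    slope = (vb - va + np.sqrt((vb - va) ** 2 + 4 * cov**2)) / (2 * cov) if cov != 0 else 1.0
    icept = bf.mean() - slope * af.mean()
    for ta in np.linspace(af.max(), af.min(), 100):
        tb = slope * ta + icept
        below = (af < ta) & (bf < tb)
        if below.sum() < 2:
            continue
        x, y = af[below], bf[below]
        if x.std() == 0 or y.std() == 0:
            r = 0.0
        else:
            r = np.corrcoef(x, y)[0, 1]
        if r <= 0:
            return float(ta), float(tb)
    return float(af.min()), float(slope * af.min() + icept)


def coloc_coefficient(
    pair: ChannelPair,
    method: str = "manders_m1",
    threshold_strategy: str = "otsu",
    fixed_thresholds: tuple[float, float] | None = None,
    smooth_sigma_px: float = 0.0,
    partner_dilation_px: int = 0,
) -> ColocResult:
    """Co-localization coefficient of two channels within the ROI.

    - ``manders_m1``: Σ A over above-threshold A pixels where B > thr_B,
      divided by Σ A over above-threshold A pixels (the thresholded
      Manders coefficient reported by Zeiss/Fiji colocalization tools;
      with thresholds (0, 0) it reduces to the classic Σ A[B>0] / Σ A)
    - ``manders_m2``: the symmetric quantity with roles of A and B swapped
    - ``pearson_costes``: Pearson correlation over pixels above the Costes
      joint thresholds, clipped at 0 for reporting

    Thresholds come from per-channel Otsu (default), a fixed pair, or the
    Costes procedure (for ``pearson_costes``). The A-channel threshold in
    the Manders denominator is what lets the coefficient ignore camera
    background and recover a ground-truth spot overlap fraction.

    ``smooth_sigma_px`` > 0 applies a Gaussian matched filter to both
    channels before thresholding and summation — for diffraction-limited
    spot images, set it to the spot radius to suppress shot noise that
    would otherwise jitter the threshold masks. ``partner_dilation_px``
    grows the partner channel's positive mask by that many pixels before
    the Manders overlap is taken; 1 px compensates the boundary pixels
    that independent noise pushes just below threshold in one channel
    while the other stays above (without it the coefficient is biased
    low by a few percent at high overlap).
    """
    roi = pair.roi_mask
    if not roi.any():
        raise ValueError("roi_mask is empty")
    chan_a = np.asarray(pair.channel_a, dtype=float)
    chan_b = np.asarray(pair.channel_b, dtype=float)
    if smooth_sigma_px > 0:
        chan_a = ndimage.gaussian_filter(chan_a, smooth_sigma_px)
        chan_b = ndimage.gaussian_filter(chan_b, smooth_sigma_px)
    a = chan_a[roi]
    b = chan_b[roi]
    if a.max() == 0 or b.max() == 0:
        raise ValueError("a channel is all zero")

    if method == "pearson_costes":
        ta, tb = _costes_thresholds(a, b)
        sel = (a > ta) | (b > tb)
        if sel.sum() < 2 or a[sel].std() == 0 or b[sel].std() == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(a[sel], b[sel])[0, 1])
        return ColocResult(max(0.0, r), method, ta, tb)

    if threshold_strategy == "otsu":
        ta = float(threshold_otsu(a)) if a.min() != a.max() else 0.0
        tb = float(threshold_otsu(b)) if b.min() != b.max() else 0.0
    elif threshold_strategy == "fixed":
        if fixed_thresholds is None:
            raise ValueError("fixed strategy needs fixed_thresholds=(thr_a, thr_b)")
        ta, tb = fixed_thresholds
    else:
        raise ValueError("threshold_strategy must be 'otsu' or 'fixed'")

    def _positive(channel_2d, thr):
        pos = channel_2d > thr
        if partner_dilation_px > 0:
            pos = ndimage.binary_dilation(pos, iterations=partner_dilation_px)
        return pos[roi]

    if method == "manders_m1":
        fg = a > ta
        if not fg.any():
            raise ValueError("no channel-A pixels above threshold")
        coef = float(a[fg & _positive(chan_b, tb)].sum() / a[fg].sum())
    elif method == "manders_m2":
        fg = b > tb
        if not fg.any():
            raise ValueError("no channel-B pixels above threshold")
        coef = float(b[fg & _positive(chan_a, ta)].sum() / b[fg].sum())
    else:
        raise ValueError(f"unknown method '{method}'")
    return ColocResult(coef, method, ta, tb)


def spot_density(
    image: np.ndarray,
    roi_mask: np.ndarray,
    pixel_size_um: float,
    detect_sigma_px: float = 2.0,
    min_intensity: float | None = None,
) -> SpotDensityResult:
    """Count discrete spots (PLA signals) inside the ROI, per mm².

    Spots are Laplacian-of-Gaussian maxima above ``min_intensity``
    (default: 5x the robust background MAD of the LoG response).
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if not roi_mask.any():
        raise ValueError("roi_mask is empty")
    centers = detect_spots(np.asarray(image, dtype=float), detect_sigma_px, min_intensity)
    n = 0
    for y, x in centers:
        yi, xi = int(round(y)), int(round(x))
        if 0 <= yi < roi_mask.shape[0] and 0 <= xi < roi_mask.shape[1] and roi_mask[yi, xi]:
            n += 1
    area_mm2 = float(roi_mask.sum()) * (pixel_size_um**2) / 1e6
    return SpotDensityResult(n_spots=n, roi_area_mm2=area_mm2, density_per_mm2=n / area_mm2)


def positive_fraction(label_image: np.ndarray, marker_intensity: np.ndarray, threshold: float) -> float:
    """Percentage of labeled cells whose mean marker intensity exceeds the
    threshold (e.g. percent Ki67-positive nuclei)."""
    labels = np.asarray(label_image)
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if len(ids) == 0:
        raise ValueError("label image contains no cells")
    means = ndimage.mean(np.asarray(marker_intensity, dtype=float), labels=labels, index=ids)
    return float(100.0 * np.count_nonzero(np.asarray(means) > threshold) / len(ids))


def wound_closure(mask_series: np.ndarray, times_h: np.ndarray | None = None) -> WoundSeries:
    """Closure fraction 1 − area(t)/area(0) from wound masks over time."""
    masks = np.asarray(mask_series, dtype=bool)
    if masks.ndim != 3:
        raise ValueError("mask_series must be (time, rows, cols)")
    areas = masks.reshape(masks.shape[0], -1).sum(axis=1).astype(float)
    if areas[0] == 0:
        raise ValueError("initial wound mask is empty")
    frac = np.clip(areas / areas[0], 0.0, 1.0)
    if times_h is None:
        times_h = np.arange(masks.shape[0], dtype=float)
    return WoundSeries(times_h=np.asarray(times_h, dtype=float), area_fraction=frac)


def h_score(
    pct_level0: float,
    pct_level1: float,
    pct_level2: float,
    pct_level3: float,
    compartment: str = "membranous",
) -> HScoreRecord:
    """Build a validated H-score record from intensity-bin percentages."""
    return HScoreRecord(pct_level0, pct_level1, pct_level2, pct_level3, compartment)


def f_over_g_ratio(rec: DensitometryRecord, tcl_normalize: bool = False) -> float:
    """F/G-actin ratio = PEL/SUP band intensity.

    ``tcl_normalize`` divides both bands by the total-lysate band first —
    an algebraic no-op on the ratio, kept for lane-loading bookkeeping.
    """
    if rec.sup == 0:
        raise ValueError("SUP band intensity is zero; ratio undefined")
    pel, sup = rec.pel, rec.sup
    if tcl_normalize:
        if rec.tcl is None or rec.tcl == 0:
            raise ValueError("tcl_normalize requires a positive TCL band")
        pel, sup = pel / rec.tcl, sup / rec.tcl
    return pel / sup
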