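"""Particle image velocimetry and single-particle tracking.

Substrate displacement fields are estimated from reference/deformed bead
image pairs by windowed normalized cross-correlation with subpixel peak
refinement; cytoskeleton-anchored tracer beads are linked over time into
trajectories for downstream mean-squared-displacement analysis.

Coordinate convention: pixel centers at integer coordinates, origin at
image top-left, x = column, y = row. Displacements are in the same frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass
class DisplacementField:
    """Regular grid of 2D surface displacement vectors.

    Attributes
    ----------
    grid_x, grid_y : 2D arrays, window-center coordinates in µm.
    u_x, u_y : 2D arrays, displacements in µm.
    valid : 2D boolean array, False where the correlation peak failed QC.
    pixel_size : µm per pixel of the source images.
    """

    grid_x: np.ndarray
    grid_y: np.ndarray
    u_x: np.ndarray
    u_y: np.ndarray
    valid: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        shapes = {np.shape(a) for a in (self.grid_x, self.grid_y, self.u_x, self.u_y, self.valid)}
        if len(shapes) != 1:
            raise ValueError("all DisplacementField arrays must share one shape")
        self.grid_x = np.asarray(self.grid_x, dtype=float)
        self.grid_y = np.asarray(self.grid_y, dtype=float)
        self.u_x = np.asarray(self.u_x, dtype=float)
        self.u_y = np.asarray(self.u_y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (np.all(np.isfinite(self.u_x[self.valid])) and np.all(np.isfinite(self.u_y[self.valid]))):
            raise ValueError("displacements must be finite wherever valid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.u_x.shape

    @property
    def spacing(self) -> float:
        """Grid spacing in µm (grid must be regular)."""
        if self.shape[1] > 1:
            dx = np.diff(self.grid_x[0])
        else:
            dx = np.diff(self.grid_y[:, 0])
        if not np.allclose(dx, dx[0], rtol=1e-8, atol=1e-12) or dx[0] <= 0:
            raise ValueError("grid is not regular and monotone")
        return float(dx[0])

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u_x, self.u_y)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "grid_x_um": self.grid_x.ravel(),
                "grid_y_um": self.grid_y.ravel(),
                "ux_um": self.u_x.ravel(),
                "uy_um": self.u_y.ravel(),
                "valid": self.valid.ravel().astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, pixel_size: float = 1.0) -> "DisplacementField":
        df = pd.read_csv(path)
        xs = np.unique(df["grid_x_um"])
        ys = np.unique(df["grid_y_um"])
        shape = (len(ys), len(xs))
        order = np.lexsort((df["grid_x_um"], df["grid_y_um"]))
        d = df.iloc[order]
        return cls(
            grid_x=d["grid_x_um"].to_numpy().reshape(shape),
            grid_y=d["grid_y_um"].to_numpy().reshape(shape),
            u_x=d["ux_um"].to_numpy().reshape(shape),
            u_y=d["uy_um"].to_numpy().reshape(shape),
            valid=d["valid"].to_numpy().astype(bool).reshape(shape),
            pixel_size=pixel_size,
        )


def regular_grid(shape: tuple[int, int], spacing: float) -> tuple[np.ndarray, np.ndarray]:
    """Window/pixel-center coordinate grids (x, y) in µm for a (rows, cols) shape."""
    rows, cols = shape
    y, x = np.mgrid[0:rows, 0:cols]
    return x * spacing, y * spacing


@dataclass
class TrajectoryEnsemble:
    """Ensemble of bead trajectories in nm, uniformly sampled in time.

    ``frames`` is a tidy table with columns ``bead_id, t_s, x_nm, y_nm``;
    each bead's times are strictly increasing with spacing
    ``frame_interval_s`` and every track has at least two frames.
    """

    frames: pd.DataFrame
    frame_interval_s: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"bead_id", "t_s", "x_nm", "y_nm"}
        if not required.issubset(self.frames.columns):
            raise ValueError(f"trajectory table needs columns {sorted(required)}")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        for bead, grp in self.frames.groupby("bead_id"):
            t = grp["t_s"].to_numpy()
            if len(t) < 2:
                raise ValueError(f"bead {bead} has fewer than 2 frames")
            dt = np.diff(t)
            if np.any(dt <= 0) or not np.allclose(dt, self.frame_interval_s, rtol=1e-6):
                raise ValueError(f"bead {bead}: times not uniform at frame_interval_s")

    @property
    def n_beads(self) -> int:
        return self.frames["bead_id"].nunique()

    def iter_tracks(self):
        """Yield ``(bead_id, t_s array, (n, 2) xy array in nm)`` per bead."""
        for bead, grp in self.frames.groupby("bead_id", sort=True):
            g = grp.sort_values("t_s")
            yield bead, g["t_s"].to_numpy(), g[["x_nm", "y_nm"]].to_numpy()

    def to_csv(self, path) -> None:
        self.frames.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame_interval_s: float | None = None) -> "TrajectoryEnsemble":
        df = pd.read_csv(path)
        if frame_interval_s is None:
            t = np.sort(df[df["bead_id"] == df["bead_id"].iloc[0]]["t_s"].to_numpy())
            frame_interval_s = float(np.median(np.diff(t)))
        return cls(frames=df, frame_interval_s=frame_interval_s)


# --------------------------------------------------------------------------
# displacement estimation
# --------------------------------------------------------------------------

def _subpixel_offset(c: np.ndarray, peak: tuple[int, int]) -> tuple[float, float]:
    """Three-point Gaussian peak interpolation per axis (parabolic fallback)."""
    out = []
    for axis in (0, 1):
        idx = list(peak)
        vals = []
        for d in (-1, 0, 1):
            idx[axis] = peak[axis] + d
            if 0 <= idx[axis] < c.shape[axis]:
                vals.append(c[tuple(idx)])
            else:
                vals.append(np.nan)
        cm, c0, cp = vals
        if np.isnan(cm) or np.isnan(cp):
            out.append(0.0)
            continue
        if cm > 0 and c0 > 0 and cp > 0:
            num = np.log(cm) - np.log(cp)
            den = 2.0 * (np.log(cm) + np.log(cp) - 2.0 * np.log(c0))
        else:  # parabolic: any non-positive neighbor
            num = cm - cp
            den = 2.0 * (cm + cp - 2.0 * c0)
        out.append(float(num / den) if den != 0 else 0.0)
    return out[0], out[1]


def estimate_displacement(
    reference: np.ndarray,
    deformed: np.ndarray,
    window_px: int = 32,
    overlap_fraction: float = 0.5,
    pixel_size: float = 1.0,
    search_px: int | None = None,
    peak_ratio_min: float = 1.2,
) -> DisplacementField:
    """Estimate the displacement field between a bead image pair.

    Each interrogation window contributes one vector: the reference
    window is matched against a search region of the deformed image by
    normalized cross-correlation (Fourier-based template matching, which
    avoids the periodic wrap-around bias of cyclic window correlation),
    the integer peak is refined to subpixel precision by a three-point
    Gaussian fit per axis, and vectors whose primary peak is not at least
    ``peak_ratio_min`` times the second peak are marked invalid and
    replaced by the median of their valid neighbors.

    The estimate is symmetrized: the deformed window is also matched back
    into the reference image and the two half-estimates averaged, which
    cancels the odd-order subpixel bias that neighboring particle images
    induce in a single correlation pass.

    Parameters
    ----------
    reference, deformed : 2D arrays of equal shape.
    window_px : interrogation window size, ≥ 16.
    overlap_fraction : fractional window overlap in [0, 1).
    pixel_size : µm per pixel; output coordinates and vectors are in µm.
    search_px : search radius around zero displacement (default
        ``window_px // 4``, the largest displacement reliably measurable).
    """
    from skimage.feature import match_template

    reference = np.asarray(reference, dtype=float)
    deformed = np.asarray(deformed, dtype=float)
    if reference.shape != deformed.shape:
        raise ValueError("images must share a shape")
    if window_px < 16:
        raise ValueError("window_px must be >= 16")
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    if window_px > min(reference.shape):
        raise ValueError("window larger than image")
    if search_px is None:
        search_px = window_px // 4

    step = max(1, int(round(window_px * (1 - overlap_fraction))))
    # inset the window grid by the search radius so every window sees the
    # full symmetric search range (border windows cannot measure shifts
    # that would carry them past the image edge)
    inset = min(search_px, (min(reference.shape) - window_px) // 2)
    rows = range(inset, reference.shape[0] - window_px - inset + 1, step)
    cols = range(inset, reference.shape[1] - window_px - inset + 1, step)
    nr, nc = len(rows), len(cols)
    ux = np.zeros((nr, nc))
    uy = np.zeros((nr, nc))
    valid = np.ones((nr, nc), dtype=bool)
    gx = np.zeros((nr, nc))
    gy = np.zeros((nr, nc))

    def match_one(template_img, search_img, r0, c0):
        """One-way window match; returns (dx, dy) in px or None."""
        a = template_img[r0 : r0 + window_px, c0 : c0 + window_px]
        if a.std() == 0:
            return None
        sr0 = max(0, r0 - search_px)
        sc0 = max(0, c0 - search_px)
        sr1 = min(search_img.shape[0], r0 + window_px + search_px)
        sc1 = min(search_img.shape[1], c0 + window_px + search_px)
        search = search_img[sr0:sr1, sc0:sc1]
        if search.std() == 0:
            return None
        c = match_template(search, a)
        peak = np.unravel_index(np.argmax(c), c.shape)
        # second peak outside a 5x5 exclusion zone around the primary
        masked = c.copy()
        masked[
            max(0, peak[0] - 2) : peak[0] + 3,
            max(0, peak[1] - 2) : peak[1] + 3,
        ] = -np.inf
        second = masked.max() if np.isfinite(masked).any() else -np.inf
        if second > 0 and c[peak] / second < peak_ratio_min:
            return None
        sy, sx = _subpixel_offset(c, peak)
        return (peak[1] + sx - (c0 - sc0), peak[0] + sy - (r0 - sr0))

    for i, r0 in enumerate(rows):
        for j, c0 in enumerate(cols):
            gx[i, j] = (c0 + (window_px - 1) / 2.0) * pixel_size
            gy[i, j] = (r0 + (window_px - 1) / 2.0) * pixel_size
            fwd = match_one(reference, deformed, r0, c0)
            bwd = match_one(deformed, reference, r0, c0)
            if fwd is None and bwd is None:
                valid[i, j] = False
                continue
            if fwd is None:
                dx, dy = -bwd[0], -bwd[1]
            elif bwd is None:
                dx, dy = fwd
            else:
                dx = (fwd[0] - bwd[0]) / 2.0
                dy = (fwd[1] - bwd[1]) / 2.0
            ux[i, j] = dx * pixel_size
            uy[i, j] = dy * pixel_size

    ux, uy = _fill_invalid(ux, uy, valid)
    return DisplacementField(grid_x=gx, grid_y=gy, u_x=ux, u_y=uy, valid=valid, pixel_size=pixel_size)


def _fill_invalid(ux: np.ndarray, uy: np.ndarray, valid: np.ndarray):
    """Replace invalid vectors by the median of valid 3x3 neighbors."""
    if valid.all():
        return ux, uy
    out_x, out_y = ux.copy(), uy.copy()
    bad = np.argwhere(~valid)
    for r, c in bad:
        r0, r1 = max(0, r - 1), min(valid.shape[0], r + 2)
        c0, c1 = max(0, c - 1), min(valid.shape[1], c + 2)
        sel = valid[r0:r1, c0:c1]
        if sel.any():
            out_x[r, c] = np.median(ux[r0:r1, c0:c1][sel])
            out_y[r, c] = np.median(uy[r0:r1, c0:c1][sel])
        else:
            out_x[r, c] = 0.0
            out_y[r, c] = 0.0
    return out_x, out_y


# --------------------------------------------------------------------------
# bead tracking
# --------------------------------------------------------------------------

def detect_spots(
    image: np.ndarray,
    detect_sigma_px: float = 2.0,
    min_intensity: float | None = None,
) -> np.ndarray:
    """Detect bright spots as Laplacian-of-Gaussian maxima.

    Returns an (n, 2) array of (y, x) subpixel centers from
    intensity-weighted centroid refinement. ``min_intensity`` is a
    threshold on the scale-normalized LoG response; by default it is
    5x the robust (MAD-based) spread of the response, which keeps the
    expected number of false noise maxima below ~0.1 per megapixel.
    """
    image = np.asarray(image, dtype=float)
    resp = -(detect_sigma_px**2) * ndimage.gaussian_laplace(image, detect_sigma_px)
    if min_intensity is None:
        med = np.median(resp)
        mad = np.median(np.abs(resp - med)) * 1.4826
        min_intensity = med + 5.0 * mad if mad > 0 else resp.max() * 0.5
    footprint = np.ones((3, 3), dtype=bool)
    local_max = resp == ndimage.maximum_filter(resp, footprint=footprint)
    candidates = local_max & (resp > min_intensity)
    # the reflected boundary of the LoG filter can fabricate edge maxima
    border = int(np.ceil(2 * detect_sigma_px))
    if border > 0:
        candidates[:border, :] = candidates[-border:, :] = False
        candidates[:, :border] = candidates[:, -border:] = False
    peaks = np.argwhere(candidates)
    if len(peaks) == 0:
        return np.empty((0, 2))
    # non-maximum suppression: response plateaus and saddle shoulders can
    # flag 2+ maxima per spot; keep the strongest within ~2 sigma
    order = np.argsort(resp[peaks[:, 0], peaks[:, 1]])[::-1]
    min_d2 = (2.0 * detect_sigma_px) ** 2
    kept: list[np.ndarray] = []
    for idx in order:
        p = peaks[idx]
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_d2 for q in kept):
            kept.append(p)
    peaks = np.asarray(kept)
    # intensity-weighted centroid in a window around each LoG maximum
    half = max(2, int(round(2 * detect_sigma_px)))
    centers = []
    for y, x in peaks:
        y0, y1 = max(0, y - half), min(image.shape[0], y + half + 1)
        x0, x1 = max(0, x - half), min(image.shape[1], x + half + 1)
        patch = image[y0:y1, x0:x1] - image[y0:y1, x0:x1].min()
        tot = patch.sum()
        if tot == 0:
            centers.append((float(y), float(x)))
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        centers.append(((yy * patch).sum() / tot, (xx * patch).sum() / tot))
    return np.asarray(centers)


def track_beads(
    stack: np.ndarray,
    detect_sigma_px: float = 2.0,
    max_step_px: float = 5.0,
    pixel_size_um: float = 1.0,
    frame_interval_s: float = 1.0,
    min_intensity: float | None = None,
) -> TrajectoryEnsemble:
    """Link per-frame spot detections into bead trajectories.

    Frames are linked by greedy nearest-neighbor assignment within
    ``max_step_px``; tracks are truncated at their first missed frame.
    Positions are reported in nm using ``pixel_size_um``.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must be (frames, rows, cols) with >= 2 frames")

    detections = [detect_spots(f, detect_sigma_px, min_intensity) for f in stack]
    if any(len(d) == 0 for d in detections):
        warnings.warn("a frame has no detections; tracks end there", stacklevel=2)

    rows: list[tuple[int, float, float, float]] = []
    next_id = 0
    # active: bead_id -> (y, x) at previous frame
    active: dict[int, tuple[float, float]] = {}
    history: dict[int, list[tuple[int, float, float]]] = {}

    for t_idx, dets in enumerate(detections):
        taken = np.zeros(len(dets), dtype=bool)
        new_active: dict[int, tuple[float, float]] = {}
        # greedy: process links in order of increasing distance
        if active and len(dets):
            ids = list(active)
            prev = np.array([active[i] for i in ids])
            d2 = ((prev[:, None, :] - dets[None, :, :]) ** 2).sum(-1)
            order = np.argsort(d2, axis=None)
            used_prev = set()
            for flat in order:
                pi, di = np.unravel_index(flat, d2.shape)
                if ids[pi] in used_prev or taken[di]:
                    continue
                if d2[pi, di] > max_step_px**2:
                    break
                bead = ids[pi]
                used_prev.add(bead)
                taken[di] = True
                y, x = dets[di]
                new_active[bead] = (y, x)
                history[bead].append((t_idx, y, x))
        # unmatched detections start new tracks
        for di in np.flatnonzero(~taken):
            y, x = dets[di]
            new_active[next_id] = (y, x)
            history[next_id] = [(t_idx, y, x)]
            next_id += 1
        active = new_active  # beads not matched this frame are truncated

    for bead, pts in sorted(history.items()):
        if len(pts) < 2:
            continue
        for t_idx, y, x in pts:
            rows.append((bead, t_idx * frame_interval_s, x * pixel_size_um * 1e3, y * pixel_size_um * 1e3))

    df = pd.DataFrame(rows, columns=["bead_id", "t_s", "x_nm", "y_nm"])
    return TrajectoryEnsemble(frames=df, frame_interval_s=frame_interval_s)


def remove_drift(trajectories: TrajectoryEnsemble) -> TrajectoryEnsemble:
    """Subtract the per-frame median displacement (stage drift) from all beads.

    With fewer than 3 beads the correction is skipped with a warning.
    """
    if trajectories.n_beads < 3:
        warnings.warn("fewer than 3 beads; drift correction skipped", stacklevel=2)
        return TrajectoryEnsemble(
            frames=trajectories.frames.copy(), frame_interval_s=trajectories.frame_interval_s
        )
    df = trajectories.frames.copy()
    df["_step"] = np.round(df["t_s"] / trajectories.frame_interval_s).astype(int)
    # per-bead frame-to-frame increments
    df = df.sort_values(["bead_id", "_step"])
    inc_x = df.groupby("bead_id")["x_nm"].diff()
    inc_y = df.groupby("bead_id")["y_nm"].diff()
    med = (
        pd.DataFrame({"_step": df["_step"], "dx": inc_x, "dy": inc_y})
        .dropna()
        .groupby("_step")
        .median()
    )
    all_steps = np.arange(df["_step"].max() + 1)
    drift_x = np.zeros(len(all_steps))
    drift_y = np.zeros(len(all_steps))
    for s in med.index:
        drift_x[int(s)] = med.loc[s, "dx"]
        drift_y[int(s)] = med.loc[s, "dy"]
    cum_x = np.cumsum(drift_x)
    cum_y = np.cumsum(drift_y)
    df["x_nm"] = df["x_nm"] - cum_x[df["_step"].to_numpy()]
    df["y_nm"] = df["y_nm"] - cum_y[df["_step"].to_numpy()]
    df = df.drop(columns="_step")
    return TrajectoryEnsemble(frames=df, frame_interval_s=trajectories.frame_interval_s)
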