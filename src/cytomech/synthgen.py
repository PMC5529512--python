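"""Synthetic-data generators for every pipeline stage.

Everything the pipeline consumes can be generated here with a seed and a
known ground truth: force-balanced traction scenes on a soft gel, the
corresponding surface displacements via a real-space Boussinesq oracle,
bead image pairs, power-law (fractional Brownian) tracer trajectories,
two-channel spot images with a controlled overlap fraction, and qPCR Ct
tables following a log-linear standard curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .fttm import GelSubstrate, TractionField
from .piv import DisplacementField, TrajectoryEnsemble, regular_grid

__all__ = [
    "GelSubstrate",
    "DipoleSpec",
    "ActiveTrajectoryModel",
    "ColocScene",
    "QpcrSimSpec",
    "BeadImagePair",
    "ChannelPair",
    "make_traction_scene",
    "forward_displacement_oracle",
    "render_bead_images",
    "simulate_trajectories",
    "make_coloc_scene",
    "simulate_ct_table",
]

# analytic ∫ 1/r dA over a square of side a, divided by a: 4·ln(1+√2)
_SQUARE_SELF_INTEGRAL = 4.0 * np.log(1.0 + np.sqrt(2.0))


@dataclass(frozen=True)
class DipoleSpec:
    """A force-balanced pair of opposing Gaussian traction patches.

    The two patches sit at ``center ± (separation/2)·axis``; each
    integrates to ``force_magnitude`` (pN) and points along ∓``axis``
    (``sense='contractile'``: forces point toward the center, giving a
    negative net contractile moment of magnitude F·d).
    """

    center: tuple[float, float]  # (x, y) µm
    axis: tuple[float, float] = (1.0, 0.0)
    force_magnitude: float = 1e5  # pN
    separation: float = 20.0  # µm
    patch_sigma: float = 3.0  # µm
    sense: str = "contractile"

    def __post_init__(self) -> None:
        norm = float(np.hypot(*self.axis))
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("axis must be a unit vector (|axis| = 1 within 1e-9)")
        if self.separation <= 0 or self.patch_sigma <= 0:
            raise ValueError("separation and patch_sigma must be positive")
        if self.force_magnitude < 0:
            raise ValueError("force_magnitude must be >= 0")
        if self.sense not in ("contractile", "tensile"):
            raise ValueError("sense must be 'contractile' or 'tensile'")


def make_traction_scene(substrate: GelSubstrate, dipoles: list[DipoleSpec]) -> TractionField:
    """Sum of force-balanced dipole traction patches on the substrate grid.

    Each Gaussian patch is discretely normalized so it integrates exactly
    to its force magnitude, which makes the net force of every dipole
    cancel to machine precision. Patches must decay below 1e-6 of their
    peak at the grid boundary.
    """
    rows, cols = substrate.grid_shape
    gx, gy = regular_grid((rows, cols), substrate.grid_spacing)
    tx = np.zeros((rows, cols))
    ty = np.zeros((rows, cols))
    xmax = (cols - 1) * substrate.grid_spacing
    ymax = (rows - 1) * substrate.grid_spacing
    decay_radius = np.sqrt(2.0 * np.log(1e6))  # ~5.26 sigma

    for dip in dipoles:
        ax = np.asarray(dip.axis, dtype=float)
        c = np.asarray(dip.center, dtype=float)
        for sign in (-1.0, +1.0):
            pc = c + sign * 0.5 * dip.separation * ax
            if not (0 <= pc[0] <= xmax and 0 <= pc[1] <= ymax):
                raise ValueError(f"dipole patch at {tuple(pc)} lies off the grid")
            edge = min(pc[0], xmax - pc[0], pc[1], ymax - pc[1])
            if edge < decay_radius * dip.patch_sigma:
                raise ValueError(
                    "patch too close to boundary: Gaussian does not decay to <1e-6 of peak"
                )
            g = np.exp(-((gx - pc[0]) ** 2 + (gy - pc[1]) ** 2) / (2.0 * dip.patch_sigma**2))
            g /= g.sum() * substrate.grid_spacing**2  # discrete unit integral
            # contractile: force at each patch points toward the center
            direction = -sign * ax if dip.sense == "contractile" else sign * ax
            tx += dip.force_magnitude * g * direction[0]
            ty += dip.force_magnitude * g * direction[1]

    return TractionField(t_x=tx, t_y=ty, spacing=substrate.grid_spacing, meta={"n_dipoles": len(dipoles)})


def forward_displacement_oracle(traction: TractionField, substrate: GelSubstrate) -> DisplacementField:
    """Real-space Boussinesq summation — an independent oracle for the
    Fourier forward operator.

    Sums the tangential surface point response

        G_ij(r) = ((1+ν) / (π E r)) [ (1−ν) δ_ij + ν r_i r_j / r² ]

    over all source pixels (force = traction x pixel area). The singular
    self-pixel is replaced by the analytic displacement at the center of a
    uniformly loaded square patch of side ``grid_spacing``. Quadratic
    cost; intended for grids up to ~64x64.
    """
    if tuple(substrate.grid_shape) != traction.shape:
        raise ValueError("traction grid does not match substrate grid")
    E = substrate.youngs_modulus
    nu = substrate.poisson_ratio
    h = substrate.grid_spacing
    gx, gy = traction.coords()
    pts = np.column_stack([gx.ravel(), gy.ravel()])  # µm
    fx = traction.t_x.ravel() * h**2  # pN
    fy = traction.t_y.ravel() * h**2

    rx = pts[:, 0][:, None] - pts[:, 0][None, :]
    ry = pts[:, 1][:, None] - pts[:, 1][None, :]
    r2 = rx**2 + ry**2
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_r = 1.0 / np.sqrt(r2)
        pref = (1.0 + nu) / (np.pi * E) * inv_r
        gxx = pref * ((1.0 - nu) + nu * rx**2 / r2)
        gyy = pref * ((1.0 - nu) + nu * ry**2 / r2)
        gxy = pref * nu * rx * ry / r2
    # self term: uniformly loaded square patch, displacement at its center
    self_coeff = (1.0 + nu) * (1.0 - nu / 2.0) * _SQUARE_SELF_INTEGRAL / (np.pi * E * h)
    diag = np.arange(len(pts))
    gxx[diag, diag] = self_coeff
    gyy[diag, diag] = self_coeff
    gxy[diag, diag] = 0.0

    ux = (gxx @ fx + gxy @ fy).reshape(traction.shape)
    uy = (gxy @ fx + gyy @ fy).reshape(traction.shape)
    return DisplacementField(
        grid_x=gx, grid_y=gy, u_x=ux, u_y=uy,
        valid=np.ones(traction.shape, dtype=bool),
        pixel_size=h,
    )


# --------------------------------------------------------------------------
# bead images
# --------------------------------------------------------------------------

@dataclass
class BeadImagePair:
    """Reference/deformed fluorescent bead images with ground truth."""

    reference: np.ndarray
    deformed: np.ndarray
    positions_px: np.ndarray  # (n, 2) (x, y) in the reference frame
    displacements_px: np.ndarray  # (n, 2) applied shift per bead
    pixel_size_um: float


def _render_spots(shape, centers, sigma, amplitudes):
    img = np.zeros(shape)
    half = int(np.ceil(5 * sigma))
    for (cx, cy), amp in zip(centers, amplitudes):
        x0, x1 = int(np.floor(cx)) - half, int(np.floor(cx)) + half + 1
        y0, y1 = int(np.floor(cy)) - half, int(np.floor(cy)) + half + 1
        x0c, x1c = max(0, x0), min(shape[1], x1)
        y0c, y1c = max(0, y0), min(shape[0], y1)
        if x0c >= x1c or y0c >= y1c:
            continue
        yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
        img[y0c:y1c, x0c:x1c] += amp * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma**2)
        )
    return img


def render_bead_images(
    displacement: DisplacementField,
    n_beads: int,
    bead_sigma_px: float = 1.5,
    noise_sd: float = 0.0,
    seed: int = 0,
    pixel_size_um: float | None = None,
) -> BeadImagePair:
    """Render a reference/deformed image pair from a displacement field.

    The reference image holds Gaussian spots at random positions; in the
    deformed image each spot is advected by the displacement field
    interpolated at its center. Additive Gaussian noise on both.
    """
    if n_beads <= 0:
        raise ValueError("n_beads must be >= 1 (nothing to correlate otherwise)")
    if pixel_size_um is None:
        pixel_size_um = displacement.pixel_size
    rng = np.random.default_rng(seed)

    spacing = displacement.spacing
    extent_x = displacement.grid_x.max() + spacing
    extent_y = displacement.grid_y.max() + spacing
    shape = (int(round(extent_y / pixel_size_um)), int(round(extent_x / pixel_size_um)))

    interp_x = RegularGridInterpolator(
        (displacement.grid_y[:, 0], displacement.grid_x[0]),
        displacement.u_x, bounds_error=False, fill_value=0.0,
    )
    interp_y = RegularGridInterpolator(
        (displacement.grid_y[:, 0], displacement.grid_x[0]),
        displacement.u_y, bounds_error=False, fill_value=0.0,
    )

    max_disp_px = float(displacement.magnitude().max()) / pixel_size_um
    if max_disp_px >= min(shape) / 4:
        raise ValueError("displacement magnitudes must stay below 1/4 of the image extent")

    margin = 4 * bead_sigma_px
    px = rng.uniform(margin, shape[1] - 1 - margin, n_beads)
    py = rng.uniform(margin, shape[0] - 1 - margin, n_beads)
    amps = rng.uniform(0.7, 1.0, n_beads)

    pos_um = np.column_stack([py * pixel_size_um, px * pixel_size_um])  # (y, x) for interp
    dx_px = interp_x(pos_um) / pixel_size_um
    dy_px = interp_y(pos_um) / pixel_size_um

    reference = _render_spots(shape, np.column_stack([px, py]), bead_sigma_px, amps)
    deformed = _render_spots(shape, np.column_stack([px + dx_px, py + dy_px]), bead_sigma_px, amps)
    if noise_sd > 0:
        reference = reference + rng.normal(0.0, noise_sd, shape)
        deformed = deformed + rng.normal(0.0, noise_sd, shape)

    return BeadImagePair(
        reference=reference,
        deformed=deformed,
        positions_px=np.column_stack([px, py]),
        displacements_px=np.column_stack([dx_px, dy_px]),
        pixel_size_um=pixel_size_um,
    )


# --------------------------------------------------------------------------
# power-law trajectories
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ActiveTrajectoryModel:
    """Generative model of cytoskeleton-anchored tracer motion.

    x and y are independent fractional Brownian paths with Hurst exponent
    H = alpha_true/2, scaled so the 2D ensemble MSD is
    dstar_true · τ^alpha_true (nm², τ in s). α = 1 is the Brownian limit;
    α > 1 emulates the super-diffusive, actively remodeling cytoskeleton.
    """

    alpha_true: float = 1.5
    dstar_true: float = 2.0  # nm²/s^α
    n_beads: int = 75  # ~50-100 beads per field of view
    frame_interval: float = 1.0  # s
    duration: float = 300.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha_true < 2:
            raise ValueError("alpha_true must lie in (0, 2)")
        if self.dstar_true <= 0:
            raise ValueError("dstar_true must be positive")
        if self.n_beads < 1:
            raise ValueError("n_beads must be >= 1")
        if not self.duration >= self.frame_interval > 0:
            raise ValueError("need duration >= frame_interval > 0")


def _fgn(rng: np.random.Generator, hurst: float, n: int, n_series: int, var1: float) -> np.ndarray:
    """Exact-covariance fractional Gaussian noise via circulant embedding.

    Returns (n_series, n) increments with Var = ``var1`` at unit step and
    autocovariance γ(k) = var1/2 · (|k+1|^2H − 2|k|^2H + |k−1|^2H)
    (Davies–Harte; the embedding is non-negative for fGn at any H).
    """
    k = np.arange(n + 1, dtype=float)
    g = 0.5 * var1 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst) + np.abs(k - 1) ** (2 * hurst))
    row = np.concatenate([g, g[-2:0:-1]])
    lam = np.fft.fft(row).real
    lam = np.clip(lam, 0.0, None)  # tiny negatives from roundoff
    m = len(row)
    z = rng.standard_normal((n_series, m)) + 1j * rng.standard_normal((n_series, m))
    return np.fft.fft(np.sqrt(lam / m) * z, axis=1).real[:, :n]


def simulate_trajectories(model: ActiveTrajectoryModel) -> TrajectoryEnsemble:
    """Simulate a seeded fractional-Brownian bead ensemble.

    Per axis the increment variance over one frame is
    (dstar_true/2) · Δt^alpha so the 2D ensemble MSD at lag τ equals
    dstar_true · τ^alpha exactly (in expectation, at every lag).
    """
    rng = np.random.default_rng(model.seed)
    n_frames = int(np.floor(model.duration / model.frame_interval)) + 1
    n_inc = n_frames - 1
    hurst = model.alpha_true / 2.0
    var1 = (model.dstar_true / 2.0) * model.frame_interval**model.alpha_true
    inc = _fgn(rng, hurst, n_inc, 2 * model.n_beads, var1)
    paths = np.concatenate(
        [np.zeros((2 * model.n_beads, 1)), np.cumsum(inc, axis=1)], axis=1
    )
    x = paths[: model.n_beads]
    y = paths[model.n_beads :]
    t = np.arange(n_frames) * model.frame_interval
    frames = pd.DataFrame(
        {
            "bead_id": np.repeat(np.arange(model.n_beads), n_frames),
            "t_s": np.tile(t, model.n_beads),
            "x_nm": x.ravel(),
            "y_nm": y.ravel(),
        }
    )
    return TrajectoryEnsemble(
        frames=frames,
        frame_interval_s=model.frame_interval,
        meta={"alpha_true": model.alpha_true, "dstar_true": model.dstar_true, "seed": model.seed},
    )


# --------------------------------------------------------------------------
# two-channel co-localization scenes
# --------------------------------------------------------------------------

@dataclass
class ChannelPair:
    """Two aligned intensity channels with an analysis ROI."""

    channel_a: np.ndarray
    channel_b: np.ndarray
    roi_mask: np.ndarray
    pixel_size: float = 1.0  # µm/px

    def __post_init__(self) -> None:
        if self.channel_a.shape != self.channel_b.shape or self.channel_a.shape != self.roi_mask.shape:
            raise ValueError("channels and roi_mask must share a shape")


@dataclass(frozen=True)
class ColocScene:
    """Spot-image scene with a controlled true overlap fraction."""

    image_shape: tuple[int, int] = (256, 256)
    n_spots_a: int = 60
    overlap_fraction: float = 0.5
    n_extra_b: int = 30
    spot_sigma: float = 2.0  # px
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if self.spot_sigma <= 0:
            raise ValueError("spot_sigma must be positive")


def _spread_positions(rng, n, shape, margin, min_sep, existing=None):
    """Random spot centers with a minimum pairwise separation (dart throwing)."""
    pts: list[tuple[float, float]] = [] if existing is None else list(map(tuple, existing))
    n_existing = len(pts)
    attempts = 0
    while len(pts) - n_existing < n and attempts < 200 * n:
        attempts += 1
        p = (
            rng.uniform(margin, shape[1] - 1 - margin),
            rng.uniform(margin, shape[0] - 1 - margin),
        )
        if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 >= min_sep**2 for q in pts):
            pts.append(p)
    if len(pts) - n_existing < n:
        raise ValueError("could not place spots with the requested separation; enlarge the image")
    return np.asarray(pts[n_existing:])


def make_coloc_scene(scene: ColocScene) -> tuple[ChannelPair, dict]:
    """Render a two-channel spot scene with known overlap ground truth.

    Channel A holds ``n_spots_a`` spots; channel B re-uses
    ``round(overlap_fraction · n_spots_a)`` of A's centers and adds
    ``n_extra_b`` independent spots. Returns the pair plus a ground-truth
    dict (true overlap fraction actually realized, spot centers).
    """
    rng = np.random.default_rng(scene.seed)
    margin = 5 * scene.spot_sigma
    min_sep = 6 * scene.spot_sigma
    pos_a = _spread_positions(rng, scene.n_spots_a, scene.image_shape, margin, min_sep)
    n_shared = int(round(scene.overlap_fraction * scene.n_spots_a))
    shared_idx = rng.choice(scene.n_spots_a, size=n_shared, replace=False)
    pos_b_shared = pos_a[shared_idx]
    pos_b_extra = _spread_positions(
        rng, scene.n_extra_b, scene.image_shape, margin, min_sep, existing=pos_a
    ) if scene.n_extra_b else np.empty((0, 2))
    pos_b = np.vstack([pos_b_shared, pos_b_extra])

    amp_a = np.ones(len(pos_a))
    amp_b = np.ones(len(pos_b))
    a = _render_spots(scene.image_shape, pos_a, scene.spot_sigma, amp_a)
    b = _render_spots(scene.image_shape, pos_b, scene.spot_sigma, amp_b)
    if scene.noise_sd > 0:
        a = np.clip(a + rng.normal(0, scene.noise_sd, scene.image_shape), 0, None)
        b = np.clip(b + rng.normal(0, scene.noise_sd, scene.image_shape), 0, None)

    pair = ChannelPair(
        channel_a=a, channel_b=b, roi_mask=np.ones(scene.image_shape, dtype=bool)
    )
    truth = {
        "overlap_fraction_true": n_shared / scene.n_spots_a if scene.n_spots_a else 0.0,
        "n_shared": n_shared,
        "positions_a": pos_a,
        "positions_b": pos_b,
    }
    return pair, truth


# --------------------------------------------------------------------------
# qPCR Ct tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class QpcrSimSpec:
    """Generative model of a Taqman-style qPCR run against a standard curve.

    Ct_i = intercept_ct − log10(N_i)/log10(1 + efficiency) + ε,
    ε ~ N(0, noise_sd²). ``true_equivalents`` are the unknown samples'
    human-cell equivalents; a 10-fold standard dilution series
    (``standard_equivalents``) is emitted alongside them.
    """

    efficiency: float = 1.0
    intercept_ct: float = 38.0  # Ct at 1 cell equivalent
    noise_sd: float = 0.2  # cycles
    true_equivalents: tuple = (10.0, 100.0, 1000.0)
    standard_equivalents: tuple = (1.0, 10.0, 100.0, 1e3, 1e4, 1e5)
    n_replicates: int = 3  # technical qPCR replicates per well
    sample_labels: tuple | None = None  # optional (sample, tissue, group) triples
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.efficiency <= 1:
            raise ValueError("efficiency must lie in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(n <= 0 for n in self.true_equivalents):
            raise ValueError("all true_equivalents must be positive")


def _ct_from_equivalents(n, efficiency, intercept_ct):
    return intercept_ct - np.log10(n) / np.log10(1.0 + efficiency)


def simulate_ct_table(spec: QpcrSimSpec) -> pd.DataFrame:
    """Simulate a tidy Ct table with standards and unknown samples.

    Each well is run with ``n_replicates`` technical replicates (one row
    each, independent noise). Columns: sample, tissue, group, replicate,
    ct, is_standard, known_equivalents (NaN for unknowns),
    true_equivalents (ground truth, all rows).
    """
    rng = np.random.default_rng(spec.seed)
    rows = []

    def _emit(sample, tissue, group, n, is_standard, known):
        base_ct = _ct_from_equivalents(n, spec.efficiency, spec.intercept_ct)
        for rep in range(spec.n_replicates):
            ct = base_ct + (rng.normal(0, spec.noise_sd) if spec.noise_sd > 0 else 0.0)
            rows.append((sample, tissue, group, rep, ct, is_standard, known, n))

    for i, n in enumerate(spec.standard_equivalents):
        _emit(f"std_{i}", "standard", "standard", n, True, n)
    labels = spec.sample_labels
    for i, n in enumerate(spec.true_equivalents):
        if labels is not None:
            sample, tissue, group = labels[i]
        else:
            sample, tissue, group = f"sample_{i}", "tissue", "unknown"
        _emit(sample, tissue, group, n, False, np.nan)
    return pd.DataFrame(
        rows,
        columns=[
            "sample", "tissue", "group", "replicate", "ct",
            "is_standard", "known_equivalents", "true_equivalents",
        ],
    )
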