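"""Fourier-transform traction cytometry on an elastic half-space.

A cell adherent to a soft gel deforms the gel surface; given the gel's
Young's modulus E and Poisson ratio ν, the surface displacement field u
and the traction stress field T it exerts are related through the
Boussinesq half-space response. In Fourier space the tangential surface
response is the 2x2 matrix

    G(k) = (2(1+ν) / (E k³)) · [[(1−ν)k² + ν k_y²,  −ν k_x k_y],
                                [−ν k_x k_y,        (1−ν)k² + ν k_x²]]

so that ũ(k) = G(k) T̃(k). The forward map, its unconstrained inverse,
a support-constrained least-squares inverse, and the scalar mechanics
metrics derived from the traction field (RMS traction, strain energy,
net contractile moment, prestress) live here.

Units: lengths in µm, stresses in Pa (1 pN/µm² = 1 Pa), forces in pN,
strain energy in pJ, contractile moment in pNm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .piv import DisplacementField, regular_grid

__all__ = [
    "GelSubstrate",
    "TractionField",
    "CellMask",
    "MechanicalMetrics",
    "forward_displacement",
    "invert_unconstrained",
    "invert_constrained",
    "mechanics_metrics",
]


@dataclass(frozen=True)
class GelSubstrate:
    """Elastic gel substrate and the regular grid tractions live on.

    Defaults match soft polyacrylamide traction gels: E = 1300 Pa,
    ν = 0.48 (nearly incompressible).
    """

    youngs_modulus: float = 1300.0
    poisson_ratio: float = 0.48
    grid_spacing: float = 1.0
    grid_shape: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        if self.youngs_modulus <= 0:
            raise ValueError("youngs_modulus must be > 0")
        if not 0 < self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must lie in (0, 0.5)")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be > 0")
        if any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape entries must be positive")


@dataclass
class TractionField:
    """2D traction stress vectors (Pa) on a regular grid."""

    t_x: np.ndarray
    t_y: np.ndarray
    spacing: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t_x = np.asarray(self.t_x, dtype=float)
        self.t_y = np.asarray(self.t_y, dtype=float)
        if self.t_x.shape != self.t_y.shape:
            raise ValueError("t_x and t_y must share a shape")
        if not (np.all(np.isfinite(self.t_x)) and np.all(np.isfinite(self.t_y))):
            raise ValueError("traction must be finite everywhere")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.t_x.shape

    @property
    def pixel_area(self) -> float:
        return self.spacing**2

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        return regular_grid(self.shape, self.spacing)

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.t_x, self.t_y)

    def net_force(self) -> np.ndarray:
        """Integrated force vector in pN (Pa · µm² = pN)."""
        return np.array([self.t_x.sum(), self.t_y.sum()]) * self.pixel_area

    def to_frame(self) -> pd.DataFrame:
        gx, gy = self.coords()
        return pd.DataFrame(
            {
                "grid_x_um": gx.ravel(),
                "grid_y_um": gy.ravel(),
                "tx_pa": self.t_x.ravel(),
                "ty_pa": self.t_y.ravel(),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class CellMask:
    """Boolean cell-projection mask aligned to the traction grid."""

    mask: np.ndarray
    pixel_area: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("mask must contain at least one pixel")
        if self.pixel_area <= 0:
            raise ValueError("pixel_area must be positive")


@dataclass(frozen=True)
class MechanicalMetrics:
    """Scalar contractility metrics for one cell."""

    projected_area: float  # µm²
    rms_traction: float  # Pa
    strain_energy: float  # pJ
    net_contractile_moment_signed: float  # pNm, negative = contractile
    net_contractile_moment: float  # pNm (magnitude)
    prestress: float  # Pa

    def to_dict(self) -> dict:
        return {
            "area_um2": self.projected_area,
            "rms_traction_pa": self.rms_traction,
            "strain_energy_pj": self.strain_energy,
            "net_contractile_moment_pnm": self.net_contractile_moment,
            "net_contractile_moment_signed_pnm": self.net_contractile_moment_signed,
            "prestress_pa": self.prestress,
        }


# --------------------------------------------------------------------------
# Fourier kernel
# --------------------------------------------------------------------------

def _greens_fourier(shape, spacing, youngs_modulus, poisson_ratio):
    """G(k) components on an FFT grid; DC mode zeroed, Nyquist coupling zeroed."""
    nr, nc = shape
    ky = 2 * np.pi * np.fft.fftfreq(nr, d=spacing)[:, None]
    kx = 2 * np.pi * np.fft.fftfreq(nc, d=spacing)[None, :]
    k2 = kx**2 + ky**2
    k = np.sqrt(k2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pref = 2.0 * (1.0 + poisson_ratio) / (youngs_modulus * k**3)
    pref[0, 0] = 0.0
    gxx = pref * ((1 - poisson_ratio) * k2 + poisson_ratio * ky**2)
    gyy = pref * ((1 - poisson_ratio) * k2 + poisson_ratio * kx**2)
    gxy = -pref * poisson_ratio * kx * ky
    gxx[0, 0] = gyy[0, 0] = gxy[0, 0] = 0.0
    # pure-Nyquist rows/columns: zero the off-diagonal coupling so the
    # kernel stays consistent with Hermitian symmetry of real fields
    if nr % 2 == 0:
        gxy[nr // 2, :] = 0.0
    if nc % 2 == 0:
        gxy[:, nc // 2] = 0.0
    return gxx, gxy, gyy


def _check_substrate(field_shape, substrate: GelSubstrate):
    if tuple(substrate.grid_shape) != tuple(field_shape):
        raise ValueError(
            f"grid mismatch: field {tuple(field_shape)} vs substrate {tuple(substrate.grid_shape)}"
        )


def _pad(a: np.ndarray, pad_factor: int) -> np.ndarray:
    if pad_factor == 1:
        return a
    nr, nc = a.shape
    out = np.zeros((nr * pad_factor, nc * pad_factor))
    out[:nr, :nc] = a
    return out


def forward_displacement(
    traction: TractionField,
    substrate: GelSubstrate,
    pad_factor: int = 2,
) -> DisplacementField:
    """Surface displacement produced by a traction field on the half-space.

    ``pad_factor`` zero-pads each dimension before the Fourier product to
    suppress periodic wrap-around; use 1 for strictly periodic fields.
    """
    _check_substrate(traction.shape, substrate)
    tx = _pad(traction.t_x, pad_factor)
    ty = _pad(traction.t_y, pad_factor)
    gxx, gxy, gyy = _greens_fourier(
        tx.shape, substrate.grid_spacing, substrate.youngs_modulus, substrate.poisson_ratio
    )
    ftx = np.fft.fft2(tx)
    fty = np.fft.fft2(ty)
    ux = np.fft.ifft2(gxx * ftx + gxy * fty).real
    uy = np.fft.ifft2(gxy * ftx + gyy * fty).real
    nr, nc = traction.shape
    gx, gy = regular_grid(traction.shape, substrate.grid_spacing)
    return DisplacementField(
        grid_x=gx,
        grid_y=gy,
        u_x=ux[:nr, :nc],
        u_y=uy[:nr, :nc],
        valid=np.ones(traction.shape, dtype=bool),
        pixel_size=substrate.grid_spacing,
    )


def invert_unconstrained(
    displacement: DisplacementField,
    substrate: GelSubstrate,
    regularization: float = 0.0,
    pad_factor: int = 2,
) -> TractionField:
    """Unconstrained FTT cytometry: T̃(k) = G(k)⁻¹ ũ(k) for k > 0.

    The k = 0 traction mode is set to zero (net-force-free gauge). With
    ``regularization`` λ > 0 a Tikhonov-filtered inverse (G² + λI)⁻¹ G is
    applied instead of the plain inverse.
    """
    _check_substrate(displacement.shape, substrate)
    spacing = displacement.spacing  # raises on irregular grids
    if not np.isclose(spacing, substrate.grid_spacing, rtol=1e-6):
        raise ValueError("displacement grid spacing does not match substrate")
    ux = _pad(displacement.u_x, pad_factor)
    uy = _pad(displacement.u_y, pad_factor)
    gxx, gxy, gyy = _greens_fourier(
        ux.shape, spacing, substrate.youngs_modulus, substrate.poisson_ratio
    )
    fux = np.fft.fft2(ux)
    fuy = np.fft.fft2(uy)
    lam = float(regularization)
    # per-k 2x2 solve; G is symmetric positive definite for k > 0
    det = gxx * gyy - gxy**2
    if lam == 0.0:
        with np.errstate(divide="ignore", invalid="ignore"):
            ixx = gyy / det
            iyy = gxx / det
            ixy = -gxy / det
    else:
        # (G² + λI)⁻¹ G, all 2x2 symmetric so closed form via G² entries
        hxx = gxx**2 + gxy**2 + lam
        hyy = gyy**2 + gxy**2 + lam
        hxy = gxy * (gxx + gyy)
        hdet = hxx * hyy - hxy**2
        with np.errstate(divide="ignore", invalid="ignore"):
            ixx = (hyy * gxx - hxy * gxy) / hdet
            ixy = (hyy * gxy - hxy * gyy) / hdet
            iyy = (-hxy * gxy + hxx * gyy) / hdet
    for arr in (ixx, ixy, iyy):
        arr[0, 0] = 0.0
        arr[~np.isfinite(arr)] = 0.0
    ftx = ixx * fux + ixy * fuy
    fty = ixy * fux + iyy * fuy
    nr, nc = displacement.shape
    tx = np.fft.ifft2(ftx).real[:nr, :nc]
    ty = np.fft.ifft2(fty).real[:nr, :nc]
    return TractionField(t_x=tx, t_y=ty, spacing=spacing, meta={"mode": "unconstrained", "lambda": lam})


def invert_constrained(
    displacement: DisplacementField,
    substrate: GelSubstrate,
    mask: CellMask,
    pad_factor: int = 2,
    tol: float = 1e-6,
    maxiter: int = 500,
) -> TractionField:
    """Constrained FTT cytometry: least-squares traction supported on the mask.

    Minimizes ‖forward(T) − u‖² over tractions that are exactly zero
    outside the cell mask, by conjugate gradients on the normal equations
    (the padded forward operator is self-adjoint and positive
    semi-definite). Iterations stop when the relative change in the data
    residual falls below ``tol`` or after ``maxiter`` iterations; the
    final residual is reported in ``meta``.
    """
    _check_substrate(displacement.shape, substrate)
    if mask.mask.shape != displacement.shape:
        raise ValueError("mask not aligned to displacement grid")
    spacing = displacement.spacing
    m = mask.mask

    def fwd(tx, ty):
        f = forward_displacement(TractionField(tx, ty, spacing), substrate, pad_factor=pad_factor)
        return f.u_x, f.u_y

    ux_obs, uy_obs = displacement.u_x, displacement.u_y

    def apply_normal(tx, ty):
        ax, ay = fwd(tx, ty)
        bx, by = fwd(ax, ay)  # Mᵀ M = M M (self-adjoint)
        return np.where(m, bx, 0.0), np.where(m, by, 0.0)

    # right-hand side: Sᵀ M u
    bx, by = fwd(ux_obs, uy_obs)
    bx = np.where(m, bx, 0.0)
    by = np.where(m, by, 0.0)

    tx = np.zeros_like(ux_obs)
    ty = np.zeros_like(uy_obs)
    rx, ry = bx.copy(), by.copy()
    px, py = rx.copy(), ry.copy()
    rs_old = (rx**2 + ry**2).sum()

    def data_residual(tx, ty):
        ax, ay = fwd(tx, ty)
        return float(np.sqrt(((ax - ux_obs) ** 2 + (ay - uy_obs) ** 2).sum()))

    u_norm = float(np.sqrt((ux_obs**2 + uy_obs**2).sum()))
    res_prev = data_residual(tx, ty)
    n_iter = 0
    converged = False
    for n_iter in range(1, maxiter + 1):
        qx, qy = apply_normal(px, py)
        denom = (px * qx + py * qy).sum()
        if denom <= 0:
            converged = True
            break
        alpha = rs_old / denom
        tx = tx + alpha * px
        ty = ty + alpha * py
        rx = rx - alpha * qx
        ry = ry - alpha * qy
        rs_new = (rx**2 + ry**2).sum()
        res = data_residual(tx, ty)
        # stop at machine-precision fit: past this point CG iterates on
        # roundoff noise in the normal-equation residual and diverges
        if res <= 1e-9 * u_norm:
            res_prev = res
            converged = True
            break
        if res_prev > 0 and abs(res_prev - res) / res_prev < tol:
            res_prev = res
            converged = True
            break
        res_prev = res
        beta = rs_new / rs_old if rs_old > 0 else 0.0
        px = rx + beta * px
        py = ry + beta * py
        rs_old = rs_new
        if rs_old == 0:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"constrained inversion did not converge in {maxiter} iterations "
            f"(residual {res_prev:.3e})",
            stacklevel=2,
        )
    return TractionField(
        t_x=np.where(m, tx, 0.0),
        t_y=np.where(m, ty, 0.0),
        spacing=spacing,
        meta={"mode": "constrained", "residual": res_prev, "n_iter": n_iter, "converged": converged},
    )


def mechanics_metrics(
    traction: TractionField,
    displacement: DisplacementField,
    mask: CellMask,
    effective_height_um: float = 5.0,
) -> MechanicalMetrics:
    """Scalar mechanics metrics over the cell-projected area.

    - projected area: mask pixel count x pixel area (µm²)
    - RMS traction: sqrt(mean |T|²) over the mask (Pa)
    - strain energy: U = ½ Σ T·u · pixel_area, in pJ (1 Pa µm³ = 1e−6 pJ)
    - net contractile moment: trace of the symmetrized first moment matrix
      M_ij = Σ ½(x_i T_j + x_j T_i) · pixel_area with coordinates relative
      to the traction-weighted centroid, in pNm (negative trace =
      contractile); reported both signed and as a magnitude
    - prestress: |μ| / (2 · A · h) with effective cell height h (Pa)
    """
    if traction.shape != displacement.shape or mask.mask.shape != traction.shape:
        raise ValueError("traction, displacement and mask must share one grid")
    if effective_height_um <= 0:
        raise ValueError("effective_height_um must be positive")
    m = mask.mask
    area = float(m.sum()) * mask.pixel_area

    tmag2 = traction.t_x**2 + traction.t_y**2
    rms = float(np.sqrt(tmag2[m].mean()))

    dot = traction.t_x * displacement.u_x + traction.t_y * displacement.u_y
    strain_energy_pa_um3 = 0.5 * float(dot[m].sum()) * mask.pixel_area
    strain_energy_pj = strain_energy_pa_um3 * 1e-6

    gx, gy = traction.coords()
    w = np.sqrt(tmag2)
    wsum = float(w[m].sum())
    if wsum > 0:
        cx = float((gx * w)[m].sum()) / wsum
        cy = float((gy * w)[m].sum()) / wsum
    else:
        cx = float(gx[m].mean())
        cy = float(gy[m].mean())
    x = gx - cx
    y = gy - cy
    mxx = float((x * traction.t_x)[m].sum()) * mask.pixel_area
    myy = float((y * traction.t_y)[m].sum()) * mask.pixel_area
    moment_signed_pnm = (mxx + myy) * 1e-6  # Pa µm³ -> pNm
    moment_pnm = abs(moment_signed_pnm)

    # |μ| in pN·µm over (2 A h) in µm³ gives pN/µm² = Pa
    prestress = (moment_pnm * 1e6) / (2.0 * area * effective_height_um)

    return MechanicalMetrics(
        projected_area=area,
        rms_traction=rms,
        strain_energy=strain_energy_pj,
        net_contractile_moment_signed=moment_signed_pnm,
        net_contractile_moment=moment_pnm,
        prestress=prestress,
    )
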