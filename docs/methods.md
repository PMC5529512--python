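# Methods

This note documents the models, estimators and numerical choices behind
cytomech, what the synthetic-data generators do and do not emulate, and
the known limitations of each stage.

## Elastic substrate model and traction reconstruction

The substrate is an isotropic, linear-elastic half-space; the cell
exerts purely tangential tractions on its flat surface. For a
tangential point force **F** at the origin, the surface displacement at
in-plane offset **r** is the Boussinesq solution

    u_i(r) = G_ij(r) F_j,
    G_ij(r) = ((1+ν)/(π E r)) [ (1−ν) δ_ij + ν r_i r_j / r² ],

and its 2D Fourier transform gives the diagonalizable surface response
G(k) used by the forward operator ũ(k) = G(k) T̃(k) (see README for
the explicit matrix). Assumptions: substrate thickness ≫ displacement
decay length (no finite-thickness correction), small strains, no
out-of-plane traction.

**Discretization.** Tractions live on a regular grid (default 2 µm
spacing). The forward map multiplies the FFT of T by G(k) with the DC
mode zeroed (a net force on an infinite half-space has no bounded
displacement; measured fields are force-balanced to good approximation)
and, on even-sized grids, the off-diagonal coupling zeroed on pure
Nyquist rows/columns to preserve the Hermitian symmetry of real
fields.

**Padding.** FFT convolution is cyclic. The forward and inverse
operators accept a `pad_factor` (default 2: each dimension zero-padded
to twice its size) to suppress wrap-around from the slowly decaying
1/r kernel. Two consequences worth knowing:

- With padding, "invert(forward(T))" is *not* an exact identity on a
  cropped grid (the forward displacement extends into the padding
  region that the inverse never sees). On strictly periodic fields the
  unpadded operators (`pad_factor=1`) are exact mutual inverses to
  machine precision, which is how the round-trip identity is tested.
- Against the free-space real-space oracle (below), `pad_factor=2`
  leaves ~3% wrap-around residue on a 48×48 dipole scene; `pad_factor=4`
  brings agreement below 0.5%. Operator-accuracy comparisons therefore
  use factor 4; routine analyses keep the cheaper factor 2.

**Real-space oracle.** An independent check of the Fourier operator
sums the point response over all source pixels directly (quadratic
cost, fine to ~64×64). The singular self-pixel is replaced by the
analytic displacement at the center of a uniformly loaded square patch
of side *a*: u = (1+ν)(1−ν/2)·4 ln(1+√2)·a·t/(π E), using
∫_square dA/r = 4a ln(1+√2) (verified numerically before freezing).

**Unconstrained inversion** solves the 2×2 system per wavevector (G is
symmetric positive definite for k > 0 and ν ∈ (0, ½); det G ∝
(1−ν)k⁴). Optional Tikhonov filtering (G² + λI)⁻¹G is available
(default λ = 0; synthetic displacement fields are smooth enough not to
need it — real, noisy PIV fields may).

**Constrained inversion** finds the least-squares traction supported
exactly on the cell mask by conjugate gradients on the normal
equations. The padded forward operator is self-adjoint (convolution
with an even kernel restricted by zero-pad/crop), so the normal
operator is just the forward applied twice, projected onto the mask.
Stopping: relative change of the data residual < 1e-6, a hard cap of
500 iterations, *and* an absolute floor of 1e-9·‖u‖ — without the
floor, CG keeps iterating on roundoff noise after reaching machine
precision and diverges. Non-convergence returns the current iterate
with a warning and the residual in `meta`.

**Metrics.** Projected area, RMS traction over the mask, strain energy
U = ½ Σ T·u·ΔA (1 Pa µm³ = 1e-6 pJ), and the net contractile moment:
trace of the symmetrized first moment matrix of the traction field with
coordinates taken relative to the |T|-weighted centroid, in pNm
(1 Pa µm³ = 1e-6 pNm). Centroid referencing makes the moment exactly
translation invariant even for slightly unbalanced measured fields. A
contractile cell gives a negative trace; the magnitude is reported
alongside. Prestress is estimated as |μ|/(2·A·h) with an effective cell
height h (default 5 µm, configurable); this is a declared surrogate —
the literature offers no single canonical prestress estimator, and h
rescales the value linearly.

## Displacement estimation (PIV) and bead tracking

Interrogation windows (default 32 px, 50% overlap) are matched into a
search region of the other image (radius window/4) by normalized
cross-correlation computed via FFT template matching. Valid-mode
matching was chosen over the textbook cyclic window correlation because
wrap-around and partial particles at window edges bias the cyclic
subpixel estimate by 0.1–0.5 px; valid-mode matching at realistic
seeding (~10–15 particles per window) keeps every vector within
±0.05 px on rigid translations. The integer peak is refined by a
three-point Gaussian fit per axis (parabolic fallback when a neighbor
is non-positive), and the estimate is symmetrized — deformed matched
back into reference, the two half-estimates averaged — which cancels
the odd-order bias from overlapping particle images. Windows whose
correlation peak is not ≥ 1.2× the second peak (outside a 5×5 exclusion
zone), or with constant content, are marked invalid and filled with the
median of valid neighbors. The window grid is inset by the search
radius: border windows cannot observe shifts past the image edge.
Limitations: no iterative window deformation, so strong displacement
gradients within a window bias toward the window mean; maximum
measurable displacement is the search radius.

Bead tracking detects spots per frame as scale-normalized
Laplacian-of-Gaussian maxima (threshold: median + 5×1.4826·MAD of the
response — 3×MAD admits tens of false noise maxima per megapixel at
SNR 10), suppresses non-maxima within 2σ, excludes a 2σ border band
(the filter's reflected boundary fabricates edge maxima), and refines
positions by intensity-weighted centroid. Frames are linked by greedy
nearest-neighbor assignment in order of increasing distance, capped at
`max_step_px`; tracks truncate at the first missed frame (no gap
closing). Greedy linking is adequate for sparse, slow beads; dense or
fast scenes would need global assignment. Stage drift is removed as the
per-frame median displacement across beads (≥ 3 beads required;
median, not mean, so a few active beads do not drag the correction).

## Tracer rheology (MSD and power-law fit)

The ensemble MSD at lag τ = mΔt averages |r(t+τ) − r(t)|² over beads
and, by default, over all overlapping time origins
(`averaging="ensemble_time"`); `ensemble_only` uses only t = 0, giving
independent per-bead samples at the cost of variance. The power law
MSD = D*·τ^α is fitted by unweighted OLS of log MSD on log τ over lags
in (10, 300] s — the standard analysis window for this assay — with
the slope's standard error and r² from the regression. Below-zero MSD
values cannot occur; zero values (all-stationary) are dropped with a
warning. Classification: α > 1.05 superdiffusive, α < 0.95
subdiffusive, else diffusive (tolerance 0.05, configurable).

Estimator precision matters for classification: at 100 beads × 300
frames the fitted α has a seed-to-seed SD of ≈ 0.03 (the long-lag MSD
estimates are few-sample and strongly correlated), so single-field
classification against a ±0.05 band misfires a few percent of the
time. The Brownian-control validation therefore pools three fields
(300 beads), bringing the SD to ≈ 0.02; per-field fits remain the unit
of replication for group comparisons, matching practice.

**Generator.** Bead motion is simulated as independent fractional
Brownian motion per axis with Hurst H = α/2, exact covariance via
Davies–Harte circulant embedding (eigenvalues of the embedded circulant
are non-negative for fGn at any H; tiny numerical negatives are
clipped). Per-axis increment variance (D*/2)Δt^α makes the expected 2D
MSD exactly D*·τ^α at every lag. fBm is a *statistical stand-in*: real
cytoskeletal bead motion is driven by motor activity and remodeling,
not Gaussian long-memory noise. Passing recovery tests shows the
MSD/fit machinery is unbiased for power-law ensembles — not that cells
are fBm.

## Image quantification

**Co-localization.** The default coefficient is the thresholded
Manders M1: Σ A over pixels above both channels' thresholds divided by
Σ A over above-threshold A pixels — the quantity commercial confocal
software reports as "colocalization coefficient". (The classic
unthresholded M1, Σ A[B>thr]/Σ A, is recovered with thresholds (0,0);
it degrades at realistic SNR because diffuse background dominates the
denominator.) Thresholds are per-channel Otsu by default, or fixed, or
Costes joint thresholds for the Pearson variant (clipped at 0 for
reporting). Two opt-in refinements for diffraction-limited spot
images: a Gaussian matched filter (`smooth_sigma_px` ≈ spot σ) before
thresholding, and a 1 px dilation of the partner mask
(`partner_dilation_px`) that compensates boundary pixels pushed just
below threshold by independent noise in one channel — without it M1 is
biased low by ~3% at full overlap.

**Spot density** counts LoG maxima (same detector as tracking) inside
the ROI per mm². The area denominator is the supplied ROI mask — for
tissue PLA work, whether that ROI is epithelium or whole tissue is the
caller's decision and changes the number.

**Positive fraction, wound closure, H-score, F/G ratio** are direct
arithmetic on their inputs; H-score bins (0/1+/2+/3+) are pathologist
input, not computed from images, and validation enforces the
percentages summing to 100 and the 0–300 range. Wound closure is
clipped to [0, 1].

## Alu-qPCR burden

The standard curve is OLS of (replicate-averaged) Ct on
log₁₀(equivalents), requiring ≥ 3 distinct dilutions spanning ≥ 2
decades; efficiency = 10^(−1/slope) − 1 with a warning outside
(0, 1.1]. Unknowns invert the curve; non-detects map to a configurable
floor (default half the lowest standard). The generator emits three
technical replicates per well with independent N(0, 0.2²)-cycle noise —
standard Taqman practice; with single wells a 0.2-cycle SD alone makes
±20% quantification a coin flip. Fold change defaults to each
knockdown sample over its tissue's control median, with the overall
median and range over all per-sample folds; a ratio-of-medians variant
is provided for sensitivity analysis. The published fold-change
construction is not fully specified, so these are declared choices.

## Statistics

Pooled-variance t (scipy), tie-corrected Kruskal–Wallis H with
χ²_{k−1} tail (own implementation, cross-checked against scipy and a
from-scratch rank-formula oracle; all-identical values return H = 0,
p = 1 by convention), Mann–Whitney U with exact p by full enumeration
of group assignments for n+m ≤ 20 (midranks, so ties are handled;
two-sided p = twice the smaller tail, capped at 1) and a
tie/continuity-corrected normal approximation beyond. Šidák threshold
1 − (1−α)^(1/m). Power uses the one-sided normal approximation
Φ(d√(n/2) − z₁₋α), which reproduces the conventional 76.6% figure for
n = 5, d = 1.5; the exact noncentral-t power (also provided) is lower
at small n, and the discrepancy is the approximation's known optimism.

## Pipeline and determinism

`run_pipeline` validates the YAML config against a closed key set
(unknown keys are named in the error), derives every stage seed from
the single top-level seed, and writes per-stage CSVs plus one
`report.json` whose SHA-256 (over the canonical, sorted-key JSON body)
certifies bit-identical reruns. Floats in the report are rounded to 10
decimals so the hash reflects results, not accumulation order noise.
Demo problem sizes (48×48 traction grid, 75-bead fields, 256² scenes,
5 animals per group × 3 tissues) were chosen to mirror the real assays'
scale while keeping a full run around a second.

## Known limitations

- 2D tangential tractions on a semi-infinite substrate only; no finite
  gel thickness, no 3D reconstruction, no reference-free methods.
- Single-pass PIV (no window deformation), greedy tracking (no gap
  closing or global assignment).
- The synthetic scenes use isotropic Gaussian spots with additive
  Gaussian noise — no PSF asymmetry, shot noise, photobleaching, or
  tissue autofluorescence; recovery results bound estimator bias under
  these idealizations, not under real microscope physics.
- The prestress surrogate and the fold-change pairing rule are declared
  conventions, not reproductions of an exactly specified published
  computation.
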