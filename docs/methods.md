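# Methods

This note documents the models, numerical choices and limitations of
the `doubletmech` pipeline. Coordinates are row-major grids with x along
columns, y along rows, origin at the top-left pixel centre, and angles
in degrees counter-clockwise from +x. Lengths are µm, tractions Pa
(= pN/µm²), forces nN, 2D stresses Pa·µm.

## Elastic substrate and forward model

The substrate is a semi-infinite, homogeneous, isotropic elastic
half-space (the same assumption standard Fourier-transform traction
cytometry makes). Its surface response to in-plane traction is the
Boussinesq solution in Fourier space,

    û(k) = Ĝ(k) · T̂(k),
    Ĝ(k) = (2(1+ν)/(E k³)) [[(1−ν)k² + ν ky², −ν kx ky],
                             [−ν kx ky, (1−ν)k² + ν kx²]],

with Young's modulus E in Pa and k in rad/µm. Two named presets cover
the experimental substrates this pipeline targets: `fibronectin_30kPa`
(E = 30 kPa) and `ecadherin_15kPa` (E = 15 kPa). The Poisson ratio is
not reported for these gels; the default ν = 0.5 (incompressible
silicone elastomer) is the standard choice for PDMS-type TFM substrates
and is configurable.

The forward model evaluates Ĝ·T̂ on a grid zero-padded to twice its
size (suppressing periodic wrap-around of the slowly decaying 1/r
displacement tails) and trims the padding. The zero mode is nulled: a
rigid translation of the surface is unobservable. The model is linear
to machine precision and agrees with direct real-space quadrature of
the Boussinesq point-force kernel to < 0.5% for compact sources
(verified in the test suite against a 4× supersampled quadrature).

Finite gel thickness is neglected; for beads within a few µm of the
surface of a ≫10 µm gel the half-space approximation is the accepted
practice.

## Synthetic doublet scenes

`make_doublet_scene` builds the ground truth every downstream stage is
verified against. Two disk-shaped cells (default radius 15 µm, an
MDCK-scale footprint) sit on a 128 µm field at 0.5 µm/pixel, their
territories split along the perpendicular bisector so the two masks are
exactly disjoint. Each cell carries six Gaussian traction hotspots
(σ = 3 µm, 400 Pa) pointing toward its own centre — contraction — and
placed on the cell's **outward-facing side**, matching the observed
organization of control doublets, where traction hotspots arise at the
doublet periphery under lamellipodia and are absent from the junctional
area. Hotspot fields are clipped to the owning cell's mask and balanced
by a uniform in-mask compensation, so each cell's resultant is exactly
zero before tugging.

A tugging force f_tug (nN) adds a uniform traction of magnitude
f_tug/area to each cell along the junction normal, **pointing toward
the other cell**: each cell leans on the substrate against the junction
pull, which is what makes the transjunctional force visible in the
substrate and puts the junction under tension (positive σ⊥). Per-cell
resultants are therefore ±f_tug exactly (to round-off), the global sum
is zero, and f_tug = 0 encodes the pre-contact state.

Bead images place beads uniformly at continuous coordinates (so
subpixel recovery is honestly testable), render them as analytic
Gaussians, and shift each bead by the locally interpolated
displacement for the deformed frame. Defaults: bead density 0.4/µm²
(dense enough that a 16-px interrogation window holds ~25 bead images;
the experimental dilution protocol does not map to an areal density, so
this is chosen for PIV robustness and flagged as such), PSF σ =
0.375 µm (a diffraction-limited dry objective), peak amplitude 1000
with additive Gaussian noise (2% of peak in the standard noisy
condition). All generators are deterministic under a fixed seed.

`make_smooth_traction` provides the smooth calibration field for
operator round-trip benchmarks: Gaussian dipole pairs (two opposite
blobs 3σ apart) in the central 40% of the field. Each pair integrates
to zero and has a 1/r² far field, so the field is C∞, zero-net-force
and compact — reconstruction error then measures the operators, not
Gibbs ringing from mask edges.

## PIV

Single-pass windowed cross-correlation (default window 32 px, overlap
0.5; the doublet chain uses 16 px windows at overlap 0.75 for finer
node spacing). Per window: mean subtraction, multiplication by a
Gaussian window weight (σ = w/4), FFT circular cross-correlation, peak
search within a quarter-window radius, peak-to-second-peak
signal-to-noise validation (threshold 1.3), and three-point Gaussian
subpixel interpolation with a parabolic fallback where a log of a
non-positive value would occur.

Two details matter for accuracy at the small displacements TFM
produces (often < 0.5 px):

- **Window weighting.** Bead images clipped at the window border
  contribute asymmetric correlation mass; without weighting this biases
  the subpixel estimate multiplicatively toward zero (measured factor
  ≈ 0.82 at 16-px windows with σ_PSF = 1 px). The Gaussian weight
  suppresses border beads and removes most of the bias; uniform and
  Hann weights remain available.
- **Discrete window offset.** After the integer peak is found, the
  deformed window is re-extracted at that offset (sliding the reference
  window instead near the image border) and re-correlated, so matching
  content aligns. Integer displacements are then recovered exactly and
  the residual subpixel estimate is unbiased to first order.

Windows failing validation are replaced by the median of their valid
8-neighbours in one pass; unreplaceable nodes stay NaN with
`valid = False`. The reference frame is always the relaxed (post-lysis)
image, supplied explicitly. `correct_drift` removes rigid stage drift
as the median displacement over a user-supplied cell-free background
mask (≥ 5% of nodes).

On noise-free synthetic doublet scenes the RMS PIV error is < 0.03 px;
the acceptance bound is 0.1 px.

## FTTC

Per wavevector, T̂ = (ĜᵀĜ + λ²g I)⁻¹ Ĝᵀ û with g = (2(1+ν)/(E k₀))²
and k₀ = 2π/L the fundamental wavevector of the mirror-padded field.
This normalization makes λ dimensionless and turns it into a low-pass
with cutoff near k₀/λ, so values in 0.01–0.1 are the useful range.
The fixed default λ = 0.02 is the L-curve corner measured on the noisy
synthetic calibration scene (128 µm field, 5% displacement noise);
`select_lambda_lcurve` re-derives the corner per dataset — the doublet
chain uses it, because PIV-grid data arrive already low-passed by the
interrogation windows and need less spectral regularization than
full-resolution displacement fields.

The displacement field is mirror-padded to twice its size before the
FFT (continuous periodic extension) and the result trimmed; the
returned traction is exactly zero-mean. Grids of any size are inverted
directly (numpy's FFT has no power-of-two restriction); optional
power-of-two resampling exists but is off by default because the
bilinear round trip measurably attenuates recovered forces.

Mask-restricted summaries report the mean traction magnitude (Pa) and
the vectorial resultant (nN = Σ T·a / 1000 with a the pixel area in
µm²). For per-cell force budgets on reconstructed traction the pipeline
uses *generous* masks — the doublet footprint grown by 8 µm and split
by nearest-cell assignment — emulating the generous manually drawn
masks used in practice: the measurement chain low-passes traction
beyond the cell outline, and a tight mask clips part of the budget. The
remaining systematic loss (smearing across the junction bisector, where
the two cells' budgets cancel) keeps full-chain recovery of a 50 nN tug
within the ±20% acceptance band.

## BISM

The in-plane stress tensor σ = (σxx, σyy, σxy) obeys force balance
with the traction the cell exerts on the substrate,

    ∂x σxx + ∂y σxy = tx,   ∂x σxy + ∂y σyy = ty,

so contractile cells carry positive (tensile) normal stress. The MAP
estimate minimizes ‖Dσ − t‖² + Λ s² ‖σ‖² on the smallest rectangle
encompassing the doublet (expandable margin, default 2 nodes), with D
the centered-difference divergence operator (second-order one-sided
stencils at edges) and Λ = 10⁵ by default. The nondimensionalizing
scale is s² = 1/(Λ_scale h²) with h the grid spacing and Λ_scale = 10⁹
a fixed calibration constant recorded in the output metadata; it makes
Λ = 10⁵ weakly informative (≈1% shrinkage of the smoothest mode of a
40-node domain) while keeping the normal equations well conditioned.
‖σ‖ is non-increasing in Λ and the solution is linear in t.

Free stress boundary conditions σ·n = 0 on the rectangle edges are
imposed by exact elimination of the constrained components (σxx and
σxy on left/right edges, σyy and σxy on top/bottom): the boundary
residual is exactly zero and the sparse normal-equation solve agrees
with an independent dense least-squares solution to ~10⁻¹² on a 12×12
domain. A soft quadratic penalty (configurable weight) is available;
large penalty weights square into the normal equations' condition
number, which is why elimination is the default. Height variations
within the doublet are neglected: σ is a 2D tensor in Pa·µm, and the
estimate is qualitative in the same sense the free-boundary rectangle
makes the experimental one qualitative — sufficient for comparing
conditions and components.

On the 1D contractile-strip oracle (tx = −T₀ sign x) the recovered σxx
matches the analytic triangular tension profile within 8% over the
central 80% and is tensile throughout. Per-node principal components
(closed-form 2×2 eigendecomposition, λ₁ ≥ λ₂, orientation in
(−90°, 90°], isotropic nodes flagged) support the stress-ellipse
rendering convention (tension red, compression blue).

## Junction-relative quantities

The junction domain is the overlap of the two cell masks after dilation
by a disk (default radius 2 px, guaranteeing overlap of touching
segmentations); an empty overlap is the distinct "no contact" state
(`None`), not an error. The midline is the skeleton of the overlap
ordered along its principal axis, and the mean orientation θ is the
total-least-squares direction of the midline points (endpoint-chord
estimation available). On synthetic scenes θ lands within 5° of the
generating junction angle.

Traction decomposition projects every in-mask vector on (cos θ, sin θ)
and its normal, ranks nodes by their coordinate along θ, and splits
them into four quarters of **equal node count** (remainders assigned
from the centre outward — equal-count is robust to irregular mask
shapes; equal-length is the untaken alternative). Centre = middle two
quarters; the summary holds means of absolute projections per
subdomain and their parallel/perpendicular ratios. Degree-exact
trigonometry (`cosdg`/`sindg`) keeps axis-aligned junctions free of
round-off, and the arithmetic matches a per-node reference loop
bit-for-bit.

Stress components rotate the tensor at the single mean θ —
σ∥ = σxx cos²θ + σyy sin²θ + 2σxy sinθ cosθ, σ⊥ the same at θ+90° —
and average over the junction mask. The straight-junction treatment is
justified for roughly straight junctions, where following the contour
changes the estimates negligibly; a per-segment variant is not
implemented. Trace is invariant: σ∥ + σ⊥ equals the averaged σxx + σyy
to 10⁻¹².

`anisotropy_report` resamples a time series at 30-minute marks over the
first 3 h after a user-specified contact frame (six marks, nearest
frame within half an interval), reporting σ∥, σ⊥, their ratio and the
traction summaries per mark — the standard presentation of junctional
stress buildup after contact.

## Morphometrics

Junction length is the accumulated polyline length; straightness the
euclidean/accumulated ratio in (0, 1] (closed loops return 0 with a
warning). Angular deviation compares per-frame endpoint-chord angles
against the frame-0 chord, wrapped axially to [0°, 90°]; the summary
statistic over the time window is the mean absolute deviation by
default (maximum available) — the underlying figure label does not fix
the statistic, so it is configurable. The chord (not TLS) axis is used
here because these traces come from fluorescence midlines without a
mask. Pearson colocalization is computed over in-ROI pixels only, with
a `None` undefined-result signal on zero variance. Line profiles sample
bilinearly at equidistant arc-length positions and normalize to the
per-scan maximum (per-line rather than whole-image normalization; both
readings of the protocol are defensible and per-line is the default).
Particle analysis thresholds (absolute or Otsu) and counts 8-connected
components above a minimum area, in µm².

## What the synthetic tests do and do not show

The generators emulate the mechanical observables only: smooth
zero-net-force traction with a known transjunctional component,
half-space elasticity, Gaussian bead optics and additive Gaussian
noise, rigid junction drift, and prescribed inter-channel correlation.
They do not emulate cell-shape irregularity, traction dynamics within a
frame, bead polydispersity or photobleaching, out-of-plane (z)
displacements, finite gel thickness, or segmentation error in the cell
masks — so passing tests certify the analysis chain on data obeying the
stated physics, not the upstream imaging or segmentation steps of a
real experiment. Problem sizes used throughout (128–256 px fields,
~3000–6500 beads, 41-node strip, 12×12 solver cross-checks) were chosen
so the full verification cycle runs in well under a minute on one CPU
while keeping every estimate's sampling error far below the tolerances
tested.

## Known limitations

- Single-pass PIV with a fixed window: no iterative window deformation,
  no multi-frame optical flow, 2D in-plane only.
- FTTC and the forward model assume an infinite half-space and
  spatially uniform stiffness.
- BISM returns a point MAP estimate; no posterior uncertainty, no
  curved-boundary domains, single-doublet scale only.
- The junction decomposition assumes a roughly straight junction and
  user-supplied (or synthetic) masks; no automatic segmentation.
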