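# Methods

This note documents the models, numerical choices and validation design
behind `tfmkit`, including the places where the design was genuinely
open and a choice had to be made.

## Coordinate and sign conventions

Images and fields are row-major arrays; `x` is the column index, `y` the
row index, origin top-left, `y` positive downward; fields are sampled at
pixel/grid-cell centers. Displacement fields map *relaxed* to *tensed*
coordinates: `u(x)` is where the material imaged at relaxed position `x`
moved to. Tractions are the stresses the cell exerts on the substrate
(Pa); sheet stress is in N/m with tension positive.

## Displacement

Drift between the two acquisitions is estimated by phase
cross-correlation of the whole pair with 10× Fourier upsampling
(≈0.1 px resolution), removed by spline interpolation, and both images
are cropped by ⌈|shift|⌉ pixels on the trailing edges so only the common
field of view remains.

TV-L1 optical flow minimizes an L1 brightness-constancy data term plus
total-variation smoothness on a coarse-to-fine pyramid. Parameters
(`FlowParams`): `lam` — the data weight, typical range 0.01–1.0, smaller
values smooth more (default 0.1); `n_scales` (4) and `scale_step` (0.5)
— pyramid depth and decimation; `warps` (5) — relinearizations per
level; `epsilon` (0.01) — the per-warp stopping tolerance; `n_iter` (10)
— inner iterations per warp. Images are normalized to [0, 1] per image
before flow. The quoted `lam` range follows the convention of solvers
operating on 8-bit-scaled intensities; internally it is mapped to the
attachment weight of the [0, 1]-scale solver as `attachment = 100·lam`.
Flow values within one base pyramid window of the border are flagged in
a mask but kept.

An optional component-wise median filter exists but is off everywhere by
default. `subsample_field` block-averages a field onto a coarser grid
(each output sample is the mean of a `step × step` block, located at the
block center); it is the standard grid-preparation step before FTTC and
reduces uncorrelated flow noise by the block size.

## FTTC

With the substrate a linear elastic half-space, the surface response to
a tangential traction of wavevector **k** is diagonal in the basis
(k̂, k̂⊥):

    g∥ = 2(1+ν)(1−ν)/(E k),    g⊥ = 2(1+ν)/(E k)     [µm/Pa]

(the Fourier transform of the Boussinesq/Cerruti surface kernel). No
1/(1−2ν) factor appears, so ν = ½ is regular. The k = 0 mode carries no
traction information; the mean displacement is removed and the DC
traction set to zero (net-force-free convention).

*Forward map*: tractions are zero-padded to twice the linear size,
multiplied by G(k), inverse-transformed and cropped — the exact model
used both for ground-truth generation and GCV. *Inverse*: per
wavevector `t = g/(g² + λ)·u` in the eigenbasis; the displacement is
edge-extended with a Hann taper into the padding ring before the FFT to
suppress wrap-around. λ carries units (µm/Pa)².

*GCV*: `V(λ) = ‖(I−A)u‖²/tr(I−A)²` with `A = g²/(g²+λ)` evaluated on
the padded spectra; the default grid is 20 log-spaced points over
[1e−6, 1e2] × median(g⊥)², and a boundary minimum warns. On noise-free
synthetic data the minimum sits at the lower grid edge by construction
(nothing to suppress); the solver floors λ at 1e−16 in that case.

*Finite thickness*: for a gel of thickness h bonded to a rigid support
the tangential response is attenuated by
`f(s) = (sinh 2s − 2s)/(cosh 2s + 2s² + 1)`, s = kh — the incompressible
bonded-layer result — applied isotropically. It satisfies the physical
limits (→1 for kh ≫ 1, →0 like s³ for kh → 0, monotone in h) through
which it is validated.

*Lanczos filter*: separable `[sinc(kx/kN)·sinc(ky/kN)]^p` with kN the
Nyquist wavevector; p = 0 is the identity, DC gain is 1, and signal
power never increases. Applied to tractions after inversion (the
alternative — filtering displacements before inversion — differs only
by commuting diagonal operators at fixed λ, but would change the GCV
input; post-inversion keeps the selector's data model clean).

## MSM

Equilibrium of a thin sheet bonded to the substrate reads
`div σ = T`. FTTC guarantees only global balance, so before solving, a
uniform offset (net force over mask area) and a rigid-rotation field
(net torque about the mask centroid) are subtracted inside the mask;
the correction magnitudes are reported as a quality metric.

The mask boundary is extracted as a polygon (holes preserved), lightly
simplified, resampled at the target edge length; the interior is filled
with a hexagonal lattice and triangulated by Delaunay restricted to the
polygon. Elements are 3-node linear triangles (constant strain). Grid
tractions are transferred conservatively: each grid cell deposits its
force `−T·d²` onto the containing triangle's nodes with barycentric
weights — exact total-force transfer even for load bands narrower than
an element (centroid-sampling quadrature, the obvious alternative,
loses force exactly there, which the square-plate benchmark's one-cell
edge bands expose). Residual net force/torque in the assembled load
vector is projected out, after which the three minimal rigid-body
constraints (one node pinned in x and y, the farthest node in y) do not
influence the stress — verified by a node-permutation test. Element
stresses `σ = D B u` are averaged to nodes with area weights. Because
the loads are self-equilibrated, the recovered stress is independent of
the assumed sheet modulus (machine precision) and changes < 2% between
ν_sheet 0.3 and 0.5; ν_sheet defaults to 0.5.

## Synthetic ground truth

*Dipoles* — two force dipoles with a common center, rotated 90° apart:
poles are disks of radius 3 µm separated by 30 µm (the H-pattern doublet
scale; the separation is not a printed quantity and is config-exposed),
uniform traction pointing inward, per-disk force = total/2 exactly on
the discrete grid, so the field is force-free to round-off. Total
forces 0.0025/0.025/0.25 µN on E = 20 kPa, ν = 0.5 substrate produce
peak displacements of ≈0.12/1.2/12 px at 0.108 µm/px — spanning the
sub-pixel, optimal (1–10 px) and large-displacement regimes.

*Bead images* — Gaussian spots (σ = 0.15 µm) at uniform random
positions, Poisson count at 1.0 beads/µm² (≈1 µm mean spacing, typical
of high-magnification TFM substrates; much sparser fields leave dense
optical flow without texture to track), amplitudes 4000–8000 counts on
a 100-count background, Poisson shot noise plus Gaussian read noise
(σ = 10) per acquisition — the tensed frame is the warped relaxed frame
re-noised independently, as two camera exposures are. Warping inverts
`X + u(X) = x` by fixed-point iteration so the rendered pair is
consistent with the ground-truth field beyond first order.

*Square plate* — inward uniform traction bands one grid cell wide along
the four edges of a 60 µm square; integrating equilibrium across a band
gives constant interior stress σxx = σyy = the line load, σxy = 0, with
linear ramps across the bands. Correlations against this closed form
are computed over the full raster canvas (recovered stress rasterized
from the mesh, zero outside; analytic field zero outside the plate),
i.e. between stress *maps* — the interior is constant, so node-level
correlation would measure only the edge ramp and mean nothing. Interior
accuracy is scored separately as mean relative error > 2 cells from the
bands.

*Active cell* — a round cell (R = 25 µm) of plane-stress sheet
stiffness hc·Ec (hc = 1 µm, Ec = 10 kPa, νc = 0.5) carries a constant
isotropic active stress `hc·Ec/(2(1−νc))·P0` and adheres through an
elastic foundation `t = Ys·u` (Ys = 1000 Pa/µm) on 19 islands of radius
2.5 µm at 90% of the cell radius. These parameters are representative of
contour-model studies of strongly adherent contractile cells, not
canonical values, and are config-exposed. With P0 = 0.6 the free
contraction would be 30%; the islands restrain it to an ≈18% area
shrink. The contraction is finite, so the static problem is solved by
fixed-point iteration on the geometry — stiffness and active loads
reassembled on the current configuration, foundation springs anchored
at the material island sites, relaxation 0.7, convergence when the
update falls below 1e−5 µm, with element inversion or iteration
exhaustion raising an error that reports the residual. Outputs (deformed
shape, internal stress = elastic + active, foundation tractions
rasterized conservatively through subdivided elements) all live on the
deformed configuration, which is what a microscope would see.

## Validation protocol and what it shows

The end-to-end dipole benchmark renders beads at 512² (55 µm field),
runs TV-L1 (5 scales, 10 warps, 20 inner iterations) with the data
weight adapted to the displacement regime as the method's own guidance
prescribes — 0.02 (low: sub-pixel, noise-limited), 0.15 (medium), 0.3
(high: large, clear displacements) — then block-averages 8× and inverts
with GCV. Scores at these settings: displacement correlations ≈0.93
(low) and ≈0.99 (medium/high); medium-force DTM ≈ −0.13, DTPS ≈ 0.05,
DTA ≈ 3°; low-force DTM ≈ −0.14.

Passing these benchmarks shows the pipeline recovers fields generated by
its own forward model under realistic sampling and camera noise. It
does not probe real-data complications the generator omits: non-Gaussian
bead shapes and aggregates, uneven illumination, focus drift, spherical
aberration at field edges, photobleaching, or reference-image artifacts.
Two systematic gaps against experimental-texture validations are known
and expected: the synthetic speckle is cleaner than real bead images, so
the spurious-background level (DTPS) here is lower than typically
reported, and in the large-force scenario the flow does not break down
(peak displacements stay ≈12 px), so no artifact-driven background
appears. For the active cell, handing the simulation's exact tractions
and deformed mask to MSM recovers the stress nearly exactly (the
equilibrium stress field under prescribed tractions on a simply
connected domain is almost independent of the constitutive constants);
correlations of 0.92–0.97 and a −3…−5% high-stress bias here measure
discretization smoothing of the island stress peaks, not a fundamental
MSM error. Degradation to ~0.9 correlations appears when the MSM mesh is
coarsened relative to the island scale.

## Numerical details and degenerate inputs

- Constant images cannot be registered and raise; non-finite intensities
  or displacements raise.
- Padded FFT size is twice the linear grid size; the round trip
  forward → inverse at λ → 0 is exact for periodic band-limited
  tractions and ≈2% for localized tractions under windowing.
- Drift shifts larger than half the field warn but are applied.
- Meshing rejects edge lengths below 2 pixels and element counts beyond
  a configurable cap; meshes must be a single connected component.
- GCV grids must be sorted, ≥ 2 points; boundary minima warn.
- Batch runs hold λ fixed across frames (selected on the first frame)
  unless per-frame GCV is explicitly requested, which warns: comparisons
  across conditions are only meaningful under consistent regularization.
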