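# tfmkit

Headless traction force microscopy (TFM) and monolayer stress microscopy
(MSM) in Python: from fluorescent-bead substrate images to cellular
traction fields and internal sheet stress, with a full synthetic
ground-truth benchmark suite.

Adherent cells pull on their substrate. On a linear elastic gel with
embedded fiducial beads, comparing a *tensed* image (cell attached) with
a *relaxed* reference (cell removed) reveals the substrate deformation,
from which the traction the cell exerted can be reconstructed; force
balance on the cell sheet then yields its internal stress. `tfmkit`
implements this pipeline for people who quantify cell mechanics —
single cells, doublets on micropatterns, small monolayers — and for
method developers who need a transparent, scriptable reference
implementation with exact forward models to test against.

## Methods

**Displacement** — global drift is removed by upsampled phase
cross-correlation; the deformation field is then recovered with TV-L1
optical flow (L1 brightness constancy + total-variation smoothness,
coarse-to-fine pyramid), giving dense sub-pixel displacements
`u(x)` mapping relaxed to tensed coordinates.

**Traction (FTTC)** — on an elastic half-space the surface displacement
is a convolution of the traction with the Boussinesq Green's function,
diagonal per wavevector **k** in Fourier space:

```
u(k) = G(k) t(k),   G(k) = 2(1+ν)/(E k³) · [k² I − ν k kᵀ]
```

with Young's modulus `E`, Poisson ratio `ν` (the incompressible case
ν = ½ is regular). The ill-posed inversion is stabilized by Tikhonov
regularization, `t(k) = G/(G² + λ) u(k)`, with λ chosen manually or by
generalized cross-validation (GCV); an optional finite-thickness
correction handles gels bonded to glass, and a Lanczos (sinc-window)
filter provides additional smoothing.

**Monolayer stress (MSM)** — the cell sheet is modeled as a thin elastic
plate in equilibrium with the substrate, `∂σᵢⱼ/∂xⱼ = Tᵢ` (sheet stress σ
in N/m, tension positive). Residual net force and torque are corrected,
the cell mask is triangulated, and a plane-stress linear FEM recovers
the per-node stress tensor — a result independent of the assumed sheet
modulus and only weakly dependent on its Poisson ratio.

**Synthetic truth** — generators for (i) contractile force-dipole pairs
(the traction pattern of a cell doublet on an H-pattern) with exact
forward-simulated displacements and rendered/warped bead images, (ii) a
uniformly edge-loaded square plate with closed-form constant interior
stress, and (iii) an actively contracting elastic cell adhering at 19
peripheral islands, solved to force balance by FEM. Standard error
metrics (magnitude correlation, DTM, DTPS, DTA, magnitude-binned
relative error) score every stage.

## Worked example

`examples/02_traction_reconstruction.py` builds the medium-force dipole
(two 90°-rotated dipoles, 3 µm disks, 0.025 µN total, E = 20 kPa,
ν = 0.5), forward-simulates displacements, adds 2% noise and inverts:

```
GCV-selected lambda: 7.964e-10 (µm/Pa)²
traction magnitude correlation: 0.926
DTM  -0.069   (signed error of mean in-disk traction)
DTPS 0.112    (spurious background / in-disk mean)
DTA  4.44 deg (direction error inside the disks)
```

DTM near zero means the in-disk traction magnitude is recovered almost
unbiased; DTPS is the spurious traction left outside the true force
regions relative to the in-disk mean; DTA is the mean angular error of
the recovered force directions. The other examples cover displacement
recovery from bead images (01), the square-plate MSM benchmark (03), the
active-cell validation (04) and the batch pipeline/CLI layout (05).

A thin CLI wraps the same functions:

```bash
tfm displace --tensed beads.tif --relaxed ref.tif --pixel-size 0.108 --out out/
tfm traction --disp out/displacement_000.tif --e 20000 --nu 0.5 --gcv --out out/
tfm stress   --traction out/traction.tif --mask mask.tif --out out/
tfm validate --scenario dipole-mid --seed 0 --out val/
tfm run      --config config.yaml
```

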