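"""Dense substrate displacement from tensed/relaxed bead-image pairs.

Drift between the two acquisitions is removed first by upsampled phase
cross-correlation; the residual deformation is then recovered with TV-L1
optical flow on a multi-scale pyramid.

Direction convention: the returned field maps *relaxed* coordinates to
*tensed* coordinates, i.e. ``(u(x, y), v(x, y))`` is the displacement, in
pixels, of the substrate material imaged at relaxed-state position
``(x, y)``.  Equivalently ``tensed(x + u, y + v) ≈ relaxed(x, y)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import partial

import numpy as np
import scipy.ndimage as ndi
from skimage.registration import phase_cross_correlation
from skimage.registration._optical_flow import _tvl1
from skimage.registration._optical_flow_utils import _coarse_to_fine

from .fields import VectorField2D

__all__ = [
    "BeadImagePair",
    "FlowParams",
    "drift_correct",
    "compute_flow",
    "median_filter_field",
    "subsample_field",
]

# Bridge between the λ convention commonly quoted for TV-L1 optical flow
# (data-fidelity weight on 8-bit-scaled intensities, typical range
# 0.01-1.0) and the attachment weight of the solver used here, which
# operates on [0, 1]-normalized images.
_LAM_TO_ATTACHMENT = 100.0


@dataclass
class BeadImagePair:
    """A tensed/relaxed bead-image pair with its pixel size (µm/px)."""

    tensed: np.ndarray
    relaxed: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.tensed = np.asarray(self.tensed, dtype=float)
        self.relaxed = np.asarray(self.relaxed, dtype=float)
        if self.tensed.shape != self.relaxed.shape:
            raise ValueError(
                f"image shapes differ: {self.tensed.shape} vs {self.relaxed.shape}"
            )
        if self.tensed.ndim != 2:
            raise ValueError("bead images must be 2D grayscale")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if not (np.isfinite(self.tensed).all() and np.isfinite(self.relaxed).all()):
            raise ValueError("bead images contain non-finite intensities")


@dataclass(frozen=True)
class FlowParams:
    """TV-L1 optical-flow parameters.

    ``lam`` balances data fitting against total-variation smoothness
    (typical 0.01-1.0; smaller = smoother), ``n_scales`` is the number of
    pyramid levels (typical 3-5), ``warps`` the number of refinement
    warps per level, ``epsilon`` the per-warp stopping tolerance and
    ``scale_step`` the size factor between pyramid levels (typical
    0.5-0.8).
    """

    lam: float = 0.1
    n_scales: int = 4
    warps: int = 5
    epsilon: float = 0.01
    scale_step: float = 0.5
    n_iter: int = 10

    def __post_init__(self) -> None:
        if not self.lam > 0:
            raise ValueError("lam must be positive")
        if not 0.0 < self.scale_step < 1.0:
            raise ValueError("scale_step must lie in (0, 1)")
        if self.n_scales < 1 or self.warps < 1:
            raise ValueError("n_scales and warps must be >= 1")


def _normalize(img: np.ndarray) -> np.ndarray:
    lo, hi = float(img.min()), float(img.max())
    if hi == lo:
        raise ValueError("constant image: cannot register or compute flow")
    return (img - lo) / (hi - lo)


def drift_correct(
    pair: BeadImagePair, upsample_factor: int = 10
) -> tuple[BeadImagePair, np.ndarray]:
    """Remove the global rigid drift between tensed and relaxed images.

    The translation of the tensed image relative to the relaxed one is
    estimated by phase cross-correlation of the whole pair (sub-pixel via
    Fourier upsampling), the tensed image is shifted back onto the relaxed
    frame, and both images are cropped to the overlapping field of view.

    Returns
    -------
    (pair, shift)
        The aligned/cropped pair and the estimated shift ``(dx, dy)`` of
        the tensed image relative to the relaxed one, in pixels.
    """
    relaxed = _normalize(pair.relaxed)
    tensed = _normalize(pair.tensed)
    # skimage returns the (row, col) shift that maps the moving image onto
    # the reference; the drift of tensed relative to relaxed is its negative.
    shift_rc, _, _ = phase_cross_correlation(
        relaxed, tensed, upsample_factor=upsample_factor
    )
    drift = np.array([-shift_rc[1], -shift_rc[0]])  # (dx, dy)

    ny, nx = pair.tensed.shape
    if abs(drift[0]) > nx / 2 or abs(drift[1]) > ny / 2:
        warnings.warn(
            f"estimated drift {drift} exceeds half the field of view; "
            "applying anyway",
            stacklevel=2,
        )

    if np.allclose(drift, 0.0):
        return BeadImagePair(pair.tensed.copy(), pair.relaxed.copy(), pair.pixel_size), drift

    # content of tensed sits at +drift relative to relaxed; shift it back
    aligned = ndi.shift(pair.tensed, (-drift[1], -drift[0]), order=3, mode="nearest")

    # Crop ceil(|shift|) pixels from the edges where data was pulled in
    # from outside the field of view (both images cropped identically).
    cx, cy = int(np.ceil(abs(drift[0]))), int(np.ceil(abs(drift[1])))
    xs = slice(0, nx - cx) if drift[0] > 0 else slice(cx, nx)
    ys = slice(0, ny - cy) if drift[1] > 0 else slice(cy, ny)
    out = BeadImagePair(aligned[ys, xs], pair.relaxed[ys, xs].copy(), pair.pixel_size)
    return out, drift


def compute_flow(pair: BeadImagePair, params: FlowParams | None = None) -> VectorField2D:
    """Dense TV-L1 optical flow of a (drift-corrected) bead-image pair.

    The caller is responsible for drift correction (see
    :func:`drift_correct`); residual global translation is otherwise
    absorbed into the deformation field.  Images are intensity-normalized
    to [0, 1] per image before flow computation.

    Returns a pixel-valued :class:`VectorField2D` mapping relaxed to
    tensed coordinates, with a ``border`` mask in ``meta`` flagging
    samples within one base pyramid window of the image edge.
    """
    if params is None:
        params = FlowParams()
    relaxed = _normalize(pair.relaxed).astype(np.float32)
    tensed = _normalize(pair.tensed).astype(np.float32)

    solver = partial(
        _tvl1,
        attachment=params.lam * _LAM_TO_ATTACHMENT,
        tightness=0.3,
        num_warp=params.warps,
        num_iter=params.n_iter,
        tol=params.epsilon,
        prefilter=True,
    )
    flow = _coarse_to_fine(
        relaxed,
        tensed,
        solver,
        downscale=1.0 / params.scale_step,
        nlevel=params.n_scales,
        min_size=16,
    )
    v, u = flow[0].astype(float), flow[1].astype(float)

    border = np.zeros(u.shape, dtype=bool)
    margin = max(4, int(round(1.0 / params.scale_step)) * 4)
    border[:margin, :] = border[-margin:, :] = True
    border[:, :margin] = border[:, -margin:] = True
    return VectorField2D(
        u,
        v,
        spacing=pair.pixel_size,
        units="px",
        meta={"params": params, "border": border},
    )


def median_filter_field(field: VectorField2D, window: int) -> VectorField2D:
    """Component-wise median filtering of a vector field (optional
    post-processing; not applied by default anywhere in the pipeline)."""
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    out = field.copy()
    out.u = ndi.median_filter(field.u, size=window)
    out.v = ndi.median_filter(field.v, size=window)
    return out


def subsample_field(field: VectorField2D, step: int) -> VectorField2D:
    """Block-average a field onto a coarser regular grid.

    Each output sample is the mean of a ``step``×``step`` block, so it sits
    at the block center; ``spacing`` is multiplied by ``step``.  Trailing
    rows/columns that do not fill a block are dropped.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    ny, nx = field.shape
    if step > min(ny, nx):
        raise ValueError("step exceeds field extent")
    if step == 1:
        return field.copy()
    my, mx = ny // step, nx // step

    def block(a: np.ndarray) -> np.ndarray:
        return a[: my * step, : mx * step].reshape(my, step, mx, step).mean(axis=(1, 3))

    return VectorField2D(
        block(field.u),
        block(field.v),
        spacing=field.spacing * step,
        units=field.units,
        meta=dict(field.meta, subsample_step=step),
    )
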