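"""Fourier Transform Traction Cytometry (FTTC).

Relates surface displacements of a linear elastic substrate to the
tractions that caused them through the Boussinesq half-space Green's
function, which is diagonal per wavevector in Fourier space.  Provides
the exact forward map (tractions → displacements), the Tikhonov-
regularized inverse, generalized cross-validation (GCV) for the
regularization parameter, an optional finite-thickness correction and a
Lanczos low-pass filter.

Units: displacements in µm, tractions in Pa, wavevectors in 1/µm, so the
Green's tensor has units µm/Pa and the Tikhonov parameter λ units
(µm/Pa)².

For a tangential surface traction with in-plane wavevector **k** on a
half-space (Young's modulus E, Poisson ratio ν) the surface response is

    G(k) = 2(1+ν) / (E k³) · [k² I − ν k kᵀ]

with eigenvalues 2(1+ν)(1−ν)/(E k) along k̂ and 2(1+ν)/(E k) across it.
The incompressible case ν = 1/2 is perfectly regular here (no 1/(1−2ν)
factor appears in the surface kernel).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fields import ElasticSubstrate, VectorField2D

__all__ = [
    "RegularizationChoice",
    "greens_tensor_fourier",
    "finite_thickness_correction",
    "forward_displacement",
    "fttc_solve",
    "gcv_select_lambda",
    "lanczos_filter",
]


@dataclass
class RegularizationChoice:
    """Tikhonov regularization: fixed ``lam`` (``mode="manual"``) or
    data-driven selection over ``lam_grid`` (``mode="gcv"``)."""

    mode: str = "gcv"
    lam: float | None = None
    lam_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("manual", "gcv"):
            raise ValueError("mode must be 'manual' or 'gcv'")
        if self.mode == "manual":
            if self.lam is None or not self.lam > 0:
                raise ValueError("manual mode requires lam > 0")
        if self.lam_grid is not None:
            g = np.asarray(self.lam_grid, dtype=float)
            if np.any(np.diff(g) <= 0):
                raise ValueError("lam_grid must be sorted ascending")
            self.lam_grid = g


def _thickness_factor(k: np.ndarray, thickness: float) -> np.ndarray:
    """Attenuation of the tangential surface response for an elastic layer
    of finite thickness bonded to a rigid support, relative to the
    half-space response.

    For the incompressible layer the exact tangential point-load response
    carries the factor

        f(s) = (sinh 2s − 2s) / (cosh 2s + 2s² + 1),      s = k·h,

    which tends to 1 for k·h ≫ 1 (short wavelengths never feel the rigid
    base) and to 0 like s³ for k·h → 0 (long wavelengths are fully
    suppressed).  It is applied here as an isotropic multiplicative
    correction per wavevector.
    """
    s = np.minimum(k * thickness, 20.0)  # f(20) == 1 to double precision
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (np.sinh(2 * s) - 2 * s) / (np.cosh(2 * s) + 2 * s**2 + 1)
    return np.where(s > 0, f, 0.0)


def _kernel_eigenvalues(
    kx: np.ndarray, ky: np.ndarray, substrate: ElasticSubstrate
) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (g_parallel, g_perpendicular) of G(k) in µm/Pa.

    The zero mode is set to 0: a uniform displacement carries no traction
    information, so the mean is removed before solving and the DC traction
    is fixed at zero (net-force-free convention).
    """
    k = np.hypot(kx, ky)
    with np.errstate(divide="ignore"):
        g_perp = np.where(k > 0, 2.0 * (1.0 + substrate.nu) / (substrate.E * np.where(k > 0, k, 1.0)), 0.0)
    g_par = g_perp * (1.0 - substrate.nu)
    if substrate.thickness is not None:
        f = _thickness_factor(k, substrate.thickness)
        g_par = g_par * f
        g_perp = g_perp * f
    return g_par, g_perp


def greens_tensor_fourier(
    kx: np.ndarray, ky: np.ndarray, substrate: ElasticSubstrate
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boussinesq surface Green's tensor in Fourier space.

    Parameters
    ----------
    kx, ky : ndarray
        Angular wavevector components (1/µm), broadcastable.
    substrate : ElasticSubstrate

    Returns
    -------
    (Gxx, Gxy, Gyy) : ndarray
        Tensor components in µm/Pa; the (symmetric) tensor per wavevector
        is ``[[Gxx, Gxy], [Gxy, Gyy]]``.  The k = 0 entry is 0 by
        convention.
    """
    kx = np.asarray(kx, dtype=float)
    ky = np.asarray(ky, dtype=float)
    k = np.hypot(kx, ky)
    g_par, g_perp = _kernel_eigenvalues(kx, ky, substrate)
    with np.errstate(invalid="ignore", divide="ignore"):
        ex = np.where(k > 0, kx / np.where(k > 0, k, 1.0), 0.0)
        ey = np.where(k > 0, ky / np.where(k > 0, k, 1.0), 0.0)
    # G = g_perp I + (g_par - g_perp) k̂ k̂ᵀ
    gxx = g_perp + (g_par - g_perp) * ex * ex
    gyy = g_perp + (g_par - g_perp) * ey * ey
    gxy = (g_par - g_perp) * ex * ey
    return gxx, gxy, gyy


def finite_thickness_correction(
    kx: np.ndarray, ky: np.ndarray, thickness: float, substrate: ElasticSubstrate
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Green's tensor corrected for a substrate of finite ``thickness``
    (µm) bonded to a rigid support; converges to the half-space tensor as
    thickness → ∞."""
    if not thickness > 0:
        raise ValueError("thickness must be positive")
    sub = ElasticSubstrate(substrate.E, substrate.nu, thickness)
    return greens_tensor_fourier(kx, ky, sub)


def _wavevectors(shape: tuple[int, int], spacing: float) -> tuple[np.ndarray, np.ndarray]:
    ny, nx = shape
    kx = 2.0 * np.pi * np.fft.fftfreq(nx, d=spacing)
    ky = 2.0 * np.pi * np.fft.fftfreq(ny, d=spacing)
    return np.meshgrid(kx, ky)


def _pad_widths(shape: tuple[int, int]) -> tuple[tuple[int, int], tuple[int, int]]:
    # pad to 2x linear size
    return ((shape[0] // 2, shape[0] - shape[0] // 2),
            (shape[1] // 2, shape[1] - shape[1] // 2))


def _taper_pad(a: np.ndarray) -> np.ndarray:
    """Pad to twice the linear size, extending edge values and tapering
    them smoothly (Hann ramp) to zero, to suppress periodic wrap-around."""
    pw = _pad_widths(a.shape)
    out = np.pad(a, pw, mode="edge")
    win = []
    for (lo, hi), n in zip(pw, a.shape):
        w = np.ones(lo + n + hi)
        if lo:
            ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(lo) / lo))
            w[:lo] = ramp
        if hi:
            ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(hi) / hi))
            w[-hi:] = ramp[::-1]
        win.append(w)
    return out * np.outer(win[0], win[1])


def _crop(a: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    pw = _pad_widths(shape)
    return a[pw[0][0] : pw[0][0] + shape[0], pw[1][0] : pw[1][0] + shape[1]]


def _to_eigenbasis(fu, fv, kx, ky):
    k = np.hypot(kx, ky)
    ex = np.where(k > 0, kx / np.where(k > 0, k, 1.0), 1.0)
    ey = np.where(k > 0, ky / np.where(k > 0, k, 1.0), 0.0)
    f_par = ex * fu + ey * fv
    f_perp = -ey * fu + ex * fv
    return f_par, f_perp, ex, ey


def forward_displacement(
    traction: VectorField2D, substrate: ElasticSubstrate, pad: bool = True
) -> VectorField2D:
    """Exact forward map: substrate surface displacement (µm) produced by
    a traction field (Pa) on a regular grid.

    Tractions are zero-padded to twice the linear size before the FFT to
    suppress periodic wrap-around, and the result is cropped back.
    """
    if traction.units and traction.units != "Pa":
        raise ValueError("traction field must be in Pa")
    shape = traction.shape
    if pad:
        pw = _pad_widths(shape)
        tx = np.pad(traction.u, pw)
        ty = np.pad(traction.v, pw)
    else:
        tx, ty = traction.u, traction.v
    kx, ky = _wavevectors(tx.shape, traction.spacing)
    g_par, g_perp = _kernel_eigenvalues(kx, ky, substrate)
    ftx, fty = np.fft.fft2(tx), np.fft.fft2(ty)
    t_par, t_perp, ex, ey = _to_eigenbasis(ftx, fty, kx, ky)
    u_par = g_par * t_par
    u_perp = g_perp * t_perp
    fu = ex * u_par - ey * u_perp
    fv = ey * u_par + ex * u_perp
    u = np.fft.ifft2(fu).real
    v = np.fft.ifft2(fv).real
    if pad:
        u, v = _crop(u, shape), _crop(v, shape)
    return VectorField2D(u, v, traction.spacing, "um", {"substrate": substrate})


def _spectrum(disp: VectorField2D, pad: bool):
    """Demeaned, (optionally) taper-padded displacement spectrum and the
    matching kernel eigen-spectra."""
    u = disp.u - disp.u.mean()
    v = disp.v - disp.v.mean()
    if pad:
        u, v = _taper_pad(u), _taper_pad(v)
    kx, ky = _wavevectors(u.shape, disp.spacing)
    fu, fv = np.fft.fft2(u), np.fft.fft2(v)
    u_par, u_perp, ex, ey = _to_eigenbasis(fu, fv, kx, ky)
    return u_par, u_perp, ex, ey, kx, ky


def gcv_select_lambda(
    disp: VectorField2D,
    substrate: ElasticSubstrate,
    lam_grid: np.ndarray | None = None,
    pad: bool = True,
) -> tuple[float, np.ndarray]:
    """Select the Tikhonov parameter by generalized cross-validation.

    Minimizes ``V(λ) = ‖(I − A(λ)) u‖² / tr(I − A(λ))²`` where
    ``A(λ) = G²/(G² + λ)`` is the Fourier-diagonal influence operator of
    the regularized inverse.  Returns the minimizing λ and the full GCV
    curve (one value per grid point); warns when the minimum sits on the
    grid boundary.
    """
    u_par, u_perp, _, _, kx, ky = _spectrum(disp, pad)
    g_par, g_perp = _kernel_eigenvalues(kx, ky, substrate)
    if lam_grid is None:
        scale = float(np.median(g_perp[g_perp > 0]) ** 2)
        lam_grid = scale * np.logspace(-6, 2, 20)
    lam_grid = np.asarray(lam_grid, dtype=float)
    if lam_grid.size < 2:
        raise ValueError("lam_grid needs at least 2 candidates")

    nonzero = (g_par > 0)  # excludes only the k = 0 mode
    p2 = np.abs(u_par[nonzero]) ** 2
    q2 = np.abs(u_perp[nonzero]) ** 2
    gp2 = g_par[nonzero] ** 2
    gq2 = g_perp[nonzero] ** 2

    curve = np.empty(lam_grid.size)
    for i, lam in enumerate(lam_grid):
        rp = lam / (gp2 + lam)
        rq = lam / (gq2 + lam)
        num = np.sum(rp**2 * p2) + np.sum(rq**2 * q2)
        den = (np.sum(rp) + np.sum(rq)) ** 2
        curve[i] = num / den
    i_star = int(np.argmin(curve))
    if i_star in (0, lam_grid.size - 1):
        warnings.warn(
            "GCV minimum at the edge of the lambda grid; widen the grid",
            stacklevel=2,
        )
    return float(lam_grid[i_star]), curve


def fttc_solve(
    disp: VectorField2D,
    substrate: ElasticSubstrate,
    reg: RegularizationChoice | None = None,
    pad: bool = True,
) -> VectorField2D:
    """Tikhonov-regularized FTTC inversion of a displacement field (µm).

    Per wavevector ``t(k) = G/(G² + λ) · u(k)`` in the kernel eigenbasis;
    the mean displacement is removed first and the k = 0 traction is fixed
    at zero (net-force-free convention), so global force balance holds
    over the full field.  The λ actually used is recorded in
    ``meta["lam"]``.
    """
    if disp.units == "px":
        raise ValueError("displacement must be converted to µm (see to_um)")
    if not (np.isfinite(disp.u).all() and np.isfinite(disp.v).all()):
        raise ValueError("displacement contains non-finite values")
    if reg is None:
        reg = RegularizationChoice()
    if reg.mode == "gcv":
        lam, curve = gcv_select_lambda(disp, substrate, reg.lam_grid, pad=pad)
    else:
        lam, curve = float(reg.lam), None
    if not lam > 0:
        raise ValueError("lambda must be positive")

    u_par, u_perp, ex, ey, kx, ky = _spectrum(disp, pad)
    g_par, g_perp = _kernel_eigenvalues(kx, ky, substrate)
    t_par = g_par / (g_par**2 + lam) * u_par
    t_perp = g_perp / (g_perp**2 + lam) * u_perp
    t_par[(g_par == 0)] = 0.0
    t_perp[(g_perp == 0)] = 0.0
    ftx = ex * t_par - ey * t_perp
    fty = ey * t_par + ex * t_perp
    tx = np.fft.ifft2(ftx).real
    ty = np.fft.ifft2(fty).real
    if pad:
        tx, ty = _crop(tx, disp.shape), _crop(ty, disp.shape)
    return VectorField2D(
        tx,
        ty,
        disp.spacing,
        "Pa",
        {"lam": lam, "gcv_curve": curve, "substrate": substrate, "mode": reg.mode},
    )


def lanczos_filter(field: VectorField2D, exponent: float) -> VectorField2D:
    """Fourier-domain Lanczos (separable sinc-window) low-pass filter.

    Multiplies the spectrum by ``[sinc(kx/kmax) · sinc(ky/kmax)]^p`` with
    kmax the Nyquist wavevector; exponent 0 is the identity and larger
    exponents smooth more strongly.  DC gain is 1 and total signal power
    never increases.
    """
    if exponent < 0:
        raise ValueError("exponent must be non-negative")
    if exponent == 0:
        return field.copy()
    kx, ky = _wavevectors(field.shape, field.spacing)
    kmax = np.pi / field.spacing
    w = (np.abs(np.sinc(kx / kmax)) * np.abs(np.sinc(ky / kmax))) ** exponent
    out = field.copy()
    out.u = np.fft.ifft2(np.fft.fft2(field.u) * w).real
    out.v = np.fft.ifft2(np.fft.fft2(field.v) * w).real
    out.meta["lanczos_exponent"] = exponent
    return out
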