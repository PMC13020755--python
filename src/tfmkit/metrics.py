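"""Validation statistics for reconstructed vector fields.

Conventions (documented because several variants circulate in the TFM
literature):

* correlations are Pearson r of the pooled vector *magnitudes* of the
  two fields, matching the scalar per-scenario values usually reported;
* DTM (deviation of traction magnitude) is the signed relative deviation
  of the mean reconstructed magnitude from the mean ground-truth
  magnitude inside the force-bearing region;
* DTPS (traction in surrounding regions; also written DTMS) is the mean
  reconstructed magnitude *outside* that region divided by the mean
  ground-truth magnitude inside it — spurious background traction;
* DTA (deviation of traction angle) is the ground-truth-magnitude-
  weighted mean angle between reconstructed and true vectors inside the
  region, in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import VectorField2D

__all__ = [
    "TractionScore",
    "field_correlation",
    "relative_error_binned",
    "traction_scores",
]


@dataclass(frozen=True)
class TractionScore:
    corr: float
    dtm: float
    dtps: float
    dta: float  # degrees

    def as_dict(self) -> dict[str, float]:
        return {"corr": self.corr, "dtm": self.dtm, "dtps": self.dtps, "dta": self.dta}


def field_correlation(a: VectorField2D, b: VectorField2D) -> float:
    """Pearson correlation of the pooled vector magnitudes of two fields."""
    if a.shape != b.shape:
        raise ValueError("fields must share a grid")
    ma, mb = a.magnitude().ravel(), b.magnitude().ravel()
    if np.ptp(ma) == 0 or np.ptp(mb) == 0:
        raise ValueError("correlation undefined for a constant-magnitude field")
    return float(np.corrcoef(ma, mb)[0, 1])


def relative_error_binned(
    calc: VectorField2D,
    gt: VectorField2D,
    bins: np.ndarray,
    floor: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean relative magnitude error per bin of ground-truth magnitude.

    ``(|calc| − |gt|) / |gt|`` averaged within each bin of ``|gt|``;
    samples with ``|gt| < floor`` (default 0.05, in the fields' units)
    are excluded.  Empty bins are NaN, not zero.

    Returns ``(bin_centers, mean_relative_error)``.
    """
    if calc.shape != gt.shape:
        raise ValueError("fields must share a grid")
    bins = np.asarray(bins, dtype=float)
    mc, mg = calc.magnitude().ravel(), gt.magnitude().ravel()
    keep = mg >= floor
    mc, mg = mc[keep], mg[keep]
    rel = (mc - mg) / mg
    idx = np.digitize(mg, bins) - 1
    out = np.full(len(bins) - 1, np.nan)
    for i in range(len(bins) - 1):
        sel = idx == i
        if sel.any():
            out[i] = rel[sel].mean()
    centers = 0.5 * (bins[:-1] + bins[1:])
    return centers, out


def traction_scores(
    calc: VectorField2D, gt: VectorField2D, force_region_mask: np.ndarray
) -> TractionScore:
    """DTM, DTPS and DTA of a reconstructed traction field, plus the
    magnitude correlation, scored against the ground truth inside/outside
    the force-bearing region."""
    if calc.shape != gt.shape or calc.shape != force_region_mask.shape:
        raise ValueError("fields and mask must share a grid")
    m = np.asarray(force_region_mask, dtype=bool)
    if not m.any():
        raise ValueError("empty force-region mask")
    mc, mg = calc.magnitude(), gt.magnitude()

    mean_gt_in = mg[m].mean()
    dtm = (mc[m].mean() - mean_gt_in) / mean_gt_in
    outside = ~m
    dtps = mc[outside].mean() / mean_gt_in if outside.any() else 0.0

    dot = calc.u[m] * gt.u[m] + calc.v[m] * gt.v[m]
    denom = mc[m] * mg[m]
    ok = denom > 0
    cosang = np.clip(dot[ok] / denom[ok], -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    w = mg[m][ok]
    dta = float((w * ang).sum() / w.sum()) if w.sum() > 0 else 0.0

    corr = field_correlation(calc, gt)
    return TractionScore(corr=corr, dtm=float(dtm), dtps=float(dtps), dta=dta)
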