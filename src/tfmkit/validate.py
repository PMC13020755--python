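"""End-to-end validation protocols against synthetic ground truth.

Three benchmarks, each runnable in seconds-to-minutes on one CPU:

* ``run_dipole_validation`` — render beads for a force-dipole scenario,
  recover displacements with TV-L1, invert with GCV-regularized FTTC on
  a block-averaged grid, and score displacement and traction against the
  ground truth (correlation, DTM, DTPS, DTA, binned relative error).
* ``run_square_plate_validation`` — recover the constant interior sheet
  stress of a uniformly edge-loaded square plate by MSM and score it
  against the closed-form solution.
* ``run_active_cell_validation`` — contract the active elastic cell to
  force balance, hand its foundation tractions to MSM on the deformed
  cell mask, and score the recovered stress against the simulation's
  internal stress.

The TV-L1 data-weight λ is adapted to the displacement regime of each
dipole scenario (stronger smoothing for noisy sub-pixel data, more
detail for large clear displacements), as the method's parameter
guidance prescribes; all other choices are fixed across scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .displacement import FlowParams, compute_flow, drift_correct, subsample_field
from .fields import VectorField2D
from .fttc import RegularizationChoice, fttc_solve, gcv_select_lambda
from .mesh import build_mesh
from .metrics import field_correlation, relative_error_binned, traction_scores
from .msm import balance_forces, msm_solve
from .synthetic import (
    ActiveCellParams,
    ValidationScenario,
    make_dipole_scenario,
    simulate_active_cell,
    square_plate_case,
)

__all__ = [
    "DIPOLE_FLOW_LAM",
    "DipoleValidation",
    "PlateValidation",
    "ActiveCellValidation",
    "run_dipole_validation",
    "run_square_plate_validation",
    "run_active_cell_validation",
    "run_scenario",
]

#: TV-L1 data weight per dipole force level (see module docstring)
DIPOLE_FLOW_LAM = {"low": 0.02, "mid": 0.15, "high": 0.3}

#: block-averaging step from the flow grid to the FTTC grid (px)
FTTC_SUBSAMPLE_STEP = 8

#: smallest admissible Tikhonov parameter when GCV hits the grid floor
LAM_FLOOR = 1e-16


@dataclass
class DipoleValidation:
    scenario: ValidationScenario
    displacement: VectorField2D  # recovered, px
    traction: VectorField2D  # recovered, Pa, on the coarse grid
    disp_corr: float
    scores: "object"  # TractionScore
    rel_err_bins: tuple[np.ndarray, np.ndarray]
    lam: float

    def as_records(self) -> list[dict]:
        rows = [
            {"scenario": self.scenario.name, "metric": "disp_corr", "value": self.disp_corr},
            {"scenario": self.scenario.name, "metric": "traction_corr", "value": self.scores.corr},
            {"scenario": self.scenario.name, "metric": "dtm", "value": self.scores.dtm},
            {"scenario": self.scenario.name, "metric": "dtps", "value": self.scores.dtps},
            {"scenario": self.scenario.name, "metric": "dta_deg", "value": self.scores.dta},
            {"scenario": self.scenario.name, "metric": "fttc_lambda", "value": self.lam},
        ]
        centers, errs = self.rel_err_bins
        for c, e in zip(centers, errs):
            rows.append(
                {
                    "scenario": self.scenario.name,
                    "metric": f"rel_err@{c:.2f}px",
                    "value": e,
                }
            )
        return rows


def run_dipole_validation(
    level: str = "mid",
    shape: tuple[int, int] = (512, 512),
    pixel_size: float = 0.108,
    seed: int = 0,
    flow_params: FlowParams | None = None,
    subsample_step: int = FTTC_SUBSAMPLE_STEP,
) -> DipoleValidation:
    """Run the full TFM pipeline on one dipole scenario and score it."""
    sc = make_dipole_scenario(level, shape=shape, pixel_size=pixel_size, seed=seed)
    if flow_params is None:
        flow_params = FlowParams(
            lam=DIPOLE_FLOW_LAM.get(level, 0.1), n_scales=5, warps=10, n_iter=20
        )
    pair, _ = drift_correct(sc.bead_pair)
    flow = compute_flow(pair, flow_params)
    disp_corr = field_correlation(flow, sc.gt_displacement)

    disp_um = flow.to_um(pixel_size)
    disp_c = subsample_field(disp_um, subsample_step)
    gt_t = subsample_field(sc.gt_traction, subsample_step)
    fm = sc.force_mask.astype(float)
    mask_c = (
        subsample_field(
            VectorField2D(fm, fm, pixel_size), subsample_step
        ).u
        >= 0.5
    )
    lam, _ = gcv_select_lambda(disp_c, sc.substrate)
    lam = max(lam, LAM_FLOOR)
    traction = fttc_solve(disp_c, sc.substrate, RegularizationChoice("manual", lam=lam))
    scores = traction_scores(traction, gt_t, mask_c)

    bins = np.array([0.05, 0.3, 1.0, 3.0, 10.0, 30.0])
    rel = relative_error_binned(flow, sc.gt_displacement, bins, floor=0.05)
    return DipoleValidation(
        scenario=sc,
        displacement=flow,
        traction=traction,
        disp_corr=disp_corr,
        scores=scores,
        rel_err_bins=rel,
        lam=lam,
    )


@dataclass
class PlateValidation:
    correlations: dict[str, float]  # per component, over the raster canvas
    mean_rel_err_pct: float  # interior, mean over components
    stress: "object"  # StressField
    case: "object"  # PlateCase

    @property
    def min_corr(self) -> float:
        return min(self.correlations.values())


def run_square_plate_validation(
    side: float = 60.0,
    load: float = 1e-3,
    shape: tuple[int, int] = (128, 128),
    spacing: float = 1.0,
    target_edge_length: float = 2.5,
    nu_sheet: float = 0.5,
) -> PlateValidation:
    """Square-plate MSM benchmark against the closed-form stress.

    Correlations are computed over the full raster canvas (recovered
    stress rasterized from the mesh, zero outside; analytic field zero
    outside the plate) — the natural scoring for stress maps.  The mean
    relative error is computed over the plate interior, more than two
    grid cells away from the loaded edge bands, against the constant
    analytic values.
    """
    case = square_plate_case(side=side, load=load, shape=shape, spacing=spacing)
    bal, _ = balance_forces(case.traction, case.mask.mask)
    mesh = build_mesh(case.mask, target_edge_length=target_edge_length)
    stress = msm_solve(bal, mesh, nu_sheet=nu_sheet)

    grids = stress.to_grid(shape, spacing)
    xx, yy = case.traction.coords()
    ana = case.analytic_stress(np.column_stack([xx.ravel(), yy.ravel()]))
    ana_maps = {
        "sxx": ana[:, 0],
        "syy": ana[:, 1],
        "snormal": 0.5 * (ana[:, 0] + ana[:, 1]),
    }
    corrs = {}
    for name, ana_v in ana_maps.items():
        rec = np.nan_to_num(grids[name]).ravel()
        corrs[name] = float(np.corrcoef(rec, ana_v)[0, 1])

    d = spacing
    interior = (
        (xx > case.x_edges[0] + 2 * d)
        & (xx < case.x_edges[1] - 2 * d)
        & (yy > case.y_edges[0] + 2 * d)
        & (yy < case.y_edges[1] - 2 * d)
    )
    errs = [
        float(np.nanmean(np.abs(grids[n][interior] - case.load)) / case.load)
        for n in ("sxx", "syy", "snormal")
    ]
    return PlateValidation(
        correlations=corrs,
        mean_rel_err_pct=100.0 * float(np.mean(errs)),
        stress=stress,
        case=case,
    )


@dataclass
class ActiveCellValidation:
    correlations: dict[str, float]
    substantial_bias_pct: float  # mean signed rel. error where |gt| > max/2
    result: "object"  # ActiveCellResult
    stress: "object"  # recovered StressField

    @property
    def min_corr(self) -> float:
        return min(self.correlations.values())


def run_active_cell_validation(
    params: ActiveCellParams | None = None,
    sim_edge_length: float = 1.0,
    msm_edge_length: float = 2.5,
    nu_sheet: float = 0.5,
) -> ActiveCellValidation:
    """MSM validation on the contracting active cell.

    The simulation's foundation tractions (on the deformed
    configuration) are balanced, the deformed cell mask is meshed, and
    the plane-stress MSM solution is compared with the simulation's
    internal sheet stress on a common raster: per-component Pearson
    correlations and, over cells where the ground-truth mean normal
    stress exceeds half its maximum, the mean signed relative error of
    the recovered stress magnitude (percent).
    """
    res = simulate_active_cell(params, mesh_edge_length=sim_edge_length)
    bal, _ = balance_forces(res.traction, res.cell_mask)
    mesh = build_mesh(res.cell_mask, target_edge_length=msm_edge_length)
    stress = msm_solve(bal, mesh, nu_sheet=nu_sheet)

    shape = res.traction.shape
    sp = res.traction.spacing
    rec = stress.to_grid(shape, sp)
    gt = res.stress.to_grid(shape, sp)
    ok = np.isfinite(rec["sxx"]) & np.isfinite(gt["sxx"])
    corrs = {
        n: float(np.corrcoef(rec[n][ok], gt[n][ok])[0, 1])
        for n in ("sxx", "syy", "snormal")
    }
    gtm = np.abs(gt["snormal"])
    sel = ok & (gtm > 0.5 * np.nanmax(gtm))
    bias = float(
        np.mean((np.abs(rec["snormal"][sel]) - gtm[sel]) / gtm[sel]) * 100.0
    )
    return ActiveCellValidation(
        correlations=corrs, substantial_bias_pct=bias, result=res, stress=stress
    )


def run_scenario(name: str, seed: int = 0, **kwargs):
    """Dispatch a named validation scenario.

    ``name`` is one of ``dipole-low``, ``dipole-mid``, ``dipole-high``,
    ``square-plate``, ``active-cell``.
    """
    if name.startswith("dipole-"):
        return run_dipole_validation(name.split("-", 1)[1], seed=seed, **kwargs)
    if name == "square-plate":
        return run_square_plate_validation(**kwargs)
    if name == "active-cell":
        return run_active_cell_validation(**kwargs)
    raise ValueError(f"unknown scenario {name!r}")
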