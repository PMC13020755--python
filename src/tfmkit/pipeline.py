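"""Batch pipeline: drift correction → TV-L1 flow → FTTC → optional MSM.

Each experimental field of view is a frame: one page of the tensed
stack, registered against a shared relaxed reference.  Per-frame outputs
go to ``<out_dir>/frame_<i>/`` with stage-named files; a top-level
``summary.csv`` collects scalar results, ``run.log`` records stage
timings and correction magnitudes, and every CSV carries the config
hash, so identical config + seed reproduce identical outputs.

When a batch spans several frames, the FTTC regularization parameter is
selected once (GCV on the first frame) and held fixed across the batch
unless ``gcv_per_frame`` is set — comparisons across frames are only
meaningful under consistent regularization, so per-frame GCV emits a
warning.
"""

from __future__ import annotations

import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .displacement import BeadImagePair, compute_flow, drift_correct, median_filter_field, subsample_field
from .fttc import RegularizationChoice, fttc_solve, gcv_select_lambda, lanczos_filter
from .io import RunConfig, load_stack, save_field, write_csv
from .mesh import CellMask, build_mesh, segment_mask
from .msm import balance_forces, msm_solve, stress_summaries

__all__ = ["run_pipeline"]


def _log(fh, msg: str) -> None:
    fh.write(msg + "\n")
    fh.flush()


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Run the full pipeline described by ``config``; returns the summary
    table (also written to ``summary.csv``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    config.to_yaml(out / "config.yaml")

    tensed_stack = load_stack(config.tensed)
    relaxed = load_stack(config.relaxed)[0]

    mask = None
    if config.cell_mask:
        m = load_stack(config.cell_mask)[0]
        mask = CellMask(m > 0, config.pixel_size)
    elif config.cell_image:
        img = load_stack(config.cell_image)[0]
        mask = segment_mask(img, config.pixel_size, config.threshold_mode)
        mask = CellMask(mask.mask, config.pixel_size)

    rows = []
    batch_lam = None if config.gcv else config.lam
    with open(out / "run.log", "w") as log:
        _log(log, f"config_hash={chash} frames={len(tensed_stack)}")
        for i, tensed in enumerate(tensed_stack):
            t0 = time.time()
            fdir = out / f"frame_{i:03d}"
            fdir.mkdir(exist_ok=True)
            try:
                pair = BeadImagePair(tensed, relaxed, config.pixel_size)
                pair, drift = drift_correct(pair)
                flow = compute_flow(pair, config.flow)
                if config.median_window:
                    flow = median_filter_field(flow, config.median_window)
                save_field(fdir / "displacement.tif", flow, {"config_hash": chash})

                disp = flow.to_um(config.pixel_size)
                if config.subsample_step > 1:
                    disp = subsample_field(disp, config.subsample_step)
                if batch_lam is None:
                    lam, _ = gcv_select_lambda(disp, config.substrate)
                    if not config.gcv_per_frame:
                        batch_lam = lam
                    else:
                        warnings.warn(
                            "gcv_per_frame varies regularization across the "
                            "batch; frame-to-frame comparisons may reflect "
                            "analysis, not biology",
                            stacklevel=2,
                        )
                else:
                    lam = batch_lam
                traction = fttc_solve(
                    disp, config.substrate, RegularizationChoice("manual", lam=lam)
                )
                if config.lanczos_exponent > 0:
                    traction = lanczos_filter(traction, config.lanczos_exponent)
                save_field(fdir / "traction.tif", traction, {"config_hash": chash})

                tmag = traction.magnitude()
                dA = (traction.spacing * 1e-6) ** 2
                row = {
                    "frame": i,
                    "drift_x_px": drift[0],
                    "drift_y_px": drift[1],
                    "mean_disp_um": float(disp.magnitude().mean()),
                    "max_disp_um": float(disp.magnitude().max()),
                    "mean_traction_pa": float(tmag.mean()),
                    "max_traction_pa": float(tmag.max()),
                    "strain_energy_J": float(
                        0.5 * dA * np.sum(
                            traction.u * disp.u * 1e-6 + traction.v * disp.v * 1e-6
                        )
                    ),
                    "lambda": lam,
                }

                if mask is not None:
                    mgrid = mask.mask
                    if mgrid.shape != traction.shape:
                        # mask supplied at image resolution; reduce to grid
                        s = config.subsample_step
                        ny, nx = traction.shape
                        mgrid = (
                            mgrid[: ny * s, : nx * s]
                            .reshape(ny, s, nx, s)
                            .mean(axis=(1, 3))
                            >= 0.5
                        )
                    grid_mask = CellMask(mgrid, traction.spacing)
                    bal, rep = balance_forces(traction, grid_mask.mask)
                    mesh = build_mesh(grid_mask, config.mesh_edge_length_um)
                    stress = msm_solve(bal, mesh, nu_sheet=config.nu_sheet)
                    summ = stress_summaries(stress, grid_mask)
                    nodal = pd.DataFrame(
                        {
                            "x_um": mesh.nodes[:, 0],
                            "y_um": mesh.nodes[:, 1],
                            "sxx_N_per_m": stress.sxx,
                            "syy_N_per_m": stress.syy,
                            "sxy_N_per_m": stress.sxy,
                        }
                    )
                    write_csv(fdir / "stress_nodes.csv", nodal, chash)
                    row.update(
                        {f"net_force_corr_{k}": v for k, v in zip("xy", rep["net_force"])}
                    )
                    row["net_torque_corr"] = rep["net_torque"]
                    row.update(summ)

                rows.append(row)
                _log(log, f"frame {i}: ok ({time.time() - t0:.1f}s) drift={drift}")
            except Exception as exc:  # noqa: BLE001 - batch robustness
                _log(log, f"frame {i}: FAILED {exc!r}")
                if config.fail_fast:
                    raise

    df = pd.DataFrame(rows)
    write_csv(out / "summary.csv", df, chash)
    return df
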