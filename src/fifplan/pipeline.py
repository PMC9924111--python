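"""End-to-end orchestration: phantom -> aperture -> initial plan -> FIF ->
evaluation, with all artifacts written to an output directory.

A run is reproducible from its configuration alone; the config used is
copied into the output directory.  Artifacts:

* ``phantom/``: density grid and structure masks (NIfTI)
* ``plan_initial.yaml`` / ``plan_final.yaml``: structured plan files
* ``dose_initial.nii`` / ``dose_final.nii``: normalized dose grids
* ``iterations.csv``: one row per FIF iteration (the IterationRecord fields)
* ``metrics.csv`` / ``metrics.txt``: before/after metric report
* ``dvh_<structure>.csv``: final-plan DVH curves
"""

from __future__ import annotations

import logging
import os

import pandas as pd

from .config import RunConfig, dump_config
from .dose import DoseEngine
from .evaluate import compute_dvh, plan_metrics
from .fif import make_initial_plan, run_fif
from .grids import ImageGrid, StructureMask, read_grid, read_mask, write_grid, write_mask
from .optimize import normalize_plan
from .phantom import make_head_phantom
from .plans import write_plan

logger = logging.getLogger(__name__)

STRUCTURES = ("body", "bone", "brain", "eye_L", "eye_R", "lens_L", "lens_R")


def load_or_make_phantom(cfg: RunConfig) -> tuple[ImageGrid, dict[str, StructureMask]]:
    if cfg.phantom.density_path is not None:
        density = read_grid(cfg.phantom.density_path)
        masks = {}
        for name in STRUCTURES:
            path = os.path.join(cfg.phantom.masks_dir, f"{name}.nii")
            if os.path.exists(path):
                masks[name] = read_mask(path, name, reference=density)
        return density, masks
    return make_head_phantom(cfg.phantom.spec())


def write_phantom(density: ImageGrid, masks: dict[str, StructureMask], outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    write_grid(density, os.path.join(outdir, "density.nii"))
    for name, m in masks.items():
        write_mask(m, os.path.join(outdir, f"{name}.nii"))


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "iteration": r.iteration,
                "n_fields": r.n_fields,
                "pre_max_hotspot_pct": r.pre_max_hotspot_pct,
                "block_threshold_pct": r.block_threshold_pct,
                "v_hotspot_before_cm3": r.v_hotspot_before_cm3,
                "v_hotspot_after_cm3": r.v_hotspot_after_cm3,
                "accepted": r.accepted,
                "stop_reason": r.stop_reason,
                "cost_before": r.cost_before,
                "cost_after": r.cost_after,
                "normalization_scale": r.normalization_scale,
            }
            for r in records
        ]
    )


def metrics_frame(before, after) -> pd.DataFrame:
    b, a = before.as_flat_dict(), after.as_flat_dict()
    rows = [
        {"metric": k, "initial_plan": b[k], "fif_plan": a.get(k)} for k in b
    ]
    return pd.DataFrame(rows)


def run_pipeline(cfg: RunConfig, outdir: str) -> dict:
    """Execute the whole planning workflow; returns a result summary dict."""
    cfg.validate()
    os.makedirs(outdir, exist_ok=True)
    dump_config(cfg, os.path.join(outdir, "config.yaml"))

    density, masks = load_or_make_phantom(cfg)
    write_phantom(density, masks, os.path.join(outdir, "phantom"))

    plan = make_initial_plan(
        masks,
        cfg.fif,
        gantry_pair=cfg.beams.gantry_pair,
        sad_mm=cfg.beams.sad_mm,
        isocenter=cfg.beams.isocenter,
        margin_mm=cfg.beams.margin_mm,
        leaf_width_mm=cfg.beams.leaf_width_mm,
        bev_spacing_mm=cfg.beams.bev_spacing_mm,
        bev_half_extent_mm=cfg.beams.bev_half_extent_mm,
        mu_per_weight=cfg.mu_per_weight,
    )
    engine = DoseEngine(density, cfg.engine)
    norm = cfg.normalization.spec()

    fds = [
        engine.compute_field_dose(f.geometry, f.aperture, f.field_id)
        for f in plan.fields
    ]
    from .dose import compute_plan_dose

    raw = compute_plan_dose(fds, plan.weights)
    plan0, dose0, _ = normalize_plan(plan, raw, masks["brain"], norm)
    write_plan(plan0, os.path.join(outdir, "plan_initial.yaml"))
    write_grid(dose0, os.path.join(outdir, "dose_initial.nii"))
    metrics0 = plan_metrics(
        dose0, masks, cfg.fif.rx_gy, cfg.fif.hotspot_fraction
    )

    final_plan, records, final_dose = run_fif(
        plan0, masks, cfg.fif, engine=engine, norm=norm,
        objective=cfg.weight_objective(),
    )
    write_plan(final_plan, os.path.join(outdir, "plan_final.yaml"))
    write_grid(final_dose, os.path.join(outdir, "dose_final.nii"))
    records_to_frame(records).to_csv(os.path.join(outdir, "iterations.csv"), index=False)

    metrics1 = plan_metrics(
        final_dose, masks, cfg.fif.rx_gy, cfg.fif.hotspot_fraction
    )
    frame = metrics_frame(metrics0, metrics1)
    frame.to_csv(os.path.join(outdir, "metrics.csv"), index=False)
    with open(os.path.join(outdir, "metrics.txt"), "w") as fh:
        fh.write(frame.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
        fh.write("\n")

    for name in ("brain", "eye_L", "eye_R", "lens_L", "lens_R"):
        if name in masks:
            dvh = compute_dvh(final_dose, masks[name])
            pd.DataFrame(
                {"dose_gy": dvh.edges_gy, "fraction_ge": dvh.cum_fraction}
            ).to_csv(os.path.join(outdir, f"dvh_{name}.csv"), index=False)

    return {
        "plan": final_plan,
        "records": records,
        "dose_initial": dose0,
        "dose_final": final_dose,
        "metrics_initial": metrics0,
        "metrics_final": metrics1,
        "masks": masks,
        "density": density,
        "stop_reason": records[-1].stop_reason if records else None,
    }
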