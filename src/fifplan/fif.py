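"""The field-in-field (FIF) hotspot-reduction loop.

Forward-planned whole-brain radiotherapy starts from two equal-weight
parallel-opposed lateral fields normalized so 99.9% of the brain volume
receives the prescription (30 Gy in 10 fractions).  The head's shape leaves
supra-prescription hotspots in the skull and scalp; the FIF loop removes
them by iteratively adding pairs of opposed subfields whose MLC leaves block
the current high-dose region:

1. normalize the plan and measure the maximum hotspot percentage, where a
   hotspot is any connected component larger than 1 cm^3 above 107% of Rx;
2. pick the block level one fixed decrement (3% of Rx) below the current
   maximum, floored at the 107% target — e.g. a 116% hotspot is blocked at
   the 113% iso-dose level;
3. conform an opposed subfield pair to the main aperture minus the
   beam's-eye-view projection of the supra-block-level region;
4. re-optimize all beam weights (bounded quasi-Newton, minimum 5 MU per
   field) and renormalize;
5. accept the iteration only if the hotspot volume did not grow, otherwise
   revert the pair and stop.

The loop terminates on one of three clinical conditions — target level
reached, subfield budget (six) exhausted, or hotspot growth — plus two
degenerate-geometry guards (a block with no in-field projection, or a
subtraction that closes the aperture).  Every setting is configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import ndimage

from .bev import (
    BeamGeometry,
    BevMap,
    DegenerateApertureError,
    conform_mlc,
    make_whole_brain_aperture,
    mirror_aperture,
    project_to_bev,
)
from .dose import DoseEngine, compute_plan_dose
from .grids import ImageGrid, StructureMask
from .optimize import (
    NormalizationSpec,
    WeightObjective,
    _cost_grad,
    dose_matrix,
    normalization_scale,
    optimize_weights,
)
from .plans import Field, Plan

logger = logging.getLogger(__name__)


class InvalidPlanError(ValueError):
    pass


class DegenerateSubfieldError(DegenerateApertureError):
    """Blocking at the current level would close the subfield aperture."""


@dataclass
class FIFConfig:
    """Clinical FIF settings (all configurable; defaults are the standard
    whole-brain practice values)."""

    rx_gy: float = 30.0
    fractions: int = 10
    hotspot_fraction: float = 1.07  # hotspot threshold as fraction of Rx
    min_hotspot_volume_cm3: float = 1.0
    decrement: float = 0.03  # block-level decrement, fraction of Rx
    max_subfields: int = 6
    min_mu: float = 5.0  # per field per fraction
    target_coverage: float = 0.999  # of brain volume at 100% of Rx
    connectivity: int = 26  # 6 or 26-neighbor components
    block_per_component: bool = False  # block only the hottest component
    # separate iteration cap; None means the cap implied by the subfield
    # budget (one opposed pair per iteration)
    max_iterations: int | None = None

    def validate(self) -> None:
        if self.rx_gy <= 0 or self.fractions <= 0:
            raise ValueError("prescription and fraction count must be positive")
        if self.decrement <= 0:
            raise ValueError("decrement must be positive")
        if self.min_hotspot_volume_cm3 < 0:
            raise ValueError("minimum hotspot volume must be non-negative")
        if self.max_subfields < 0 or self.max_subfields % 2:
            raise ValueError("max subfields must be an even non-negative count")
        if self.min_mu < 0:
            raise ValueError("minimum MU must be non-negative")
        if not 0 < self.target_coverage <= 1:
            raise ValueError("target coverage must be in (0, 1]")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")

    @property
    def target_pct(self) -> float:
        return 100.0 * self.hotspot_fraction

    @property
    def decrement_pct(self) -> float:
        return 100.0 * self.decrement


@dataclass
class Hotspot:
    label: int
    volume_cm3: float
    peak_gy: float


@dataclass
class HotspotSet:
    """Qualifying connected supra-threshold components inside the body."""

    components: list[Hotspot]
    threshold_gy: float
    labels: np.ndarray  # labeled component array (all supra-threshold voxels)
    max_hotspot_pct: float | None = None  # of Rx, over qualifying components

    def __len__(self) -> int:
        return len(self.components)

    def component_mask(self, i: int) -> np.ndarray:
        return self.labels == self.components[i].label

    def peak_gy(self) -> float | None:
        return max((c.peak_gy for c in self.components), default=None)


def _conn_structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, 3 if connectivity == 26 else 1)


def find_hotspots(
    dose: ImageGrid,
    body: StructureMask,
    threshold_gy: float,
    min_volume_cm3: float = 1.0,
    connectivity: int = 26,
    rx_gy: float | None = None,
) -> HotspotSet:
    """Connected components of body voxels with dose >= threshold, keeping
    those strictly larger than ``min_volume_cm3``."""
    body.check_aligned(dose)
    supra = (dose.values >= threshold_gy) & body.mask
    labels, n = ndimage.label(supra, structure=_conn_structure(connectivity))
    comps: list[Hotspot] = []
    if n:
        voxel = dose.voxel_volume_cm3
        counts = np.bincount(labels.ravel())[1:]
        peaks = ndimage.labeled_comprehension(
            dose.values, labels, np.arange(1, n + 1), np.max, float, 0.0
        )
        for lab, (cnt, pk) in enumerate(zip(counts, np.atleast_1d(peaks)), start=1):
            vol = cnt * voxel
            if vol > min_volume_cm3:
                comps.append(Hotspot(lab, float(vol), float(pk)))
    hs = HotspotSet(comps, threshold_gy, labels)
    if rx_gy is not None and comps:
        hs.max_hotspot_pct = 100.0 * max(c.peak_gy for c in comps) / rx_gy
    return hs


def select_block_threshold(
    max_hotspot_pct: float,
    decrement_pct: float = 3.0,
    target_pct: float = 107.0,
) -> float | None:
    """Block level for this iteration, in % of Rx, or None to stop.

    The level sits one fixed decrement below the current maximum hotspot
    percentage (a 116% maximum is blocked at 113%) but never below the
    target level, so near convergence the block cannot overshoot into cold
    spots.  At or below the target the loop stops.
    """
    if max_hotspot_pct <= target_pct + 1e-9:
        return None
    return max(max_hotspot_pct - decrement_pct, target_pct)


def _main_pair(plan: Plan) -> tuple[Field, Field]:
    mains = [f for f in plan.fields if f.role == "main"]
    if len(mains) != 2:
        raise InvalidPlanError("expected exactly two main opposed fields")
    return mains[0], mains[1]


def make_subfield_pair(
    plan: Plan,
    dose: ImageGrid,
    block_threshold_gy: float,
    body: StructureMask,
    config: FIFConfig | None = None,
    pair_index: int = 1,
) -> tuple[Field, Field] | None:
    """Opposed subfield pair whose apertures block the supra-threshold region.

    The block region is the union of all body voxels at or above the block
    level (optionally only the hottest connected component).  It is projected
    into the first main beam's BEV, subtracted from that beam's main aperture,
    MLC-conformed, and mirrored for the opposed beam.  Returns None when the
    block has no in-field projection (a no-op iteration); raises
    :class:`DegenerateSubfieldError` when the subtraction closes the field.
    """
    config = config or FIFConfig()
    main_a, main_b = _main_pair(plan)
    block = (dose.values >= block_threshold_gy) & body.mask
    if config.block_per_component and block.any():
        labels, n = ndimage.label(block, structure=_conn_structure(config.connectivity))
        peaks = ndimage.labeled_comprehension(
            dose.values, labels, np.arange(1, n + 1), np.max, float, 0.0
        )
        block = labels == (1 + int(np.argmax(np.atleast_1d(peaks))))
    block_mask = StructureMask("block", block, dose.spacing, dose.origin)

    frame = main_a.aperture.bev
    du = frame.spacing[0]
    half_extent = du * (frame.values.shape[0] // 2)
    block_bev = project_to_bev(block_mask, main_a.geometry, du, half_extent)

    if not np.any(block_bev.values & frame.values):
        return None
    region = frame.values & ~block_bev.values
    if not region.any():
        raise DegenerateSubfieldError(
            "block region covers the whole main aperture"
        )
    ap_a = conform_mlc(
        BevMap(region, frame.spacing, frame.origin),
        main_a.aperture.leaf_width_mm,
        rule="largest_open_run",
        avoid=BevMap(
            block_bev.values & frame.values, frame.spacing, frame.origin
        ),
    )
    if not ap_a.is_open():
        raise DegenerateSubfieldError("blocking closed every leaf pair")
    ap_b = mirror_aperture(ap_a)
    w0 = config.min_mu / plan.mu_per_weight if plan.mu_per_weight > 0 else 0.0
    fa = Field(f"sub{pair_index}_{main_a.geometry.gantry_deg:g}", main_a.geometry, ap_a, w0, "subfield")
    fb = Field(f"sub{pair_index}_{main_b.geometry.gantry_deg:g}", main_b.geometry, ap_b, w0, "subfield")
    return fa, fb


@dataclass
class IterationRecord:
    """One row of the FIF run log."""

    iteration: int
    n_fields: int
    pre_max_hotspot_pct: float | None
    block_threshold_pct: float | None
    v_hotspot_before_cm3: float
    v_hotspot_after_cm3: float | None
    accepted: bool
    stop_reason: str | None = None
    cost_before: float | None = None
    cost_after: float | None = None
    normalization_scale: float | None = None


def make_initial_plan(
    masks: dict[str, StructureMask],
    config: FIFConfig | None = None,
    gantry_pair: tuple[float, float] = (90.0, 270.0),
    sad_mm: float = 1000.0,
    isocenter: tuple[float, float, float] | None = None,
    margin_mm: float = 7.0,
    leaf_width_mm: float = 5.0,
    bev_spacing_mm: float = 2.0,
    bev_half_extent_mm: float = 160.0,
    blocked_structures: tuple[str, ...] = ("eye_L", "eye_R", "lens_L", "lens_R"),
    mu_per_weight: float = 100.0,
) -> Plan:
    """Equal-weight opposed-lateral whole-brain plan.

    The isocenter defaults to the brain centroid; the first beam's aperture
    is the dilated brain BEV minus the blocked-structure BEVs, and the
    opposed beam carries its mirror so both open onto the same anatomy.
    """
    config = config or FIFConfig()
    brain = masks["brain"]
    if isocenter is None:
        sp = np.asarray(brain.spacing)
        com = np.asarray(ndimage.center_of_mass(brain.mask))
        isocenter = tuple(np.asarray(brain.origin) + com * sp)
    geom_a = BeamGeometry(gantry_pair[0], isocenter, sad_mm)
    geom_b = BeamGeometry(gantry_pair[1], isocenter, sad_mm)
    brain_bev = project_to_bev(brain, geom_a, bev_spacing_mm, bev_half_extent_mm)
    blocked = [
        project_to_bev(masks[nm], geom_a, bev_spacing_mm, bev_half_extent_mm)
        for nm in blocked_structures
        if nm in masks
    ]
    ap_a = make_whole_brain_aperture(brain_bev, blocked, margin_mm, leaf_width_mm)
    ap_b = mirror_aperture(ap_a)
    return Plan(
        fields=[
            Field(f"main_{gantry_pair[0]:g}", geom_a, ap_a, 1.0, "main"),
            Field(f"main_{gantry_pair[1]:g}", geom_b, ap_b, 1.0, "main"),
        ],
        rx_gy=config.rx_gy,
        fractions=config.fractions,
        mu_per_weight=mu_per_weight,
    )


def _hotspot_volume_cm3(dose: ImageGrid, body: StructureMask, thr_gy: float) -> float:
    return float(((dose.values >= thr_gy) & body.mask).sum()) * dose.voxel_volume_cm3


def _renormalize(weights, field_doses, brain, norm, rx_gy, floor):
    """Normalize, then re-apply the minimum-MU weight floor (a few fixed-point
    passes; the floor fields carry negligible dose so this converges fast)."""
    s_total = 1.0
    for _ in range(8):
        dose = compute_plan_dose(field_doses, weights)
        s = normalization_scale(dose, brain, norm, rx_gy)
        s_total *= s
        weights = weights * s
        low = weights < floor - 1e-12
        if abs(s - 1.0) < 1e-12 and not low.any():
            break
        weights[low] = floor
    return weights, compute_plan_dose(field_doses, weights), s_total


def run_fif(
    initial_plan: Plan,
    masks: dict[str, StructureMask],
    config: FIFConfig | None = None,
    engine: DoseEngine | None = None,
    density: ImageGrid | None = None,
    norm: NormalizationSpec | None = None,
    objective: WeightObjective | None = None,
) -> tuple[Plan, list[IterationRecord], ImageGrid]:
    """Run the FIF loop; returns (final plan, iteration log, final dose grid).

    Deterministic given its inputs.  ``engine`` may be supplied directly
    (reusing its per-geometry raytrace cache) or built from ``density``.
    """
    config = config or FIFConfig()
    config.validate()
    if engine is None:
        if density is None:
            raise ValueError("provide a DoseEngine or a density grid")
        engine = DoseEngine(density)
    brain, body = masks["brain"], masks["body"]
    if not brain.mask.any():
        raise InvalidPlanError("brain mask is empty")
    norm = norm or NormalizationSpec(coverage=config.target_coverage)
    floor = config.min_mu / initial_plan.mu_per_weight
    objective = objective or WeightObjective(rx_gy=config.rx_gy, min_weight=floor)

    plan = initial_plan.copy()
    fds = [
        engine.compute_field_dose(f.geometry, f.aperture, f.field_id)
        for f in plan.fields
    ]
    raw = compute_plan_dose(fds, plan.weights)
    if raw.values[brain.mask].max() <= 0:
        raise InvalidPlanError("initial plan delivers no dose to the brain")

    weights = np.maximum(plan.weights, floor)
    weights, dose, s0 = _renormalize(weights, fds, brain, norm, config.rx_gy, floor)
    hot_thr = config.hotspot_fraction * config.rx_gy
    records: list[IterationRecord] = []
    it = 0

    while True:
        it += 1
        hs = find_hotspots(
            dose, body, hot_thr, config.min_hotspot_volume_cm3,
            config.connectivity, config.rx_gy,
        )
        max_pct = hs.max_hotspot_pct
        v_before = _hotspot_volume_cm3(dose, body, hot_thr)
        rec = IterationRecord(
            iteration=it,
            n_fields=len(plan.fields),
            pre_max_hotspot_pct=max_pct,
            block_threshold_pct=None,
            v_hotspot_before_cm3=v_before,
            v_hotspot_after_cm3=None,
            accepted=False,
        )
        thr_pct = (
            None if max_pct is None
            else select_block_threshold(max_pct, config.decrement_pct, config.target_pct)
        )
        if thr_pct is None:
            rec.stop_reason = "target_reached"
            records.append(rec)
            break
        if plan.n_subfields() >= config.max_subfields:
            rec.stop_reason = "max_subfields"
            records.append(rec)
            break
        if config.max_iterations is not None and sum(
            1 for r in records if r.accepted
        ) >= config.max_iterations:
            rec.stop_reason = "max_iterations"
            records.append(rec)
            break
        rec.block_threshold_pct = thr_pct

        try:
            pair = make_subfield_pair(
                plan, dose, thr_pct / 100.0 * config.rx_gy, body, config,
                pair_index=plan.n_subfields() // 2 + 1,
            )
        except DegenerateSubfieldError:
            rec.stop_reason = "degenerate_subfield"
            records.append(rec)
            break
        if pair is None:
            rec.stop_reason = "no_op_block"
            records.append(rec)
            break

        new_fds = [
            engine.compute_field_dose(f.geometry, f.aperture, f.field_id)
            for f in pair
        ]
        trial_fds = fds + new_fds
        start = np.concatenate([weights, [floor, floor]])
        a_over = dose_matrix(trial_fds, body, objective.voxel_stride)
        a_under = dose_matrix(trial_fds, brain, objective.voxel_stride)
        rec.cost_before = _cost_grad(start, a_over, a_under, objective)[0]
        w_opt = optimize_weights(
            trial_fds, brain, objective, start, overdose_region=body
        )
        w_opt, dose_new, s = _renormalize(
            w_opt, trial_fds, brain, norm, config.rx_gy, floor
        )
        rec.cost_after = _cost_grad(w_opt, a_over, a_under, objective)[0]
        rec.normalization_scale = s
        v_after = _hotspot_volume_cm3(dose_new, body, hot_thr)
        rec.v_hotspot_after_cm3 = v_after

        if v_after <= v_before + 1e-9:
            plan.fields.extend(pair)
            fds = trial_fds
            weights = w_opt
            dose = dose_new
            rec.accepted = True
            rec.n_fields = len(plan.fields)
            records.append(rec)
            logger.info(
                "iteration %d accepted: max %.1f%% blocked at %.1f%%, "
                "V_hot %.1f -> %.1f cm3",
                it, max_pct, thr_pct, v_before, v_after,
            )
        else:
            rec.stop_reason = "hotspot_increased"
            records.append(rec)
            break

    plan.set_weights(weights)
    plan.normalized = True
    if len(plan.fields) % 2:
        raise InvalidPlanError("plan ended with an odd number of fields")
    return plan, records, dose
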