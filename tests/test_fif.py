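"""FIF core: hotspot detection vs. a flood-fill oracle, block-threshold rule,
subfield construction, and the loop's stopping behavior on phantom regimes."""

from collections import deque

import numpy as np
import pytest

from fifplan.dose import DoseEngine, compute_plan_dose
from fifplan.fif import (
    FIFConfig,
    find_hotspots,
    make_initial_plan,
    make_subfield_pair,
    run_fif,
    select_block_threshold,
)
from fifplan.grids import ImageGrid, StructureMask
from fifplan.optimize import NormalizationSpec, normalize_plan
from fifplan.phantom import make_head_phantom, mild_phantom_spec


def flood_fill_components(supra: np.ndarray, connectivity: int):
    """Independent BFS connected-component labelling oracle."""
    if connectivity == 26:
        offsets = [
            (i, j, k)
            for i in (-1, 0, 1)
            for j in (-1, 0, 1)
            for k in (-1, 0, 1)
            if (i, j, k) != (0, 0, 0)
        ]
    else:
        offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    seen = np.zeros_like(supra, dtype=bool)
    comps = []
    for start in np.argwhere(supra):
        start = tuple(start)
        if seen[start]:
            continue
        queue = deque([start])
        seen[start] = True
        comp = []
        while queue:
            p = queue.popleft()
            comp.append(p)
            for o in offsets:
                q = tuple(np.add(p, o))
                if all(0 <= q[d] < supra.shape[d] for d in range(3)):
                    if supra[q] and not seen[q]:
                        seen[q] = True
                        queue.append(q)
        comps.append(comp)
    return comps


def dose_with_blobs(shape=(20, 20, 20), spacing=2.0):
    """30 Gy background with two disjoint supra-threshold blobs of 0.5 and
    2.0 cm^3 (voxel volume 0.008 cm^3)."""
    vals = np.full(shape, 30.0)
    n_small = int(round(0.5 / 0.008))  # 62 voxels
    n_big = int(round(2.0 / 0.008))  # 250 voxels
    flat = vals[2:6, 2:6, 2:6].ravel()
    flat[:n_small] = 33.0
    vals[2:6, 2:6, 2:6] = flat.reshape(4, 4, 4)
    flat = vals[10:17, 10:17, 10:17].ravel()
    flat[:n_big] = 34.0
    vals[10:17, 10:17, 10:17] = flat.reshape(7, 7, 7)
    g = ImageGrid(vals, (spacing,) * 3, (0.0, 0.0, 0.0))
    body = StructureMask("body", np.ones(shape, bool), g.spacing, g.origin)
    return g, body


class TestFindHotspots:
    def test_minimum_volume_filter_keeps_only_large_component(self):
        dose, body = dose_with_blobs()
        hs = find_hotspots(dose, body, threshold_gy=1.07 * 30.0, min_volume_cm3=1.0,
                           rx_gy=30.0)
        assert len(hs) == 1
        assert hs.components[0].volume_cm3 == pytest.approx(2.0, abs=0.01)
        assert hs.components[0].peak_gy == pytest.approx(34.0)
        assert hs.max_hotspot_pct == pytest.approx(100.0 * 34.0 / 30.0)

    def test_uniform_subthreshold_dose_has_no_hotspots(self):
        g = ImageGrid(np.full((8, 8, 8), 30.0))
        body = StructureMask("b", np.ones((8, 8, 8), bool), g.spacing, g.origin)
        hs = find_hotspots(g, body, threshold_gy=32.1)
        assert len(hs) == 0
        assert hs.max_hotspot_pct is None

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_agrees_with_flood_fill_oracle_on_random_grids(self, connectivity):
        voxel = 0.008  # 2 mm isotropic
        for seed in range(6):
            rng = np.random.default_rng(seed)
            vals = np.where(rng.random((20, 20, 20)) > 0.8, 33.0, 30.0)
            g = ImageGrid(vals, (2.0, 2.0, 2.0), (0.0, 0.0, 0.0))
            body = StructureMask("b", np.ones((20, 20, 20), bool), g.spacing, g.origin)
            hs = find_hotspots(g, body, 32.1, min_volume_cm3=0.0,
                               connectivity=connectivity)
            oracle = flood_fill_components(vals >= 32.1, connectivity)
            assert len(hs) == len(oracle)
            assert sorted(c.volume_cm3 for c in hs.components) == pytest.approx(
                sorted(len(c) * voxel for c in oracle)
            )

    def test_detection_restricted_to_body(self):
        dose, _ = dose_with_blobs()
        body = StructureMask(
            "b", np.zeros(dose.shape, bool), dose.spacing, dose.origin
        )
        body.mask[10:, 10:, 10:] = True  # exclude the small blob's octant
        hs = find_hotspots(dose, body, 32.1, min_volume_cm3=0.0)
        assert all(c.peak_gy == pytest.approx(34.0) for c in hs.components)


class TestBlockThreshold:
    def test_fixed_decrement_worked_example(self):
        # a 116% maximum hotspot is blocked at the 113% level
        assert select_block_threshold(116.0, 3.0, 107.0) == pytest.approx(113.0)

    def test_stop_at_target_level(self):
        assert select_block_threshold(107.0, 3.0, 107.0) is None
        assert select_block_threshold(106.2, 3.0, 107.0) is None

    def test_floor_at_target(self):
        assert select_block_threshold(108.5, 3.0, 107.0) == pytest.approx(107.0)


@pytest.fixture(scope="module")
def mild_setup():
    grid, masks = make_head_phantom(mild_phantom_spec())
    cfg = FIFConfig()
    plan = make_initial_plan(masks, cfg)
    engine = DoseEngine(grid)
    fds = [engine.compute_field_dose(f.geometry, f.aperture, f.field_id)
           for f in plan.fields]
    raw = compute_plan_dose(fds, plan.weights)
    plan0, dose0, _ = normalize_plan(plan, raw, masks["brain"], NormalizationSpec())
    return grid, masks, cfg, plan0, dose0, engine


class TestSubfieldPair:
    def test_subfield_apertures_subset_of_main(self, mild_setup):
        _, masks, cfg, plan0, dose0, _ = mild_setup
        thr = 1.085 * 30.0
        pair = make_subfield_pair(plan0, dose0, thr, masks["body"], cfg)
        assert pair is not None
        for sub, main in zip(pair, plan0.fields):
            sm, mm = sub.aperture.intervals, main.aperture.intervals
            open_rows = sm[:, 1] > sm[:, 0]
            assert np.all(sm[open_rows, 0] >= mm[open_rows, 0] - 1e-9)
            assert np.all(sm[open_rows, 1] <= mm[open_rows, 1] + 1e-9)
            assert not np.any(open_rows & ~(mm[:, 1] > mm[:, 0]))
            assert sub.aperture.open_area_cm2() < main.aperture.open_area_cm2()

    def test_pair_is_exact_mirror(self, mild_setup):
        _, masks, cfg, plan0, dose0, _ = mild_setup
        pair = make_subfield_pair(plan0, dose0, 1.085 * 30.0, masks["body"], cfg)
        a, b = pair
        np.testing.assert_allclose(
            b.aperture.intervals,
            np.column_stack([-a.aperture.intervals[:, 1], -a.aperture.intervals[:, 0]]),
        )

    def test_block_outside_field_is_noop(self, mild_setup):
        _, masks, cfg, plan0, dose0, _ = mild_setup
        # no voxel reaches 10x the prescription: empty block projection
        pair = make_subfield_pair(plan0, dose0, 300.0, masks["body"], cfg)
        assert pair is None


class TestRunFif:
    def test_converged_run_reaches_target(self, mild_run):
        records = mild_run["records"]
        assert records[-1].stop_reason == "target_reached"
        plan = mild_run["plan"]
        assert plan.n_subfields() == 2
        last = records[-1].pre_max_hotspot_pct
        assert last is None or last <= 107.0 + 1e-6

    def test_no_hotspot_phantom_adds_no_subfields(self, flat_run):
        records = flat_run["records"]
        assert len(records) == 1
        assert records[0].stop_reason == "target_reached"
        assert flat_run["plan"].n_subfields() == 0
        assert len(flat_run["plan"].fields) == 2

    def test_budget_exhausted_on_persistent_hotspots(self, stress_run):
        records = stress_run["records"]
        assert records[-1].stop_reason == "max_subfields"
        assert stress_run["plan"].n_subfields() == 6

    def test_accepted_iterations_never_grow_hotspot(self, default_run, stress_run):
        for run in (default_run, stress_run):
            for r in run["records"]:
                if r.accepted:
                    assert r.v_hotspot_after_cm3 <= r.v_hotspot_before_cm3 + 1e-9

    def test_rejected_iteration_reverts_subfield_pair(self):
        # this jitter seed produces a hotspot whose blocking grows the
        # hotspot volume: the pair must be withdrawn and the loop stopped
        grid, masks = make_head_phantom(mild_phantom_spec(seed=123))
        cfg = FIFConfig()
        plan = make_initial_plan(masks, cfg)
        engine = DoseEngine(grid)
        fds = [engine.compute_field_dose(f.geometry, f.aperture, f.field_id)
               for f in plan.fields]
        raw = compute_plan_dose(fds, plan.weights)
        plan0, _, _ = normalize_plan(plan, raw, masks["brain"], NormalizationSpec())
        final, records, _ = run_fif(plan0, masks, cfg, engine=engine)
        assert records[-1].stop_reason == "hotspot_increased"
        assert not records[-1].accepted
        # field count rolled back to the pre-iteration value
        assert len(final.fields) == records[-1].n_fields
        assert len(final.fields) % 2 == 0

    def test_zero_subfield_budget_skips_fif(self, mild_setup):
        grid, masks, _, plan0, _, engine = mild_setup
        cfg = FIFConfig(max_subfields=0)
        final, records, _ = run_fif(plan0, masks, cfg, engine=engine)
        assert len(final.fields) == 2
        assert records[-1].stop_reason == "max_subfields"

    def test_deterministic_given_inputs(self, mild_setup):
        grid, masks, cfg, plan0, _, engine = mild_setup
        f1, r1, d1 = run_fif(plan0, masks, cfg, engine=engine)
        f2, r2, d2 = run_fif(plan0, masks, cfg, engine=engine)
        np.testing.assert_array_equal(d1.values, d2.values)
        assert [f.weight for f in f1.fields] == [f.weight for f in f2.fields]
        assert [r.stop_reason for r in r1] == [r.stop_reason for r in r2]

    def test_config_validation(self):
        with pytest.raises(ValueError):
            FIFConfig(max_subfields=3).validate()  # pairs only
        with pytest.raises(ValueError):
            FIFConfig(decrement=0.0).validate()
        with pytest.raises(ValueError):
            FIFConfig(connectivity=18).validate()
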