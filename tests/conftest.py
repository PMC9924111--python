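"""Shared fixtures: phantom-regime pipeline runs (built once per session) and
small synthetic grids for unit tests."""

from __future__ import annotations

import numpy as np
import pytest

from fifplan.config import PhantomConfig, RunConfig
from fifplan.grids import ImageGrid, StructureMask
from fifplan.pipeline import run_pipeline


def _run_preset(preset: str, tmp_path_factory) -> dict:
    cfg = RunConfig(phantom=PhantomConfig(preset=preset))
    outdir = tmp_path_factory.mktemp(f"run_{preset}")
    result = run_pipeline(cfg, str(outdir))
    result["outdir"] = outdir
    result["config"] = cfg
    return result


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline on the default head phantom (hotspots persist)."""
    return _run_preset("default", tmp_path_factory)


@pytest.fixture(scope="session")
def stress_run(tmp_path_factory):
    """Full pipeline on the stress phantom (subfield budget exhausted)."""
    return _run_preset("stress", tmp_path_factory)


@pytest.fixture(scope="session")
def mild_run(tmp_path_factory):
    """Full pipeline on the mild phantom (converges to the 107% target)."""
    return _run_preset("mild", tmp_path_factory)


@pytest.fixture(scope="session")
def flat_run(tmp_path_factory):
    """Full pipeline on the flat-dose phantom (no hotspot at all)."""
    return _run_preset("flat", tmp_path_factory)


@pytest.fixture()
def small_grid():
    """10x10x10 grid at 2 mm, origin centered."""
    def make(values=None, spacing=(2.0, 2.0, 2.0)):
        if values is None:
            values = np.zeros((10, 10, 10))
        n = np.asarray(values.shape)
        origin = -(n - 1) * np.asarray(spacing) / 2.0
        return ImageGrid(values, tuple(spacing), tuple(origin))

    return make


@pytest.fixture()
def mask_like():
    def make(grid: ImageGrid, mask: np.ndarray, name: str = "m") -> StructureMask:
        return StructureMask(name, mask, grid.spacing, grid.origin)

    return make
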