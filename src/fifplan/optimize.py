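"""Beam-weight optimization and plan normalization.

Weights are the only optimization variables (FIF is forward planning: leaf
positions come from the iso-dose geometry, not from the optimizer).  The
objective is a two-sided least-squares penalty,

    C(w) = alpha * sum_{v in O} max(0, D_v(w) - Rx)^2
         + beta  * sum_{v in T} max(0, Rx - D_v(w))^2,    D(w) = sum_i w_i D_i,

minimized with the bounded quasi-Newton solver L-BFGS-B from the current
weights.  T is the target structure (brain).  The overdose region O defaults
to T, but the FIF loop runs it over the whole body: whole-brain hotspots sit
in the skull and scalp, outside the target, and a target-scoped overdose term
is blind to them — trading main-field weight into a hotspot-blocking subfield
would leave such a cost exactly flat.

Coverage is not a hard constraint inside the solver: the subsequent
normalization step rescales all weights by one scalar so that the configured
fraction of the target volume (default 99.9%) receives the prescription, and
is the final arbiter of coverage.  Weight lower bounds encode the
minimum-MU-per-field rule through the linear weight-to-MU map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize as sciopt

from .dose import FieldDose
from .grids import ImageGrid, StructureMask
from .plans import Plan

logger = logging.getLogger(__name__)


class NormalizationError(ValueError):
    pass


@dataclass
class WeightObjective:
    """Two-sided quadratic dose objective (overdose vs. underdose hinge)."""

    rx_gy: float = 30.0
    overdose_weight: float = 1.0
    underdose_weight: float = 1.0
    min_weight: float = 0.05  # from min MU via the weight->MU map
    max_weight: float = np.inf
    voxel_stride: int = 1  # cost subsampling of voxels

    def validate(self) -> None:
        if self.overdose_weight < 0 or self.underdose_weight < 0:
            raise ValueError("penalty weights must be non-negative")
        if not self.min_weight < self.max_weight:
            raise ValueError("weight lower bound must be below upper bound")


@dataclass
class NormalizationSpec:
    """Coverage-based plan normalization: ``coverage`` of the target volume
    receives ``dose_level`` * Rx.  Defaults to the clinical 99.9% @ 100%;
    renormalization levels such as 99.5% are expressed by ``dose_level``."""

    coverage: float = 0.999
    dose_level: float = 1.0

    def validate(self) -> None:
        if not 0 < self.coverage <= 1:
            raise ValueError("coverage fraction must be in (0, 1]")
        if self.dose_level <= 0:
            raise ValueError("dose level must be positive")


def dose_matrix(
    field_doses: list[FieldDose], region: StructureMask, stride: int = 1
) -> np.ndarray:
    """Stack per-field unit doses over (subsampled) region voxels: (nvox, nfields)."""
    cols = [fd.dose.values[region.mask][::stride] for fd in field_doses]
    return np.column_stack(cols)


def _cost_grad(w, a_over, a_under, objective):
    over = np.maximum(a_over @ w - objective.rx_gy, 0.0)
    under = np.maximum(objective.rx_gy - a_under @ w, 0.0)
    c = (
        objective.overdose_weight * over @ over
        + objective.underdose_weight * under @ under
    )
    g = 2.0 * (
        objective.overdose_weight * (a_over.T @ over)
        - objective.underdose_weight * (a_under.T @ under)
    )
    return float(c), g


def cost(
    weights,
    field_doses: list[FieldDose],
    target: StructureMask,
    objective: WeightObjective,
    overdose_region: StructureMask | None = None,
) -> float:
    """Objective value at ``weights``; the overdose term runs over
    ``overdose_region`` when given, otherwise over the target."""
    a_under = dose_matrix(field_doses, target, objective.voxel_stride)
    a_over = (
        a_under
        if overdose_region is None
        else dose_matrix(field_doses, overdose_region, objective.voxel_stride)
    )
    return _cost_grad(np.asarray(weights, dtype=float), a_over, a_under, objective)[0]


def optimize_weights(
    field_doses: list[FieldDose],
    target: StructureMask,
    objective: WeightObjective,
    start_weights=None,
    overdose_region: StructureMask | None = None,
    max_iter: int = 200,
    gtol: float = 1e-6,
) -> np.ndarray:
    """Bounded L-BFGS-B minimization of the weight objective.

    Starts from ``start_weights`` (default: all ones) and never returns a
    point worse than the start: on solver failure or a worse final cost the
    starting weights come back with a logged warning.
    """
    objective.validate()
    n = len(field_doses)
    w0 = np.ones(n) if start_weights is None else np.asarray(start_weights, dtype=float)
    w0 = np.clip(w0, objective.min_weight, objective.max_weight)
    a_under = dose_matrix(field_doses, target, objective.voxel_stride)
    a_over = (
        a_under
        if overdose_region is None
        else dose_matrix(field_doses, overdose_region, objective.voxel_stride)
    )
    bounds = [(objective.min_weight, objective.max_weight)] * n

    c0, _ = _cost_grad(w0, a_over, a_under, objective)
    res = sciopt.minimize(
        _cost_grad,
        w0,
        args=(a_over, a_under, objective),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "gtol": gtol},
    )
    c1, _ = _cost_grad(res.x, a_over, a_under, objective)
    if c1 > c0:
        if not res.success:
            logger.warning(
                "weight optimization failed (%s); keeping start weights", res.message
            )
        return w0
    return res.x


def coverage_dose(dose: ImageGrid, target: StructureMask, coverage: float) -> float:
    """Largest dose level received by at least ``coverage`` of the target volume."""
    v = np.sort(dose.values[target.mask])
    if v.size == 0:
        raise NormalizationError("target mask is empty")
    k = int(np.floor((1.0 - coverage) * v.size))
    return float(v[min(k, v.size - 1)])


def normalization_scale(
    dose: ImageGrid, target: StructureMask, spec: NormalizationSpec, rx_gy: float
) -> float:
    """Global scalar taking the plan to the requested coverage level."""
    spec.validate()
    d = coverage_dose(dose, target, spec.coverage)
    if d <= 0:
        raise NormalizationError("target receives no dose; cannot normalize")
    return spec.dose_level * rx_gy / d


def normalize_plan(
    plan: Plan,
    plan_dose: ImageGrid,
    target: StructureMask,
    spec: NormalizationSpec,
) -> tuple[Plan, ImageGrid, float]:
    """Rescale all weights by one scalar so ``coverage`` of the target gets
    ``dose_level * Rx``; the dose grid is rescaled by linearity."""
    s = normalization_scale(plan_dose, target, spec, plan.rx_gy)
    scaled = plan.copy()
    scaled.scale_weights(s)
    scaled.normalized = True
    return scaled, plan_dose.like(plan_dose.values * s), s


def assign_mu(plan: Plan, weights=None) -> np.ndarray:
    """Monitor units per field per fraction via the linear weight->MU map."""
    w = plan.weights if weights is None else np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    return w * plan.mu_per_weight
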