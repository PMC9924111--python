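"""Treatment-plan containers and their structured-text serialization.

A plan is an ordered list of fields (beam geometry + MLC aperture + relative
weight), a prescription, and a normalization state.  Whole-brain FIF plans
always hold an even number of fields: a main opposed-lateral pair plus zero
or more opposed subfield pairs.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field as dfield

import numpy as np
import yaml

from .bev import Aperture, BeamGeometry, BevMap


@dataclass
class Field:
    """One deliverable beam."""

    field_id: str
    geometry: BeamGeometry
    aperture: Aperture
    weight: float = 1.0
    role: str = "main"  # "main" or "subfield"


@dataclass
class Plan:
    """An ordered set of fields with a prescription.

    ``mu_per_weight`` maps the dimensionless optimization weight to monitor
    units per fraction (a linear stand-in for machine MU calculation).
    """

    fields: list[Field] = dfield(default_factory=list)
    rx_gy: float = 30.0
    fractions: int = 10
    mu_per_weight: float = 100.0
    normalized: bool = False

    @property
    def weights(self) -> np.ndarray:
        return np.array([f.weight for f in self.fields])

    def set_weights(self, weights) -> None:
        weights = np.asarray(weights, dtype=float)
        if len(weights) != len(self.fields):
            raise ValueError("one weight per field required")
        for f, w in zip(self.fields, weights):
            f.weight = float(w)

    def scale_weights(self, s: float) -> None:
        for f in self.fields:
            f.weight *= s

    def mu(self) -> np.ndarray:
        """Monitor units per field per fraction."""
        return self.weights * self.mu_per_weight

    def n_subfields(self) -> int:
        return sum(1 for f in self.fields if f.role == "subfield")

    def copy(self) -> "Plan":
        return copy.deepcopy(self)


# ---------------- serialization ----------------


def _aperture_to_dict(ap: Aperture) -> dict:
    return {
        "leaf_width_mm": float(ap.leaf_width_mm),
        "leaf_v0": float(ap.leaf_v0),
        "intervals": [[float(a), float(b)] for a, b in ap.intervals],
        "jaw": [float(x) for x in ap.jaw],
        "bev_spacing": [float(s) for s in ap.bev.spacing],
        "bev_origin": [float(o) for o in ap.bev.origin],
        "bev_shape": list(ap.bev.values.shape),
    }


def _aperture_from_dict(d: dict) -> Aperture:
    from .bev import _rasterize  # rebuild the raster from the leaves

    frame = BevMap(
        np.zeros(tuple(d["bev_shape"]), dtype=bool),
        tuple(d["bev_spacing"]),
        tuple(d["bev_origin"]),
    )
    intervals = np.asarray(d["intervals"], dtype=float)
    jaw = tuple(d["jaw"])
    bev = _rasterize(intervals, d["leaf_width_mm"], d["leaf_v0"], jaw, frame)
    return Aperture(intervals, d["leaf_width_mm"], d["leaf_v0"], bev, jaw)


def plan_to_dict(plan: Plan) -> dict:
    return {
        "prescription_gy": float(plan.rx_gy),
        "fractions": int(plan.fractions),
        "mu_per_weight": float(plan.mu_per_weight),
        "normalized": bool(plan.normalized),
        "fields": [
            {
                "id": f.field_id,
                "role": f.role,
                "gantry_deg": float(f.geometry.gantry_deg),
                "isocenter": [float(x) for x in f.geometry.isocenter],
                "sad_mm": float(f.geometry.sad_mm),
                "energy": f.geometry.energy,
                "weight": float(f.weight),
                "mu_per_fraction": float(f.weight * plan.mu_per_weight),
                "aperture": _aperture_to_dict(f.aperture),
            }
            for f in plan.fields
        ],
    }


def plan_from_dict(d: dict) -> Plan:
    fields = [
        Field(
            field_id=fd["id"],
            geometry=BeamGeometry(
                gantry_deg=fd["gantry_deg"],
                isocenter=tuple(fd["isocenter"]),
                sad_mm=fd["sad_mm"],
                energy=fd.get("energy", "6 MV"),
            ),
            aperture=_aperture_from_dict(fd["aperture"]),
            weight=fd["weight"],
            role=fd.get("role", "main"),
        )
        for fd in d["fields"]
    ]
    return Plan(
        fields=fields,
        rx_gy=d["prescription_gy"],
        fractions=d["fractions"],
        mu_per_weight=d["mu_per_weight"],
        normalized=d.get("normalized", False),
    )


def write_plan(plan: Plan, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(plan_to_dict(plan), fh, sort_keys=False)


def read_plan(path: str) -> Plan:
    with open(path) as fh:
        return plan_from_dict(yaml.safe_load(fh))
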