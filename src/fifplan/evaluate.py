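"""Dose-volume histograms and plan quality metrics.

All plan quality numbers come off cumulative DVHs: for each structure the
fraction of its volume receiving at least each dose level.  Dx% (dose to the
hottest x% ... strictly, the largest dose received by at least x% of the
volume) and Vd (volume at or above dose d) are DVH lookups with linear
interpolation between bins.  The report mirrors the clinical whole-brain
metric set: brain D99/D95/D1, mean eye dose, maximum lens dose, the hotspot
volume V107% in cm^3 and as a percentage of the brain volume, and the
maximum hotspot percentage of the prescription.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import ImageGrid, StructureMask

DEFAULT_BIN_GY = 0.01


@dataclass
class DVH:
    """Cumulative dose-volume curve: fraction of volume >= each bin edge."""

    structure: str
    edges_gy: np.ndarray
    cum_fraction: np.ndarray  # starts at 1.0, non-increasing, ends at 0
    volume_cm3: float

    @property
    def bin_width(self) -> float:
        return float(self.edges_gy[1] - self.edges_gy[0])


def compute_dvh(
    dose: ImageGrid, mask: StructureMask, bin_width: float = DEFAULT_BIN_GY
) -> DVH:
    """Cumulative >=-dose histogram of the masked voxels."""
    mask.check_aligned(dose)
    v = dose.values[mask.mask]
    if v.size == 0:
        raise ValueError(f"structure {mask.name!r} is empty")
    vmax = float(v.max())
    n_bins = int(np.ceil(vmax / bin_width)) + 2
    edges = bin_width * np.arange(n_bins + 1)
    vs = np.sort(v)
    cum = 1.0 - np.searchsorted(vs, edges, side="left") / v.size
    return DVH(mask.name, edges, cum, mask.volume_cm3())


def dose_at_volume(dvh: DVH, fraction: float) -> float:
    """Largest dose such that at least ``fraction`` of the volume receives it
    (linear interpolation between bins)."""
    if not 0 < fraction <= 1:
        raise ValueError("volume fraction must be in (0, 1]; for fraction 0 use the maximum dose")
    cum = dvh.cum_fraction
    idx = np.flatnonzero(cum >= fraction)
    if idx.size == 0:
        return 0.0
    i = idx[-1]
    if i + 1 >= len(cum) or cum[i] == cum[i + 1]:
        return float(dvh.edges_gy[i])
    f = (cum[i] - fraction) / (cum[i] - cum[i + 1])
    return float(dvh.edges_gy[i] + f * dvh.bin_width)


def volume_at_dose(dvh: DVH, dose_gy: float) -> tuple[float, float]:
    """(absolute cm^3, fraction) of the structure receiving >= ``dose_gy``."""
    frac = float(np.interp(dose_gy, dvh.edges_gy, dvh.cum_fraction))
    return frac * dvh.volume_cm3, frac


@dataclass
class MetricsReport:
    """The whole-brain metric set for one dose grid."""

    rx_gy: float
    brain_d99_gy: float | None = None
    brain_d95_gy: float | None = None
    brain_d1_gy: float | None = None
    eye_mean_gy: dict = field(default_factory=dict)  # name -> Gy
    lens_max_gy: dict = field(default_factory=dict)  # name -> Gy
    v107_cm3: float | None = None
    v107_pct_of_brain: float | None = None
    max_hotspot_pct: float | None = None
    max_dose_gy: float | None = None
    missing: list = field(default_factory=list)

    def as_flat_dict(self) -> dict:
        d = {
            "rx_gy": self.rx_gy,
            "brain_d99_gy": self.brain_d99_gy,
            "brain_d95_gy": self.brain_d95_gy,
            "brain_d1_gy": self.brain_d1_gy,
            "v107_cm3": self.v107_cm3,
            "v107_pct_of_brain": self.v107_pct_of_brain,
            "max_hotspot_pct": self.max_hotspot_pct,
            "max_dose_gy": self.max_dose_gy,
        }
        for k, v in self.eye_mean_gy.items():
            d[f"{k}_mean_gy"] = v
        for k, v in self.lens_max_gy.items():
            d[f"{k}_max_gy"] = v
        return d


def _max_dose(dose_values: np.ndarray, mask: np.ndarray, voxel_cm3: float, small_volume_cc: float) -> float:
    """Maximum structure dose; optionally dose to the hottest small volume."""
    v = dose_values[mask]
    if small_volume_cc <= 0:
        return float(v.max())
    n = max(int(round(small_volume_cc / voxel_cm3)), 1)
    n = min(n, v.size)
    return float(np.partition(v, -n)[-n])


def plan_metrics(
    plan_dose: ImageGrid,
    masks: dict[str, StructureMask],
    rx_gy: float = 30.0,
    hotspot_fraction: float = 1.07,
    bin_width: float = DEFAULT_BIN_GY,
    max_dose_volume_cc: float = 0.0,
) -> MetricsReport:
    """Compute the clinical metric set from a plan dose grid.

    Hotspot volume V107% is measured over the body (hotspots live in skull
    and scalp, outside the brain) but reported as a percentage of the brain
    structure volume.  The maximum hotspot percentage is 100 * max body dose
    / Rx.  ``max_dose_volume_cc`` > 0 switches lens/plan maxima from the
    single hottest voxel to the dose covering that small volume.
    Missing structures are listed in the report; the rest is still computed.
    """
    rep = MetricsReport(rx_gy=rx_gy)
    if "brain" in masks:
        dvh = compute_dvh(plan_dose, masks["brain"], bin_width)
        rep.brain_d99_gy = dose_at_volume(dvh, 0.99)
        rep.brain_d95_gy = dose_at_volume(dvh, 0.95)
        rep.brain_d1_gy = dose_at_volume(dvh, 0.01)
    else:
        rep.missing.append("brain")
    for name in ("eye_L", "eye_R"):
        if name in masks:
            rep.eye_mean_gy[name] = float(plan_dose.values[masks[name].mask].mean())
        else:
            rep.missing.append(name)
    voxel_cm3 = plan_dose.voxel_volume_cm3
    for name in ("lens_L", "lens_R"):
        if name in masks:
            rep.lens_max_gy[name] = _max_dose(
                plan_dose.values, masks[name].mask, voxel_cm3, max_dose_volume_cc
            )
        else:
            rep.missing.append(name)
    if "body" in masks:
        body = masks["body"]
        thr = hotspot_fraction * rx_gy
        hot = (plan_dose.values >= thr) & body.mask
        rep.v107_cm3 = float(hot.sum()) * voxel_cm3
        if "brain" in masks:
            rep.v107_pct_of_brain = 100.0 * rep.v107_cm3 / masks["brain"].volume_cm3()
        rep.max_dose_gy = _max_dose(
            plan_dose.values, body.mask, voxel_cm3, max_dose_volume_cc
        )
        rep.max_hotspot_pct = 100.0 * float(plan_dose.values[body.mask].max()) / rx_gy
    else:
        rep.missing.append("body")
    return rep
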