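"""Toy megavoltage photon dose model.

Clinical FIF planning delegates dosimetry to a treatment planning system;
this module is its deliberately simple stand-in, built to reproduce the dose
*geometry* that drives the FIF loop rather than clinical accuracy.  Per-field
dose at a voxel factorizes as

    D = T(u, v) * ISq(r) * B(d)

where T is the binary MLC aperture transmission at the voxel's divergent BEV
projection (optionally Gaussian-blurred for a penumbra), ISq = (SAD/r)^2 is
inverse-square falloff with distance r from the source, and B is a
depth-dose factor of the radiological depth d (density line integral along
the ray from the source-side surface):

    B(d) = d / d_max                      for d <  d_max   (build-up ramp)
    B(d) = exp(-mu * (d - d_max))         for d >= d_max   (attenuation)

With water-like mu and d_max this produces the classic opposed-lateral
pattern: peak dose just past build-up in the bone shell and scalp, a cooler
midline, and hotter short-chord periphery — the hotspots the FIF loop
removes.  Plan dose is the weighted sum of cached unit-weight field doses;
the weight optimizer never re-raytraces.

Radiological depth is computed on a divergent beam-space raster (fan
coordinates u, v at the isocenter plane, arc length s along each ray) by
sampling the density grid and accumulating, then interpolated back to the
voxel grid.  Depth and inverse-square factors depend only on the beam
geometry, so they are cached per geometry and shared by all subfields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .bev import Aperture, BeamGeometry
from .grids import GridAlignmentError, ImageGrid


@dataclass
class EngineParams:
    """Dose-model parameters (water-equivalent 6 MV regime).

    mu_cm : effective linear attenuation coefficient, 1/cm.
    d_max_cm : build-up depth, cm.
    use_inverse_square : include (SAD/r)^2 falloff.
    penumbra_sigma_mm : Gaussian blur of the aperture transmission at the
        isocenter plane; 0 keeps transmission binary and aperture-subset
        invariants exact.
    step_mm / bev_sample_mm : beam-space raster resolution for the depth table.
    """

    mu_cm: float = 0.046
    d_max_cm: float = 1.5
    use_inverse_square: bool = True
    penumbra_sigma_mm: float = 0.0
    step_mm: float = 2.0
    bev_sample_mm: float = 2.0

    def validate(self) -> None:
        if self.mu_cm <= 0:
            raise ValueError("attenuation coefficient mu must be positive")
        if self.d_max_cm < 0:
            raise ValueError("build-up depth must be non-negative")
        if self.step_mm <= 0 or self.bev_sample_mm <= 0:
            raise ValueError("raster steps must be positive")


@dataclass
class FieldDose:
    """Unit-weight dose grid (Gy per weight) for one field."""

    field_id: str
    dose: ImageGrid


def depth_dose_factor(depth_cm: np.ndarray, params: EngineParams) -> np.ndarray:
    """Build-up ramp then exponential attenuation; continuous at d_max."""
    d = np.asarray(depth_cm, dtype=float)
    if params.d_max_cm == 0:
        return np.exp(-params.mu_cm * d)
    ramp = d / params.d_max_cm
    atten = np.exp(-params.mu_cm * (d - params.d_max_cm))
    return np.where(d < params.d_max_cm, ramp, atten)


class DoseEngine:
    """Raycast dose calculator bound to one density grid.

    Per-geometry quantities (voxel BEV coordinates, radiological depth,
    inverse-square and depth-dose factors) are computed once and cached, so a
    new subfield on an existing beam costs only an aperture-transmission
    lookup and a multiply.
    """

    def __init__(self, density: ImageGrid, params: EngineParams | None = None):
        self.density = density
        self.params = params or EngineParams()
        self.params.validate()
        self._cache: dict = {}

    # ---------------- geometry-level cache ----------------

    def _geom_key(self, geom: BeamGeometry):
        return (geom.gantry_deg, geom.isocenter, geom.sad_mm)

    def _voxel_positions(self) -> np.ndarray:
        xs, ys, zs = self.density.voxel_centers()
        return np.stack(np.meshgrid(xs, ys, zs, indexing="ij"), axis=-1)

    def _geom_fields(self, geom: BeamGeometry) -> dict:
        key = self._geom_key(geom)
        if key in self._cache:
            return self._cache[key]
        p = self.params
        pts = self._voxel_positions()
        u, v, t = geom.project_points(pts.reshape(-1, 3))
        shape = self.density.shape
        u = u.reshape(shape)
        v = v.reshape(shape)
        t = t.reshape(shape)
        r = t * np.sqrt(1.0 + (u * u + v * v) / geom.sad_mm**2)

        depth = self._radiological_depth(geom, u, v, r)
        b = depth_dose_factor(depth, p)
        if p.use_inverse_square:
            b = b * (geom.sad_mm / r) ** 2
        entry = {"u": u, "v": v, "bisq": b}
        self._cache[key] = entry
        return entry

    def _radiological_depth(self, geom, u_vox, v_vox, r_vox) -> np.ndarray:
        """Depth (cm) from the surface to each voxel along its divergent ray."""
        p = self.params
        half = max(
            float(np.abs(u_vox).max()), float(np.abs(v_vox).max())
        ) + 2 * p.bev_sample_mm
        ug = np.arange(-half, half + p.bev_sample_mm, p.bev_sample_mm)
        vg = ug.copy()
        s0 = float(r_vox.min()) - 2 * p.step_mm
        s1 = float(r_vox.max()) + 2 * p.step_mm
        sg = np.arange(s0, s1 + p.step_mm, p.step_mm)

        src = geom.source_position
        # unit ray direction for each (u, v): (iso + u*uhat + v*vhat - src) / norm
        duv = (
            geom.beam_direction[None, None, :] * geom.sad_mm
            + ug[:, None, None] * geom.u_axis[None, None, :]
            + vg[None, :, None] * geom.v_axis[None, None, :]
        )
        norm = np.sqrt(geom.sad_mm**2 + (ug**2)[:, None] + (vg**2)[None, :])
        e = duv / norm[:, :, None]

        # sample density along every ray
        pts = src[None, None, None, :] + e[:, :, None, :] * sg[None, None, :, None]
        spacing = np.asarray(self.density.spacing)
        origin = np.asarray(self.density.origin)
        idx = (pts - origin) / spacing
        dens = ndimage.map_coordinates(
            self.density.values,
            [idx[..., 0].ravel(), idx[..., 1].ravel(), idx[..., 2].ravel()],
            order=1,
            mode="constant",
            cval=0.0,
        ).reshape(len(ug), len(vg), len(sg))
        step_cm = p.step_mm / 10.0
        depth = np.cumsum(dens, axis=2) * step_cm - dens * (step_cm / 2.0)

        # interpolate the depth table at each voxel's (u, v, s)
        iu = (u_vox - ug[0]) / p.bev_sample_mm
        iv = (v_vox - vg[0]) / p.bev_sample_mm
        is_ = (r_vox - sg[0]) / p.step_mm
        out = ndimage.map_coordinates(
            depth,
            [iu.ravel(), iv.ravel(), is_.ravel()],
            order=1,
            mode="nearest",
        ).reshape(u_vox.shape)
        return np.maximum(out, 0.0)

    # ---------------- public API ----------------

    def compute_field_dose(
        self, geom: BeamGeometry, aperture: Aperture, field_id: str = ""
    ) -> FieldDose:
        """Unit-weight dose grid for one shaped field."""
        g = self._geom_fields(geom)
        p = self.params
        if p.penumbra_sigma_mm > 0:
            t = self._blurred_transmission(aperture, g["u"], g["v"])
        else:
            t = aperture.transmission(g["u"], g["v"])
        return FieldDose(field_id, self.density.like(t * g["bisq"]))

    def _blurred_transmission(self, aperture, u_vox, v_vox):
        p = self.params
        bev = aperture.bev
        t_map = ndimage.gaussian_filter(
            bev.values.astype(float), p.penumbra_sigma_mm / bev.spacing[0]
        )
        iu = (u_vox - bev.origin[0]) / bev.spacing[0]
        iv = (v_vox - bev.origin[1]) / bev.spacing[1]
        return ndimage.map_coordinates(
            t_map, [iu.ravel(), iv.ravel()], order=1, mode="constant", cval=0.0
        ).reshape(u_vox.shape)


def compute_field_dose(
    density: ImageGrid,
    geom: BeamGeometry,
    aperture: Aperture,
    params: EngineParams | None = None,
    field_id: str = "",
) -> FieldDose:
    """One-shot field dose (no cross-call caching; see :class:`DoseEngine`)."""
    return DoseEngine(density, params).compute_field_dose(geom, aperture, field_id)


def compute_plan_dose(field_doses: list[FieldDose], weights) -> ImageGrid:
    """Voxelwise weighted superposition of per-field unit doses."""
    weights = np.asarray(weights, dtype=float)
    if len(field_doses) != len(weights):
        raise ValueError("one weight per field required")
    if np.any(weights < 0):
        raise ValueError("field weights must be non-negative")
    ref = field_doses[0].dose
    total = np.zeros(ref.shape)
    for fd, w in zip(field_doses, weights):
        if not fd.dose.same_frame(ref):
            raise GridAlignmentError("field dose grids are not co-registered")
        total += w * fd.dose.values
    return ref.like(total)
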