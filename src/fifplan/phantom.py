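"""Synthetic head phantoms for whole-brain planning experiments.

No public CT data accompany this planner, so the substrate is a parametric
head phantom: an ellipsoidal body of soft tissue wrapped in a higher-density
bone shell, enclosing an ellipsoidal brain, with small anterior eye and lens
spheres.  Under two parallel-opposed lateral beams this geometry reproduces
the clinical failure mode the field-in-field technique targets: short lateral
ray paths through the skull and scalp receive more dose than the midline, so
supra-prescription hotspots form on the periphery.

Geometry is explicit plumbing, not anatomy: densities and semi-axes are
configuration values.  Several presets span the hotspot regimes used in
testing, from a deliberately inhomogeneous "stress" head to a wide, flat-dose
geometry with no hotspot at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grids import ImageGrid, StructureMask


class GeometryError(ValueError):
    """A requested structure does not fit inside the phantom head."""


@dataclass
class PhantomSpec:
    """Parametric description of a head phantom.

    All lengths are mm, densities g/cm^3.  ``jitter_amplitude_mm`` adds a
    seeded low-order sinusoidal perturbation to the outer body (and bone)
    surface so that hotspot connected components are irregular rather than
    perfect ellipsoid shells.
    """

    body_semi_axes: tuple[float, float, float] = (75.0, 95.0, 85.0)
    brain_semi_axes: tuple[float, float, float] = (60.0, 75.0, 65.0)
    brain_center: tuple[float, float, float] = (0.0, 5.0, 12.0)
    bone_thickness_mm: float = 6.0
    density_air: float = 0.0
    density_soft: float = 1.0
    density_bone: float = 1.6
    eye_radius_mm: float = 11.0
    lens_radius_mm: float = 4.0
    # anterior-inferior orbits, placed so their lateral-beam BEV shadows
    # clear the dilated brain projection (eye blocks must not cost coverage)
    eye_centers: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (25.0, -61.0, -39.0),
        (-25.0, -61.0, -39.0),
    )
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    padding_mm: float = 6.0
    jitter_amplitude_mm: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if any(a <= 0 for a in self.body_semi_axes + self.brain_semi_axes):
            raise GeometryError("semi-axes must be positive")
        if self.bone_thickness_mm < 0 or self.bone_thickness_mm >= min(self.body_semi_axes):
            raise GeometryError("bone thickness must be non-negative and smaller than every body semi-axis")
        for d in (self.density_air, self.density_soft, self.density_bone):
            if d < 0:
                raise GeometryError("densities must be non-negative")
        if self.lens_radius_mm > self.eye_radius_mm:
            raise GeometryError("lens radius exceeds eye radius")


def _ellipsoid_rho(x, y, z, center, semi_axes):
    """Normalized radial coordinate: <=1 inside the ellipsoid."""
    return np.sqrt(
        ((x - center[0]) / semi_axes[0]) ** 2
        + ((y - center[1]) / semi_axes[1]) ** 2
        + ((z - center[2]) / semi_axes[2]) ** 2
    )


def _surface_jitter(x, y, z, center, amplitude_mm, mean_axis_mm, seed):
    """Smooth seeded angular modulation of the ellipsoid boundary, in rho units."""
    if amplitude_mm <= 0:
        return 0.0
    rng = np.random.default_rng(seed)
    dx, dy, dz = x - center[0], y - center[1], z - center[2]
    r = np.sqrt(dx * dx + dy * dy + dz * dz) + 1e-9
    theta = np.arccos(np.clip(dz / r, -1, 1))
    phi = np.arctan2(dy, dx)
    g = np.zeros_like(r)
    for _ in range(4):
        n = rng.integers(2, 5)
        m = rng.integers(2, 5)
        p1, p2 = rng.uniform(0, 2 * np.pi, 2)
        g += np.sin(n * theta + p1) * np.sin(m * phi + p2)
    g /= 4.0  # |g| <= 1
    return amplitude_mm * g / mean_axis_mm


def make_head_phantom(spec: PhantomSpec) -> tuple[ImageGrid, dict[str, StructureMask]]:
    """Build the density grid and structure masks for a head phantom.

    Returns the density :class:`ImageGrid` and masks named ``body``, ``bone``,
    ``brain``, ``eye_L``, ``eye_R``, ``lens_L``, ``lens_R``.  The grid is
    centered on the body ellipsoid with ``padding_mm`` of air on every side.
    Deterministic for a fixed spec (including its seed).

    Raises
    ------
    GeometryError
        If the brain does not fit inside the bone shell or an eye/lens is not
        fully inside the body.
    """
    spec.validate()
    a = np.asarray(spec.body_semi_axes)
    sp = np.asarray(spec.spacing)
    half = a + spec.padding_mm
    n = np.ceil(2 * half / sp).astype(int) + 1
    origin = -((n - 1) * sp) / 2.0
    xs, ys, zs = (origin[i] + sp[i] * np.arange(n[i]) for i in range(3))
    x, y, z = np.meshgrid(xs, ys, zs, indexing="ij")

    body_center = (0.0, 0.0, 0.0)
    mean_axis = float(np.mean(a))
    jit = _surface_jitter(x, y, z, body_center, spec.jitter_amplitude_mm, mean_axis, spec.seed)
    rho_body = _ellipsoid_rho(x, y, z, body_center, a)
    body = rho_body <= 1.0 + jit

    inner_axes = a - spec.bone_thickness_mm
    if spec.bone_thickness_mm > 0:
        rho_inner = _ellipsoid_rho(x, y, z, body_center, inner_axes)
        soft_interior = rho_inner <= 1.0 + jit
        bone = body & ~soft_interior
    else:
        soft_interior = body.copy()
        bone = np.zeros_like(body)

    brain = _ellipsoid_rho(x, y, z, spec.brain_center, spec.brain_semi_axes) <= 1.0
    if np.any(brain & ~soft_interior):
        raise GeometryError("brain ellipsoid does not fit inside the bone shell")

    eyes = []
    lenses = []
    for cx, cy, cz in spec.eye_centers:
        eye = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= spec.eye_radius_mm**2
        # lens sits at the anterior pole of the eye
        ly = cy - (spec.eye_radius_mm - spec.lens_radius_mm)
        lens = (x - cx) ** 2 + (y - ly) ** 2 + (z - cz) ** 2 <= spec.lens_radius_mm**2
        if np.any(eye & ~body):
            raise GeometryError(f"eye at ({cx}, {cy}, {cz}) pokes outside the body")
        eyes.append(eye)
        lenses.append(lens & eye)

    eye_union = eyes[0] | eyes[1]
    brain = brain & ~eye_union  # disjointness by construction
    bone = bone & ~eye_union  # orbital openings: eyes are soft tissue

    density = np.where(bone, spec.density_bone,
                       np.where(body, spec.density_soft, spec.density_air))
    grid = ImageGrid(density.astype(np.float64), tuple(sp), tuple(origin))

    def m(name, arr):
        return StructureMask(name, arr, grid.spacing, grid.origin)

    masks = {
        "body": m("body", body),
        "bone": m("bone", bone),
        "brain": m("brain", brain),
        "eye_L": m("eye_L", eyes[0]),
        "eye_R": m("eye_R", eyes[1]),
        "lens_L": m("lens_L", lenses[0]),
        "lens_R": m("lens_R", lenses[1]),
    }
    return grid, masks


# --------------------------------------------------------------------------
# Presets spanning the hotspot regimes exercised in testing.
# --------------------------------------------------------------------------

def default_phantom_spec(**overrides) -> PhantomSpec:
    """Adult-head-like geometry; develops peripheral skull/scalp hotspots
    under equal-weight opposed laterals."""
    return replace(PhantomSpec(), **overrides)


def stress_phantom_spec(**overrides) -> PhantomSpec:
    """Strongly eccentric head with a thick bone shell: the chord-length
    spread across the field is large, so a qualifying hotspot survives every
    iteration and the subfield budget is exhausted."""
    spec = PhantomSpec(
        body_semi_axes=(75.0, 108.0, 98.0),
        brain_semi_axes=(60.0, 80.0, 70.0),
        brain_center=(0.0, 5.0, 12.0),
        bone_thickness_mm=8.0,
        eye_centers=((26.0, -78.0, -28.0), (-26.0, -78.0, -28.0)),
        seed=1,
    )
    return replace(spec, **overrides)


def mild_phantom_spec(**overrides) -> PhantomSpec:
    """Wide, mildly eccentric head with a small brain and thin bone: the
    initial hotspot is a few percent above target, so the loop can converge
    to the 107% level within the subfield budget."""
    spec = PhantomSpec(
        body_semi_axes=(62.0, 116.0, 117.0),
        brain_semi_axes=(45.0, 64.0, 55.0),
        brain_center=(0.0, 0.0, 10.0),
        bone_thickness_mm=5.0,
        eye_centers=((22.0, -88.0, -15.0), (-22.0, -88.0, -15.0)),
        seed=2,
    )
    return replace(spec, **overrides)


def flat_phantom_spec(**overrides) -> PhantomSpec:
    """Very wide head around a small central brain, no bone shell: ray paths
    vary little across the field, the normalized opposed-pair dose stays
    below the hotspot threshold, and the loop should add no subfields."""
    spec = PhantomSpec(
        body_semi_axes=(55.0, 140.0, 135.0),
        brain_semi_axes=(30.0, 40.0, 38.0),
        brain_center=(0.0, 0.0, 0.0),
        bone_thickness_mm=0.0,
        eye_centers=((20.0, -105.0, -10.0), (-20.0, -105.0, -10.0)),
        jitter_amplitude_mm=0.0,
        seed=3,
    )
    return replace(spec, **overrides)
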