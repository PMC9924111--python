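"""Beam geometry, beam's-eye-view projection, and MLC aperture shaping.

A treatment beam is a point source at source-axis distance (SAD) from the
machine isocenter.  Anatomy is projected through the source onto the
isocenter plane (the beam's-eye-view, BEV), with similar-triangle
magnification.  Apertures are shaped by a multi-leaf collimator (MLC): paired
leaves travel along the BEV u-axis, one pair per leaf row along v, each pair
leaving a single open interval [x_left, x_right].

The whole-brain aperture built here is a deliberately simple stand-in for
landmark-based clinical field design: the brain BEV dilated by a flash
margin, minus the projections of blocked structures (eyes, lenses), conformed
to the MLC.

Conventions: gantry angle 0 puts the source anterior; 90/270 are the left and
right laterals used for whole-brain plans.  BEV u is the leaf-travel
(crossplane) axis, v the leaf-row (inplane, superior) axis; opposed lateral
beams see the same anatomy mirrored in u.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .grids import ImageGrid, StructureMask


class BeamGeometryError(ValueError):
    pass


class DegenerateApertureError(ValueError):
    """Blocking removed all open area from an aperture."""


@dataclass(frozen=True)
class BeamGeometry:
    """One external beam: gantry angle, isocenter, SAD and energy label."""

    gantry_deg: float
    isocenter: tuple[float, float, float] = (0.0, 0.0, 0.0)
    sad_mm: float = 1000.0
    energy: str = "6 MV"

    def __post_init__(self) -> None:
        if self.sad_mm <= 0:
            raise BeamGeometryError("SAD must be positive")

    @property
    def source_direction(self) -> np.ndarray:
        """Unit vector from isocenter toward the source (in the axial plane)."""
        th = np.deg2rad(self.gantry_deg)
        return np.array([np.sin(th), -np.cos(th), 0.0])

    @property
    def source_position(self) -> np.ndarray:
        return np.asarray(self.isocenter) + self.sad_mm * self.source_direction

    @property
    def beam_direction(self) -> np.ndarray:
        """Unit vector from source toward isocenter."""
        return -self.source_direction

    @property
    def u_axis(self) -> np.ndarray:
        """BEV crossplane axis (leaf travel direction), = beam_dir x z."""
        u = np.cross(self.beam_direction, np.array([0.0, 0.0, 1.0]))
        n = np.linalg.norm(u)
        if n < 1e-9:
            raise BeamGeometryError("vertical beams are not supported")
        return u / n

    @property
    def v_axis(self) -> np.ndarray:
        """BEV inplane axis: patient superior."""
        return np.array([0.0, 0.0, 1.0])

    def opposed(self) -> "BeamGeometry":
        return replace(self, gantry_deg=(self.gantry_deg + 180.0) % 360.0)

    def project_points(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Project world points (..., 3) to BEV (u, v) at the isocenter plane.

        Returns (u, v, t) where t is the distance along the central axis from
        the source; u, v are scaled to the isocenter plane by SAD/t.
        """
        rel = np.asarray(points) - self.source_position
        t = rel @ self.beam_direction
        if np.any(t <= 0):
            raise BeamGeometryError("points at or behind the source plane")
        scale = self.sad_mm / t
        u = scale * (rel @ self.u_axis)
        v = scale * (rel @ self.v_axis)
        return u, v, t


@dataclass
class BevMap:
    """Boolean map on a regular (u, v) raster at the isocenter plane."""

    values: np.ndarray  # shape (nu, nv), axis 0 = u, axis 1 = v
    spacing: tuple[float, float]  # (du, dv) mm
    origin: tuple[float, float]  # (u, v) of pixel (0, 0) center, mm

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        nu, nv = self.values.shape
        return (
            self.origin[0] + self.spacing[0] * np.arange(nu),
            self.origin[1] + self.spacing[1] * np.arange(nv),
        )

    def same_frame(self, other: "BevMap") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def area_cm2(self) -> float:
        return float(self.values.sum()) * self.spacing[0] * self.spacing[1] / 100.0


def bev_frame(half_extent_mm: float = 160.0, spacing_mm: float = 2.0) -> tuple[int, float]:
    """Number of pixels per axis and origin for a centered symmetric BEV frame."""
    n = 2 * int(np.ceil(half_extent_mm / spacing_mm)) + 1
    origin = -spacing_mm * (n // 2)
    return n, origin


def project_to_bev(
    mask: StructureMask,
    geom: BeamGeometry,
    bev_spacing: float = 2.0,
    half_extent_mm: float = 160.0,
) -> BevMap:
    """Divergent projection of a 3D mask onto the isocenter-plane BEV raster.

    A BEV pixel is set when the ray from the source through that pixel
    intersects the mask.  Voxel centers are projected with similar-triangle
    magnification and splatted to the nearest pixel; a one-pixel morphological
    closing fills sampling gaps left by magnification.  An empty mask yields
    an empty map.  The frame is symmetric about the central axis so that
    opposed-beam maps mirror exactly.
    """
    n, o = bev_frame(half_extent_mm, bev_spacing)
    out = np.zeros((n, n), dtype=bool)
    idx = np.argwhere(mask.mask)
    if idx.size == 0:
        return BevMap(out, (bev_spacing, bev_spacing), (o, o))

    src = geom.source_position
    lo = mask.origin + idx.min(axis=0) * np.asarray(mask.spacing)
    hi = mask.origin + idx.max(axis=0) * np.asarray(mask.spacing)
    if np.all(src >= lo - 1e-9) and np.all(src <= hi + 1e-9):
        raise BeamGeometryError("beam source lies inside the mask bounding box")

    pts = np.asarray(mask.origin) + idx * np.asarray(mask.spacing)
    u, v, _ = geom.project_points(pts)
    iu = np.rint((u - o) / bev_spacing).astype(int)
    iv = np.rint((v - o) / bev_spacing).astype(int)
    keep = (iu >= 0) & (iu < n) & (iv >= 0) & (iv < n)
    out[iu[keep], iv[keep]] = True
    out = ndimage.binary_closing(out, structure=np.ones((3, 3), dtype=bool))
    return BevMap(out, (bev_spacing, bev_spacing), (o, o))


@dataclass
class Aperture:
    """A shaped field opening: MLC leaf intervals plus their BEV raster.

    ``intervals`` has one (x_left, x_right) pair per leaf row in mm at the
    isocenter plane; a closed pair has x_left == x_right.  Leaf row k spans
    v in [leaf_v0 + k*w, leaf_v0 + (k+1)*w).  ``bev`` is the rasterization of
    the MLC realization on the shared BEV frame, so map and leaves agree
    exactly.  ``jaw`` is (u_min, u_max, v_min, v_max).
    """

    intervals: np.ndarray  # (n_leaves, 2)
    leaf_width_mm: float
    leaf_v0: float
    bev: BevMap
    jaw: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if np.any(self.intervals[:, 1] < self.intervals[:, 0]):
            raise ValueError("leaf interval right edge left of left edge")

    @property
    def n_leaves(self) -> int:
        return len(self.intervals)

    def is_open(self) -> bool:
        return bool(np.any(self.intervals[:, 1] > self.intervals[:, 0]))

    def open_area_cm2(self) -> float:
        widths = np.clip(self.intervals[:, 1] - self.intervals[:, 0], 0, None)
        return float(widths.sum() * self.leaf_width_mm) / 100.0

    def transmission(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Binary transmission at isocenter-plane coordinates (vectorized)."""
        u = np.asarray(u)
        v = np.asarray(v)
        k = np.floor((v - self.leaf_v0) / self.leaf_width_mm).astype(int)
        k_ok = (k >= 0) & (k < self.n_leaves)
        kc = np.clip(k, 0, self.n_leaves - 1)
        left = self.intervals[kc, 0]
        right = self.intervals[kc, 1]
        open_ = k_ok & (u >= left) & (u < right)
        u0, u1, v0, v1 = self.jaw
        open_ &= (u >= u0) & (u < u1) & (v >= v0) & (v < v1)
        return open_.astype(float)


def _rasterize(intervals, leaf_width, leaf_v0, jaw, frame: BevMap) -> BevMap:
    uu, vv = frame.coords()
    ap = Aperture(intervals, leaf_width, leaf_v0, frame, jaw)
    t = ap.transmission(uu[:, None], vv[None, :])
    return BevMap(t > 0.5, frame.spacing, frame.origin)


def _longest_run(band: np.ndarray) -> tuple[int, int]:
    """Start and end (inclusive) column indices of the longest True run."""
    idx = np.flatnonzero(band)
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], splits + 1])
    ends = np.concatenate([splits, [idx.size - 1]])
    lengths = ends - starts
    best = int(np.argmax(lengths))  # ties: lowest u, deterministic
    return int(idx[starts[best]]), int(idx[ends[best]])


def conform_mlc(
    region: BevMap,
    leaf_width_mm: float = 5.0,
    rule: str = "over_cover",
    avoid: BevMap | None = None,
) -> Aperture:
    """Conform MLC leaves to a BEV region.

    Leaf rows tile the v axis starting at the lower edge of the map; rows
    without region are closed and the jaw is the bounding rectangle of the
    open leaves.  An empty region yields an all-closed aperture.  Within each
    leaf row the single open interval is chosen by ``rule``:

    * ``over_cover`` — the [min, max] u-extent (outer pixel edges) of the
      region pixels in that row.  Conservative for a target opening: the
      leaves never cut into the region.
    * ``largest_open_run`` — the longest contiguous run of region pixels.
      A leaf pair can only leave one open interval, so when a blocked area
      splits a row the row must give up its smaller lobe; this is the rule
      subfield shaping uses, closing in on a hotspot from one side the way a
      planner would.

    ``avoid`` marks pixels the leaves should cover if at all possible: any
    column of a leaf band containing an avoid pixel is treated as closed when
    choosing the open run (blocking wins over opening inside a band), while
    plain region collapse errs toward keeping columns open.
    """
    if rule not in ("over_cover", "largest_open_run"):
        raise ValueError(f"unknown MLC conformance rule {rule!r}")
    if avoid is not None and not avoid.same_frame(region):
        raise ValueError("avoid map frame differs from region frame")
    du, dv = region.spacing
    nu, nv = region.values.shape
    uu, _ = region.coords()
    leaf_v0 = region.origin[1] - dv / 2.0
    n_leaves = int(np.ceil(nv * dv / leaf_width_mm))
    intervals = np.zeros((n_leaves, 2))
    for k in range(n_leaves):
        v_lo = leaf_v0 + k * leaf_width_mm
        v_hi = v_lo + leaf_width_mm
        # pixel rows whose center v lies in this leaf band
        j0 = int(np.ceil((v_lo - region.origin[1]) / dv - 1e-9))
        j1 = int(np.ceil((v_hi - region.origin[1]) / dv - 1e-9))
        j0, j1 = max(j0, 0), min(j1, nv)
        if j1 <= j0:
            continue
        band = region.values[:, j0:j1].any(axis=1)
        if avoid is not None:
            band &= ~avoid.values[:, j0:j1].any(axis=1)
        if band.any():
            if rule == "over_cover":
                cols = np.flatnonzero(band)
                c0, c1 = int(cols[0]), int(cols[-1])
            else:
                c0, c1 = _longest_run(band)
            intervals[k] = (uu[c0] - du / 2.0, uu[c1] + du / 2.0)

    open_rows = np.flatnonzero(intervals[:, 1] > intervals[:, 0])
    if open_rows.size:
        jaw = (
            float(intervals[open_rows, 0].min()),
            float(intervals[open_rows, 1].max()),
            leaf_v0 + open_rows[0] * leaf_width_mm,
            leaf_v0 + (open_rows[-1] + 1) * leaf_width_mm,
        )
    else:
        jaw = (0.0, 0.0, 0.0, 0.0)
    frame = BevMap(np.zeros_like(region.values), region.spacing, region.origin)
    bev = _rasterize(intervals, leaf_width_mm, leaf_v0, jaw, frame)
    return Aperture(intervals, leaf_width_mm, leaf_v0, bev, jaw)


def make_whole_brain_aperture(
    brain_bev: BevMap,
    blocked_bevs: list[BevMap] | None = None,
    margin_mm: float = 7.0,
    leaf_width_mm: float = 5.0,
) -> Aperture:
    """Simplified whole-brain field aperture.

    The brain BEV is dilated by a flash ``margin_mm`` (Euclidean disk), the
    union of blocked-structure BEVs (eyes, lenses) is subtracted, the largest
    connected open region is kept, and the result is MLC-conformed.
    """
    region = brain_bev.values
    if margin_mm > 0 and region.any():
        dist = ndimage.distance_transform_edt(
            ~region, sampling=brain_bev.spacing
        )
        region = dist <= margin_mm
    for blocked in blocked_bevs or []:
        if not blocked.same_frame(brain_bev):
            raise ValueError("blocked BEV map frame differs from brain BEV frame")
        region = region & ~blocked.values
    if not region.any():
        raise DegenerateApertureError("blocking removed all open area")
    labels, n = ndimage.label(region)
    if n > 1:
        sizes = np.bincount(labels.ravel())[1:]
        region = labels == (1 + int(np.argmax(sizes)))
    return conform_mlc(
        BevMap(region, brain_bev.spacing, brain_bev.origin), leaf_width_mm
    )


def mirror_aperture(aperture: Aperture) -> Aperture:
    """Left-right mirror (u -> -u) for the opposed beam of a lateral pair.

    Opposed lateral beams share the superior axis but see the anatomy with
    the crossplane axis reversed, so the opposed subfield opens onto the same
    anatomy as the input.  Applying the mirror twice is the identity.
    """
    intervals = np.column_stack([-aperture.intervals[:, 1], -aperture.intervals[:, 0]])
    u0, u1, v0, v1 = aperture.jaw
    jaw = (-u1, -u0, v0, v1)
    bev = BevMap(
        aperture.bev.values[::-1, :].copy(), aperture.bev.spacing, aperture.bev.origin
    )
    return Aperture(intervals, aperture.leaf_width_mm, aperture.leaf_v0, bev, jaw)
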