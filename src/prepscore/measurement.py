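"""Deviation mapping and the seven canonical cavity readings.

After alignment, every prepared-tooth vertex is compared with the unprepared
reference surface. The signed deviation is the exact closest-surface
distance, positive where material was removed (the vertex sits below the
reference surface) and negative where the scan sits above it.

Seven readings characterise a Class-I/II style occlusal channel preparation:

* three depths (mesial, middle, distal probe points),
* two isthmus widths (buccolingual extent of the cavity at a mesial and a
  distal cross-section plane),
* two remaining-marginal-ridge distances (intact tooth structure between
  the cavity end and the mesial / distal proximal surface).

Probe geometry is never auto-detected: a :class:`LandmarkConfig` pins the
probe points, section planes and ridge segments in the reference frame, so
measurements are reproducible and auditable. Lateral distances for the depth
probes and ridge segments are measured perpendicular to the occlusal
approach axis (default +z), because the quantity of interest is where the
cavity lies in the occlusal plane, not how deep its floor happens to be.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .mesh import Mesh, SurfaceIndex, VertexMask

__all__ = [
    "DeviationMap",
    "CrossSectionPlane",
    "RidgeSegment",
    "LandmarkConfig",
    "MeasurementSet",
    "LandmarkMissError",
    "deviation_map",
    "depth_reading",
    "isthmus_width",
    "ridge_remaining",
    "measure_all",
]


class LandmarkMissError(ValueError):
    """A probe, plane or segment found no mesh vertices to measure."""

    def __init__(self, landmark: str, message: str = ""):
        self.landmark = landmark
        super().__init__(f"landmark {landmark!r}: {message or 'no vertices found'}")


@dataclass
class DeviationMap:
    """Signed deviations (mm) of prepared vertices from the reference surface.

    Positive = material removed (vertex below the reference surface).
    """

    vertex_indices: np.ndarray
    points: np.ndarray  # prepared vertex coordinates, reference frame
    deviations: np.ndarray

    def __post_init__(self) -> None:
        if not np.isfinite(self.deviations).all():
            raise ValueError("non-finite deviations")
        if len(self.vertex_indices) != len(self.deviations) or len(self.points) != len(
            self.deviations
        ):
            raise ValueError("inconsistent deviation map lengths")

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "vertex_index": self.vertex_indices,
                "x": self.points[:, 0],
                "y": self.points[:, 1],
                "z": self.points[:, 2],
                "deviation_mm": self.deviations,
            }
        )


@dataclass(frozen=True)
class CrossSectionPlane:
    """Cutting plane for an isthmus width: a point, the plane normal (along
    the mesiodistal axis) and the in-plane buccolingual width axis."""

    point: tuple[float, float, float]
    normal: tuple[float, float, float]
    width_axis: tuple[float, float, float]
    name: str = "section"

    def unit_normal(self) -> np.ndarray:
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise ValueError(f"plane {self.name!r} has a degenerate normal")
        return n / norm

    def unit_width_axis(self) -> np.ndarray:
        a = np.asarray(self.width_axis, dtype=float)
        norm = np.linalg.norm(a)
        if norm < 1e-12:
            raise ValueError(f"plane {self.name!r} has a degenerate width axis")
        return a / norm


@dataclass(frozen=True)
class RidgeSegment:
    """Probe segment for remaining marginal-ridge structure, running from the
    proximal surface toward the central fossa."""

    proximal_point: tuple[float, float, float]
    inner_point: tuple[float, float, float]
    lateral_radius: float = 0.75
    name: str = "ridge"


@dataclass
class LandmarkConfig:
    """All probe geometry, expressed in the reference mesh's frame."""

    probe_mesial: tuple[float, float, float]
    probe_middle: tuple[float, float, float]
    probe_distal: tuple[float, float, float]
    plane_mesial: CrossSectionPlane
    plane_distal: CrossSectionPlane
    ridge_mesial: RidgeSegment
    ridge_distal: RidgeSegment
    probe_radius: float = 0.25
    slab_half_width: float = 0.2
    cavity_depth_threshold: float = 0.5
    occlusal_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def unit_occlusal_axis(self) -> np.ndarray:
        a = np.asarray(self.occlusal_axis, dtype=float)
        return a / np.linalg.norm(a)

    def transformed(self, t) -> "LandmarkConfig":
        """Landmarks mapped through a rigid transform (for invariance checks)."""

        def mp(p):
            return tuple(t.apply(np.asarray(p, dtype=float)[None, :])[0])

        def mv(v):
            return tuple(t.rotation @ np.asarray(v, dtype=float))

        def plane(pl):
            return CrossSectionPlane(mp(pl.point), mv(pl.normal), mv(pl.width_axis), pl.name)

        def ridge(r):
            return RidgeSegment(mp(r.proximal_point), mp(r.inner_point), r.lateral_radius, r.name)

        return LandmarkConfig(
            probe_mesial=mp(self.probe_mesial),
            probe_middle=mp(self.probe_middle),
            probe_distal=mp(self.probe_distal),
            plane_mesial=plane(self.plane_mesial),
            plane_distal=plane(self.plane_distal),
            ridge_mesial=ridge(self.ridge_mesial),
            ridge_distal=ridge(self.ridge_distal),
            probe_radius=self.probe_radius,
            slab_half_width=self.slab_half_width,
            cavity_depth_threshold=self.cavity_depth_threshold,
            occlusal_axis=mv(self.occlusal_axis),
        )


@dataclass
class MeasurementSet:
    """The seven readings (mm), all non-negative."""

    depth_mesial: float
    depth_middle: float
    depth_distal: float
    width_mesial_isthmus: float
    width_distal_isthmus: float
    ridge_mesial_remaining: float
    ridge_distal_remaining: float

    READING_NAMES = (
        "depth_mesial",
        "depth_middle",
        "depth_distal",
        "width_mesial_isthmus",
        "width_distal_isthmus",
        "ridge_mesial_remaining",
        "ridge_distal_remaining",
    )

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"reading {f.name} must be finite and >= 0, got {v}")

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in self.READING_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.READING_NAMES], dtype=float)


def deviation_map(
    reference: Mesh | SurfaceIndex,
    prepared_aligned: Mesh,
    zone: VertexMask | None = None,
) -> DeviationMap:
    """Signed deviation of each included prepared vertex from the reference
    surface (positive = removed material)."""
    index = reference if isinstance(reference, SurfaceIndex) else SurfaceIndex(reference)
    if zone is None:
        zone = VertexMask.all_of(prepared_aligned, "occlusal zone (all)")
    zone.validate_for(prepared_aligned, minimum=1)
    idx = np.flatnonzero(zone.included)
    pts = prepared_aligned.vertices[idx]
    # SurfaceIndex signs distances positive on the outward-normal side
    # (above the surface); removal means below it, so flip the sign.
    dev = -index.signed_distances(pts)
    return DeviationMap(vertex_indices=idx, points=pts, deviations=dev)


def _lateral_distance(points: np.ndarray, origin: np.ndarray, axis: np.ndarray) -> np.ndarray:
    rel = points - origin
    return np.linalg.norm(rel - np.outer(rel @ axis, axis), axis=1)


def depth_reading(
    dmap: DeviationMap,
    probe,
    radius: float = 0.25,
    occlusal_axis=(0.0, 0.0, 1.0),
    name: str = "depth probe",
) -> float:
    """Median deviation among map vertices within ``radius`` of the probe,
    measured perpendicular to the occlusal axis; clipped below at 0."""
    probe = np.asarray(probe, dtype=float)
    axis = np.asarray(occlusal_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    lat = _lateral_distance(dmap.points, probe, axis)
    sel = lat <= radius
    if not sel.any():
        raise LandmarkMissError(name, f"no vertices within {radius} mm of probe")
    return float(max(0.0, np.median(dmap.deviations[sel])))


def isthmus_width(
    dmap: DeviationMap,
    plane: CrossSectionPlane,
    depth_threshold: float = 0.5,
    slab_half_width: float = 0.2,
) -> float:
    """Buccolingual extent of the cavity at a cross-section plane.

    Vertices within the slab around the plane whose deviation reaches
    ``depth_threshold`` form the cavity set; the width is the spread of their
    projections on the plane's width axis (0 for an empty cavity set).
    """
    n = plane.unit_normal()
    a = plane.unit_width_axis()
    p0 = np.asarray(plane.point, dtype=float)
    in_slab = np.abs((dmap.points - p0) @ n) <= slab_half_width
    if not in_slab.any():
        raise LandmarkMissError(plane.name, "cross-section plane misses the mesh")
    cavity = in_slab & (dmap.deviations >= depth_threshold)
    if not cavity.any():
        return 0.0
    proj = (dmap.points[cavity] - p0) @ a
    return float(proj.max() - proj.min())


def ridge_remaining(
    dmap: DeviationMap,
    segment: RidgeSegment,
    depth_threshold: float = 0.5,
    occlusal_axis=(0.0, 0.0, 1.0),
) -> float:
    """Intact distance along a ridge segment from the proximal surface to the
    nearest cavity vertex; the full segment length if the cavity never
    reaches the segment.

    Geometry is evaluated in the occlusal plane (positions projected along
    the occlusal axis), so the reading does not depend on cavity depth.
    """
    axis = np.asarray(occlusal_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)

    p0 = np.asarray(segment.proximal_point, dtype=float)
    p1 = np.asarray(segment.inner_point, dtype=float)
    p0f = p0 - (p0 @ axis) * axis
    p1f = p1 - (p1 @ axis) * axis
    u = p1f - p0f
    length = np.linalg.norm(u)
    if length < 1e-12:
        raise LandmarkMissError(segment.name, "zero-length ridge segment")
    u = u / length

    pts = dmap.points - np.outer(dmap.points @ axis, axis)
    rel = pts - p0f
    t = rel @ u
    lat = np.linalg.norm(rel - np.outer(t, u), axis=1)
    near = (lat <= segment.lateral_radius) & (t >= -1e-9) & (t <= length + 1e-9)
    if not near.any():
        raise LandmarkMissError(segment.name, "segment misses the mesh")
    cavity = near & (dmap.deviations >= depth_threshold)
    if not cavity.any():
        return float(length)
    return float(np.clip(t[cavity].min(), 0.0, length))


def measure_all(
    reference: Mesh | SurfaceIndex,
    prepared_aligned: Mesh,
    config: LandmarkConfig,
    zone: VertexMask | None = None,
) -> MeasurementSet:
    """Populate all seven readings; deterministic given the inputs.

    Any landmark that finds no vertices aborts with the landmark named.
    """
    ref_mesh = reference.mesh if isinstance(reference, SurfaceIndex) else reference
    axis_v = config.unit_occlusal_axis()

    def in_plane(p):
        p = np.atleast_2d(np.asarray(p, dtype=float))
        return p - np.outer(p @ axis_v, axis_v)

    ref_flat = in_plane(ref_mesh.vertices)
    lo, hi = ref_flat.min(axis=0), ref_flat.max(axis=0)
    for pname in ("probe_mesial", "probe_middle", "probe_distal"):
        p = in_plane(getattr(config, pname))[0]
        # probe height along the occlusal axis is informational (distances
        # are lateral), so only the occlusal-plane position is validated
        if ((p < lo - 1.0) | (p > hi + 1.0)).any():
            raise LandmarkMissError(pname, "probe point outside the reference footprint")

    dmap = deviation_map(reference, prepared_aligned, zone)
    axis = tuple(config.unit_occlusal_axis())
    thr = config.cavity_depth_threshold
    return MeasurementSet(
        depth_mesial=depth_reading(
            dmap, config.probe_mesial, config.probe_radius, axis, "probe_mesial"
        ),
        depth_middle=depth_reading(
            dmap, config.probe_middle, config.probe_radius, axis, "probe_middle"
        ),
        depth_distal=depth_reading(
            dmap, config.probe_distal, config.probe_radius, axis, "probe_distal"
        ),
        width_mesial_isthmus=isthmus_width(
            dmap, config.plane_mesial, thr, config.slab_half_width
        ),
        width_distal_isthmus=isthmus_width(
            dmap, config.plane_distal, thr, config.slab_half_width
        ),
        ridge_mesial_remaining=ridge_remaining(dmap, config.ridge_mesial, thr, axis),
        ridge_distal_remaining=ridge_remaining(dmap, config.ridge_distal, thr, axis),
    )
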