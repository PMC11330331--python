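"""Synthetic fixtures with analytic ground truth.

Real scan pairs of prepared teeth are not redistributable, so every fixture
is generated: a parametric occlusal surface (heightfield with Gaussian
cusps and a flat-bottomed central groove), a carved mesiodistal channel of
known depth/width/extension, rigid perturbation plus vertex noise to create
the alignment problem, and a Gaussian-copula simulator for correlated
paired examiner scores.

The heightfield has no undercuts, which keeps every ground-truth reading
analytic; all seven canonical measurements are occlusal or proximal, so
nothing of interest is lost. The default tooth is roughly molar-sized
(11 × 10 mm footprint, four cusps, 8 vertices/mm) and the default cavity is
the ideal channel: 1.50 mm deep, 1.25 mm wide, stopping 2.0 mm short of
each proximal surface.

Axes: x = mesiodistal (0 at the mesial proximal surface), y = buccolingual,
z = occlusal (up). All generators are deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .agreement import PairedScores
from .measurement import (
    CrossSectionPlane,
    LandmarkConfig,
    MeasurementSet,
    RidgeSegment,
)
from .mesh import BoxRegion, Mesh
from .registration import RigidTransform

__all__ = [
    "ToothParams",
    "CavityParams",
    "GroundTruth",
    "generate_tooth",
    "carve_cavity",
    "perturb",
    "simulate_paired_scores",
    "default_landmarks",
    "cavity_exclusion_region",
]


@dataclass(frozen=True)
class ToothParams:
    """Parametric occlusal surface.

    length/width: footprint extents in mm (mesiodistal × buccolingual);
    cusp positions are mirrored about the central groove, far enough from it
    that the channel floor region stays nearly flat (slope < ~7°, so
    closest-surface depths match vertical carve depths to < 0.02 mm).
    """

    length: float = 11.0
    width: float = 10.0
    base_height: float = 6.0
    cusp_height: float = 1.2
    cusp_sigma: float = 1.3
    cusp_x: tuple[float, float] = (3.0, 8.0)
    cusp_y_offset: float = 3.2
    groove_depth: float = 0.4
    groove_sigma: float = 1.2
    resolution: float = 8.0  # vertices per mm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0 or self.width <= 0:
            raise ValueError("footprint extents must be positive")
        if self.resolution < 1:
            raise ValueError("resolution must be >= 1 vertex/mm")

    @property
    def groove_y(self) -> float:
        return self.width / 2.0

    def surface_height(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Analytic occlusal height z(x, y)."""
        z = np.full(np.broadcast(x, y).shape, self.base_height, dtype=float)
        yc = self.groove_y
        for cx in self.cusp_x:
            for cy in (yc - self.cusp_y_offset, yc + self.cusp_y_offset):
                z = z + self.cusp_height * np.exp(
                    -((x - cx) ** 2 + (y - cy) ** 2) / (2.0 * self.cusp_sigma**2)
                )
        # quartic-exponential profile: flat-bottomed central groove
        z = z - self.groove_depth * np.exp(-(((y - yc) / self.groove_sigma) ** 4))
        return z


@dataclass(frozen=True)
class CavityParams:
    """Carved mesiodistal channel.

    depth/width in mm; start_from_mesial / end_from_distal give the intact
    ridge left at each proximal surface (the extension ground truth).
    """

    depth: float = 1.50
    width: float = 1.25
    start_from_mesial: float = 2.0
    end_from_distal: float = 2.0
    floor_roughness: float = 0.0
    wall_draft_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.depth < 0 or self.width <= 0:
            raise ValueError("depth must be >= 0 and width > 0")
        if self.start_from_mesial < 0 or self.end_from_distal < 0:
            raise ValueError("extension margins must be >= 0")


@dataclass
class GroundTruth:
    """Analytic truth for a carved fixture."""

    measurements: MeasurementSet
    cavity: CavityParams
    perturbation: RigidTransform | None = None


def generate_tooth(params: ToothParams | None = None) -> Mesh:
    """Triangulated heightfield occlusal surface; deterministic per params."""
    p = params or ToothParams()
    nx = int(round(p.length * p.resolution)) + 1
    ny = int(round(p.width * p.resolution)) + 1
    xs = np.linspace(0.0, p.length, nx)
    ys = np.linspace(0.0, p.width, ny)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    Z = p.surface_height(X, Y)
    vertices = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    # grid triangulation, CCW seen from +z so face normals point occlusally
    i, j = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1), indexing="ij")
    v00 = (i * ny + j).ravel()
    v01 = v00 + 1
    v10 = v00 + ny
    v11 = v10 + 1
    faces = np.concatenate(
        [np.column_stack([v00, v10, v11]), np.column_stack([v00, v11, v01])]
    )
    return Mesh(vertices, faces, name="synthetic tooth")


def carve_cavity(
    tooth: Mesh,
    cavity: CavityParams | None = None,
    tooth_params: ToothParams | None = None,
    depth_threshold: float = 0.5,
) -> tuple[Mesh, GroundTruth]:
    """Lower channel vertices by the carve depth and return the prepared mesh
    plus analytic ground truth.

    Vertices in the channel footprint drop to (local height − depth); with a
    non-zero wall draft the drop shoulders off linearly toward the channel
    edge. Ground-truth widths are quoted at the ``depth_threshold`` contour
    (equal to the nominal width for vertical walls).
    """
    cav = cavity or CavityParams()
    tp = tooth_params or ToothParams()
    x0 = cav.start_from_mesial
    x1 = tp.length - cav.end_from_distal
    if x1 <= x0:
        raise ValueError("cavity channel has non-positive mesiodistal extent")
    if x1 > tp.length or cav.width / 2.0 > tp.width / 2.0:
        raise ValueError("cavity channel extends outside the tooth footprint")

    v = tooth.vertices.copy()
    yc = tp.groove_y
    dx_in = (v[:, 0] >= x0 - 1e-9) & (v[:, 0] <= x1 + 1e-9)
    dy = np.abs(v[:, 1] - yc)
    half = cav.width / 2.0
    in_channel = dx_in & (dy <= half + 1e-9)

    drop = np.zeros(len(v))
    if cav.wall_draft_deg > 0:
        shoulder = cav.depth * np.tan(np.radians(cav.wall_draft_deg))
        inner = max(half - shoulder, 0.0)
        ramp = np.clip((half - dy) / max(shoulder, 1e-12), 0.0, 1.0)
        drop[in_channel] = cav.depth * np.where(dy[in_channel] <= inner, 1.0, ramp[in_channel])
    else:
        drop[in_channel] = cav.depth
    if cav.floor_roughness > 0:
        tex = cav.floor_roughness * np.sin(2 * np.pi * v[:, 0] / 0.9) * np.sin(
            2 * np.pi * v[:, 1] / 0.7
        )
        drop[in_channel & (drop >= cav.depth - 1e-9)] += tex[
            in_channel & (drop >= cav.depth - 1e-9)
        ]
    v[:, 2] -= drop

    if cav.depth >= depth_threshold:
        if cav.wall_draft_deg > 0:
            shoulder = cav.depth * np.tan(np.radians(cav.wall_draft_deg))
            width_at_thr = 2 * (half - (depth_threshold / cav.depth) * shoulder)
        else:
            width_at_thr = cav.width
        gt_depth = cav.depth
        ridge_m = cav.start_from_mesial
        ridge_d = cav.end_from_distal
    else:  # carve too shallow to register as a cavity at all
        width_at_thr = 0.0
        gt_depth = cav.depth
        ridge_m = tp.length / 2.0
        ridge_d = tp.length / 2.0
    truth = GroundTruth(
        measurements=MeasurementSet(
            depth_mesial=gt_depth,
            depth_middle=gt_depth,
            depth_distal=gt_depth,
            width_mesial_isthmus=width_at_thr,
            width_distal_isthmus=width_at_thr,
            ridge_mesial_remaining=ridge_m,
            ridge_distal_remaining=ridge_d,
        ),
        cavity=cav,
    )
    return Mesh(v, tooth.faces.copy(), name="synthetic prepared tooth"), truth


def perturb(
    mesh: Mesh,
    rotation_deg: float = 0.0,
    translation=(0.0, 0.0, 0.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    axis=(0.0, 0.0, 1.0),
) -> tuple[Mesh, RigidTransform]:
    """Apply a rigid motion (rotation about the centroid) then Gaussian
    vertex noise; returns the perturbed mesh and the exact transform so
    alignment tests can recover it."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    centroid = mesh.vertices.mean(axis=0)
    t = RigidTransform.about_axis(axis, rotation_deg, center=centroid)
    t = RigidTransform(t.rotation, t.translation + np.asarray(translation, dtype=float))
    v = t.apply(mesh.vertices)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
    return Mesh(v, mesh.faces.copy(), name=mesh.name + " (perturbed)"), t


def default_landmarks(
    tooth_params: ToothParams | None = None,
    ideal: CavityParams | None = None,
) -> LandmarkConfig:
    """Landmark configuration for the synthetic fixture, placed for the
    *ideal* channel geometry (as an examiner would configure once against
    the ideal preparation, not per student)."""
    tp = tooth_params or ToothParams()
    cav = ideal or CavityParams()
    yc = tp.groove_y
    x0 = cav.start_from_mesial
    x1 = tp.length - cav.end_from_distal
    z_probe = tp.base_height - cav.depth  # expected floor level (informational)
    span = x1 - x0
    return LandmarkConfig(
        probe_mesial=(x0 + 0.2 * span, yc, z_probe),
        probe_middle=(x0 + 0.5 * span, yc, z_probe),
        probe_distal=(x1 - 0.2 * span, yc, z_probe),
        plane_mesial=CrossSectionPlane(
            point=(x0 + 0.3 * span, yc, z_probe),
            normal=(1.0, 0.0, 0.0),
            width_axis=(0.0, 1.0, 0.0),
            name="mesial isthmus",
        ),
        plane_distal=CrossSectionPlane(
            point=(x1 - 0.3 * span, yc, z_probe),
            normal=(1.0, 0.0, 0.0),
            width_axis=(0.0, 1.0, 0.0),
            name="distal isthmus",
        ),
        ridge_mesial=RidgeSegment(
            proximal_point=(0.0, yc, tp.base_height),
            inner_point=(tp.length / 2.0, yc, tp.base_height),
            name="mesial ridge",
        ),
        ridge_distal=RidgeSegment(
            proximal_point=(tp.length, yc, tp.base_height),
            inner_point=(tp.length / 2.0, yc, tp.base_height),
            name="distal ridge",
        ),
    )


def cavity_exclusion_region(
    tooth_params: ToothParams | None = None,
    ideal: CavityParams | None = None,
    margin: float = 0.75,
) -> BoxRegion:
    """Box around the (ideal) cavity channel, used to exclude the prepared
    region from the alignment so removed material cannot bias the pose."""
    tp = tooth_params or ToothParams()
    cav = ideal or CavityParams()
    yc = tp.groove_y
    half = cav.width / 2.0 + margin
    return BoxRegion(
        lower=(cav.start_from_mesial - margin, yc - half, -np.inf),
        upper=(tp.length - cav.end_from_distal + margin, yc + half, np.inf),
    )


def simulate_paired_scores(
    n: int = 70,
    target_spearman: float = 0.73,
    mean_panel: float = 60.91,
    sd: float = 18.24,
    seed: int = 0,
    mean_software: float | None = None,
    sd_software: float | None = None,
) -> PairedScores:
    """Correlated paired grader scores via a Gaussian copula.

    The latent normal correlation is r = 2·sin(π·ρ_s/6), which makes the
    copula's population Spearman correlation equal ``target_spearman``.
    Margins are normal (panel mean/SD defaulting to a realistic exam score
    distribution, software slightly higher as automated graders tend to be)
    and clipped to [0, 100].
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if not -1.0 < target_spearman < 1.0:
        raise ValueError("target_spearman must be in (-1, 1)")
    mean_software = mean_panel + 3.2 if mean_software is None else mean_software
    sd_software = sd * 0.88 if sd_software is None else sd_software
    r = 2.0 * np.sin(np.pi * target_spearman / 6.0)
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, r], [r, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
    panel = np.clip(mean_panel + sd * z[:, 0], 0.0, 100.0)
    software = np.clip(mean_software + sd_software * z[:, 1], 0.0, 100.0)
    ids = [f"S{i + 1:04d}" for i in range(n)]
    return PairedScores(ids, panel, software)
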