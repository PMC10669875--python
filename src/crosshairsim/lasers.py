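"""The crosshair simulator's laser geometry.

Two laser emitters are mounted on an L-shaped rack, one above (the *top* emitter)
and one to the side of the working volume. Each projects a cross of two fan
planes; the two crosses share a coplanar centreline, so the four fans span exactly
three mutually orthogonal planes. Those three planes define the simulator
coordinate system (SCS), the optical twin of the scanner's reference-image frame.

This module builds (optionally mis-calibrated) rigs, projects their crosshairs
onto triangle meshes, scores the mismatch between two labelled curve sets, and
runs the curvature-sensitivity experiment relating surface curvature radius to
projection distortion under a small pose tilt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh
from scipy.spatial.transform import Rotation

from . import geometry
from .imaging import CurveSet, intersect_clip_resample
from .transforms import Frame, FrameError, RigidTransform

__all__ = [
    "EmitterSpec",
    "SimulatorRig",
    "ProjectionCurves",
    "nominal_emitters",
    "build_rig",
    "project_crosshair",
    "curve_misfit",
    "curvature_sensitivity",
]

#: simulator planes are orthogonal/coincident within this tolerance when calibrated
INTRINSIC_TOL = 1e-9

#: default mounting stand-off of each emitter from the SCS origin (mm); does not
#: affect the plane geometry of a calibrated rig
DEFAULT_STANDOFF_MM = 400.0

ProjectionCurves = CurveSet


@dataclass(frozen=True)
class EmitterSpec:
    """One laser emitter: mounting position, boresight, and its two fan planes.

    Each fan plane contains the boresight direction; ``fan_labels`` name the
    reference plane each fan reproduces (``sagittal`` / ``coronal`` / ``axial``).
    Coordinates are in the rig (SCS) frame, millimetres.
    """

    position: np.ndarray
    boresight: np.ndarray
    fan_normals: np.ndarray          # (2, 3)
    fan_labels: tuple[str, str]

    def __post_init__(self) -> None:
        pos = np.array(self.position, dtype=float)
        b = np.array(self.boresight, dtype=float)
        b /= np.linalg.norm(b)
        fans = np.array(self.fan_normals, dtype=float)
        fans /= np.linalg.norm(fans, axis=1, keepdims=True)
        if np.abs(fans @ b).max() > 1e-9:
            raise ValueError("each fan plane must contain the boresight direction")
        for a in (pos, b, fans):
            a.flags.writeable = False
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "boresight", b)
        object.__setattr__(self, "fan_normals", fans)

    def rotated(self, rotvec: np.ndarray) -> "EmitterSpec":
        """The emitter tilted about its mount by an axis-angle vector (radians)."""
        R = Rotation.from_rotvec(np.asarray(rotvec, dtype=float)).as_matrix()
        return EmitterSpec(
            self.position, R @ self.boresight, self.fan_normals @ R.T, self.fan_labels
        )


def nominal_emitters(standoff_mm: float = DEFAULT_STANDOFF_MM) -> tuple[EmitterSpec, EmitterSpec]:
    """The factory-perfect pair: top emitter looking down, side emitter looking left."""
    ex, ey, ez = np.eye(3)
    top = EmitterSpec(
        position=standoff_mm * ez,
        boresight=-ez,
        fan_normals=np.stack([ex, ey]),
        fan_labels=("sagittal", "coronal"),
    )
    side = EmitterSpec(
        position=standoff_mm * ex,
        boresight=-ex,
        fan_normals=np.stack([ey, ez]),
        fan_labels=("coronal", "axial"),
    )
    return top, side


@dataclass(frozen=True)
class SimulatorRig:
    """Two emitters plus the rig pose (SCS -> WORLD).

    ``perturbation`` records the ground-truth per-emitter miscalibration rotation
    vectors when the rig was built with a known error, for recovery experiments.
    """

    emitters: tuple[EmitterSpec, EmitterSpec]
    pose: RigidTransform
    perturbation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.pose.source is not Frame.SCS or self.pose.target is not Frame.WORLD:
            raise FrameError("rig pose must map SCS -> WORLD")

    @property
    def intrinsic_ok(self) -> bool:
        """True when the four fans span three orthogonal planes meeting in one point."""
        planes = self.fan_planes()
        by_label: dict[str, list] = {}
        for label, point, normal, _vis in planes:
            by_label.setdefault(label, []).append((point, normal))
        # shared (coronal) plane must be stored once, i.e. the two fans coincide
        for label, entries in by_label.items():
            if len(entries) == 2:
                (p1, n1), (p2, n2) = entries
                if np.linalg.norm(np.cross(n1, n2)) > INTRINSIC_TOL:
                    return False
                if abs(n1 @ (p1 - p2)) > INTRINSIC_TOL:
                    return False
        normals = [entries[0][1] for entries in by_label.values()]
        for i in range(len(normals)):
            for j in range(i + 1, len(normals)):
                if abs(normals[i] @ normals[j]) > INTRINSIC_TOL:
                    return False
        return True

    def fan_planes(self, world: bool = False):
        """The four fan planes as ``(label, point, normal, toward_emitter)`` tuples.

        In the SCS frame by default; posed into the world frame when ``world``.
        """
        out = []
        R, t = self.pose.rotation, self.pose.translation
        for em in self.emitters:
            for normal, label in zip(em.fan_normals, em.fan_labels):
                point, n, vis = em.position, normal, -em.boresight
                if world:
                    point, n, vis = R @ point + t, R @ n, R @ vis
                out.append((label, point, n, vis))
        return out

    def with_pose(self, pose: RigidTransform) -> "SimulatorRig":
        return SimulatorRig(self.emitters, pose, self.perturbation)

    def with_corrections(self, rotvecs: np.ndarray) -> "SimulatorRig":
        """Apply per-emitter correction rotations (2, 3) to the fan geometry."""
        rotvecs = np.asarray(rotvecs, dtype=float).reshape(2, 3)
        emitters = tuple(em.rotated(rv) for em, rv in zip(self.emitters, rotvecs))
        return SimulatorRig(emitters, self.pose, self.perturbation)


def build_rig(
    perturbation: np.ndarray | None = None,
    pose: RigidTransform | None = None,
    standoff_mm: float = DEFAULT_STANDOFF_MM,
) -> SimulatorRig:
    """Assemble a rig, optionally mis-calibrated by per-emitter tilts.

    Parameters
    ----------
    perturbation:
        ``(2, 3)`` rotation vectors (radians) tilting the top and side emitter,
        or None for a factory-perfect rig. Must stay in the small-angle regime
        (< 0.2 rad) where the calibration procedure is defined.
    pose:
        SCS -> WORLD rig pose; identity when omitted.
    """
    if pose is None:
        pose = RigidTransform.identity(Frame.SCS, Frame.WORLD)
    top, side = nominal_emitters(standoff_mm)
    if perturbation is None:
        return SimulatorRig((top, side), pose, None)
    pert = np.asarray(perturbation, dtype=float).reshape(2, 3)
    if np.linalg.norm(pert, axis=1).max() >= 0.2:
        raise ValueError("perturbation angles must stay below 0.2 rad")
    return SimulatorRig((top.rotated(pert[0]), side.rotated(pert[1])), pose, pert.copy())


def _grouped_world_planes(rig: SimulatorRig, labels=None):
    """Fan planes in world coordinates, coincident same-label planes merged.

    Returns ``(label, point, normal, [toward-emitter dirs])`` with the shared
    coronal plane of a calibrated rig intersected only once (both visibility
    directions retained); distinct planes of a mis-calibrated rig stay separate.
    """
    groups: dict[str, list] = {}
    for label, point, normal, vis in rig.fan_planes(world=True):
        if labels is not None and label not in labels:
            continue
        merged = False
        for entry in groups.setdefault(label, []):
            p0, n0, viss = entry
            if (
                np.linalg.norm(np.cross(n0, normal)) < 1e-12
                and abs(n0 @ (point - p0)) < 1e-9
            ):
                viss.append(vis)
                merged = True
                break
        if not merged:
            groups[label].append((point, normal, [vis]))
    return [
        (label, point, normal, viss)
        for label, entries in groups.items()
        for point, normal, viss in entries
    ]


def project_crosshair(
    rig: SimulatorRig,
    surface: trimesh.Trimesh,
    step_mm: float = 0.5,
    clip_visibility: bool = True,
    labels=None,
) -> CurveSet:
    """The laser curves a posed rig paints on a surface (world frame).

    Each fan plane is intersected with the mesh; only facets facing the emitting
    laser keep their segments; polylines are resampled at ``step_mm``.
    """
    curves: dict[str, list[np.ndarray]] = {}
    empty: list[str] = []
    wanted = set(labels) if labels is not None else None
    for label, point, normal, viss in _grouped_world_planes(rig, wanted):
        polys = intersect_clip_resample(
            surface, point, normal, viss, step_mm, clip_visibility=clip_visibility
        )
        curves.setdefault(label, []).extend(polys)
    for label, polys in curves.items():
        if not polys:
            empty.append(label)
    return CurveSet(curves, Frame.WORLD, tuple(empty), step_mm)


def curve_misfit(a: CurveSet, b: CurveSet) -> float:
    """Symmetric mean closest-point distance (mm) between matching labelled curves.

    For every matching label, each vertex of one side is measured against the
    polyline segments of the other, in both directions; the pooled mean over all
    labels is returned. Zero iff the curves coincide within sampling tolerance.
    """
    if set(a.curves) != set(b.curves):
        raise ValueError(
            f"curve labels differ: {sorted(a.curves)} vs {sorted(b.curves)}"
        )
    if a.frame is not b.frame:
        raise FrameError("curve sets must live in the same frame")
    distances = []
    for label in a.curves:
        pa, pb = a.points(label), b.points(label)
        sa, sb = a.segments(label), b.segments(label)
        if len(pa) == 0 or len(pb) == 0:
            raise ValueError(f"label {label!r} has an empty curve")
        distances.append(geometry.points_to_segments_distance(pa, sb))
        distances.append(geometry.points_to_segments_distance(pb, sa))
    return float(np.concatenate(distances).mean())


def hausdorff_misfit(a: CurveSet, b: CurveSet) -> float:
    """Symmetric Hausdorff (max-min) distance between matching curves; diagnostic."""
    if set(a.curves) != set(b.curves):
        raise ValueError("curve labels differ")
    worst = 0.0
    for label in a.curves:
        d1 = geometry.points_to_segments_distance(a.points(label), b.segments(label))
        d2 = geometry.points_to_segments_distance(b.points(label), a.segments(label))
        worst = max(worst, float(d1.max()), float(d2.max()))
    return worst


def curvature_sensitivity(
    radii_mm,
    tilt_rad: float,
    aperture_mm: float = 80.0,
    step_mm: float = 0.5,
) -> pd.DataFrame:
    """Projection distortion of a tilted crosshair versus surface curvature radius.

    For each apex curvature radius a paraboloid test surface is generated and the
    top-emitter crosshair is projected twice: at the nominal pose (SCS origin at
    the apex) and tilted by ``tilt_rad`` about an oblique in-plane axis. The
    misfit between the two projections quantifies how strongly surface curvature
    converts a pose error into visible line mismatch: tightly curved surfaces
    (small radius) betray the tilt, flat ones hide it.

    Returns a DataFrame with columns ``radius_mm`` and ``misfit_mm``.
    """
    from .phantoms import make_parabolic_surface

    radii = np.atleast_1d(np.asarray(radii_mm, dtype=float))
    if np.any(radii <= 0):
        raise ValueError("curvature radii must be positive")
    axis = np.array([1.0, 1.0, 0.0]) / np.sqrt(2.0)  # tilts both top-emitter fans
    nominal = build_rig()
    tilted = nominal.with_pose(
        RigidTransform.from_rotvec(Frame.SCS, Frame.WORLD, tilt_rad * axis)
    )
    labels = ("sagittal", "coronal")
    rows = []
    for rho in radii:
        surf = make_parabolic_surface(rho, aperture_mm)
        ref = project_crosshair(nominal, surf, step_mm, labels=labels)
        per = project_crosshair(tilted, surf, step_mm, labels=labels)
        rows.append((rho, curve_misfit(ref, per)))
    return pd.DataFrame(rows, columns=["radius_mm", "misfit_mm"])
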