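"""Scan geometry of the reference image and scanner-marked laser lines.

The reference-image coordinate system (RICS) is fixed by the scanner's laser
positioning at acquisition time and can be pictured as three mutually orthogonal
planes through the gantry laser origin: the *sagittal* plane (normal along x),
the *coronal* plane (normal along y) and the *axial* plane (normal along z).
Patient axes follow the LPS convention (x left, y posterior, z superior).

``mark_reference_lines`` reproduces the skin lines a technician would draw where
the gantry lasers strike the head: the intersection of each reference plane with
the head surface, restricted to the laser-visible side and resampled at a fixed
arc-length step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from . import geometry
from .transforms import Frame, FrameError, RigidTransform

__all__ = [
    "ScanGeometry",
    "Plane",
    "CurveSet",
    "MarkedLines",
    "voxel_spacing",
    "reference_planes",
    "mark_reference_lines",
    "REFERENCE_AXES",
    "VISIBILITY_DIRECTIONS",
]


@dataclass(frozen=True)
class ScanGeometry:
    """In-plane field of view / acquisition matrix and slice stack of the scan."""

    fov_mm: tuple[float, float]
    matrix: tuple[int, int]
    slice_thickness_mm: float
    n_slices: int

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fov_mm):
            raise ValueError("field of view must be strictly positive")
        if any(int(m) != m or m <= 0 for m in self.matrix):
            raise ValueError("acquisition matrix entries must be positive integers")
        if self.slice_thickness_mm <= 0 or self.n_slices <= 0:
            raise ValueError("slice thickness and count must be strictly positive")

    def to_dict(self) -> dict:
        return {
            "fov_mm": list(self.fov_mm),
            "matrix": [int(m) for m in self.matrix],
            "slice_thickness_mm": self.slice_thickness_mm,
            "n_slices": int(self.n_slices),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        return cls(
            tuple(d["fov_mm"]), tuple(d["matrix"]),
            d["slice_thickness_mm"], d["n_slices"],
        )


def voxel_spacing(g: ScanGeometry) -> np.ndarray:
    """Voxel size (mm): in-plane FOV / matrix, slice thickness through-plane."""
    return np.array(
        [
            g.fov_mm[0] / g.matrix[0],
            g.fov_mm[1] / g.matrix[1],
            g.slice_thickness_mm,
        ]
    )


@dataclass(frozen=True)
class Plane:
    """An oriented plane ``{p : normal . p = offset}`` (offset in mm from the origin)."""

    normal: np.ndarray
    offset: float = 0.0

    def __post_init__(self) -> None:
        n = np.array(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if not np.isfinite(norm) or norm == 0:
            raise ValueError("plane normal must be a nonzero finite vector")
        n /= norm
        n.flags.writeable = False
        object.__setattr__(self, "normal", n)
        object.__setattr__(self, "offset", float(self.offset))

    @classmethod
    def from_point_normal(cls, point: np.ndarray, normal: np.ndarray) -> "Plane":
        n = np.asarray(normal, dtype=float)
        n = n / np.linalg.norm(n)
        return cls(n, float(n @ np.asarray(point, dtype=float)))

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.normal - self.offset


#: reference-plane labels -> frame-axis index of their normal
REFERENCE_AXES = {"sagittal": 0, "coronal": 1, "axial": 2}

#: which emitter(s) illuminate each line: directions *toward* the emitters,
#: expressed in the reference/simulator frame (top emitter above, side emitter left)
_TOP = np.array([0.0, 0.0, 1.0])
_SIDE = np.array([1.0, 0.0, 0.0])
VISIBILITY_DIRECTIONS = {
    "sagittal": (_TOP,),           # drawn across the crown
    "coronal": (_TOP, _SIDE),      # the shared plane: arcs on top and on the side
    "axial": (_SIDE,),             # drawn on the side of the head
}


def reference_planes(frame: Frame = Frame.RICS) -> dict[str, Plane]:
    """The three orthogonal reference planes through the RICS origin."""
    if frame is not Frame.RICS:
        raise FrameError("reference planes are defined in the RICS frame")
    eye = np.eye(3)
    return {label: Plane(eye[axis], 0.0) for label, axis in REFERENCE_AXES.items()}


@dataclass
class CurveSet:
    """Labelled polylines on a surface: per label, a list of ``(n, 3)`` vertex arrays.

    Used both for scanner-marked reference lines and for simulator laser
    projections; a label may hold several disjoint arcs (visibility clipping can
    split a closed intersection curve).
    """

    curves: dict[str, list[np.ndarray]]
    frame: Frame
    empty_labels: tuple[str, ...] = ()
    step_mm: float | None = None

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.curves)

    def points(self, label: str) -> np.ndarray:
        """All vertices of a label, concatenated."""
        polys = self.curves[label]
        if not polys:
            return np.empty((0, 3))
        return np.concatenate(polys, axis=0)

    def segments(self, label: str) -> np.ndarray:
        segs = [geometry.polyline_segments(p) for p in self.curves[label] if len(p) > 1]
        if not segs:
            return np.empty((0, 2, 3))
        return np.concatenate(segs, axis=0)

    def n_points(self) -> int:
        return sum(len(p) for polys in self.curves.values() for p in polys)

    def total_length(self, label: str | None = None) -> float:
        labels = [label] if label is not None else list(self.curves)
        return sum(
            geometry.polyline_length(p) for lb in labels for p in self.curves[lb]
        )

    def transformed(self, T: RigidTransform) -> "CurveSet":
        if T.source is not self.frame:
            raise FrameError(f"curves are in {self.frame.name}, not {T.source.name}")
        return CurveSet(
            {lb: [T.apply(p) for p in polys] for lb, polys in self.curves.items()},
            T.target,
            self.empty_labels,
            self.step_mm,
        )

    # --------------------------------------------------------------- serialization
    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for label, polys in self.curves.items():
            for ci, poly in enumerate(polys):
                for pi, (x, y, z) in enumerate(poly):
                    rows.append((label, ci, pi, x, y, z))
        return pd.DataFrame(
            rows, columns=["label", "curve_index", "point_index", "x", "y", "z"]
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame: Frame = Frame.WORLD) -> "CurveSet":
        df = pd.read_csv(path)
        curves: dict[str, list[np.ndarray]] = {}
        for (label, _ci), grp in df.groupby(["label", "curve_index"], sort=True):
            grp = grp.sort_values("point_index")
            curves.setdefault(str(label), []).append(
                grp[["x", "y", "z"]].to_numpy(dtype=float)
            )
        return cls(curves, frame)

    def to_json(self, path) -> None:
        payload = {
            "frame": self.frame.value,
            "empty_labels": list(self.empty_labels),
            "curves": {
                lb: [p.tolist() for p in polys] for lb, polys in self.curves.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "CurveSet":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            {lb: [np.array(p, dtype=float) for p in polys] for lb, polys in d["curves"].items()},
            Frame(d["frame"]),
            tuple(d["empty_labels"]),
        )


#: scanner-marked lines are plain labelled curve sets
MarkedLines = CurveSet


def intersect_clip_resample(
    surface: trimesh.Trimesh,
    plane_point: np.ndarray,
    plane_normal: np.ndarray,
    visibility_dirs,
    step_mm: float,
    clip_visibility: bool = True,
    min_length_factor: float = 2.0,
) -> list[np.ndarray]:
    """Intersect a plane with a mesh, keep laser-visible segments, resample.

    A segment is kept when the outward normal of its generating face has positive
    dot product with at least one direction toward an emitter. Arcs shorter than
    ``min_length_factor * step_mm`` are dropped.
    """
    segs, faces = trimesh.intersections.mesh_plane(
        surface, np.asarray(plane_normal, dtype=float),
        np.asarray(plane_point, dtype=float), return_faces=True,
    )
    if len(segs) == 0:
        return []
    if clip_visibility:
        normals = surface.face_normals[faces]
        visible = np.zeros(len(segs), dtype=bool)
        for d in visibility_dirs:
            visible |= normals @ np.asarray(d, dtype=float) > 0.0
        segs = segs[visible]
        if len(segs) == 0:
            return []
    out = []
    for poly in geometry.chain_segments(segs):
        if geometry.polyline_length(poly) >= min_length_factor * step_mm:
            out.append(geometry.resample_polyline(poly, step_mm))
    return out


def mark_reference_lines(
    surface: trimesh.Trimesh,
    scanner_pose: RigidTransform,
    step_mm: float = 0.5,
    clip_visibility: bool = True,
) -> CurveSet:
    """Skin lines where the scanner's positioning lasers strike the surface.

    Parameters
    ----------
    surface:
        Head surface in the world frame (outward normals).
    scanner_pose:
        RICS -> WORLD pose of the reference-image frame.
    step_mm:
        Arc-length resampling step of the output polylines.
    clip_visibility:
        Keep only the side of the surface facing the (virtual) emitters; disable
        to obtain the full closed intersection curves.
    """
    if scanner_pose.source is not Frame.RICS or scanner_pose.target is not Frame.WORLD:
        raise FrameError("scanner_pose must map RICS -> WORLD")
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")
    R, origin = scanner_pose.rotation, scanner_pose.translation
    curves: dict[str, list[np.ndarray]] = {}
    empty: list[str] = []
    for label, axis in REFERENCE_AXES.items():
        polys = intersect_clip_resample(
            surface,
            origin,
            R[:, axis],
            [R @ d for d in VISIBILITY_DIRECTIONS[label]],
            step_mm,
            clip_visibility=clip_visibility,
        )
        curves[label] = polys
        if not polys:
            empty.append(label)
    return CurveSet(curves, Frame.WORLD, tuple(empty), step_mm)
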