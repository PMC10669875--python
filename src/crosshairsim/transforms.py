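"""Proper rigid transforms between the named coordinate frames of the navigation chain.

The registration method maps a planned model from the reference-image frame to the
patient through a chain of rigid transforms linking six frames:

* ``WORLD``   — the global frame established by the head-mounted display's SLAM.
* ``HMD``     — the headset itself.
* ``VCS``     — the virtual frame anchored to the tracked image target on the rig.
* ``RICS``    — the reference-image frame fixed by the scanner's positioning lasers.
* ``SCS``     — the frame spanned by the simulator's three orthogonal laser planes.
* ``SCANNER`` — the scanner's mechanical frame, reproduced on the patient by the rig.

Conventions: column vectors, ``p' = R @ p + t``; a transform labelled ``A -> B`` maps
coordinates expressed in frame A to coordinates in frame B; the product ``T2 @ T1``
applies ``T1`` first.  All translations are in millimetres; frames are right-handed.
Internally every transform is a homogeneous 4x4 matrix with last row (0, 0, 0, 1).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Frame",
    "FrameError",
    "RigidTransform",
    "FrameGraph",
    "compose",
    "invert",
    "chain_world_to_scanner",
    "random_rigid_transform",
]

#: maximum departure from orthonormality accepted before a rotation block is rejected
ORTHONORMALITY_TOL = 1e-6


class Frame(enum.Enum):
    """The six coordinate frames of the registration chain."""

    WORLD = "WORLD"
    SCANNER = "SCANNER"
    RICS = "RICS"
    SCS = "SCS"
    VCS = "VCS"
    HMD = "HMD"


class FrameError(ValueError):
    """Raised on frame-label contract violations (mismatched or missing frames)."""


def _repair_rotation(R: np.ndarray) -> np.ndarray:
    """Re-project a near-orthonormal matrix onto SO(3) via polar decomposition.

    Matrices farther than ``ORTHONORMALITY_TOL`` from orthonormal, and reflections
    (det < 0), are rejected: this package models proper rigid motion only.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or not np.all(np.isfinite(R)):
        raise ValueError("rotation must be a finite 3x3 matrix")
    err = np.abs(R.T @ R - np.eye(3)).max()
    if err > ORTHONORMALITY_TOL:
        raise ValueError(
            f"matrix is not orthonormal (max |R^T R - I| = {err:.3e} > {ORTHONORMALITY_TOL:g})"
        )
    if err < 1e-12:  # already orthonormal: keep bits stable (round-trip identity)
        if np.linalg.det(R) < 0:
            raise ValueError("matrix is a reflection (det = -1); proper rotations only")
        return R
    U, _, Vt = np.linalg.svd(R)
    repaired = U @ Vt
    if np.linalg.det(repaired) < 0:
        raise ValueError("matrix is a reflection (det = -1); proper rotations only")
    return repaired


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid map between two named frames.

    Attributes
    ----------
    source, target:
        Frame labels; ``apply`` takes coordinates in ``source`` to ``target``.
    matrix:
        4x4 homogeneous matrix, rotation block re-projected onto SO(3) at
        construction (polar decomposition) when within tolerance.
    """

    source: Frame
    target: Frame
    matrix: np.ndarray

    def __post_init__(self) -> None:
        if not isinstance(self.source, Frame) or not isinstance(self.target, Frame):
            raise FrameError("source and target must be Frame labels")
        M = np.array(self.matrix, dtype=float)
        if M.shape != (4, 4) or not np.all(np.isfinite(M)):
            raise ValueError("matrix must be a finite 4x4 homogeneous matrix")
        if not np.allclose(M[3], [0.0, 0.0, 0.0, 1.0], atol=1e-12):
            raise ValueError("last homogeneous row must be (0, 0, 0, 1)")
        M[:3, :3] = _repair_rotation(M[:3, :3])
        M[3] = (0.0, 0.0, 0.0, 1.0)
        M.flags.writeable = False
        object.__setattr__(self, "matrix", M)

    # ------------------------------------------------------------------ builders
    @classmethod
    def identity(cls, source: Frame, target: Frame | None = None) -> "RigidTransform":
        return cls(source, source if target is None else target, np.eye(4))

    @classmethod
    def from_rotation_translation(
        cls,
        source: Frame,
        target: Frame,
        rotation: np.ndarray | None = None,
        translation: np.ndarray | None = None,
    ) -> "RigidTransform":
        M = np.eye(4)
        if rotation is not None:
            M[:3, :3] = np.asarray(rotation, dtype=float)
        if translation is not None:
            M[:3, 3] = np.asarray(translation, dtype=float)
        return cls(source, target, M)

    @classmethod
    def from_rotvec(
        cls,
        source: Frame,
        target: Frame,
        rotvec: np.ndarray,
        translation: np.ndarray | None = None,
    ) -> "RigidTransform":
        """Build from an axis-angle rotation vector (radians) and a translation (mm)."""
        R = Rotation.from_rotvec(np.asarray(rotvec, dtype=float)).as_matrix()
        return cls.from_rotation_translation(source, target, R, translation)

    # ---------------------------------------------------------------- properties
    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]

    @property
    def rotvec(self) -> np.ndarray:
        return Rotation.from_matrix(self.rotation).as_rotvec()

    # ---------------------------------------------------------------- operations
    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map points (``(..., 3)``, mm) from the source frame to the target frame."""
        pts = np.asarray(points, dtype=float)
        if pts.shape[-1] != 3:
            raise ValueError("points must have trailing dimension 3")
        if not np.all(np.isfinite(pts)):
            raise ValueError("points must be finite")
        return pts @ self.rotation.T + self.translation

    def invert(self) -> "RigidTransform":
        """The inverse map: frames swapped, R -> R^T, t -> -R^T t."""
        Rt = self.rotation.T
        M = np.eye(4)
        M[:3, :3] = Rt
        M[:3, 3] = -Rt @ self.translation
        return RigidTransform(self.target, self.source, M)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        """Matrix-product convention: ``T2 @ T1`` applies ``T1`` first."""
        return compose(other, self)

    def is_close(self, other: "RigidTransform", atol: float = 1e-9) -> bool:
        return (
            self.source is other.source
            and self.target is other.target
            and np.allclose(self.matrix, other.matrix, atol=atol)
        )

    # --------------------------------------------------------------- serialization
    def to_dict(self) -> dict:
        return {
            "source": self.source.value,
            "target": self.target.value,
            "matrix": [float(x) for x in self.matrix.ravel()],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        M = np.array(d["matrix"], dtype=float).reshape(4, 4)
        return cls(Frame(d["source"]), Frame(d["target"]), M)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RigidTransform":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def compose(first: RigidTransform, second: RigidTransform) -> RigidTransform:
    """Compose two transforms, *first* applied first.

    ``compose(T[A->B], T[B->C])`` returns ``T[A->C]`` whose matrix is the product
    ``second.matrix @ first.matrix`` (the left factor acts after the right).
    """
    if first.target is not second.source:
        raise FrameError(
            f"cannot compose {first.source.name}->{first.target.name} with "
            f"{second.source.name}->{second.target.name}: intermediate frames "
            f"{first.target.name} and {second.source.name} differ"
        )
    return RigidTransform(first.source, second.target, second.matrix @ first.matrix)


def invert(T: RigidTransform) -> RigidTransform:
    return T.invert()


class FrameGraph:
    """Container of rigid transforms keyed by ordered frame pair.

    At most one edge is stored per ordered pair; querying the reverse pair returns
    the inverse of the stored edge.
    """

    def __init__(self, transforms=()) -> None:
        self._edges: dict[tuple[Frame, Frame], RigidTransform] = {}
        for t in transforms:
            self.add(t)

    def add(self, transform: RigidTransform) -> None:
        key = (transform.source, transform.target)
        if key in self._edges or key[::-1] in self._edges:
            raise FrameError(
                f"an edge between {key[0].name} and {key[1].name} is already stored"
            )
        self._edges[key] = transform

    def get(self, source: Frame, target: Frame) -> RigidTransform:
        if (source, target) in self._edges:
            return self._edges[(source, target)]
        if (target, source) in self._edges:
            return self._edges[(target, source)].invert()
        raise FrameError(f"no transform {source.name}->{target.name} in graph")

    def __contains__(self, key: tuple[Frame, Frame]) -> bool:
        return key in self._edges or key[::-1] in self._edges

    def __len__(self) -> int:
        return len(self._edges)

    def transforms(self) -> list[RigidTransform]:
        return list(self._edges.values())

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([t.to_dict() for t in self.transforms()], fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FrameGraph":
        with open(path) as fh:
            return cls(RigidTransform.from_dict(d) for d in json.load(fh))


#: the five factors of the world-to-scanner chain, innermost (applied first) first,
#: with the symbols conventionally used for them
CHAIN_FACTORS = (
    (Frame.WORLD, Frame.HMD, "T_WH"),
    (Frame.HMD, Frame.VCS, "T_HV"),
    (Frame.VCS, Frame.RICS, "T_VR"),
    (Frame.RICS, Frame.SCS, "T_RS"),
    (Frame.SCS, Frame.SCANNER, "T_SSc"),
)


def chain_world_to_scanner(graph: FrameGraph) -> RigidTransform:
    """The five-factor product T_SSc . T_RS . T_VR . T_HV . T_WH (WORLD -> SCANNER).

    This single product carries a point from the SLAM world frame through the
    headset, tracked-target, reference-image and simulator frames into the scanner
    frame; it equals the stepwise pairwise composition of the same factors.
    """
    total: RigidTransform | None = None
    for source, target, symbol in CHAIN_FACTORS:
        try:
            edge = graph.get(source, target)
        except FrameError as exc:
            raise FrameError(
                f"missing transform {symbol} ({source.name}->{target.name})"
            ) from exc
        total = edge if total is None else compose(total, edge)
    return total


def random_rigid_transform(
    rng: np.random.Generator,
    source: Frame,
    target: Frame,
    max_translation_mm: float = 100.0,
) -> RigidTransform:
    """A uniformly random rotation with a uniform box translation; test/fixture helper."""
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.uniform(-max_translation_mm, max_translation_mm, 3)
    return RigidTransform.from_rotation_translation(source, target, R, t)
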