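"""Seeded generators of head-like surfaces, fiducials and complete registration fixtures.

No imaging data is downloaded: the head is a smooth closed superellipsoid with a
protruding paraboloid "nose" (a deliberately low-curvature-radius region, since
tightly curved patches are what make crosshair projections pose-sensitive), six
scalp fiducials are scattered with a minimum-separation rule, and the scanner
pose is drawn near the head centroid with a small seeded tilt. Every generator
is a pure function of its parameters and a seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from .evaluation import FiducialSet
from .imaging import CurveSet, ScanGeometry, mark_reference_lines
from .transforms import Frame, FrameGraph, RigidTransform, compose, random_rigid_transform

__all__ = [
    "make_head_mesh",
    "make_parabolic_surface",
    "place_fiducials",
    "FixtureConfig",
    "PhantomFixture",
    "make_fixture",
    "make_frame_graph",
    "save_fixture",
    "load_fixture",
]

#: default scan geometry of the reference image the fixtures emulate
DEFAULT_SCAN_GEOMETRY = ScanGeometry(
    fov_mm=(251.0, 251.0), matrix=(128, 128), slice_thickness_mm=0.625, n_slices=272
)


def make_head_mesh(
    seed: int = 0,
    half_axes_mm: tuple[float, float, float] = (75.0, 95.0, 85.0),
    exponent: float = 2.5,
    nose_height_mm: float = 22.0,
    nose_width_rad: float = 0.22,
    asymmetry: float = 0.03,
    subdivisions: int = 4,
) -> trimesh.Trimesh:
    """A watertight head-like surface: superellipsoid plus a paraboloid-nose bump.

    Axes follow LPS (x left, y posterior, z superior); the nose protrudes
    anteriorly (-y), slightly below the equator. ``seed`` jitters the half-axes
    by up to 2% so distinct fixtures have distinct but reproducible shapes.
    """
    if min(half_axes_mm) <= 0 or nose_height_mm < 0 or exponent <= 0:
        raise ValueError("size parameters must be positive")
    rng = np.random.default_rng(seed)
    axes = np.asarray(half_axes_mm, dtype=float) * (1.0 + 0.02 * rng.uniform(-1, 1, 3))
    base = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    u = base.vertices / np.linalg.norm(base.vertices, axis=1, keepdims=True)
    # superellipsoid radius along each unit direction
    r = np.sum(np.abs(u / axes) ** exponent, axis=1) ** (-1.0 / exponent)
    # mild left-right asymmetry coupled to the anterior-posterior coordinate
    r = r * (1.0 + asymmetry * u[:, 0] * u[:, 1])
    nose_dir = np.array([0.0, -1.0, -0.30])
    nose_dir /= np.linalg.norm(nose_dir)
    ang = np.arccos(np.clip(u @ nose_dir, -1.0, 1.0))
    r = r + nose_height_mm * np.exp(-((ang / nose_width_rad) ** 2))
    return trimesh.Trimesh(vertices=r[:, None] * u, faces=base.faces, process=False)


def make_parabolic_surface(
    curvature_radius_mm: float,
    aperture_mm: float = 80.0,
    n_radial: int = 40,
    n_angular: int = 96,
) -> trimesh.Trimesh:
    """An open paraboloid patch ``z = (x^2 + y^2) / (2 rho)`` over a circular aperture.

    ``rho`` is the apex curvature radius: the osculating sphere at the apex has
    exactly this radius. Outward normals point up (+z), toward an overhead emitter.
    """
    if curvature_radius_mm <= 0 or aperture_mm <= 0:
        raise ValueError("curvature radius and aperture must be positive")
    rho, rmax = float(curvature_radius_mm), aperture_mm / 2.0
    radii = np.linspace(0.0, rmax, n_radial + 1)[1:]
    theta = np.linspace(0.0, 2.0 * np.pi, n_angular, endpoint=False)
    rr, tt = np.meshgrid(radii, theta, indexing="ij")
    x, y = (rr * np.cos(tt)).ravel(), (rr * np.sin(tt)).ravel()
    verts = np.column_stack([x, y, (x**2 + y**2) / (2.0 * rho)])
    verts = np.vstack([[0.0, 0.0, 0.0], verts])

    def vid(i_ring: int, j_ang: int) -> int:
        return 1 + i_ring * n_angular + (j_ang % n_angular)

    faces = []
    for j in range(n_angular):  # central fan (counter-clockwise seen from +z)
        faces.append([0, vid(0, j), vid(0, j + 1)])
    for i in range(n_radial - 1):
        for j in range(n_angular):
            a, b, c, d = vid(i, j), vid(i + 1, j), vid(i + 1, j + 1), vid(i, j + 1)
            faces.append([a, b, c])
            faces.append([a, c, d])
    return trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)


def place_fiducials(
    mesh: trimesh.Trimesh,
    n: int = 6,
    seed: int = 0,
    min_separation_mm: float = 55.0,
    max_tries: int = 50,
) -> FiducialSet:
    """Scatter ``n`` well-separated scalp fiducials on the mesh surface.

    Candidate sites are mesh vertices on the upper part of the head (outward
    normal not pointing down); a rejection loop enforces the minimum pairwise
    separation. Labels run A, B, C, ... Fiducials are evaluation-only landmarks:
    they play no role in registration.
    """
    if n < 3:
        raise ValueError("need at least 3 fiducials")
    rng = np.random.default_rng(seed)
    normals = mesh.vertex_normals
    zmin = np.percentile(mesh.vertices[:, 2], 30.0)
    candidates = np.flatnonzero((normals[:, 2] > -0.2) & (mesh.vertices[:, 2] > zmin))
    for _ in range(max_tries):
        order = rng.permutation(candidates)
        chosen: list[int] = []
        for idx in order:
            p = mesh.vertices[idx]
            if all(
                np.linalg.norm(p - mesh.vertices[j]) >= min_separation_mm
                for j in chosen
            ):
                chosen.append(int(idx))
                if len(chosen) == n:
                    labels = tuple(chr(ord("A") + k) for k in range(n))
                    return FiducialSet(
                        labels, mesh.vertices[chosen].copy(), Frame.WORLD
                    )
    raise RuntimeError(
        f"could not place {n} fiducials at >= {min_separation_mm} mm separation"
    )


@dataclass(frozen=True)
class FixtureConfig:
    """Everything a registration fixture needs besides the seed."""

    half_axes_mm: tuple[float, float, float] = (75.0, 95.0, 85.0)
    subdivisions: int = 4
    n_fiducials: int = 6
    fiducial_separation_mm: float = 55.0
    scanner_tilt_deg: float = 5.0
    scanner_offset_mm: float = 10.0
    step_mm: float = 0.5
    scan_geometry: ScanGeometry = DEFAULT_SCAN_GEOMETRY


@dataclass
class PhantomFixture:
    """A complete, internally consistent synthetic registration scenario.

    ``marked_lines`` are generated from ``scanner_pose`` on ``mesh``, so running
    the deployment, chaining and evaluation stages on a fixture with zero noise
    must close to machine precision.
    """

    mesh: trimesh.Trimesh
    fiducials: FiducialSet
    scanner_pose: RigidTransform           # RICS -> WORLD
    marked_lines: CurveSet
    scan_geometry: ScanGeometry
    seed: int


def make_fixture(config: FixtureConfig | None = None, seed: int = 0) -> PhantomFixture:
    """Generate mesh, fiducials, a seeded scanner pose and its marked lines."""
    cfg = config or FixtureConfig()
    mesh = make_head_mesh(
        seed=seed, half_axes_mm=cfg.half_axes_mm, subdivisions=cfg.subdivisions
    )
    fiducials = place_fiducials(
        mesh, cfg.n_fiducials, seed=seed + 1,
        min_separation_mm=cfg.fiducial_separation_mm,
    )
    rng = np.random.default_rng(seed + 2)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    rotvec = np.deg2rad(rng.uniform(0.0, cfg.scanner_tilt_deg)) * axis
    translation = mesh.vertices.mean(axis=0) + rng.uniform(
        -cfg.scanner_offset_mm, cfg.scanner_offset_mm, 3
    )
    scanner_pose = RigidTransform.from_rotvec(
        Frame.RICS, Frame.WORLD, rotvec, translation
    )
    marked = mark_reference_lines(mesh, scanner_pose, cfg.step_mm)
    return PhantomFixture(mesh, fiducials, scanner_pose, marked, cfg.scan_geometry, seed)


def make_frame_graph(fixture: PhantomFixture, seed: int = 0) -> FrameGraph:
    """Ground-truth transform graph for a fixture (zero-error conditions).

    The headset (T_WH) and image-target (T_HV) transforms are arbitrary seeded
    rigid motions — in hardware they come from SLAM and target tracking, which
    are inputs here. A calibrated simulator perfectly deployed on the marked
    lines gives T_RS = T_SSc = identity, and T_VR is derived so that the full
    chain reproduces the fixture's scanner pose exactly.
    """
    rng = np.random.default_rng(seed + 1000)
    t_wh = random_rigid_transform(rng, Frame.WORLD, Frame.HMD, 500.0)
    t_hv = random_rigid_transform(rng, Frame.HMD, Frame.VCS, 500.0)
    t_rs = RigidTransform.identity(Frame.RICS, Frame.SCS)
    t_ssc = RigidTransform.identity(Frame.SCS, Frame.SCANNER)
    world_to_rics = fixture.scanner_pose.invert()
    t_wv = compose(t_wh, t_hv)
    t_vr = compose(t_wv.invert(), world_to_rics)   # VCS -> WORLD -> RICS
    return FrameGraph([t_wh, t_hv, t_vr, t_rs, t_ssc])


# ---------------------------------------------------------------------- file I/O

def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def save_fixture(fixture: PhantomFixture, outdir) -> dict:
    """Write mesh (ASCII STL), fiducials CSV, marked-lines CSV and a manifest JSON."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    mesh_path = out / "head.stl"
    mesh_path.write_text(
        trimesh.exchange.stl.export_stl_ascii(fixture.mesh)
    )
    fid_path = out / "fiducials.csv"
    fixture.fiducials.to_csv(fid_path)
    lines_path = out / "marked_lines.csv"
    fixture.marked_lines.to_csv(lines_path)
    pose_path = out / "scanner_pose.json"
    fixture.scanner_pose.to_json(pose_path)
    manifest = {
        "seed": fixture.seed,
        "scan_geometry": fixture.scan_geometry.to_dict(),
        "files": {
            p.name: _sha256(p) for p in (mesh_path, fid_path, lines_path, pose_path)
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_fixture(indir) -> PhantomFixture:
    from pathlib import Path

    d = Path(indir)
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    mesh = trimesh.load_mesh(d / "head.stl", process=False)
    return PhantomFixture(
        mesh=mesh,
        fiducials=FiducialSet.from_csv(d / "fiducials.csv"),
        scanner_pose=RigidTransform.from_json(d / "scanner_pose.json"),
        marked_lines=CurveSet.from_csv(d / "marked_lines.csv"),
        scan_geometry=ScanGeometry.from_dict(manifest["scan_geometry"]),
        seed=manifest["seed"],
    )
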