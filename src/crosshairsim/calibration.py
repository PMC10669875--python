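"""Calibration-sphere geometry and the intrinsic / extrinsic calibration procedures.

The calibration sphere carries three great-circle arcs (GCAs) on mutually
orthogonal diametral planes — a tangible stand-in for the three reference planes —
plus three small-circle arcs (SCAs), one parallel to each same-colour great
circle at the tangency offset R/sqrt(2), where the three small circles touch
pairwise on the sphere. Any per-colour choice of {great, small} yields three
mutually orthogonal planes, giving eight *calibration positions*: one primary
(all great, the PCP) and seven secondary (the SCPs).

*Intrinsic* calibration orthogonalizes the rig's laser fans: the projected arcs
on a sphere secured at the PCP are driven onto the marked arcs, then verified at
the seven SCPs. *Extrinsic* calibration recovers the tracked-target-to-image
transform T_VR by rigidly aligning a virtual copy of the sphere's great circles
with the physical sphere at the PCP.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares, minimize
from scipy.spatial.transform import Rotation

from .lasers import SimulatorRig, build_rig
from .transforms import Frame, RigidTransform, compose

__all__ = [
    "CalibrationSphere",
    "CalibrationPosition",
    "CalibrationError",
    "build_calibration_sphere",
    "enumerate_orthogonal_combinations",
    "arc_residual",
    "intrinsic_calibrate",
    "extrinsic_calibrate",
    "sample_virtual_sphere",
    "IntrinsicReport",
]

#: arc colours in axis order; the laser fan reproducing each colour's plane
COLORS = ("red", "blue", "black")
COLOR_AXIS = {"red": 0, "blue": 1, "black": 2}
#: fan-plane label (see :mod:`crosshairsim.lasers`) aligned with each colour
COLOR_LABEL = {"red": "sagittal", "blue": "coronal", "black": "axial"}

DEFAULT_SEED = 20231107


class CalibrationError(RuntimeError):
    """Raised when a calibration optimization fails to converge."""


@dataclass(frozen=True)
class CalibrationSphere:
    """Radius-R sphere with three orthogonal great-circle planes and their
    parallel small-circle planes at offset ``sca_offset`` (mm, from the centre).

    ``gca_normals`` may be perturbed (for miscalibration experiments);
    ``sca_normals`` stay at the engraved nominal directions.
    """

    radius: float
    centre: np.ndarray
    gca_normals: np.ndarray    # (3, 3), rows in COLORS order
    sca_normals: np.ndarray    # (3, 3)
    sca_offset: float

    def __post_init__(self) -> None:
        for name in ("centre", "gca_normals", "sca_normals"):
            a = np.array(getattr(self, name), dtype=float)
            a.flags.writeable = False
            object.__setattr__(self, name, a)

    def normal(self, color: str, kind: str) -> np.ndarray:
        idx = COLORS.index(color)
        return self.gca_normals[idx] if kind == "great" else self.sca_normals[idx]

    def circle(self, color: str, kind: str) -> tuple[np.ndarray, np.ndarray, float]:
        """(centre, unit normal, radius) of a marked circle, in sphere coordinates."""
        n = self.normal(color, kind)
        off = 0.0 if kind == "great" else self.sca_offset
        r = np.sqrt(self.radius**2 - off**2)
        return self.centre + off * n, n, r

    def with_tilted_gca(self, color: str, rotvec: np.ndarray) -> "CalibrationSphere":
        """A defective sphere whose one great-circle plane is tilted (SCAs untouched)."""
        R = Rotation.from_rotvec(np.asarray(rotvec, dtype=float)).as_matrix()
        g = self.gca_normals.copy()
        g[COLORS.index(color)] = R @ g[COLORS.index(color)]
        return replace(self, gca_normals=g)


def build_calibration_sphere(
    radius: float = 60.0, centre=(0.0, 0.0, 0.0)
) -> CalibrationSphere:
    """The nominal sphere: orthogonal axis-aligned great circles, SCAs at R/sqrt(2).

    The small-circle offset is the tangency value: at ``d = R/sqrt(2)`` two small
    circles on orthogonal planes meet in exactly one point on the sphere
    (``z^2 = R^2 - 2 d^2 = 0``), so the three small circles touch pairwise.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    return CalibrationSphere(
        radius=float(radius),
        centre=np.asarray(centre, dtype=float),
        gca_normals=np.eye(3),
        sca_normals=np.eye(3),
        sca_offset=float(radius) / np.sqrt(2.0),
    )


@dataclass(frozen=True)
class CalibrationPosition:
    """A per-colour {great, small} selection; all-great is the primary position."""

    choice: tuple[str, str, str]   # kinds in COLORS order

    def __post_init__(self) -> None:
        if any(k not in ("great", "small") for k in self.choice):
            raise ValueError("choices must be 'great' or 'small'")

    @property
    def is_primary(self) -> bool:
        return all(k == "great" for k in self.choice)

    @property
    def label(self) -> str:
        return "PCP" if self.is_primary else "SCP-" + "".join(
            k[0].upper() for k in self.choice
        )


PCP = CalibrationPosition(("great", "great", "great"))


def enumerate_orthogonal_combinations(
    sphere: CalibrationSphere, tol_rad: float = 1e-9
) -> list[CalibrationPosition]:
    """All per-colour {great, small} triples whose planes are mutually orthogonal.

    For the nominal sphere this is exactly 8 (the one PCP and seven SCPs);
    engraving defects reduce the count.
    """
    out = []
    for kinds in itertools.product(("great", "small"), repeat=3):
        normals = [sphere.normal(c, k) for c, k in zip(COLORS, kinds)]
        ok = all(
            abs(float(normals[i] @ normals[j])) <= np.sin(tol_rad) + 1e-15
            for i, j in itertools.combinations(range(3), 2)
        )
        if ok:
            out.append(CalibrationPosition(tuple(kinds)))
    return out


def small_circle_intersections_on_sphere(
    radius: float, offset: float, n_grid: int = 200001
) -> int:
    """Count intersection points of two small circles (planes x=d and y=d) on the sphere.

    Brute-force root count of ``z^2 = R^2 - 2 d^2``: 2 roots below the tangency
    offset, 1 at it, 0 above. Used as an independent check of the tangency value.
    """
    z2 = radius**2 - 2.0 * offset**2
    if abs(z2) < 1e-9 * radius**2:
        return 1
    return 2 if z2 > 0 else 0


def _sphere_centre_for_position(
    sphere: CalibrationSphere, position: CalibrationPosition
) -> np.ndarray:
    """Sphere centre (SCS frame) that puts the selected arcs on the laser planes.

    Securing the sphere at a calibration position means the selected plane of
    each colour coincides with the rig's same-colour laser plane through the SCS
    origin; with the sphere axes aligned to the SCS axes the centre simply backs
    off by each selected offset.
    """
    offsets = np.array(
        [0.0 if k == "great" else sphere.sca_offset for k in position.choice]
    )
    return -offsets


def _point_circle_distance(
    points: np.ndarray, centre: np.ndarray, normal: np.ndarray, radius: float
) -> np.ndarray:
    """Exact 3D distance from points to a circle (centre, unit normal, radius)."""
    v = np.asarray(points, dtype=float) - centre
    h = v @ normal
    v_in = v - h[:, None] * normal
    rho = np.linalg.norm(v_in, axis=1)
    return np.sqrt((rho - radius) ** 2 + h**2)


def _projected_arc_samples(
    rig: SimulatorRig, sphere_centre_w: np.ndarray, radius: float, n_samples: int
):
    """Sample points of each laser fan's projection circle on the posed sphere.

    Yields ``(label, samples)``; raises if a fan plane misses the sphere.
    """
    for label, point, normal, _vis in rig.fan_planes(world=True):
        a = float((sphere_centre_w - point) @ normal)
        if abs(a) >= radius:
            raise CalibrationError(
                f"laser fan ({label}) misses the calibration sphere"
            )
        centre = sphere_centre_w - a * normal
        r = np.sqrt(radius**2 - a**2)
        # orthonormal basis of the fan plane
        u = np.cross(normal, [0.0, 0.0, 1.0])
        if np.linalg.norm(u) < 1e-6:
            u = np.cross(normal, [0.0, 1.0, 0.0])
        u /= np.linalg.norm(u)
        w = np.cross(normal, u)
        th = np.linspace(0.0, 2.0 * np.pi, n_samples, endpoint=False)
        samples = centre + r * (np.outer(np.cos(th), u) + np.outer(np.sin(th), w))
        yield label, samples


def arc_residual(
    rig: SimulatorRig,
    sphere: CalibrationSphere,
    position: CalibrationPosition = PCP,
    n_samples: int = 180,
) -> float:
    """Mean distance (mm) between projected and marked arcs at a calibration position.

    The sphere is secured so the selected marked arcs lie on the nominal laser
    planes; each fan's projection circle is sampled and measured against the
    same-colour marked circle. Zero for a calibrated rig at any of the eight
    positions.
    """
    centre_scs = _sphere_centre_for_position(sphere, position)
    centre_w = rig.pose.apply(centre_scs)
    R = rig.pose.rotation
    marked = {}
    for color, kind in zip(COLORS, position.choice):
        c, n, r = sphere.circle(color, kind)
        # posed into world with the sphere secured at the position
        c_w = R @ (c - sphere.centre + centre_scs) + rig.pose.translation
        marked[COLOR_LABEL[color]] = (c_w, R @ n, r)
    dists = []
    for label, samples in _projected_arc_samples(
        rig, centre_w, sphere.radius, n_samples
    ):
        c_w, n_w, r = marked[label]
        dists.append(_point_circle_distance(samples, c_w, n_w, r))
    return float(np.concatenate(dists).mean())


@dataclass
class IntrinsicReport:
    """Before/after residuals per position, plus recovered vs. true corrections."""

    before_mm: dict[str, float]
    after_mm: dict[str, float]
    correction_rotvecs: np.ndarray          # (2, 3), applied to the input rig
    true_perturbation: np.ndarray | None    # (2, 3) if the rig recorded one
    n_iterations: int

    @property
    def recovery_error_rad(self) -> float | None:
        """Angle between the applied correction and the exact inverse perturbation."""
        if self.true_perturbation is None:
            return None
        worst = 0.0
        for rv_corr, rv_true in zip(self.correction_rotvecs, self.true_perturbation):
            R_corr = Rotation.from_rotvec(rv_corr)
            R_true_inv = Rotation.from_rotvec(rv_true).inv()
            worst = max(worst, float((R_corr * R_true_inv.inv()).magnitude()))
        return worst


def intrinsic_calibrate(
    rig: SimulatorRig,
    sphere: CalibrationSphere | None = None,
    n_samples: int = 180,
    residual_tol_mm: float = 1e-3,
    max_restarts: int = 3,
) -> tuple[SimulatorRig, IntrinsicReport]:
    """Orthogonalize the laser fans against the sphere at the primary position.

    A derivative-free simplex search over the four fan adjustment angles (two
    per emitter, parameterized as per-emitter rotation vectors) minimizes the
    projected-vs-marked arc residual at the PCP only; the seven secondary
    positions are held out and evaluated afterwards as verification, mirroring
    the physical screw-adjustment procedure.
    """
    sphere = sphere or build_calibration_sphere()
    positions = enumerate_orthogonal_combinations(sphere)

    def objective(params: np.ndarray) -> float:
        return arc_residual(
            rig.with_corrections(params.reshape(2, 3)), sphere, PCP, n_samples
        )

    before = {
        p.label: arc_residual(rig, sphere, p, n_samples) for p in positions
    }
    x = np.zeros(6)
    n_iter = 0
    for _ in range(max_restarts):
        res = minimize(
            objective,
            x,
            method="Nelder-Mead",
            options=dict(
                xatol=1e-9, fatol=1e-13, maxiter=6000, maxfev=9000, adaptive=True
            ),
        )
        x, n_iter = res.x, n_iter + res.nit
        if res.fun <= residual_tol_mm * 1e-2:
            break
    calibrated = rig.with_corrections(x.reshape(2, 3))
    after = {
        p.label: arc_residual(calibrated, sphere, p, n_samples) for p in positions
    }
    if max(after.values()) > residual_tol_mm:
        raise CalibrationError(
            f"intrinsic calibration did not converge: worst residual "
            f"{max(after.values()):.3e} mm after {n_iter} iterations"
        )
    report = IntrinsicReport(
        before_mm=before,
        after_mm=after,
        correction_rotvecs=x.reshape(2, 3),
        true_perturbation=rig.perturbation,
        n_iterations=n_iter,
    )
    return calibrated, report


def sample_virtual_sphere(
    sphere: CalibrationSphere,
    true_t_vr: RigidTransform,
    n_samples: int = 500,
    noise_sigma_mm: float = 0.0,
    seed: int = DEFAULT_SEED,
) -> dict[str, np.ndarray]:
    """Simulated observation of the virtual sphere's great circles in the VCS.

    The physical sphere sits at the PCP in the RICS; the virtual copy is its
    image under the inverse of the true extrinsic transform, with optional
    isotropic per-point noise. Returns per-colour sample points in the VCS.
    """
    if true_t_vr.source is not Frame.VCS or true_t_vr.target is not Frame.RICS:
        raise ValueError("true_t_vr must map VCS -> RICS")
    rng = np.random.default_rng(seed)
    inv = true_t_vr.invert()
    out = {}
    for color in COLORS:
        c, n, r = sphere.circle(color, "great")
        u = np.cross(n, [0.0, 0.0, 1.0])
        if np.linalg.norm(u) < 1e-6:
            u = np.cross(n, [0.0, 1.0, 0.0])
        u /= np.linalg.norm(u)
        w = np.cross(n, u)
        th = np.linspace(0.0, 2.0 * np.pi, n_samples, endpoint=False)
        pts = c + r * (np.outer(np.cos(th), u) + np.outer(np.sin(th), w))
        pts = inv.apply(pts)
        if noise_sigma_mm > 0:
            pts = pts + rng.normal(0.0, noise_sigma_mm, pts.shape)
        out[color] = pts
    return out


def extrinsic_calibrate(
    initial: RigidTransform,
    virtual_points: dict[str, np.ndarray],
    sphere: CalibrationSphere | None = None,
    max_residual_mm: float | None = None,
) -> RigidTransform:
    """Recover T_VR by aligning the virtual great circles with the physical sphere.

    Six-DOF least squares (Levenberg-Marquardt) on the distances from the
    transformed virtual sample points to the corresponding physical great
    circles of the sphere secured at the PCP. ``initial`` must be within the
    convergence basin (about 20 mm / 15 degrees in simulation).
    """
    if initial.source is not Frame.VCS or initial.target is not Frame.RICS:
        raise ValueError("initial guess must map VCS -> RICS")
    sphere = sphere or build_calibration_sphere()
    circles = {c: sphere.circle(c, "great") for c in COLORS}

    def residuals(params: np.ndarray) -> np.ndarray:
        T = RigidTransform.from_rotvec(Frame.VCS, Frame.RICS, params[:3], params[3:])
        per = [
            _point_circle_distance(T.apply(virtual_points[c]), *circles[c])
            for c in COLORS
        ]
        return np.concatenate(per)

    x0 = np.concatenate([initial.rotvec, initial.translation])
    res = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
    rms = float(np.sqrt(np.mean(res.fun**2)))
    if max_residual_mm is not None and rms > max_residual_mm:
        raise CalibrationError(
            f"extrinsic calibration residual {rms:.3e} mm exceeds "
            f"{max_residual_mm:.3e} mm — initialization outside the basin?"
        )
    return RigidTransform.from_rotvec(
        Frame.VCS, Frame.RICS, res.x[:3], res.x[3:]
    )
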