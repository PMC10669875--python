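"""Simulator deployment (pose recovery against marked lines) and hologram registration.

Deploying the simulator means adjusting its six-DOF pose until the laser curves
it projects on the head coincide with the skin lines marked at scan time. The
physical procedure is manual; here a seeded multi-start simplex search minimizes
the labelled curve misfit, which reproduces the same alignment criterion. On a
perfect alignment the simulator occupies the scanner's acquisition frame, so the
residual simulator-to-scanner transform T_SSc is the identity (any remaining
misfit is reported, never silently absorbed).

Hologram registration then pushes model points from the reference-image frame
through the five-factor chain into the world; the freeze/unfreeze state machine
models anchoring the hologram to a spatial snapshot (with optional random-walk
drift) versus live target tracking.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy.optimize import minimize

from . import geometry
from .imaging import CurveSet
from .lasers import SimulatorRig, _grouped_world_planes, curve_misfit, project_crosshair
from .transforms import (
    Frame,
    FrameError,
    FrameGraph,
    RigidTransform,
    chain_world_to_scanner,
    compose,
)

__all__ = [
    "DeployOptions",
    "DeployResult",
    "DeploymentError",
    "deploy_simulator",
    "deployment_objective",
    "deployment_hessian",
    "register_holograms",
    "Mode",
    "RegistrationState",
    "freeze",
    "unfreeze",
    "drift_step",
    "current_transform",
]


class DeploymentError(RuntimeError):
    """Raised when no start reaches an acceptable curve misfit."""

    def __init__(self, message: str, best_misfit_mm: float):
        super().__init__(message)
        self.best_misfit_mm = best_misfit_mm


@dataclass(frozen=True)
class DeployOptions:
    """Knobs of the pose search.

    The basin describes how far the initial guess may be from the truth; extra
    starts are scattered inside half of it. ``fail_threshold_mm`` is the misfit
    above which deployment is declared failed (a well-aligned simulator on a
    0.5 mm-sampled fixture sits well below 0.05 mm).
    """

    n_starts: int = 4
    seed: int = 0
    basin_translation_mm: float = 10.0
    basin_rotation_deg: float = 10.0
    fail_threshold_mm: float = 0.5
    max_points_per_label: int = 150
    final_step_mm: float = 0.5
    maxiter: int = 800
    xatol: float = 1e-5
    labels: tuple[str, ...] | None = None


def _pose_from_params(params: np.ndarray) -> RigidTransform:
    return RigidTransform.from_rotvec(Frame.SCS, Frame.WORLD, params[:3], params[3:])


def _subsample(points: np.ndarray, n_max: int) -> np.ndarray:
    if len(points) <= n_max:
        return points
    idx = np.linspace(0, len(points) - 1, n_max).round().astype(int)
    return points[idx]


def deployment_objective(
    marked: CurveSet,
    surface: trimesh.Trimesh,
    rig: SimulatorRig,
    labels=None,
    max_points_per_label: int = 150,
    squared: bool = False,
):
    """Build the misfit function of the 6-DOF pose parameters (rotvec, translation).

    The returned callable intersects each laser plane with the mesh at the
    candidate pose and scores the symmetric distance between marked points and
    projected segments (both directions, no polyline chaining — this is the fast
    path used inside the optimizer; the public ``curve_misfit`` on full
    projections is reported at the end). ``squared`` switches to mean squared
    distance, the smooth form used for curvature (Hessian) analysis.
    """
    wanted = set(labels) if labels is not None else set(marked.curves)
    # coarsen the marked curves for optimizer-side scoring: contiguous segments at
    # a ~1.5 mm step keep the chord-sag bias well below the recovery tolerance
    # while cutting the pairwise-distance work by an order of magnitude
    coarse_step = max(1.5, 3.0 * (marked.step_mm or 0.5))
    coarse = {
        lb: [geometry.resample_polyline(p, coarse_step) for p in marked.curves[lb]]
        for lb in wanted
    }
    marked_pts = {
        lb: _subsample(np.concatenate(coarse[lb]), max_points_per_label)
        for lb in wanted
    }
    marked_segs = {
        lb: np.concatenate(
            [geometry.polyline_segments(p) for p in coarse[lb] if len(p) > 1]
        )
        for lb in wanted
    }
    face_normals = np.array(surface.face_normals)
    penalty = float(surface.extents.max()) * 10.0

    def objective(params: np.ndarray) -> float:
        pose = _pose_from_params(params)
        posed = rig.with_pose(pose)
        dists = []
        for label, point, normal, viss in _grouped_world_planes(posed, wanted):
            segs, faces = trimesh.intersections.mesh_plane(
                surface, normal, point, return_faces=True
            )
            if len(segs):
                fn = face_normals[faces]
                visible = np.zeros(len(segs), dtype=bool)
                for d in viss:
                    visible |= fn @ d > 0.0
                segs = segs[visible]
            if len(segs) == 0:
                return penalty
            d1 = geometry.points_to_segments_distance(marked_pts[label], segs)
            mids = _subsample(segs.mean(axis=1), max_points_per_label)
            d2 = geometry.points_to_segments_distance(mids, marked_segs[label])
            d = np.concatenate([d1, d2])
            dists.append(d**2 if squared else d)
        return float(np.concatenate(dists).mean())

    return objective


@dataclass
class DeployResult:
    """Recovered pose, reported misfit, and the resulting T_SSc convention."""

    pose: RigidTransform                 # SCS -> WORLD
    misfit_mm: float
    t_ssc: RigidTransform                # identity on success, by convention
    start_misfits_mm: list[float]
    n_evaluations: int


def deploy_simulator(
    marked: CurveSet,
    surface: trimesh.Trimesh,
    rig: SimulatorRig,
    init: RigidTransform,
    opts: DeployOptions | None = None,
) -> DeployResult:
    """Recover the rig pose that aligns projected crosshairs with the marked lines.

    Multi-start Nelder-Mead on (rotation-vector, translation): the first start is
    the initial guess, the rest are seeded perturbations inside half the basin.
    Succeeds when the best pose's curve misfit falls below the failure threshold;
    raises :class:`DeploymentError` (carrying the best misfit) otherwise.
    """
    opts = opts or DeployOptions()
    if init.source is not Frame.SCS or init.target is not Frame.WORLD:
        raise FrameError("initial pose must map SCS -> WORLD")
    objective = deployment_objective(
        marked, surface, rig, opts.labels, opts.max_points_per_label
    )
    rng = np.random.default_rng(opts.seed)
    x0 = np.concatenate([init.rotvec, init.translation])
    starts = [x0]
    for _ in range(opts.n_starts - 1):
        d = np.concatenate(
            [
                rng.uniform(-0.5, 0.5, 3) * np.deg2rad(opts.basin_rotation_deg),
                rng.uniform(-0.5, 0.5, 3) * opts.basin_translation_mm,
            ]
        )
        starts.append(x0 + d)

    best, n_eval, start_vals = None, 0, []
    for x_start in starts:
        res = minimize(
            objective,
            x_start,
            method="Nelder-Mead",
            options=dict(
                xatol=opts.xatol, fatol=1e-10, maxiter=opts.maxiter,
                maxfev=2 * opts.maxiter, adaptive=True,
            ),
        )
        n_eval += res.nfev
        start_vals.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    # polish the winner once from its own optimum
    res = minimize(
        objective,
        best.x,
        method="Nelder-Mead",
        options=dict(
            xatol=opts.xatol / 10.0, fatol=1e-11, maxiter=opts.maxiter // 2,
            maxfev=opts.maxiter, adaptive=True,
        ),
    )
    n_eval += res.nfev
    if res.fun < best.fun:
        best = res
    pose = _pose_from_params(best.x)
    projected = project_crosshair(
        rig.with_pose(pose), surface, opts.final_step_mm, labels=opts.labels
    )
    reported = curve_misfit(
        projected,
        marked
        if opts.labels is None
        else CurveSet(
            {lb: marked.curves[lb] for lb in opts.labels}, marked.frame
        ),
    )
    if reported > opts.fail_threshold_mm:
        raise DeploymentError(
            f"deployment failed: best misfit {reported:.3f} mm exceeds "
            f"threshold {opts.fail_threshold_mm:.3f} mm",
            reported,
        )
    return DeployResult(
        pose=pose,
        misfit_mm=reported,
        t_ssc=RigidTransform.identity(Frame.SCS, Frame.SCANNER),
        start_misfits_mm=start_vals,
        n_evaluations=n_eval,
    )


def deployment_hessian(
    marked: CurveSet,
    surface: trimesh.Trimesh,
    rig: SimulatorRig,
    pose: RigidTransform,
    labels=None,
    delta_rot: float = 2e-3,
    delta_trans: float = 0.2,
) -> np.ndarray:
    """Finite-difference 6x6 Hessian of the squared misfit at a pose.

    Used for constraint (degree-of-freedom) analysis: on a generically curved
    surface all six eigenvalues are positive; a single crosshair on a flat plate
    leaves the boresight translation unconstrained (a near-zero eigenvalue whose
    eigenvector points along the surface normal).
    """
    objective = deployment_objective(marked, surface, rig, labels, squared=True)
    x0 = np.concatenate([pose.rotvec, pose.translation])
    h = np.array([delta_rot] * 3 + [delta_trans] * 3)
    H = np.zeros((6, 6))
    f0 = objective(x0)
    for i in range(6):
        ei = np.zeros(6)
        ei[i] = h[i]
        fpp = objective(x0 + ei)
        fmm = objective(x0 - ei)
        H[i, i] = (fpp - 2 * f0 + fmm) / h[i] ** 2
        for j in range(i + 1, 6):
            ej = np.zeros(6)
            ej[j] = h[j]
            fpq = objective(x0 + ei + ej)
            fpm = objective(x0 + ei - ej)
            fmq = objective(x0 - ei + ej)
            fm2 = objective(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpq - fpm - fmq + fm2) / (4 * h[i] * h[j])
    return H


def register_holograms(
    graph: FrameGraph, model_points: np.ndarray
) -> dict[Frame, np.ndarray]:
    """Map model points given in the RICS to the scanner and world frames.

    Uses the five-factor chain: points go RICS -> SCS -> SCANNER directly, and
    into the world through the inverse of the full world-to-scanner product.
    With all-true transforms the world image of the model fiducials coincides
    with the physical fiducials.
    """
    pts = np.asarray(model_points, dtype=float)
    rics_to_scanner = compose(
        graph.get(Frame.RICS, Frame.SCS), graph.get(Frame.SCS, Frame.SCANNER)
    )
    world_to_scanner = chain_world_to_scanner(graph)
    in_scanner = rics_to_scanner.apply(pts)
    return {
        Frame.SCANNER: in_scanner,
        Frame.WORLD: world_to_scanner.invert().apply(in_scanner),
    }


class Mode(enum.Enum):
    LIVE = "LIVE"
    FROZEN = "FROZEN"


@dataclass
class RegistrationState:
    """Freeze/unfreeze state of a registered hologram.

    In LIVE mode the reported transform follows the live source; FREEZE snapshots
    it to a spatial anchor. An optional isotropic random walk on the anchor
    translation emulates the slow holographic drift of a frozen anchor; the walk
    is discarded on unfreeze (the loop-closure analogue). Drift is off by default
    and its magnitude is a placeholder, not a measured rate.
    """

    live: RigidTransform                      # RICS -> WORLD
    mode: Mode = Mode.LIVE
    drift_sigma_mm: float = 0.0
    seed: int = 0
    _anchor: RigidTransform | None = None
    _drift: np.ndarray = field(default_factory=lambda: np.zeros(3))
    _rng: np.random.Generator | None = None

    def __post_init__(self) -> None:
        if self._rng is None:
            self._rng = np.random.default_rng(self.seed)


def freeze(state: RegistrationState) -> RegistrationState:
    state.mode = Mode.FROZEN
    state._anchor = state.live
    state._drift = np.zeros(3)
    return state


def unfreeze(state: RegistrationState) -> RegistrationState:
    state.mode = Mode.LIVE
    state._anchor = None
    state._drift = np.zeros(3)
    return state


def drift_step(state: RegistrationState, n_steps: int = 1) -> RegistrationState:
    """Advance the frozen anchor's random walk by ``n_steps`` (no-op when LIVE)."""
    if state.mode is Mode.FROZEN and state.drift_sigma_mm > 0:
        steps = state._rng.normal(0.0, state.drift_sigma_mm, (n_steps, 3))
        state._drift = state._drift + steps.sum(axis=0)
    return state


def current_transform(state: RegistrationState) -> RigidTransform:
    if state.mode is Mode.LIVE:
        return state.live
    anchored = state._anchor
    return RigidTransform.from_rotation_translation(
        anchored.source,
        anchored.target,
        anchored.rotation,
        anchored.translation + state._drift,
    )
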