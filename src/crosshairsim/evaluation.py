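"""Target-registration-error measurement protocol and statistics.

After a registration, accuracy is probed at scalp fiducials that took no part in
the registration itself: for fiducial ``i`` the known reference point ``P_i`` is
compared with the probed position ``Q_i`` and the per-point TRE is the Euclidean
distance ``|P_i - Q_i|``, with signed per-axis components kept for histograms.
The protocol nests measurements as registrations x sessions x markers (the
reference study shape is 3 x 3 x 6 = 54 points); a per-registration rigid bias
models deployment error and an isotropic Gaussian models per-probe perception
noise. A rigid least-squares fit ``T_PQ`` (Kabsch) extrapolates the fiducial
deviations over the whole head for distance-map rendering, and a one-way ANOVA
tests TRE differences between registrations or between markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .transforms import Frame, RigidTransform

__all__ = [
    "FiducialSet",
    "MeasurementSession",
    "TREReport",
    "tre",
    "run_protocol",
    "fit_rigid_lsq",
    "model_to_model_distance",
    "summarize",
    "anova_oneway",
]

DEFAULT_LABELS = ("A", "B", "C", "D", "E", "F")


@dataclass(frozen=True)
class FiducialSet:
    """Labelled reference points ``P_i`` (mm) in a named frame."""

    labels: tuple[str, ...]
    points: np.ndarray
    frame: Frame = Frame.RICS

    def __post_init__(self) -> None:
        pts = np.array(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("points must be (n, 3)")
        if len(self.labels) != len(pts):
            raise ValueError("labels and points length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")
        pts.flags.writeable = False
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "labels", tuple(self.labels))

    def __len__(self) -> int:
        return len(self.labels)

    def transformed(self, T: RigidTransform) -> "FiducialSet":
        return FiducialSet(self.labels, T.apply(self.points), T.target)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"label": self.labels,
             "x": self.points[:, 0], "y": self.points[:, 1], "z": self.points[:, 2]}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame: Frame = Frame.WORLD) -> "FiducialSet":
        df = pd.read_csv(path)
        return cls(tuple(df["label"]), df[["x", "y", "z"]].to_numpy(dtype=float), frame)


@dataclass(frozen=True)
class MeasurementSession:
    """Probed positions ``Q_i`` of one measurement round."""

    registration_id: int
    session_id: int
    labels: tuple[str, ...]
    probed: np.ndarray
    noise_sigma: float = 0.0
    seed: int | None = None


@dataclass
class TREReport:
    """Per-point deviations over registrations x sessions x markers.

    ``data`` columns: registration, session, marker, dx, dy, dz (signed, Q - P)
    and distance (mm).
    """

    data: pd.DataFrame
    n_registrations: int
    n_sessions: int
    n_markers: int

    def __post_init__(self) -> None:
        expected = self.n_registrations * self.n_sessions * self.n_markers
        if len(self.data) != expected:
            raise ValueError(
                f"report has {len(self.data)} rows, expected "
                f"{self.n_registrations} x {self.n_sessions} x {self.n_markers}"
            )

    @property
    def distances(self) -> np.ndarray:
        return self.data["distance"].to_numpy()

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _deviation_frame(P: FiducialSet, labels, probed: np.ndarray) -> pd.DataFrame:
    if tuple(labels) != P.labels:
        by_label = dict(zip(P.labels, P.points))
        missing = [lb for lb in labels if lb not in by_label]
        if missing:
            raise ValueError(f"probed labels {missing} not in fiducial set")
        ref = np.array([by_label[lb] for lb in labels])
    else:
        ref = P.points
    delta = np.asarray(probed, dtype=float) - ref
    return pd.DataFrame(
        {
            "marker": list(labels),
            "dx": delta[:, 0],
            "dy": delta[:, 1],
            "dz": delta[:, 2],
            "distance": np.linalg.norm(delta, axis=1),
        }
    )


def tre(P: FiducialSet, Q: MeasurementSession) -> pd.DataFrame:
    """Per-fiducial deviation of one session: signed components and distance (mm)."""
    return _deviation_frame(P, Q.labels, Q.probed)


def run_protocol(
    P: FiducialSet,
    n_registrations: int = 3,
    n_sessions: int = 3,
    noise_sigma: float = 0.0,
    seed: int = 0,
    deployment_sigma_mm: float = 0.0,
    deployment_sigma_deg: float = 0.0,
) -> TREReport:
    """Simulate the nested measurement protocol.

    Each registration draws one rigid bias (rotation-vector components
    ~ N(0, deployment_sigma_deg), translation components ~ N(0, deployment_sigma_mm)),
    standing in for an imperfect simulator deployment; each probed point then adds
    isotropic Gaussian perception noise of standard deviation ``noise_sigma`` per
    axis. With both at zero the protocol returns exact zeros.
    """
    if n_registrations < 1 or n_sessions < 1:
        raise ValueError("need at least one registration and one session")
    if noise_sigma < 0 or deployment_sigma_mm < 0 or deployment_sigma_deg < 0:
        raise ValueError("noise magnitudes must be non-negative")
    rng = np.random.default_rng(seed)
    frames = []
    for reg in range(1, n_registrations + 1):
        rotvec = rng.normal(0.0, np.deg2rad(deployment_sigma_deg), 3)
        shift = rng.normal(0.0, deployment_sigma_mm, 3)
        bias = RigidTransform.from_rotvec(P.frame, P.frame, rotvec, shift)
        biased = bias.apply(P.points)
        for ses in range(1, n_sessions + 1):
            probed = biased + rng.normal(0.0, noise_sigma, biased.shape)
            df = _deviation_frame(P, P.labels, probed)
            df.insert(0, "session", ses)
            df.insert(0, "registration", reg)
            frames.append(df)
    data = pd.concat(frames, ignore_index=True)
    return TREReport(data, n_registrations, n_sessions, len(P))


def fit_rigid_lsq(P: FiducialSet, Q: np.ndarray | FiducialSet) -> RigidTransform:
    """Least-squares proper rigid transform ``T_PQ`` from P to Q (Kabsch/SVD).

    Minimizes ``sum_i |T P_i - Q_i|^2`` over rotations with det = +1 and
    translations; a reflection is never returned. Requires >= 3 non-collinear
    point pairs.
    """
    q = Q.points if isinstance(Q, FiducialSet) else np.asarray(Q, dtype=float)
    p = P.points
    if q.shape != p.shape:
        raise ValueError("P and Q must have matching shapes")
    if len(p) < 3:
        raise ValueError("need at least 3 point pairs")
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    H = (p - pc).T @ (q - qc)
    U, S, Vt = np.linalg.svd(H)
    if S[1] <= 1e-9 * max(S[0], 1.0):
        raise ValueError("degenerate (collinear) fiducial configuration")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    return RigidTransform.from_rotation_translation(P.frame, P.frame, R, t)


def model_to_model_distance(mesh, T: RigidTransform) -> np.ndarray:
    """Per-vertex distance (mm) between a mesh and its rigidly transformed copy.

    Corresponding-vertex convention, as used for colour-mapped error rendering.
    """
    V = np.asarray(mesh.vertices, dtype=float)
    return np.linalg.norm(T.apply(V) - V, axis=1)


def _group_stats(values: np.ndarray) -> dict:
    return {
        "n": int(values.size),
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if values.size > 1 else 0.0,
        "min": float(values.min()),
        "max": float(values.max()),
    }


def summarize(report: TREReport, cutoff_mm: float = 5.0) -> dict:
    """Mean +/- sd (n-1), min, max overall and per grouping; fraction below cutoff.

    Also reports per-axis RMSE of the signed components, the aggregate form of
    the per-point distances along the three principal axes.
    """
    if len(report.data) == 0:
        raise ValueError("empty report")
    d = report.distances
    out = {
        "overall": {
            **_group_stats(d),
            "fraction_below_cutoff": float(np.mean(d < cutoff_mm)),
            "cutoff_mm": float(cutoff_mm),
        },
        "per_registration": {
            str(reg): _group_stats(grp["distance"].to_numpy())
            for reg, grp in report.data.groupby("registration")
        },
        "per_marker": {
            str(m): _group_stats(grp["distance"].to_numpy())
            for m, grp in report.data.groupby("marker")
        },
        "per_axis_rmse": {
            ax: float(np.sqrt(np.mean(report.data[f"d{ax}"] ** 2)))
            for ax in ("x", "y", "z")
        },
    }
    return out


def anova_oneway(groups) -> tuple[float, float]:
    """Classical fixed-effects one-way ANOVA: F on (k-1, N-k) df and its p-value.

    When every observation is identical (zero variance within and between
    groups) the F ratio is defined as 0 with p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 samples each")
    allv = np.concatenate(groups)
    if np.ptp(allv) == 0.0:
        return 0.0, 1.0
    F, p = stats.f_oneway(*groups)
    return float(F), float(p)
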