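"""Polyline geometry helpers: segment chaining, resampling, closest-point distances.

Plane-mesh intersections (from :mod:`trimesh`) come back as unordered 3D segments;
the helpers here chain them into ordered polylines, resample by arc length, and
measure point-to-polyline distances. All distances are in millimetres.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "chain_segments",
    "polyline_length",
    "resample_polyline",
    "polyline_segments",
    "points_to_segments_distance",
]


def chain_segments(segments: np.ndarray, decimals: int = 6) -> list[np.ndarray]:
    """Chain unordered 3D segments ``(n, 2, 3)`` into ordered polylines.

    Endpoints are matched after rounding to ``decimals`` (default 1e-6 mm, well below
    any sampling step used here). Returns a list of ``(k, 3)`` vertex arrays; closed
    loops repeat their first vertex at the end.
    """
    segments = np.asarray(segments, dtype=float)
    if segments.size == 0:
        return []

    def key(p: np.ndarray) -> tuple:
        return tuple(np.round(p, decimals))

    # adjacency: endpoint key -> list of (segment index, end index)
    adjacency: dict[tuple, list[tuple[int, int]]] = {}
    for i, seg in enumerate(segments):
        for e in (0, 1):
            adjacency.setdefault(key(seg[e]), []).append((i, e))

    used = np.zeros(len(segments), dtype=bool)
    polylines: list[np.ndarray] = []

    def extend(tip: np.ndarray) -> list[np.ndarray]:
        """Greedily follow unused segments away from ``tip``."""
        out = []
        while True:
            candidates = [(i, e) for i, e in adjacency.get(key(tip), []) if not used[i]]
            if not candidates:
                return out
            i, e = candidates[0]
            used[i] = True
            tip = segments[i, 1 - e]
            out.append(tip)

    # prefer chains seeded at open endpoints so open curves come out in one piece
    degree = {k: len(v) for k, v in adjacency.items()}
    order = sorted(
        range(len(segments)),
        key=lambda i: min(degree[key(segments[i, 0])], degree[key(segments[i, 1])]),
    )
    for i in order:
        if used[i]:
            continue
        used[i] = True
        head, tail = segments[i, 0], segments[i, 1]
        forward = extend(tail)
        backward = extend(head)
        pts = list(reversed(backward)) + [head, tail] + forward
        poly = np.array(pts)
        # drop zero-length duplicate steps
        keep = np.ones(len(poly), dtype=bool)
        keep[1:] = np.linalg.norm(np.diff(poly, axis=0), axis=1) > 10.0 ** (-decimals)
        poly = poly[keep]
        if len(poly) >= 2:
            polylines.append(poly)
    return polylines


def polyline_length(points: np.ndarray) -> float:
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def resample_polyline(points: np.ndarray, step_mm: float) -> np.ndarray:
    """Resample a polyline at (at most) ``step_mm`` arc-length spacing.

    Both endpoints are preserved; the spacing is uniform along the accumulated
    chord length. A closed polyline (first point repeated last) stays closed.
    """
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")
    points = np.asarray(points, dtype=float)
    seg_len = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = s[-1]
    if total == 0.0:
        return points[:1].copy()
    n = max(int(np.ceil(total / step_mm)), 1)
    si = np.linspace(0.0, total, n + 1)
    return np.column_stack([np.interp(si, s, points[:, k]) for k in range(3)])


def polyline_segments(points: np.ndarray) -> np.ndarray:
    """Consecutive-vertex segments ``(n-1, 2, 3)`` of a polyline."""
    points = np.asarray(points, dtype=float)
    return np.stack([points[:-1], points[1:]], axis=1)


def points_to_segments_distance(points: np.ndarray, segments: np.ndarray) -> np.ndarray:
    """Distance from each point to the nearest of a set of 3D segments.

    Vectorized ``(n_points, n_segments)`` evaluation; fine for the curve sizes used
    here (hundreds of points per curve).
    """
    P = np.asarray(points, dtype=float)            # (n, 3)
    S = np.asarray(segments, dtype=float)
    A, B = S[:, 0, :], S[:, 1, :]                  # (m, 3)
    AB = B - A
    ab2 = np.einsum("ij,ij->i", AB, AB)            # (m,)
    # all pairwise quantities via matrix products; d^2(t) expanded analytically
    pa_ab = P @ AB.T - np.einsum("ij,ij->i", A, AB)          # (n, m): (P-A).AB
    with np.errstate(invalid="ignore", divide="ignore"):
        t = pa_ab / ab2
    t = np.where(ab2 > 0, np.clip(t, 0.0, 1.0), 0.0)
    pa2 = (
        np.einsum("ij,ij->i", P, P)[:, None]
        - 2.0 * (P @ A.T)
        + np.einsum("ij,ij->i", A, A)[None, :]
    )
    d2 = pa2 - 2.0 * t * pa_ab + t**2 * ab2
    return np.sqrt(np.maximum(d2.min(axis=1), 0.0))
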