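"""Discrete differential geometry of unbranched centerline paths.

A traced path is a polyline of node centers with per-node radii.  Local
bending is quantified by the Menger curvature κ of consecutive point
triples — the reciprocal of the radius of the circle through the three
points, which matches the geometric definition "curvature = 1/radius of the
local curve" and is exact whenever the samples are concyclic.  Out-of-plane
winding is quantified by a signed discrete torsion τ from consecutive
quadruples: the rotation rate of the osculating-plane normal (binormal),
with right-handed spirals positive.  Both are in µm⁻¹.

Averages over a path or a whole network weight each point by the arc length
it represents (half the sum of its incident chord lengths), so that sparsely
and densely sampled stretches contribute in proportion to their physical
length rather than their node count.  Because manual tracing places nodes at
irregular intervals, profiles are by default computed after resampling the
polyline at a uniform arc-length step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateGeometryError, ParameterError

__all__ = [
    "resample_path",
    "curvature_profile",
    "torsion_profile",
    "arc_length_weights",
    "PathGeometry",
    "path_geometry",
]


def _chords(points: np.ndarray, closed: bool = False) -> np.ndarray:
    """Consecutive chord vectors; for closed curves includes the wrap chord."""
    if closed:
        return np.roll(points, -1, axis=0) - points
    return np.diff(points, axis=0)


def resample_path(points: np.ndarray, radii: np.ndarray, step: float
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Resample a polyline at uniform arc-length spacing.

    Points are placed every ``step`` µm of arc length along the
    piecewise-linear curve, with both endpoints preserved (the final
    interval may be shorter than ``step``).  Radii are linearly interpolated
    in arc length.

    Parameters
    ----------
    points : (n, 3) array
    radii : (n,) array
    step : float
        Target spacing in µm; must be positive.
    """
    if step <= 0:
        raise ParameterError(f"resampling step must be > 0, got {step}")
    points = np.asarray(points, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) < 2:
        raise ParameterError("need at least 2 points of shape (n, 3)")
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    targets = np.arange(0.0, total, step)
    # keep the endpoint; drop a penultimate sample that coincides with it
    if total - targets[-1] < 1e-12:
        targets = targets[:-1]
    targets = np.append(targets, total)
    new_pts = np.column_stack([np.interp(targets, s, points[:, k]) for k in range(3)])
    new_r = np.interp(targets, s, radii)
    return new_pts, new_r


def curvature_profile(points: np.ndarray, closed: bool = False) -> np.ndarray:
    """Menger curvature at each interior point, µm⁻¹.

    For the triple (A, B, C) centered on each interior point,
    κ = 4·Area(ABC)/(|AB|·|BC|·|AC|) — the reciprocal circumradius.
    Collinear triples give κ = 0.  Open paths with fewer than 3 points give
    an empty profile; closed curves treat every point as interior.
    Coincident consecutive points are rejected.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if (not closed and n < 3) or (closed and n < 3):
        return np.zeros(0)
    if closed:
        a = np.roll(points, 1, axis=0)   # P_{i-1}
        b = points
        c = np.roll(points, -1, axis=0)  # P_{i+1}
    else:
        a, b, c = points[:-2], points[1:-1], points[2:]
    e1 = b - a
    e2 = c - b
    chord = c - a
    l1 = np.linalg.norm(e1, axis=1)
    l2 = np.linalg.norm(e2, axis=1)
    lc = np.linalg.norm(chord, axis=1)
    if np.any(l1 == 0) or np.any(l2 == 0):
        raise DegenerateGeometryError("coincident consecutive points")
    cross = np.cross(e1, e2)
    area2 = np.linalg.norm(cross, axis=1)          # = 2·Area
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(lc > 0, 2.0 * area2 / (l1 * l2 * np.where(lc > 0, lc, 1.0)), 0.0)
    return kappa


def torsion_profile(points: np.ndarray, closed: bool = False) -> np.ndarray:
    """Signed discrete torsion at each interior point, µm⁻¹.

    For each quadruple (P₀, P₁, P₂, P₃) of consecutive points, the torsion
    assigned to P₁ is the angle between the binormals of (P₀,P₁,P₂) and
    (P₁,P₂,P₃) divided by the middle chord length |P₁P₂|, signed by the
    scalar triple product of the chords (right-handed → positive).  A
    coplanar quadruple gives τ = 0; if either triple is collinear the
    binormal is undefined and τ = 0 there by convention.  Mirror reflection
    of the path negates the profile.  Open paths with fewer than 4 points
    give an empty profile.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if not closed and n < 4:
        return np.zeros(0)
    if closed and n < 4:
        return np.zeros(n)
    if closed:
        e1 = points - np.roll(points, 1, axis=0)        # P_i     - P_{i-1}
        e2 = np.roll(points, -1, axis=0) - points       # P_{i+1} - P_i
        e3 = np.roll(points, -2, axis=0) - np.roll(points, -1, axis=0)
    else:
        chords = np.diff(points, axis=0)
        e1, e2, e3 = chords[:-2], chords[1:-1], chords[2:]
    b1 = np.cross(e1, e2)
    b2 = np.cross(e2, e3)
    n1 = np.linalg.norm(b1, axis=1)
    n2 = np.linalg.norm(b2, axis=1)
    l2 = np.linalg.norm(e2, axis=1)
    if np.any(l2 == 0):
        raise DegenerateGeometryError("coincident consecutive points")
    # rotation angle of the binormal between the two triples
    sin_phi = np.linalg.norm(np.cross(b1, b2), axis=1)
    cos_phi = np.einsum("ij,ij->i", b1, b2)
    phi = np.arctan2(sin_phi, cos_phi)
    sign = np.sign(np.einsum("ij,ij->i", b1, e3))
    ok = (n1 > 0) & (n2 > 0)
    tau = np.zeros(len(e2))
    tau[ok] = sign[ok] * phi[ok] / l2[ok]
    return tau


def arc_length_weights(points: np.ndarray, closed: bool = False) -> np.ndarray:
    """Arc length represented by each point (Voronoi weights), µm.

    Each point receives half of each incident chord; the weights sum to the
    polyline's total arc length.  Endpoints of an open path carry half their
    single chord.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise ParameterError("need at least 2 points")
    seg = np.linalg.norm(_chords(points, closed=closed), axis=1)
    if closed:
        return 0.5 * (seg + np.roll(seg, 1))
    w = np.zeros(len(points))
    w[:-1] += 0.5 * seg
    w[1:] += 0.5 * seg
    return w


@dataclass
class PathGeometry:
    """Per-point geometric profiles of one unbranched path.

    Attributes
    ----------
    points : (n, 3) array
        Sample points, µm (resampled unless raw mode was requested).  For
        closed paths the first point is not repeated.
    diameters : (n,) array
        Local outer diameter (2 × interpolated radius), µm.
    weights : (n,) array
        Arc length represented by each point; sums to ``arc_length``.
    curvature, torsion : arrays
        Interior-point profiles (µm⁻¹); for an open path of n points these
        have n−2 and n−3 entries, for a closed path n entries each.
    curvature_weights, torsion_weights : arrays
        Arc-length weights of the points carrying each profile value.
    closed : bool
    arc_length : float
        Total arc length of the (possibly resampled) polyline, µm.
    """

    points: np.ndarray
    diameters: np.ndarray
    weights: np.ndarray
    curvature: np.ndarray
    torsion: np.ndarray
    curvature_weights: np.ndarray
    torsion_weights: np.ndarray
    closed: bool
    arc_length: float

    @property
    def mean_diameter(self) -> float:
        """Length-weighted mean outer diameter of the path, µm."""
        return float(np.average(self.diameters, weights=self.weights))


def _moving_average(values: np.ndarray, window_pts: int, closed: bool) -> np.ndarray:
    if window_pts <= 1:
        return values
    kernel = np.ones(window_pts) / window_pts
    if closed:
        pad = window_pts // 2
        ext = np.concatenate([values[-pad:], values, values[:pad]])
        sm = np.convolve(ext, kernel, mode="same")
        return sm[pad:pad + len(values)]
    return np.convolve(values, kernel, mode="same") / np.convolve(
        np.ones_like(values), kernel, mode="same")


def path_geometry(points: np.ndarray, radii: np.ndarray, *,
                  closed: bool = False,
                  resample_step: float | None = 1.0,
                  smoothing_window: float = 0.0) -> PathGeometry:
    """Compute the full geometric profile of one path.

    Parameters
    ----------
    points, radii:
        Raw node centers and radii in path order.  For closed paths the
        first point must be repeated at the end (as produced by
        :meth:`UnbranchedPath.points`).
    resample_step:
        Uniform arc-length spacing in µm before estimation, or ``None`` to
        operate on the raw nodes.
    smoothing_window:
        Optional moving-average window in µm applied to the coordinates
        before curvature/torsion estimation; 0 disables smoothing.
    """
    points = np.asarray(points, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if resample_step is not None:
        points, radii = resample_path(points, radii, resample_step)
    if closed:
        # drop the duplicated closing point; wrap-around handled cyclically
        points, radii = points[:-1], radii[:-1]
    if smoothing_window > 0 and len(points) > 2:
        spacing = float(np.mean(np.linalg.norm(_chords(points, closed), axis=1)))
        window_pts = max(1, int(round(smoothing_window / spacing)))
        sm = np.column_stack([
            _moving_average(points[:, k], window_pts, closed) for k in range(3)])
        if not closed:
            sm[0], sm[-1] = points[0], points[-1]
        points = sm

    weights = arc_length_weights(points, closed=closed) if len(points) >= 2 \
        else np.zeros(len(points))
    kappa = curvature_profile(points, closed=closed) if len(points) >= 3 \
        else np.zeros(0)
    tau = torsion_profile(points, closed=closed) if len(points) >= 4 \
        else np.zeros(0)
    if closed:
        kw = weights.copy()
        tw = weights.copy()
    else:
        kw = weights[1:-1] if len(kappa) else np.zeros(0)
        tw = weights[1:len(tau) + 1] if len(tau) else np.zeros(0)
    return PathGeometry(
        points=points,
        diameters=2.0 * radii,
        weights=weights,
        curvature=kappa,
        torsion=tau,
        curvature_weights=kw,
        torsion_weights=tw,
        closed=closed,
        arc_length=float(weights.sum()),
    )
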