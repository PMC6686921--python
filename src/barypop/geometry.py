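"""Simplex geometry: the EFA triangle, planarization, barycentric coordinates.

Each anchor group's expected-distance triple (distance to the first three
reference populations) is a point in 3-space; the three points form the EFA
triangle. A rigid transform maps the triangle to the z = 0 plane with side
FA parallel to the x-axis; barycentric coordinates of a subject's point with
respect to the planarized triangle, clamped and renormalized, are its
ancestry proportions.

Frame convention (the method leaves orientation open, this module fixes it):
origin at V_F, A on the positive x-axis, E with positive y, and
z-axis = normalized (V_A - V_F) x (V_E - V_F). This makes the out-of-plane
coordinate of a point (its GD3 score) deterministic in sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Relative determinant threshold below which a frame is unusable.
DEGENERACY_RTOL = 1e-9


class DegenerateTriangleError(ValueError):
    """Triangle vertices are (near-)collinear."""


class UnstableFrameError(ValueError):
    """Barycentric determinant too small for a reliable solution."""


@dataclass(frozen=True)
class Triangle3D:
    """EFA triangle in expected-distance space (vertex order E, F, A)."""

    v_e: np.ndarray
    v_f: np.ndarray
    v_a: np.ndarray

    @property
    def vertices(self) -> np.ndarray:
        return np.stack([self.v_e, self.v_f, self.v_a])


@dataclass(frozen=True)
class PlanarFrame:
    """Rigid map from 3-space to the triangle plane.

    ``axes`` rows are the orthonormal (x, y, z) frame axes; ``origin`` is
    V_F. ``vertices2d`` are the in-plane (E, F, A) vertices with
    F = (0, 0), A = (|FA|, 0), y_E > 0.
    """

    origin: np.ndarray  # (3,)
    axes: np.ndarray  # (3, 3) rows x̂, ŷ, ẑ
    vertices2d: np.ndarray  # (3, 2) rows E, F, A

    def to_frame(self, points) -> np.ndarray:
        """Map 3-space points to (x, y, z) frame coordinates.

        The z component is the signed out-of-plane coordinate (GD3).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        rel = pts - self.origin
        out = rel @ self.axes.T
        return out if np.asarray(points).ndim > 1 else out[0]


def build_triangle(d_e, d_f, d_a) -> Triangle3D:
    """Build the EFA triangle from three expected-distance triples."""
    v_e, v_f, v_a = (np.asarray(v, dtype=np.float64).reshape(3) for v in (d_e, d_f, d_a))
    if not all(np.isfinite(v).all() for v in (v_e, v_f, v_a)):
        raise ValueError("triangle vertices must be finite")
    cross = np.cross(v_a - v_f, v_e - v_f)
    perim = (
        np.linalg.norm(v_a - v_f) + np.linalg.norm(v_e - v_f) + np.linalg.norm(v_e - v_a)
    )
    if np.linalg.norm(cross) <= DEGENERACY_RTOL * perim**2:
        raise DegenerateTriangleError("EFA triangle is degenerate (collinear vertices)")
    return Triangle3D(v_e=v_e, v_f=v_f, v_a=v_a)


def planarize(tri: Triangle3D, points=None):
    """Rigidly map the triangle (and optional points) onto the z = 0 plane.

    Returns ``frame`` or ``(frame, transformed_points)`` where the
    transformed points carry their in-plane (x, y) and out-of-plane z.
    """
    fa = tri.v_a - tri.v_f
    fe = tri.v_e - tri.v_f
    x_hat = fa / np.linalg.norm(fa)
    z = np.cross(fa, fe)
    z_hat = z / np.linalg.norm(z)
    y_hat = np.cross(z_hat, x_hat)
    axes = np.stack([x_hat, y_hat, z_hat])
    vertices2d = np.array(
        [
            [fe @ x_hat, fe @ y_hat],
            [0.0, 0.0],
            [np.linalg.norm(fa), 0.0],
        ]
    )
    frame = PlanarFrame(origin=tri.v_f.copy(), axes=axes, vertices2d=vertices2d)
    if points is None:
        return frame
    return frame, frame.to_frame(points)


def _det3(p1x, p1y, p2x, p2y, p3x, p3y):
    """det [[1, x1, y1], [1, x2, y2], [1, x3, y3]] (twice the signed area)."""
    return (p2x - p1x) * (p3y - p1y) - (p3x - p1x) * (p2y - p1y)


def _frame_vertices(frame) -> np.ndarray:
    if isinstance(frame, PlanarFrame):
        return frame.vertices2d
    v = np.asarray(frame, dtype=np.float64)
    if v.shape != (3, 2):
        raise ValueError("expected a PlanarFrame or a (3, 2) vertex array")
    return v


def barycentric(frame, q) -> np.ndarray:
    """Barycentric coordinates of 2-D point(s) q in the planar triangle.

    Computed as ratios of 3x3 determinants; the three coordinates always sum
    to 1 (signed — negative entries mean q lies outside the triangle).
    Raises :class:`UnstableFrameError` when the triangle determinant is below
    the degeneracy threshold.
    """
    v = _frame_vertices(frame)
    (xe, ye), (xf, yf), (xa, ya) = v
    perim = (
        np.hypot(xf - xe, yf - ye) + np.hypot(xa - xf, ya - yf) + np.hypot(xe - xa, ye - ya)
    )
    det_t = _det3(xe, ye, xf, yf, xa, ya)
    if abs(det_t) <= DEGENERACY_RTOL * perim**2:
        raise UnstableFrameError("barycentric determinant below degeneracy threshold")
    q = np.asarray(q, dtype=np.float64)
    single = q.ndim == 1
    qs = np.atleast_2d(q)
    xi, yi = qs[:, 0], qs[:, 1]
    lam_e = _det3(xi, yi, xf, yf, xa, ya) / det_t
    lam_f = _det3(xe, ye, xi, yi, xa, ya) / det_t
    lam_a = _det3(xe, ye, xf, yf, xi, yi) / det_t
    lam = np.stack([lam_e, lam_f, lam_a], axis=-1)
    return lam[0] if single else lam


def proportions(lam) -> np.ndarray:
    """Clamp-and-renormalize barycentric coordinates into ancestry proportions.

    P_m = max(0, lambda_m) / sum_m max(0, lambda_m). Points outside the
    triangle are projected onto it by zeroing negative coordinates.
    """
    lam = np.asarray(lam, dtype=np.float64)
    pos = np.maximum(lam, 0.0)
    total = pos.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("all barycentric coordinates non-positive (contract violation)")
    return pos / total


def barycentric_to_cartesian(lam, frame) -> np.ndarray:
    """Map barycentric coordinates back to 2-D Cartesian in a (possibly
    different) planar frame: the re-projection step of score normalization."""
    v = _frame_vertices(frame)
    lam = np.asarray(lam, dtype=np.float64)
    return lam @ v


def batch_planarize(v_e: np.ndarray, v_f: np.ndarray, v_a: np.ndarray, q: np.ndarray):
    """Vectorized planarization of n subject-specific triangles with points.

    Parameters are (n, 3) arrays of vertices and subject points. Returns
    ``(vertices2d, q2d, z, det_t, valid)`` where ``vertices2d`` is
    (n, 3, 2), ``q2d`` (n, 2) in-plane coordinates, ``z`` (n,) out-of-plane
    (GD3), ``det_t`` the barycentric determinants and ``valid`` a mask that
    is False for degenerate/unstable subset triangles.
    """
    fa = v_a - v_f
    fe = v_e - v_f
    nfa = np.linalg.norm(fa, axis=1)
    zc = np.cross(fa, fe)
    nz = np.linalg.norm(zc, axis=1)
    perim3d = nfa + np.linalg.norm(fe, axis=1) + np.linalg.norm(v_e - v_a, axis=1)
    valid = nz > DEGENERACY_RTOL * perim3d**2

    with np.errstate(divide="ignore", invalid="ignore"):
        x_hat = fa / nfa[:, None]
        z_hat = zc / nz[:, None]
    y_hat = np.cross(z_hat, x_hat)

    e2 = np.stack([(fe * x_hat).sum(1), (fe * y_hat).sum(1)], axis=1)
    f2 = np.zeros_like(e2)
    a2 = np.stack([nfa, np.zeros_like(nfa)], axis=1)
    vertices2d = np.stack([e2, f2, a2], axis=1)

    rel = q - v_f
    q2d = np.stack([(rel * x_hat).sum(1), (rel * y_hat).sum(1)], axis=1)
    z = (rel * z_hat).sum(1)

    det_t = _det3(
        e2[:, 0], e2[:, 1], f2[:, 0], f2[:, 1], a2[:, 0], a2[:, 1]
    )
    perim2d = (
        np.linalg.norm(e2 - f2, axis=1)
        + np.linalg.norm(a2 - f2, axis=1)
        + np.linalg.norm(e2 - a2, axis=1)
    )
    valid &= np.abs(det_t) > DEGENERACY_RTOL * perim2d**2
    return vertices2d, q2d, z, det_t, valid


def batch_barycentric(vertices2d: np.ndarray, q2d: np.ndarray) -> np.ndarray:
    """Barycentric coordinates for n points, each in its own triangle."""
    e2, f2, a2 = vertices2d[:, 0], vertices2d[:, 1], vertices2d[:, 2]
    det_t = _det3(e2[:, 0], e2[:, 1], f2[:, 0], f2[:, 1], a2[:, 0], a2[:, 1])
    xi, yi = q2d[:, 0], q2d[:, 1]
    lam_e = _det3(xi, yi, f2[:, 0], f2[:, 1], a2[:, 0], a2[:, 1]) / det_t
    lam_f = _det3(e2[:, 0], e2[:, 1], xi, yi, a2[:, 0], a2[:, 1]) / det_t
    lam_a = _det3(e2[:, 0], e2[:, 1], f2[:, 0], f2[:, 1], xi, yi) / det_t
    return np.stack([lam_e, lam_f, lam_a], axis=1)
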