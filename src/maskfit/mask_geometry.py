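"""Parametric rigid mask geometry.

A mask design is an ordered closed loop of 3D reference points.  A periodic
piecewise cubic spline (the *reference line*) interpolates them, and the
mask's contact nodes are sampled along the curve at roughly equal arc-length
intervals (default 1 mm), optionally extruded into a small cross-section
profile in the plane normal to the curve (rotation-minimizing frame).

The spline is parameterized by cumulative chord length.  Per axis the
second derivatives g'' at the knots solve the cyclic tridiagonal continuity
system

    l(k-1) g''(k-1) + 2 (l(k-1) + l(k)) g''(k) + l(k) g''(k+1)
        = 6 [ (g(k+1) - g(k)) / l(k) - (g(k) - g(k-1)) / l(k-1) ]

with periodic closure (value, slope and curvature match at the seam).  The
cyclic system is solved with two banded tridiagonal solves plus a
Sherman-Morrison correction for the corner entries.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import integrate
from scipy.linalg import solve_banded

from .errors import GeometryError, ParameterError

__all__ = [
    "CrossSectionProfile",
    "MaskDesign",
    "PeriodicCubicSpline",
    "MaskNodeSet",
    "fit_periodic_spline",
    "sample_mask_nodes",
    "adjust_reference_points",
    "load_reference_points",
    "save_reference_points",
]


@dataclass(frozen=True)
class CrossSectionProfile:
    """Cross-section node pattern in the local normal-plane frame (mm).

    Default is a single node on the reference line itself (line contact).
    ``flat_strip`` builds m nodes spread across width w.
    """

    offsets: tuple[tuple[float, float], ...] = ((0.0, 0.0),)

    def __post_init__(self) -> None:
        if len(self.offsets) < 1:
            raise ParameterError("profile needs at least one offset")
        arr = np.asarray(self.offsets, dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ParameterError("profile offsets must be finite")

    @property
    def m(self) -> int:
        return len(self.offsets)

    @classmethod
    def flat_strip(cls, m: int, width: float) -> "CrossSectionProfile":
        if m < 1 or width <= 0:
            raise ParameterError("flat strip needs m >= 1 and width > 0")
        xs = np.linspace(-width / 2.0, width / 2.0, m) if m > 1 else [0.0]
        return cls(tuple((float(x), 0.0) for x in xs))


@dataclass(frozen=True)
class MaskDesign:
    """Closed loop of reference points plus sampling options."""

    reference_points: np.ndarray
    profile: CrossSectionProfile = CrossSectionProfile()
    spacing: float = 1.0
    design_id: str = "design-0"

    def __post_init__(self) -> None:
        pts = np.ascontiguousarray(self.reference_points, dtype=float)
        object.__setattr__(self, "reference_points", pts)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ParameterError("reference_points must be an (n, 3) array")
        if len(pts) < 4:
            raise ParameterError("a mask design needs at least 4 reference points")
        chords = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
        if np.any(chords <= 1e-6):
            raise GeometryError("consecutive reference points coincide")
        if self.spacing <= 0:
            raise ParameterError("spacing must be positive")

    @property
    def n_points(self) -> int:
        return len(self.reference_points)


@dataclass(frozen=True)
class PeriodicCubicSpline:
    """Closed C2 piecewise-cubic space curve through n reference points.

    knots: parameter values p(0..n) (cumulative chord length, p(n) closes
    the loop); values: g(k) per axis, with the seam point repeated; and
    second_derivatives: g''(k) per axis (periodic, also repeated at seam).
    """

    knots: np.ndarray           # (n+1,)
    values: np.ndarray          # (n+1, 3)
    second_derivatives: np.ndarray  # (n+1, 3)

    @property
    def n_pieces(self) -> int:
        return len(self.knots) - 1

    @property
    def section_lengths(self) -> np.ndarray:
        return np.diff(self.knots)

    @property
    def period(self) -> float:
        return float(self.knots[-1] - self.knots[0])

    def _wrap(self, p):
        p = np.asarray(p, dtype=float)
        return self.knots[0] + np.mod(p - self.knots[0], self.period)

    def evaluate(self, p, order: int = 0) -> np.ndarray:
        """Evaluate the curve (order 0) or its derivatives (order 1, 2).

        The parameter wraps periodically; shape of the result is (..., 3).
        """
        if order not in (0, 1, 2):
            raise ParameterError("order must be 0, 1 or 2")
        p = self._wrap(p)
        scalar = p.ndim == 0
        p = np.atleast_1d(p)
        k = np.clip(np.searchsorted(self.knots, p, side="right") - 1, 0, self.n_pieces - 1)
        l = self.section_lengths[k][:, None]
        g0 = self.values[k]
        g1 = self.values[k + 1]
        d0 = self.second_derivatives[k]
        d1 = self.second_derivatives[k + 1]
        t0 = (p - self.knots[k])[:, None]        # p - p(k)
        t1 = (p - self.knots[k + 1])[:, None]    # p - p(k+1)
        if order == 0:
            out = (
                d1 * (t0**3 / (6.0 * l) - l * t0 / 6.0)
                + d0 * (-(t1**3) / (6.0 * l) + l * t1 / 6.0)
                + g1 * t0 / l
                - g0 * t1 / l
            )
        elif order == 1:
            out = (
                d1 * (3.0 * t0**2 / (6.0 * l) - l / 6.0)
                + d0 * (-(3.0 * t1**2) / (6.0 * l) + l / 6.0)
                + (g1 - g0) / l
            )
        else:
            out = d1 * t0 / l - d0 * t1 / l
        return out[0] if scalar else out

    __call__ = evaluate

    def arc_length(self, p0: float, p1: float) -> float:
        """Arc length between parameters (adaptive quadrature, rel err < 1e-6)."""
        val, _ = integrate.quad(
            lambda p: float(np.linalg.norm(self.evaluate(p, order=1))),
            p0,
            p1,
            epsrel=1e-8,
            limit=200,
        )
        return val

    def total_length(self) -> float:
        # piecewise to keep the quadrature adaptive within each cubic piece
        return float(
            sum(self.arc_length(a, b) for a, b in zip(self.knots[:-1], self.knots[1:]))
        )


def _solve_cyclic_tridiagonal(dl, d, du, corner_lo, corner_up, rhs):
    """Solve a cyclic tridiagonal system via Sherman-Morrison.

    Matrix = tridiag(dl, d, du) + corner entries A[0, -1] = corner_up and
    A[-1, 0] = corner_lo.  rhs may have several columns.
    """
    n = len(d)
    gamma = -d[0]
    dd = d.copy()
    dd[0] -= gamma
    dd[-1] -= corner_up * corner_lo / gamma
    ab = np.zeros((3, n))
    ab[0, 1:] = du[:-1]
    ab[1] = dd
    ab[2, :-1] = dl[1:]
    y = solve_banded((1, 1), ab, rhs)
    u = np.zeros(n)
    u[0] = gamma
    u[-1] = corner_lo
    z = solve_banded((1, 1), ab, u)
    v = np.zeros(n)
    v[0] = 1.0
    v[-1] = corner_up / gamma
    frac = (v @ y) / (1.0 + v @ z)
    return y - np.outer(z, frac) if rhs.ndim > 1 else y - z * frac


def fit_periodic_spline(points) -> PeriodicCubicSpline:
    """Fit the closed C2 cubic reference line through ordered loop points.

    The three coordinate axes are fitted as independent periodic cubic
    splines over the cumulative-chord-length parameter.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 4:
        raise ParameterError("need an (n>=4, 3) array of loop points")
    closed = np.vstack([pts, pts[:1]])
    chords = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    if np.any(chords <= 1e-6):
        raise GeometryError("duplicate consecutive reference points")
    knots = np.concatenate([[0.0], np.cumsum(chords)])
    n = len(pts)
    l = chords  # l[k] = p(k+1) - p(k), k = 0..n-1

    # cyclic system over the n distinct knots (seam counted once)
    l_prev = np.roll(l, 1)  # l(k-1)
    diag = 2.0 * (l_prev + l)
    lower = l_prev.copy()   # multiplies g''(k-1)
    upper = l.copy()        # multiplies g''(k+1)
    g_next = np.roll(closed[:-1], -1, axis=0)
    g_prev = np.roll(closed[:-1], 1, axis=0)
    rhs = 6.0 * (
        (g_next - closed[:-1]) / l[:, None]
        - (closed[:-1] - g_prev) / l_prev[:, None]
    )
    d2 = _solve_cyclic_tridiagonal(
        lower, diag, upper, corner_lo=upper[-1], corner_up=lower[0], rhs=rhs
    )
    d2 = np.asarray(d2)
    second = np.vstack([d2, d2[:1]])
    return PeriodicCubicSpline(knots, closed, second)


@dataclass(frozen=True)
class MaskNodeSet:
    """Sampled rigid mask contact nodes (mm)."""

    nodes: np.ndarray
    section_index: np.ndarray
    design_id: str = "design-0"

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_sections(self) -> int:
        return int(self.section_index.max()) + 1 if len(self.section_index) else 0


def _rotation_minimizing_frames(points: np.ndarray, tangents: np.ndarray):
    """Double-reflection rotation-minimizing frames along a sampled curve."""
    t = tangents / np.linalg.norm(tangents, axis=1, keepdims=True)
    # initial normal: any vector orthogonal to t[0]
    seed = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(seed, t[0])) > 0.9:
        seed = np.array([1.0, 0.0, 0.0])
    r = seed - np.dot(seed, t[0]) * t[0]
    r /= np.linalg.norm(r)
    normals = np.empty_like(t)
    normals[0] = r
    for i in range(len(points) - 1):
        v1 = points[i + 1] - points[i]
        c1 = np.dot(v1, v1)
        rL = normals[i] - (2.0 / c1) * np.dot(v1, normals[i]) * v1
        tL = t[i] - (2.0 / c1) * np.dot(v1, t[i]) * v1
        v2 = t[i + 1] - tL
        c2 = np.dot(v2, v2)
        if c2 < 1e-30:
            normals[i + 1] = rL
        else:
            normals[i + 1] = rL - (2.0 / c2) * np.dot(v2, rL) * v2
        normals[i + 1] -= np.dot(normals[i + 1], t[i + 1]) * t[i + 1]
        normals[i + 1] /= np.linalg.norm(normals[i + 1])
    binormals = np.cross(t, normals)
    return normals, binormals


def sample_mask_nodes(design: MaskDesign) -> MaskNodeSet:
    """Sample the mask's contact nodes along the reference line.

    The number of cross-sections is round(L / spacing) (minimum 8) with
    section origins equally spaced in arc length; at each origin the profile
    offsets are mapped into the plane normal to the curve tangent using a
    rotation-minimizing frame.
    """
    spline = fit_periodic_spline(design.reference_points)
    piece_len = np.array(
        [spline.arc_length(a, b) for a, b in zip(spline.knots[:-1], spline.knots[1:])]
    )
    cum = np.concatenate([[0.0], np.cumsum(piece_len)])
    L = float(cum[-1])
    n_sections = max(8, int(round(L / design.spacing)))
    targets = L * np.arange(n_sections) / n_sections

    # invert s(p): fine per-piece speed grid anchored to the adaptive
    # quadrature piece lengths, then monotone interpolation
    m = 32
    frac = np.linspace(0.0, 1.0, m + 1)
    p_grid = (
        spline.knots[:-1, None] + frac[None, :] * np.diff(spline.knots)[:, None]
    )
    speeds = np.linalg.norm(
        spline.evaluate(p_grid.ravel(), order=1), axis=1
    ).reshape(p_grid.shape)
    seg = 0.5 * (speeds[:, 1:] + speeds[:, :-1]) * (
        np.diff(spline.knots)[:, None] / m
    )
    s_piece = np.cumsum(seg, axis=1)
    # rescale so each piece ends exactly at its quadrature length
    s_piece *= (piece_len / s_piece[:, -1])[:, None]
    s_grid = np.concatenate([[0.0], (cum[:-1, None] + s_piece).ravel()])
    p_flat = np.concatenate([[spline.knots[0]], p_grid[:, 1:].ravel()])
    params = np.interp(targets, s_grid, p_flat)

    origins = spline.evaluate(params)
    tangents = spline.evaluate(params, order=1)

    if design.profile.m == 1 and design.profile.offsets[0] == (0.0, 0.0):
        nodes = origins
        section = np.arange(n_sections)
    else:
        normals, binormals = _rotation_minimizing_frames(origins, tangents)
        offs = np.asarray(design.profile.offsets, dtype=float)
        nodes = (
            origins[:, None, :]
            + offs[None, :, 0, None] * normals[:, None, :]
            + offs[None, :, 1, None] * binormals[:, None, :]
        ).reshape(-1, 3)
        section = np.repeat(np.arange(n_sections), design.profile.m)
    return MaskNodeSet(nodes, section, design.design_id)


def adjust_reference_points(
    design: MaskDesign,
    point_indices: Sequence[int],
    axis: str = "X",
    offset: float = 0.0,
) -> MaskDesign:
    """Return a new design with the named reference points translated by
    ``offset`` mm along ``axis`` (X, Y or Z); the original is unmodified."""
    ax = {"X": 0, "Y": 1, "Z": 2}.get(str(axis).upper())
    if ax is None:
        raise ParameterError(f"axis must be X, Y or Z, got {axis!r}")
    pts = design.reference_points.copy()
    for i in point_indices:
        if not -len(pts) <= int(i) < len(pts):
            raise ParameterError(f"reference point index {i} out of range")
    pts[list(point_indices), ax] += float(offset)
    return replace(design, reference_points=pts)


def load_reference_points(path) -> np.ndarray:
    """Reference points from JSON ({"points": [[x,y,z],...], "closed": true})
    or CSV (x,y,z per row); loops are closed by construction."""
    import json
    from pathlib import Path

    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            data = json.load(fh)
        pts = np.asarray(data["points"] if isinstance(data, dict) else data, float)
    else:
        pts = np.loadtxt(path, delimiter=",", dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ParameterError(f"{path}: expected an (n, 3) point list")
    return pts


def save_reference_points(points: np.ndarray, path) -> None:
    import json

    with open(path, "w") as fh:
        json.dump(
            {"points": np.asarray(points, float).tolist(), "closed": True}, fh, indent=2
        )
        fh.write("\n")
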