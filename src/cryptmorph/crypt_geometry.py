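"""Crypt shape: energy functional, gradient-flow curve evolution, domain
length and derived crypt observables.

The crypt line is an open planar curve (x(s), y(s)) with both endpoints
pinned; the periodic cell coordinate identifies the two endpoints.  The
energy functional penalises deviation of the curve from a target profile in
which every crypt segment (a contiguous arc of elevated progenitor density)
digs a smooth tanh-shaped well whose depth is proportional to the segment's
peak progenitor density:

    E = integral ( y + A * sum_seg max(C0_seg) * (tanh((d_seg - |x - x*_seg|)/eps0) + 1)/2 - b )^2

with d_seg = (integral of C0 over the segment) / max(C0_seg) an effective
crypt diameter, x*_seg the horizontal position of the segment's density
peak, b the baseline offset and eps0 the shape sharpness.  The depth scale A
is the package's growing-domain closure: it is chosen so that the arclength
of the relaxed target curve equals the dynamic domain length driven by net
cell production, making geometric length and integrated production agree by
construction.  For a single crypt and A = 1 the functional reduces to the
plain tanh-well form.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .model_state import GeometryParams, Grid

__all__ = [
    "CryptCurve",
    "CryptSegment",
    "CryptSummary",
    "crypt_segments",
    "energy",
    "gradient_flow_step",
    "domain_length",
    "summarize_crypts",
    "flat_curve",
    "match_depth_scale",
    "relax_curve",
]


@dataclasses.dataclass
class CryptCurve:
    """Open planar curve over n+1 nodes; node j sits at xi = j/n.

    The endpoints (nodes 0 and n) stay pinned during the flow.  Field arrays
    of length n map onto nodes 0..n-1, with node n wrapping to field index 0.
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1 or self.x.size < 3:
            raise ValueError("curve needs matching 1-d x and y arrays of >= 3 nodes")

    @property
    def n_nodes(self) -> int:
        return self.x.size

    def copy(self) -> "CryptCurve":
        return CryptCurve(self.x.copy(), self.y.copy())

    def node_field(self, f: np.ndarray) -> np.ndarray:
        """Extend a periodic grid field (length n) to the n+1 curve nodes."""
        return np.concatenate([f, f[:1]])


def flat_curve(n_points: int, gp: GeometryParams) -> CryptCurve:
    """Straight segment between the pinned endpoints, n_points + 1 nodes."""
    t = np.linspace(0.0, 1.0, n_points + 1)
    ax, ay = gp.endpoint_a
    bx, by = gp.endpoint_b
    return CryptCurve(ax + (bx - ax) * t, ay + (by - ay) * t)


# ---------------------------------------------------------------------------
# crypt segmentation
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CryptSegment:
    """One contiguous periodic arc of supra-threshold progenitor density."""

    indices: np.ndarray  # grid indices in arc order (may wrap)
    argmax: int  # grid index of the density peak
    peak: float  # max C0 on the arc
    mass: float  # integral of C0 over the arc (s units)

    @property
    def diameter(self) -> float:
        """Effective crypt diameter d(C0) = mass / peak (length units)."""
        return self.mass / self.peak if self.peak > 0 else 0.0


def crypt_segments(C0: np.ndarray, grid: Grid, threshold: float) -> list[CryptSegment]:
    """Maximal contiguous arcs with C0 > threshold, merged across the seam.

    Arcs narrower than two grid cells are discarded.  An everywhere-supra-
    threshold field yields a single arc spanning the whole circle.
    """
    C0 = np.asarray(C0, dtype=float)
    n = C0.size
    above = C0 > threshold
    if not np.any(above):
        return []
    if np.all(above):
        idx = np.arange(n)
        return [_make_segment(C0, grid, idx)]
    # walk runs on the doubled array to merge across the periodic seam
    segments: list[np.ndarray] = []
    padded = np.concatenate([above, above])
    i = 0
    # start scanning at the first below-threshold point so no run is split
    start0 = int(np.argmin(above))
    i = start0
    end = start0 + n
    while i < end:
        if padded[i]:
            j = i
            while j < start0 + 2 * n and padded[j]:
                j += 1
            segments.append(np.arange(i, min(j, i + n)) % n)
            i = j
        else:
            i += 1
    segments = [s for s in segments if s.size >= 2]
    return [_make_segment(C0, grid, s) for s in segments]


def _make_segment(C0: np.ndarray, grid: Grid, idx: np.ndarray) -> CryptSegment:
    vals = C0[idx]
    k = int(np.argmax(vals))
    return CryptSegment(
        indices=idx,
        argmax=int(idx[k]),
        peak=float(vals[k]),
        mass=float(np.sum(vals) * grid.h),
    )


# ---------------------------------------------------------------------------
# energy functional and gradient flow
# ---------------------------------------------------------------------------


def _target_wells(
    x: np.ndarray,
    segments: list[CryptSegment],
    curve_x_of_grid: np.ndarray,
    gp: GeometryParams,
    width_scale: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Depth profile sum_seg peak*(tanh((d-|x-x*|)/eps0)+1)/2 and its x-derivative.

    ``width_scale`` maps the segment diameter d (measured along the tissue
    coordinate s) into curve-x units; the engine passes x-span / L so wells
    narrow as the tissue grows while the endpoint window stays fixed.
    """
    A = np.zeros_like(x)
    dA = np.zeros_like(x)
    for seg in segments:
        xc = curve_x_of_grid[seg.argmax]
        arg = (width_scale * seg.diameter - np.abs(x - xc)) / gp.epsilon0
        th = np.tanh(arg)
        A += seg.peak * (th + 1.0) / 2.0
        dA += seg.peak * (1.0 - th**2) / 2.0 * (-np.sign(x - xc) / gp.epsilon0)
    # taper to zero at the pinned endpoints: the crypt mouth flattens into
    # the fixed tissue edge, so the minimiser is exactly attainable there
    ax, bx = sorted((gp.endpoint_a[0], gp.endpoint_b[0]))
    delta = 2.0 * gp.epsilon0
    ta = np.tanh(np.clip((x - ax) / delta, 0.0, None))
    tb = np.tanh(np.clip((bx - x) / delta, 0.0, None))
    w = ta * tb
    dw = (1.0 - ta**2) / delta * tb - ta * (1.0 - tb**2) / delta
    dA = dA * w + A * dw
    A = A * w
    return A, dA


def _width_scale(gp: GeometryParams, grid: Optional[Grid]) -> float:
    if grid is None:
        return 1.0
    return abs(gp.endpoint_b[0] - gp.endpoint_a[0]) / grid.L


def energy(
    curve: CryptCurve,
    C0: np.ndarray,
    gp: GeometryParams,
    grid: Optional[Grid] = None,
    depth_scale: float = 1.0,
    segments: Optional[list[CryptSegment]] = None,
) -> tuple[float, np.ndarray]:
    """Total energy and pointwise integrand of the tanh-well functional.

    Evaluated per crypt segment (peak, peak position and diameter computed
    segment-wise) and summed; E >= 0 with equality exactly when the curve
    matches the target profile.  With no crypts the integrand reduces to
    (y - b)^2, minimised by the flat line y = b.
    """
    n = C0.size
    ws = _width_scale(gp, grid)
    if grid is None:
        grid = Grid(n, 1.0)
    if curve.n_nodes != n + 1:
        raise ValueError("curve and C0 must share the grid (n+1 nodes for n points)")
    if segments is None:
        thr = gp.segment_threshold_frac * C0.max() if C0.max() > 0 else np.inf
        segments = crypt_segments(C0, grid, thr) if np.isfinite(thr) else []
    xg = curve.x[:-1]  # curve x at grid points
    A, _ = _target_wells(curve.x, segments, xg, gp, ws)
    integrand = (curve.y + depth_scale * A - gp.baseline_b) ** 2
    # trapezoid in the node parameter (uniform xi spacing)
    w = np.full(n + 1, 1.0 / n)
    w[0] = w[-1] = 0.5 / n
    return float(np.sum(integrand * w)), integrand


def gradient_flow_step(
    curve: CryptCurve,
    C0: np.ndarray,
    C1: Optional[np.ndarray],
    gp: GeometryParams,
    dt: float,
    grid: Optional[Grid] = None,
    depth_scale: float = 1.0,
    segments: Optional[list[CryptSegment]] = None,
    max_backtracks: int = 30,
) -> CryptCurve:
    """One explicit descent step of the curve against the variational
    derivative of the energy; endpoints re-pinned, energy never increases
    (the step is backtracked on an increase).

    C1 is accepted for signature compatibility; the tanh-well energy depends
    on the cell pattern only through C0.
    """
    n = C0.size
    grid_arg = grid
    ws = _width_scale(gp, grid)
    if grid is None:
        grid = Grid(n, 1.0)
    if segments is None:
        thr = gp.segment_threshold_frac * C0.max() if C0.max() > 0 else np.inf
        segments = crypt_segments(C0, grid, thr) if np.isfinite(thr) else []
    xg = curve.x[:-1]
    E0, _ = energy(curve, C0, gp, grid_arg, depth_scale, segments)
    # explicit stability: the y-Hessian of the integrand is 2, the x-direction
    # is stiffer by ~(depth_scale * dA)^2; clamp the step and precondition x.
    # The x-direction of this energy is near-degenerate (it only reparametrises
    # the curve) and lets nodes drift off the endpoint window, so it is
    # immobile unless explicitly enabled.
    step = min(gp.flow_rate * dt, 0.45)
    A, dA = _target_wells(curve.x, segments, xg, gp, ws)
    precond_x = 1.0 + (depth_scale * dA) ** 2
    for _ in range(max_backtracks):
        mis = curve.y + depth_scale * A - gp.baseline_b
        gy = 2.0 * mis
        yn = curve.y - step * gy
        if gp.flow_in_x:
            gx = 2.0 * mis * depth_scale * dA / precond_x
            xn = curve.x - step * gx
        else:
            xn = curve.x.copy()
        xn[0], yn[0] = gp.endpoint_a
        xn[-1], yn[-1] = gp.endpoint_b
        cand = CryptCurve(xn, yn)
        E1, _ = energy(cand, C0, gp, grid_arg, depth_scale, segments)
        if E1 <= E0 * (1.0 + 1e-12) + 1e-300:
            return cand
        step *= 0.5
    raise RuntimeError("gradient-flow backtracking failed to decrease the energy")


def relax_curve(
    curve: CryptCurve,
    C0: np.ndarray,
    gp: GeometryParams,
    grid: Grid,
    depth_scale: float,
    dt: float,
    n_steps: int,
) -> CryptCurve:
    """Run several gradient-flow steps with frozen cells (quasi-static limit)."""
    thr = gp.segment_threshold_frac * C0.max() if C0.max() > 0 else np.inf
    segments = crypt_segments(C0, grid, thr) if np.isfinite(thr) else []
    for _ in range(n_steps):
        curve = gradient_flow_step(
            curve, C0, None, gp, dt, grid, depth_scale, segments=segments
        )
    return curve


# ---------------------------------------------------------------------------
# domain length
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(6)


def domain_length(curve: CryptCurve) -> float:
    """Arclength of the curve between the pinned endpoints.

    Cubic-spline parameterisation with per-interval Gauss-Legendre
    quadrature of sqrt(x'^2 + y'^2); never below the straight-line distance
    between the endpoints.
    """
    n = curve.n_nodes
    t = np.linspace(0.0, 1.0, n)
    sx = CubicSpline(t, curve.x)
    sy = CubicSpline(t, curve.y)
    dxs = sx.derivative()
    dys = sy.derivative()
    h = t[1] - t[0]
    mid = (t[:-1] + t[1:]) / 2.0
    pts = mid[:, None] + (h / 2.0) * _GL_NODES[None, :]
    speed = np.sqrt(dxs(pts) ** 2 + dys(pts) ** 2)
    return float(np.sum(speed @ _GL_WEIGHTS) * h / 2.0)


def _target_curve_length(
    segments: list[CryptSegment],
    curve_x_of_grid: np.ndarray,
    gp: GeometryParams,
    depth_scale: float,
    width_scale: float = 1.0,
    n_fine: int = 2000,
) -> float:
    """Arclength of the ideal relaxed curve y = b - A*wells(x) with x uniform."""
    ax, bx = gp.endpoint_a[0], gp.endpoint_b[0]
    x = np.linspace(min(ax, bx), max(ax, bx), n_fine)
    _, dA = _target_wells(x, segments, curve_x_of_grid, gp, width_scale)
    dy = -depth_scale * dA
    return float(np.trapezoid(np.sqrt(1.0 + dy**2), x))


def match_depth_scale(
    segments: list[CryptSegment],
    curve_x_of_grid: np.ndarray,
    gp: GeometryParams,
    L_target: float,
    width_scale: float = 1.0,
) -> float:
    """Depth scale A such that the relaxed target curve has arclength L_target.

    This is the growing-domain closure: the tissue's geometric length is the
    length produced by net cell proliferation, distributed into crypt wells
    in proportion to local progenitor density.  Returns 0 when there are no
    crypts or when L_target does not exceed the flat endpoint distance.
    """
    flat = abs(gp.endpoint_b[0] - gp.endpoint_a[0])
    if not segments or L_target <= flat * (1.0 + 1e-12):
        return 0.0

    def f(A: float) -> float:
        return _target_curve_length(segments, curve_x_of_grid, gp, A, width_scale) - L_target

    hi = 1.0
    while f(hi) < 0 and hi < 1e9:
        hi *= 2.0
    if f(hi) < 0:
        raise RuntimeError("could not bracket the depth scale")
    return float(brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-10))


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CryptSummary:
    """Derived crypt observables: count, per-crypt depth and tip statistics."""

    count: int
    heights: np.ndarray  # depth below the baseline per crypt
    tip_positions: np.ndarray  # s-location of each progenitor peak
    tip_densities: np.ndarray  # C0 at each peak

    def __post_init__(self) -> None:
        if not (self.count == len(self.heights) == len(self.tip_positions) == len(self.tip_densities)):
            raise ValueError("inconsistent crypt summary")


def summarize_crypts(
    curve: CryptCurve,
    C0: np.ndarray,
    grid: Grid,
    gp: GeometryParams,
    threshold: Optional[float] = None,
) -> CryptSummary:
    """Count crypts and measure their depths and tip densities.

    The default threshold is ``segment_threshold_frac`` times the global
    maximum of C0; height is the baseline offset minus the minimum curve y
    over the segment's nodes (>= 0 on a relaxed curve).
    """
    c0max = float(np.max(C0)) if C0.size else 0.0
    if threshold is None:
        threshold = gp.segment_threshold_frac * c0max
    if c0max <= 0 or c0max <= threshold:
        return CryptSummary(0, np.array([]), np.array([]), np.array([]))
    segments = crypt_segments(C0, grid, threshold)
    heights = []
    tips = []
    dens = []
    for seg in segments:
        ymin = float(np.min(curve.y[seg.indices]))
        heights.append(max(gp.baseline_b - ymin, 0.0))
        tips.append(float(grid.s[seg.argmax]))
        dens.append(seg.peak)
    return CryptSummary(len(segments), np.array(heights), np.array(tips), np.array(dens))
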