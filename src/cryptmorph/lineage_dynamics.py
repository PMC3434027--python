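"""Cell-lineage dynamics: replication probability, TD death rate, the
velocity closure, the progenitor transport-reaction right-hand side, and
ablation interventions.

Only the progenitor density C0 is evolved; C1 is defined as 1 - C0, which the
velocity closure makes algebraically consistent with the TD equation.  The
closure dV/ds = v0*C0 - d1*C1 is split into a zero-mean periodic velocity
(the fluctuating part) plus a uniform dilation absorbed into domain growth:
the domain-mean of the source is returned separately as the net growth rate
that drives dL/dt.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .fourier import apply_filter, exponential_filter, periodic_antiderivative, spectral_derivative
from .model_state import Grid, LineageParams, LineageState, MorphogenState

__all__ = [
    "ReplicationField",
    "replication_probability",
    "death_rate_field",
    "compute_velocity",
    "lineage_rhs",
    "ablate_progenitors",
]


@dataclasses.dataclass
class ReplicationField:
    """Replication probability per grid point, in [0, p0_max]."""

    p0: np.ndarray


def replication_probability(m: MorphogenState, lp: LineageParams) -> ReplicationField:
    """Hill response of progenitor self-renewal to Wnt (up) and BMP (down):

        p0 = p0_max * (gW*W)^n / (1 + (gW*W)^n + (gB*B)^m)

    p0 vanishes where Wnt vanishes, increases with Wnt and decreases with BMP.
    """
    if np.any(m.wnt < 0) or np.any(m.bmp < 0):
        raise ValueError("concentrations must be nonnegative")
    uW = np.where(m.wnt > 0, (lp.gamma_W * m.wnt) ** lp.n, 0.0)
    uB = np.where(m.bmp > 0, (lp.gamma_B * m.bmp) ** lp.m, 0.0)
    return ReplicationField(p0=lp.p0_max * uW / (1.0 + uW + uB))


def death_rate_field(grid: Grid, cells: LineageState, lp: LineageParams) -> np.ndarray:
    """Spatial TD-cell removal rate d1(s), bounded by (0, d1_max].

    "constant" returns d1_max everywhere.  "apex_localized" concentrates
    removal at the crypt tops -- the point(s) farthest along the periodic
    axis from progenitor maxima -- as a smooth raised-cosine bump over a
    floor of d1_floor_frac * d1_max, emulating shedding at the luminal
    surface.
    """
    n = grid.n_points
    if lp.d1_profile == "constant":
        return np.full(n, lp.d1_max)
    if lp.d1_profile == "apex_localized":
        floor = lp.d1_floor_frac * lp.d1_max
        c0max = cells.C0.max()
        if c0max <= 0:
            return np.full(n, lp.d1_max)
        # smooth "distance from progenitor peaks" weight: low where C0 is
        # high, maximal at the antipode of the dominant peak structure
        w = 1.0 - cells.C0 / c0max
        # emphasise the farthest points with a smooth power, renormalized
        w = w**2
        wmax = w.max()
        prof = floor + (lp.d1_max - floor) * (w / wmax if wmax > 0 else w)
        return prof
    raise ValueError(f"unknown d1 profile {lp.d1_profile!r}")


def compute_velocity(
    cells: LineageState,
    d1: np.ndarray,
    lp: LineageParams,
    grid: Grid,
    norm_tol: float = 1e-8,
) -> tuple[np.ndarray, float]:
    """Velocity closure dV/ds = v0*C0 - d1*C1 on the periodic domain.

    Returns (V, net_growth_rate):  V is the zero-mean periodic antiderivative
    of the fluctuating part of the source; net_growth_rate is the full
    domain integral of the source, i.e. dL/dt of the growing domain.
    """
    if np.max(np.abs(cells.C0 + cells.C1 - 1.0)) > norm_tol:
        raise ValueError("C0 + C1 = 1 violated beyond tolerance in compute_velocity")
    source = lp.v0 * cells.C0 - d1 * cells.C1
    V = periodic_antiderivative(source, grid.L)
    net_growth_rate = float(np.mean(source) * grid.L)
    return V, net_growth_rate


def lineage_rhs(
    cells: LineageState,
    p0: ReplicationField,
    d1: np.ndarray,
    V: np.ndarray,
    lp: LineageParams,
    grid: Grid,
    filter_mask: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Transport-reaction right-hand side for the progenitor density:

        dC0/dt = v0 (2 p0 - 1) C0 - d(V C0)/ds + motility * d2C0/ds2

    The growing-domain dilution term -(Ldot/L) C0 is added by the engine,
    which owns the length dynamics.  The advective flux derivative is
    evaluated spectrally with a high-order exponential filter on the top
    third of modes to control aliasing; the small random-migration term
    keeps the compressive crypt-boundary fronts at a finite width.
    """
    flux_deriv = spectral_derivative(V * cells.C0, 1, grid.L)
    if filter_mask is not None:
        flux_deriv = apply_filter(flux_deriv, filter_mask)
    out = lp.v0 * (2.0 * p0.p0 - 1.0) * cells.C0 - flux_deriv
    if lp.cell_motility > 0:
        out = out + lp.cell_motility * spectral_derivative(cells.C0, 2, grid.L)
    return out


def ablate_progenitors(
    cells: LineageState,
    region: tuple[float, float] | np.ndarray,
    fraction: float,
) -> LineageState:
    """Replace a fraction of progenitors by TD cells inside a periodic arc.

    ``region`` is either a boolean mask over the grid or an (start_frac,
    end_frac) arc in computational-coordinate fractions (wrapped if start >
    end).  Inside the region C0 <- (1 - fraction) * C0 and C1 <- 1 - C0, so
    the total cell density stays exactly 1 everywhere.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("ablation fraction must lie in [0, 1]")
    n = cells.C0.size
    if isinstance(region, np.ndarray) and region.dtype == bool:
        mask = region
    else:
        start, end = region
        xi = np.arange(n) / n
        if start <= end:
            mask = (xi >= start) & (xi < end)
        else:  # wraps the periodic seam
            mask = (xi >= start) | (xi < end)
    if not np.any(mask):
        raise ValueError("empty ablation region")
    C0 = cells.C0.copy()
    C0[mask] *= 1.0 - fraction
    return LineageState.from_progenitor(C0, V=cells.V.copy())


def default_filter_mask(n: int, cutoff: float = 2.0 / 3.0) -> np.ndarray:
    """Convenience: the engine's documented aliasing filter for this grid."""
    return exponential_filter(n, cutoff=cutoff)
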