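"""Fourier-spectral discretization and the master time loop.

Fast/slow coupling: at every evaluation of the cell right-hand side the
molecular fields are replaced by their quasi-steady state (the fast clock),
then the replication probability, death rate and velocity closure give the
progenitor transport-reaction rate (the slow clock).  The domain grows with
net cell production, dL/dt = integral(v0*C0 - d1*C1) ds, and a uniform
dilution -(Ldot/L)*C0 accounts for the stretch of the fixed computational
coordinate.  Cells and length form a closed ODE system in (C0, L) once the
molecules are eliminated; it is advanced with Heun's method (the aliasing
filter lives inside the advective term, so the vector field itself is what
any reference integrator sees).  The embedded crypt curve is a quasi-static
readout relaxed by gradient flow with its depth scale matched to L.

The low-level periodic primitives (spectral_derivative & co.) are defined in
:mod:`cryptmorph.fourier` and re-exported here.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import deque
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .crypt_geometry import (
    CryptCurve,
    crypt_segments,
    domain_length,
    energy,
    flat_curve,
    gradient_flow_step,
    match_depth_scale,
    summarize_crypts,
)
from .fourier import (  # noqa: F401  (re-exported spectral primitives)
    apply_filter,
    exponential_filter,
    helmholtz_solve,
    periodic_antiderivative,
    spectral_derivative,
    wavenumbers,
)
from .lineage_dynamics import (
    compute_velocity,
    death_rate_field,
    lineage_rhs,
    replication_probability,
)
from .model_state import (
    Config,
    ExogenousWntSource,
    Grid,
    LineageState,
    MorphogenState,
)
from .morphogen_dynamics import solve_quasi_steady

__all__ = [
    "CryptSimulator",
    "RunResult",
    "remap_fields",
    "spectral_derivative",
    "periodic_antiderivative",
    "exponential_filter",
    "apply_filter",
]


def remap_fields(fields: dict[str, np.ndarray], L_old: float, L_new: float) -> dict[str, np.ndarray]:
    """Carry fields from length L_old to L_new on the fixed xi grid.

    Lagrangian-in-xi convention: point values are unchanged, only the metric
    updates, so any density integral over the domain changes exactly by the
    factor L_new / L_old.  The dilution term in the time step accounts for
    the corresponding density effect.
    """
    if L_old <= 0 or L_new <= 0:
        raise ValueError("lengths must be positive")
    return {k: np.asarray(v, dtype=float).copy() for k, v in fields.items()}


@dataclasses.dataclass
class RunResult:
    """Outcome of a simulation run."""

    timeseries: pd.DataFrame
    steady_time: Optional[float]
    t_end: float
    final_grid: Grid
    final_cells: LineageState
    final_morphogens: MorphogenState
    final_curve: CryptCurve
    depth_scale: float


class EngineError(RuntimeError):
    """Time loop aborted (NaN state or solver failure); carries diagnostics."""

    def __init__(self, message: str, t: float):
        super().__init__(f"{message} at t = {t:.4f}")
        self.t = t


class CryptSimulator:
    """Coupled cells + molecules + geometry integrator.

    Parameters
    ----------
    cfg : Config
        Full parameter set; `cfg.numerics` controls grid, step and tolerances.
    cells, morphogens : initial fields on the grid.
    grid : optional grid override (e.g. restart at a grown length).
    curve : optional initial curve; defaults to the flat pinned segment.
    source : optional exogenous Wnt source window.
    freeze_length : keep L fixed (no growth, no dilution) -- fixed-domain mode.
    freeze_geometry : skip the curve flow (cells do not feed back on it).
    clamp_morphogens : bypass the QSS solve and hold the given molecular
        state fixed (testing hook for controlled replication fields).
    """

    def __init__(
        self,
        cfg: Config,
        cells: LineageState,
        morphogens: MorphogenState,
        grid: Optional[Grid] = None,
        curve: Optional[CryptCurve] = None,
        source: Optional[ExogenousWntSource] = None,
        t0: float = 0.0,
        freeze_length: bool = False,
        freeze_geometry: bool = False,
        clamp_morphogens: Optional[MorphogenState] = None,
        geometry_every: int = 20,
        geometry_substeps: int = 4,
    ):
        self.cfg = cfg
        num = cfg.numerics
        self.grid = grid if grid is not None else Grid(num.n_points, num.L0)
        if cells.C0.size != self.grid.n_points:
            raise ValueError("initial cells do not match the grid")
        self.cells = cells.copy()
        self.morph = morphogens.copy()
        self.curve = curve.copy() if curve is not None else flat_curve(self.grid.n_points, cfg.geometry)
        self.source = source if source is not None else cfg.source
        self.t = t0
        self.freeze_length = freeze_length
        self.freeze_geometry = freeze_geometry
        self.clamp = clamp_morphogens
        self.geometry_every = geometry_every
        self.geometry_substeps = geometry_substeps
        self.depth_scale = 1.0
        self._filter = exponential_filter(self.grid.n_points, cutoff=num.filter_cutoff)
        self._qss_warm = self.morph.copy()
        self._step_count = 0
        self._last_growth = 0.0
        self._last_shedding = 0.0
        self._t_start = t0
        self._L0 = self.grid.L

    # -- right-hand side of the reduced (C0, L) system ----------------------

    def _solve_molecules(self, cells: LineageState, L: float, V: Optional[np.ndarray] = None) -> MorphogenState:
        if self.clamp is not None:
            return self.clamp
        grid = self.grid.with_length(L)
        out = solve_quasi_steady(
            cells, self.cfg.morphogen, grid, self._qss_warm, self.cfg.numerics, src=self.source, V=V
        )
        self._qss_warm = out  # warm start for the next call
        return out

    def rhs(self, C0: np.ndarray, L: float) -> tuple[np.ndarray, float]:
        """(dC0/dt, dL/dt) at the given state; molecules at quasi-steady state.

        The domain grows with net cell production but cannot outrun the
        crypt geometry: dL/dt = min(P, rho * (L_cap - L)) with P the
        production integral and L_cap the arclength of the fully relaxed
        energy-minimising curve.  Production in excess of the geometric
        capacity is shed (uniform extrusion into the lumen).  Shedding
        removes both cell types in proportion, so the C0 composition
        equation keeps the full -(P/L) C0 damping (dilution + shedding)
        regardless of how much of P becomes length.
        """
        cells = LineageState.from_progenitor(np.clip(C0, 0.0, 1.0))
        grid = self.grid.with_length(L)
        morph = self._solve_molecules(cells, L)
        p0 = replication_probability(morph, self.cfg.lineage)
        d1 = death_rate_field(grid, cells, self.cfg.lineage)
        V, growth = compute_velocity(cells, d1, self.cfg.lineage, grid)
        dC0 = lineage_rhs(cells, p0, d1, V, self.cfg.lineage, grid, filter_mask=self._filter)
        # dilution + proportional shedding always damp the composition by the
        # full specific production P/L; how much of P becomes length is a
        # separate question (geometric capacity, or none on a frozen domain)
        dC0 = dC0 - (growth / L) * C0
        if self.freeze_length:
            growth_eff = 0.0
        else:
            growth_eff = growth
            if growth > 0:
                cap = self._length_capacity(cells.C0, grid)
                growth_eff = min(growth, self.cfg.geometry.cap_rate * max(cap - L, 0.0))
        self._last_V = V
        self._last_growth = growth
        self._last_shedding = growth - growth_eff
        self._last_morph = morph
        self._last_p0 = p0
        return dC0, growth_eff

    def _length_capacity(self, C0: np.ndarray, grid: Grid) -> float:
        """Arclength of the relaxed unit-depth-scale curve for the current pattern."""
        from .crypt_geometry import _target_curve_length

        gp = self.cfg.geometry
        c0max = float(C0.max())
        if c0max <= 0:
            return abs(gp.endpoint_b[0] - gp.endpoint_a[0])
        C0r = np.roll(C0, -getattr(self, "_geom_roll", 0))
        segments = crypt_segments(C0r, grid, gp.segment_threshold_frac * c0max)
        ws = abs(gp.endpoint_b[0] - gp.endpoint_a[0]) / grid.L
        return _target_curve_length(segments, self.curve.x[:-1], gp, gp.depth_gain, ws, n_fine=800)

    # -- time stepping -------------------------------------------------------

    def step(self, dt: Optional[float] = None) -> None:
        """One Heun (RK2) step of (C0, L), then the quasi-static geometry update."""
        num = self.cfg.numerics
        dt = num.dt if dt is None else dt
        C0 = self.cells.C0
        L = self.grid.L

        k1, g1 = self.rhs(C0, L)
        C0p = C0 + dt * k1
        Lp = L + dt * g1
        k2, g2 = self.rhs(np.clip(C0p, 0.0, 1.0), Lp)
        C0n = C0 + 0.5 * dt * (k1 + k2)
        Ln = L + 0.5 * dt * (g1 + g2)

        if not np.all(np.isfinite(C0n)) or not np.isfinite(Ln):
            raise EngineError("non-finite state detected", self.t)
        lo = float(C0n.min())
        in_grace = self.t - self._t_start < num.positivity_grace
        if lo < -num.positivity_tol and not in_grace:
            raise EngineError(f"progenitor density positivity violated (min {lo:.2e})", self.t)
        np.clip(C0n, 0.0, 1.0, out=C0n)

        cfl = float(np.max(np.abs(self._last_V)) * dt / self.grid.with_length(Ln).h)
        if cfl > 1.0:
            warnings.warn(f"CFL number |V| dt / h = {cfl:.2f} > 1 at t = {self.t:.3f}", RuntimeWarning)

        self._steady_rate = float(np.max(np.abs(C0n - C0)) / dt)
        self.cells = LineageState.from_progenitor(C0n, V=self._last_V)
        self.grid = self.grid.with_length(Ln)
        self.morph = self._last_morph if self.clamp is None else self.clamp
        self.t += dt
        self._step_count += 1

        if not self.freeze_geometry and self._step_count % self.geometry_every == 0:
            self.update_geometry(dt * self.geometry_every)

    def _curve_frame_C0(self) -> np.ndarray:
        """Progenitor field in the curve frame.

        The curve is an open line with pinned endpoints, the cells are
        periodic: the seam (where the periodic coordinate is cut) is placed
        at the progenitor minimum so the endpoints never bisect a crypt.
        """
        C0 = self.cells.C0
        kernel = np.ones(5) / 5.0
        smooth = np.convolve(np.concatenate([C0[-2:], C0, C0[:2]]), kernel, mode="valid")
        self._geom_roll = int(np.argmin(smooth))
        return np.roll(C0, -self._geom_roll)

    def update_geometry(self, dt_geom: float) -> None:
        """Match the depth scale to the current length and relax the curve."""
        gp = self.cfg.geometry
        C0 = self._curve_frame_C0()
        c0max = float(C0.max())
        thr = gp.segment_threshold_frac * c0max if c0max > 0 else np.inf
        segments = crypt_segments(C0, self.grid, thr) if np.isfinite(thr) else []
        ws = abs(gp.endpoint_b[0] - gp.endpoint_a[0]) / self.grid.L
        if self.freeze_length:
            # no length budget on a frozen domain: render the wells at the
            # prescribed depth per unit peak density
            self.depth_scale = gp.depth_gain
        else:
            self.depth_scale = match_depth_scale(segments, self.curve.x[:-1], gp, self.grid.L, ws)
        sub = dt_geom / self.geometry_substeps
        for _ in range(self.geometry_substeps):
            self.curve = gradient_flow_step(
                self.curve, C0, None, gp, sub, self.grid, self.depth_scale, segments=segments
            )

    # -- main loop -----------------------------------------------------------

    def run(
        self,
        t_end: Optional[float] = None,
        stop_at_steady: bool = True,
        record_every: Optional[float] = None,
        callback: Optional[Callable[["CryptSimulator"], None]] = None,
    ) -> RunResult:
        """Advance to ``t_end`` (default from config), recording a time series.

        Steady state is declared when the max-norm rate of change of C0 per
        unit time stays below ``steady_tol`` over a sliding window of
        ``steady_window`` time units; the detection time is reported, and the
        loop stops there if ``stop_at_steady``.
        """
        num = self.cfg.numerics
        t_end = num.t_end if t_end is None else t_end
        record_every = num.snapshot_every if record_every is None else record_every
        rows = []
        window: deque[tuple[float, float]] = deque()
        steady_time: Optional[float] = None
        next_record = self.t

        def record() -> None:
            rows.append(self._observables())

        while self.t < t_end - 1e-12:
            if self.t >= next_record - 1e-12:
                record()
                next_record += record_every
                if callback is not None:
                    callback(self)
            self.step(min(num.dt, t_end - self.t))
            window.append((self.t, self._steady_rate))
            while window and window[0][0] < self.t - num.steady_window:
                window.popleft()
            spans = window[-1][0] - window[0][0] >= num.steady_window * 0.999
            if steady_time is None and spans and max(r for _, r in window) < num.steady_tol:
                steady_time = self.t
                if stop_at_steady:
                    break
            if float(self.cells.C0.max()) < num.extinction_floor:
                break  # extinct: nothing left to evolve
            if not self.freeze_length and self.grid.L < 0.5 * self._L0:
                break  # tissue involuted: the crypt line has collapsed
        if not self.freeze_geometry:
            self.update_geometry(num.dt * self.geometry_every)
        record()
        ts = pd.DataFrame(rows)
        return RunResult(
            timeseries=ts,
            steady_time=steady_time,
            t_end=self.t,
            final_grid=self.grid,
            final_cells=self.cells,
            final_morphogens=self.morph,
            final_curve=self.curve,
            depth_scale=self.depth_scale,
        )

    def _observables(self) -> dict:
        grid = self.grid
        C0 = np.roll(self.cells.C0, -getattr(self, "_geom_roll", 0))
        summary = summarize_crypts(self.curve, C0, grid, self.cfg.geometry)
        E, _ = energy(self.curve, C0, self.cfg.geometry, grid, self.depth_scale)
        return {
            "t": self.t,
            "L": grid.L,
            "L_geo": domain_length(self.curve),
            "max_C0": float(C0.max()),
            "mass_C0": float(C0.sum() * grid.h),
            "crypt_count": summary.count,
            "tip_densities": tuple(np.round(summary.tip_densities, 6)),
            "net_growth_rate": self._last_growth,
            "energy": E,
            "depth_scale": self.depth_scale,
        }
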