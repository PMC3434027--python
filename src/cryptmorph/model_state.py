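"""Domain types, configuration schema and seeded initial conditions.

The model couples a two-stage cell lineage (progenitor density C0, terminally
differentiated density C1 = 1 - C0, cell velocity V) to three secreted
morphogens (Wnt, a diffusible Wnt inhibitor, and BMP) on a periodic,
growing one-dimensional tissue.  Everything downstream consumes the types
defined here.

Units convention
----------------
Cell time is measured in units of (cell cycle length / ln 2), i.e. the
progenitor turnover rate ``v0`` defaults to 1.  Molecular rate constants are
quoted per second as in the source literature; the quasi-steady-state
treatment of the molecules makes only the ratios D/d (squared diffusion
lengths) and the production/removal ratios dynamically relevant, so the two
clocks never need to be reconciled.  Concentrations are in uM, lengths in
the dimensionless tissue unit of the crypt axis (initial domain 0.2).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

__all__ = [
    "Grid",
    "LineageState",
    "MorphogenState",
    "LineageParams",
    "MorphogenParams",
    "GeometryParams",
    "ExogenousWntSource",
    "NumericsParams",
    "ScenarioSpec",
    "Config",
    "load_config",
    "dump_config",
    "apply_overrides",
    "make_initial_state",
    "save_snapshot",
    "load_snapshot",
]

NORM_TOL = 1e-10  # pointwise tolerance on C0 + C1 = 1


# ---------------------------------------------------------------------------
# grid and field containers
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class Grid:
    """Uniform periodic collocation grid on the crypt axis.

    ``xi`` is the fixed computational coordinate in [0, 1); the physical
    arclength-like coordinate is s = xi * L with current domain length L.
    """

    n_points: int
    L: float

    def __post_init__(self) -> None:
        if self.n_points < 8 or self.n_points % 2 != 0:
            raise ValueError("n_points must be even and >= 8")
        if not self.L > 0:
            raise ValueError("domain length must be positive")

    @property
    def xi(self) -> np.ndarray:
        return np.arange(self.n_points) / self.n_points

    @property
    def s(self) -> np.ndarray:
        return self.xi * self.L

    @property
    def h(self) -> float:
        """Physical grid spacing L / n."""
        return self.L / self.n_points

    def with_length(self, L: float) -> "Grid":
        return Grid(self.n_points, L)


@dataclasses.dataclass
class LineageState:
    """Cell half of the model: progenitor density C0, TD density C1, velocity V.

    C1 is stored for convenience but is always 1 - C0 by construction; the
    constructor enforces the normalization.
    """

    C0: np.ndarray
    C1: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        self.C0 = np.asarray(self.C0, dtype=float)
        self.C1 = np.asarray(self.C1, dtype=float)
        self.V = np.asarray(self.V, dtype=float)
        if not (self.C0.shape == self.C1.shape == self.V.shape):
            raise ValueError("C0, C1, V must share the grid length")
        if np.max(np.abs(self.C0 + self.C1 - 1.0)) > NORM_TOL:
            raise ValueError("C0 + C1 = 1 violated beyond tolerance")

    @classmethod
    def from_progenitor(cls, C0: np.ndarray, V: Optional[np.ndarray] = None) -> "LineageState":
        C0 = np.asarray(C0, dtype=float)
        if V is None:
            V = np.zeros_like(C0)
        return cls(C0=C0, C1=1.0 - C0, V=V)

    def copy(self) -> "LineageState":
        return LineageState(self.C0.copy(), self.C1.copy(), self.V.copy())


@dataclasses.dataclass
class MorphogenState:
    """Signaling half of the model: Wnt, Wnt-inhibitor and BMP concentrations (uM)."""

    wnt: np.ndarray
    inhibitor: np.ndarray
    bmp: np.ndarray

    def __post_init__(self) -> None:
        self.wnt = np.asarray(self.wnt, dtype=float)
        self.inhibitor = np.asarray(self.inhibitor, dtype=float)
        self.bmp = np.asarray(self.bmp, dtype=float)
        if not (self.wnt.shape == self.inhibitor.shape == self.bmp.shape):
            raise ValueError("morphogen arrays must share the grid length")

    @classmethod
    def zeros(cls, n: int) -> "MorphogenState":
        return cls(np.zeros(n), np.zeros(n), np.zeros(n))

    def copy(self) -> "MorphogenState":
        return MorphogenState(self.wnt.copy(), self.inhibitor.copy(), self.bmp.copy())

    def check_nonnegative(self, clip_tol: float = 1e-12) -> "MorphogenState":
        """Clip tiny numerical negatives; raise on anything larger."""
        for name in ("wnt", "inhibitor", "bmp"):
            arr = getattr(self, name)
            lo = arr.min() if arr.size else 0.0
            if lo < -clip_tol:
                raise ValueError(f"negative {name} concentration: min = {lo:.3e}")
            np.clip(arr, 0.0, None, out=arr)
        return self


# ---------------------------------------------------------------------------
# parameter schema (pydantic -- validated, serializable)
# ---------------------------------------------------------------------------


class _Params(BaseModel):
    model_config = ConfigDict(validate_assignment=True, extra="forbid")


class LineageParams(_Params):
    """Cell-lineage rates and the Hill response of the replication probability.

    p0 = p0_max * (gamma_W * Wnt)^n / (1 + (gamma_W * Wnt)^n + (gamma_B * BMP)^m)

    gamma_W and gamma_B are reciprocal EC50s (1/uM): larger values mean the
    cells respond to lower concentrations, i.e. stronger feedback.
    """

    v0: float = Field(1.0, gt=0, description="progenitor turnover rate, 1/(cell cycle/ln2)")
    p0_max: float = Field(1.0, gt=0, le=1, description="maximal replication probability")
    gamma_W: float = Field(4.0, gt=0, description="reciprocal EC50 of Wnt on replication (1/uM)")
    gamma_B: float = Field(5.0, gt=0, description="reciprocal EC50 of BMP on replication (1/uM)")
    n: float = Field(2.0, gt=0, description="Hill exponent for Wnt")
    m: float = Field(2.0, gt=0, description="Hill exponent for BMP")
    d1_max: float = Field(0.35, gt=0, description="maximal TD-cell removal rate (cell time unit)")
    d1_profile: Literal["constant", "apex_localized"] = "apex_localized"
    d1_floor_frac: float = Field(0.1, gt=0, le=1, description="floor of spatial d1 as fraction of d1_max")
    cell_motility: float = Field(5.0e-6, ge=0, description="random cell migration coefficient (length^2/cell time); regularises advective fronts")


class MorphogenParams(_Params):
    """Diffusion, production and removal constants of the three morphogens.

    The Wnt/inhibitor pair is the Turing pair: Wnt self-activates through a
    saturating Hill term and drives its own long-range inhibitor.  BMP is a
    linear relaxation sourced by TD cells.  Molecular rates are per second;
    diffusion coefficients in tissue-length^2 per second.
    """

    D_W: float = Field(1.6e-7, gt=0, description="Wnt diffusion coefficient")
    D_I: float = Field(9.6e-6, gt=0, description="inhibitor diffusion coefficient")
    D_B: float = Field(1.26e-6, gt=0, description="BMP diffusion coefficient")
    mu0: float = Field(1.2e-4, gt=0, description="Wnt production per unit progenitor density (uM/s)")
    mu1: float = Field(2.5e-4, gt=0, description="BMP production per unit TD density (uM/s)")
    alpha_W: float = Field(0.114, gt=0, description="self-enhanced Wnt activation rate (uM/s)")
    alpha_I: float = Field(1.2e-2, gt=0, description="inhibitor synthesis rate (uM/s)")
    beta_W: float = Field(1.0, gt=0, description="reciprocal EC50 of Wnt autoactivation (1/uM)")
    beta_I: float = Field(16.0, gt=0, description="reciprocal EC50 of inhibitor on Wnt (1/uM)")
    beta_W_inh: float = Field(1.0, gt=0, description="reciprocal EC50 of Wnt on inhibitor synthesis (1/uM)")
    n_W: float = Field(2.0, gt=0, description="Hill coefficient, Wnt autoactivation")
    m_W: float = Field(2.0, gt=0, description="Hill coefficient, inhibitor repression of Wnt")
    n_I: float = Field(2.0, gt=0, description="Hill coefficient, Wnt activation of inhibitor")
    d_W: float = Field(2.0e-3, gt=0, description="Wnt removal rate (1/s)")
    d_I: float = Field(4.0e-3, gt=0, description="inhibitor removal rate (1/s)")
    d_B: float = Field(1.4e-3, gt=0, description="BMP removal rate (1/s)")

    @property
    def removal_ratio(self) -> float:
        """d_I / d_W, the inhibitor-adaptation speed ratio of the stability analysis."""
        return self.d_I / self.d_W

    @property
    def diffusion_ratio(self) -> float:
        """D_I / D_W, the range ratio of the Turing pair."""
        return self.D_I / self.D_W


class GeometryParams(_Params):
    """Energy-functional and gradient-flow settings for the embedded crypt curve."""

    epsilon0: float = Field(0.01, gt=0, description="sharpness of the crypt shape (length)")
    baseline_b: float = Field(0.0, description="baseline offset of the crypt mouth line")
    endpoint_a: tuple[float, float] = Field((-0.1, 0.0), description="fixed left endpoint")
    endpoint_b: tuple[float, float] = Field((0.1, 0.0), description="fixed right endpoint")
    flow_rate: float = Field(50.0, gt=0, description="gradient-flow relaxation coefficient (1/cell time)")
    flow_in_x: bool = Field(False, description="also flow the x-coordinate (off: y-graph flow, x pinned)")
    cap_rate: float = Field(2.0, gt=0, description="rate at which L tracks the geometric capacity (1/cell time)")
    depth_gain: float = Field(0.15, gt=0, description="crypt depth per unit peak progenitor density")
    energy_kind: Literal["tanh_wells"] = "tanh_wells"
    segment_threshold_frac: float = Field(0.1, gt=0, lt=1, description="crypt-segmentation threshold as fraction of max C0")

    @model_validator(mode="after")
    def _endpoints_distinct(self) -> "GeometryParams":
        if tuple(self.endpoint_a) == tuple(self.endpoint_b):
            raise ValueError("endpoints must be distinct")
        return self


class ExogenousWntSource(_Params):
    """Constant-rate Wnt source over a periodic window [p - w/2, p + w/2] (fractions of L)."""

    position_p: float = Field(0.75, ge=0, lt=1, description="window centre as fraction of L")
    width_omega: float = Field(0.05, gt=0, le=1, description="window width as fraction of L")
    rate_theta: float = Field(0.0, ge=0, description="constant production rate (uM/s)")

    def mask(self, grid: Grid) -> np.ndarray:
        """Boolean indicator of the source window on the grid, wrapped periodically."""
        d = np.abs(((grid.xi - self.position_p + 0.5) % 1.0) - 0.5)
        return d <= self.width_omega / 2.0


class NumericsParams(_Params):
    """Discretization and solver settings."""

    n_points: int = Field(256, ge=8)
    L0: float = Field(0.2, gt=0, description="initial domain length")
    dt: float = Field(1.0e-3, gt=0, description="cell-clock time step")
    t_end: float = Field(100.0, gt=0)
    positivity_tol: float = Field(1.0e-8, gt=0, description="abort when C0 dips below -positivity_tol")
    positivity_grace: float = Field(1.0, ge=0, description="initial window (cell time) in which undershoots from discontinuous initial data are clipped, not fatal")
    qss_tol: float = Field(1.0e-8, gt=0, description="max-norm residual tolerance for molecular QSS (uM/s)")
    qss_max_iter: int = Field(60000, gt=0)
    qss_include_advection: bool = False
    seed: int = Field(0, ge=0)
    snapshot_every: float = Field(5.0, gt=0, description="output cadence in cell time")
    steady_tol: float = Field(1.0e-6, gt=0, description="max-norm dC0/dt threshold for steady-state detection")
    extinction_floor: float = Field(1.0e-4, gt=0, description="stop the run once max C0 stays below this (tissue gone; the shrinking domain would otherwise collapse)")
    steady_window: float = Field(1.0, gt=0, description="sliding window (cell time) for steady detection")
    filter_cutoff: float = Field(2.0 / 3.0, gt=0, lt=1)
    strict_nonnegative: bool = False

    @field_validator("n_points")
    @classmethod
    def _even(cls, v: int) -> int:
        if v % 2 != 0:
            raise ValueError("n_points must be even")
        return v


class ScenarioSpec(_Params):
    """Which experiment to run and its protocol options."""

    name: Literal[
        "formation",
        "dW_scan",
        "dB_scan",
        "d1_scan",
        "regeneration_partial",
        "regeneration_full",
        "bmp_knockout",
        "phase_diagram",
        "localized_seed",
        "exogenous_wnt",
    ] = "formation"
    options: dict = Field(default_factory=dict)


class Config(_Params):
    """Full validated run configuration."""

    lineage: LineageParams = Field(default_factory=LineageParams)
    morphogen: MorphogenParams = Field(default_factory=MorphogenParams)
    geometry: GeometryParams = Field(default_factory=GeometryParams)
    numerics: NumericsParams = Field(default_factory=NumericsParams)
    scenario: ScenarioSpec = Field(default_factory=ScenarioSpec)
    source: Optional[ExogenousWntSource] = None

    def grid(self) -> Grid:
        return Grid(self.numerics.n_points, self.numerics.L0)


# ---------------------------------------------------------------------------
# config I/O
# ---------------------------------------------------------------------------


def load_config(path: str | Path | None = None, overrides: Sequence[str] = ()) -> Config:
    """Load a YAML config, fill unspecified fields from package defaults, validate.

    ``overrides`` are ``section.key=value`` strings (the CLI ``--set``
    mechanism) applied after the file.  Raises pydantic.ValidationError naming
    the offending field for missing/invalid entries.
    """
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    cfg = Config.model_validate(data)
    if overrides:
        cfg = apply_overrides(cfg, overrides)
    return cfg


def apply_overrides(cfg: Config, overrides: Sequence[str]) -> Config:
    """Apply dotted ``section.key=value`` overrides; values parsed as YAML scalars."""
    data = cfg.model_dump()
    for item in overrides:
        if "=" not in item:
            raise ValueError(f"override must look like section.key=value, got {item!r}")
        key, raw = item.split("=", 1)
        parts = key.strip().split(".")
        node = data
        for p in parts[:-1]:
            if p not in node or node[p] is None:
                node[p] = {}
            node = node[p]
        node[parts[-1]] = yaml.safe_load(raw)
    return Config.model_validate(data)


def dump_config(cfg: Config, path: str | Path) -> None:
    """Write the effective configuration as YAML (lossless round-trip)."""
    with open(path, "w") as fh:
        yaml.safe_dump(json.loads(cfg.model_dump_json()), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# seeded initial conditions
# ---------------------------------------------------------------------------


def _band_limited_noise(rng: np.random.Generator, n: int, amplitude: float, n_modes: int = 16) -> np.ndarray:
    """Zero-mean noise restricted to the first ``n_modes`` Fourier modes,
    scaled to the requested max-abs amplitude."""
    if amplitude == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    fh = np.fft.rfft(white)
    fh[0] = 0.0
    fh[n_modes + 1 :] = 0.0
    field = np.fft.irfft(fh, n=n)
    peak = np.max(np.abs(field))
    return field * (amplitude / peak) if peak > 0 else field


def make_initial_state(
    kind: str,
    grid: Grid,
    options: Optional[dict] = None,
    seed: int = 0,
) -> tuple[LineageState, MorphogenState]:
    """Generate a seeded initial condition of the named kind.

    Kinds
    -----
    uniform_noisy_wnt
        Uniform progenitor density ``c0`` (default 0.1) with a low,
        band-limited fluctuating Wnt field about ``wnt_mean`` (default 0.01 uM,
        noise ``wnt_noise`` default 0.005 uM, first 16 modes); no inhibitor or
        BMP.  Optional ``c0_noise`` adds band-limited progenitor fluctuations.
    random_wnt_field
        Random per-mode Wnt field (uniform amplitudes, random phases over the
        first ``n_modes`` modes) -- the alternative random initial Wnt fields
        used to probe multiplicity of patterned steady states.
    localized_spots
        ``spots`` = list of (center_frac, width_frac, level); default a single
        spot of level 0.1 over the central tenth of the domain.  Exact step
        profile; morphogens zero.
    from_snapshot
        Restart from ``path`` (a snapshot written by :func:`save_snapshot`).

    Identical seeds give bit-identical states.
    """
    opts = dict(options or {})
    rng = np.random.default_rng(seed)
    n = grid.n_points

    if kind == "uniform_noisy_wnt":
        c0 = float(opts.pop("c0", 0.1))
        wnt_mean = float(opts.pop("wnt_mean", 0.01))
        wnt_noise = float(opts.pop("wnt_noise", 0.005))
        c0_noise = float(opts.pop("c0_noise", 0.0))
        n_modes = int(opts.pop("n_modes", 16))
        _reject_extra(kind, opts)
        if not 0 <= c0 <= 1:
            raise ValueError("uniform progenitor level must lie in [0, 1]")
        C0 = np.full(n, c0)
        if c0_noise > 0:
            C0 = np.clip(C0 + _band_limited_noise(rng, n, c0_noise, n_modes), 0.0, 1.0)
        W = np.clip(wnt_mean + _band_limited_noise(rng, n, wnt_noise, n_modes), 0.0, None)
        cells = LineageState.from_progenitor(C0)
        return cells, MorphogenState(W, np.zeros(n), np.zeros(n))

    if kind == "random_wnt_field":
        c0 = float(opts.pop("c0", 0.1))
        amplitude = float(opts.pop("amplitude", 0.02))
        n_modes = int(opts.pop("n_modes", 16))
        _reject_extra(kind, opts)
        amps = rng.uniform(0.0, 1.0, n_modes)
        phases = rng.uniform(0.0, 2.0 * np.pi, n_modes)
        fh = np.zeros(n // 2 + 1, dtype=complex)
        fh[1 : n_modes + 1] = amps * np.exp(1j * phases)
        field = np.fft.irfft(fh, n=n)
        peak = np.max(np.abs(field))
        if peak > 0:
            field *= amplitude / peak
        W = np.clip(amplitude + field, 0.0, None)
        cells = LineageState.from_progenitor(np.full(n, c0))
        return cells, MorphogenState(W, np.zeros(n), np.zeros(n))

    if kind == "localized_spots":
        spots = opts.pop("spots", [(0.5, 0.1, 0.1)])
        _reject_extra(kind, opts)
        C0 = np.zeros(n)
        xi = grid.xi
        for center, width, level in spots:
            if not 0 <= level <= 1:
                raise ValueError(f"spot level {level} outside [0, 1]")
            if width > 1:
                raise ValueError("spot width exceeds the domain")
            d = np.abs(((xi - center + 0.5) % 1.0) - 0.5)
            C0[d < width / 2.0] = level
        cells = LineageState.from_progenitor(C0)
        return cells, MorphogenState.zeros(n)

    if kind == "from_snapshot":
        path = opts.pop("path")
        _reject_extra(kind, opts)
        _, cells, morph, _, _ = load_snapshot(path)
        return cells, morph

    raise ValueError(f"unknown initial-state kind {kind!r}")


def _reject_extra(kind: str, opts: dict) -> None:
    if opts:
        raise ValueError(f"unknown options for initial-state kind {kind!r}: {sorted(opts)}")


# ---------------------------------------------------------------------------
# snapshots
# ---------------------------------------------------------------------------


def save_snapshot(
    path: str | Path,
    grid: Grid,
    cells: LineageState,
    morph: MorphogenState,
    t: float,
    cfg: Optional[Config] = None,
    curve: Optional[dict] = None,
) -> None:
    """Write a self-contained snapshot (npz container) of the full state."""
    payload = dict(
        n_points=grid.n_points,
        L=grid.L,
        t=t,
        C0=cells.C0,
        C1=cells.C1,
        V=cells.V,
        wnt=morph.wnt,
        inhibitor=morph.inhibitor,
        bmp=morph.bmp,
    )
    if curve is not None:
        payload["curve_x"] = curve["x"]
        payload["curve_y"] = curve["y"]
    if cfg is not None:
        payload["config_json"] = np.array(cfg.model_dump_json())
    np.savez(path, **payload)


def load_snapshot(path: str | Path):
    """Read a snapshot; returns (grid, cells, morphogens, t, config-or-None)."""
    with np.load(path, allow_pickle=False) as z:
        grid = Grid(int(z["n_points"]), float(z["L"]))
        cells = LineageState(z["C0"], z["C1"], z["V"])
        morph = MorphogenState(z["wnt"], z["inhibitor"], z["bmp"])
        t = float(z["t"])
        cfg = None
        if "config_json" in z:
            cfg = Config.model_validate_json(str(z["config_json"]))
    return grid, cells, morph, t, cfg
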