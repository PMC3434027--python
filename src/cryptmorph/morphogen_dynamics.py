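"""Reaction kinetics of the Wnt / Wnt-inhibitor / BMP system and its
quasi-steady states on the current domain.

The molecular clock (seconds) is fast relative to the cell clock (cell
cycles), so at every cell step the three concentration fields are replaced by
a stationary solution of

    0 = D_X d^2 X / ds^2 + f_X(W, I, B; C0, C1)      X in {W, I, B}

on the periodic domain.  Molecular convection by the slow cell flow is
dropped at quasi-steady state (a config switch retains it for sensitivity
checks).  BMP is linear and solved exactly in Fourier space; the coupled
Wnt/inhibitor pair is relaxed in pseudo-time (which selects a *stable*
stationary state, exactly what the fast subsystem would do physically) and
polished by Newton iteration warm-started from the previous step.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .fourier import helmholtz_solve, spectral_derivative, wavenumbers
from .model_state import (
    ExogenousWntSource,
    Grid,
    LineageState,
    MorphogenParams,
    MorphogenState,
    NumericsParams,
)

__all__ = [
    "ReactionRates",
    "reaction_rates",
    "solve_quasi_steady",
    "homogeneous_fixed_point",
    "FixedPoints",
    "QSSError",
    "hill_activation",
    "hill_repression",
]


class QSSError(RuntimeError):
    """Quasi-steady-state solve failed; carries the final residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (residual {residual:.3e})")
        self.residual = residual


# ---------------------------------------------------------------------------
# Hill responses (shared with the stability analysis)
# ---------------------------------------------------------------------------


def hill_activation(x: np.ndarray | float, beta: float, n: float) -> np.ndarray | float:
    """(beta x)^n / (1 + (beta x)^n), defined as 0 at x = 0 (the limit)."""
    x = np.asarray(x, dtype=float)
    u = np.where(x > 0, (beta * x) ** n, 0.0)
    out = u / (1.0 + u)
    return out if out.ndim else float(out)


def hill_activation_deriv(x: np.ndarray | float, beta: float, n: float) -> np.ndarray | float:
    """d/dx of :func:`hill_activation`; 0 at x = 0 for n > 1."""
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(x > 0, (beta * x) ** n, 0.0)
        d = np.where(x > 0, n * u / (x * (1.0 + u) ** 2), beta if n == 1 else 0.0)
    return d if d.ndim else float(d)


def hill_repression(x: np.ndarray | float, beta: float, m: float) -> np.ndarray | float:
    """1 / (1 + (beta x)^m), the inhibitory factor."""
    x = np.asarray(x, dtype=float)
    v = np.where(x > 0, (beta * x) ** m, 0.0)
    out = 1.0 / (1.0 + v)
    return out if out.ndim else float(out)


def hill_repression_deriv(x: np.ndarray | float, beta: float, m: float) -> np.ndarray | float:
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(x > 0, (beta * x) ** m, 0.0)
        d = np.where(x > 0, -m * v / (x * (1.0 + v) ** 2), -beta if m == 1 else 0.0)
    return d if d.ndim else float(d)


# ---------------------------------------------------------------------------
# pointwise reaction rates
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ReactionRates:
    """Local net reaction rates (uM/s), production minus removal, no transport."""

    r_wnt: np.ndarray
    r_inh: np.ndarray
    r_bmp: np.ndarray


def _source_term(src: Optional[ExogenousWntSource], n: int) -> np.ndarray | float:
    if src is None or src.rate_theta == 0:
        return 0.0
    grid = Grid(n, 1.0)  # indicator depends only on xi, not on L
    return src.rate_theta * src.mask(grid).astype(float)


def wnt_production(W, I, C0, p: MorphogenParams, src_term=0.0):
    """mu0*C0 + alpha_W * act(W) * rep(I) + exogenous source (no removal)."""
    return (
        p.mu0 * C0
        + p.alpha_W * hill_activation(W, p.beta_W, p.n_W) * hill_repression(I, p.beta_I, p.m_W)
        + src_term
    )


def inhibitor_production(W, p: MorphogenParams):
    """alpha_I * act(W) (no removal)."""
    return p.alpha_I * hill_activation(W, p.beta_W_inh, p.n_I)


def reaction_rates(
    m: MorphogenState,
    cells: LineageState,
    p: MorphogenParams,
    src: Optional[ExogenousWntSource] = None,
) -> ReactionRates:
    """Pointwise net kinetic rates of the three species.

    The Wnt rate is mu0*C0 + self-activation Hill term (repressed by the
    inhibitor) - d_W*W, plus theta inside the exogenous source window; the
    self-activation evaluates to 0 at W = 0.  The BMP rate is exactly
    mu1*C1 - d_B*B.
    """
    for name, arr in (("wnt", m.wnt), ("inhibitor", m.inhibitor), ("bmp", m.bmp)):
        if np.any(arr < 0):
            raise ValueError(f"negative {name} concentration passed to reaction_rates")
    n = m.wnt.size
    if cells.C0.size != n:
        raise ValueError("cell and morphogen states must share a grid")
    src_term = _source_term(src, n)
    r_wnt = wnt_production(m.wnt, m.inhibitor, cells.C0, p, src_term) - p.d_W * m.wnt
    r_inh = inhibitor_production(m.wnt, p) - p.d_I * m.inhibitor
    r_bmp = p.mu1 * cells.C1 - p.d_B * m.bmp
    return ReactionRates(np.asarray(r_wnt), np.asarray(r_inh), np.asarray(r_bmp))


# ---------------------------------------------------------------------------
# quasi-steady-state solver
# ---------------------------------------------------------------------------

_D2_CACHE: dict[int, np.ndarray] = {}


def _second_derivative_matrix(n: int) -> np.ndarray:
    """Dense spectral d^2/dxi^2 matrix on the unit periodic domain (cached)."""
    if n not in _D2_CACHE:
        eye = np.eye(n)
        cols = [spectral_derivative(eye[:, j], 2, 1.0) for j in range(n)]
        _D2_CACHE[n] = np.column_stack(cols)
    return _D2_CACHE[n]


def _qss_residual(W, I, C0, p: MorphogenParams, L: float, src_term) -> tuple[np.ndarray, np.ndarray]:
    rw = p.D_W * spectral_derivative(W, 2, L) + wnt_production(W, I, C0, p, src_term) - p.d_W * W
    ri = p.D_I * spectral_derivative(I, 2, L) + inhibitor_production(W, p) - p.d_I * I
    return rw, ri


def solve_quasi_steady(
    cells: LineageState,
    p: MorphogenParams,
    grid: Grid,
    init: MorphogenState,
    num: NumericsParams,
    src: Optional[ExogenousWntSource] = None,
    V: Optional[np.ndarray] = None,
) -> MorphogenState:
    """Stationary molecular state for the given (frozen) cell fields.

    Returns a state whose stationary residual ||D f'' + reaction||_inf is at
    most ``num.qss_tol`` for each species.  Deterministic given inputs.  BMP
    decouples (linear) and is solved exactly; the Wnt/inhibitor pair is
    relaxed by a positivity-preserving semi-implicit pseudo-time iteration
    with an automatic step, then polished by damped Newton once close.

    When ``num.qss_include_advection`` is set and a velocity is supplied, the
    convection term d(V X)/ds is retained in the stationary balance.
    """
    init.check_nonnegative()
    L = grid.L
    n = grid.n_points
    src_term = _source_term(src, n)
    adv = None
    if num.qss_include_advection and V is not None and np.any(V):
        adv = np.asarray(V, dtype=float)

    def transport(X: np.ndarray, D: float) -> np.ndarray:
        out = D * spectral_derivative(X, 2, L)
        if adv is not None:
            out -= spectral_derivative(adv * X, 1, L)
        return out

    # --- BMP: linear, exact solve ------------------------------------------
    if adv is None:
        B = helmholtz_solve(p.mu1 * cells.C1, p.D_B, p.d_B, L)
    else:  # iterate the (small) advective correction
        B = helmholtz_solve(p.mu1 * cells.C1, p.D_B, p.d_B, L)
        for _ in range(200):
            rhs = p.mu1 * cells.C1 - spectral_derivative(adv * B, 1, L)
            B_new = helmholtz_solve(rhs, p.D_B, p.d_B, L)
            if np.max(np.abs(B_new - B)) < 1e-14 + 1e-12 * np.max(np.abs(B_new)):
                B = B_new
                break
            B = B_new
    B = np.clip(B, 0.0, None)

    W = init.wnt.copy()
    I = init.inhibitor.copy()

    def residual(W, I):
        rw = transport(W, p.D_W) + wnt_production(W, I, cells.C0, p, src_term) - p.d_W * W
        ri = transport(I, p.D_I) + inhibitor_production(W, p) - p.d_I * I
        return rw, ri

    def resnorm(W, I):
        rw, ri = residual(W, I)
        return max(np.max(np.abs(rw)), np.max(np.abs(ri)))

    tol = num.qss_tol
    r = resnorm(W, I)
    if r <= tol:
        return MorphogenState(W, I, B)

    # --- pseudo-time relaxation --------------------------------------------
    # The pseudo-time flow is the molecular dynamics itself: it leaves
    # unstable (Turing) stationary states along their growing modes and
    # settles only on a *stable* stationary state, which is the physically
    # correct quasi-steady state.  Newton is used purely as an endgame
    # accelerator and is armed only while the residual is shrinking, so it
    # cannot capture the homogeneous saddle during pattern growth (there the
    # residual grows with the unstable mode).
    kW = p.d_W + p.D_W * wavenumbers(n, L) ** 2
    kI = p.d_I + p.D_I * wavenumbers(n, L) ** 2
    iters = 0
    newton_gate = max(100.0 * tol, 1e-5 * max(p.alpha_W, p.d_W))
    safety = 1.0
    history: list[float] = [r]

    # A near-uniform iterate sitting on a Turing-unstable homogeneous state
    # is a saddle, not the quasi-steady state: the pattern content still
    # present in the field will grow.  Such iterates must not be accepted
    # (nor handed to Newton, which would land exactly on the saddle).
    c0_uniform = float(np.ptp(cells.C0)) <= 1e-9 * max(float(np.max(np.abs(cells.C0))), 1e-30)
    roundoff_floor = 1e-12

    def _on_unstable_uniform(W, I) -> bool:
        if not c0_uniform or src is not None:
            return False
        scale = max(float(np.max(W)), 1e-30)
        content = max(float(np.ptp(W)), float(np.ptp(I))) / scale
        if content > 1e-2 or content <= roundoff_floor:
            return False
        from .turing_analysis import dispersion_relation  # local: avoids cycle

        J = _kinetics_jacobian_wi(float(np.mean(W)), float(np.mean(I)), p)
        disp = dispersion_relation(J, (p.D_W, p.D_I), L, n_modes=n // 2)
        return bool(np.any(disp.growth_rates[1:] > 0))

    newton_cooldown = 0
    stagnant_since = 0
    stagnant_accept = False
    while (r > tol or _on_unstable_uniform(W, I)) and iters < num.qss_max_iter:
        recent = history[-6:]
        shrinking = len(history) >= 4 and history[-1] < 0.98 * max(history[-4:-1])
        stagnant = len(recent) == 6 and max(recent) < 1.05 * min(recent)
        if stagnant:
            stagnant_since += 1
        else:
            stagnant_since = 0
        # A persistently stagnant iterate sits on a slow near-neutral
        # manifold (e.g. a creeping Wnt front pinned by the cell field): the
        # fast subsystem has no nearby stationary state, only a slow drift
        # that the following cell steps carry along.  Accept it once the
        # stationary residual is negligible against the kinetic rate scale.
        soft_cap = max(10.0 * tol, 1e-5 * p.alpha_W)
        if (
            (stagnant_since > 50 or iters > 3000)
            and r <= soft_cap
            and not _on_unstable_uniform(W, I)
        ):
            stagnant_accept = True
            break
        if r <= newton_gate and (shrinking or stagnant or r <= 100.0 * tol) and newton_cooldown == 0:
            W2, I2, r2 = _newton_polish(
                W, I, cells.C0, p, L, src_term, residual, resnorm, tol, num, adv
            )
            if _on_unstable_uniform(W2, I2):
                # Newton found the homogeneous saddle: refuse it and let the
                # pattern keep growing in pseudo-time before trying again.
                newton_cooldown = 200
            elif r2 >= 0.5 * r:
                # Newton is not closing (near-singular Jacobian on a slow
                # manifold): rest it for a while, pseudo-time still shrinks
                newton_cooldown = 100
                if r2 < r:
                    W, I, r = W2, I2, r2
                    history.append(r)
            elif r2 < r:
                W, I, r = W2, I2, r2
                history.append(r)
                if r <= tol:
                    break
        dtau = safety * _pseudo_time_bound(W, I, p)
        prod_W = wnt_production(W, I, cells.C0, p, src_term)
        prod_I = inhibitor_production(W, p)
        if adv is not None:
            prod_W = prod_W - spectral_derivative(adv * W, 1, L)
            prod_I = prod_I - spectral_derivative(adv * I, 1, L)
        W_new = np.fft.irfft(np.fft.rfft(W + dtau * prod_W) / (1.0 + dtau * kW), n=n)
        I_new = np.fft.irfft(np.fft.rfft(I + dtau * prod_I) / (1.0 + dtau * kI), n=n)
        # the k = 0 pair is a weakly damped spiral that the semi-implicit
        # update only circles; advance the means by backward Euler instead
        # (A-stable for the oscillation)
        Wm, Im = float(np.mean(W)), float(np.mean(I))
        Jm = _kinetics_jacobian_wi(max(Wm, 0.0), max(Im, 0.0), p)
        fm = np.array(
            [
                float(np.mean(wnt_production(W, I, cells.C0, p, src_term))) - p.d_W * Wm,
                float(np.mean(inhibitor_production(W, p))) - p.d_I * Im,
            ]
        )
        try:
            delta = np.linalg.solve(np.eye(2) - dtau * Jm, dtau * fm)
        except np.linalg.LinAlgError:
            delta = dtau * fm
        W_new = W_new - np.mean(W_new) + (Wm + delta[0])
        I_new = I_new - np.mean(I_new) + (Im + delta[1])
        # tolerate tiny interior negatives (the Hill terms treat x <= 0 as 0);
        # a hard clip here pins a spurious residual at near-zero troughs
        floor_W = -1e-5 * max(float(np.max(W_new)), 1e-12)
        W_new = np.clip(W_new, floor_W, None)
        I_new = np.clip(I_new, floor_W, None)
        r_new = resnorm(W_new, I_new)
        if r_new > 10.0 * max(r, 10.0 * tol) and safety > 1e-3:
            safety *= 0.5  # overshoot: retry smaller
            iters += 1
            continue
        if r_new < r:
            safety = min(1.0, safety * 1.25)
        W, I, r = W_new, I_new, r_new
        history.append(r)
        iters += 1
        if newton_cooldown > 0:
            newton_cooldown -= 1

    if r > tol and not stagnant_accept:
        soft_cap = max(10.0 * tol, 1e-5 * p.alpha_W)
        if r <= soft_cap and not _on_unstable_uniform(W, I):
            stagnant_accept = True  # slow-manifold drift, carried across steps
        else:
            raise QSSError("quasi-steady-state iteration did not converge", r)

    state = MorphogenState(W, I, B)
    if num.strict_nonnegative:
        state.check_nonnegative()
    else:
        state.wnt = np.clip(state.wnt, 0.0, None)
        state.inhibitor = np.clip(state.inhibitor, 0.0, None)
    return state


def _pseudo_time_bound(W: np.ndarray, I: np.ndarray, p: MorphogenParams) -> float:
    """Largest stable pseudo-time step for the semi-implicit relaxation.

    The update treats removal + diffusion implicitly and the production
    terms explicitly.  Pointwise the explicit part has the 2x2 Jacobian
    [[a, b], [c, 0]] with a = dP_W/dW >= 0, b = dP_W/dI <= 0, c = dP_I/dW
    >= 0.  For the complex-pair case (the weakly damped Wnt/inhibitor
    spiral) linear stability of the update against the implicit damping
    d = min(d_W, d_I) requires roughly
        dtau <= 2 (d - a/2) / (|b c| - d^2),
    and for real spectra the growth is physical, so the step is merely kept
    at the tracking scale 1/max(a, d).
    """
    a = p.alpha_W * hill_activation_deriv(W, p.beta_W, p.n_W) * hill_repression(I, p.beta_I, p.m_W)
    b = p.alpha_W * hill_activation(W, p.beta_W, p.n_W) * hill_repression_deriv(I, p.beta_I, p.m_W)
    c = p.alpha_I * hill_activation_deriv(W, p.beta_W_inh, p.n_I)
    d = 0.5 * (p.d_W + p.d_I)
    bc = np.abs(b * c)
    osc = (a * a - 4.0 * bc < 0) & (bc > d * d)
    dtau = 1.0 / max(float(np.max(a)), d)
    if np.any(osc):
        num_ = np.clip(d - a[osc] / 2.0, 0.02 * d, None)
        dtau = min(dtau, float(np.min(2.0 * num_ / (bc[osc] - d * d))))
    return dtau


def _newton_polish(W, I, C0, p, L, src_term, residual, resnorm, tol, num, adv):
    n = W.size
    D2 = _second_derivative_matrix(n) / L**2
    LW = p.D_W * D2
    LI = p.D_I * D2
    r = resnorm(W, I)
    for _ in range(60):
        if r <= tol:
            break
        rw, ri = residual(W, I)
        F = np.concatenate([rw, ri])
        act = hill_activation(W, p.beta_W, p.n_W)
        dact = hill_activation_deriv(W, p.beta_W, p.n_W)
        rep = hill_repression(I, p.beta_I, p.m_W)
        drep = hill_repression_deriv(I, p.beta_I, p.m_W)
        dfw_dW = p.alpha_W * dact * rep - p.d_W
        dfw_dI = p.alpha_W * act * drep
        dfi_dW = p.alpha_I * hill_activation_deriv(W, p.beta_W_inh, p.n_I)
        J = np.zeros((2 * n, 2 * n))
        J[:n, :n] = LW + np.diag(dfw_dW)
        J[:n, n:] = np.diag(dfw_dI)
        J[n:, :n] = np.diag(dfi_dW)
        J[n:, n:] = LI - p.d_I * np.eye(n)
        if adv is not None:  # first-order convection enters linearly
            from .fourier import spectral_derivative as sd

            # build dense advection operator lazily (rare path)
            A = np.column_stack([sd(adv * np.eye(n)[:, j], 1, L) for j in range(n)])
            J[:n, :n] -= A
            J[n:, n:] -= A
        try:
            step = np.linalg.solve(J, -F)
        except np.linalg.LinAlgError:
            break
        lam = 1.0
        floor = -1e-5 * max(float(np.max(W)), 1e-12)
        for _bt in range(20):
            W_new = np.clip(W + lam * step[:n], floor, None)
            I_new = np.clip(I + lam * step[n:], floor, None)
            r_new = resnorm(W_new, I_new)
            if r_new < r:
                break
            lam *= 0.5
        else:
            break
        W, I, r = W_new, I_new, r_new
    return W, I, r


def evolve_morphogens(
    morph: MorphogenState,
    cells: LineageState,
    p: MorphogenParams,
    grid: Grid,
    dtau: float,
    n_steps: int,
    record_every: int = 1,
) -> list[MorphogenState]:
    """Integrate the molecular reaction-diffusion system in its own (fast)
    time at frozen cells, semi-implicitly with a fixed step.

    Unlike :func:`solve_quasi_steady` this follows the transient -- it is
    the tool for measuring modal growth rates against the linear dispersion
    relation.  Returns the recorded states (including the initial one).
    """
    L, n = grid.L, grid.n_points
    kW = p.d_W + p.D_W * wavenumbers(n, L) ** 2
    kI = p.d_I + p.D_I * wavenumbers(n, L) ** 2
    W = morph.wnt.copy()
    I = morph.inhibitor.copy()
    B = morph.bmp.copy()
    out = [MorphogenState(W.copy(), I.copy(), B.copy())]
    for step in range(1, n_steps + 1):
        prod_W = wnt_production(W, I, cells.C0, p)
        prod_I = inhibitor_production(W, p)
        W = np.fft.irfft(np.fft.rfft(W + dtau * prod_W) / (1.0 + dtau * kW), n=n)
        I = np.fft.irfft(np.fft.rfft(I + dtau * prod_I) / (1.0 + dtau * kI), n=n)
        if step % record_every == 0:
            out.append(MorphogenState(W.copy(), I.copy(), B.copy()))
    return out


# ---------------------------------------------------------------------------
# homogeneous fixed points (base states for the stability analysis)
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class FixedPoints:
    """All homogeneous stationary states found, plus the selected branch.

    ``roots`` is a list of (W*, I*, B*) triples; ``selected`` indexes the
    default branch (the largest-W kinetically stable root, falling back to
    the largest-W root if none is stable).  ``stable`` marks kinetic (k = 0)
    stability of the Wnt/inhibitor pair per root.
    """

    roots: list[tuple[float, float, float]]
    stable: list[bool]
    selected: int

    @property
    def selected_root(self) -> tuple[float, float, float]:
        return self.roots[self.selected]


def homogeneous_fixed_point(
    c0: float,
    c1: float,
    p: MorphogenParams,
    n_scan: int = 4000,
) -> FixedPoints:
    """Uniform stationary states (W*, I*, B*) of the kinetics at frozen cell
    densities.

    B* = mu1*c1/d_B exactly; I* = alpha_I*act(W*)/d_I; W* solves the scalar
    reduced equation, located by a dense bracketing scan plus Brent refinement
    over [0, (mu0*c0 + alpha_W)/d_W].
    """
    from scipy.optimize import brentq

    if c0 < 0 or c1 < 0:
        raise ValueError("cell densities must be nonnegative")
    B = p.mu1 * c1 / p.d_B

    def I_of_W(W: float) -> float:
        return p.alpha_I * float(hill_activation(W, p.beta_W_inh, p.n_I)) / p.d_I

    def g(W: float) -> float:
        return float(wnt_production(W, I_of_W(W), c0, p)) - p.d_W * W

    W_hi = (p.mu0 * c0 + p.alpha_W) / p.d_W * 1.01
    Ws = np.linspace(0.0, W_hi, n_scan)
    I_arr = p.alpha_I * hill_activation(Ws, p.beta_W_inh, p.n_I) / p.d_I
    gs = wnt_production(Ws, I_arr, c0, p) - p.d_W * Ws
    roots: list[float] = []
    if abs(gs[0]) < 1e-14 * max(p.alpha_W, p.d_W):
        roots.append(0.0)
    for i in range(len(Ws) - 1):
        a, b = gs[i], gs[i + 1]
        if a == 0.0 and Ws[i] not in roots:
            roots.append(Ws[i])
        elif a * b < 0:
            roots.append(brentq(g, Ws[i], Ws[i + 1], xtol=1e-15, rtol=1e-14))
    if not roots:
        raise RuntimeError("no homogeneous fixed point found in search bracket")

    triples = [(W, I_of_W(W), B) for W in roots]
    stable = []
    for W, I, _ in triples:
        J = _kinetics_jacobian_wi(W, I, p)
        stable.append(bool(np.all(np.real(np.linalg.eigvals(J)) < 0)))
    sel_candidates = [i for i, s in enumerate(stable) if s]
    pool = sel_candidates if sel_candidates else list(range(len(triples)))
    selected = max(pool, key=lambda i: triples[i][0])
    return FixedPoints(roots=triples, stable=stable, selected=selected)


def _kinetics_jacobian_wi(W: float, I: float, p: MorphogenParams) -> np.ndarray:
    """2x2 Jacobian of the Wnt/inhibitor kinetics at (W, I) (BMP frozen)."""
    act = float(hill_activation(W, p.beta_W, p.n_W))
    dact = float(hill_activation_deriv(W, p.beta_W, p.n_W))
    rep = float(hill_repression(I, p.beta_I, p.m_W))
    drep = float(hill_repression_deriv(I, p.beta_I, p.m_W))
    return np.array(
        [
            [p.alpha_W * dact * rep - p.d_W, p.alpha_W * act * drep],
            [p.alpha_I * float(hill_activation_deriv(W, p.beta_W_inh, p.n_I)), -p.d_I],
        ]
    )
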