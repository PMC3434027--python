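"""Morphogen kinetics and the quasi-steady-state solver."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from cryptmorph import (
    Config,
    Grid,
    LineageState,
    MorphogenState,
    homogeneous_fixed_point,
    reaction_rates,
    solve_quasi_steady,
)
from cryptmorph.fourier import spectral_derivative
from cryptmorph.model_state import MorphogenParams, NumericsParams


def independent_rates(W, I, B, C0, C1, p):
    """Hand-coded second implementation of the reaction terms, written in
    the saturating-Hill form with negative exponents (oracle)."""
    with np.errstate(divide="ignore", over="ignore"):
        act = 1.0 / (1.0 + (p.beta_W * W) ** (-p.n_W))
        act = np.where(W > 0, act, 0.0)
        act_i = 1.0 / (1.0 + (p.beta_W_inh * W) ** (-p.n_I))
        act_i = np.where(W > 0, act_i, 0.0)
    rep = 1.0 / (1.0 + (p.beta_I * I) ** p.m_W)
    r_w = p.mu0 * C0 + p.alpha_W * act * rep - p.d_W * W
    r_i = p.alpha_I * act_i - p.d_I * I
    r_b = p.mu1 * C1 - p.d_B * B
    return r_w, r_i, r_b


class TestReactionRates:
    def test_zero_wnt_branch_is_kinetically_silent(self):
        p = MorphogenParams()
        cells = LineageState.from_progenitor(np.zeros(8))
        m = MorphogenState.zeros(8)
        r = reaction_rates(m, cells, p)
        assert np.all(r.r_wnt == 0.0)  # mu0*0 and the Hill limit at W = 0
        assert np.all(r.r_inh == 0.0)
        assert np.allclose(r.r_bmp, p.mu1)  # C1 = 1 sources BMP

    def test_bmp_balance_closed_form(self):
        p = MorphogenParams()
        cells = LineageState.from_progenitor(np.zeros(8))  # C1 = 1
        m = MorphogenState(np.zeros(8), np.zeros(8), np.full(8, p.mu1 / p.d_B))
        r = reaction_rates(m, cells, p)
        assert np.max(np.abs(r.r_bmp)) < 1e-18

    def test_matches_independent_expression_oracle(self, rng):
        p = MorphogenParams()
        n = 16
        C0 = rng.uniform(0, 1, n)
        cells = LineageState.from_progenitor(C0)
        m = MorphogenState(rng.uniform(0, 2, n), rng.uniform(0, 1, n), rng.uniform(0, 0.5, n))
        r = reaction_rates(m, cells, p)
        ow, oi, ob = independent_rates(m.wnt, m.inhibitor, m.bmp, cells.C0, cells.C1, p)
        assert np.allclose(r.r_wnt, ow, atol=1e-15)
        assert np.allclose(r.r_inh, oi, atol=1e-15)
        assert np.allclose(r.r_bmp, ob, atol=1e-15)

    def test_negative_concentration_rejected(self):
        p = MorphogenParams()
        cells = LineageState.from_progenitor(np.zeros(4))
        m = MorphogenState(np.array([-0.1, 0, 0, 0]), np.zeros(4), np.zeros(4))
        with pytest.raises(ValueError):
            reaction_rates(m, cells, p)


class TestQuasiSteady:
    def test_td_only_tissue_has_linear_bmp_solution(self):
        cfg = Config()
        grid = Grid(64, 0.2)
        cells = LineageState.from_progenitor(np.zeros(64))  # C0=0, C1=1
        out = solve_quasi_steady(cells, cfg.morphogen, grid, MorphogenState.zeros(64), cfg.numerics)
        assert np.max(out.wnt) < 1e-12
        assert np.max(out.inhibitor) < 1e-12
        assert np.allclose(out.bmp, cfg.morphogen.mu1 / cfg.morphogen.d_B, rtol=1e-10)

    def test_homogeneous_fixed_point_is_preserved(self):
        cfg = Config()
        c0 = 0.1
        fp = homogeneous_fixed_point(c0, 1 - c0, cfg.morphogen)
        W, I, B = fp.selected_root
        grid = Grid(64, 0.2)
        cells = LineageState.from_progenitor(np.full(64, c0))
        init = MorphogenState(np.full(64, W), np.full(64, I), np.full(64, B))
        out = solve_quasi_steady(cells, cfg.morphogen, grid, init, cfg.numerics)
        # residual was already below tolerance: returned unchanged
        assert np.max(np.abs(out.wnt - W)) < 1e-12
        assert np.max(np.abs(out.inhibitor - I)) < 1e-12

    def test_qss_residual_contract(self, rng):
        cfg = Config()
        n = 64
        grid = Grid(n, 0.2)
        C0 = 0.1 + 0.4 * np.exp(-(((grid.xi - 0.5) / 0.08) ** 2))
        cells = LineageState.from_progenitor(C0)
        init = MorphogenState(np.full(n, 0.2), np.full(n, 0.2), np.zeros(n))
        out = solve_quasi_steady(cells, cfg.morphogen, grid, init, cfg.numerics)
        p = cfg.morphogen
        rw = p.D_W * spectral_derivative(out.wnt, 2, 0.2) + independent_rates(
            out.wnt, out.inhibitor, out.bmp, cells.C0, cells.C1, p
        )[0]
        assert np.max(np.abs(rw)) < 10 * cfg.numerics.qss_tol

    def test_matches_time_integration_oracle(self):
        """A localized progenitor bump: the stationary state found by the
        solver agrees with brute-force time integration of the molecular
        PDE (method of lines + LSODA) run to stationarity."""
        cfg = Config()
        n, L = 48, 0.2
        grid = Grid(n, L)
        C0 = 0.1 + 0.5 * np.exp(-(((grid.xi - 0.5) / 0.1) ** 2))
        cells = LineageState.from_progenitor(C0)
        init = MorphogenState(np.full(n, 0.3), np.full(n, 0.2), np.zeros(n))
        out = solve_quasi_steady(cells, cfg.morphogen, grid, init, cfg.numerics)

        p = cfg.morphogen

        def rhs(_t, y):
            W, I = y[:n], y[n:]
            rw, ri, _ = independent_rates(np.clip(W, 0, None), np.clip(I, 0, None), 0.0, C0, 1 - C0, p)
            return np.concatenate(
                [p.D_W * spectral_derivative(W, 2, L) + rw, p.D_I * spectral_derivative(I, 2, L) + ri]
            )

        sol = solve_ivp(
            rhs,
            [0.0, 2e5],
            np.concatenate([init.wnt, init.inhibitor]),
            method="LSODA",
            rtol=1e-10,
            atol=1e-12,
        )
        W_ref, I_ref = sol.y[:n, -1], sol.y[n:, -1]
        tol = 10 * cfg.numerics.qss_tol
        # compare through the stationary residual scale: fields agree where
        # the oracle has settled
        assert np.max(np.abs(out.wnt - W_ref)) < 1e-4
        assert np.max(np.abs(out.inhibitor - I_ref)) < 1e-4

    def test_bmp_monotone_in_removal_rate(self):
        cfg = Config()
        grid = Grid(64, 0.2)
        cells = LineageState.from_progenitor(np.full(64, 0.1))
        init = MorphogenState.zeros(64)
        p_lo = cfg.morphogen
        p_hi = p_lo.model_copy(update={"d_B": 2 * p_lo.d_B})
        b_lo = solve_quasi_steady(cells, p_lo, grid, init, cfg.numerics).bmp
        b_hi = solve_quasi_steady(cells, p_hi, grid, init.copy(), cfg.numerics).bmp
        assert np.all(b_hi <= b_lo + 1e-15)


class TestHomogeneousFixedPoints:
    def test_empty_tissue_has_trivial_root(self):
        fp = homogeneous_fixed_point(0.0, 0.0, MorphogenParams())
        W, I, B = fp.roots[0]
        assert (W, I, B) == (0.0, 0.0, 0.0)

    def test_bmp_component_closed_form(self):
        p = MorphogenParams()
        fp = homogeneous_fixed_point(0.3, 0.7, p)
        for _, _, B in fp.roots:
            assert B == pytest.approx(p.mu1 * 0.7 / p.d_B, rel=1e-12)

    def test_roots_agree_with_dense_scan_oracle(self):
        """The scalar reduced Wnt equation, scanned and bracketed with the
        independently coded kinetics, yields the same root set."""
        p = MorphogenParams()
        c0 = 0.5

        def g(W):
            I = p.alpha_I * (1.0 / (1.0 + (p.beta_W_inh * W) ** (-p.n_I)) if W > 0 else 0.0) / p.d_I
            rw, _, _ = independent_rates(np.array([W]), np.array([I]), 0.0, c0, 1 - c0, p)
            return float(rw[0])

        Ws = np.linspace(1e-9, (p.mu0 * c0 + p.alpha_W) / p.d_W, 6000)
        gs = np.array([g(w) for w in Ws])
        roots = [brentq(g, Ws[i], Ws[i + 1], xtol=1e-14) for i in range(len(Ws) - 1) if gs[i] * gs[i + 1] < 0]
        fp = homogeneous_fixed_point(c0, 1 - c0, p)
        ours = sorted(W for W, _, _ in fp.roots)
        assert len(ours) == len(roots)
        assert np.allclose(ours, sorted(roots), atol=1e-8)

    def test_selected_root_is_stable_and_largest(self):
        fp = homogeneous_fixed_point(0.1, 0.9, MorphogenParams())
        assert fp.stable[fp.selected]
        stable_ws = [r[0] for r, s in zip(fp.roots, fp.stable) if s]
        assert fp.selected_root[0] == max(stable_ws)
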