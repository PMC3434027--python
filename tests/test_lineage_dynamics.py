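"""Replication probability, death-rate profiles, velocity closure,
progenitor transport and ablation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cryptmorph import (
    Grid,
    LineageState,
    MorphogenState,
    ablate_progenitors,
    compute_velocity,
    death_rate_field,
    lineage_rhs,
    replication_probability,
)
from cryptmorph.lineage_dynamics import ReplicationField
from cryptmorph.model_state import LineageParams


class TestReplicationProbability:
    def test_vanishes_without_wnt(self):
        lp = LineageParams()
        m = MorphogenState(np.zeros(8), np.zeros(8), np.linspace(0, 5, 8))
        assert np.all(replication_probability(m, lp).p0 == 0.0)

    def test_half_maximal_at_wnt_ec50(self):
        lp = LineageParams()
        w = 1.0 / lp.gamma_W  # (gamma_W W)^n = 1
        m = MorphogenState(np.full(4, w), np.zeros(4), np.zeros(4))
        assert replication_probability(m, lp).p0 == pytest.approx(lp.p0_max / 2)

    def test_one_third_when_both_hills_at_ec50(self):
        lp = LineageParams()
        m = MorphogenState(np.full(4, 1 / lp.gamma_W), np.zeros(4), np.full(4, 1 / lp.gamma_B))
        assert replication_probability(m, lp).p0 == pytest.approx(lp.p0_max / 3)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        w=st.floats(0.01, 3.0),
        b=st.floats(0.0, 2.0),
        scale=st.floats(1.1, 4.0),
    )
    def test_monotone_in_bmp_feedback_strength(self, w, b, scale):
        lp = LineageParams()
        stronger = lp.model_copy(update={"gamma_B": lp.gamma_B * scale})
        m = MorphogenState(np.array([w]), np.zeros(1), np.array([b]))
        assert replication_probability(m, stronger).p0[0] <= replication_probability(m, lp).p0[0] + 1e-15


class TestDeathRate:
    def test_constant_profile(self):
        lp = LineageParams(d1_profile="constant", d1_max=0.02)
        grid = Grid(32, 0.2)
        cells = LineageState.from_progenitor(np.linspace(0, 0.8, 32))
        assert np.all(death_rate_field(grid, cells, lp) == 0.02)

    def test_apex_localization_contract(self):
        """Removal is weakest at the progenitor peak and strongest far from it."""
        lp = LineageParams(d1_profile="apex_localized", d1_max=0.3)
        grid = Grid(64, 0.2)
        C0 = 0.8 * np.exp(-(((grid.xi - 0.25) / 0.06) ** 2))
        cells = LineageState.from_progenitor(C0)
        d1 = death_rate_field(grid, cells, lp)
        peak = np.argmax(C0)
        antipode = (peak + 32) % 64
        assert d1[peak] <= d1[antipode]
        assert np.all(d1 > 0) and np.all(d1 <= lp.d1_max + 1e-15)
        assert d1[peak] == pytest.approx(lp.d1_floor_frac * lp.d1_max, rel=1e-6)

    def test_profile_integral_converges_with_resolution(self):
        lp = LineageParams(d1_profile="apex_localized", d1_max=0.3)
        vals = []
        for n in (64, 128, 256):
            grid = Grid(n, 0.2)
            C0 = 0.8 * np.exp(-(((grid.xi - 0.5) / 0.08) ** 2))
            cells = LineageState.from_progenitor(C0)
            vals.append(np.sum(death_rate_field(grid, cells, lp)) * grid.h)
        assert abs(vals[2] - vals[1]) < 4 * abs(vals[1] - vals[0]) + 1e-12
        assert abs(vals[2] - vals[1]) / vals[2] < 1e-3


class TestVelocityClosure:
    def test_perfect_balance_is_stationary(self):
        lp = LineageParams(d1_profile="constant", d1_max=0.5, v0=1.0)
        # v0 C0 = d1 C1 pointwise at C0 = 1/3
        grid = Grid(32, 0.2)
        cells = LineageState.from_progenitor(np.full(32, 1.0 / 3.0))
        d1 = death_rate_field(grid, cells, lp)
        V, growth = compute_velocity(cells, d1, lp, grid)
        assert np.max(np.abs(V)) < 1e-15
        assert growth == pytest.approx(0.0, abs=1e-15)

    def test_pure_td_tissue_shrinks_uniformly(self):
        lp = LineageParams(d1_profile="constant", d1_max=0.1)
        grid = Grid(32, 0.4)
        cells = LineageState.from_progenitor(np.zeros(32))
        d1 = death_rate_field(grid, cells, lp)
        V, growth = compute_velocity(cells, d1, lp, grid)
        assert np.max(np.abs(V)) < 1e-15
        assert growth == pytest.approx(-0.1 * 0.4, rel=1e-12)  # -d1 * L

    def test_sinusoidal_source_matches_quadrature_oracle(self):
        lp = LineageParams(d1_profile="constant", d1_max=0.2)
        n, L = 128, 0.5
        grid = Grid(n, L)
        C0 = 0.2 + 0.1 * np.sin(2 * np.pi * grid.xi)
        cells = LineageState.from_progenitor(C0)
        d1 = death_rate_field(grid, cells, lp)
        V, growth = compute_velocity(cells, d1, lp, grid)
        src = lp.v0 * C0 - d1 * (1 - C0)
        fluct = src - src.mean()
        # trapezoid cumulative integral of the fluctuating part (oracle)
        cum = np.concatenate([[0.0], np.cumsum((fluct[:-1] + fluct[1:]) / 2.0 * grid.h)])
        cum -= cum.mean()
        assert np.max(np.abs(V - cum)) < 1e-5  # trapezoid truncation of the oracle
        assert growth == pytest.approx(src.mean() * L, rel=1e-12)

    def test_normalization_violation_rejected(self):
        lp = LineageParams()
        grid = Grid(16, 0.2)
        bad = LineageState.__new__(LineageState)
        bad.C0 = np.full(16, 0.5)
        bad.C1 = np.full(16, 0.6)
        bad.V = np.zeros(16)
        with pytest.raises(ValueError):
            compute_velocity(bad, np.full(16, 0.1), lp, grid)


class TestLineageRHS:
    def test_neutral_replication_is_stationary(self):
        lp = LineageParams(cell_motility=0.0)
        grid = Grid(64, 0.2)
        cells = LineageState.from_progenitor(np.full(64, 0.4))
        p0 = ReplicationField(np.full(64, 0.5))
        rhs = lineage_rhs(cells, p0, np.full(64, 0.1), np.zeros(64), lp, grid)
        assert np.max(np.abs(rhs)) < 1e-14

    def test_no_spontaneous_progenitors(self):
        lp = LineageParams()
        grid = Grid(64, 0.2)
        cells = LineageState.from_progenitor(np.zeros(64))
        p0 = ReplicationField(np.full(64, 0.9))
        rhs = lineage_rhs(cells, p0, np.full(64, 0.1), np.zeros(64), lp, grid)
        assert np.max(np.abs(rhs)) < 1e-14

    def test_advection_term_matches_fd_oracle(self):
        lp = LineageParams(cell_motility=0.0)
        n, L = 256, 0.5
        grid = Grid(n, L)
        xi = grid.xi
        C0 = 0.3 + 0.2 * np.cos(2 * np.pi * xi)
        V = 0.05 * np.sin(4 * np.pi * xi)
        cells = LineageState.from_progenitor(C0)
        p0 = ReplicationField(np.full(n, 0.5))
        rhs = lineage_rhs(cells, p0, np.zeros(n), V, lp, grid)
        h = L / n
        flux = V * C0
        fd = -(np.roll(flux, -1) - np.roll(flux, 1)) / (2 * h)
        # smooth fields: second-order FD agrees to O(h^2)
        assert np.max(np.abs(rhs - fd)) < 10 * h**2 * np.max(np.abs(flux)) * (4 * np.pi / L) ** 3


class TestAblation:
    def _state(self):
        grid = Grid(64, 0.2)
        C0 = 0.8 * np.exp(-(((grid.xi - 0.3) / 0.05) ** 2))
        return LineageState.from_progenitor(C0), grid

    def test_half_removal_halves_density_in_region(self):
        cells, grid = self._state()
        region = (0.2, 0.4)
        out = ablate_progenitors(cells, region, 0.5)
        mask = (grid.xi >= 0.2) & (grid.xi < 0.4)
        assert np.allclose(out.C0[mask], 0.5 * cells.C0[mask])
        assert np.array_equal(out.C0[~mask], cells.C0[~mask])
        assert np.max(np.abs(out.C0 + out.C1 - 1.0)) == 0.0

    def test_full_removal_replaces_by_td_cells(self):
        cells, grid = self._state()
        out = ablate_progenitors(cells, (0.2, 0.4), 1.0)
        mask = (grid.xi >= 0.2) & (grid.xi < 0.4)
        assert np.all(out.C0[mask] == 0.0)
        assert np.all(out.C1[mask] == 1.0)

    def test_zero_fraction_is_identity_and_region_wraps(self):
        cells, _ = self._state()
        out = ablate_progenitors(cells, (0.9, 0.1), 0.0)
        assert np.array_equal(out.C0, cells.C0)
        with pytest.raises(ValueError):
            ablate_progenitors(cells, np.zeros(64, dtype=bool), 0.5)
        with pytest.raises(ValueError):
            ablate_progenitors(cells, (0.2, 0.4), 1.5)
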