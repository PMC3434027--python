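"""Linear stability analysis of the Wnt / Wnt-inhibitor kinetics.

The Wnt-inhibitor pair is the diffusion-driven (Turing) pair: Wnt is the
short-range self-activator, the inhibitor the long-range repressor.  The
pair is linearized about a homogeneous stationary state with the cell field
(hence the basal production mu0*c0) and BMP frozen at their uniform values
-- the cells vary on the slow clock.  A state is Turing-unstable when the
kinetics alone are stable (growth at k = 0 negative) but some finite
wavenumber grows; on the periodic domain of length L the admissible
wavenumbers are k_j = 2*pi*j/L, and the fastest-growing admissible mode
predicts the number of Wnt peaks, hence the crypt count.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

from .model_state import MorphogenParams
from .morphogen_dynamics import FixedPoints, _kinetics_jacobian_wi, homogeneous_fixed_point

__all__ = [
    "DispersionResult",
    "kinetics_jacobian",
    "dispersion_relation",
    "instability_map",
    "InstabilityMap",
    "predict_crypt_count",
    "ModeCountPrediction",
]


# ---------------------------------------------------------------------------
# Jacobian of the reaction kinetics
# ---------------------------------------------------------------------------


def kinetics_jacobian(
    W_star: float,
    I_star: float,
    c0: float,
    p: MorphogenParams,
    check_tol: Optional[float] = None,
) -> np.ndarray:
    """2x2 matrix of partial derivatives of the (Wnt, inhibitor) reaction
    terms at a homogeneous fixed point, BMP and cells frozen.

    The inhibitor row is (d f_I/dW, -d_I) -- the removal is linear.  Raises
    if (W*, I*) is not a fixed point of the kinetics at the given c0.
    """
    from .morphogen_dynamics import inhibitor_production, wnt_production

    if check_tol is None:
        check_tol = 1e-8 * max(p.alpha_W, p.d_W)
    rw = float(wnt_production(W_star, I_star, c0, p)) - p.d_W * W_star
    ri = float(inhibitor_production(W_star, p)) - p.d_I * I_star
    res = max(abs(rw), abs(ri))
    if res > check_tol:
        raise ValueError(f"(W*, I*) is not a homogeneous fixed point (residual {res:.3e})")
    return _kinetics_jacobian_wi(W_star, I_star, p)


# ---------------------------------------------------------------------------
# dispersion relation
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class DispersionResult:
    """Growth rate versus wavenumber for the linearized pair.

    ``wavenumbers[j]`` = 2*pi*j/L and ``growth_rates[j]`` is the leading real
    part of the eigenvalues of J - k^2 diag(D).  ``unstable_band`` is the
    continuum (k_min, k_max) with positive growth (None when empty);
    ``fastest_mode`` the admissible mode index with maximal growth;
    ``turing_unstable`` requires kinetic stability at k = 0 plus a
    non-empty band.
    """

    wavenumbers: np.ndarray
    growth_rates: np.ndarray
    unstable_band: Optional[tuple[float, float]]
    fastest_mode: int
    turing_unstable: bool
    L: float

    @property
    def fastest_growth(self) -> float:
        return float(self.growth_rates[self.fastest_mode])


def _growth(J: np.ndarray, D: np.ndarray, k: np.ndarray) -> np.ndarray:
    """max Re eig(J - k^2 diag D) for each k (closed form for 2x2)."""
    a = J[0, 0] - D[0] * k**2
    d = J[1, 1] - D[1] * k**2
    tr = a + d
    det = a * d - J[0, 1] * J[1, 0]
    disc = tr**2 - 4.0 * det
    sq = np.sqrt(np.abs(disc))
    return np.where(disc >= 0, (tr + sq) / 2.0, tr / 2.0)


def dispersion_relation(
    J: np.ndarray,
    D: tuple[float, float],
    L: float,
    n_modes: int = 64,
) -> DispersionResult:
    """Dispersion relation of the linearized reaction-diffusion pair.

    The continuum unstable band follows in closed form from the quadratic
    (in k^2) determinant det(J - k^2 diag D): with stable kinetics the trace
    stays negative for all k, so positive growth occurs exactly where the
    determinant is negative, between its two roots.
    """
    if L <= 0:
        raise ValueError("domain length must be positive")
    J = np.asarray(J, dtype=float)
    D = np.asarray(D, dtype=float)
    k = 2.0 * np.pi * np.arange(n_modes + 1) / L
    growth = _growth(J, D, k)
    kinetics_stable = _growth(J, D, np.array([0.0]))[0] < 0

    # roots of DW*DI*q^2 - (DI*J11 + DW*J22)*q + detJ = 0, q = k^2
    a = D[0] * D[1]
    b = -(D[1] * J[0, 0] + D[0] * J[1, 1])
    c = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
    disc = b**2 - 4.0 * a * c
    band = None
    if disc > 0:
        q1 = (-b - np.sqrt(disc)) / (2.0 * a)
        q2 = (-b + np.sqrt(disc)) / (2.0 * a)
        if q2 > 0:
            band = (float(np.sqrt(max(q1, 0.0))), float(np.sqrt(q2)))
    if not kinetics_stable:
        # growth already positive at k = 0: not a Turing band
        turing = False
    else:
        turing = band is not None and band[1] > band[0]
    if band is not None and kinetics_stable and band[1] <= band[0]:
        band = None
    fastest = int(np.argmax(growth))
    return DispersionResult(
        wavenumbers=k,
        growth_rates=growth,
        unstable_band=band if turing else None,
        fastest_mode=fastest,
        turing_unstable=bool(turing),
        L=L,
    )


# ---------------------------------------------------------------------------
# parameter-plane instability map
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class InstabilityMap:
    """Turing-instability classification over (D_I/D_W, d_I/d_W) ratios.

    ``unstable[i, j]`` refers to diffusion ratio i and removal ratio j;
    ``no_hss`` marks cells where no homogeneous state could be found.
    """

    diffusion_ratios: np.ndarray
    removal_ratios: np.ndarray
    unstable: np.ndarray
    no_hss: np.ndarray
    monotone_in_diffusion: bool


def _branch_turing(fp: FixedPoints, c0: float, p: MorphogenParams, L: float) -> bool:
    """True if any kinetically stable homogeneous branch is Turing-unstable."""
    for (W, I, _), stable in zip(fp.roots, fp.stable):
        if not stable:
            continue
        J = _kinetics_jacobian_wi(W, I, p)
        disp = dispersion_relation(J, (p.D_W, p.D_I), L)
        if disp.turing_unstable:
            return True
    return False


def instability_map(
    ratio_grid_D: np.ndarray,
    ratio_grid_d: np.ndarray,
    base: MorphogenParams,
    c0: float,
    L: float = 0.2,
) -> InstabilityMap:
    """Scan the (D_I/D_W, d_I/d_W) plane for Turing instability.

    Each cell rebuilds the parameter set with D_I = ratio * D_W and
    d_I = ratio * d_W, finds all homogeneous states, and classifies the cell
    unstable when any stable branch carries a band.  The map is checked for
    monotonicity along the diffusion-ratio axis (once unstable, larger
    ratios should stay unstable) and the flag reports violations.
    """
    rD = np.asarray(ratio_grid_D, dtype=float)
    rd = np.asarray(ratio_grid_d, dtype=float)
    if np.any(rD <= 0) or np.any(rd <= 0):
        raise ValueError("ratio grids must be positive")
    unstable = np.zeros((rD.size, rd.size), dtype=bool)
    no_hss = np.zeros_like(unstable)
    for i, rdiff in enumerate(rD):
        for j, rrem in enumerate(rd):
            p = base.model_copy(update={"D_I": rdiff * base.D_W, "d_I": rrem * base.d_W})
            try:
                fp = homogeneous_fixed_point(c0, 1.0 - c0, p)
            except RuntimeError:
                no_hss[i, j] = True
                continue
            unstable[i, j] = _branch_turing(fp, c0, p, L)
    monotone = True
    for j in range(rd.size):
        col = unstable[:, j]
        first = np.argmax(col) if col.any() else None
        if first is not None and not col[first:].all():
            monotone = False
    return InstabilityMap(rD, rd, unstable, no_hss, monotone)


# ---------------------------------------------------------------------------
# mode-count prediction
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class ModeCountPrediction:
    """Predicted number of Wnt peaks (= crypt count) from linear theory."""

    count: int
    status: str  # "turing" or "stable"
    dispersion: Optional[DispersionResult]
    base_state: tuple[float, float, float]


def predict_crypt_count(p: MorphogenParams, c0: float, L: float) -> ModeCountPrediction:
    """Fastest-growing admissible mode about the pattern-forming branch.

    Returns count 0 with status "stable" when no kinetically stable branch
    has an unstable band.
    """
    fp = homogeneous_fixed_point(c0, 1.0 - c0, p)
    best: Optional[DispersionResult] = None
    base = fp.selected_root
    for (W, I, B), stable in zip(fp.roots, fp.stable):
        if not stable:
            continue
        J = _kinetics_jacobian_wi(W, I, p)
        disp = dispersion_relation(J, (p.D_W, p.D_I), L)
        if disp.turing_unstable and (best is None or disp.fastest_growth > best.fastest_growth):
            best = disp
            base = (W, I, B)
    if best is None:
        return ModeCountPrediction(0, "stable", None, fp.selected_root)
    return ModeCountPrediction(best.fastest_mode, "turing", best, base)
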