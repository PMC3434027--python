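# Model and numerical methods

`cryptmorph` simulates the spontaneous formation, regeneration and
(in)stability of intestinal crypts as the interaction of a two-stage cell
lineage with three secreted signals on a one-dimensional periodic tissue
whose length can change and whose shape is rendered as a planar curve.

## The model

**Cell lineage.** The epithelium is a confluent line of cells at constant
total density: a progenitor fraction `C0(s,t)` (stem plus transit-amplifying
cells) and a terminally differentiated (TD) fraction `C1 = 1 - C0`.
Progenitors divide at rate `v0`; each division yields progenitors with
replication probability `p0` and TD cells otherwise; TD cells are removed at
rate `d1(s)`.  Incompressibility closes the system with a cell velocity `V`:

    dC0/dt + d(V C0)/ds = v0 (2 p0 - 1) C0 + motility * d2C0/ds2
    dV/ds               = v0 C0 - d1 C1                       (closure)

Only `C0` is integrated; `C1 = 1 - C0` holds *by construction*, making the
normalization invariant structural rather than numerical.  The velocity is
the zero-mean periodic antiderivative of the fluctuating part of the
closure source; the mean of the source is the specific growth rate of the
tissue (below).  The small `motility` term is cell-level random migration;
it is also what keeps the compressive fronts at crypt boundaries at a
finite width (a pure advection closure steepens them to the grid scale at
any resolution).

**Replication control.**

    p0 = p0_max (gW W)^n / (1 + (gW W)^n + (gB B)^m)

Wnt (`W`) promotes self-renewal, BMP (`B`) suppresses it; `gW`, `gB` are
reciprocal EC50s, i.e. feedback strengths.

**Signals.** Wnt, a diffusible Wnt inhibitor `I`, and BMP obey
reaction–diffusion equations.  Wnt is produced by progenitors (`mu0 C0`)
and by a saturating autocatalytic term repressed by the inhibitor; the
inhibitor is induced by Wnt; BMP is produced linearly by TD cells.  Wnt is
short-ranged, the inhibitor long-ranged: the pair is a classical
activator–inhibitor Turing system, and its patterned state dictates where
progenitors accumulate — crypts form at Wnt peaks.

**Quasi-steady molecules.** Molecular kinetics run on a clock of seconds,
cells on the cell-cycle clock; at every cell step the three fields are
replaced by a stationary state of their reaction–diffusion system at frozen
cells.  Molecular convection by the slow cell flow is dropped at quasi-steady
state (`numerics.qss_include_advection` retains it for sensitivity checks).

**Geometry.** The crypt line is an open planar curve with endpoints pinned
at (-0.1, 0) and (0.1, 0).  An energy functional penalises deviation from a
target profile in which every crypt segment (contiguous arc of elevated
`C0`) digs a tanh-shaped well of depth proportional to its peak progenitor
density; the curve relaxes by gradient flow of this energy.  The periodic
cell coordinate is cut at the progenitor minimum so the pinned endpoints
never bisect a crypt, and the well profile is tapered to zero over `2*eps0`
at the endpoints so the energy minimum is exactly attainable.

**Growing domain.** The tissue length obeys

    dL/dt = min(P, cap_rate * (L_cap - L)),     P = Int (v0 C0 - d1 C1) ds

`P` is net cell production; `L_cap` is the arclength of the fully relaxed
energy-minimising curve (`depth_gain` deep wells per unit peak density).
While the geometry has capacity, length growth *is* the integrated net
production, so the total cell number audit `d/dt Int (C0+C1) ds = P` holds
exactly.  Production beyond the geometric capacity is shed — uniform
extrusion into the lumen, the tissue staying confluent.  Because shedding
removes both cell types in proportion, the composition equation carries the
full `-(P/L) C0` damping (dilution plus shedding) in either regime; only
the length update changes.  Fields live on the fixed computational
coordinate `xi = s/L` (Lagrangian-in-xi convention), so point values never
interpolate when `L` changes.

Several headline experiments (formation, removal-rate scans, regeneration,
the phase diagram) are run on a *frozen* domain — shedding absorbs all net
production and the analysis concerns the pattern, not the growth.  The
growing domain is exercised by the knockout/phase-diagram scenarios and the
growth-episode consistency checks.

## Linear (Turing) analysis

The Wnt/inhibitor pair is linearized about homogeneous stationary states
with cells and BMP frozen (the cells move on the slow clock).  All roots of
the scalar reduced Wnt equation are located by a dense bracketing scan plus
Brent refinement; per-branch dispersion relations
`growth(k) = max Re eig(J - k^2 diag(D_W, D_I))` use the closed 2x2 form,
and the continuum unstable band follows from the quadratic (in `k^2`)
determinant.  On the periodic domain admissible modes are `k_j = 2 pi j / L`
and the fastest-growing admissible mode predicts the number of Wnt peaks,
hence crypts.  The analysis also produces the (D_I/D_W, d_I/d_W)
instability map: patterning requires the inhibitor to spread far
(`D_I/D_W` large) and adapt rapidly (`d_I/d_W` not too small).

## Parameters

All defaults are package-calibrated (the calibration targets: a mode-2
instability of the uniform `c0 = 0.1` state on the initial domain, a stable
two-crypt nonlinear steady state, and a removal-rate sweep along which the
predicted and realised crypt counts climb together).  Units: cell time in
units of cell-cycle/ln 2 (`v0 = 1`), molecular rates per second (only the
ratios `D/d` and production/removal matter after the quasi-steady
reduction), concentrations in uM, lengths with the initial domain at 0.2.

| parameter | value | meaning |
|---|---|---|
| `v0` | 1 | progenitor turnover rate (defines the cell clock) |
| `p0_max` | 1 | maximal replication probability |
| `gamma_W`, `n` | 4, 2 | Wnt feedback strength / Hill exponent on `p0` |
| `gamma_B`, `m` | 5, 2 | BMP feedback strength / Hill exponent on `p0` |
| `d1_max` | 0.35 | TD removal rate (apex-localized profile, floor 0.1 x) |
| `cell_motility` | 5e-6 | random cell migration (front regularisation) |
| `D_W, D_I, D_B` | 1.6e-7, 9.6e-6, 1.26e-6 | diffusivities (length^2/s) |
| `mu0, mu1` | 1.2e-4, 2.5e-4 | cell-bound production of Wnt / BMP (uM/s) |
| `alpha_W, beta_W, n_W` | 0.114, 1, 2 | Wnt autocatalysis (rate, EC50^-1, Hill) |
| `alpha_I, beta_W_inh, n_I` | 1.2e-2, 1, 2 | inhibitor induction by Wnt |
| `beta_I, m_W` | 16, 2 | inhibitor repression of Wnt |
| `d_W, d_I, d_B` | 2e-3, 4e-3, 1.4e-3 | removal rates (1/s) |
| `epsilon0` | 0.01 | crypt shape sharpness (length) |
| `depth_gain` | 0.15 | crypt depth per unit peak density (sets `L_cap`) |
| `n_points`, `dt` | 256, 1e-3 | grid, cell-clock step (tests/scans use 128, 2e-3) |

Worth knowing about this operating point:

- The uniform `c0 = 0.1` state is *monostable* on the pattern-forming
  branch (`W* = 0.30`), so formation needs only low fluctuating Wnt.  At
  removal rates above ~3x the kinetics become bistable and a low Wnt state
  is inert; the removal-rate sweep therefore seeds the pattern-forming
  branch with its fastest mode at small amplitude — the clean nonlinear
  realisation of the instability being predicted.
- The inhibitor repression operates deep in saturation
  (`(beta_I I*)^2 ~ 15`), which is what lets the Turing branch survive
  proportional scaling of both removal rates with the mode number growing
  like `sqrt(d_W)` — more removal, more crypts.
- `d_I/d_W = 2`: damping of the uniform Wnt/inhibitor spiral.  At ratios
  near 1 the uniform kinetics has a stable limit cycle and never settles.
- BMP is crypt-local (`l_B = sqrt(D_B/d_B) ~ 0.03`); with a long-ranged
  BMP pool the crypts compete through it (winner-takes-all coarsening).

## Numerics

- **Space:** Fourier collocation on the periodic `xi` grid; derivatives and
  Helmholtz solves exact in the spectral sense; an exponential filter on
  the top third of modes is applied to the advective flux derivative
  *inside* the right-hand side, so any reference integrator sees the same
  vector field.
- **Cells in time:** Heun (RK2) on the reduced `(C0, L)` system; no stiff
  term remains once the molecules are eliminated.  Halving `dt` changes
  the formation transient by < 1e-3.  Positivity is monitored
  (`positivity_tol`, default 1e-8); a short grace window after
  discontinuous interventions (exact ablation steps) lets motility smooth
  the data first.  Runs stop early on extinction (max C0 below 1e-4) or
  domain collapse (L below half its initial value).
- **Molecules:** BMP is linear and solved exactly in Fourier space.  The
  Wnt/inhibitor stationary system is relaxed in pseudo-time — semi-implicit
  in removal+diffusion, explicit in production, with the near-neutral k=0
  spiral advanced by backward Euler and the step bounded by the local
  production Jacobian.  Pseudo-time *is* the fast molecular dynamics: it
  leaves Turing-unstable homogeneous states along their growing modes and
  settles only on stable stationary states, which is the physically correct
  quasi-steady state; a Newton polish accelerates the endgame and is armed
  only when the residual is shrinking or stagnant, with results that land
  on the (recognisable) homogeneous saddle refused.  When a depinned Wnt
  front leaves no nearby stationary state, a stagnant residual below
  `max(10 qss_tol, 1e-5 alpha_W)` is accepted and the slow drift is carried
  across cell steps.
- **Geometry:** explicit preconditioned descent with backtracking (the
  energy never increases across a step); by default only `y` flows — the
  `x`-gradient of this energy is a near-degenerate reparameterization
  direction that lets nodes drift off the endpoint window
  (`geometry.flow_in_x` re-enables it).  The depth scale is matched to the
  current length by bracketing/Brent on the relaxed target arclength.
- **Steady detection:** max-norm `dC0/dt` below `steady_tol` (1e-6) over a
  sliding unit-time window.
- Identical config and seed give bit-identical trajectories; the crypt
  count and tip density of the formation steady state are unchanged from
  128 to 256 grid points.

## What the synthetic initial states emulate — and what they do not

The generator produces the study's initial conditions: uniform cells with
low band-limited Wnt noise (de-novo formation), alternative random Wnt
fields, exact localized progenitor spots, and snapshot restarts.  These are
idealisations: real crypt formation starts from a tissue with cellular
discreteness, anisotropic geometry and signalling beyond Wnt/BMP.  Passing
tests therefore demonstrate the *mechanism* — short-range activation plus
long-range inhibition patterning a proliferative lineage — not a
quantitative match to any tissue.  Where single cells dominate (e.g.
recolonisation of a fully ablated crypt through a handful of migrating
progenitors) a continuum density is a coarse description.

## Known limitations

- A stable single crypt does not exist on the default domain at default
  removal rates (mode 2 wins); the exogenous-Wnt protocol therefore
  constructs its single-crypt baseline at 1.78x removal, where one crypt is
  the attractor.
- Localized seeds below the Wnt ignition threshold (`C0 ~ 0.1` over a tenth
  of the domain, at default `mu0`) fail to establish a crypt; seeds at
  0.5 and 1.0 ignite and converge to the same final state.  Spots ignite
  the wavelength-matched antipodal site as well, so a single seed yields
  the two-crypt attractor, not one crypt.
- At the 2-to-3 mode boundary of the removal sweep (~1.78x) neither array
  is an attractor and the pattern coarsens to a single crypt; the default
  sweep factors {1, 1.19, 1.41, 2, 2.83} avoid that knife-edge, and wider
  user scans report trend violations in the scan summary.
- On the frozen domain the TD death-rate scan *raises* the homeostatic
  progenitor mean (`<C0> = <d1 C1>/v0`), so peak and total progenitor
  density increase with `d1` — the opposite of what an unconstrained
  growing tissue shows.
- Under the bounded-density closure, an "unstable progenitor pool" appears
  as progenitor take-over (tip density >= 0.8, mean fraction >= 0.35)
  rather than literally unbounded mass, and regeneration is compared modulo
  the translation gauge of the periodic domain (sub-grid phase alignment).
- The alternative fingering/branching energy functional is not included;
  the energy interface accepts the tanh-well form only (`energy_kind`).
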