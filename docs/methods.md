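# Model and methods

## The model

`notchwnt` simulates cells of the intestinal crypt epithelium, each running
a twelve-species reaction network coupling the Notch pathway (cell-fate
specification) to the canonical Wnt pathway (mitotic regulation) through
the Hes1 promoter.

**Notch submodel (7 species).** Delta ligand `D` on a neighbouring cell
binds Notch receptor `N`, whose cleavage releases NICD `F`. NICD binds
β-catenin to form the transcriptionally active complex `I1`, which drives
Hes1 (`H1`) production. Hes1 represses its own promoter, represses the
proneural factor Ngn3 (`P`) — which would otherwise upregulate Delta — and
represses Hath1 (`H2`), the secretory-fate readout. The loop
`N → F → I1 → H1 ⊣ P → D → (neighbour) N` implements lateral inhibition
between cells; in a single "homogeneous" cell (mean neighbouring Delta
identified with the cell's own Delta) it is a delayed negative feedback
loop that supports oscillations.

**Wnt submodel (5 species).** Free GSK3β `G` is incorporated into the
destruction complex `C` at a rate `Ψ_{W,A}` that increases with the Axin
level `A` and is repressed by the extracellular Wnt stimulus `W`; the
complex binds β-catenin `B` into `I2`, whose degradation returns only `C`
to the pool (the pool `G + C + I2` is closed by default and set by the
initial condition; a config flag adds first-order decay to `G` and `C`).
β-catenin is produced at rate `α₃ + α₄·W` and transcribes Axin, closing a
negative feedback.

**Crosstalk.** Three points: NICD sequesters β-catenin into `I1`
(mass-action, rate `k₃`); `I1` drives the *Notch-mediated* route of Hes1
transcription (weight `θ₂`); β-catenin drives the *Wnt-mediated* route
directly with weight `1 − θ₂`, without being consumed. A further
Wnt-dependent factor `Ψ_W` (Dishevelled acting on the promoter, not
modelled as a species) represses Hes1 production as `W` rises. Productions
use Hill functions, inhibitions the complementary hyperbolas, decays are
first order; Hill exponents are m = n = 3, reflecting the cooperativity
needed to oscillate without an explicit transcriptional delay.

Units are nM and minutes; `W` is dimensionless with `W = 1` ≡ 100 ng/ml
(`W = 0` crypt orifice, `W = 1` crypt base, `W = 2` hyperstimulation).

## Calibration of the shipped defaults

The defaults were produced with the package's own calibration machinery
(`notchwnt.calibration`), in three stages, and then frozen.

1. **Wnt side.** The decoupled Wnt submodel (NICD reference 0) has a unique
   β-catenin steady state `B*(W)` for every stimulus (the total destruction
   flux is strictly increasing in `B`). The production coefficients
   `(α₃, α₄)` follow in closed form from any two pinned values `B*(Wᵢ) = bᵢ`
   (`fit_bstar_two_point`); the remaining shape constants were solved so
   that `B*(1) = 25 nM` with hyperstimulation fold changes
   `B*(2)/B*(1) = 2.2` and `B*(2)/B*(0) = 8.3`, the observed fold-change
   behaviour of hyperstimulated mutants. Two further constraints were
   imposed during this solve:
   * `α₄` carries the largest normalised sensitivity `NS` of `B*` among the
     Wnt-side parameters. This is *not* automatic: when the destruction
     flux is `k_CB·C·B` with `I2` sequestration and a saturated Axin
     feedback, `NS(k_CB) = −1` identically and `α₄` cannot reach 1. The
     shipped set therefore keeps the Axin feedback responsive (`κ_A`,
     `κ_GA` inside their operating ranges), which pulls `|NS(k_CB)|`
     below `NS(α₄)`.
   * `NS_{B*}(α₄) < 1`, because the period sensitivity of every Wnt
     parameter other than `κ₇` is proportional to its `B*` sensitivity;
     `κ₇` can only rank first for the period if `α₄`'s influence on `B*`
     is slightly sub-proportional.
2. **Notch side.** With `B` fixed at `b_ref = B*(1)`, the seven-species
   decoupled Notch pair was centred so that each regulated species sits
   near its half-saturation point, then tuned (grid searches over the
   promoter constants, followed by a uniform time rescale of the loop
   rates, which changes no steady state) so that a homogeneous pair shows
   damped Hes1 oscillations of period ≈ 2.2 h — within 10% of the 2 h
   benchmark — while the θ₂/W regime map behaves as described below. NICD
   consumption is dominated by β-catenin binding (`k₃·B ≫ μ_F`), which
   makes the `I1` input to the promoter nearly independent of the Wnt
   level; without this the Notch oscillator would die at `W = 0` where
   β-catenin is low.
3. **Hes1 concentration scale.** The joint rescaling of `α_H1, κ₅, κ₂, κ₆`
   is an exact output scaling of the deterministic system: every
   trajectory's Hes1 branch scales and nothing else changes. No
   concentration value pins it, so it was chosen such that additive noise
   of σ = 1 nM on the Hes1 production term is a moderate perturbation —
   stochastic runs switch pattern in a substantial minority of cases
   rather than always or never.

Axin turnover is fast (`μ_A = 0.2 min⁻¹`): slow Axin gives the
`B → A → C → B` feedback enough phase lag to ring at zero Wnt, producing
small spurious Hes1 oscillations through the promoter's steep response at
low β-catenin.

## Dynamic regimes

With the defaults, a heterogeneous healthy pair (Notch species at
0.50/0.51 nM, Wnt species at the `W`-appropriate steady state) shows:

* `θ₂ = 1` (purely Notch-mediated), `W ∈ {0, 1}` — Hes1 oscillations of
  ≈ 2 h that persist through the standard measurement window, with a
  slowly growing inter-cell difference (the patterned state forms on a
  longer timescale);
* `θ₂ = 0.75` (the standard mix) — transient oscillation followed by a
  patterned, bistable state: one high-Hes1 (absorptive-like) and one
  low-Hes1 (secretory-like) cell, the lateral-inhibition outcome;
* `θ₂ ≤ 0.55` or `W = 2` — oscillations damp within the window and the
  pair settles homogeneously; the Wnt-mediated route and the
  Dsh-mediated repression both stabilise the promoter.

Oscillation is measured by the calibration protocol throughout: discard a
2 h transient, detect maxima over the following 12 h (sub-grid parabolic
peak refinement), average the inter-peak intervals, and disregard
oscillations with peak-to-trough amplitude below 0.001 nM. The regime
classifier labels a pair `oscillatory` if the filtered oscillation
persists through this window, else `heterogeneous-bistable` if the cells
disagree by more than 5% at the horizon, else `homogeneous-steady`. At
near-parity promoter mixing with zero Wnt (θ₂ ≈ 0.55, W = 0) damping is
weaker than at `W = 1`; the shipped set settles there too, but this corner
is the least robust of the map.

## Structural analysis and its limits

`notchwnt.network` exports the reaction network (species, integer
stoichiometry, promoter/inhibitor influence annotations) in a line-based
dialect for the external concordance toolbox, and provides a *numerical
multistability surrogate*: log-uniform parameter draws (×/÷10 around the
defaults) with a deduplicated multistart steady-state search. A
`multistable` verdict (two distinct non-negative roots for any draw) is
positive evidence; `monostable` is one-sided and flagged as such.

One structural fact matters when interpreting the surrogate against the
published concordance pattern: under the canonical Hill instantiation the
*homogeneous* reduction is provably monostable whenever Hes1 transcription
is purely Notch-mediated — eliminating species pairwise leaves a strictly
decreasing scalar residual in NICD, so exactly one steady state exists for
every parameter set. The discordance results of reaction-network theory
are existence statements over all weakly monotonic kinetics, not about any
particular instantiation; the surrogate accordingly reproduces the
monostable cells of the pattern but cannot exhibit the multistable ones.
The multistability those cells describe appears dynamically in the
*coupled pair* (the patterned states above) rather than in the
single-cell reduction.

## Stochastic extension

Extrinsic noise enters only the Hes1 production term, on a fixed-step
Euler scheme: in `wiener` mode the state increment is `σ√dt·Z`
(step-size-consistent Euler–Maruyama); in `literal` mode `N(0, σ²)` is
added to the Hes1 time derivative at each step. The pattern-switching
experiment uses the literal mode with dt = 0.1 min, σ = 1, on the bistable
θ₂ = 0.75, W = 0 pair over 24 h: noise erases the 2% initial asymmetry
during the undecided phase, so a substantial fraction of runs locks into
the opposite patterned state from the deterministic run. Negative
intermediate concentrations are clipped to zero; ensembles are
reproducible from a single seed.

## Sensitivity and fitting

Local sensitivities are forward differences `S_k = (X(k+δk) − X(k))/δk`
with `δk = 0.01·k` by default, normalised as `NS_k = (k/X)·S_k`. The
ranked set for both scalar outputs (`B*` and the Hes1 period) is the
Wnt-side parameter list: the constants of the Wnt-submodel ODEs plus
`κ₇`, the dissociation constant of the β-catenin route at the Hes1
promoter. `κ_Ψ` (Dishevelled repression of the promoter) is treated as
promoter machinery, not a Wnt-pathway parameter; the ranking is not
meaningful across that boundary because `Ψ_W` multiplies the whole
production term. On the shipped defaults `α₄` ranks first for `B*` and
`κ₇` first for the period.

The sequential fit sweeps each free parameter in ranking order over a
linear grid of 1000 values spanning ±100% of its current value, accepts
the grid minimiser (ties broken toward the smallest change), and loops
until the objective drops below a relative tolerance (default 1%).
Parameter-recovery tests use noise-free synthetic timecourses with six
observations over three hours; the fit recovers a perturbed production
coefficient to within one grid step. The scheme is a local coordinate
search and makes no claim to global optimality.

## Numerical choices

* Deterministic integration: LSODA with rtol 1e-8, atol 1e-10 (period
  measurements are tolerance-sensitive); events are handled by stopping
  and restarting the solver with the updated environment, so the state is
  continuous across mutations.
* Steady states: multistart damped root finding (`hybr`) on the
  homogeneous vector field with the redundant destruction-complex balance
  replaced by the GSK-pool constraint; starts are log-uniform over a
  physiological box plus long-integration endpoints; accepted roots must
  satisfy `max|rhs| < 1e-10` and are deduplicated at relative 1e-4 with an
  absolute floor of 1e-6 nM (1e-4 in the parameter-drawn probe, where
  solver precision scales with the drawn rates).
* Stability labels drop the structural zero eigenvalue contributed by the
  closed pool.
* The amplitude filter (0.001 nM) and the 2 h + 12 h measurement window
  follow the calibration protocol; simulations default to 36 h horizons
  for regime classification and 16 h for period measurement — large enough
  for the classifications to be unambiguous at the shipped tolerances
  while keeping sweeps fast.

## What the synthetic data do and do not show

The fixture generator (`generate_synthetic_target`) samples the model's
own deterministic trajectories and adds i.i.d. Gaussian noise. It
emulates sparse, noisy timecourse sampling of a single observable, but
not: systematic measurement bias, cell-to-cell parameter variability,
intrinsic (copy-number) stochasticity, or model misspecification. Passing
recovery tests therefore demonstrate that the fitting procedure inverts
the model under ideal conditions, not that the model or its parameters
are identified by real data.

## Known limitations

* No nucleus/cytoplasm compartments, no Hes1 mRNA/dimerisation/delay, no
  explicit Dishevelled species; Hath1 is a pure readout.
* Cell graphs are static (no division, death or movement) and the Wnt
  field is prescribed per cell.
* The reduced 4-equation Notch steady-state analysis (NICD and `I1`
  proportional to Notch) is not exposed; the full system is analysed
  numerically instead.
* Fold-change targets are imposed at the decoupled steady state; the
  coupled pair reproduces them to ≈ 1% because crosstalk consumption of
  β-catenin is a few percent of its production.
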