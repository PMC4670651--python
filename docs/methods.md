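# Methods

`aggimmuno` contains two independent mechanistic simulators addressing the
same scientific question: through which pathway can aggregates of a
therapeutic protein product (TPP) drive anti-drug-antibody (ADA)
responses?  The first asks whether aggregates can activate B cells
directly, without T-cell help, by cross-linking B cell receptors (BCR).
The second asks how aggregate-associated perturbations — faster antigen
uptake or processing, extra or higher-affinity MHC class II epitopes, and
a stronger innate danger signal — propagate to ADA output in a
T-cell-dependent response.

## 1. Multivalent aggregate–BCR cross-linking

### Model

An aggregate is a homogeneous particle of `n` monomers, each contributing
one BCR binding site (valency `n`, default 100; physiological range
10–100).  Binding is sequential:

    Ag_a + BCR            <-> Ag_aBCR_1
    Ag_aBCR_{i-1} + BCR   <-> Ag_aBCR_i        (i = 2..n)

A BCR may attach to any free site and detach from any bound site, so the
mass-action fluxes carry statistical factors: binding into `Ag_aBCR_i`
proceeds at `(n−i+1)·k_i·[BCR]·[Ag_aBCR_{i−1}]` and dissociation out of it
at `i·k_{−i}·[Ag_aBCR_i]`.  These factors make conservation of total
aggregate and of total BCR (free + site-weighted bound) exact by
construction; both are verified numerically to 1e−6 relative tolerance in
the tests.

Rates: the per-site binding rate is constant, `k_i = k_on = 8.64e−3
pM⁻¹ day⁻¹`, the scale typical of antibody–antigen association.  The
per-bond dissociation rate decays geometrically with bond number,
`k_{−i} = (k_on/Ka)·b^{i−1}` with base `b = 0.5`, so that
`Ka = k_1/k_{−1}` holds exactly and multi-point attachment is increasingly
stable (avidity).  The base is exposed as `decay_base`; `b = 1` recovers
bond-independent kinetics.

Initial conditions: `[Ag_a⁰] = [Ag]·p/n` from total drug `[Ag]`
(500–1e5 pM), aggregation fraction `p` (2–15%) and valency; the free-BCR
pool is `receptors/cell × B cells/L × antigen-specific fraction`,
converted to pM with Avogadro's number (1e5 receptors/cell and 1e8
B cells/L give 16.6 pM at fraction 1).

### Readout

The signal-transducing complex (STC) count is `STC = Σ_{i≥s} [Ag_aBCR_i]`
— aggregates cross-linking at least `s` receptors (`s` of order 2–15 is
the reported activation requirement).  `stc_per_cell` converts to
molecules per liter and divides by the antigen-specific B-cell
concentration (`B cells/L × fraction`), because the BCR pool in the ODEs
is built from that same fraction.

### Time horizon: why equilibrium is the wrong target

With a geometrically decaying `k_{−i}`, deep complexes are effectively
irreversible: `k_{−100} ≈ k_{−1}·2^{−99}`.  The network's true chemical
equilibrium is therefore degenerate — detailed balance puts essentially
all receptors into maximum-occupancy complexes regardless of `Ka` — but
reaching it requires climbing a ladder of bimolecular steps whose rates
collapse with the free-receptor concentration; relaxation times exceed any
physiological horizon by many orders of magnitude.  The meaningful readout
is the metastable plateau the system reaches after the fast capture
transient.  `simulate` therefore integrates with a stiff-capable solver
(LSODA, rtol 1e−8, atol 1e−12 pM) to a hard cap of `t_end = 100` days,
stopping earlier only if every species' relative rate of change falls
below 1e−9/day; `cap_hit`/`quasi_steady` flags record which rule stopped
the run.  The plateau is insensitive to the horizon (readouts are flat
from ~10 to 100 days across the default grid), so the cap choice does not
steer the results.  The stopping criterion is per-species on purpose: a
criterion scaled by the conserved totals goes quiet during the slow
cascade and truncates the trace complexes that constitute the STC signal.

### Sweeps and thresholds

`sweep` evaluates `stc_per_cell` over the grid Ka ∈ {1e−7, 1e−5, 1e−3}
pM⁻¹ × [Ag_a⁰] ∈ {0.1, 12, 1500} pM × a fraction ladder up to 1%, for
s ∈ {2, 5, 10}, one row per grid point per s, with per-row failure
status rather than aborting.  `fraction_threshold` bisects the
antigen-specific fraction (log-space, bracket [1e−7, 1e−2], relative
tolerance 1e−3) for the smallest fraction reaching a target STC/cell,
after probing that the readout is nondecreasing in the fraction; an
unreachable target returns a "not attained" sentinel rather than raising.

On the default grid the model reproduces the qualitative findings: STC
never reaches one per cell for s = 5 or 10 anywhere, nor for low-affinity
antibodies (Ka = 1e−7 pM⁻¹) at s = 2, and at mid affinity only the
highest aggregate level near the 1% fraction limit exceeds one.  For
affinity-matured antibodies (Ka = 1e−3 pM⁻¹) all three aggregate levels
exceed one STC per cell only above a common fraction threshold; in this
implementation that worst-case threshold is ≈0.09% (per-level thresholds
0.062%, 0.0025% and 0.092%), an order of magnitude above the ~0.006%
sometimes quoted for this configuration.  The discrepancy is structural,
not a horizon artifact (see above); the package reports what its
mechanically derived scheme computes.

### Stochastic validation oracle

`ssa` implements the direct-method (Gillespie) event simulation of the
identical reaction network at integer copy numbers in a virtual volume
(≤1e4 molecules), with per-pair binding propensity
`k_on/(N_A·V)` and the same statistical factors.  For mass-action kinetics
the method is exact, so replicate means must match the ODE solution up to
finite-copy-number effects; the tests require agreement within three
standard errors at n = 2 and n = 4 with hundreds of molecules, and exact
integer conservation per replicate.  The oracle validates the ODE engine
and is never used as the production path.

## 2. T-cell-dependent ADA induction

### Scope and calibration philosophy

This module is a deliberately minimal ODE instantiation of the multiscale
ADA induction cascade (whole-body PK → endosomal antigen presentation →
cellular activation → affinity-structured ADA).  The printed anchor
values are used verbatim: internalization rate IR₀ = 14.4 day⁻¹,
degradation rate DR₀ = 17.28 day⁻¹, epitope MHC II affinities
{123, 85} nM (high-affinity set), {1230, 850} nM (µM-range set) and 38 nM
(aggregate-induced epitope), danger signal 350 ng LPS-equivalent at
baseline, biweekly doses of 0.04–40 mg, 17 ADA affinity subgroups, and
16.6-fold rate perturbations.  Every remaining rate constant is a single
frozen calibration, chosen once for mechanistic plausibility and shipped
as the dataclass defaults; no scenario overrides them.

### Whole-body scale

Two-compartment PK with a subcutaneous depot: absorption `ka = 0.25/d`,
central–peripheral exchange 0.3/0.15 per day, linear elimination
0.0462/d (t½ ≈ 15 d, IgG-like), central volume 3 L, dose converted from
mg with a configurable molecular weight (default 150 kg/mol).  Total ADA
adds a clearance term `k_ada·ADA_total·C` (default 1e−5 pM⁻¹d⁻¹), so a
strong ADA response measurably reduces exposure without dominating the
baseline kinetics.

### Subcellular scale

Endosomal antigen `E` obeys `dE/dt = IR·c_plasma − DR·E`; each epitope j
has a peptide pool `dP_j/dt = copies_j·DR·E − d_P·P_j` (`d_P = 10/d`).
Two identities hold in closed form and are verified to 1e−6: `E* ∝
IR/DR` (so 16.6× DR empties the endosome exactly 16.6-fold and 16.6× IR
fills it 16.6-fold), and `P_j*` is independent of DR — degradation speed
relocates antigen, it does not create peptide.  Loading onto a finite
surface pool (`MHC_total = 1e5` per APC) is competitive and saturable:
`dM_j/dt = k_load·MHC_free·P_j/(K_m + ΣP) − k_surf·Kd_j·M_j` with
`k_load = 1/d`, `K_m = 1e−4` (peptide units) and `k_surf = 0.1 d⁻¹nM⁻¹`.
Because `ΣP ≫ K_m` throughout the dose range, presentation is
supply-saturated: scaling all peptide pools (e.g. by raising IR) leaves
`M_j` unchanged, while the per-epitope surface loss ∝ Kd makes
high-affinity epitopes accumulate more complexes.  These two structural
facts — IR-insensitivity and affinity-dominance of presentation — are the
mechanistic core of the module.

### Cellular scale

Dendritic-cell maturation is a Hill function of the danger signal
(EC50 = 5000 ng, coefficient 2); with the 350 ng baseline deep in the
rising limb, a 5× danger-signal step amplifies T help ≈22-fold, which
propagates linearly to cumulative ADA (the observed ~20-fold class of
behavior).  T-cell help is `matureDC × Hill(max_j M_j; M50 = 2000,
coefficient 2)` — the best-presented epitope drives help, so adding
epitopes that merely split the peptide supply does not increase (in fact
slightly decreases) activation, whereas one epitope clearing the M50
threshold switches help on.  B cells occupy a 17-rung geometric ladder of
antigen-binding Kd from 1 µM down to 0.1 nM; rung i precursors (relative
abundance 0.5^{i−1}, rare high-affinity clones) activate at a rate ∝
T help × drug occupancy `C/(C+Kd_i)`, drift one rung up at
`k_mat = 0.4/d` (affinity maturation), differentiate into plasma cells
(0.1/d) that secrete subgroup ADA (100 pM/d per cell unit, decay
0.033/d).  `ADA_total` is the exact subgroup sum at every time point and
is the quantity all fold changes are computed from, as the time integral
(cumulative ADA) over the simulated course — trajectories are pulsatile
under repeated dosing, and the integral is the robust scalar.

Default course: 6 biweekly doses plus a 28-day washout (112 days), output
grid 0.1 day, all scales integrated as one coupled stiff system with
bolus depot resets at dose times.

### What the scenario generator does and does not emulate

The preset catalogue holds exactly the published parameter combinations:
the cross-linking grid; the danger-signal ladder (1750/350 ng printed,
sub-baseline rungs {175, 70, 35, 7} ng are synthetic stand-ins); the
16.6× IR/DR perturbations on the high-affinity epitope set; 2/3/4
epitopes (the added 500 and 1000 nM values are synthetic stand-ins inside
the µM–nM window); the µM-affinity baseline ± 16.6× IR ± the 38 nM
epitope; and that triplet crossed with the four-dose ladder.
`random_grid` samples the cross-linking parameter space log-uniformly
inside the physiological bounds for property tests.

The generator emulates parameter scenarios, not data: there is no
biological variability, no measurement noise, no patient-to-patient PK or
HLA diversity, and aggregate state enters only through the five named
perturbation channels.  Passing tests therefore demonstrate internal
consistency and the stated mechanistic consequences under these idealized
conditions — they do not validate the calibration against clinical ADA
incidence.

### Numerical choices and degenerate inputs

LSODA throughout (the cross-linking system is stiff: `k_{−1}` spans
8.64–8.64e4 day⁻¹ across the Ka grid).  Valency n = 1 collapses to simple
bimolecular binding and is supported (and used as the closed-form check,
via the cancellation-free quadratic root).  Zero dose, zero danger signal
and zero aggregate all yield identically zero responses rather than
errors; `k_on = 0` freezes the stochastic system (valid absorbing state).
The T-help driver `max_j M_j` is non-smooth at argmax switches; LSODA
handles the mild discontinuity, and ties at `M = 0` resolve to zero help.
Cumulative ADA uses trapezoidal integration on the 0.1-day grid.

### Known limitations

- The cross-linking worst-case fraction threshold (~0.09%) and the
  claim that all aggregate levels exceed one STC per cell at 0.01%
  specific B cells do not reproduce under this derivation of the
  kinetics; see the time-horizon discussion above.
- The ADA calibration is one self-consistent point, not a fit; absolute
  ADA trajectories are in arbitrary-scaled pM and only fold changes and
  directions are meaningful.
- No HLA-DM editing, immune tolerance, disease states, FcR signaling
  detail, antibody isotypes, or stochastic immune-cell dynamics.
- Aggregated and nonaggregated drug share one plasma pool; aggregation
  acts only through the five perturbation channels.
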