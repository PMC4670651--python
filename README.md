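# aggimmuno

Mechanistic models of how aggregates of therapeutic protein products (TPP)
— monoclonal antibodies, fusion proteins, cytokines — can drive unwanted
anti-drug-antibody (ADA) responses.  Built for quantitative pharmacology
and immunogenicity-risk modelers who want a tested, scriptable
implementation of two questions:

1. **T-cell-independent pathway.** Can a multivalent aggregate activate a
   B cell directly by cross-linking its receptors?  A mass-action model of
   sequential aggregate–BCR binding,

       Ag_a + BCR <-> Ag_aBCR_1,   Ag_aBCR_{i-1} + BCR <-> Ag_aBCR_i,

   with statistical factors (n−i+1) for binding and i for dissociation and
   a geometrically decaying per-bond off-rate k₋ᵢ = (k_on/Ka)·0.5^{i−1},
   is integrated over physiological grids of association constant Ka,
   aggregate concentration [Ag_a⁰] = [Ag]·p/n, and antigen-specific B-cell
   fraction.  The readout is the signal-transducing complex (STC) count
   per antigen-specific B cell, STC = Σ_{i≥s} [Ag_aBCRᵢ]: aggregates
   cross-linking at least s receptors.  A Gillespie direct-method oracle
   validates the ODE engine at small copy numbers.

2. **T-cell-dependent pathway.** A minimal multiscale ADA model — depot →
   two-compartment pharmacokinetics, endosomal processing (internalization
   rate IR₀ = 14.4 day⁻¹, degradation rate DR₀ = 17.28 day⁻¹), competitive
   saturable MHC class II loading with affinity-dependent surface loss,
   danger-signal-driven dendritic-cell maturation, and a 17-subgroup
   affinity ladder of B cells / ADA with affinity-maturation drift — used
   to ask which aggregate-associated perturbations (faster uptake or
   processing, more epitopes, higher-affinity epitopes, stronger danger
   signal) actually move ADA output.

## Worked example

Find the antigen-specific B-cell percentage above which every aggregate
level forms at least one STC per cell, for affinity-matured antibodies
(Ka = 1e−3 pM⁻¹, valency 100, minimum cross-link number s = 2):

```
$ python examples/stc_threshold.py
aggregate     0.1 pM: threshold fraction = 0.06205%
aggregate    12.0 pM: threshold fraction = 0.002454%
aggregate  1500.0 pM: threshold fraction = 0.09248%

worst case over aggregate levels: 0.09248%
-> below this percentage of antigen-specific B cells, at least one
   aggregate level stays under one STC per cell.

low-affinity antibodies (Ka = 1e-7 pM^-1): attained = False
-> without affinity maturation the threshold is never reached.
```

Even at the highest affinity, roughly one antigen-specific B cell per
thousand is needed before every aggregate level supports a single
cross-linking complex per cell; for low-affinity repertoires the
threshold is unreachable — direct B-cell activation by aggregates is an
edge case, not the norm.

On the T-cell-dependent side:

```
$ python examples/ada_epitope_affinity.py
low-affinity           cumulative ADA      207.4 pM*day  fold      1  peak MHC II complexes [403. 582.]
low-affinity-ir-x16.6  cumulative ADA      207.4 pM*day  fold      1  peak MHC II complexes [403. 582.]
plus-high-affinity     cumulative ADA       2496 pM*day  fold     12  peak MHC II complexes [ 263.  380. 8016.]
-> the 38 nM epitope lifts presentation ~14-fold and cumulative ADA
   >4-fold; a 16.6x faster internalization rate leaves both flat.
```

Because MHC loading is supply-saturated, a 16.6-fold faster
internalization rate changes neither presentation nor ADA, while one
aggregate-induced high-affinity epitope (Kd = 38 nM) multiplies
cumulative ADA twelve-fold.  `examples/ada_danger_signal.py` shows the
complementary danger-signal route (5× danger signal → ~22× ADA), and
`examples/ode_vs_gillespie.py` the stochastic validation of the
cross-linking ODEs.

## Library and CLI surface

```python
from aggimmuno import crosslink, ada
from aggimmuno.scenarios import build_preset, run_preset

table = crosslink.sweep()                      # STC grid, tidy DataFrame
res = crosslink.fraction_threshold(Ka=1e-3, Aga0=12.0, n=100, s=2)
results = run_preset("epitope-affinity")       # name -> AdaResult
```

Presets (`crosslink-grid`, `danger-signal-ladder`, `processing-rates`,
`epitope-number`, `epitope-affinity`, `epitope-affinity-dose-ladder`) are
auditable YAML files under `src/aggimmuno/presets/`.  The same operations
are available from the shell:

```
aggimmuno crosslink sweep --out-dir results
aggimmuno crosslink threshold --ka 1e-3 --aga0 12
aggimmuno crosslink validate --n 2
aggimmuno ada run --scenario epitope-affinity --out-dir results
aggimmuno scenarios list
```

Every CLI run writes a manifest (config hash, package version, seed) and
numerically byte-stable CSV/JSON outputs.

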