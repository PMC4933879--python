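# darpflex

Quantitative analysis of affinity maturation in a tubulin-binding DARPin
(designed ankyrin repeat protein): equilibrium and kinetic inference of
binding constants from fluorescence and SPR experiments, ELISA-based
affinity ranking, structural comparison of binder conformations, and
limited-proteolysis fragment-mass assignment — with a seeded
synthetic-data generator standing in for the raw experimental traces.

The package is aimed at protein engineers and structural biologists who
characterize binder variants with the standard trio of experiments
(titration, stopped-flow kinetics, SPR) and want the whole analysis chain
— model, fit, error propagation, cross-checks — reproducible from a seed.

## The models

For a 1:1 interaction `D* + T <=> D*T` with labeled probe `D*` at total
concentration `[D*]` and ligand at total concentration `[T]`:

**Equilibrium titration** (tight-binding / probe-depletion isotherm):

    dFluo = Fluo_max * ((K_D + [T] + [D*]) - sqrt((K_D + [T] + [D*])^2 - 4 [T][D*])) / (2 [D*])

This is the exact quadratic solution of the equilibrium; it must be used
instead of the hyperbola whenever `[D*]` is comparable to or larger than
`K_D` (here: 15-100 nM probe against sub-nM to 127 nM constants).

**Kinetics.** A chase with excess unlabeled competitor gives a
mono-exponential decay with `k_obs = k_off`.  Association under
pseudo-first-order conditions (>= 5-fold ligand excess) gives a rise with
`k_obs = k_on [T] + k_off`; the slope of `k_obs` vs `[T]` is `k_on`.  The
kinetic dissociation constant is `K_D = k_off / k_on`, with first-order
error propagation on the ratio.

**SPR.** 1:1 Langmuir sensorgrams:
`R(t) = R_eq (1 - exp(-(k_on C + k_off) t))` during injection, pure
`exp(-k_off t)` wash-out afterwards, `R_eq = R_max C / (C + K_D)`; fitted
per curve or globally across a concentration series, plus the
model-independent plateau analysis `R_eq` vs `C`.

All closed forms are validated against a mass-action ODE integrator that
is part of the package (`darpflex.models.ode_oracle`).

**Structure.** Kabsch superposition with identity-based atom pairing,
motif rotation angles (superpose on a reference selection, then fit the
motif alone), interface residues at a 4 Å heavy-atom cutoff, clash
enumeration, Shrake-Rupley SASA and buried surface area, and
occupancy-weighted B-factor means — the metrics used to show that the
two-helix C-cap of the matured binders rotates ~25° on binding, buries
~30% less surface when disordered, and is the mobile part of the molecule.

**Proteolysis MS.** Average masses of contiguous fragments and exhaustive
matching of observed intact masses, reproducing the reasoning that
assigns two ~15.8 kDa species 71 Da apart to cleavage after residues
148/149 (the one-alanine step) rather than a double cut.

## Worked example

Simulate and fit the full fluorescence workflow for the four study
variants at their published constants (1% Gaussian noise, seed 1):

```sh
$ darpflex run-all --seed 1
variant           K_D(titr) nM   k_off 1/s  k_on 1/(M s)  k_off/k_on nM consistent
A-C2                    0.8598    0.007101     1.586e+07         0.4478       True
D1                       125.6       1.495     1.293e+07          115.7       True
TM-3                    0.8522    0.004869     1.817e+07          0.268      False
digested TM-3           0.8659    0.004593     2.678e+07         0.1715      False
```

Each row is fitted from synthetic titration, chase and association-series
data generated at the configured truths.  For the parent binder D1 the
equilibrium value (125.6 nM) and the kinetic ratio (115.7 nM) agree
within 10%.  For TM-3 the `consistent` flag fires: the titration value
(0.85 nM) sits 3-fold above `k_off/k_on` (0.268 nM) because a 15 nM probe
cannot resolve a sub-0.3 nM constant — the titration only bounds it; the
same 3-fold gap is present between the corresponding published values.

Fragment-mass assignment with the built-in (synthetic, consensus-scaffold)
TM-3 sequence, for two observed species 72 Da apart:

```sh
$ darpflex match-masses --mass 15810.85 --mass 15738.70
observed 15810.85 Da:
  1-149  computed 15810.85 Da  delta -0.00 Da
observed 15738.70 Da:
  11-160  computed 15737.64 Da  delta -1.06 Da
  1-148  computed 15739.77 Da  delta +1.07 Da
```

The heavier species is uniquely the 1-149 fragment; the lighter one is
ambiguous between 1-148 (one Ala shorter) and the double-cut 11-160.

Other subcommands: `simulate`, `fit-titration`, `fit-kinetics`,
`fit-spr`, `rank-elisa`, `compare-structures` (try
`darpflex compare-structures --toy`).  Everything is also available as a
library (`darpflex.kinetics`, `darpflex.spr`, `darpflex.structure`, ...).

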