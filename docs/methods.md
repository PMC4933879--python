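# Methods

This note documents the models, numerical choices and design decisions
behind darpflex, and what the synthetic-data tests do and do not
establish about real data.

## Binding models and units

All internal quantities are SI (mol/L, s, 1/(M s)); nM and other
reporting units appear only at I/O boundaries.  The model core
(`darpflex.models`) is pure and deterministic.

The equilibrium titration model is the exact quadratic solution of the
1:1 scheme (tight-binding isotherm).  Its discriminant
`(K_D + T + D)^2 - 4 T D` is mathematically non-negative but can round
below zero at stoichiometric points; it is clamped at zero when within
1e-12 relative of zero.  Kinetic transients are single exponentials: a
chase at saturating competitor decays with `k_obs = k_off` (no
competitor-concentration extrapolation is implemented — the protocol
checks saturation by repeating the chase at two competitor
concentrations), and pseudo-first-order association rises with
`k_obs = k_on [T] + k_off`.  SPR sensorgrams follow the 1:1 Langmuir
form with no analyte depletion (flow cell) and no mass-transport term;
the only nuisance parameter is a constant per-curve baseline offset.

### The ODE oracle

`ode_oracle` integrates `d[AB]/dt = k_on [A][B] - k_off [AB]` and is the
accuracy standard for every closed form.  It integrates the
dimensionless bound fraction `u = [AB]/A_total` (LSODA, atol 1e-12,
rtol 1e-9), so accuracy is relative to the probe concentration whatever
its absolute scale; with nanomolar species an absolute tolerance on
mol/L would be six orders of magnitude too loose for the 1e-6 relative
agreement the tests demand.  A `constant_ligand` mode pins the free
ligand (the SPR flow condition) and confirms the Langmuir form.

## Fitting

Nonlinear fits use damped least squares (Levenberg–Marquardt via scipy)
with analytic model evaluation.  Two parametrization choices matter:

* **K_D is fitted on a log scale** (titration and plateau fits), and the
  SPR rates likewise.  These are positive scale parameters that sit
  6–10 decades below 1 in SI units; on the linear scale the default
  finite-difference step (floored at `sqrt(eps)·max(1, |x|)`) dwarfs the
  parameter itself and produces meaningless Jacobians and covariances.
  On the log scale noiseless synthetic data are recovered to machine
  precision and the delta-method standard errors match the empirical
  sampling spread (coverage of nominal 95% intervals is 93–95% in the
  recovery experiments).
* **Multi-start for the titration**: the quadratic isotherm's likelihood
  is flat in K_D in the tight-binding regime, so the fit starts from a
  half-saturation crossing-point heuristic and 0.1×/10× of it, keeping
  the best sum of squares.

Mono-exponential fits are initialized by log-linear regression on the
baseline-subtracted signal; a fitted amplitude below three residual RMS
(with a tiny absolute floor for exactly flat traces) raises a
"no transition" error rather than returning a garbage rate.  The
`k_obs`-vs-concentration line is weighted by `1/SE^2` when the per-trace
SEs are available; its intercept is reported for comparison with the
chase `k_off` but never averaged into it.

Standard errors are asymptotic (covariance-based), matching the
unweighted least-squares treatment the experiments imply; residuals are
unweighted because the synthetic noise is homoscedastic.

The SPR global fit shares `k_on`, `k_off`, `R_max` across curves.
Per-curve mode is exposed because it is not recorded whether the
original fits shared `R_max`; global is the default since the synthetic
sets are generated with a common surface capacity.  "Plateau" is
operationalized as the mean response over the last 10% of the
association window, baseline-referenced to the pre-injection segment;
the kinetic fit flags curves whose association window reaches >= 99% of
`R_eq`.  A plateau series that is linear in concentration (hyperbola
degenerate) raises a "K_D above tested range" error instead of returning
an unconstrained estimate.

## Synthetic data

Generators (`darpflex.synth`) are pure functions of their parameters and
seed, with independent per-generator random streams so adding one
generator never shifts another's draws.  Defaults encode the study
conditions: 100 nM labeled probe for the parent binder and 15 nM for the
high-affinity variants; association series at >= 5× ligand excess (a
warning below 5×, an error below 2×); five SPR concentrations spanning
K_D/4 to 4·K_D geometrically with a 180 s injection (60 s for the
fast-dissociating parent in the examples); 1% Gaussian signal noise in
recovery experiments.  The titration design — 12 log-spaced ligand
concentrations from `D*/10` to `max(20 K_D, 5 D*)` — is a repository
choice covering the depletion and saturation regimes; the original
point spacing is not recorded.

The noise model is i.i.d. Gaussian on the signal.  No baseline drift,
photobleaching, stopped-flow dead time, or SPR bulk-shift artifacts are
emulated, so passing recovery tests demonstrates correctness of the
estimators under the stated noise model, not robustness to instrument
systematics.

The toy complex is a pseudo-C-alpha two-chain fixture: a 20-residue
binder whose last six residues (the "cap" motif) sit 10 Å from a
recorded rotation axis, and a receptor carrying a configurable number of
atoms placed 1.5 Å from distinct unrotated motif atoms.  The bound pose
rotates the motif by an exact, recorded angle; the construction
guarantees clash relief for rotations of roughly 20° and above at the
default geometry.  Motif atoms carry B = 75, the rest 47, mirroring the
mobility contrast the structural analysis quantifies.

## Structural comparison

PDB input is parsed with gemmi; alternate locations are resolved to the
highest-occupancy conformer (ties alphabetically) before any geometry,
and hydrogens/waters are excluded throughout.  Superpositions pair atoms
by chain/author-residue-number/atom-name identity, dropping and counting
unmatched atoms (deposited entries differ in modeled residues — the
matured binder's cap is absent from its complex structure).  C-alpha
pairing is the default for superpositions; interfaces, clashes and SASA
use all heavy atoms.  The rotation angle reported for a motif is the
total angle `arccos((tr R - 1)/2)` of the optimal motif transform after
superposing on the reference selection; the axis is also available.

SASA is Shrake–Rupley (960 Fibonacci points per atom, probe 1.4 Å, via
biotite) with a Bondi-style radii table (C 1.70, N 1.55, O 1.52, S 1.80,
P 1.80 Å; unknown elements fall back to 1.70 Å with a warning).  Buried
surface area is `SASA(A) + SASA(B) - SASA(AB)`.  The tool and radii
behind the published buried-surface figures are not recorded, which is
why the structural comparisons carry ±5% bands.  Residue-range defaults
for "reference" vs "cap" selections (<= 149 vs >= 150) follow the
proteolysis boundary and are config-overridable; B-factor means are
reported both all-atom and C-alpha-only since the published averaging
convention is unstated.

The deposited entries themselves (4DRX, 4DUI, 5EYL, 5EYP) are not
bundled — they are multi-megabyte PDB files; `scripts/fetch_structures.py`
downloads them, and the corresponding acceptance test runs only when
they are present locally.

## Fragment masses

Average (not monoisotopic) residue masses to 0.01 Da plus one water per
fragment — ESI-MS of ~16 kDa species reports average mass.  Terminal
modifications are the caller's responsibility via the sequence input.
The default matching tolerance is 2 Da: single-residue discrimination at
16 kDa (the smallest residue step, Gly, is 57 Da; the diagnostic Ala
step is 71.08 Da) while absorbing table rounding.

The built-in TM-3 sequence is a **synthetic stand-in**, reconstructed
from the canonical consensus DARPin scaffold (his-tag, N-cap, three
internal repeats, C-cap) because the actual sequence figure is not
machine-readable.  Every position the study's numbering pins down
(His118, Ile122, Glu127, Val131, Ala149, Phe150, Ile152, Asp155, Asn158,
Glu159, and the three mutations H118R/I152T/N158S) falls on the
consensus framework residue, which strongly constrains the
reconstruction; the free library positions were fixed once so the 1-149
fragment mass lands near 15.8 kDa.  Conclusions that depend on the exact
residues at randomized positions should not be drawn from this fixture.

## ELISA ranking

Classification uses competitor-condition signal ratios against the
parent binder: low < 2×, medium 3–6×, high >= 8×.  The bands do not tile
the ratio axis; ratios in [2, 3) and (6, 8) are reported as a distinct
"indeterminate" class rather than forced into a neighbor — the original
visual assignment is not an algorithm, and silent binning would
overstate certainty.  Buffer-condition ratios are reported as auxiliary
output only, since the differentiation is much weaker without the
rebinding competitor.

## Known limitations

* Single-site 1:1 binding only: no cooperative, multi-site, or
  conformational-selection schemes, and no mass-transport-limited SPR.
* The published uncertainty on the `k_off/k_on` ratios was computed by
  an unrecorded method; first-order propagation reproduces the central
  values but is not guaranteed to reproduce the printed ± figures.
* Titrations cannot resolve constants far below the probe concentration;
  the consistency check (factor-2 default) deliberately flags this
  regime instead of hiding it.
* The fragment-mass fixture is a reconstruction (above), and the
  crystal-structure metrics require user-supplied PDB downloads.

## Problem sizes

Recovery experiments use 200 seeded replicates per variant at 1% noise;
oracle sweeps use 10 random parameter sets; the neighbor-search
cross-validation uses 100 random structures; ELISA recovery uses 10
panels of 12 variants.  These sizes give medians and coverage stable to
well within the asserted tolerances.
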