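# Methods

`lactrace` analyses in vivo [U-¹³C]-lactate bolus-tracing experiments of the
kind used to probe brown-adipose-tissue (BAT) metabolism across housing
temperatures, and ships a fully synthetic data path so every analysis stage is
testable without animal data. This note records the models, the defaults and
the design choices, in the order the method runs.

## Natural-abundance correction (`lactrace.isotope`)

A measured mass isotopologue distribution (MID) `y` over mass shifts
m+0…m+n mixes tracer-derived label with naturally occurring ¹³C. The forward
model is binomial and carbon-only: entry `M[i, j]` is the probability of
observing shift `i` given `j` tracer-labelled carbons, with each of the
`n − j` remaining carbons naturally ¹³C with probability `p13` and each
labelled carbon truly ¹³C with probability `tracer_purity`. Columns are
probability distributions (sum to 1); at purity 1 the matrix is lower
triangular.

* `p13` default **0.01109**, the consensus natural ¹³C abundance; configurable.
* `tracer_purity` default **0.99**; commercial [U-¹³C]-lactate purity is not
  always reported, so the term is configurable and not asserted.
* Correction is carbon-only because an Orbitrap-class high-resolution
  instrument mass-resolves the isotopic contributions of O/H/N away; no
  correction for non-carbon elements is attempted.
* Inversion is by **non-negative least squares** followed by renormalization,
  not a plain matrix inverse: on noisy data the inverse can produce negative
  fractions, while NNLS keeps the fraction simplex and still recovers the
  exact answer on any vector generated by the forward model.

From the corrected fractions `x` the module computes three statistics:

* molecular enrichment `E = Σ k·x_k / n` (mean labelled fraction of the
  skeleton, in [0, 1]);
* the contribution ratio `E_metabolite / E_lactate`, paired within the same
  animal **and** compartment (plasma to plasma lactate, each tissue to its own
  lactate);
* the pyruvate-cycling proxy `(x₁ + x₂)/x₃` for three-carbon metabolites.

Undefined ratios (zero tracer enrichment, zero m+3) propagate as explicit
missing values with a reason code, never as 0 or ∞. Mass-shift indexing is
0-based everywhere.

## Label-propagation simulator (`lactrace.simulate`)

The synthetic cohort generator is an atom-mapped positional-isotopomer model
of the lactate–pyruvate–TCA network: LDH exchange, PDH, pyruvate carboxylase
(PC), one TCA turn with the citrate-synthase transition `Cit(dcbfea)` from
`OAA(abcd) + AcCoA(ef)`, decarboxylations to α-ketoglutarate and succinate,
symmetric succinate/fumarate passage, and the two pyruvate-recycling routes
(PEPCK + pyruvate kinase from oxaloacetate; malic enzyme from malate), plus
identity equilibrations for aspartate, glutamate, glutamine and cis-aconitate.
States are explicit distributions over the `2^n` labelling patterns (largest
pool: citrate, 64 states); the network is small enough that clarity beats an
EMU decomposition.

Model assumptions:

* **CO₂ is infinite and unlabelled** — carboxylation inserts ¹²C, label lost
  by decarboxylation is never re-fixed.
* **Lactate is clamped** at a fixed `tracer_fraction` of the m+3 species
  (default **0.14**, the order of plasma label recovery observed ~15 min after
  a bolus); concentration kinetics are deliberately separated into the
  tolerance-test module. A consequence is that simulated *lactate* cycling
  ratios are zero — the cycling readout in synthetic data is carried by
  pyruvate.
* **Symmetry is deterministic**: passage through succinate/fumarate applies a
  50/50 orientation mixture, so steady states are exactly reproducible.
* **Flux closure**: the four-carbon pool is closed — one TCA turn conserves
  its carbon count — so the total PEPCK+PK / malic-enzyme return equals the PC
  input `v_pc`, with `v_pepck_pk : v_me` acting as the split between the two
  routes. This is the only closure under which the stated carbon balances hold
  and the cycling ratio is monotone in `v_pc`; treating the return fluxes as
  independent constants makes the ratio *decrease* in `v_pc`. Surplus
  pyruvate production returns to lactate through the LDH equilibrium, which is
  why configurations with `v_pdh > v_ldh_exchange` are rejected.

The steady state is a damped fixed-point iteration on the flux-weighted
mixture equations (tolerance 1e-12, at most 1e5 sweeps, damping 0.5 engaged
only if the change sequence stops contracting). Glucose is the
self-convolution of the gluconeogenic triose (phosphoenolpyruvate =
oxaloacetate carbons 1–3) mixed with an unlabelled hexose source at weight
`v_gluconeo/(v_gluconeo + 1)` — a single fixed rule standing in for
glycogenolysis and dietary dilution.

Cohort emission forward-convolves natural abundance, scales to
instrument-like intensities and applies multiplicative log-normal noise
(default CV **5%**, a typical peak-integration repeatability), fully seeded.
The default design is **5 animals per group** in three housing groups
(4 °C / 21 °C / 30 °C) across plasma, iBAT, SCAT, liver and kidney. Presets
encode the qualitative biology: strong iBAT pyruvate cycling at 4/21 °C that
collapses at thermoneutrality (30 °C) together with the TCA contribution, and
a cold-specific rise in the lactate→glucose flux of liver/kidney/plasma. What
passing tests show is that the *pipeline* recovers exactly these configured
contrasts from corrupted data; they say nothing about inter-tissue exchange,
bolus non-stationarity within the 15-min labelling window, lipogenic fates, or
the identifiability of the pyruvate-kinase versus malic-enzyme routes — none
of which the simulator models.

## Tolerance-test kinetics (`lactrace.kinetics`)

Blood lactate after an intraperitoneal bolus (dose **6 µmol/g** body weight)
follows a one-compartment Bateman form — first-order peritoneal absorption
`ka` and clearance `k_clear` (per minute), with `vd_scale` (mM per µmol/g)
mapping dose to apparent concentration — sampled at 0, 5, …, 30 min, the in
vivo protocol. The 21 °C preset (`ka 0.5`, `k_clear 0.15`, `vd 2.2`, basal
2.5 mM) peaks near 10 mM at the first post-injection sample; the 4 °C and
30 °C presets change only `k_clear` (0.28 / 0.07). Noise is additive Gaussian
(default SD 0.4 mM, meter-level error), truncated at zero, seeded per animal.

AUC is the **total** trapezoidal area from zero; whether a published AUC is
baseline-subtracted is often unstated, so total AUC is the conservative
default and `--baseline-subtract` provides the incremental variant — group
contrasts are preserved under either.

Parameter recovery fits `(ka, k_clear, vd_scale)` by Levenberg–Marquardt in
log-parameters (positivity), with basal and dose fixed. The Bateman form is
symmetric under swapping the two rates, so fits are canonicalized to
`ka ≥ k_clear` with the compensating `vd` rescale. On a 7-point curve with
0.3 mM noise the per-cohort mean `k_clear` carries a small upward
finite-sample bias (~7–8%), dominated by the rate-swap canonicalization when
noisy estimates approach each other; noise-free fits are exact to machine
precision. Flat curves yield a failed-fit result, not an exception.

## Statistics (`lactrace.stats`)

The group-comparison decision tree is deterministic and auditable:
Shapiro–Wilk per group (α 0.05) → all normal: parametric; otherwise natural-
log transform and retest (the chosen branch is base-invariant) → normal on the
log scale: parametric on logs; else nonparametric. Non-positive values block
the log branch. Within parametric branches, Levene's test on medians (α 0.05)
— the variance-equality trigger is not standardized in practice, so the
median-centred robust variant was chosen — routes to ANOVA + Tukey (or pooled
t) versus Welch ANOVA + Dunnett-T3-style post hoc (or Welch t); the
nonparametric branch uses Kruskal–Wallis + Dunn (or Mann–Whitney). Dunnett's
T3 uses the studentized maximum modulus, which no installed library provides;
the implementation uses Šidák-adjusted pairwise Welch t tests, a close,
documented approximation. Tolerance curves get a two-way (group × time) ANOVA
with Tukey contrasts at each time point.

Outlier exclusion is a **simplified univariate ROUT** at FDR Q = 1%: robust
location = median, robust scale = finite-sample-corrected normal-consistent
MAD, candidates flagged by Benjamini–Hochberg on two-sided t-tail
probabilities. Two details matter for calibration: the MAD gets Williams-type
small-sample unbiasedness factors, and the t-tail uses the MAD's equivalent
degrees of freedom (≈ 0.37·(n − 1), its asymptotic efficiency) rather than
n − 1, because the scale estimate's own noise makes the residual ratio
heavier-tailed than t(n−1) — without this, clean normal samples are flagged
in 3–6% of cases instead of < 1%. Samples with n < 3 are never pruned. The
original ROUT is a proprietary robust-regression procedure; equivalence is not
claimed.

qPCR fold changes use 2^−ΔΔCt with the reference Ct as the arithmetic mean of
the two housekeeping Cts — on the expression scale (2^−Ct) this is exactly
normalization to the housekeeping geometric mean, the only reading consistent
with the ΔΔCt method.

## Pipeline (`lactrace.pipeline`, CLI `lactrace`)

Commands `simulate`, `correct`, `enrich`, `cycling`, `ltt-auc`, `stats`,
`analyze`, `all` run the stages over fixed CSV dialects (UTF-8, comma,
mandatory header; missing values empty with reason codes in a `flags`
column). Every output carries the seed and a hash of the run configuration
(output-directory independent), making runs byte-reproducible under a fixed
seed.

## Problem sizes and numerical choices

Test and verification sizes were chosen to exercise each property at
convincing scale: 1000 random round-trip vectors (n = 2…6, p13 ≤ 0.05,
recovery ~1e-15, asserted at 1e-7); 100 noisy five-animal cohorts for
group-ordering recovery; 20 fifteen-animal cohorts for kinetic bias; 2000
null replicates per decision-tree branch (realized type-I error asserted in
[0.03, 0.07]). Fixed-point tolerance is 1e-12; NNLS handles rank-complete
triangular-like systems of size ≤ 7, where it is numerically exact.

## Known limitations

* No inter-tissue label exchange (e.g. tissue-produced m+1/m+2 lactate
  re-exported to blood), so simulated plasma/tissue lactate MIDs understate
  the Cori-type component of cycling.
* The simulator is steady-state; real bolus experiments are sampled during a
  transient. The clamped `tracer_fraction` stands in for the bolus dilution at
  sampling time.
* Pyruvate-kinase versus malic-enzyme routes are exposed as separate fluxes
  but are not claimed identifiable from MIDs alone.
* The ROUT and Dunnett-T3 implementations are stated approximations of the
  originals.
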