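# lactrace

Analysis of in vivo **[U-¹³C]-lactate bolus-tracing** experiments: natural-
abundance correction of mass isotopologue distributions (MIDs), molecular ¹³C
enrichment and tracer-contribution ratios, the `(m+1 + m+2)/m+3` pyruvate-
cycling statistic, lactate-tolerance-test kinetics, and a deterministic
statistical decision tree — together with an atom-mapped isotopomer simulator
that generates realistic synthetic cohorts so the whole pipeline is testable
without animal data.

It is written for metabolism researchers who trace ¹³C-lactate into tissues
(brown/beige fat, liver, kidney, plasma) and want a scripted, reproducible
route from integrated LC-HRMS isotopologue intensities to corrected fractions,
contribution ratios, cycling statistics and group-level tests.

## The statistics at the core

For a metabolite with `n` carbons and corrected MID `x = (x₀ … x_n)`:

* **Molecular ¹³C enrichment** — the mean labelled fraction of the carbon
  skeleton: `E = Σₖ k·xₖ / n ∈ [0, 1]`.
* **Contribution ratio** — `E_metabolite / E_lactate`, computed within the
  same animal and compartment (plasma vs. each tissue), measuring the relative
  contribution of the lactate tracer to that metabolite's carbon.
* **Pyruvate-cycling ratio** — `(x₁ + x₂)/x₃` for lactate/pyruvate. A
  [U-¹³C] tracer makes m+3 pyruvate; recycling through pyruvate carboxylase →
  oxaloacetate/malate → PEPCK + pyruvate kinase or malic enzyme strips one or
  two ¹³C atoms (after scrambling in the symmetric four-carbon intermediates),
  so m+1/m+2 species diagnose pyruvate cycling: the higher the ratio, the
  higher the recycling.

Correction removes natural ¹³C (binomial forward model, `p13 = 0.01109`,
optional tracer-impurity term) by non-negative least squares; it is exact on
any vector generated by the forward model and never yields negative fractions
on noisy data.

## Worked example

Simulate a cohort (three housing groups, 5 animals each, 5% intensity noise)
and analyse it end to end:

```sh
lactrace all --out results --seed 3
```

which prints `44 endpoints analyzed` and writes `mids.csv`,
`ground_truth.csv`, `ltt.csv`, `enrichments.csv`, `cycling.csv`, `auc.csv`
and `stats_report.json` under `results/`. In Python:

```python
>>> import lactrace as lt
>>> mids, truth = lt.emit_cohort(n_animals=5, noise_cv=0.05, seed=3)
>>> enr = lt.process_mid_table(mids)
>>> enr[(enr.tissue == "iBAT") & (enr.metabolite == "pyruvate")] \
...     .groupby("group")["cycling_ratio"].mean().round(3)
group
21C    1.055
30C    0.167
4C     1.064
Name: cycling_ratio, dtype: float64
```

The thermoneutral (30 °C) group's brown-fat cycling ratio collapses roughly
seven-fold relative to the 4 °C and 21 °C groups — the configured biology of
the default presets (thermoneutrality represses pyruvate cycling in brown
fat), recovered here from noisy, natural-abundance-corrupted intensities.
Plasma lactate enrichment in the same cohort averages ≈ 0.14: the injected
m+3 tracer diluted ~7-fold by endogenous unlabelled lactate.

The same `--seed` reproduces every file byte for byte; each output carries
the seed and a configuration hash in its header.

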