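# metasample

Meta-research tooling for quantifying **sampling inequality**, synthesising
**classifier performance**, and rating **study quality** in the literature on
neuroimaging-based machine-learning diagnosis of psychiatric disorders.

Diagnostic classifiers (MRI/fMRI, EEG, MEG, fNIRS, PET) are trained on
samples recruited almost entirely in a handful of wealthy countries, and
their reported accuracies depend strongly on methodological choices —
cross-validation scheme, external validation, case–control balance.
`metasample` turns these concerns into numbers:

* **Sampling inequality** — treat the total sampled population per
  geographic unit as an allocation and measure its concentration with the
  Gini coefficient `G = ΣᵢΣⱼ|yᵢ−yⱼ|/(2n²ȳ)`, the Theil index
  `T = (1/n)Σ(yᵢ/ȳ)ln(yᵢ/ȳ)`, and Lorenz curves.  With units labelled by
  economic bloc (MEDC/LEDC), Dagum's decomposition splits
  `G = G_w + G_nb + G_t` into within-bloc, net between-bloc and
  transvariation (overlap) parts.  Significance comes from a permutation
  test against an equal-allocation multinomial null.
* **Performance synthesis** — accuracies pooled with inverse-variance
  weights `wᵢ = nᵢ/(p̃ᵢ(1−p̃ᵢ))`, rank-sum contrasts between strata
  (LOOCV vs k-fold, within- vs cross-country validation), Cohen's d, JZS
  Bayes factors, case–control skewness `max(n_p,n_c)/min(n_p,n_c)`.
* **Trends & associations** — Mann–Kendall trend tests, exponential
  growth-curve fits for yearly study counts, Spearman correlations with
  bootstrap CIs, permutation correlation tests, and a penalized-spline
  semi-parametric regression (GDP → inequality).
* **Quality rating** — the five-item N-ML-MAP-P checklist (sample
  representativeness, CV scheme, external validation, reporting
  transparency, data/model availability), 0–10 points mapped to a 5-star
  scale, with a replaceable rubric file and a dual-rater adjudication rule.
* **Synthetic corpora** — a seeded generator producing evidence tables and
  two-level geographies with known ground truth (allocation Gini, accuracy
  effects, skew prevalence), so the entire pipeline is testable end to end
  without any external data.

See `docs/methods.md` for the full model descriptions, defaults and
numerical choices.

## Worked example

Generate a synthetic corpus under the default study conditions (476
studies, 1995–2021, GDP-weighted country allocation calibrated to an
expected Gini of ~0.81) and run the full analysis:

```python
from metasample import CorpusConfig, RunConfig, generate_corpus, run_full_analysis

corpus = generate_corpus(CorpusConfig(seed=7))
report = run_full_analysis(corpus.evidence, corpus.country_samples,
                           config=RunConfig(seed=7))

ineq = report["stages"]["inequality"]
print(ineq["gini"], ineq["theil"], ineq["permutation"]["p_value"])
# 0.6557 0.7826 9.999e-05
print({k: round(ineq["dagum"][k], 4) for k in
       ("G_total", "G_within", "G_between_net", "G_transvariation")})
# {'G_total': 0.6557, 'G_within': 0.4312, 'G_between_net': 0.2147,
#  'G_transvariation': 0.0097}
perf = report["stages"]["performance"]["loocv_vs_kfold"]
print([round(100 * m, 2) for m in perf["means"]], perf["stat_W"])
# [84.75, 77.73] 42187.0
print(report["stages"]["quality"]["summary"]["share_low_quality"])
# 0.9055
```

Reading the output: the realised country allocation of this corpus has
Gini 0.66 (the permutation p ≈ 1e-4 says an equal allocation essentially
never looks this unequal), and the Dagum split attributes about a third of
it to the MEDC/LEDC divide.  LOOCV studies report a precision-weighted
accuracy 7 points above k-fold studies, and 90.6% of studies fall below
the 3-star quality cutoff.

The same analysis is available from the shell:

```bash
metasample simulate --seed 7 --out synth/
metasample gini --input synth/units.csv --permutations 10000 --seed 7 --out gini.json
metasample report --evidence synth/evidence.csv --units synth/units.csv \
    --seed 7 --out run/
```

Real coded evidence tables (CSV/TSV, one row per study; see
`metasample.evidence` for the schema and aliasing) drop into the same
commands via `metasample ingest` / `report`.

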