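# gamquant

Quantification and prognosis statistics for glioma-associated
microglia/macrophages (GAMs) measured by immunohistochemistry on tissue
microarrays (TMAs), plus the accompanying expression-side statistics.

Myeloid cells are the dominant non-neoplastic population of the
glioblastoma microenvironment, and how much of a tumor they occupy is a
candidate prognostic marker. This package implements the full analysis
chain used to ask that question from brightfield H-DAB slides:

- **Automated DAB-area quantification** per TMA spot: Beer–Lambert
  conversion to optical density (`od = log10(I0 / I)`), color
  deconvolution into hematoxylin/DAB channels, tissue/glass separation,
  and a **two-step minimum-entropy threshold** for the DAB-positive
  area. The per-spot statistic is `r = DAB area / total tissue area`.
- **Cohort statistics**: first-core selection, exclusion of cores with
  more than 30% necrosis, two-sample Wilcoxon rank-sum tests with
  Bonferroni–Holm adjustment, Spearman agreement (repeat cores,
  raters, manual vs. automated), Kruskal–Wallis + Dunn tests across
  tumor regions (vital tumor T, infiltration zone IZ, normal-appearing
  brain NAB).
- **Dichotomized survival analysis**: Kaplan–Meier curves for marker
  high vs. low arms, split at the median or at the maximally selected
  ("best") cutpoint, compared with the log-rank and
  Gehan–Breslow–Wilcoxon tests.
- **Expression statistics**: `|log2FC| >= 2` DEG screen, Ward
  minimum-variance clustering, Pearson coexpression, rank-product
  permutation significance (pfp), and ΔΔCt qPCR quantification with
  standard-curve efficiencies.
- **Synthetic data generators** for all three input kinds — rendered
  H-DAB spots with known positive-area fraction, survival cohorts with
  a planted marker-dependent hazard, and expression matrices with
  planted fold changes — so the entire pipeline runs and is testable
  with no external data.

## Worked example

```python
from gamquant import SpotSpec, generate_spot, quantify_spot

spot = generate_spot(SpotSpec(positive_fraction=0.20, seed=42))
res = quantify_spot(spot.image)
```

Running `python examples/quantify_spot.py` prints:

```
true positive fraction : 0.2035
estimated DAB ratio    : 0.2199
first-pass threshold t1: 0.361 OD
final threshold t2     : 0.361 OD
tissue area            : 41391 px
DAB-positive area      : 9103 px
```

The generator placed DAB-positive cells over 20.35% of the tissue disc;
the estimator recovered 21.99% without access to the ground truth. `t1`
is the threshold estimated from all tissue pixels; the second pass kept
it (the refinement only replaces `t1` when the first pass selected
mostly background, which happens under strong or spatially varying
background staining).

`python examples/survival_median_split.py` simulates a 240-patient
cohort in which marker-high patients have 0.6× the hazard and prints:

```
239 patients after first-core selection and necrosis filter
median split at 25.6% positive cells (low n=120, high n=119)
  log-rank: chi2=17.49 p=2.88e-05
  Gehan   : chi2=8.73 p=3.13e-03
best split at 25.2% (scanned 192 cutpoints; p unadjusted for selection)
  log-rank: chi2=20.17 p=7.07e-06
```

The planted protective effect is detected by both tests; the best-split
p-value is flagged as unadjusted because maximally selected statistics
inflate type-I error. See `examples/expression_screen.py` and
`examples/qpcr_ddct.py` for the expression and qPCR capabilities.

A thin command-line interface mirrors the library
(`gamquant simulate-spots | quantify | compare | survive | deg | pfp |
ddct | stdcurve | run-all`); `gamquant run-all` executes the whole
simulate → quantify → survive → screen pipeline from one YAML config and
writes a deterministic JSON report.

## Layout

```
src/gamquant/
  ihc.py         stain deconvolution + two-step minimum-entropy DAB estimator
  synthetic.py   ground-truthed spot / cohort / expression generators
  cohort.py      filter rules, rank tests, KM, log-rank/Gehan, median/best split
  expression.py  DEG screen, Ward, Pearson, rank-product pfp, ΔΔCt
  pipeline.py    config-driven end-to-end runs
  cli.py         click CLI
examples/        one narrative script per capability
docs/methods.md  models, assumptions, parameter choices, limitations
```
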