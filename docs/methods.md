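# Methods

This note documents the models implemented in gamquant, the parameter
choices that matter, what the synthetic generators do and do not
emulate, and the numerical conventions.

## Image model and DAB-area estimation

### Optical density and color deconvolution

Brightfield stains attenuate light multiplicatively, so absorbances add
in optical density: `od_c = log10(I0 / I_c)` per RGB channel with
`I0 = 255` and intensities clamped to `[1, I0]` so saturated pixels stay
finite. A pixel's OD vector is modelled as a non-negative combination of
unit-norm stain vectors; concentrations are obtained by inverting the
stain matrix and clipping negatives to zero. The default H-DAB basis is
the published reference pair (hematoxylin ≈ (0.650, 0.704, 0.286), DAB ≈
(0.269, 0.568, 0.778), residual = normalized cross product); the basis
is configurable per batch because scanners and staining protocols shift
it.

### Tissue segmentation

Total tissue area is the denominator of the spot statistic. Tissue is
separated from glass on the combined hematoxylin + DAB concentration
with a fixed physical cutoff of 0.1 OD by default: clean glass plus
scanner noise stays well below 0.1 OD while counterstained tissue lies
above it. Entropy-based cutoffs (`tissue_method='li'|'kapur'`) are
selectable but not the default, for a structural reason: the glass mode
sits at near-zero OD and therefore carries almost no *optical mass* (Li)
— and as a tight spike little entropy (Kapur) — so on spots with strong
specific staining both criteria place their global optimum between
unstained and stained *tissue* rather than at the glass boundary. An
optional exclusion mask (annotated necrosis, artifacts) is subtracted
from the tissue area.

### Two-step minimum-entropy DAB threshold

The DAB-positive area is found per spot, with no parameters shared
across spots:

1. **Step 1** estimates `t1` by exhaustive minimization of Li's
   cross-entropy criterion over all interior edges of a 256-bin
   histogram of the tissue DAB values. The histogram spans
   `[0, max(2.5, observed max))` so bin widths are comparable across
   spots. The criterion for an edge is
   `-m1·log(m1/w1) - m2·log(m2/w2)` with `w` the count and `m` the
   intensity mass below/above the edge; ties (runs of empty bins induce
   exactly tied edges) resolve to the lowest edge within a 1e-9
   relative tolerance of the minimum. Kapur's maximum-entropy criterion
   is selectable via `method='kapur'`.
2. **Step 2** re-estimates a threshold `t2` from only the pixels with
   DAB ≥ `t1`. When unspecific background (haze, a staining gradient,
   textured background uptake) dominates the spot, `t1` lands inside the
   background distribution and the first-pass selection is mostly
   background; the second-pass histogram is then bimodal (residual
   background vs. stained cells) and `t2` recovers the true boundary.
   The refinement is **accepted only if it reclassifies the majority
   (≥ 50%) of the first-pass selection as background** — the signature
   of exactly that failure mode. When the first pass already isolated
   the stained cells, the step-2 histogram is a thin edge-shoulder
   against the object mode, its minimizer falls inside the object
   population and would bias the area downward by roughly
   `2σ·Φ⁻¹(a)/r` per cell of radius `r` (edge blur σ, threshold at
   amplitude fraction `a`); in that case `t2 = t1` and the spot is
   flagged `t2_refinement_rejected`. The acceptance fraction is
   insensitive over a wide band (≈ 0.35–0.8); 0.5 is the principled
   majority rule.
3. The final mask is `tissue & (dab ≥ t2)` (inclusive comparison,
   fixed tie rule), and the spot statistic is
   `r = dab_area_px / total_area_px`.

Degenerate spots: all tissue DAB in the lowest histogram bin ⇒ no DAB
signal (`t1 = t2 = +inf`, `r = 0`); a uniformly stained single-bin
histogram above zero ⇒ the whole tissue is positive (`r = 1`); a
degenerate second pass falls back to `t2 = t1`.

The hematoxylin-channel threshold is estimated and reported but does not
enter `r`.

## Synthetic spot generator

`generate_spot` renders a TMA core through the same Beer–Lambert model
the estimator inverts: a tissue disc (45% of the frame radius; the rest
glass) with a faint hematoxylin background (0.12 OD), ~250 nuclei,
DAB-positive cells as filled discs of radius 9–14 px placed at random
uncovered tissue positions until the target area fraction is reached
(overshoot bounded by one disc, < 0.5 pp), per-cell DAB OD drawn from
N(0.8, 0.12) truncated above the local haze, background DAB haze
(constant 0.1 OD by default, or a linear gradient), spatially correlated
unspecific background texture (sd 0.08 OD, 3 px correlation length),
σ = 1 px Gaussian edge blur applied *after* the ground-truth mask is
frozen, and per-pixel OD noise (sd 0.02). Absorbances compose additively
in OD space.

The defaults are chosen to resemble a 20× TMA core with
macrophage-soma-sized objects and realistically messy background — the
textured background is what makes a single global threshold fail and
the two-step refinement meaningful. What the generator does **not**
emulate: nuclear texture and chromatin, cell shapes beyond discs,
scanner optics (chromatic aberration, vignetting, JPEG artifacts), and
true stain co-localization. Passing tests therefore demonstrate that the
estimator inverts the stated forward model under realistic noise, not
that it is validated on real histology.

A zero-signal spot (no DAB at all but nonzero noise/texture) is a known
limitation: any histogram-entropy threshold without a minimum-contrast
floor will split the noise. The acceptance studies use true fractions
≥ 0.01.

## Cohort model and survival statistics

`generate_cohort` draws per-patient marker levels from Beta(2, 5)
scaled to [0, 100] (right-skewed, as marker distributions in glioma
cohorts are), exponential survival with baseline hazard 0.046/month
(median ≈ 15 months, glioblastoma-like), multiplied by
`exp(log HR)` for patients above the dichotomization point (cohort
median, or a planted change-point), and independent censoring: each
patient is censored with the configured probability at a uniform
fraction of their event time. Repeat cores add N(0, 2) noise; necrosis
fractions follow Beta(1, 19) so ~0.1% of cores exceed the 30% exclusion
cutoff.

Filter rules: analyses use the first core per patient (lowest available
index if core 1 is missing, flagged) and drop cores with necrosis
strictly greater than 30%.

Tests: two-sample comparisons use the Wilcoxon rank-sum / Mann–Whitney
test (exact enumeration for both n ≤ 10 without ties, tie-corrected
normal approximation otherwise) — the compared groups are independent,
so the rank-sum rather than signed-rank form applies. Families of
comparisons are adjusted by Bonferroni–Holm. Agreement analyses use
Spearman's ρ on mid-ranks. Region comparisons (T / IZ / NAB) use
Kruskal–Wallis followed by Dunn's pairwise z-tests with tie-corrected
pooled-rank variance and Holm adjustment.

Survival: the Kaplan–Meier product-limit estimator (subjects censored at
an event time remain at risk for that event; events processed first).
Arms are compared with the weighted log-rank family: weight 1 (log-rank)
and weight = number at risk (Gehan–Breslow–Wilcoxon — "Wilcoxon" in the
clinical-software sense, which up-weights early events). The chi-square
statistic is `(Σ w(O−E))² / Σ w²V` with hypergeometric variance `V`, on
1 df. Dichotomization: the high arm is strictly above the cutpoint and
ties go to the low arm. `best_split` scans every distinct observed value
leaving at least 10% of patients per arm, returns the full scan table,
and flags its p-value as unadjusted for maximal selection — with ~200
candidate cutpoints the nominal p is seriously optimistic, and the scan
table exists so users can see the selection landscape.

Measured operating characteristics at the defaults (see
`scripts/acceptance.py`): type-I error of the median-split log-rank
pipeline 0.045–0.054 at α = 0.05 (2000 null cohorts, n = 100); power
0.90 for HR 0.6 at n = 240; a planted change-point at 30% marker is
recovered within ±5 units in ≥ 92% of strong-effect (HR 0.4) cohorts.

## Expression statistics

The module consumes already-normalized log2 matrices (probe-level
processing is upstream and out of scope). The DEG screen computes
`log2FC = mean(case) − mean(reference)` per gene and passes genes with
`|log2FC| ≥ 2`, boundary inclusive. Ward clustering uses the
minimum-variance criterion on Euclidean distances
(scipy linkage; heights are `sqrt(2·ΔESS)` and non-decreasing).
Pearson coexpression reports the gene × gene correlation matrix with
constant genes as missing.

Rank products: per case sample, genes are ranked by fold change against
the mean of the reference samples; a gene's score is the geometric mean
of its ranks (up- and downregulation scored separately). Significance is
the pfp — expected false predictions at the gene's score divided by its
observed rank — with the null obtained by permuting expression values
within each sample. For tiny matrices an exact mode enumerates all
per-sample rank combinations (each equally likely under within-sample
permutation). The pfp method and permutation scheme are a documented
convention: rank products are the standard pfp-producing procedure, but
nothing in the consumed data format pins the choice. Caveat: with a
single pooled reference column, the reference term is shared across all
case fold changes, which induces rank consistency for genes with extreme
reference values and inflates the number of small pfps; multi-sample
references avoid this.

ΔΔCt: technical replicates are averaged first (wells > 0.5 cycles from
their triplicate median are flagged);
`dCT = CT(target) − CT(reference gene)` per sample,
`ddCT = dCT − mean dCT(control group)`, `R = 2^(−ddCT) · 100%`. R
assumes exact doubling per cycle; the standard-curve fit
(CT vs log10 concentration, efficiency `10^(−1/slope) − 1`) is the check
on that assumption and errors out for non-negative slopes or dilution
series spanning < 2 log10 units.

## Numerical conventions and problem sizes

All pixel comparisons use `≥ threshold`; all generators are
deterministic per seed (`numpy.random.default_rng`); the pipeline
derives per-stage seeds from one master seed, so identical configs give
byte-identical reports. The acceptance studies use 256² px spots (200
flat-haze spots for accuracy, 100 gradient-haze pairs for the
two-step/one-step comparison), 2000 null cohorts of n = 100 for
calibration, 500 cohorts of n = 240 for power, and 200 cohorts for
change-point recovery — sizes at which the binomial uncertainty of the
measured rates is a small fraction of the acceptance bands.
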