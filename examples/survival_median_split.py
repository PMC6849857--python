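"""Dichotomized survival analysis of a marker in a synthetic GBM-like cohort.

Simulates 240 patients whose hazard is reduced (HR 0.6) when their
marker lies above the cohort median — the protective
high-infiltration pattern — applies the first-core and necrosis filter
rules, and compares high vs. low arms with the log-rank and
Gehan-Wilcoxon tests under both a median and a maximally selected
("best") split.
"""

import numpy as np

from gamquant import (
    CohortSpec, best_split, exclude_necrotic, first_core_select,
    generate_cohort, median_split,
)

cohort = generate_cohort(
    CohortSpec(n_patients=240, log_hazard_ratio_high_vs_low=float(np.log(0.6)),
               cores_per_patient=3, seed=1)
)
table = exclude_necrotic(first_core_select(cohort))
print(f"{table.shape[0]} patients after first-core selection and necrosis filter")

med = median_split(table)
print(f"median split at {med.cutpoint:.1f}% positive cells "
      f"(low n={med.n_low}, high n={med.n_high})")
print(f"  log-rank: chi2={med.logrank.statistic:.2f} p={med.logrank.p_value:.2e}")
print(f"  Gehan   : chi2={med.gehan.statistic:.2f} p={med.gehan.p_value:.2e}")

best = best_split(table)
print(f"best split at {best.cutpoint:.1f}% "
      f"(scanned {len(best.scan)} cutpoints; p unadjusted for selection)")
print(f"  log-rank: chi2={best.logrank.statistic:.2f} p={best.logrank.p_value:.2e}")

# A small p-value means the dichotomized marker separates the survival
# curves; the best-split p is optimistically biased and flagged as such.
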