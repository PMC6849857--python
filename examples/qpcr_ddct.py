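"""Relative qPCR quantification (ddCT) and standard-curve efficiency.

Builds a small CT table (triplicate wells, one reference gene, one
control sample), computes dCT/ddCT/R per sample, and fits a standard
curve to a 10-fold dilution series.
"""

import numpy as np
import pandas as pd

from gamquant import ddct_quantify, standard_curve

wells = {
    ("WM_ctrl", "RPLP0"): 15.0, ("WM_ctrl", "TLR2"): 21.0,
    ("GAM_1", "RPLP0"): 15.2, ("GAM_1", "TLR2"): 18.9,
    ("GAM_2", "RPLP0"): 14.8, ("GAM_2", "TLR2"): 19.3,
}
ct = pd.DataFrame([
    {"sample": s, "gene": g, "ct": v + 0.05 * rep, "replicate": rep}
    for (s, g), v in wells.items() for rep in range(3)
])

out = ddct_quantify(ct, reference_gene="RPLP0", control_samples=["WM_ctrl"])
for _, row in out.iterrows():
    print(f"{row['sample']:>8} {row['gene']}: dCT={row['dct']:+.2f} "
          f"ddCT={row['ddct']:+.2f} R={row['r_value']:.0f}% of control")

conc = np.array([10.0, 1.0, 0.1, 0.01])
cts = 12.0 - np.log2(conc) + np.array([0.02, -0.01, 0.03, -0.02])
curve = standard_curve(conc, cts)
print(f"standard curve: slope={curve.slope:.3f}, R2={curve.r_squared:.4f}, "
      f"efficiency={curve.efficiency * 100:.1f}%")

# R > 100% means the target is more abundant than in the control group
# (after reference-gene normalization); efficiency ~100% validates the
# exact-doubling assumption behind R = 2^(-ddCT).
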