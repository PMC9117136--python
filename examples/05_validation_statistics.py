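"""Validation statistics for benchmarking an assay.

Demonstrates the quantile dose-response curve (log-odds of disease vs mean
standardized PRS across 50 equal-count quantiles), paired-classification
concordance with the Matthews correlation coefficient, and variant-site
sensitivity/PPV against a truth set.
"""

import numpy as np
from scipy.special import expit

from clinprs import stats

rng = np.random.default_rng(2)

# --- quantile log-odds curve on a simulated cohort ------------------------
z = rng.standard_normal(50_000)
labels = (rng.random(50_000) < expit(-2.0 + 0.5 * z)).astype(int)
curve = stats.quantile_log_odds(z, labels, n_quantiles=50)
print(f"quantile curve: 50 bins, Pearson r = {curve.pearson_r:.3f}")
print("  (log-odds of disease rises linearly with the standardized score;")
print("   r near 1 means the score is monotonically dose-responsive)")

# --- paired dichotomous concordance ---------------------------------------
pairs = [(False, False)] * 95 + [(True, True)] * 13 + [(True, False),
                                                       (False, True)]
res = stats.concordance(pairs)
print(f"\nconcordance: {res.n_concordant}/{res.n_pairs} pairs agree "
      f"({100 * res.agreement:.1f}%), MCC = {res.mcc:.2f}")
print("  (MCC accounts for the dominance of average-risk calls; 1.0 is")
print("   perfect agreement, 0 is chance)")

# --- variant-site concordance against a truth set -------------------------
truth = {("1", p, "A", "G") for p in range(100, 1100, 10)}
calls = set(list(truth)[:95]) | {("1", 5000 + p, "C", "T") for p in range(3)}
site = stats.site_concordance(calls, truth)
print(f"\nsite concordance: TP={site.tp} FP={site.fp} FN={site.fn} -> "
      f"sensitivity {site.sensitivity:.3f}, PPV {site.ppv:.3f}")
print("  (fraction of truth sites recovered, and of called sites that are")
print("   real - the array/imputation analytical-performance metrics)")
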