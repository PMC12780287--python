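"""Compare every method against ground truth over a phantom cohort.

Generates a heterogeneous cohort (varying infarct extent, transmurality,
morphology and edema halo), runs all methods, and tabulates modified
Bland-Altman bias +/- SD, 95% limits of agreement, Lin's concordance
correlation coefficient and the bias-test p-value, one row per method.
"""

import warnings

import pandas as pd

from lgequant import compare_all, sample_cohort

warnings.filterwarnings("ignore")

pd.set_option("display.width", 120)

cases = sample_cohort(12, seed=1)
table = compare_all(cases)
cols = ["method", "ccc", "slope", "intercept", "bias", "sd_diff",
        "loa_low", "loa_high", "p_value"]
print(table[cols].round(3).to_string(index=False))

# Reading the table: bias is the mean of (method - truth) in %-points of LV
# mass; a p-value below 0.05 marks a statistically significant bias.  The
# intensity-weighted and feature-based methods (EWA, Heiberg-08, FACT) and
# FWHM track the truth closely, while the n-SD family overestimates -- most
# at 2 SD, least at 6 SD -- because low thresholds sweep up the enhancing
# edema halo and noise.  Otsu always finds two classes, infarct or not.
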