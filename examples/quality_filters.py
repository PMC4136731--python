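"""Record-level quality filtering of an eye-level study table.

Attaches perimetry reliability indices and OCT signal strength to a
synthetic table, then applies the study's inclusion rules: fixation
losses < 33%, false positives/negatives < 20%, signal strength >= 7/10.
"""

import numpy as np

from gcc2vfs import CohortConfig, generate_cohort
from gcc2vfs.io import apply_quality_filters

table = generate_cohort(CohortConfig(n_eyes=20, seed=4))
rng = np.random.default_rng(0)
table["fixation_loss_frac"] = rng.uniform(0.0, 0.5, len(table))
table["false_pos_frac"] = rng.uniform(0.0, 0.3, len(table))
table["false_neg_frac"] = rng.uniform(0.0, 0.3, len(table))
table["ssi"] = rng.integers(5, 11, len(table))

kept, report = apply_quality_filters(table)
print(f"input eyes:               {report.n_input}")
print(f"excluded (reliability):   {report.n_excluded_reliability}")
print(f"excluded (signal index):  {report.n_excluded_ssi}")
print(f"retained for analysis:    {report.n_retained}")
for eye, reason in report.excluded.items():
    print(f"  {eye}: {reason}")
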