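"""The full simulated experiment: an 8-listener cohort in five conditions.

Each listener identifies all 54 test contours twice per condition
(vibration alone, 4- or 8-channel vocoder alone, and the two combinations).
Takes ~1 minute, dominated by vocoding the stimulus set once up front.
"""

import numpy as np
import pandas as pd

from mcisim.cohort import CohortSpec, cohort_summary, sample_cohort
from mcisim.experiment import CONDITIONS, prepare_stimuli, run_mci_condition
from mcisim.stimuli import generate_test_set

rng = np.random.default_rng(42)
prepared = prepare_stimuli(generate_test_set(), seed=42)
listeners = sample_cohort(CohortSpec(rng_seed=42))
print(cohort_summary(listeners).round(3).to_string(index=False))

rows = []
for i, listener in enumerate(listeners):
    for cond in CONDITIONS:
        res = run_mci_condition(listener, prepared, cond, n_runs=2, rng=rng)
        rows.append({"listener": i, "condition": cond, "pct": res.percent_correct,
                     **{f"f0_{int(k)}": v for k, v in res.by_middle_f0().items()},
                     **{f"iv_{k}": v for k, v in res.by_interval().items()}})
df = pd.DataFrame(rows)
print("\ncohort means by condition (percent correct):")
print(df.groupby("condition").mean().drop(columns="listener").round(1).to_string())
df.to_csv("scratch/cohort_results.csv", index=False)
# Expected structure: vibration-alone ~ 4-channel < 8-channel; accuracy
# rising with interval size; the 4-channel condition gains from added
# vibration mostly at 880 Hz, where its own pitch cues are weakest.
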