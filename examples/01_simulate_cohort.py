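"""Generate a synthetic glaucoma cohort and inspect its composition.

Builds visual-field (VF) and EHR tables for 2,000 eyes with the cohort
structure the pipeline assumes: ~9% fast progressors, sparse irregular visit
schedules (median 4 tests per eye), and baseline covariates linked to the
progression phenotype.
"""

import numpy as np

from vfcast import SimConfig, simulate_cohort

vf, ehr, truth = simulate_cohort(SimConfig(n_eyes=2000, seed=42))

fast_frac = (truth.eyes["true_class"] == "fast").mean()
counts = vf.groupby(["patient_id", "eye"])["test_date"].count()
span = vf.groupby(["patient_id", "eye"])["test_date"].agg(lambda s: s.max() - s.min())

print(f"VF rows: {len(vf)}   EHR rows (patients): {len(ehr)}   eyes: {len(truth.eyes)}")
print(f"fast-progressor fraction: {fast_frac:.4f}  (generative target 0.0892)")
print(f"median tests per eye: {np.median(counts):.0f}   median follow-up span: {span.median():.0f} days")
age = ehr.groupby(ehr["patient_id"].isin(
    truth.eyes.loc[truth.eyes.true_class == "fast", "patient_id"]))["age_baseline"].mean()
print(f"mean baseline age — patients with a fast eye: {age.get(True, float('nan')):.1f} y, "
      f"others: {age.get(False, float('nan')):.1f} y")
print("\nFast eyes are generated younger and declining ~-2.5 dB/year in mean deviation;")
print("slow eyes are stable (~+0.2 dB/year). The tables feed the cohort pipeline as CSV.")
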