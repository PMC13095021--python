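"""Generate a synthetic immunotherapy cohort and inspect its structure.

Draws 300 patients with nine baseline clinical variables, a 120-feature
radiomics table, and censored PFS/OS endpoints, then prints the cohort
marginals next to their configured targets.
"""

import numpy as np

from hypersurv import SyntheticConfig, generate_cohort

cfg = SyntheticConfig(n=300, seed=1)
cohort, truth = generate_cohort(cfg)

clin = cohort.clinical
print(f"patients: {cohort.n_patients}, radiomics features: {cohort.radiomics.n_features}")
print(f"male fraction        {(clin.sex == 'male').mean():.3f}  (target {cfg.p_male})")
print(f"smoking fraction     {(clin.smoking == 'yes').mean():.3f}  (target {cfg.p_smoking})")
print(f"median age           {clin.age.median():.1f}   (target {cfg.age_median})")
print(f"median dNLR          {clin.dnlr.median():.2f}   (target {cfg.dnlr_median})")
print(f"median true PFS time {np.median(truth.event_time):.2f}  (target {cfg.median_pfs} months)")
print(f"event fraction       {cohort.survival.pfs_event.mean():.3f}  "
      f"(target {1 - cfg.censor_frac:.3f})")
print()
print("Each patient carries a latent prognosis class; the class shifts a subset of")
print("clinical variables and, together with an idiosyncratic radiomics factor,")
print("drives an exponential proportional-hazards PFS time.")
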