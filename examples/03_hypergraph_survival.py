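"""The full two-step protocol: encoder graph + hypergraph network + survival.

Trains on one synthetic cohort, locks the model, applies it to a second
held-out cohort (which gets its own graph via the trained encoder), and
reports Harrell C-indices for both endpoints.
"""

from hypersurv import (
    DHGNConfig,
    PAEConfig,
    PipelineConfig,
    SyntheticConfig,
    generate_cohort,
    harrell_c,
)
from hypersurv.pipeline import fit_pipeline, score_cohort

train_cohort, _ = generate_cohort(SyntheticConfig(n=300, seed=1))
test_cohort, _ = generate_cohort(SyntheticConfig(n=150, seed=10001))

config = PipelineConfig(seed=1, cv_folds=5, pae=PAEConfig(seed=1), dhgn=DHGNConfig(seed=1))
fitted = fit_pipeline(train_cohort, config)
print(f"training graph: {fitted.n_edges} hyperedges over {train_cohort.n_patients} patients")
print(f"cross-validated C-index (PFS): {fitted.cv.mean_cindex:.3f}")

scores, hg_test = score_cohort(fitted, test_cohort)
for endpoint in ("pfs", "os"):
    times, events = getattr(test_cohort, endpoint)()
    c, ci = harrell_c(scores.values, times, events, n_boot=500, seed=1)
    print(f"held-out C-index ({endpoint.upper()}): {c:.3f}  95% CI ({ci[0]:.3f}, {ci[1]:.3f})")
print()
print("The model is trained once on PFS; the same locked scores are evaluated")
print("against both PFS and OS. C-indices above 0.5 mean higher-scored patients")
print("survive longer; ~0.7 matches what population-graph models achieve on")
print("real immunotherapy cohorts.")
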