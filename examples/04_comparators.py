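"""Supervised encoder graph vs unsupervised Gower graph vs Cox controls.

Runs every comparator on the same train/test cohorts: the hypergraph network
on the encoder-derived graph, the same network on a Gower-distance
ε-radius graph (ε = 0.5), and the three screened Cox models (clinical-only,
radiomics-only, composite).
"""

from hypersurv import DHGNConfig, PAEConfig, PipelineConfig, SyntheticConfig, generate_cohort
from hypersurv.pipeline import run_comparison

train_cohort, _ = generate_cohort(SyntheticConfig(n=300, seed=1))
test_cohort, _ = generate_cohort(SyntheticConfig(n=150, seed=10001))
config = PipelineConfig(seed=1, cv_folds=0, pae=PAEConfig(seed=1), dhgn=DHGNConfig(seed=1))

report = run_comparison(config, train_cohort=train_cohort, test_cohort=test_cohort)
print(f"{'model':26s}  C-index (PFS)   C-index (OS)")
for name in ("dhgn_pae", "dhgn_gower", "cox_clinical", "cox_radiomics", "cox_composite"):
    entry = report[name]
    if entry.get("degenerate"):
        print(f"{name:26s}  degenerate (nothing passed the univariate screen)")
        continue
    print(f"{name:26s}  {entry['cindex_pfs']:.3f}          {entry['cindex_os']:.3f}")
print()
print("The encoder graph should outperform the unsupervised Gower graph and all")
print("three Cox controls: supervision concentrates edges on prognostically")
print("similar patients, which the shared-weight network exploits.")
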