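"""Filter radiomics features by agreement across repeat readings.

Simulates two replicate feature tables (repeat segmentations by independent
readers) at two noise levels and shows how the ICC(2,1) filter keeps
reproducible features and drops unreliable ones.
"""

from hypersurv import SyntheticConfig, generate_cohort, icc_filter
from hypersurv.simulate import generate_replicates

cohort, _ = generate_cohort(SyntheticConfig(n=100, seed=5))

for noise in (0.2, 0.8, 2.0):
    reps = generate_replicates(cohort, noise_sd=noise, n_replicates=2, seed=5)
    report = icc_filter(cohort.radiomics, reps, threshold=0.75)
    kept = report.selected.sum()
    mean_icc = report.to_frame()["icc"].mean()
    print(f"reader noise sd {noise:.1f}: mean ICC {mean_icc:.3f}, "
          f"kept {kept}/{report.to_frame().shape[0]} features at threshold 0.75")
print()
print("Features of unit variance have expected ICC = 1 / (1 + noise_sd^2):")
print("mild reader noise keeps everything, heavy noise fails the 0.75 bar,")
print("mirroring reproducibility filtering of real radiomics panels.")
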