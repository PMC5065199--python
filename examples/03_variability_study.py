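"""Run a small end-to-end variability study and print the CV table.

Simulates lesions read by two readers (reader 1 twice) on three
reconstruction variants, extracts all 15 features for each of the nine
measurements per lesion, and summarizes variability by source as
coefficients of variation with robustness categories.
"""

from ctradiomics import StudyConfig, run_study

config = StudyConfig(
    n_lesions=8,
    seed=11,
    grid_shape=(64, 64, 48),
    size_mean_mm=20.0,
    size_sd_mm=5.0,
    size_range_mm=(12.0, 30.0),
)
result = run_study(config)

print(f"{len(result.features)} feature rows ({config.n_lesions} lesions x 9 measurements)")
cols = ["feature", "cv_intra_reader", "cv_inter_reader",
        "cv_recon_FBP_S3", "cv_recon_FBP_S5", "cv_recon_S3_S5"]
print(result.cv_table[cols].to_string(index=False, float_format="%.2f"))

print("\nAlgorithm comparison (reader R1):")
print(result.comparisons["R1"][["feature", "test", "p_value"]]
      .to_string(index=False))

# CVs are in percent; intra-reader (repeat reads, 0.3 mm jitter) is smaller
# than inter-reader (0.8 mm jitter); inter-reconstruction CVs are zero for
# shape features because the identical ROI is propagated, and the
# shape-feature comparison test is the explicit not-available sentinel.
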