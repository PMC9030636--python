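"""Run the complete clinical pipeline on a batch of synthetic cases.

For each case: measure dimensions from the landmarks, compute the
(A/B)xH360 index, select the best bank template for the implanted side,
register it with the four landmarks, classify every electrode, and compare
with the simulator's ground truth.
"""

import scalafit as sf
from scalafit.pipeline import case_from_synthetic
from scalafit.studies import build_synthetic_bank

bank, _ = build_synthetic_bank(seed=7)
config = sf.PipelineConfig()

cases = [case_from_synthetic(c) for c in sf.synth_cohort(10, seed=5)]
summary = sf.run_batch(config, cases, bank)

cols = ["case_id", "index_value", "template", "rms_residual_mm",
        "n_st", "n_int", "n_sv", "translocated", "accuracy"]
print(summary[cols].to_string(index=False,
                              float_format=lambda v: f"{v:.3f}"))
print("\nEach row is one implanted cochlea: the measured index picked the "
      "template, rms_residual_mm is the landmark merge error, and accuracy "
      "compares the per-electrode calls with the simulator's ground truth.")
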