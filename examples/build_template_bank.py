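"""Build a 5-template membrane bank and measure how well it fits a cohort.

Emulates the bank-construction procedure: 22 specimen-like cochleae are
candidates, a Gaussian is fitted to the (A/B)xH360 index of 100
patient-like cochleae, and the candidates nearest the 10/30/50/70/90th
percentiles become the bank.  A fresh 30-case cohort then selects its best
template by measured index, registers it through the four landmarks, and
reports the membrane-to-membrane distance over the 90-540 degree window.
"""

from scalafit.studies import build_synthetic_bank, run_bank_fit_study

bank, reference = build_synthetic_bank(n_candidates=22, n_reference=100, seed=7)

print("reference index sample: "
      f"mean {reference.mean():.2f}, sd {reference.std(ddof=1):.2f} (n=100)")
print("bank template indices (right side):",
      [f"{v:.3f}" for v in bank.index_values])
print("selection percentiles:", bank.selection_percentiles)

fit = run_bank_fit_study(n_cases=30, seed=1, bank=bank)
print(f"\nmean membrane distance after registration: "
      f"{fit.mean_distances.mean():.3f} mm "
      f"(sd {fit.mean_distances.std(ddof=1):.3f}, n={fit.n_cases})")
print(f"without registration the same comparison averages "
      f"{fit.baseline_distances.mean():.1f} mm")
print(f"cases under 0.5 mm: {100 * fit.fraction_under_half_mm:.0f}%")
print("\nEach case used the template whose index was nearest its own; the "
      "residual distance reflects shape differences the similarity "
      "transform cannot absorb.")
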