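"""Precision-based filtering of a fused call set.

Shows how the expected-precision curve turns a target precision into a
cutoff on the ranked list, and how the estimated TP/FP counts at the
cutoff read off the curve.
"""

from vcfuse.pipeline import run_fusion
from vcfuse.precision import filter_at_precision
from vcfuse.svm_fusion import GridConfig
from vcfuse.synthetic import TruthModel, default_profiles, simulate_callsets, simulate_truth

model = TruthModel(reference_length=60_000, n_sites=400, snp_fraction=0.8,
                   n_samples=4, seed=7)
truth = simulate_truth(model)
callsets, _ = simulate_callsets(truth, default_profiles(4), 7)
result = run_fusion(callsets, reference=truth.reference,
                    grid=GridConfig(seed=7, fine_halfwidth=0.4))

curve = result.curve
print(f"{len(curve)} ranked variants; "
      f"expected precision spans {curve.e_prec[0]:.3f} .. {curve.e_prec[-1]:.3f}")

for target in (0.99, 0.95, 0.90, 0.80):
    i, threshold = filter_at_precision(curve, target)
    tp = curve.tp_est[i - 1] if i else 0.0
    fp = curve.fp_est[i - 1] if i else 0.0
    print(f"target precision {target:.2f}: keep top {i:>4} variants "
          f"(probability >= {threshold:.4f}), estimated TP {tp:7.1f} / FP {fp:5.1f}")

print("\nLowering the target precision keeps more variants (higher recall) at "
      "the cost of more expected false calls; the expected FDR at each cutoff "
      "is 1 minus the target.")
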