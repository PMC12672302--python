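"""Run the full two-stage pipeline and print the horizon-stratified metrics.

Simulate -> filter/label/split -> weighted logistic Stage 1 -> per-stratum
FPCA -> routed trajectory prediction on the test split -> RMSE/R^2 by
prediction horizon with eye-level bootstrap CIs.
"""

import warnings

from vfcast import PipelineConfig, run_pipeline
from vfcast.simulate import SimConfig

cfg = PipelineConfig(sim=SimConfig(n_eyes=1000, seed=5), seed=5, bootstrap_B=300)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    report = run_pipeline(cfg)

c = report["counts"]
print(f"retained eyes: {c['eyes']} ({c['fast_eyes']} labeled fast) from {c['patients']} patients")
s1 = report["stage1"]["test_metrics"]
print(f"Stage 1 (test): AUROC {s1['auroc']:.3f}  balanced acc {s1['balanced_accuracy']:.3f}  "
      f"F1 {s1['f1']:.3f}  threshold {report['stage1']['threshold']:.2f}  "
      f"class weight {report['stage1']['class_weight']:.2f}")
print("\nTrajectory metrics by horizon (true-label strata, bootstrap medians):")
for strat in ("slow", "fast"):
    print(f"  {strat} progressors:")
    for row in report["trajectory"]["by_true_label"][strat]:
        r2 = row.get("r2_median")
        rmse = row.get("rmse_median")
        if rmse is None:
            print(f"    {row['interval']:<20} n={row['n']:<4} (insufficient data)")
        else:
            r2s = f"{r2:6.3f}" if isinstance(r2, float) and r2 == r2 else "   n/a"
            print(f"    {row['interval']:<20} n={row['n']:<4} RMSE {rmse:5.2f}  R^2 {r2s}")
print("\nNear-term predictions are sharp; accuracy decays with horizon, and the small")
print("fast stratum is noisy at long horizons — misrouted eyes carry the wrong mean.")
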