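"""Benchmark predictions against a gold standard and calibrate matched sets.

Uses the planted truth of a simulated genome as the gold standard:
sensitivity counts gold islands touched by any prediction, and the
lower-bound PPV counts every non-overlapping prediction as a false
positive. Calibration then picks the p-value threshold that yields a
prediction set of exactly the sliding-window set's size, so the two
methods can be compared at matched numbers.
"""

from cgikit import (
    ClusterParams,
    SimulationConfig,
    benchmark_vs_gold,
    calibrate_pvalue_threshold,
    predict_islands,
    simulate_genome,
    tj_predict,
)

config = SimulationConfig(seed=42, genome_length=500_000, n_islands=25)
chrom, gold = simulate_genome(config)

relaxed = predict_islands(chrom, ClusterParams(pvalue_threshold=1e-5))
tj = tj_predict(chrom)

for name, pred in [("cluster relaxed", relaxed), ("sliding window", tj)]:
    r = benchmark_vs_gold(pred, gold)
    print(
        f"{name:15s} n={r.n_predicted:4d} tp={r.tp:4d} touched={r.gold_touched:3d} "
        f"fn={r.fn:2d}  SN={r.sn:.3f}  PPV>={r.ppv:.3f}"
    )

cal = calibrate_pvalue_threshold(relaxed, target_count=len(tj))
print(
    f"matched set: top {cal.n_selected} cluster islands at "
    f"-log10(p) >= {cal.log10_threshold:.2f} (tied at cut: {cal.tied})"
)
r = benchmark_vs_gold(list(cal.selected), gold)
print(f"matched-size cluster set: SN={r.sn:.3f}  PPV>={r.ppv:.3f}")
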