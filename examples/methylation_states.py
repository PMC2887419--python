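"""Classify methylation states of CpGs and islands on simulated data.

Simulates a 12-tissue amplicon-style methylation table over a genome with
planted unmethylated, methylated and differentially methylated islands,
classifies each CpG by the 80/20 rules with clone/tissue filters, rolls the
CpG states up to island labels, and checks them against the planted truth.
Also reports methylation heterogeneity of sliding-window islands that host
several cluster islands.
"""

from collections import Counter

from cgikit import (
    SimulationConfig,
    classify_cpgs_table,
    classify_island,
    predict_islands,
    scan_cpg_positions,
    simulate_genome,
    simulate_methylation,
    swa_heterogeneity,
    tj_predict,
)

config = SimulationConfig(seed=8, genome_length=300_000, n_islands=20)
chrom, truth = simulate_genome(config)
table, planted = simulate_methylation(chrom, truth, config)
print(f"{len(table):,} methylation records; planted labels: {Counter(planted.values())}")

states = classify_cpgs_table(table)
pos_states = {p: s for (_, p), s in states.items()}
print(f"CpG states: {Counter(s.value for s in states.values())}")

positions = scan_cpg_positions(chrom)
correct = 0
for iv in truth:
    cpgs = positions[(positions >= iv.start) & (positions < iv.end)].tolist()
    predicted = classify_island(cpgs, pos_states)
    correct += predicted.value == planted[iv.label]
print(f"island labels recovered: {correct}/{len(truth)}")

outer = tj_predict(chrom)
inner = predict_islands(chrom)
het = swa_heterogeneity(outer, inner, table)
print(
    f"window islands hosting >=2 cluster islands: {het.n_tested} "
    f"(skipped {het.n_skipped}); fraction with max methylation difference "
    f"> 30 points: {het.fraction_above:.2f}"
)
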