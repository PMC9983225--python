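"""Call two-group DMRs and score them against planted truth.

Simulates two balanced 5-sample groups at ~30x coverage with 60 planted
regions (|delta-beta| 0.3-0.5), runs the caller, and reports recovery
at 50% reciprocal overlap.
"""

import dmrcascade as dc

cfg = dc.recovery_config(seed=1)
genes = dc.simulate_gene_models(cfg)
matrix, truth = dc.simulate_methylation_cohort(cfg, genes)

groups = matrix.samples.groupby("group")["sample_id"].apply(list)
calls = dc.call_dmrs(matrix, groups["t821"], groups["non_t821"])

truth_regions = [
    dc.DMR(chrom=t.chrom, start=t.start, end=t.end,
           delta=t.effect_size, direction=t.direction)
    for t in truth.itertuples(index=False)
]
score = dc.score_recovery(calls, truth_regions)

print(f"planted regions: {score.n_truth}   called regions: {score.n_called}")
print(f"recall: {score.recall:.3f}   precision: {score.precision:.3f}")
for c in calls[:3]:
    print(f"  {c.chrom}:{c.start}-{c.end}  n_cpgs={c.n_cpgs} "
          f"delta={c.delta:+.2f} {c.direction}  q={c.q_value:.2e}")
print(
    "\ndelta is the group-a minus group-b mean methylation level; a call\n"
    "matches truth when the intervals share >= 50% of each other's length\n"
    "with the same direction."
)
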