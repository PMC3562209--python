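"""Simulate a full 20-scan screen and recover the planted interactions.

Builds the study-scale synthetic experiment (9,125 proteins, 10 RNA loci
probed on both strands, 137 planted sense-specific interactions), runs the
complete pipeline, and compares the recovered binary interaction matrix to
the planted truth.
"""

from rbpscreen import analyze_scans
from rbpscreen.synthetic import SimConfig, simulate_experiment

cfg = SimConfig.default(seed=1)
scans, truth = simulate_experiment(cfg)
result = analyze_scans(scans, seed=cfg.seed)

print(f"scans analysed:                 {result.summary['n_scans']}")
print(f"proteins per array:             {result.summary['proteins_tested']}")
print(f"proteins binding >= 1 RNA:      {result.summary['any_rna_binders']}")
print(f"sense-specific interactions:    {result.matrix.n_interactions}")
print(f"common binders (>= 75% scans):  {len(result.common)}")

recovered = {(p, r) for p in result.matrix.proteins for r in result.matrix.rnas
             if result.matrix.values.loc[p, r] == 1}
tp = len(recovered & truth.interactions)
print(f"planted interactions recovered: {tp} / {len(truth.interactions)}")
# The matrix cell (protein, RNA) is 1 iff the protein passed the dual filter
# (every duplicate spot >= 2.5-fold over background AND Z >= 3) on the sense
# scan but not on the antisense scan of that locus.
#
# At the default noise level a handful of planted binders sit exactly at the
# 2.5-fold cutoff, where measurement noise drops one duplicate below
# threshold about half the time — so recovery is high but not perfect. With
# noise switched off (nonspecific_log_sd=0, duplicate_log_sd=0) recovery is
# exact, and with planted folds >= 4 it is complete even under noise.
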