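"""Assign the four epigenetic feature groups to each guide by position.

T = four signed TSS distances (primary/secondary CAGE TSS x two anchors),
A = chromatin accessibility (ATAC), M = DNA methylation (coverage-weighted
over a +/-100 bp window), R = RNA expression. All seven scalars are min-max
normalized to [0,1] with training-set statistics.
"""

import epiguide as eg
from epiguide.annotate import annotate_dataset, fit_norm_stats, apply_norm_stats

dataset, tracks, _ = eg.simulate_screen(eg.preset("smoke", seed=1))

raw = annotate_dataset(dataset, tracks)
print("raw feature slots (TSS distances in bp, tracks on their own scales):")
print(raw.head(4).round(2).to_string())

stats = fit_norm_stats(raw)
norm = apply_norm_stats(raw, stats)
print()
print("after min-max normalization (all slots in [0,1]):")
print(norm.head(4).round(3).to_string())
print()
print(f"normalization stats kept for reuse on new data, e.g. atac: "
      f"min={stats.minima['atac']:.3f} max={stats.maxima['atac']:.3f}")
# The stats are fit once on training data and reapplied verbatim (with
# clipping) to validation/test/prediction inputs to avoid leakage.
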