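"""Generate a synthetic CRISPR silencing screen with planted ground truth.

The generator emits everything the real pipeline consumes: a toy genome,
gene-grouped sgRNAs with phenotype scores, a TSS table, and bedGraph-style
ATAC/methylation/expression tracks. The truth table records each guide's
latent activity, so downstream recovery can be verified.
"""

import epiguide as eg

cfg = eg.preset("smoke", seed=1)
dataset, tracks, truth = eg.simulate_screen(cfg)

print(f"screen: {len(dataset)} sgRNAs across {cfg.n_genes} genes "
      f"({cfg.guides_per_gene} guides each)")
print(f"genome: {tracks.genome.length(cfg.chrom):,} bp on {cfg.chrom}")
print(f"planted sequence effects: {cfg.sequence_effects}")
print()
print("first three guides:")
for rec in dataset.records[:3]:
    print(f"  {rec.sgrna_id}  {rec.chrom}:{rec.start}-{rec.end}({rec.strand})  "
          f"{rec.protospacer}+{rec.pam}  phenotype={rec.raw_score:+.3f}")
print()
print("truth table head (latent activity decomposed into its components):")
print(truth.head(3).round(3).to_string())
# A negative phenotype score means a stronger growth defect, i.e. a more
# active silencing guide; latent_activity = seq + epi + TSS-proximity + noise.
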