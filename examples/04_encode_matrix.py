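"""Encode one sgRNA as the model's channels x positions input matrix.

The default silencing encoder emits an 11 x 40 matrix: rows 1-4 one-hot the
40-mer context (9 bp upstream + 20 bp protospacer + 3 bp PAM + 8 bp
downstream) in fixed A/C/G/T order; rows 5-11 broadcast the seven
normalized epigenetic scalars as constant rows.
"""

import numpy as np

import epiguide as eg
from epiguide.encode import EncoderConfig, extract_context

dataset, tracks, _ = eg.simulate_screen(eg.preset("smoke", seed=1))
labels = eg.assign_labels(dataset)
samples = eg.encode_screen(dataset, tracks, labels=labels)

rec = dataset.records[0]
cfg = EncoderConfig()
seq = extract_context(rec, tracks.genome, cfg)
print(f"guide {rec.sgrna_id} ({rec.strand} strand)")
print(f"40-mer context: {seq}")
print(f"                {' ' * 9}{'^' * 20}{'*' * 3}        (protospacer ^, PAM *)")
print()
m = samples.X[0]
print(f"matrix shape: {m.shape}  (channels: {', '.join(samples.channels)})")
print("sequence rows, first 12 positions:")
for name, row in zip("ACGT", m[:4, :12].astype(int)):
    print(f"  {name}: {row}")
print(f"epigenetic rows are constant, e.g. atac = {m[8, 0]:.3f}")
print(f"every sequence column sums to 1: {bool(np.all(m[:4].sum(axis=0) == 1))}")
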