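"""Attribute predictions to sequence features with both interpretation
tracks: TreeSHAP on engineered tabular features, and expected-gradients
attribution on the trained network.

The screen plants '+G at protospacer position 20' as the dominant rule, so
both tracks should surface G_20 / (position 20, G) at the top.
"""

import numpy as np

import epiguide as eg
from epiguide.interpret import deep_attribution, engineer_features, tree_importance
from epiguide.model import SplitPlan, train
from epiguide.nn import ModelConfig

cfg = eg.preset("planted-seq", seed=7, n_genes=300)
dataset, tracks, truth = eg.simulate_screen(cfg)
labels = eg.assign_labels(dataset)
samples = eg.encode_screen(dataset, tracks, labels=labels)
model, report = train(samples, SplitPlan(seed=7),
                      ModelConfig(task="classification", max_epochs=12, patience=4, seed=7))
print(f"trained CNN, held-out AUC {report.auc:.3f}")

# --- track 1: TreeSHAP on engineered features (latent activity as target)
feats = engineer_features(dataset.records, tm_method="wallace")
res = tree_importance(feats, truth["latent_activity"].to_numpy(), seed=0)
print("\ntop 5 features by mean |SHAP| (TreeSHAP on gradient-boosted trees):")
for name, value in res.top(5).items():
    print(f"  {name:<8} {value:.3f}")

# --- track 2: expected gradients on the CNN, per (position, base)
attr = deep_attribution(model.net, samples.X, n=300, n_background=25, steps=16, seed=0)
gm = attr.guide_map()
pos, base = gm.abs().stack().idxmax()
print(f"\ndeep attribution peak: base {base} at protospacer position {pos} "
      f"(signed value {gm.loc[pos, base]:+.3f}; positive = favored)")
print("positions 16-23 of the signed map:")
print(gm.loc[16:23].round(3).to_string())
# Both tracks should rank the planted G at position 20 first, mirroring how
# PAM-proximal guanine is reported to favor efficient silencing/activation.
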