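"""Model interpretation: global tabular importance and positional saliency.

Two complementary tracks, mirroring how sgRNA design rules are usually
distilled from a trained predictor:

* ``engineer_features`` + ``tree_importance`` — hand-crafted tabular features
  (position-specific mono-/di-nucleotides over the 23-mer with the PAM at
  positions 21-23, GC content, melting temperatures, the seven epigenetic
  slots) fit with gradient-boosted trees; per-feature importance is the mean
  |SHAP| over training samples, computed by xgboost's exact TreeSHAP.
* ``deep_attribution`` — expected gradients (integrated gradients averaged
  over a background sample set) on the convolutional network, yielding a
  signed mean attribution per (position, base). Positive = the base at that
  position pushes predicted activity up.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import xgboost as xgb
from Bio.SeqUtils import MeltingTemp

from .encode import BASES
from .io import SgRNARecord

DINUCLEOTIDES = tuple(a + b for a in BASES for b in BASES)

#: protospacer sub-segments (1-based, inclusive) whose melting temperature is
#: computed alongside the whole-protospacer Tm
TM_SEGMENTS = {"Tm_full": (1, 20), "Tm_seg1": (3, 7), "Tm_seg2": (8, 15), "Tm_seg3": (16, 20)}


def _tm(seq: str, method: str) -> float:
    if method == "wallace":
        return float(MeltingTemp.Tm_Wallace(seq))
    if method == "nn":
        return float(MeltingTemp.Tm_NN(seq))
    raise ValueError(f"unknown Tm method {method!r}")


def feature_names(epi_slots: Sequence[str] = ()) -> List[str]:
    """Deterministic column order of the engineered feature table."""
    names = [f"{b}_{p}" for p in range(1, 24) for b in BASES]
    names += [f"{d}_{p}" for p in range(1, 23) for d in DINUCLEOTIDES]
    names += ["GC_count", "GC_dinucleotide_count"]
    names += list(TM_SEGMENTS)
    names += list(epi_slots)
    return names


def engineer_features(
    records: Sequence[SgRNARecord],
    epi: Optional[pd.DataFrame] = None,
    tm_method: str = "nn",
) -> pd.DataFrame:
    """Tabular feature matrix over the 23-mer (protospacer + PAM).

    Features: binary indicators ``BASE_pos`` (positions 1-23, PAM = 21-23)
    and ``DIMER_pos`` (dimer starting at pos, 1-22); GC count and GC-dimer
    count of the 20-nt protospacer; nearest-neighbor (or Wallace-rule)
    melting temperatures of the protospacer and three sub-segments; plus the
    epigenetic slots when a feature table is supplied.
    """
    epi_slots = tuple(epi.columns) if epi is not None else ()
    cols = feature_names(epi_slots)
    rows = np.zeros((len(records), len(cols)))
    index = []
    col_index = {c: j for j, c in enumerate(cols)}
    for i, rec in enumerate(records):
        mer = rec.protospacer + rec.pam
        if len(mer) != 23:
            raise ValueError(f"{rec.sgrna_id}: need protospacer+PAM of 23 nt, got {len(mer)}")
        if not set(mer) <= set(BASES):
            raise ValueError(f"{rec.sgrna_id}: non-ACGT base in 23-mer")
        for p, b in enumerate(mer, start=1):
            rows[i, col_index[f"{b}_{p}"]] = 1.0
        for p in range(1, 23):
            rows[i, col_index[f"{mer[p-1:p+1]}_{p}"]] = 1.0
        proto = rec.protospacer
        rows[i, col_index["GC_count"]] = sum(c in "GC" for c in proto)
        rows[i, col_index["GC_dinucleotide_count"]] = sum(
            proto[j] in "GC" and proto[j + 1] in "GC" for j in range(len(proto) - 1)
        )
        for name, (lo, hi) in TM_SEGMENTS.items():
            rows[i, col_index[name]] = _tm(proto[lo - 1 : hi], tm_method)
        if epi is not None:
            for slot in epi_slots:
                rows[i, col_index[slot]] = float(epi.loc[rec.sgrna_id, slot])
        index.append(rec.sgrna_id)
    return pd.DataFrame(rows, index=index, columns=cols)


@dataclass
class TreeImportanceResult:
    importance: pd.Series          # feature -> mean |SHAP|, descending
    shap_values: np.ndarray        # n_samples x (n_features + 1); last col = bias
    expected_value: float
    model: object
    seed: int

    def top(self, k: int = 30) -> pd.Series:
        return self.importance.head(k)


def tree_importance(
    features: pd.DataFrame,
    targets: np.ndarray,
    seed: int = 0,
    n_estimators: int = 200,
    max_depth: int = 6,
    learning_rate: float = 0.1,
) -> TreeImportanceResult:
    """Fit gradient-boosted trees and rank features by mean |SHAP|.

    SHAP values are exact TreeSHAP as implemented inside xgboost
    (``pred_contribs``); per-sample contributions plus the bias term sum to
    the model's margin prediction (local accuracy).
    """
    targets = np.asarray(targets, dtype=float)
    ok = ~np.isnan(targets)
    features, targets = features.iloc[np.flatnonzero(ok)], targets[ok]
    if len(features) < 50:
        raise ValueError(f"tree_importance needs >= 50 samples, got {len(features)}")
    model = xgb.XGBRegressor(
        n_estimators=n_estimators,
        max_depth=max_depth,
        learning_rate=learning_rate,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        base_score=0.5,
    )
    model.fit(features.to_numpy(), targets)
    booster = model.get_booster()
    dm = xgb.DMatrix(features.to_numpy(), feature_names=list(features.columns))
    contribs = booster.predict(dm, pred_contribs=True)
    imp = pd.Series(
        np.abs(contribs[:, :-1]).mean(axis=0), index=features.columns
    ).sort_values(ascending=False)
    return TreeImportanceResult(
        importance=imp,
        shap_values=contribs,
        expected_value=float(contribs[0, -1]),
        model=model,
        seed=seed,
    )


@dataclass
class AttributionResult:
    positional_map: pd.DataFrame    # positions (1-based, context coords) x A,C,G,T; mean signed attribution
    upstream: int                   # flank length: protospacer position p sits at context position upstream + p
    n_background: int
    n_explained: int
    seed: int
    per_sample_sums: np.ndarray = field(default_factory=lambda: np.array([]))
    completeness_reference: np.ndarray = field(default_factory=lambda: np.array([]))

    def guide_map(self) -> pd.DataFrame:
        """Positional map restricted to the 23-mer, indexed by guide position
        1-23 (PAM = 21-23)."""
        sub = self.positional_map.iloc[self.upstream : self.upstream + 23].copy()
        sub.index = pd.RangeIndex(1, 24, name="guide_position")
        return sub


def integrated_gradients(
    net, x: np.ndarray, baseline: np.ndarray, steps: int = 64
) -> np.ndarray:
    """Midpoint-rule integrated gradients of the raw network output for one
    sample against one baseline. The ReLU network is piecewise linear along
    the straight path, so the approximation converges quickly in ``steps``."""
    alphas = (np.arange(steps) + 0.5) / steps
    path = baseline[None] + alphas[:, None, None] * (x - baseline)[None]
    grads = net.input_gradient(path)
    return (x - baseline) * grads.mean(axis=0)


def deep_attribution(
    net,
    X: np.ndarray,
    n: int = 1000,
    n_background: int = 100,
    steps: int = 16,
    seed: int = 0,
    upstream: Optional[int] = None,
    n_sequence_channels: int = 4,
) -> AttributionResult:
    """Signed attribution per (position, base), averaged over the randomly
    drawn sgRNAs that carry that base at that position, computed as
    integrated gradients against a fixed background of ``n_background``
    samples drawn from ``X``.

    Conditioning on presence matters for one-hot channels: averaged over all
    guides, the positive attribution of a favorable base when present and
    the negative attribution of its absence cancel by construction, so the
    unconditional mean map is ~0 everywhere. The presence-conditioned map is
    the per-base histogram a guide designer reads: positive = base favored
    at that position.

    Per-sample attributions (summed over all channels) approximate
    prediction(x) - mean background prediction — the completeness axiom —
    with accuracy set by ``steps``. The returned map keeps only the sequence
    channels; ``upstream`` locates the protospacer inside the context (by
    default inferred from the position count, assuming the canonical flank
    split).
    """
    rng = np.random.default_rng(seed)
    n_total = X.shape[0]
    if n > n_total:
        warnings.warn(f"requested {n} samples but only {n_total} available; using all")
        explain_idx = np.arange(n_total)
    else:
        explain_idx = rng.choice(n_total, size=n, replace=False)
    bg_idx = rng.choice(n_total, size=min(n_background, n_total), replace=False)
    background = X[bg_idx]
    nb = background.shape[0]

    alphas = (np.arange(steps) + 0.5) / steps
    nsc = n_sequence_channels
    acc = np.zeros((nsc, X.shape[2]))
    count = np.zeros((nsc, X.shape[2]))
    sums = np.empty(len(explain_idx))
    for j, i in enumerate(explain_idx):
        x = X[i]
        diff = x[None] - background                                  # nb,C,L
        path = background[None] + alphas[:, None, None, None] * diff[None]
        grads = net.input_gradient(path.reshape(-1, *X.shape[1:]))
        grads = grads.reshape(steps, nb, *X.shape[1:]).mean(axis=0)  # nb,C,L
        phi = (diff * grads).mean(axis=0)                            # C,L
        present = x[:nsc] > 0.5
        acc += np.where(present, phi[:nsc], 0.0)
        count += present
        sums[j] = phi.sum()
    acc /= np.maximum(count, 1.0)

    bg_pred = net.predict_raw(background).mean()
    ref = net.predict_raw(X[explain_idx]) - bg_pred

    L = X.shape[2]
    if upstream is None:
        from .encode import flank_split

        upstream = flank_split(L)[0] if L >= 23 else 0
    pmap = pd.DataFrame(
        acc.T,
        index=pd.RangeIndex(1, L + 1, name="position"),
        columns=list(BASES),
    )
    return AttributionResult(
        positional_map=pmap,
        upstream=upstream,
        n_background=nb,
        n_explained=len(explain_idx),
        seed=seed,
        per_sample_sums=sums,
        completeness_reference=ref,
    )
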