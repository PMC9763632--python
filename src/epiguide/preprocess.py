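"""Phenotype-score transformation, per-gene activity normalization and labels.

Growth screens report a phenotype score per sgRNA where, for silencing
screens, more negative means a stronger growth defect (stronger knock-down).
The pipeline is:

1. ``transform_scores`` — flip the sign of silencing-screen scores so that
   larger always means more active; activation scores pass through.
2. ``compute_activity_scores`` — divide each guide's transformed score by the
   absolute mean of the gene's top-k (default 3) transformed scores, so the
   best guides of each gene sit near 1.
3. ``assign_labels`` — binarize: phenotype < -0.1 (raw scale) or activity
   > 0.75, both strict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .io import ScreenDataset


@dataclass
class PreprocessConfig:
    top_k: int = 3
    phenotype_label_cutoff: float = -0.1   # label 1 when raw phenotype < cutoff
    activity_label_cutoff: float = 0.75    # label 1 when activity > cutoff
    genewise_normalization: bool = True

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not (math.isfinite(self.phenotype_label_cutoff) and math.isfinite(self.activity_label_cutoff)):
            raise ValueError("cutoffs must be finite")


@dataclass
class ActivityReport:
    """Guides excluded from model input because their gene's top-k mean is 0."""

    undefined_activity_ids: List[str] = field(default_factory=list)
    n_missing_score: int = 0


def transform_scores(dataset: ScreenDataset) -> ScreenDataset:
    """Sign-flip silencing phenotype scores so large = more active.

    An involution on the silencing branch (applying it twice restores the
    input); activation datasets pass through unchanged. Missing scores
    propagate as missing.
    """
    if dataset.score_kind != "phenotype":
        raise ValueError("transform_scores expects phenotype scores")
    if dataset.direction == "activation":
        return dataset
    flipped = [None if r.raw_score is None else -r.raw_score for r in dataset.records]
    return dataset.with_scores(flipped, score_kind="phenotype")


def _topk_mean(values: np.ndarray, k: int) -> float:
    """Mean of the k largest values (stable order on ties); all values if
    fewer than k are available."""
    if len(values) <= k:
        top = values
    else:
        # stable selection: indices of the k largest by value, ties by input order
        order = np.argsort(-values, kind="stable")[:k]
        top = values[order]
    return float(np.mean(top))


def compute_activity_scores(
    dataset: ScreenDataset, cfg: Optional[PreprocessConfig] = None
) -> tuple[ScreenDataset, ActivityReport]:
    """Per-gene normalization: activity_i = s_i / |mean(top-k s)|.

    Expects already sign-transformed scores. Genes whose top-k mean is
    exactly zero get their guides flagged undefined (activity missing) and
    reported; genes with fewer than k scored guides fall back to the mean of
    all available. With ``genewise_normalization`` disabled (single-guide
    genome-wide libraries), transformed scores are used as activities as-is.
    """
    cfg = cfg or PreprocessConfig()
    report = ActivityReport()
    scores = dataset.scores()
    report.n_missing_score = int(np.isnan(scores).sum())

    if not cfg.genewise_normalization:
        out = [None if np.isnan(s) else float(s) for s in scores]
        return dataset.with_scores(out, score_kind="activity"), report

    genes = np.array(dataset.genes())
    activities: List[Optional[float]] = [None] * len(scores)
    for gene in dict.fromkeys(genes):  # unique genes, first-seen order
        idx = np.flatnonzero(genes == gene)
        vals = scores[idx]
        ok = ~np.isnan(vals)
        if not ok.any():
            continue
        denom = abs(_topk_mean(vals[ok], cfg.top_k))
        for i, s in zip(idx, vals):
            if np.isnan(s):
                continue
            if denom == 0.0:
                report.undefined_activity_ids.append(dataset.records[i].sgrna_id)
            else:
                activities[i] = float(s / denom)
    return dataset.with_scores(activities, score_kind="activity"), report


def assign_labels(dataset: ScreenDataset, cfg: Optional[PreprocessConfig] = None) -> np.ndarray:
    """Binary activity labels; missing score -> NaN label (excluded from
    classification training).

    Phenotype rule (applied on the raw, untransformed scale): label 1 iff
    score < phenotype_label_cutoff. Activity rule: label 1 iff
    score > activity_label_cutoff. Both inequalities strict.
    """
    cfg = cfg or PreprocessConfig()
    scores = dataset.scores()
    labels = np.full(len(scores), np.nan)
    ok = ~np.isnan(scores)
    if dataset.score_kind == "phenotype":
        labels[ok] = (scores[ok] < cfg.phenotype_label_cutoff).astype(float)
    else:
        labels[ok] = (scores[ok] > cfg.activity_label_cutoff).astype(float)
    return labels
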