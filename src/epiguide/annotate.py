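"""Assign the four epigenetic feature groups to each sgRNA by position.

The feature groups (one letter each, matching the model's channel names):

* **T** — nucleosome positioning proxied by signed distance to the primary
  and secondary CAGE-defined TSS, measured from two anchors (window midpoint
  and the PAM-side window end) = 4 values per guide.
* **A** — chromatin accessibility (ATAC-seq signal overlapping the guide).
* **M** — DNA methylation (WGBS level, coverage-weighted over a +/-100 bp
  window because WGBS values are per-CpG).
* **R** — RNA expression of the locus/gene.

All seven scalars are min-max normalized to [0,1] with statistics fit on the
training split only and reapplied (with clipping) everywhere else.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .io import EpiTracks, IntervalValueTrack, ScreenDataset, SgRNARecord

#: ordered scalar feature slots of one EpiFeatureVector
FEATURE_SLOTS = (
    "tss_d1_primary",
    "tss_d2_primary",
    "tss_d1_secondary",
    "tss_d2_secondary",
    "atac",
    "methylation",
    "expression",
)

#: TSS distances are clipped to this range before normalization: tiling
#: libraries span +/-2.5 kb around the TSS, so larger distances carry no
#: extra information and would compress the min-max range.
TSS_CLIP_BP = 2500.0


@dataclass
class AnnotateConfig:
    atac_reducer: str = "max"
    methylation_reducer: str = "coverage_weighted_mean"
    expression_reducer: str = "mean"
    atac_window: int = 0
    methylation_window: int = 100
    expression_window: int = 0
    clip_tss_bp: float = TSS_CLIP_BP


def compute_tss_distances(record: SgRNARecord, tss_table: pd.DataFrame) -> Dict[str, Optional[float]]:
    """Four signed base-pair distances from the guide to its gene's TSSs.

    For each of the primary and secondary CAGE TSS two anchors are used: the
    integer midpoint of the 23-bp target window, and the PAM-side end of the
    window (``end`` for + strand guides, ``start`` for - strand guides).
    The sign is positive when the anchor lies downstream of the TSS in the
    gene's transcriptional orientation. A gene absent from the table yields
    four missing values.
    """
    out: Dict[str, Optional[float]] = {k: None for k in FEATURE_SLOTS[:4]}
    if record.gene not in tss_table.index:
        return out
    row = tss_table.loc[record.gene]
    orient = 1.0 if row["strand"] == "+" else -1.0
    midpoint = (record.start + record.end) // 2
    pam_anchor = record.end if record.strand == "+" else record.start
    out["tss_d1_primary"] = orient * (midpoint - float(row["primary_tss"]))
    out["tss_d2_primary"] = orient * (pam_anchor - float(row["primary_tss"]))
    out["tss_d1_secondary"] = orient * (midpoint - float(row["secondary_tss"]))
    out["tss_d2_secondary"] = orient * (pam_anchor - float(row["secondary_tss"]))
    return out


def annotate_track(
    record: SgRNARecord,
    track: IntervalValueTrack,
    reducer: str = "mean",
    window: int = 0,
) -> Optional[float]:
    """Aggregate track values overlapping [start-window, end+window).

    reducer: 'mean' (unweighted over overlapping intervals), 'max', or
    'coverage_weighted_mean' (weights = overlap lengths). No overlap ->
    missing (None).
    """
    qstart, qend = record.start - window, record.end + window
    hits = track.query(record.chrom, qstart, qend)
    if not hits:
        return None
    values = np.array([v for _, _, v in hits], dtype=float)
    if reducer == "mean":
        return float(values.mean())
    if reducer == "max":
        return float(values.max())
    if reducer == "coverage_weighted_mean":
        overlaps = np.array(
            [min(e, qend) - max(s, qstart) for s, e, _ in hits], dtype=float
        )
        return float((values * overlaps).sum() / overlaps.sum())
    raise ValueError(f"unknown reducer {reducer!r}")


def annotate_dataset(
    dataset: ScreenDataset, tracks: EpiTracks, cfg: Optional[AnnotateConfig] = None
) -> pd.DataFrame:
    """Raw (un-normalized) 7-slot feature table, one row per sgRNA.

    TSS distances are clipped to +/- ``cfg.clip_tss_bp``. Missing values are
    NaN; imputation and scaling happen in :func:`normalize_features`.
    """
    cfg = cfg or AnnotateConfig()
    rows = []
    for rec in dataset.records:
        feats = compute_tss_distances(rec, tracks.tss_table)
        feats["atac"] = annotate_track(rec, tracks.atac, cfg.atac_reducer, cfg.atac_window)
        feats["methylation"] = annotate_track(
            rec, tracks.methylation, cfg.methylation_reducer, cfg.methylation_window
        )
        feats["expression"] = annotate_track(
            rec, tracks.expression, cfg.expression_reducer, cfg.expression_window
        )
        rows.append(feats)
    df = pd.DataFrame(rows, columns=list(FEATURE_SLOTS), dtype=float)
    df.index = [r.sgrna_id for r in dataset.records]
    for col in FEATURE_SLOTS[:4]:
        df[col] = df[col].clip(-cfg.clip_tss_bp, cfg.clip_tss_bp)
    return df


@dataclass
class NormStats:
    """Per-slot min/max/median fit on training data, reapplied verbatim."""

    minima: Dict[str, float] = field(default_factory=dict)
    maxima: Dict[str, float] = field(default_factory=dict)
    medians: Dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"minima": self.minima, "maxima": self.maxima, "medians": self.medians},
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "NormStats":
        with open(path) as fh:
            d = json.load(fh)
        return cls(minima=d["minima"], maxima=d["maxima"], medians=d["medians"])


def fit_norm_stats(features: pd.DataFrame) -> NormStats:
    """Fit per-slot training median (for imputation) and min/max (after
    imputation). A slot with no observed value at all is an error: disable
    that channel instead of feeding undefined inputs to the model."""
    stats = NormStats()
    for col in features.columns:
        vals = features[col].to_numpy(dtype=float)
        obs = vals[~np.isnan(vals)]
        if obs.size == 0:
            raise ValueError(
                f"feature {col!r} has no observed values in the training set; "
                "disable this channel in the encoder configuration"
            )
        med = float(np.median(obs))
        imputed = np.where(np.isnan(vals), med, vals)
        stats.medians[col] = med
        stats.minima[col] = float(imputed.min())
        stats.maxima[col] = float(imputed.max())
    return stats


def apply_norm_stats(features: pd.DataFrame, stats: NormStats) -> pd.DataFrame:
    """Impute (training median), min-max scale (training extremes), clip to
    [0,1]. Constant training slots map to 0.5 everywhere."""
    out = {}
    for col in features.columns:
        vals = features[col].to_numpy(dtype=float)
        med = stats.medians[col]
        vals = np.where(np.isnan(vals), med, vals)
        lo, hi = stats.minima[col], stats.maxima[col]
        if hi == lo:
            out[col] = np.full_like(vals, 0.5)
        else:
            out[col] = np.clip((vals - lo) / (hi - lo), 0.0, 1.0)
    return pd.DataFrame(out, index=features.index, columns=features.columns)


def normalize_features(
    train_features: pd.DataFrame, *apply_to: pd.DataFrame
) -> tuple[List[pd.DataFrame], NormStats]:
    """Fit stats on the training table only, apply to it and to any further
    tables (validation/test/prediction) without refitting."""
    stats = fit_norm_stats(train_features)
    normalized = [apply_norm_stats(train_features, stats)]
    normalized.extend(apply_norm_stats(df, stats) for df in apply_to)
    return normalized, stats
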