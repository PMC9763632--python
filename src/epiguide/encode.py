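"""Channels x positions input encoding: one-hot sequence + broadcast epigenetics.

The default silencing encoder emits an 11 x 40 matrix per sgRNA: four binary
base channels (rows A, C, G, T) over a 40-mer context (9 bp upstream +
20 bp protospacer + 3 bp PAM + 8 bp downstream), followed by seven constant
rows carrying the min-max normalized epigenetic scalars. The activation
default is a 23-mer context (protospacer+PAM only, no flanks), keeping the
epigenetic channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .annotate import FEATURE_SLOTS
from .io import ScreenDataset, SgRNARecord, reverse_complement

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

SEQUENCE_CHANNELS: Tuple[str, ...] = tuple(BASES)
DEFAULT_CHANNELS: Tuple[str, ...] = SEQUENCE_CHANNELS + FEATURE_SLOTS

ALLOWED_CONTEXT_LENGTHS = (23, 30, 40, 50, 100, 200)


def flank_split(context_length: int) -> Tuple[int, int]:
    """Upstream/downstream flank lengths for a given context length.

    40 -> (9, 8) (the canonical silencing context); 23 -> (0, 0) (bare
    protospacer+PAM). For other lengths the upstream flank takes the extra
    base, mirroring the 9/8 asymmetry: up = (L-23)//2 + 1, down = L-23-up.
    """
    if context_length < 23:
        raise ValueError("context_length must be >= 23")
    if context_length == 23:
        return 0, 0
    upstream = (context_length - 23) // 2 + 1
    return upstream, context_length - 23 - upstream


@dataclass
class EncoderConfig:
    context_length: int = 40
    channels: Tuple[str, ...] = DEFAULT_CHANNELS
    protospacer_check: bool = True   # verify extracted sequence against record
    strict: bool = True              # hard-fail on protospacer mismatch

    def __post_init__(self) -> None:
        if self.context_length not in ALLOWED_CONTEXT_LENGTHS:
            raise ValueError(
                f"context_length must be one of {ALLOWED_CONTEXT_LENGTHS}"
            )
        self.channels = tuple(self.channels)
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("channel names must be unique")
        if self.channels[:4] != SEQUENCE_CHANNELS:
            raise ValueError("the first four channels must be A, C, G, T")
        unknown = set(self.channels[4:]) - set(FEATURE_SLOTS)
        if unknown:
            raise ValueError(f"unknown epigenetic channels {unknown}")

    @property
    def upstream(self) -> int:
        return flank_split(self.context_length)[0]

    @property
    def downstream(self) -> int:
        return flank_split(self.context_length)[1]

    @property
    def epi_channels(self) -> Tuple[str, ...]:
        return self.channels[4:]

    @classmethod
    def for_direction(cls, direction: str, **kw) -> "EncoderConfig":
        """Context-length defaults by editing direction: 40mer for
        silencing models, 23mer for activation models."""
        kw.setdefault("context_length", 40 if direction == "silencing" else 23)
        return cls(**kw)


@dataclass
class EncodedSample:
    matrix: np.ndarray                 # channels x positions
    sgrna_id: str
    target: Optional[float] = None     # regression target (activity score)
    label: Optional[int] = None        # binary classification label
    has_n: bool = False                # context contained an N (all-zero column)


def extract_context(record: SgRNARecord, genome, cfg: EncoderConfig) -> str:
    """Context sequence in guide orientation: flanks + protospacer + PAM.

    If the record already carries ``context_seq`` of the right length it is
    returned verbatim. Otherwise the window is read from the genome
    (reverse-complemented for minus-strand guides). The embedded protospacer
    is checked against the record; a mismatch is a hard error when
    ``cfg.strict`` else only flagged by the caller.
    """
    up, down = cfg.upstream, cfg.downstream
    if record.context_seq is not None:
        if len(record.context_seq) != cfg.context_length:
            raise ValueError(
                f"{record.sgrna_id}: context_seq length {len(record.context_seq)} "
                f"!= configured {cfg.context_length}"
            )
        return record.context_seq
    if record.strand == "+":
        gstart, gend = record.start - up, record.end + down
    else:
        gstart, gend = record.start - down, record.end + up
    if gstart < 0 or gend > genome.length(record.chrom):
        raise ValueError(
            f"{record.sgrna_id}: context window {record.chrom}:{gstart}-{gend} "
            "exceeds chromosome bounds"
        )
    seq = genome.fetch(record.chrom, gstart, gend)
    if record.strand == "-":
        seq = reverse_complement(seq)
    if cfg.protospacer_check:
        embedded = seq[up : up + 20]
        if embedded != record.protospacer:
            msg = (
                f"{record.sgrna_id}: extracted protospacer {embedded} does not "
                f"match record {record.protospacer}"
            )
            if cfg.strict:
                raise ValueError(msg)
            import warnings

            warnings.warn(msg)
    return seq


def one_hot(seq: str) -> np.ndarray:
    """4 x L binary matrix, rows in fixed order A, C, G, T; N -> all-zero
    column; any other character is an error."""
    mat = np.zeros((4, len(seq)), dtype=float)
    for j, base in enumerate(seq):
        if base == "N":
            continue
        try:
            mat[_BASE_INDEX[base], j] = 1.0
        except KeyError:
            raise ValueError(f"invalid base {base!r} at position {j + 1}") from None
    return mat


def decode_one_hot(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot` (all-zero columns decode to N)."""
    out = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        if col.sum() == 0:
            out.append("N")
        else:
            out.append(BASES[int(np.argmax(col))])
    return "".join(out)


def build_input(
    record: SgRNARecord,
    epi: Dict[str, float],
    cfg: EncoderConfig,
    genome=None,
    target: Optional[float] = None,
    label: Optional[int] = None,
) -> EncodedSample:
    """Assemble one channels x positions matrix.

    ``epi`` maps channel name -> normalized scalar in [0,1]; each scalar is
    broadcast as a constant row. Channels listed in the config but missing
    from ``epi`` (post-imputation) are a hard error — imputation belongs to
    the annotation stage.
    """
    seq = extract_context(record, genome, cfg)
    seq_mat = one_hot(seq)
    rows = [seq_mat]
    for name in cfg.epi_channels:
        v = epi.get(name)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise ValueError(
                f"{record.sgrna_id}: epigenetic channel {name!r} is missing; "
                "run feature normalization/imputation first"
            )
        rows.append(np.full((1, cfg.context_length), float(v)))
    matrix = np.vstack(rows)
    return EncodedSample(
        matrix=matrix,
        sgrna_id=record.sgrna_id,
        target=target,
        label=label,
        has_n="N" in seq,
    )


@dataclass
class SampleSet:
    """Stacked encoded samples ready for training."""

    X: np.ndarray                    # n x channels x positions
    ids: List[str]
    genes: List[str]
    targets: np.ndarray              # n, NaN where missing
    labels: np.ndarray               # n, NaN where missing
    channels: Tuple[str, ...]

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, idx) -> "SampleSet":
        idx = np.asarray(idx)
        return SampleSet(
            X=self.X[idx],
            ids=[self.ids[i] for i in idx],
            genes=[self.genes[i] for i in idx],
            targets=self.targets[idx],
            labels=self.labels[idx],
            channels=self.channels,
        )

    def channel_subset(self, channels: Sequence[str]) -> "SampleSet":
        """Restrict to a channel subset (for the feature-ablation sweeps)."""
        keep = [self.channels.index(c) for c in channels]
        return SampleSet(
            X=self.X[:, keep, :],
            ids=self.ids,
            genes=self.genes,
            targets=self.targets,
            labels=self.labels,
            channels=tuple(channels),
        )


def encode_dataset(
    dataset: ScreenDataset,
    epi_features,                     # pandas DataFrame, normalized, indexed by sgrna_id
    cfg: EncoderConfig,
    genome=None,
    labels: Optional[np.ndarray] = None,
    exclude_ids: Sequence[str] = (),
) -> SampleSet:
    """Encode a whole dataset into a :class:`SampleSet`.

    ``exclude_ids`` removes guides flagged upstream (e.g. undefined
    activity). Guides with missing activity remain but carry NaN targets.
    """
    excl = set(exclude_ids)
    mats, ids, genes, targets, labs = [], [], [], [], []
    for i, rec in enumerate(dataset.records):
        if rec.sgrna_id in excl:
            continue
        epi = (
            {k: float(epi_features.loc[rec.sgrna_id, k]) for k in cfg.epi_channels}
            if len(cfg.epi_channels)
            else {}
        )
        sample = build_input(
            rec,
            epi,
            cfg,
            genome=genome,
            target=rec.raw_score,
            label=None if labels is None or np.isnan(labels[i]) else int(labels[i]),
        )
        mats.append(sample.matrix)
        ids.append(rec.sgrna_id)
        genes.append(rec.gene)
        targets.append(np.nan if rec.raw_score is None else rec.raw_score)
        labs.append(np.nan if labels is None or np.isnan(labels[i]) else float(labels[i]))
    return SampleSet(
        X=np.stack(mats),
        ids=ids,
        genes=genes,
        targets=np.array(targets),
        labels=np.array(labs),
        channels=cfg.channels,
    )


def encode_screen(
    dataset: ScreenDataset,
    tracks,
    labels: Optional[np.ndarray] = None,
    cfg: Optional[EncoderConfig] = None,
    exclude_ids: Sequence[str] = (),
) -> SampleSet:
    """Convenience: annotate + fit/apply normalization + encode in one call.

    Normalization statistics are fit on the whole dataset passed in — use
    the lower-level functions when a strict train/test stat separation is
    required.
    """
    from .annotate import annotate_dataset, apply_norm_stats, fit_norm_stats

    raw = annotate_dataset(dataset, tracks)
    norm = apply_norm_stats(raw, fit_norm_stats(raw))
    cfg = cfg or EncoderConfig()
    return encode_dataset(dataset, norm, cfg, genome=tracks.genome,
                          labels=labels, exclude_ids=exclude_ids)
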