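"""Shared data model and readers/writers for screens, genomes and epigenetic tracks.

Coordinates are 0-based half-open (BED convention) everywhere internally.
Minus-strand records store the protospacer in guide orientation (5'->3' of
the guide), not reference orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

VALID_BASES = set("ACGT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: columns every screen table must provide
REQUIRED_COLUMNS = ("sgrna_id", "gene", "chrom", "start", "end", "strand", "protospacer")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SgRNARecord:
    """One guide: 23-bp protospacer+PAM target window plus its screen score."""

    sgrna_id: str
    gene: str
    chrom: str
    start: int          # 0-based half-open window of protospacer+PAM (23 bp)
    end: int
    strand: str         # {+, -}; strand of the guide target
    protospacer: str    # 20 nt, guide orientation
    pam: str = ""       # 3 nt, guide orientation (NGG for SpCas9)
    raw_score: Optional[float] = None
    context_seq: Optional[str] = None

    def validate(self, pam_check: bool = False) -> None:
        if self.end - self.start != 23:
            raise ValueError(
                f"{self.sgrna_id}: window must span 23 bp, got {self.end - self.start}"
            )
        if not set(self.protospacer) <= VALID_BASES:
            raise ValueError(f"{self.sgrna_id}: protospacer has non-ACGT characters")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.sgrna_id}: strand must be + or -")
        if pam_check and self.pam and not (
            len(self.pam) == 3 and self.pam[1:] == "GG"
        ):
            raise ValueError(f"{self.sgrna_id}: PAM {self.pam!r} does not match NGG")


@dataclass
class LoadReport:
    """Book-keeping for a table parse: nothing is dropped silently."""

    n_rows: int = 0
    n_records: int = 0
    n_missing_score: int = 0
    messages: List[str] = field(default_factory=list)


@dataclass
class ScreenDataset:
    """Gene-grouped sgRNA records with fixed score semantics.

    direction : 'silencing' (CRISPRoff/CRISPRi growth screens; more negative
        phenotype = stronger effect) or 'activation' (CRISPRa).
    score_kind : 'phenotype' (raw screen statistic) or 'activity'
        (sign-adjusted, per-gene top-k normalized).
    """

    records: List[SgRNARecord]
    direction: str = "silencing"
    score_kind: str = "phenotype"
    cell_line: str = ""
    name: str = ""
    metadata: Optional[pd.DataFrame] = None
    report: LoadReport = field(default_factory=LoadReport)

    def __post_init__(self) -> None:
        if self.direction not in ("silencing", "activation"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.score_kind not in ("phenotype", "activity"):
            raise ValueError(f"unknown score_kind {self.score_kind!r}")
        for r in self.records:
            if not r.gene:
                raise ValueError(f"{r.sgrna_id}: empty gene")

    def __len__(self) -> int:
        return len(self.records)

    def scores(self) -> np.ndarray:
        return np.array(
            [math.nan if r.raw_score is None else r.raw_score for r in self.records],
            dtype=float,
        )

    def genes(self) -> List[str]:
        return [r.gene for r in self.records]

    def with_scores(self, scores: Sequence[Optional[float]], score_kind: str) -> "ScreenDataset":
        if len(scores) != len(self.records):
            raise ValueError("score vector length mismatch")
        recs = [
            replace(r, raw_score=None if s is None or (isinstance(s, float) and math.isnan(s)) else float(s))
            for r, s in zip(self.records, scores)
        ]
        return ScreenDataset(
            records=recs,
            direction=self.direction,
            score_kind=score_kind,
            cell_line=self.cell_line,
            name=self.name,
            metadata=self.metadata,
            report=self.report,
        )


class InMemoryGenome:
    """Sequence provider over a dict of chromosome strings."""

    def __init__(self, sequences: Dict[str, str]):
        self._seq = {c: s.upper() for c, s in sequences.items()}

    def chroms(self) -> List[str]:
        return list(self._seq)

    def length(self, chrom: str) -> int:
        return len(self._seq[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if chrom not in self._seq:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > len(self._seq[chrom]):
            raise ValueError(
                f"window {chrom}:{start}-{end} outside chromosome (len {len(self._seq[chrom])})"
            )
        return self._seq[chrom][start:end]

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self._seq.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")


class FastaGenome:
    """Sequence provider backed by an (indexable) FASTA file via pyfaidx."""

    def __init__(self, path):
        import pyfaidx

        self._fa = pyfaidx.Fasta(str(path))

    def chroms(self) -> List[str]:
        return list(self._fa.keys())

    def length(self, chrom: str) -> int:
        return len(self._fa[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        if start < 0 or end > len(self._fa[chrom]):
            raise ValueError(f"window {chrom}:{start}-{end} outside chromosome")
        return str(self._fa[chrom][start:end]).upper()


class IntervalValueTrack:
    """bedGraph-style (chrom, start, end, value) intervals, point/range queryable.

    Overlapping intervals are permitted; queries return all overlaps so the
    annotation reducer decides how to aggregate.
    """

    def __init__(self, intervals: Iterable[Tuple[str, int, int, float]] = ()):
        self._trees: Dict[str, IntervalTree] = {}
        self.n_intervals = 0
        for chrom, start, end, value in intervals:
            self.add(chrom, int(start), int(end), float(value))

    def add(self, chrom: str, start: int, end: int, value: float) -> None:
        if not np.isfinite(value):
            raise ValueError(f"non-finite track value at {chrom}:{start}-{end}")
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end, value)
        self.n_intervals += 1

    def query(self, chrom: str, start: int, end: int) -> List[Tuple[int, int, float]]:
        """All intervals overlapping [start, end), as (start, end, value)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.begin, iv.end, iv.data) for iv in tree.overlap(start, end))


@dataclass
class EpiTracks:
    """Genome + TSS table + the three interval-value epigenetic tracks."""

    genome: object
    tss_table: pd.DataFrame  # index: gene; columns: primary_tss, secondary_tss, strand
    atac: IntervalValueTrack
    methylation: IntervalValueTrack
    expression: IntervalValueTrack

    def __post_init__(self) -> None:
        need = {"primary_tss", "secondary_tss", "strand"}
        if not need <= set(self.tss_table.columns):
            raise ValueError(f"tss_table missing columns {need - set(self.tss_table.columns)}")
        bad = set(self.tss_table["strand"]) - {"+", "-"}
        if bad:
            raise ValueError(f"tss_table has invalid strands {bad}")


def _parse_score(value) -> Optional[float]:
    if value is None:
        return None
    try:
        s = float(value)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(s) else s


def read_screen_table(
    path,
    direction: str = "silencing",
    score_kind: str = "phenotype",
    score_col: str = "score",
    one_based: bool = False,
    pam_check: bool = False,
    cell_line: str = "",
    name: str = "",
) -> ScreenDataset:
    """Parse a tab-delimited screen table into a :class:`ScreenDataset`.

    Rows with unparseable scores are retained with ``raw_score=None`` and
    counted in the load report. Unknown columns are preserved in
    ``dataset.metadata``. ``one_based=True`` converts start coordinates from
    1-based inclusive to the internal 0-based half-open convention.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty screen table")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    if score_col not in df.columns:
        raise ValueError(f"{path}: missing score column {score_col!r}")

    report = LoadReport(n_rows=len(df))
    records = []
    for _, row in df.iterrows():
        score = _parse_score(row[score_col])
        if score is None:
            report.n_missing_score += 1
        start = int(row["start"]) - (1 if one_based else 0)
        rec = SgRNARecord(
            sgrna_id=row["sgrna_id"],
            gene=row["gene"],
            chrom=row["chrom"],
            start=start,
            end=int(row["end"]),
            strand=row["strand"],
            protospacer=row["protospacer"].upper(),
            pam=row.get("pam", "").upper() if "pam" in df.columns else "",
            raw_score=score,
            context_seq=row["context_seq"].upper() if "context_seq" in df.columns and row["context_seq"] else None,
        )
        rec.validate(pam_check=pam_check)
        records.append(rec)
    report.n_records = len(records)

    extra_cols = [c for c in df.columns if c not in REQUIRED_COLUMNS + ("pam", "context_seq", score_col)]
    meta = df[extra_cols].copy() if extra_cols else None
    return ScreenDataset(
        records=records,
        direction=direction,
        score_kind=score_kind,
        cell_line=cell_line,
        name=name or Path(str(path)).stem,
        metadata=meta,
        report=report,
    )


def write_screen_table(dataset: ScreenDataset, path, score_col: str = "score") -> None:
    """Write a dataset back to TSV; inverse of :func:`read_screen_table`."""
    rows = []
    for r in dataset.records:
        rows.append(
            {
                "sgrna_id": r.sgrna_id,
                "gene": r.gene,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "strand": r.strand,
                "protospacer": r.protospacer,
                "pam": r.pam,
                score_col: "NA" if r.raw_score is None else repr(r.raw_score),
                "context_seq": r.context_seq or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_track_bedgraph(path) -> IntervalValueTrack:
    """Read a bedGraph/BED4 file (chrom, start, end, value); empty file is a
    valid, always-missing track."""
    track = IntervalValueTrack()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
            try:
                value = float(parts[3])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric value {parts[3]!r}") from None
            track.add(parts[0], int(parts[1]), int(parts[2]), value)
    return track


def write_track_bedgraph(track: IntervalValueTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(track._trees):
            for iv in sorted(track._trees[chrom]):
                fh.write(f"{chrom}\t{iv.begin}\t{iv.end}\t{iv.data!r}\n")


def read_tss_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "strand": str})
    need = {"gene", "primary_tss", "secondary_tss", "strand"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: TSS table missing columns {need - set(df.columns)}")
    return df.set_index("gene")


def write_tss_table(tss: pd.DataFrame, path) -> None:
    tss.reset_index().rename(columns={"index": "gene"}).to_csv(path, sep="\t", index=False)


def read_epitracks(genome_fasta, tss_tsv, atac_bed, meth_bed, expr_bed) -> EpiTracks:
    """Load genome, TSS table and the three epigenetic tracks from disk."""
    return EpiTracks(
        genome=FastaGenome(genome_fasta),
        tss_table=read_tss_table(tss_tsv),
        atac=read_track_bedgraph(atac_bed),
        methylation=read_track_bedgraph(meth_bed),
        expression=read_track_bedgraph(expr_bed),
    )
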