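"""Synthetic CRISPR epigenome-editing screens with known ground truth.

The generator emits everything the real pipeline consumes — a toy genome,
gene-grouped sgRNAs with phenotype scores, a TSS table and bedGraph-style
epigenetic tracks — from a latent linear-Gaussian activity model:

    a_i = sum_j w_j (1[base at planted position] - 1/4)
        + sum_f w_f (c_{f,gene} - 1/2)
        + w_tss * exp(-(d_i / tss_decay_bp)^2)
        + Normal(0, noise_sd)

where c_{f,gene} are per-gene epigenetic covariates drawn uniform on [0,1]
(shared by all guides of the gene, matching how accessibility/methylation/
expression are gene- or locus-level in real screens) and d_i is the guide
midpoint's distance to the primary TSS. Indicator and covariate terms are
mean-centered so the latent activity is centered near zero at any effect
size. Silencing screens report phenotype = -a (more negative = stronger
knock-down); activation screens report phenotype = +a.

Guides are random 23-mers constrained to an NGG PAM, placed on both strands
in non-overlapping slots and written into the genome so that sequence
extraction, track overlap and TSS annotation all recover the planted truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import (
    EpiTracks,
    InMemoryGenome,
    IntervalValueTrack,
    ScreenDataset,
    SgRNARecord,
    reverse_complement,
)

#: bases of clear sequence on each side of every guide slot, so contexts up
#: to 83-mer can be extracted without touching a neighboring guide
SLOT_MARGIN = 30

EPI_COVARIATES = ("atac", "methylation", "expression")


@dataclass
class SimConfig:
    n_genes: int = 100
    guides_per_gene: int = 10
    seed: int = 0
    #: planted positional effects: (guide position 1-23, base, weight)
    sequence_effects: Tuple[Tuple[int, str, float], ...] = ()
    #: weights of the per-gene covariates and the TSS-proximity term
    epi_effects: Dict[str, float] = field(
        default_factory=lambda: {"atac": 0.0, "methylation": 0.0, "expression": 0.0, "tss": 0.0}
    )
    noise_sd: float = 0.4
    direction: str = "silencing"
    missing_rate: float = 0.0          # per gene x track chance of an absent interval
    tss_decay_bp: float = 1000.0
    secondary_tss_offset: int = 120
    chrom: str = "chrSim"

    def __post_init__(self) -> None:
        if self.guides_per_gene < 1:
            raise ValueError("guides_per_gene must be >= 1")
        for pos, base, w in self.sequence_effects:
            if not 1 <= pos <= 23:
                raise ValueError(f"sequence effect position {pos} outside 1..23")
            if base not in "ACGT":
                raise ValueError(f"invalid effect base {base!r}")
            if not math.isfinite(w):
                raise ValueError("effect weights must be finite")

    @property
    def slot_width(self) -> int:
        return 23 + 2 * SLOT_MARGIN

    @property
    def region_length(self) -> int:
        return self.guides_per_gene * self.slot_width

    @property
    def genome_length(self) -> int:
        gap = 40
        return self.n_genes * (self.region_length + gap)


def _gene_name(i: int, n_genes: int) -> str:
    if n_genes <= 26:
        return f"GENE_{chr(65 + i)}"
    return f"G{i:05d}"


def simulate_screen(cfg: SimConfig) -> Tuple[ScreenDataset, EpiTracks, pd.DataFrame]:
    """Generate one synthetic screen; returns (dataset, tracks, truth table).

    The truth table records, per guide, the latent activity and each of its
    components, so tests can check that the pipeline recovers planted
    signal. Byte-identical across runs for a fixed config.
    """
    rng = np.random.default_rng(cfg.seed)
    genome_arr = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=cfg.genome_length)
    if cfg.genome_length < cfg.n_genes * cfg.region_length:
        raise ValueError("genome too short for the requested guides")

    gap = 40
    records: List[SgRNARecord] = []
    tss_rows = []
    truth_rows = []
    atac_iv, meth_iv, expr_iv = [], [], []

    for g in range(cfg.n_genes):
        gene = _gene_name(g, cfg.n_genes)
        region_start = g * (cfg.region_length + gap)
        region_end = region_start + cfg.region_length
        gene_strand = "+" if rng.random() < 0.5 else "-"
        primary_tss = region_start + cfg.region_length // 2
        sec_shift = cfg.secondary_tss_offset if gene_strand == "+" else -cfg.secondary_tss_offset
        secondary_tss = primary_tss + sec_shift
        tss_rows.append(
            {"gene": gene, "primary_tss": primary_tss, "secondary_tss": secondary_tss, "strand": gene_strand}
        )

        cov = {name: float(rng.random()) for name in EPI_COVARIATES}
        for name, iv in zip(EPI_COVARIATES, (atac_iv, meth_iv, expr_iv)):
            if rng.random() >= cfg.missing_rate:
                iv.append((cfg.chrom, region_start, region_end, cov[name]))

        for j in range(cfg.guides_per_gene):
            start = region_start + j * cfg.slot_width + SLOT_MARGIN
            end = start + 23
            strand = "+" if rng.random() < 0.5 else "-"
            mer = "".join(rng.choice(list("ACGT"), size=23))
            mer = mer[:21] + "GG"  # NGG PAM at guide positions 21-23
            genomic = mer if strand == "+" else reverse_complement(mer)
            genome_arr[start:end] = np.frombuffer(genomic.encode(), dtype="S1")

            seq_contrib = sum(
                w * ((1.0 if mer[pos - 1] == base else 0.0) - 0.25)
                for pos, base, w in cfg.sequence_effects
            )
            epi_contrib = sum(
                cfg.epi_effects.get(name, 0.0) * (cov[name] - 0.5) for name in EPI_COVARIATES
            )
            midpoint = (start + end) // 2
            d = abs(midpoint - primary_tss)
            tss_contrib = cfg.epi_effects.get("tss", 0.0) * math.exp(-((d / cfg.tss_decay_bp) ** 2))
            noise = float(rng.normal(0.0, cfg.noise_sd)) if cfg.noise_sd > 0 else 0.0
            latent = seq_contrib + epi_contrib + tss_contrib + noise
            phenotype = -latent if cfg.direction == "silencing" else latent

            sgrna_id = f"{gene}_sg{j:03d}"
            records.append(
                SgRNARecord(
                    sgrna_id=sgrna_id,
                    gene=gene,
                    chrom=cfg.chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    protospacer=mer[:20],
                    pam=mer[20:],
                    raw_score=phenotype,
                )
            )
            truth_rows.append(
                {
                    "sgrna_id": sgrna_id,
                    "gene": gene,
                    "latent_activity": latent,
                    "seq_contrib": seq_contrib,
                    "epi_contrib": epi_contrib,
                    "tss_contrib": tss_contrib,
                    "noise": noise,
                    **{f"cov_{k}": v for k, v in cov.items()},
                }
            )

    genome = InMemoryGenome({cfg.chrom: genome_arr.tobytes().decode()})
    tracks = EpiTracks(
        genome=genome,
        tss_table=pd.DataFrame(tss_rows).set_index("gene"),
        atac=IntervalValueTrack(atac_iv),
        methylation=IntervalValueTrack(meth_iv),
        expression=IntervalValueTrack(expr_iv),
    )
    dataset = ScreenDataset(
        records=records,
        direction=cfg.direction,
        score_kind="phenotype",
        cell_line="synthetic",
        name=f"sim_seed{cfg.seed}",
    )
    truth = pd.DataFrame(truth_rows).set_index("sgrna_id")
    return dataset, tracks, truth


# ----------------------------------------------------------------------- presets

#: planted sequence rule: dominant +G at protospacer position 20 (PAM-
#: proximal base) plus four secondary positional effects; sized so that a
#: position-weight-matrix oracle separates active/inactive guides cleanly
PLANTED_SEQ_EFFECTS: Tuple[Tuple[int, str, float], ...] = (
    (20, "G", 2.0),
    (16, "A", 0.8),
    (18, "C", -0.8),
    (5, "T", -0.6),
    (3, "G", 0.4),
)

#: base epigenetic weights for the planted-epi preset, scaled by `level`
PLANTED_EPI_BASE = {"atac": 0.6, "methylation": -0.4, "expression": 0.5, "tss": 0.6}


def preset(name: str, seed: int = 0, epi_level: float = 1.0, **overrides) -> SimConfig:
    """Named study conditions.

    * ``smoke`` — 12 genes x 6 guides, mild sequence effect; fast end-to-end runs.
    * ``planted-seq`` — 2000 genes x 10 guides (n = 20,000), strong planted
      positional effects, no epigenetic effects.
    * ``planted-epi`` — 100 genes x 12 guides, moderate sequence effects plus
      epigenetic effects scaled by ``epi_level``.
    * ``null`` — no effects at all; scores are pure noise.
    """
    if name == "smoke":
        cfg = SimConfig(
            n_genes=12, guides_per_gene=6, seed=seed,
            sequence_effects=((20, "G", 1.0),), noise_sd=0.4,
        )
    elif name == "planted-seq":
        cfg = SimConfig(
            n_genes=2000, guides_per_gene=10, seed=seed,
            sequence_effects=PLANTED_SEQ_EFFECTS, noise_sd=0.4,
        )
    elif name == "planted-epi":
        cfg = SimConfig(
            n_genes=100, guides_per_gene=12, seed=seed,
            sequence_effects=((20, "G", 1.0), (18, "C", -0.5)),
            epi_effects={k: v * epi_level for k, v in PLANTED_EPI_BASE.items()},
            noise_sd=0.4,
        )
    elif name == "null":
        cfg = SimConfig(n_genes=50, guides_per_gene=10, seed=seed,
                        sequence_effects=(), noise_sd=1.0)
    else:
        raise ValueError(f"unknown preset {name!r}")
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


# ---------------------------------------------------------------- worked example

#: hand-written silencing phenotype scores for the worked fixture; None = NA
WORKED_SCORES = {
    "GENE_A": [-4.0, -2.0, None, None],       # missing scores + fewer-than-k fallback
    "GENE_B": [-3.0, -2.0, -1.0, -0.5],       # plain top-3 normalization
    "GENE_C": [0.0, 0.0, 0.0, 0.0],           # zero denominator -> undefined activity
}

#: expected activity scores after transform + per-gene top-3 normalization
#: (hand-computed; GENE_C guides are flagged undefined and excluded)
WORKED_EXPECTED_ACTIVITY = {
    "GENE_A": [4.0 / 3.0, 2.0 / 3.0, None, None],
    "GENE_B": [1.5, 1.0, 0.5, 0.25],
    "GENE_C": [None, None, None, None],
}

#: expected binary labels from the raw phenotype rule (score < -0.1)
WORKED_EXPECTED_LABELS = {
    "GENE_A": [1, 1, None, None],
    "GENE_B": [1, 1, 1, 1],
    "GENE_C": [0, 0, 0, 0],
}


def make_worked_example() -> Tuple[ScreenDataset, EpiTracks, pd.DataFrame]:
    """Tiny 3-gene x 4-guide fixture exercising every preprocessing branch.

    Guides and tracks come from the deterministic simulator; the phenotype
    scores are replaced by the hand-written table above. The returned
    expectation frame carries hand-computed activities and labels.
    """
    cfg = SimConfig(n_genes=3, guides_per_gene=4, seed=2024,
                    sequence_effects=(), noise_sd=0.0)
    dataset, tracks, _ = simulate_screen(cfg)
    rows = []
    for rec in dataset.records:
        gene = rec.gene
        j = int(rec.sgrna_id.rsplit("sg", 1)[1])
        rec.raw_score = WORKED_SCORES[gene][j]
        rows.append(
            {
                "sgrna_id": rec.sgrna_id,
                "gene": gene,
                "phenotype": rec.raw_score,
                "expected_activity": WORKED_EXPECTED_ACTIVITY[gene][j],
                "expected_label": WORKED_EXPECTED_LABELS[gene][j],
            }
        )
    expected = pd.DataFrame(rows).set_index("sgrna_id")
    return dataset, tracks, expected
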