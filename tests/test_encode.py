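"""Sequence extraction, one-hot encoding, channel matrix assembly."""

import numpy as np
import pytest

import epiguide as eg
from epiguide.encode import (
    DEFAULT_CHANNELS,
    EncoderConfig,
    build_input,
    decode_one_hot,
    encode_dataset,
    extract_context,
    flank_split,
    one_hot,
)
from epiguide.io import SgRNARecord

EPI_HALF = {name: 0.5 for name in DEFAULT_CHANNELS[4:]}


class TestFlankSplit:
    def test_canonical_40mer_is_9_8(self):
        assert flank_split(40) == (9, 8)

    def test_23mer_has_no_flanks(self):
        assert flank_split(23) == (0, 0)

    @pytest.mark.parametrize("L", [23, 30, 40, 50, 100, 200])
    def test_flanks_sum_to_context(self, L):
        up, down = flank_split(L)
        assert up + 23 + down == L and up >= 0 and down >= 0


class TestExtractContext:
    def test_plus_strand_embeds_protospacer_and_pam(self, smoke_screen):
        ds, tracks, _ = smoke_screen
        cfg = EncoderConfig()
        rec = next(r for r in ds.records if r.strand == "+")
        seq = extract_context(rec, tracks.genome, cfg)
        assert len(seq) == 40
        assert seq[9:29] == rec.protospacer       # positions 10-29 (1-based)
        assert seq[29:32] == rec.pam              # positions 30-32

    def test_minus_strand_reverse_complemented(self, smoke_screen):
        ds, tracks, _ = smoke_screen
        cfg = EncoderConfig()
        rec = next(r for r in ds.records if r.strand == "-")
        seq = extract_context(rec, tracks.genome, cfg)
        assert seq[9:29] == rec.protospacer
        assert seq[29:31].endswith("G")           # NGG PAM in guide space

    def test_23mer_is_exactly_protospacer_pam(self, smoke_screen):
        ds, tracks, _ = smoke_screen
        cfg = EncoderConfig(context_length=23)
        rec = ds.records[0]
        assert extract_context(rec, tracks.genome, cfg) == rec.protospacer + rec.pam

    def test_context_seq_shortcut_and_length_check(self):
        rec = SgRNARecord("x", "g", "c", 100, 123, "+", "A" * 20, pam="AGG",
                          context_seq="A" * 40)
        assert extract_context(rec, None, EncoderConfig(protospacer_check=False)) == "A" * 40
        rec.context_seq = "A" * 30
        with pytest.raises(ValueError, match="length"):
            extract_context(rec, None, EncoderConfig())

    def test_out_of_bounds_names_record(self, smoke_screen):
        _, tracks, _ = smoke_screen
        rec = SgRNARecord("edge_guide", "g", "chrSim", 0, 23, "+", "A" * 20)
        with pytest.raises(ValueError, match="edge_guide"):
            extract_context(rec, tracks.genome, EncoderConfig(protospacer_check=False))

    def test_protospacer_mismatch_hard_fails_when_strict(self, smoke_screen):
        ds, tracks, _ = smoke_screen
        rec = ds.records[0]
        bad = SgRNARecord(rec.sgrna_id, rec.gene, rec.chrom, rec.start, rec.end,
                          rec.strand, "T" * 20, pam=rec.pam)
        with pytest.raises(ValueError, match="does not match"):
            extract_context(bad, tracks.genome, EncoderConfig())


class TestOneHot:
    def test_acgt_identity_pattern(self):
        assert np.array_equal(one_hot("ACGT"), np.eye(4))

    def test_homopolymer(self):
        m = one_hot("AAAA")
        assert m[0].sum() == 4 and m[1:].sum() == 0

    def test_n_gives_zero_column(self):
        m = one_hot("ANT")
        assert m[:, 1].sum() == 0

    def test_invalid_base_errors(self):
        with pytest.raises(ValueError, match="invalid base"):
            one_hot("ACGX")

    def test_decode_round_trip_random_40mers(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            seq = "".join(rng.choice(list("ACGT"), size=40))
            assert decode_one_hot(one_hot(seq)) == seq


class TestBuildInput:
    def test_default_silencing_shape_11x40(self, smoke_screen):
        ds, tracks, _ = smoke_screen
        s = build_input(ds.records[0], EPI_HALF, EncoderConfig(), genome=tracks.genome)
        assert s.matrix.shape == (11, 40)

    def test_seq_only_ablation_4x40(self, smoke_screen):
        ds, tracks, _ = smoke_screen
        cfg = EncoderConfig(channels=("A", "C", "G", "T"))
        s = build_input(ds.records[0], {}, cfg, genome=tracks.genome)
        assert s.matrix.shape == (4, 40)

    def test_activation_23mer_keeps_epi_channels(self, smoke_screen):
        ds, tracks, _ = smoke_screen
        cfg = EncoderConfig.for_direction("activation")
        s = build_input(ds.records[0], EPI_HALF, cfg, genome=tracks.genome)
        assert s.matrix.shape == (11, 23)

    def test_epi_rows_constant_broadcast(self, smoke_screen):
        ds, tracks, _ = smoke_screen
        s = build_input(ds.records[0], EPI_HALF, EncoderConfig(), genome=tracks.genome)
        assert np.all(s.matrix[4:] == 0.5)

    def test_missing_epi_value_hard_error(self, smoke_screen):
        ds, tracks, _ = smoke_screen
        epi = dict(EPI_HALF)
        epi["methylation"] = np.nan
        with pytest.raises(ValueError, match="methylation"):
            build_input(ds.records[0], epi, EncoderConfig(), genome=tracks.genome)

    def test_sequence_column_sums_are_one(self, smoke_samples):
        colsums = smoke_samples.X[:, :4, :].sum(axis=1)
        assert np.all(colsums == 1.0)

def test_encoding_purity(smoke_screen, smoke_samples):
    """Encoding a record is independent of its dataset neighbors: a subset
    encodes to the same matrices as the full dataset."""
    ds, tracks, _ = smoke_screen
    from epiguide.annotate import annotate_dataset, fit_norm_stats, apply_norm_stats

    raw = annotate_dataset(ds, tracks)
    norm = apply_norm_stats(raw, fit_norm_stats(raw))
    from epiguide.io import ScreenDataset

    sub = ScreenDataset(records=ds.records[:5], direction=ds.direction,
                        score_kind=ds.score_kind)
    sub_samples = encode_dataset(sub, norm, EncoderConfig(), genome=tracks.genome)
    assert np.array_equal(sub_samples.X, smoke_samples.X[:5])


def test_channel_order_validation():
    with pytest.raises(ValueError, match="first four"):
        EncoderConfig(channels=("C", "A", "G", "T", "atac"))
    with pytest.raises(ValueError, match="unknown"):
        EncoderConfig(channels=("A", "C", "G", "T", "histone"))
    with pytest.raises(ValueError, match="context_length"):
        EncoderConfig(context_length=37)
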