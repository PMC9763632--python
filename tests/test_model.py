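"""Metrics against brute-force oracles, grouped splits, baselines, ablations."""

import numpy as np
import pytest

from epiguide.encode import SEQUENCE_CHANNELS
from epiguide.model import (
    SplitPlan,
    auc_bruteforce,
    auc_score,
    baseline_models,
    evaluate,
    grouped_kfold,
    grouped_train_test_split,
    pwm_oracle,
    train,
)
from epiguide.nn import ModelConfig


class TestMetrics:
    def test_identity_cases(self):
        preds = np.array([0.1, 0.5, 0.9, 0.3])
        rep = evaluate(preds, preds.copy(), "regression")
        assert rep.spearman == 1.0 and rep.mse == 0.0 and rep.cosine_similarity == pytest.approx(1.0)

    def test_perfect_and_reversed_separation(self):
        labels = np.array([0, 0, 1, 1.0])
        assert auc_score(labels, np.array([0.1, 0.2, 0.8, 0.9])) == 1.0
        assert auc_score(labels, np.array([0.9, 0.8, 0.2, 0.1])) == 0.0

    def test_pairwise_counting_example(self):
        labels = np.array([0, 1, 0, 1.0])
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        assert auc_score(labels, scores) == 1.0
        assert auc_bruteforce(labels, scores) == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_rank_auc_equals_bruteforce_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        labels = rng.integers(0, 2, size=n).astype(float)
        if len(np.unique(labels)) < 2:
            labels[:2] = [0.0, 1.0]
        scores = np.round(rng.random(n), 1)   # coarse grid forces ties
        assert auc_score(labels, scores) == pytest.approx(auc_bruteforce(labels, scores), abs=1e-12)

    def test_constant_predictions_spearman_missing(self):
        rep = evaluate(np.full(5, 0.3), np.arange(5.0), "regression")
        assert rep.spearman is None and rep.mse > 0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            evaluate(np.zeros(3), np.zeros(4), "regression")


class TestGroupedSplits:
    def test_no_gene_on_both_sides(self):
        genes = [f"g{i//7}" for i in range(140)]
        tr, te = grouped_train_test_split(genes, SplitPlan(seed=0))
        assert not {genes[i] for i in tr} & {genes[i] for i in te}
        assert 0.8 < len(tr) / 140 < 1.0

    @pytest.mark.parametrize("n_folds", [3, 5])
    def test_kfold_partitions_without_leakage(self, n_folds):
        genes = [f"g{i//5}" for i in range(100)]
        seen = []
        for tr, te in grouped_kfold(genes, n_folds, seed=1):
            assert not {genes[i] for i in tr} & {genes[i] for i in te}
            seen.extend(te)
        assert sorted(seen) == list(range(100))   # folds partition the data


class TestBaselinesAndAblation:
    def test_baselines_share_split_with_oracle(self, smoke_samples):
        split = SplitPlan(seed=3)
        reports = baseline_models(smoke_samples, split, task="regression", seed=0)
        assert set(reports) == {"random_forest", "gradient_boosting"}
        oracle = pwm_oracle(smoke_samples, split, task="regression")
        hashes = {rep.per_fold[0]["split_hash"] for rep in reports.values()}
        hashes.add(oracle.per_fold[0]["split_hash"])
        assert len(hashes) == 1               # identical split manifest

    def test_ablation_sweep_reports_each_subset(self, smoke_samples):
        from epiguide.model import ablation_sweep

        cfg = ModelConfig(task="regression", kernel_sizes=(1, 2), filters_per_size=4,
                          fc_units=(8,), dropout=0.0, max_epochs=2, patience=2,
                          batch_size=32, seed=0)
        subsets = {"seq": list(SEQUENCE_CHANNELS), "full": list(smoke_samples.channels)}
        out = ablation_sweep(smoke_samples, SplitPlan(seed=0), cfg, subsets=subsets)
        assert set(out) == {"seq", "full"}
        assert all(r.n_test > 0 for r in out.values())


def test_single_class_validation_fold_errors(smoke_samples):
    """Classification training refuses a validation fold with one class."""
    samples = smoke_samples.subset(np.arange(len(smoke_samples)))
    samples.labels[:] = 1.0
    cfg = ModelConfig(task="classification", kernel_sizes=(1,), filters_per_size=2,
                      fc_units=(4,), dropout=0.0, max_epochs=1, patience=1, seed=0)
    with pytest.raises(ValueError, match="single class"):
        train(samples, SplitPlan(seed=0), cfg)


def test_noise_free_epi_channels_do_not_change_auc_much(planted_seq_bundle):
    """On the planted-seq screen the epigenetic channels are pure noise, so
    the full model and a seq-only model land at similar held-out AUC."""
    from epiguide.model import train as train_model

    bundle = planted_seq_bundle
    sub_genes = list(dict.fromkeys(bundle["samples"].genes))[:300]
    keep = np.flatnonzero(np.isin(bundle["samples"].genes, sub_genes))
    small = bundle["samples"].subset(keep)
    cfg = ModelConfig(task="classification", max_epochs=8, patience=3, seed=0)
    diffs = []
    for seed in range(5):
        import dataclasses

        c = dataclasses.replace(cfg, seed=seed)
        _, full = train_model(small, SplitPlan(seed=seed), c)
        _, seq = train_model(small.channel_subset(SEQUENCE_CHANNELS), SplitPlan(seed=seed), c)
        diffs.append(abs(full.auc - seq.auc))
    assert np.median(diffs) < 0.03
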