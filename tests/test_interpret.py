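"""Feature engineering, TreeSHAP importance, gradient-based attribution."""

import numpy as np
import pandas as pd
import pytest

from epiguide.interpret import (
    TM_SEGMENTS,
    deep_attribution,
    engineer_features,
    feature_names,
    integrated_gradients,
    tree_importance,
)
from epiguide.io import SgRNARecord
from epiguide.nn import CasCNN, ModelConfig


def _rec(proto, pam="AGG", sid="sg0"):
    return SgRNARecord(sid, "G1", "chr1", 100, 123, "+", proto, pam=pam)


def _random_records(n, seed=0):
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        proto = "".join(rng.choice(list("ACGT"), size=20))
        pam = rng.choice(list("ACGT")) + "GG"
        recs.append(_rec(proto, pam=pam, sid=f"sg{i}"))
    return recs


class TestEngineerFeatures:
    def test_positional_indicators_read_off(self):
        proto = "ACGT" * 5
        df = engineer_features([_rec(proto, pam="TGG")], tm_method="wallace")
        row = df.iloc[0]
        assert row["A_1"] == 1 and row["C_2"] == 1 and row["G_3"] == 1
        assert row["T_21"] == 1 and row["G_22"] == 1 and row["G_23"] == 1  # PAM
        assert row["AC_1"] == 1 and row["GT_3"] == 1
        assert row["A_2"] == 0

    def test_gc_counts(self):
        df = engineer_features([_rec("G" * 20)], tm_method="wallace")
        assert df.iloc[0]["GC_count"] == 20
        assert df.iloc[0]["GC_dinucleotide_count"] == 19

    def test_wallace_rule_tm(self):
        # 10 A/T + 10 G/C -> 2*10 + 4*10 = 60
        df = engineer_features([_rec("ACGTACGTACGTACGTACGT")], tm_method="wallace")
        assert df.iloc[0]["Tm_full"] == 60.0

    def test_epi_slots_appended(self):
        epi = pd.DataFrame({"atac": [0.7], "methylation": [0.1]}, index=["sg0"])
        df = engineer_features([_rec("A" * 20)], epi=epi, tm_method="wallace")
        assert df.iloc[0]["atac"] == 0.7 and df.iloc[0]["methylation"] == 0.1

    def test_non_acgt_errors(self):
        with pytest.raises(ValueError, match="non-ACGT"):
            engineer_features([_rec("N" * 20)])

    def test_feature_names_unique(self):
        names = feature_names(("atac",))
        assert len(names) == len(set(names))
        assert len(names) == 4 * 23 + 16 * 22 + 2 + len(TM_SEGMENTS) + 1


class TestTreeImportance:
    def test_planted_single_feature_dominates(self):
        recs = _random_records(800, seed=1)
        feats = engineer_features(recs, tm_method="wallace")
        rng = np.random.default_rng(2)
        targets = 2.0 * feats["G_20"].to_numpy() + rng.normal(0, 0.3, size=len(recs))
        res = tree_importance(feats, targets, seed=0)
        assert res.importance.index[0] == "G_20"
        assert res.importance.iloc[0] >= 3.0 * res.importance.iloc[1]

    def test_local_accuracy(self):
        recs = _random_records(200, seed=3)
        feats = engineer_features(recs, tm_method="wallace")
        targets = feats["GC_count"].to_numpy() / 20.0
        res = tree_importance(feats, targets, seed=0, n_estimators=50)
        margin = res.model.predict(feats.to_numpy())
        err = np.abs(res.shap_values.sum(axis=1) - margin)
        assert err.max() < 1e-5   # TreeSHAP is exact; float32 accumulation

    def test_independent_targets_below_permutation_null(self):
        """With targets independent of features, the top mean |SHAP| is not
        larger than the 95th percentile of a label-permutation null."""
        recs = _random_records(300, seed=4)
        feats = engineer_features(recs, tm_method="wallace")
        rng = np.random.default_rng(5)
        targets = rng.normal(size=len(recs))
        observed = tree_importance(feats, targets, seed=0, n_estimators=30).importance.iloc[0]
        null_max = []
        for i in range(100):
            perm = rng.permutation(targets)
            null_max.append(
                tree_importance(feats, perm, seed=0, n_estimators=30).importance.iloc[0]
            )
        assert observed <= np.quantile(null_max, 0.95)

    def test_refuses_fewer_than_50_samples(self):
        recs = _random_records(20, seed=0)
        feats = engineer_features(recs, tm_method="wallace")
        with pytest.raises(ValueError, match="50"):
            tree_importance(feats, np.zeros(20))


def _random_encoded(n, seed=0, n_channels=11, L=40):
    rng = np.random.default_rng(seed)
    X = np.zeros((n, n_channels, L))
    for i in range(n):
        X[i, :4, :] = np.eye(4)[rng.integers(0, 4, L)].T
        X[i, 4:, :] = rng.random((n_channels - 4, 1))
    return X


class TestDeepAttribution:
    def test_completeness_axiom_high_step_count(self):
        """Per-sample attributions sum to prediction - baseline prediction
        (the completeness axiom), to integration accuracy."""
        net = CasCNN(11, 40, ModelConfig(task="regression", seed=0))
        X = _random_encoded(6, seed=1)
        for i in (0, 1):
            for b in (2, 3):
                phi = integrated_gradients(net, X[i], X[b], steps=4096)
                want = net.predict_raw(X[i][None])[0] - net.predict_raw(X[b][None])[0]
                assert phi.sum() == pytest.approx(want, abs=1e-3)

    def test_untrained_map_has_no_structure(self):
        """Random-weight networks produce attribution maps whose max/median
        ratio stays inside the iid-noise null band (95th percentile ~5.45
        for ~92 cells, Monte-Carlo derived)."""
        X = _random_encoded(150, seed=2)
        ratios = []
        for seed in range(5):
            net = CasCNN(11, 40, ModelConfig(task="classification", seed=seed))
            attr = deep_attribution(net, X, n=60, n_background=15, steps=8, seed=seed)
            vals = np.abs(attr.guide_map().to_numpy())
            ratios.append(vals.max() / np.median(vals))
        assert np.median(ratios) < 5.45

    def test_reproducible_under_fixed_seed(self):
        net = CasCNN(11, 40, ModelConfig(seed=1))
        X = _random_encoded(50, seed=3)
        a1 = deep_attribution(net, X, n=20, n_background=10, steps=4, seed=9)
        a2 = deep_attribution(net, X, n=20, n_background=10, steps=4, seed=9)
        pd.testing.assert_frame_equal(a1.positional_map, a2.positional_map)
        assert np.array_equal(a1.per_sample_sums, a2.per_sample_sums)

    def test_n_larger_than_available_warns_and_uses_all(self):
        net = CasCNN(11, 40, ModelConfig(seed=0))
        X = _random_encoded(10, seed=0)
        with pytest.warns(UserWarning, match="using all"):
            attr = deep_attribution(net, X, n=50, n_background=5, steps=2, seed=0)
        assert attr.n_explained == 10
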