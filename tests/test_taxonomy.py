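"""Cascade contracts: stage training/filtering, routing, majority voting,
metrics, embedding, and ablations (each sub-model is load-bearing)."""

import numpy as np
import pandas as pd
import pytest

import serstax as sx
from serstax.errors import SchemaError, TrainingError, ValidationError
from serstax.io import AnalyteLabel
from serstax.taxonomy import (
    ConfusionCounts,
    Protocol,
    embed_2d,
    feature_columns,
    metrics,
    predict_majority,
    predict_sample,
    predict_table,
    train_taxonomy,
)


class TestTraining:
    def test_stage_training_counts(self, mini_features, mini_model):
        counts = mini_model.metadata["training_rows"]
        n = len(mini_features)
        assert counts["stage1"] == n                  # all spectra
        assert counts["stage2"] == n - 6              # minus blanks
        assert counts["stage3"] == counts["stage4"] == 11 * 6  # cerebrosides
        assert counts["reg_glc"] == 5 * 6
        assert counts["reg_gal"] == 6 * 6

    def test_missing_class_names_stage(self, mini_features, mini_hp):
        no_blanks = mini_features[mini_features["category"] != "blank"]
        with pytest.raises(TrainingError, match="stage1"):
            train_taxonomy(no_blanks, mini_hp, seed=0)

    def test_same_seed_identical_predictions(self, mini_features, mini_hp):
        m1 = train_taxonomy(mini_features, mini_hp, seed=7)
        m2 = train_taxonomy(mini_features, mini_hp, seed=7)
        probe = mini_features.sample(10, random_state=0)
        t1 = predict_table(probe, m1)
        t2 = predict_table(probe, m2)
        pd.testing.assert_frame_equal(t1, t2)


class TestRouting:
    def test_blank_routes_to_blank_and_stops(self, mini_features,
                                             mini_model):
        row = mini_features[mini_features["category"] == "blank"].iloc[[0]]
        pred = predict_sample(row, mini_model)
        assert pred.nomenclature == "MPBA blank"
        assert pred.path == ["blank"]
        assert pred.chain_raw is None

    def test_cerebroside_full_path_and_nomenclature(self, mini_features,
                                                    mini_model):
        row = mini_features[mini_features["analyte"] == "GlcCer8"].iloc[[0]]
        pred = predict_sample(row, mini_model)
        assert pred.path == ["epimer", "cerebroside", "saturated", "glc"]
        assert pred.chain_rounded is not None
        assert abs(pred.chain_raw - 8) <= 2
        assert pred.nomenclature.startswith("GlcCer")

    def test_probabilities_sum_to_one(self, mini_features, mini_model):
        row = mini_features[mini_features["analyte"] ==
                            "GalCer24:1"].iloc[[0]]
        pred = predict_sample(row, mini_model)
        for stage, pair in pred.probabilities.items():
            assert sum(pair.values()) == pytest.approx(1.0)

    def test_low_confidence_flag_never_halts_routing(self, mini_model):
        # a feature vector mid-way between two classes still routes fully
        table = predict_table(
            np.zeros((1, 95)), mini_model
        )
        assert table["nomenclature"].iloc[0] is not None

    def test_schema_mismatch_rejected(self, mini_model):
        with pytest.raises(SchemaError):
            predict_table(np.zeros((1, 10)), mini_model)


class TestMajority:
    def test_consensus_over_replicates(self, mini_features, mini_model):
        reps = mini_features[mini_features["analyte"] == "GalCer12"]
        consensus = predict_majority(reps, mini_model)
        assert consensus.path == ["epimer", "cerebroside", "saturated",
                                  "gal"]
        assert consensus.nomenclature == "GalCer12"
        assert consensus.chain_sd is not None
        assert len(consensus.table) == len(reps)

    def test_single_replicate_consensus(self, mini_features, mini_model):
        row = mini_features[mini_features["analyte"] == "glucose"].iloc[[0]]
        consensus = predict_majority(row, mini_model)
        assert consensus.nomenclature == "monosaccharide"

    def test_tie_resolved_by_mean_probability(self, mini_features,
                                              mini_model):
        # force a stage-4 tie with one Glc-routed and one Gal-routed row
        glc = mini_features[mini_features["analyte"] == "GlcCer16"].iloc[[0]]
        gal = mini_features[mini_features["analyte"] == "GalCer16"].iloc[[0]]
        pair = pd.concat([glc, gal], ignore_index=True)
        consensus = predict_majority(pair, mini_model)
        assert "stage4" in consensus.ties
        table = consensus.table
        means = {
            "glc": table["stage4_glc"].mean(),
            "gal": table["stage4_gal"].mean(),
        }
        assert consensus.path[3] == max(means, key=means.get)


class TestForwardPrediction:
    def test_zero_noise_oracle_perfect_accuracy(self, quiet_features,
                                                mini_hp):
        rep = sx.forward_prediction(
            quiet_features, "GalCer16", Protocol(iterations=2), seed=0,
            hp=mini_hp,
        )
        assert rep.overall_accuracy == 1.0
        assert all(v == 1.0 for v in rep.stage_accuracy.values())
        assert rep.chain_abs_difference <= 1
        assert not rep.chain_extrapolated

    def test_extrapolated_chain_flagged(self, quiet_features, mini_hp):
        rep = sx.forward_prediction(
            quiet_features, "GlcCer24:1", Protocol(iterations=1), seed=0,
            hp=mini_hp,
        )
        # chain 24 absent from remaining Glc classes -> flagged
        assert rep.chain_extrapolated

    def test_missing_hold_out_rejected(self, mini_features):
        subset = mini_features[mini_features["analyte"] != "GalCer16"]
        with pytest.raises(ValidationError):
            sx.forward_prediction(subset, "GalCer16",
                                  Protocol(iterations=1), seed=0)

    def test_non_cerebroside_hold_out_rejected(self, mini_features):
        with pytest.raises(ValidationError):
            sx.forward_prediction(mini_features, "glucose",
                                  Protocol(iterations=1), seed=0)


class TestConcentrationTransfer:
    def test_probe_in_training_rejected(self, mini_features, mini_hp):
        with pytest.raises(ValidationError):
            sx.concentration_transfer(mini_features, mini_features,
                                      "GalCer16", hp=mini_hp)

    def test_accuracy_columns_and_ordering(self, cfg, mini_features,
                                           mini_hp):
        train = mini_features[mini_features["analyte"] != "GalCer16"]
        probes = []
        for conc in (1e-5, 1e-8):
            ps = sx.generate_dataset(
                cfg, conc_list=[conc], seed=9, replicates=3,
                labels=[AnalyteLabel.from_nomenclature("GalCer16")],
            )
            probes.append(sx.featurize_dataset(ps))
        report = sx.concentration_transfer(
            train, pd.concat(probes, ignore_index=True), "GalCer16",
            seed=0, hp=mini_hp,
        )
        assert list(report["concentration_M"]) == [1e-5, 1e-8]
        for col in ("overall", "stage1", "stage4", "chain_mean",
                    "predicted"):
            assert col in report.columns


class TestAblations:
    """Removing a sub-model removes the corresponding structural answer."""

    def test_no_stage4_no_hexose(self, mini_features, mini_model):
        import copy
        m = copy.copy(mini_model)
        m.stages = {k: v for k, v in mini_model.stages.items()
                    if k != "stage4"}
        row = mini_features[mini_features["analyte"] == "GalCer16"].iloc[[0]]
        with pytest.raises(KeyError):
            predict_table(row, m)

    def test_no_regressors_no_chain_length(self, mini_features, mini_model):
        import copy
        m = copy.copy(mini_model)
        m.regressors = {}
        row = mini_features[mini_features["analyte"] == "GalCer16"].iloc[[0]]
        pred = predict_sample(row, m)
        assert pred.chain_raw is None
        assert "?" in pred.nomenclature


class TestMetrics:
    def test_textbook_counts(self):
        m = metrics(ConfusionCounts(9, 0, 0, 1))
        assert m.accuracy == pytest.approx(0.9)
        assert m.recall == pytest.approx(0.9)
        assert m.precision == pytest.approx(1.0)
        assert m.f1 == pytest.approx(2 * 1.0 * 0.9 / 1.9)

    def test_undefined_precision_flagged_not_raised(self):
        m = metrics(ConfusionCounts(0, 0, 10, 0))
        assert m.accuracy == 1.0
        assert m.precision is None
        assert "precision" in m.undefined

    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(5, 0, 5, 0))
        assert m.accuracy == 1.0 and m.f1 == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            ConfusionCounts(-1, 0, 0, 0)


class TestEmbedding:
    def test_tsne_shape_contract(self, mini_features):
        X = mini_features[feature_columns(mini_features)].to_numpy()
        coords = embed_2d(X, method="tsne", perplexity=20.0, seed=0)
        assert coords.shape == (len(X), 2)

    def test_too_few_samples_for_tsne(self):
        with pytest.raises(ValidationError):
            embed_2d(np.random.default_rng(0).normal(size=(20, 95)),
                     perplexity=30.0)

    def test_pca_fallback_deterministic(self):
        X = np.random.default_rng(1).normal(size=(10, 95))
        a = embed_2d(X, method="pca", seed=3)
        b = embed_2d(X, method="pca", seed=3)
        np.testing.assert_array_equal(a, b)
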