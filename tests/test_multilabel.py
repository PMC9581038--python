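"""BR/LP transformations, boosting behaviour and model persistence."""

import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier

import abclass
from abclass import multilabel as ml
from abclass.multilabel import BaseLearnerConfig, fit_adaboost

from oracles import ReferenceAdaBoost

RF = BaseLearnerConfig(kind="rf", n_trees=40, seed=0)


@pytest.fixture(scope="module")
def encoded():
    ds = abclass.generate(
        abclass.default_spec(scale=0.02, signal_strength=1.5, seed=7))
    return ds, abclass.encode_dataset(ds, "aac")


class TestBinaryRelevance:
    def test_exactly_four_members(self, encoded):
        ds, fm = encoded
        model = ml.fit(fm, ds, "binary_relevance", RF, encoder="aac")
        assert len(model.members) == 4

    def test_member_equals_standalone_one_vs_rest(self, encoded):
        """The IgG member is exactly an IgG-vs-rest forest with the same seed."""
        ds, fm = encoded
        model = ml.fit(fm, ds, "binary_relevance", RF, encoder="aac")
        X = fm.to_numpy()
        standalone = RandomForestClassifier(n_estimators=RF.n_trees,
                                            random_state=RF.seed)
        standalone.fit(X, ds.label_matrix()[:, 0])
        assert np.array_equal(model.members[0].predict(X), standalone.predict(X))

    def test_memorizes_training_data(self, encoded):
        ds, fm = encoded
        model = ml.fit(fm, ds, "binary_relevance", RF, encoder="aac")
        bits, scores = ml.predict(model, fm)
        assert abclass.hamming_loss(ds.label_matrix(), bits) < 0.02
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_all_zero_call_is_possible(self):
        """BR members are independent, so no class at all is a legal call."""
        recs = [abclass.EpitopeRecord(f"p{i}", "AAAAA", (1, 0, 0, 0))
                for i in range(5)]
        recs += [abclass.EpitopeRecord(f"n{i}", "GGGGG", (0, 1, 0, 0))
                 for i in range(5)]
        ds = abclass.Dataset(records=recs)
        fm = abclass.encode_dataset(ds, "aac")
        model = ml.fit(fm, ds, "binary_relevance", RF, encoder="aac")
        probe = abclass.Dataset(records=[
            abclass.EpitopeRecord("q", "WWWWW", None)])
        bits, _ = ml.predict(model, abclass.encode_dataset(probe, "aac"))
        assert bits.shape == (1, 4)  # whatever the call, shape holds; zeros allowed

    def test_zero_positive_label_predicts_constant_negative(self, caplog):
        recs = [abclass.EpitopeRecord(f"r{i}", "ACDEF", (1, 0, 0, 0))
                for i in range(6)]
        ds = abclass.Dataset(records=recs)
        fm = abclass.encode_dataset(ds, "aac")
        with caplog.at_level("WARNING"):
            model = ml.fit(fm, ds, "binary_relevance", RF, encoder="aac")
        assert "single class" in caplog.text
        bits, _ = ml.predict(model, fm)
        assert (bits[:, 1] == 0).all()  # IgE never called


class TestLabelPowerset:
    def test_codebook_covers_observed_combinations(self, encoded):
        ds, fm = encoded
        model = ml.fit(fm, ds, "label_powerset", RF, encoder="aac")
        census = abclass.combination_census(ds)
        assert set(model.codebook) == set(census)
        assert len(model.codebook) == 11

    def test_roundtrip_bits_to_class_to_bits(self, encoded):
        ds, fm = encoded
        model = ml.fit(fm, ds, "label_powerset", RF, encoder="aac")
        code_of = {c: i for i, c in enumerate(model.codebook)}
        for r in ds.records[:50]:
            assert model.codebook[code_of[r.labels]] == r.labels

    def test_never_emits_unseen_combination(self, encoded, rng):
        ds, fm = encoded
        model = ml.fit(fm, ds, "label_powerset", RF, encoder="aac")
        aas = np.array(list(abclass.AMINO_ACIDS))
        probes = abclass.Dataset(records=[
            abclass.EpitopeRecord(f"pr{i}",
                                  "".join(rng.choice(aas, size=12)), None)
            for i in range(40)])
        bits, _ = ml.predict(model, abclass.encode_dataset(probes, "aac"))
        seen = set(model.codebook)
        for row in bits:
            assert tuple(row) in seen


class TestDeterminismAndSpec:
    def test_identical_seed_identical_predictions(self, encoded):
        ds, fm = encoded
        for strategy in ("binary_relevance", "label_powerset"):
            a = ml.fit(fm, ds, strategy, RF, encoder="aac")
            b = ml.fit(fm, ds, strategy, RF, encoder="aac")
            ba, _ = ml.predict(a, fm)
            bb, _ = ml.predict(b, fm)
            assert np.array_equal(ba, bb)

    def test_column_mismatch_is_fatal(self, encoded):
        ds, fm = encoded
        model = ml.fit(fm, ds, "binary_relevance", RF, encoder="aac")
        with pytest.raises(ValueError):
            ml.predict(model, fm[fm.columns[::-1]])

    def test_unknown_strategy_and_bad_config(self, encoded):
        ds, fm = encoded
        with pytest.raises(ValueError):
            ml.fit(fm, ds, "classifier_chains", RF, encoder="aac")
        with pytest.raises(ValueError):
            BaseLearnerConfig(kind="svm")
        with pytest.raises(ValueError):
            BaseLearnerConfig(n_trees=0)


class TestAdaBoost:
    def _toy(self):
        # linearly separable in one dimension
        X = np.array([[x] for x in range(20)], dtype=float)
        y = np.array([-1] * 10 + [1] * 10)
        return X, y

    def test_training_error_reaches_zero_on_separable_toy(self):
        X, y = self._toy()
        booster = fit_adaboost(X, (y > 0).astype(int),
                               BaseLearnerConfig(kind="rf_adaboost",
                                                 n_trees=25, n_boost_rounds=5),
                               seed=0)
        assert (booster.predict(X) == (y > 0).astype(int)).all()
        # the classic stump-based behaviour: hand-rolled loop drives the
        # training error to zero within a few rounds
        ref = ReferenceAdaBoost(
            lambda t: DecisionTreeClassifier(max_depth=1), n_rounds=6)
        ref.fit(X.tolist(), y.tolist())
        assert ref.training_error(X.tolist(), y.tolist()) == 0.0

    def test_matches_hand_rolled_reference_with_stumps(self):
        """Same stump base learner: sklearn and the textbook loop agree."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 2))
        y = np.where(X[:, 0] + 0.3 * rng.normal(size=60) > 0, 1, -1)
        ref = ReferenceAdaBoost(
            lambda t: DecisionTreeClassifier(max_depth=1), n_rounds=8)
        ref.fit(X.tolist(), y.tolist())
        from sklearn.ensemble import AdaBoostClassifier
        sk = AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=8, random_state=0)
        sk.fit(X, y)
        agree = np.mean(np.array(ref.predict(X.tolist())) == sk.predict(X))
        assert agree >= 0.95
        assert ref.training_error(X.tolist(), y.tolist()) <= 0.1

    def test_reference_weights_stay_normalized(self):
        X, y = self._toy()
        ref = ReferenceAdaBoost(
            lambda t: DecisionTreeClassifier(max_depth=1), n_rounds=6)
        ref.fit(X.tolist(), y.tolist())
        for d in ref.weight_history:
            assert sum(d) == pytest.approx(1.0, abs=1e-9)

    def test_reference_training_error_non_increasing_in_rounds(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(50, 2)).tolist()
        y = [1 if a + b > 0 else -1 for a, b in X]
        errors = []
        for t in (1, 3, 6):
            ref = ReferenceAdaBoost(
                lambda _: DecisionTreeClassifier(max_depth=1), n_rounds=t)
            ref.fit(X, y)
            errors.append(ref.training_error(X, y))
        assert errors == sorted(errors, reverse=True) or errors[-1] <= errors[0]

    def test_single_round_is_one_forest_voting_alone(self):
        X, y = self._toy()
        y01 = (y > 0).astype(int)
        booster = fit_adaboost(X, y01,
                               BaseLearnerConfig(kind="rf_adaboost", n_trees=10,
                                                 n_boost_rounds=1), seed=0)
        assert len(booster.estimators_) == 1
        member = booster.estimators_[0]
        assert isinstance(member, RandomForestClassifier)
        assert member.n_estimators == 10
        assert np.array_equal(booster.predict(X), member.predict(X))

    def test_perfect_round_stops_boosting_early(self):
        X, y = self._toy()
        booster = fit_adaboost(X, (y > 0).astype(int),
                               BaseLearnerConfig(kind="rf_adaboost",
                                                 n_trees=50, n_boost_rounds=10),
                               seed=0)
        assert len(booster.estimators_) == 1  # zero-error first round


class TestPersistence:
    def test_save_load_roundtrips_predictions(self, encoded, tmp_path, rng):
        ds, fm = encoded
        model = ml.fit(fm, ds, "binary_relevance", RF, encoder="aac")
        path = tmp_path / "model.joblib"
        ml.save_model(model, path)
        loaded = ml.load_model(path)
        aas = np.array(list(abclass.AMINO_ACIDS))
        probes = abclass.Dataset(records=[
            abclass.EpitopeRecord(f"x{i}", "".join(rng.choice(aas, size=15)),
                                  None) for i in range(50)])
        b1, s1 = ml.predict_dataset(model, probes)
        b2, s2 = ml.predict_dataset(loaded, probes)
        assert np.array_equal(b1, b2) and np.allclose(s1, s2)
        assert loaded.encoder == model.encoder

    def test_corrupted_file_is_clean_error(self, tmp_path):
        bad = tmp_path / "bad.joblib"
        bad.write_text("not a model")
        with pytest.raises(ValueError):
            ml.load_model(bad)

    def test_version_mismatch_is_fatal(self, encoded, tmp_path):
        ds, fm = encoded
        model = ml.fit(fm, ds, "binary_relevance", RF, encoder="aac")
        path = tmp_path / "model.joblib"
        import joblib
        joblib.dump({"format_version": 999, "model": model}, path)
        with pytest.raises(ValueError, match="format"):
            ml.load_model(path)
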