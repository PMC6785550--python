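"""Distance-weighted KNN posterior scoring and effectiveness ranking."""

import pickle

import numpy as np
import pandas as pd
import pytest

from standscore.pipeline import FeatureMatrix
from standscore.predict import (MusclePairScorer, RankedPrediction,
                                label_and_aggregate, rank_parameter_sets,
                                score_events, train_models)


from oracles import eq9_oracle


def _scorer(X, y, **kw):
    return MusclePairScorer(standardize=False, **kw).fit(X, y)


class TestPosteriorScore:
    def test_all_neighbors_independent_scores_one(self):
        X = np.arange(10.0)[:, None]
        y = ["independent"] * 5 + ["assisted"] * 5
        s = _scorer(X, y)
        assert s.score_samples([[1.2]])[0] == pytest.approx(1.0)

    def test_all_neighbors_assisted_scores_zero(self):
        X = np.arange(10.0)[:, None]
        y = ["independent"] * 5 + ["assisted"] * 5
        s = _scorer(X, y)
        assert s.score_samples([[8.2]])[0] == pytest.approx(0.0)

    def test_hand_computed_mixed_neighborhood(self):
        # 3 independent at distances 1, 2, 3; 2 assisted at 1.5, 2.5;
        # equal priors (3 extra faraway assisted rows balance the count)
        X = np.array([[1.0], [2.0], [3.0], [-1.5], [-2.5],
                      [50.0], [60.0], [70.0]])
        y = ["independent"] * 3 + ["assisted"] * 2 + ["independent"] * 1 \
            + ["assisted"] * 2
        s = _scorer(X, y)
        x_new = np.array([0.0])
        got = s.score_samples([x_new])[0]
        # equal priors (4/4) cancel: score = sum(1/d_indep) / sum(1/d_all)
        wi = 1 / 1.0 + 1 / 2.0 + 1 / 3.0
        wa = 1 / 1.5 + 1 / 2.5
        assert got == pytest.approx(wi / (wi + wa), abs=1e-12)
        assert got == pytest.approx(eq9_oracle(X, y, x_new), abs=1e-12)

    @pytest.mark.parametrize("weight_mode", ["inverse_prior", "raw_distance"])
    def test_matches_brute_force_on_random_instances(self, rng, weight_mode):
        for _ in range(200):
            n = int(rng.integers(6, 21))
            d = int(rng.integers(1, 4))
            X = rng.normal(0, 1, (n, d))
            y = np.array(["independent", "assisted"])[
                rng.integers(0, 2, n)]
            if len(set(y)) < 2:
                y[0] = "independent" if y[1] == "assisted" else "assisted"
            s = _scorer(X, y, weight_mode=weight_mode)
            x_new = rng.normal(0, 1, d)
            got = s.score_samples([x_new])[0]
            want = eq9_oracle(X, y, x_new, weight_mode=weight_mode)
            assert got == pytest.approx(want, abs=1e-12)

    def test_invariant_to_training_set_duplication(self, rng):
        # duplicating every training row (doubling K along with it, so the
        # same distinct points are in the neighborhood) duplicates every
        # weight and leaves the prior-normalized posterior unchanged
        X = rng.normal(0, 1, (12, 2))
        y = ["independent"] * 7 + ["assisted"] * 5
        probe = rng.normal(0, 1, (5, 2))
        s1 = _scorer(X, y, n_neighbors=5).score_samples(probe)
        s2 = _scorer(np.vstack([X, X]), y + y,
                     n_neighbors=10).score_samples(probe)
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    def test_zero_distance_neighbor_dominates(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0], [4.0], [5.0]])
        y = ["assisted", "independent", "independent", "independent",
             "independent", "assisted"]
        s = _scorer(X, y)
        assert s.score_samples([[0.0]])[0] == 0.0

    def test_agrees_with_inverse_distance_knn_on_balanced_data(self, rng):
        """With balanced classes the prior factors cancel and the posterior
        score > 0.5 rule must reproduce inverse-distance-weighted KNN."""
        from standscore.classify import KnnStandingClassifier
        X = rng.normal(0, 1, (40, 3))
        y = np.array(["independent"] * 20 + ["assisted"] * 20)
        probe = rng.normal(0, 1, (30, 3))
        scorer = MusclePairScorer(n_neighbors=5, standardize=True).fit(X, y)
        knn = KnnStandingClassifier(n_neighbors=5, weighting="inverse",
                                    standardize=True).fit(X, y)
        assert (scorer.predict(probe) == knn.predict(probe)).all()


class TestLabelAndAggregate:
    def test_exact_half_is_assisted(self):
        rp = label_and_aggregate({"L SOL": 0.5})
        assert rp.per_muscle_label["L SOL"] == "assisted"

    def test_symmetric_scores_equal_aggregates(self):
        rp = label_and_aggregate({"L SOL": 0.7, "R SOL": 0.7,
                                  "L TA": 0.3, "R TA": 0.3})
        assert rp.aggregate_left == rp.aggregate_right == rp.aggregate_total

    def test_single_muscle_total(self):
        rp = label_and_aggregate({"L MG": 0.42})
        assert rp.aggregate_total == pytest.approx(0.42)

    def test_score_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            RankedPrediction({"L SOL": 1.2})

    def test_colormap_table(self):
        rp = label_and_aggregate({"L SOL": 0.8, "R SOL": 0.2})
        tab = rp.to_frame()
        assert set(tab.columns) == {"muscle", "score", "label"}
        assert set(tab["label"]) == {"independent", "assisted"}


def _training_matrix(muscles=("SOL", "TA"), n=30, seed=0):
    rng = np.random.default_rng(seed)
    keys, rows, ys = [], [], []
    for m in muscles:
        for side in ("L", "R"):
            for i in range(n):
                indep = i < n // 2
                keys.append(("P1", f"e{m}{side}{i}", f"{side} {m}"))
                rows.append(rng.normal(3.0 if indep else 0.0, 1.0, 3))
                ys.append("independent" if indep else "assisted")
    idx = pd.MultiIndex.from_tuples(
        keys, names=["participant", "event_id", "muscle"])
    return FeatureMatrix(df=pd.DataFrame(rows, index=idx,
                                         columns=["a", "b", "c"]),
                         y=pd.Series(ys, index=idx, name="label"),
                         stage="log")


class TestTrainModels:
    def test_one_model_per_pair(self):
        fm = _training_matrix(muscles=("SOL", "MG", "TA", "MH"))
        models = train_models(fm, ["SOL", "MG", "TA", "MH"], regime="i",
                              log_cv_accuracy=False)
        assert len(models) == 4
        assert models[0].muscle_pair == ("L SOL", "R SOL")
        assert all(m.n_train == 60 for m in models)

    def test_missing_class_names_pair_and_regime(self):
        fm = _training_matrix()
        only_assisted = FeatureMatrix(
            df=fm.df[fm.y == "assisted"], y=fm.y[fm.y == "assisted"],
            stage="log")
        with pytest.raises(ValueError, match="SOL.*regime i"):
            train_models(only_assisted, ["SOL"], regime="i",
                         log_cv_accuracy=False)

    def test_serialization_round_trip(self):
        fm = _training_matrix()
        model = train_models(fm, ["SOL"], log_cv_accuracy=False)[0]
        probe = np.random.default_rng(1).normal(0, 1, (10, 3))
        back = pickle.loads(pickle.dumps(model))
        np.testing.assert_array_equal(back.scorer.score_samples(probe),
                                      model.scorer.score_samples(probe))

    def test_harder_regime_scores_lower_cv_accuracy(self):
        """A regime built from nearly identical class distributions must
        show lower training CV accuracy than a well-separated one."""
        rng = np.random.default_rng(5)
        keys, rows, ys = [], [], []
        # independent cluster at 4; fully assisted far away at 0 (easy
        # contrast for regime i); hips-assisted right next to independent
        # at 3.6 (hard contrast for regime iii)
        spec = [("i", 40, 4.0, "independent"),
                ("a", 40, 0.0, "assisted"),
                ("h", 40, 3.6, "hips_assisted_knees_independent")]
        for tag, n, center, label in spec:
            for i in range(n):
                for side in ("L", "R"):
                    keys.append(("P1", f"{tag}{i}{side}", f"{side} SOL"))
                    rows.append(rng.normal(center, 1.0, 3))
                    ys.append(label)
        idx = pd.MultiIndex.from_tuples(
            keys, names=["participant", "event_id", "muscle"])
        fm = FeatureMatrix(df=pd.DataFrame(rows, index=idx,
                                           columns=["a", "b", "c"]),
                           y=pd.Series(ys, index=idx, name="label"),
                           stage="log")
        easy = train_models(fm, ["SOL"], regime="i", seed=0)[0]
        hard = train_models(fm, ["SOL"], regime="iii", seed=0)[0]
        assert easy.train_cv_accuracy > hard.train_cv_accuracy


class TestScoreAndRank:
    def test_score_events_schema_check(self):
        fm = _training_matrix()
        models = train_models(fm, ["SOL", "TA"], log_cv_accuracy=False)
        bad = FeatureMatrix(df=fm.df.rename(columns={"a": "z"}), y=fm.y,
                            stage="log")
        with pytest.raises(ValueError, match="schema"):
            score_events(models, bad)

    def test_parameter_set_ranking_reflects_generator_distance(self):
        fm = _training_matrix(n=40)
        models = train_models(fm, ["SOL", "TA"], log_cv_accuracy=False)
        rng = np.random.default_rng(3)

        def _events(center, tag, n_ev=6):
            keys, rows = [], []
            for i in range(n_ev):
                for ch in ("L SOL", "R SOL", "L TA", "R TA"):
                    keys.append(("P1", f"{tag}{i}", ch))
                    rows.append(rng.normal(center, 0.5, 3))
            idx = pd.MultiIndex.from_tuples(
                keys, names=["participant", "event_id", "muscle"])
            y = pd.Series(["assisted"] * len(keys), index=idx)
            return FeatureMatrix(df=pd.DataFrame(
                rows, index=idx, columns=["a", "b", "c"]), y=y, stage="log")

        near_indep = _events(3.0, "ni")
        near_assist = _events(0.0, "na")
        ranked = rank_parameter_sets(models, {"setA": near_assist,
                                              "setB": near_indep})
        assert [ps for ps, _ in ranked] == ["setB", "setA"]
        assert ranked[0][1].aggregate_total > ranked[1][1].aggregate_total

    def test_tie_keeps_input_order_and_counts(self):
        fm = _training_matrix()
        models = train_models(fm, ["SOL", "TA"], log_cv_accuracy=False)
        rng = np.random.default_rng(3)
        keys = [("P1", "x0", ch) for ch in ("L SOL", "R SOL")]
        idx = pd.MultiIndex.from_tuples(
            keys, names=["participant", "event_id", "muscle"])
        fm_ev = FeatureMatrix(
            df=pd.DataFrame(rng.normal(0, 1, (2, 3)), index=idx,
                            columns=["a", "b", "c"]),
            y=pd.Series(["assisted"] * 2, index=idx), stage="log")
        ranked = rank_parameter_sets(
            models, {f"set{i}": fm_ev for i in range(9)})
        assert len(ranked) == 9
        assert [ps for ps, _ in ranked] == [f"set{i}" for i in range(9)]
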