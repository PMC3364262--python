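import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from furcula.pfda import (
    confusion_summary,
    lambda_sweep,
    loo_accuracy,
    optimize_lambda,
    pfda_predict,
    pfda_train,
    whitening_matrix,
)
from furcula.phylo import parse_newick, simulate_bm, vcv_with_lambda
from furcula.synthetic import load_fixtures, simulate_tree


@pytest.fixture(scope="module")
def star_data(star20):
    rng = np.random.default_rng(0)
    X = pd.DataFrame(rng.standard_normal((20, 3)), index=star20.tip_labels,
                     columns=["a", "b", "c"])
    y = pd.Series(rng.choice(["u", "v"], 20), index=star20.tip_labels)
    return X, y


class TestWhitening:
    @pytest.mark.parametrize("lam", [0.0, 0.5, 1.0])
    def test_contract(self, tree16, lam):
        C = vcv_with_lambda(tree16, lam).V
        W = whitening_matrix(C)
        assert np.abs(W @ C @ W.T - np.eye(len(C))).max() < 1e-6


class TestOptimizeLambda:
    def test_single_grid_value_returned(self, tree16):
        X = simulate_bm(tree16, 1.0, n_traits=2, seed=1)
        y = pd.Series(["a"] * 8 + ["b"] * 8, index=tree16.tip_labels)
        lam, profile, _ = optimize_lambda(X, y, tree16, grid=np.array([0.37]),
                                          refine=False)
        assert lam == 0.37
        assert len(profile) == 1

    def test_star_tree_flat_profile(self, star20, star_data):
        X, y = star_data
        _, profile, flat = optimize_lambda(X, y, star20)
        assert flat
        assert profile["logL"].max() - profile["logL"].min() < 1e-6

    def test_recovers_high_lambda_for_bm_traits(self):
        hits = 0
        for i in range(50):
            tree = simulate_tree(40, seed=50 + i)
            X = simulate_bm(tree, 1.0, n_traits=3, seed=1000 + i)
            y = pd.Series(["A"] * 20 + ["B"] * 20, index=tree.tip_labels)
            lam, _, _ = optimize_lambda(X, y, tree)
            hits += lam >= 0.7
        assert hits >= 35

    def test_iid_traits_give_low_lambda(self):
        tree = simulate_tree(40, seed=99)
        X = pd.DataFrame(np.random.default_rng(0).standard_normal((40, 3)),
                         index=tree.tip_labels)
        y = pd.Series(["A"] * 20 + ["B"] * 20, index=tree.tip_labels)
        lam, _, _ = optimize_lambda(X, y, tree)
        assert lam <= 0.2


class TestTrainPredict:
    def test_star_lambda0_matches_lda_oracle(self, star20, star_data):
        X, y = star_data
        m = pfda_train(X, y, star20, lam=0.0)
        Xw = m.whitener @ X.reindex(m.training_ids).to_numpy()
        pred = m.lda.predict(Xw)
        oracle = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y).predict(
            X.reindex(m.training_ids)
        )
        assert (pred == oracle).all()

    @pytest.mark.parametrize("seed", range(20))
    def test_star_lambda0_prediction_agreement_random(self, seed):
        n = 16
        tips = [f"t{i}" for i in range(n)] + [f"u{i}" for i in range(5)]
        star = parse_newick("(" + ",".join(f"{t}:1" for t in tips) + ");")
        rng = np.random.default_rng(seed)
        train_tips = tips[:n]
        X = pd.DataFrame(rng.standard_normal((n, 2)), index=train_tips)
        y = pd.Series(rng.choice(["u", "v"], n), index=train_tips)
        if y.value_counts().min() < 2:
            y.iloc[:2] = "u"
            y.iloc[2:4] = "v"
        m = pfda_train(X, y, star, lam=0.0)
        new = pd.DataFrame(rng.standard_normal((5, 2)), index=tips[n:])
        pred = pfda_predict(m, new, star)
        oracle = LinearDiscriminantAnalysis(priors=[0.5, 0.5]).fit(X, y).predict(new)
        assert (pred["predicted"].to_numpy() == oracle).all()

    def test_separable_data_zero_training_error(self, tree16):
        X = pd.DataFrame(
            {"s": np.r_[np.zeros(8), np.ones(8) * 10]}, index=tree16.tip_labels
        )
        y = pd.Series(["lo"] * 8 + ["hi"] * 8, index=tree16.tip_labels)
        m = pfda_train(X, y, tree16, lam=0.5)
        resub = pfda_predict(m, X, tree16)
        assert (resub["predicted"] == y.reindex(resub.index)).all()

    def test_small_class_rejected(self, tree16):
        X = simulate_bm(tree16, 1.0, seed=1)
        y = pd.Series(["a"] + ["b"] * 15, index=tree16.tip_labels)
        with pytest.raises(ValueError, match="< 2 training tips"):
            pfda_train(X, y, tree16, lam=0.5)

    def test_unknown_tip_missing_from_tree(self, tree16):
        X = simulate_bm(tree16, 1.0, seed=2)
        y = pd.Series(["a"] * 8 + ["b"] * 8, index=tree16.tip_labels)
        m = pfda_train(X, y, tree16, lam=0.5)
        ghost = pd.DataFrame({"t1": [0.0]}, index=["nosuchtip"])
        with pytest.raises(ValueError, match="nosuchtip"):
            pfda_predict(m, ghost, tree16)

    def test_identical_unknown_gets_training_class(self):
        tree = parse_newick("((a:1,b:1):1,(c:1,d:1):1,(u:1,e:1):1);")
        X = pd.DataFrame({"s": [0.0, 0.1, 1.0, 1.1, 0.05]},
                         index=["a", "b", "c", "d", "e"])
        y = pd.Series(["lo", "lo", "hi", "hi", "lo"], index=X.index)
        m = pfda_train(X, y, tree, lam=0.5)
        pred = pfda_predict(m, pd.DataFrame({"s": [0.0]}, index=["u"]), tree)
        assert pred["predicted"].iloc[0] == "lo"

    def test_far_outlier_flagged_low_posterior(self, tree24):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.standard_normal((23, 2)),
                         index=tree24.tip_labels[:23])
        y = pd.Series(["a"] * 12 + ["b"] * 11, index=X.index)
        m = pfda_train(X, y, tree24, lam=0.0)
        # an unknown shape far outside training morphospace, positioned
        # between the class centroids so neither is a confident call
        mid = (X[y == "a"].mean() + X[y == "b"].mean()) / 2
        out = pd.DataFrame([mid + [0.0, 50.0]], index=[tree24.tip_labels[23]])
        pred = pfda_predict(m, out, tree24)
        assert bool(pred["low_posterior_flag"].iloc[0]) == (
            pred["max_posterior"].iloc[0] < 0.5
        )

    def test_duplicated_training_same_directions(self, tree16):
        X = simulate_bm(tree16, 1.0, n_traits=2, seed=3)
        y = pd.Series(["a"] * 8 + ["b"] * 8, index=tree16.tip_labels)
        m1 = pfda_train(X, y, tree16, lam=0.3)
        m2 = pfda_train(X, y, tree16, lam=0.3)
        assert np.allclose(m1.lda.coef_, m2.lda.coef_)


class TestLambdaSweep:
    def test_single_grid_single_column(self, tree16):
        X = simulate_bm(tree16, 1.0, n_traits=2, seed=4)
        y = pd.Series(["a"] * 8 + ["b"] * 7, index=tree16.tip_labels[:15])
        unk = X.loc[[tree16.tip_labels[15]]]
        table, stab = lambda_sweep(X.loc[y.index], y, unk, tree16,
                                   grid=np.array([0.5]))
        assert table.shape == (1, 1)
        assert stab.iloc[0] == 1.0

    def test_boundary_case_detected_unstable(self):
        # unknown tied to clade "hi" by phylogeny but with "lo" trait value:
        # prediction flips as lambda moves weight onto the phylogeny
        tree = parse_newick(
            "((a:1,b:1):3,((c:1,d:1):1,(u:1.8,e:1.8):0.2):2);"
        )
        X = pd.DataFrame({"s": [0.0, 0.2, 5.0, 5.2, 5.1]},
                         index=["a", "b", "c", "d", "e"])
        y = pd.Series(["lo", "lo", "hi", "hi", "hi"], index=X.index)
        unk = pd.DataFrame({"s": [3.0]}, index=["u"])
        table, stab = lambda_sweep(X, y, unk, tree,
                                   grid=np.linspace(0, 1, 11))
        assert stab.iloc[0] < 1.0


class TestConfusionSummary:
    def test_published_counts_reproduce_printed_summaries(self):
        t6 = load_fixtures("table6_confusion")
        true, pred = [], []
        for p in t6.index:
            for t in t6.columns:
                true += [t] * int(t6.loc[p, t])
                pred += [p] * int(t6.loc[p, t])
        cm = confusion_summary(true, pred, classes=list(t6.columns))
        assert cm.percent_correct.to_dict() == {
            "Bound": 63, "Flap": 81, "Glide": 28,
            "Poor": 33, "Preflight": 71, "Soar": 90,
        }
        assert cm.error_rate == pytest.approx(0.4)
        assert (cm.counts.to_numpy() == t6.to_numpy()).all()

    def test_identity_predictions(self):
        labs = ["a"] * 3 + ["b"] * 2
        cm = confusion_summary(labs, labs)
        assert (cm.percent_correct == 100).all()
        assert cm.error_rate == 0.0

    def test_all_wrong(self):
        cm = confusion_summary(["a", "a", "b", "b"], ["b", "b", "a", "a"])
        assert (cm.percent_correct == 0).all()
        assert cm.error_rate == 1.0

    def test_column_sums_match_true_counts(self):
        rng = np.random.default_rng(1)
        true = rng.choice(list("xyz"), 30)
        pred = rng.choice(list("xyz"), 30)
        cm = confusion_summary(true, pred)
        for c in "xyz":
            assert cm.counts[c].sum() == (true == c).sum()

    def test_stray_label_rejected(self):
        with pytest.raises(ValueError, match="outside class set"):
            confusion_summary(["a"], ["q"], classes=["a", "b"])


def test_loo_accuracy_five_class_generator(five_class_dataset, five_class_scores):
    """Training-class recovery on the synthetic generator (chance = 20%)."""
    _, scores = five_class_scores
    labels = five_class_dataset["metadata"]["flight_mode"].reindex(scores.index)
    acc = loo_accuracy(scores, labels, five_class_dataset["tree"])
    assert acc >= 0.6
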