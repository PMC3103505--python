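"""Representation spaces, LOO-LDA posteriors, and forward measure selection."""

import numpy as np
import pandas as pd
import pytest

from tractnet import (
    accuracy_from_posteriors,
    build_space,
    lda_loocv,
    sequential_forward_select,
)

ALGOS = ["FACT", "TL", "TEND"]


def table(values, subjects=None):
    values = np.asarray(values, dtype=float)
    subjects = subjects or [f"s{i}" for i in range(len(values))]
    return pd.DataFrame(values, index=subjects, columns=ALGOS)


def clusters(rng, gap=20.0, spread=1.0, n=6, d=3):
    a = rng.standard_normal((n, d)) * spread
    b = rng.standard_normal((n, d)) * spread + gap
    return np.vstack([a, b]), ["control"] * n + ["case"] * n


class TestBuildSpace:
    def test_single_measure_gives_three_dimensions(self, rng):
        space = build_space({"C": table(rng.random((12, 3)))})
        assert space.points.shape == (12, 3)
        assert space.n_dims == 3

    def test_six_measures_give_eighteen_dimensions(self, rng):
        tabs = {m: table(rng.random((12, 3))) for m in "ABCDEF"}
        space = build_space(tabs, measures=list("ABCDEF"))
        assert space.points.shape == (12, 18)
        # declared order: measure-major, algorithm-minor
        np.testing.assert_array_equal(space.points[:, :3], tabs["A"].to_numpy())

    def test_row_permutation_permutes_points(self, rng):
        vals = rng.random((6, 3))
        s1 = build_space({"C": table(vals)})
        perm = [3, 1, 0, 2, 5, 4]
        s2 = build_space({"C": table(vals[perm], subjects=[f"s{i}" for i in perm])})
        np.testing.assert_array_equal(s1.points[perm], s2.points)

    def test_missing_value_named_in_error(self, rng):
        vals = rng.random((6, 3))
        vals[2, 1] = np.nan
        with pytest.raises(ValueError, match="s2.*'C'.*TL"):
            build_space({"C": table(vals)})


class TestLdaLoocv:
    def test_separated_clusters_classified_perfectly(self, rng):
        X, labels = clusters(rng, gap=30.0, spread=1.0)
        space = build_space({"C": table(X, subjects=[f"s{i}" for i in range(12)])})
        res = lda_loocv(space, labels)
        assert res.percent_correct == 100.0
        post = res.posteriors
        assert np.all((post[:6] > 0.99) | (post[:6] < 0.01)) and np.all(post[:6] > 0.5)
        assert np.all(post[6:] < 0.01)

    def test_midpoint_of_mirror_symmetric_classes_gets_half(self):
        # held-out subject at the exact mirror point of two symmetric classes
        X = np.array(
            [[-2.0, 0], [-3, 1], [-3, -1], [2, 0], [3, 1], [3, -1], [0, 0]]
        )
        labels = ["control"] * 3 + ["case"] * 3 + ["case"]
        tabs = pd.DataFrame(X, index=[f"s{i}" for i in range(7)], columns=["a", "b"])
        space = build_space({"m": tabs})
        res = lda_loocv(space, labels)
        assert res.posteriors[-1] == pytest.approx(0.5, abs=1e-9)

    def test_posterior_pair_sums_to_one(self, rng):
        X, labels = clusters(rng, gap=3.0)
        space = build_space({"C": table(X)})
        res = lda_loocv(space, labels)
        # P(case) = 1 - P(control) by construction of the binary posterior
        assert np.all((res.posteriors >= 0) & (res.posteriors <= 1))

    def test_accuracy_invariant_under_affine_rescaling(self, rng):
        X, labels = clusters(rng, gap=4.0, spread=2.0)
        s1 = build_space({"C": table(X)})
        s2 = build_space({"C": table(X * 37.5 + 11.0)})
        assert (
            lda_loocv(s1, labels).percent_correct
            == lda_loocv(s2, labels).percent_correct
        )

    def test_permuted_labels_give_chance_accuracy(self, rng):
        X, _ = clusters(rng, gap=5.0)
        space = build_space({"C": table(X)})
        accs = []
        for _ in range(60):
            labels = list(rng.permutation(["control"] * 6 + ["case"] * 6))
            accs.append(lda_loocv(space, labels).percent_correct)
        assert abs(np.mean(accs) - 50.0) < 10.0

    def test_agrees_with_sklearn_on_well_conditioned_data(self, rng):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X, labels = clusters(rng, gap=2.5, spread=1.0, n=10, d=2)
        y = np.array([1] * 10 + [0] * 10)
        space = build_space({"C": pd.DataFrame(X, index=[f"s{i}" for i in range(20)],
                                               columns=["a", "b"])})
        res = lda_loocv(space, labels, ridge=1e-12)
        for i in range(20):
            mask = np.arange(20) != i
            sk = LinearDiscriminantAnalysis(priors=[0.5, 0.5])
            sk.fit(X[mask], y[mask])
            p_sk = sk.predict_proba(X[i : i + 1])[0, 1]
            assert res.posteriors[i] == pytest.approx(p_sk, abs=1e-6)

    def test_requires_two_members_per_class(self, rng):
        X = rng.random((4, 3))
        space = build_space({"C": table(X, subjects=[f"s{i}" for i in range(4)])})
        with pytest.raises(ValueError, match="at least 2"):
            lda_loocv(space, ["control", "case", "case", "case"])


class TestAccuracy:
    def test_worked_posterior_columns_reproduce_printed_accuracies(self):
        from reference_tables import POSTERIORS, TRUE_LABELS

        for column, printed in [("L", 66.67), ("E_glob", 91.66), ("C", 100.0),
                                ("combined", 100.0)]:
            acc = accuracy_from_posteriors(POSTERIORS[column], TRUE_LABELS)
            assert acc == pytest.approx(printed, abs=0.011)

    def test_all_correct_side_gives_100(self):
        acc = accuracy_from_posteriors(
            [0.9, 0.8, 0.2, 0.1], ["control", "control", "case", "case"]
        )
        assert acc == 100.0

    def test_posterior_at_threshold_counted_incorrect(self, caplog):
        acc = accuracy_from_posteriors([0.5, 0.9], ["control", "control"])
        assert acc == 50.0

    def test_rejects_out_of_range_posteriors(self):
        with pytest.raises(ValueError):
            accuracy_from_posteriors([1.2], ["control"])


class TestForwardSelection:
    def test_perfect_single_measure_stops_immediately(self, rng):
        X, labels = clusters(rng, gap=30.0)
        perfect = build_space({"good": table(X)})
        noise = build_space({"bad": table(rng.random((12, 3)))})
        res = sequential_forward_select({"good": perfect, "bad": noise}, labels)
        assert res.selected_measures == ["good"]
        assert res.percent_correct == 100.0

    def test_noise_measure_never_selected(self, rng):
        X, labels = clusters(rng, gap=30.0)
        for trial in range(10):
            spaces = {
                "signal": build_space({"signal": table(X)}),
                "noise": build_space({"noise": table(rng.random((12, 3)))}),
            }
            res = sequential_forward_select(spaces, labels)
            assert "noise" not in res.selected_measures

    def test_deterministic_for_fixed_inputs(self, rng):
        X, labels = clusters(rng, gap=2.0, spread=2.0)
        spaces = {
            "a": build_space({"a": table(X)}),
            "b": build_space({"b": table(X[:, ::-1])}),
        }
        r1 = sequential_forward_select(spaces, labels)
        r2 = sequential_forward_select(spaces, labels)
        assert r1.selected_measures == r2.selected_measures
        np.testing.assert_array_equal(r1.posteriors, r2.posteriors)

    def test_combined_accuracy_at_least_best_single(self, rng):
        X, labels = clusters(rng, gap=1.5, spread=2.0)
        spaces = {
            "a": build_space({"a": table(X + rng.standard_normal(X.shape))}),
            "b": build_space({"b": table(X + rng.standard_normal(X.shape))}),
        }
        singles = [lda_loocv(s, labels).percent_correct for s in spaces.values()]
        res = sequential_forward_select(spaces, labels)
        assert res.percent_correct >= max(singles)
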