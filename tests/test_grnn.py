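"""GRNN kernel regression, staged optimisation and sensitivity ratios."""

import warnings

import numpy as np
import pandas as pd
import pytest

from epiage.cohort import AgeTrendSpec, CohortSpec, generate_cohort
from epiage.grnn import (
    SplitSpec,
    fit_grnn,
    grnn_predict,
    input_subset_search,
    make_split,
    sensitivity_analysis,
    stage1_split_search,
    stage2_fixed_blind,
    stage3_replicates,
    tune_sigma,
)


def brute_force_prediction(model, query):
    """Independent direct-summation kernel average (the oracle)."""
    import math

    Xs = (model.exemplars - model.mean) / model.sd
    q = (np.asarray(query) - model.mean) / model.sd
    num = den = 0.0
    for xi, yi in zip(Xs, model.targets):
        w = math.exp(-float(np.sum((q - xi) ** 2)) / (2 * float(model.sigma) ** 2))
        num += yi * w
        den += w
    return num / den


class TestPredict:
    def test_single_exemplar_returns_its_age(self):
        model = fit_grnn(np.array([[0.3, 0.6]]), np.array([40.0]), sigma=0.5)
        assert grnn_predict(model, np.array([[0.9, 0.1]]))[0] == pytest.approx(40.0)

    def test_equidistant_queries_average_symmetrically(self):
        model = fit_grnn(np.array([[0.2], [0.8]]), np.array([20.0, 60.0]), sigma=0.7)
        assert grnn_predict(model, np.array([[0.5]]))[0] == pytest.approx(40.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(10)
        X = rng.uniform(0, 1, (10, 4))
        y = rng.uniform(2, 90, 10)
        model = fit_grnn(X, y, sigma=0.8)
        queries = rng.uniform(0, 1, (5, 4))
        fast = grnn_predict(model, queries)
        slow = [brute_force_prediction(model, q) for q in queries]
        assert np.allclose(fast, slow, atol=1e-10)

    def test_predictions_bounded_by_training_ages(self):
        rng = np.random.default_rng(11)
        X = rng.uniform(0, 1, (50, 3))
        y = rng.uniform(10, 70, 50)
        model = fit_grnn(X, y, sigma=0.3)
        pred = grnn_predict(model, rng.uniform(-1, 2, (200, 3)))
        assert pred.min() >= y.min() - 1e-9 and pred.max() <= y.max() + 1e-9

    def test_sigma_limits(self):
        rng = np.random.default_rng(12)
        X = rng.uniform(0, 1, (30, 2))
        y = rng.uniform(5, 85, 30)
        wide = fit_grnn(X, y, sigma=1e6)
        assert np.allclose(grnn_predict(wide, X * 0.5 + 0.1), y.mean(), atol=1e-6)
        narrow = fit_grnn(X, y, sigma=1e-4)
        queries = X + rng.normal(0, 0.01, X.shape)
        Xs = (X - narrow.mean) / narrow.sd
        Qs = (queries - narrow.mean) / narrow.sd
        nearest = y[np.argmin(
            ((Qs[:, None, :] - Xs[None, :, :]) ** 2).sum(axis=2), axis=1)]
        assert np.allclose(grnn_predict(narrow, queries), nearest)

    def test_dimension_mismatch_and_missing_values_rejected(self):
        model = fit_grnn(np.array([[0.1, 0.2]]), np.array([30.0]), sigma=1.0)
        with pytest.raises(ValueError, match="inputs"):
            grnn_predict(model, np.array([[0.1]]))
        with pytest.raises(ValueError, match="missing"):
            grnn_predict(model, np.array([[0.1, np.nan]]))

    def test_dataframe_queries_align_by_cpg_name(self):
        frame = pd.DataFrame({"cg_b": [0.5, 0.7], "cg_a": [0.2, 0.3]})
        model = fit_grnn(frame[["cg_a", "cg_b"]], [20.0, 60.0], sigma=1.0,
                         cpgs=("cg_a", "cg_b"))
        shuffled = frame[["cg_b", "cg_a"]]
        assert np.allclose(grnn_predict(model, shuffled),
                           grnn_predict(model, frame[["cg_a", "cg_b"]].to_numpy()))

    def test_json_round_trip(self, tmp_path):
        model = fit_grnn(np.array([[0.1, 0.9], [0.4, 0.3]]),
                         np.array([25.0, 61.0]), sigma=0.5, cpgs=("a", "b"))
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = type(model).from_json(path)
        q = np.array([[0.2, 0.5]])
        assert grnn_predict(loaded, q)[0] == pytest.approx(grnn_predict(model, q)[0])


class TestSplit:
    def test_published_rounding_convention(self):
        assert SplitSpec(0.6, 0.2, 0.2).sizes(1156) == (694, 231, 231)

    def test_partition_is_disjoint_and_complete(self):
        spec = SplitSpec(0.6, 0.2, 0.2, seed=4)
        ids = [f"S{i}" for i in range(100)]
        tr, ve, bl = make_split(ids, spec)
        assert len(set(tr) | set(ve) | set(bl)) == 100
        assert not (set(tr) & set(ve)) and not (set(tr) & set(bl))

    def test_train_proportion_outside_half_to_seventy_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(0.8, 0.1, 0.1)
        with pytest.raises(ValueError):
            SplitSpec(0.4, 0.3, 0.3)

    def test_fixed_blind_ids_respected(self):
        spec = SplitSpec(0.6, 0.2, 0.2, seed=5)
        ids = np.array([f"S{i}" for i in range(50)])
        _, _, bl = make_split(ids, spec)
        fixed = SplitSpec(0.6, 0.2, 0.2, seed=99, fixed_blind_ids=tuple(bl))
        tr2, ve2, bl2 = make_split(ids, fixed)
        assert set(bl2) == set(bl)
        assert not (set(tr2) | set(ve2)) & set(bl)


def _dense_linear_matrix(n=240, seed=0, noise=0.0):
    trend = AgeTrendSpec("cg_lin", "linear", (0.1, 0.008), noise,
                         "increasing" if True else "none")
    spec = CohortSpec(n_samples=n, trend_specs=(trend,), seed=seed)
    matrix, _ = generate_cohort(spec)
    return matrix


class TestTuneSigma:
    def test_noiseless_dense_linear_data_low_verify_mae(self):
        matrix = _dense_linear_matrix()
        tr, ve, _ = make_split(matrix.index, SplitSpec(0.6, 0.2, 0.2, seed=1))
        model, mae = tune_sigma(
            matrix.loc[list(tr)][["cg_lin"]], matrix.loc[list(tr)]["age"],
            matrix.loc[list(ve)][["cg_lin"]], matrix.loc[list(ve)]["age"],
            cpgs=("cg_lin",),
        )
        assert mae < 0.5

    def test_degenerate_identical_exemplars_warn_constant(self):
        X = np.full((10, 2), 0.5)
        y = np.linspace(20, 60, 10)
        with pytest.warns(UserWarning, match="identical"):
            model, _ = tune_sigma(X, y, X, y)
        assert np.allclose(grnn_predict(model, np.array([[0.1, 0.9]])), y.mean())

    def test_boundary_sigma_warns(self):
        # monotone score in sigma drives the optimum to a bracket edge
        rng = np.random.default_rng(14)
        X = rng.uniform(0, 1, (40, 1))
        y = 80 * X[:, 0] + 5
        with pytest.warns(UserWarning, match="boundary"):
            tune_sigma(X, y, X, y, bracket=(0.5, 0.6))


@pytest.fixture(scope="module")
def stage_matrix():
    return _dense_linear_matrix(n=200, seed=3, noise=0.02)


class TestStages:
    @pytest.fixture()
    def matrix(self, stage_matrix):
        return stage_matrix

    def test_stage1_repeatable_and_valid(self, matrix):
        a = stage1_split_search(matrix, cpgs=("cg_lin",),
                                proportions=(0.5, 0.6), repeats=2, seed=7)
        b = stage1_split_search(matrix, cpgs=("cg_lin",),
                                proportions=(0.5, 0.6), repeats=2, seed=7)
        assert a.spec == b.spec
        assert a.blind_mae == pytest.approx(b.blind_mae)
        assert 0.5 <= a.spec.p_train <= 0.7

    def test_stage2_keeps_blind_fixed(self, matrix):
        stage1 = stage1_split_search(matrix, cpgs=("cg_lin",),
                                     proportions=(0.6,), repeats=1, seed=8)
        stage2 = stage2_fixed_blind(matrix, stage1.spec, cpgs=("cg_lin",),
                                    resamples=3, seed=9)
        assert stage2.spec.fixed_blind_ids is not None
        _, _, bl = make_split(matrix.index, stage1.spec)
        assert set(stage2.spec.fixed_blind_ids) == set(bl)

    def test_stage3_replicate_summary_shape(self, matrix):
        spec = SplitSpec(0.6, 0.2, 0.2, seed=10)
        replicates, summary, detail = stage3_replicates(
            matrix, spec, cpgs=("cg_lin",), k=3, seed=11
        )
        assert len(replicates) == 3
        assert list(summary.index) == ["train", "verify", "blind"]
        assert (summary["mean_mae"] > 0).all()

    def test_stage3_single_replicate_warns_zero_sd(self, matrix):
        spec = SplitSpec(0.6, 0.2, 0.2, seed=12)
        with pytest.warns(UserWarning, match="k=1"):
            _, summary, _ = stage3_replicates(matrix, spec, cpgs=("cg_lin",),
                                              k=1, seed=13)
        assert (summary["sd_mae"] == 0).all()

    def test_replicate_blind_spread_grows_with_noise(self):
        spreads = []
        for noise in (0.01, 0.05, 0.1):
            trend = AgeTrendSpec("cg_lin", "linear", (0.1, 0.008), noise,
                                 "increasing")
            matrix, _ = generate_cohort(
                CohortSpec(n_samples=200, trend_specs=(trend,), seed=20)
            )
            _, summary, _ = stage3_replicates(
                matrix, SplitSpec(0.6, 0.2, 0.2, seed=21), cpgs=("cg_lin",),
                k=4, seed=22,
            )
            spreads.append(summary.loc["blind", "mean_mae"])
        assert spreads[0] < spreads[1] < spreads[2]


class TestSensitivity:
    def _model_with_noise_input(self, seed=0):
        trend = AgeTrendSpec("cg_inf", "linear", (0.1, 0.008), 0.02, "increasing")
        noise = AgeTrendSpec("cg_noise", "linear", (0.5,), 0.05, "none")
        matrix, _ = generate_cohort(
            CohortSpec(n_samples=300, trend_specs=(trend, noise), seed=seed)
        )
        spec = SplitSpec(0.6, 0.2, 0.2, seed=seed)
        replicates, _, _ = stage3_replicates(
            matrix, spec, cpgs=("cg_inf", "cg_noise"), k=3, seed=seed
        )
        blind_ids = replicates[0][1][2]  # blind set is fixed across replicates
        blind = matrix.loc[list(blind_ids)]
        return replicates, blind

    def test_informative_removal_dominates_noise_removal(self):
        replicates, blind = self._model_with_noise_input(seed=30)
        report = sensitivity_analysis(
            replicates, blind[["cg_inf", "cg_noise"]], blind["age"]
        )
        assert report.table.loc["cg_inf", "mean_ratio"] > 2.0
        assert report.table.loc["cg_inf", "rank"] == 1

    def test_unchanged_error_gives_ratio_one(self):
        # a constant input contributes nothing to standardized distances, so
        # its removal leaves every prediction (and the error) unchanged
        rng = np.random.default_rng(31)
        X = rng.uniform(0, 1, (80, 2))
        X[:, 1] = 0.5
        y = 80 * X[:, 0] + 5
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_grnn(X, y, sigma=0.5, cpgs=("a", "b"))
        blind = pd.DataFrame({"a": rng.uniform(0, 1, 40)})
        blind["b"] = 0.5
        report = sensitivity_analysis(model, blind, 80 * blind["a"] + 5)
        assert report.table.loc["b", "mean_ratio"] == pytest.approx(1.0, abs=1e-9)


class TestSubsetSearch:
    def test_budget_zero_returns_all_with_warning(self, small_cohort):
        matrix, _ = small_cohort
        with pytest.warns(UserWarning, match="budget"):
            selected, _ = input_subset_search(matrix, budget=0)
        assert len(selected) == 45

    def test_single_candidate_returned(self, small_cohort):
        matrix, _ = small_cohort
        selected, _ = input_subset_search(matrix, candidates=["cg22736354"],
                                          budget=100)
        assert selected == ("cg22736354",)

    def test_recovers_informative_inputs_rejects_noise(self):
        # the verification-MAE-optimal subset sits near 12 markers: extra
        # weakly-informative inputs dilute kernel distances, so the search
        # recovers most (not all) informative CpGs and almost no noise ones
        from epiage.cohort import default_cohort_spec

        for seed in range(2):
            matrix, truth = generate_cohort(
                default_cohort_spec(n_samples=1156, seed=40 + seed)
            )
            selected, _ = input_subset_search(matrix, budget=5000, seed=seed)
            informative = set(truth["informative"])
            assert len(set(selected) & informative) >= 10
            assert len(set(selected) - informative) <= 2
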