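"""Maximum-entropy core: features, fitting, outputs, contributions.

The worked numerical cases (two-cell moment matching, three-cell softmax,
log-likelihood arithmetic) were computed independently by closed form;
the optimizer is additionally checked against the brute-force
penalized-objective maximizer in ``helpers``.
"""

import math

import numpy as np
import pytest

from conftest import make_stack
from helpers import brute_force_fit, random_tiny_problem
from monarchniche.grids import LayerName, LayerStack
from monarchniche.maxent import (ConvergenceError, FeatureSpace, MaxentModel,
                                 build_features, fit_maxent, log_likelihood,
                                 logistic_output, percent_contribution,
                                 raw_output)


def feature_space_from_design(F, presence_rows):
    """Wrap a bare design matrix for direct optimizer testing."""
    from monarchniche.maxent import Feature
    F = np.asarray(F, dtype=float)
    feats = [Feature("linear", (f"f{j}",), 0.0, 1.0)
             for j in range(F.shape[1])]
    return FeatureSpace(F, feats, [f.parents[0] for f in feats],
                        np.arange(F.shape[0]),
                        np.asarray(presence_rows, dtype=int))


class TestBuildFeatures:
    def test_feature_counts_by_class(self):
        stack = make_stack(tmin_Jan=[[1.0, 2.0, 3.0]],
                           tmax_Jan=[[4.0, 6.0, 5.0]],
                           precipitation_Jan=[[7.0, 9.0, 8.0]])
        cells = [0]
        only_linear = build_features(stack, cells, classes={"linear"})
        assert only_linear.n_features == 3
        full = build_features(stack, cells,
                              classes={"linear", "quadratic", "product"})
        assert full.n_features == 3 + 3 + 3  # products: 3 choose 2

    def test_constant_layer_dropped(self):
        stack = make_stack(tmin_Jan=[[1.0, 2.0]], tmax_Jan=[[5.0, 5.0]])
        fs = build_features(stack, [0], classes={"linear"})
        assert fs.layer_names == ["tmin_Jan"]
        assert fs.n_features == 1

    def test_columns_scaled_to_unit_interval(self, small_benchmark,
                                             small_presences):
        fs = build_features(small_benchmark.current, small_presences)
        assert fs.design.min() == 0.0 and fs.design.max() == 1.0
        assert np.all(fs.design.min(axis=0) == 0.0)
        assert np.all(fs.design.max(axis=0) == 1.0)


class TestFitClosedForms:
    def test_two_cell_moment_matching(self):
        # one linear feature f=(0,1); presence mean 0.75; no penalty:
        # the optimum matches moments, q=(1/4, 3/4), lambda = ln 3
        fs = feature_space_from_design([[0.0], [1.0]], [0, 1, 1, 1])
        model = fit_maxent(fs, beta=0.0)
        assert model.lambdas[0] == pytest.approx(math.log(3), abs=1e-8)
        q = raw_output(model, fs)
        assert q == pytest.approx([0.25, 0.75], abs=1e-9)

    def test_huge_beta_fully_shrinks(self):
        fs = feature_space_from_design([[0.0], [0.3], [1.0]], [2, 2])
        model = fit_maxent(fs, beta=1e6)
        assert np.all(model.lambdas == 0.0)
        assert raw_output(model, fs) == pytest.approx([1 / 3] * 3)

    def test_soft_threshold_keeps_zero(self):
        # beta * s exceeds |fbar - E_uniform[f]| -> 0 is optimal, confirmed
        # by brute-force 1-D search
        F = np.array([[0.0], [0.5], [1.0], [0.25], [0.75]])
        rows = [1, 2, 3]
        fbar = F[rows].mean()
        s = max(F[rows].std() / math.sqrt(3), 1e-6)
        beta = 1.05 * abs(fbar - F.mean()) / s
        fs = feature_space_from_design(F, rows)
        model = fit_maxent(fs, beta=beta)
        assert model.lambdas[0] == 0.0
        lam_bf, _ = brute_force_fit(F, np.array(rows), beta)
        assert lam_bf[0] == pytest.approx(0.0, abs=1e-6)

    def test_beta_zero_with_separation_raises(self):
        fs = feature_space_from_design([[0.0], [1.0]], [1, 1])
        with pytest.raises(ConvergenceError):
            fit_maxent(fs, beta=0.0)


class TestOutputs:
    def softmax_case(self):
        fs = feature_space_from_design([[0.0], [0.5], [1.0]], [2])
        model = fit_maxent(fs, beta=1e6)  # lambdas all zero
        model.lambdas = np.array([1.0])
        return fs, model

    def test_raw_is_softmax_of_eta(self):
        fs, model = self.softmax_case()
        q = raw_output(model, fs)
        e = np.exp([0.0, 0.5, 1.0])
        assert q == pytest.approx(e / e.sum(), abs=1e-12)
        assert q == pytest.approx([0.1863, 0.3072, 0.5065], abs=5e-5)

    def test_logistic_from_hand_entropy(self):
        fs, model = self.softmax_case()
        q = raw_output(model, fs)
        model.entropy = float(-(q * np.log(q)).sum())
        p = logistic_output(model, fs)
        expected = math.e**model.entropy * q / (1 + math.e**model.entropy * q)
        assert p == pytest.approx(expected, abs=1e-12)
        assert np.all(np.diff(p[np.argsort(q)]) > 0)  # monotone in q

    def test_uniform_model_logistic_is_half(self):
        fs = feature_space_from_design([[0.0], [0.4], [1.0]], [1])
        model = fit_maxent(fs, beta=1e6)
        assert logistic_output(model, fs) == pytest.approx([0.5] * 3, abs=1e-12)

    def test_uniform_log_likelihood(self):
        fs = feature_space_from_design([[0.0], [0.4], [1.0]], [1, 2, 0, 1])
        model = fit_maxent(fs, beta=1e6)
        assert log_likelihood(model, fs) == pytest.approx(-4 * math.log(3))

    def test_two_cell_log_likelihood_arithmetic(self):
        fs = feature_space_from_design([[0.0], [1.0]], [0, 1, 1, 1])
        model = fit_maxent(fs, beta=0.0)
        lnl = log_likelihood(model, fs, presence_rows=[1, 1, 0])
        assert lnl == pytest.approx(2 * math.log(0.75) + math.log(0.25),
                                    abs=1e-8)
        assert lnl == pytest.approx(-1.9617, abs=1e-4)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(1000 + seed)
        F, rows = random_tiny_problem(rng)
        beta = float(rng.choice([0.1, 0.5, 1.0, 2.0]))
        fs = feature_space_from_design(F, rows)
        model = fit_maxent(fs, beta=beta)
        _, q_bf = brute_force_fit(F, rows, beta)
        q = raw_output(model, fs)
        assert np.max(np.abs(q - q_bf)) < 1e-4

    def test_kkt_soft_moment_bound(self):
        # |E_q[f_j] - fbar_j| <= beta * s_j at the optimum, every feature
        for seed in range(10):
            rng = np.random.default_rng(2000 + seed)
            F, rows = random_tiny_problem(rng)
            fs = feature_space_from_design(F, rows)
            model = fit_maxent(fs, beta=0.5)
            q = raw_output(model, fs)
            gap = np.abs(q @ F - F[rows].mean(axis=0))
            assert np.all(gap <= 0.5 * model.penalty_scales + 1e-6)


class TestProperties:
    def test_sparsity_monotone_in_beta(self, small_benchmark, small_presences):
        fs = build_features(small_benchmark.current, small_presences)
        ks = [np.sum(fit_maxent(fs, beta=b).lambdas != 0)
              for b in (0.1, 0.5, 1.0, 2.0, 5.0)]
        assert all(a >= b for a, b in zip(ks, ks[1:]))

    def test_deterministic_fit(self, small_benchmark, small_presences):
        fs = build_features(small_benchmark.current, small_presences)
        a = fit_maxent(fs, beta=0.5)
        b = fit_maxent(fs, beta=0.5)
        assert np.array_equal(a.lambdas, b.lambdas)

    def test_raw_sums_to_one_and_positive(self, small_benchmark,
                                          small_presences):
        fs = build_features(small_benchmark.current, small_presences)
        model = fit_maxent(fs, beta=1.0)
        q = raw_output(model, fs)
        assert q.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(q > 0)


class TestContribution:
    def test_single_layer_gets_everything(self):
        stack = make_stack(tmin_Jan=[[1.0, 2.0, 3.0, 4.0]])
        fs = build_features(stack, [3], classes={"linear"})
        model = fit_maxent(fs, beta=0.5)
        table = percent_contribution(model)
        assert table.defined
        assert table.percent["tmin_Jan"] == pytest.approx(100.0)

    def test_sums_to_hundred(self, small_benchmark, small_presences):
        fs = build_features(small_benchmark.current, small_presences)
        model = fit_maxent(fs, beta=1.0)
        table = percent_contribution(model)
        assert sum(table.percent.values()) == pytest.approx(100.0, abs=1e-6)

    def test_fully_shrunk_model_flagged_undefined(self):
        fs = feature_space_from_design([[0.0], [1.0]], [0, 1])
        model = fit_maxent(fs, beta=1e6)
        assert not percent_contribution(model).defined


def test_model_json_round_trip(tmp_path, small_benchmark, small_presences):
    fs = build_features(small_benchmark.current, small_presences)
    model = fit_maxent(fs, beta=1.0)
    path = tmp_path / "model.json"
    model.to_json(path)
    back = MaxentModel.from_json(path)
    assert np.array_equal(back.lambdas, model.lambdas)
    assert back.entropy == model.entropy
    assert back.features == model.features
    assert np.array_equal(raw_output(back, fs), raw_output(model, fs))
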