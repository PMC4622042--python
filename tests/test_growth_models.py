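import math
import warnings

import numpy as np
import pytest

from gcgwas.datatypes import WeightSeries
from gcgwas.growth_models import (
    MODELS,
    GrowthFit,
    PopulationFitSummary,
    fit_animal,
    fit_population,
    gof_summary,
    initial_estimates,
    preadjust_fixed_effects,
    predict_weight,
    select_model,
)

AGES = np.array([0.0, 6.0, 12.0, 15.0, 18.0, 24.0])


def _draw_params(model, rng):
    A = rng.uniform(300, 600)
    K = rng.uniform(0.04, 0.25)
    if model in ("brody", "bertalanffy", "richards"):
        b = rng.uniform(0.5, 0.95)
    elif model == "logistic":
        b = rng.uniform(2, 10)
    else:
        b = rng.uniform(1, 3)
    p = [A, b, K]
    if model == "richards":
        p.append(rng.uniform(0.8, 2.5))
    return np.array(p)


class TestPredict:
    def test_brody_hand_value_at_birth(self):
        # A(1 - b) with the population-mean parameters
        assert predict_weight("brody", [520.32, 0.92, 0.06], 0.0) == pytest.approx(41.6256)

    def test_logistic_hand_value_at_birth(self):
        assert predict_weight("logistic", [400, 4.85, 0.2], 0.0) == pytest.approx(400 / 5.85)

    @pytest.mark.parametrize("model,expected", [
        ("brody", lambda A, b: A * (1 - b)),
        ("bertalanffy", lambda A, b: A * (1 - b) ** 3),
        ("logistic", lambda A, b: A / (1 + b)),
        ("gompertz", lambda A, b: A * math.exp(-b)),
    ])
    def test_closed_form_at_t0(self, model, expected):
        A, b, K = 450.0, 0.8, 0.1
        assert predict_weight(model, [A, b, K], 0.0) == pytest.approx(expected(A, b))

    def test_brody_asymptote(self):
        # Kt >= 50 puts the curve within 1e-9 of A
        assert predict_weight("brody", [500, 0.9, 0.06], 1000.0) == pytest.approx(500, abs=1e-9)

    def test_richards_complex_base_raises(self):
        with pytest.raises(ValueError, match="complex"):
            predict_weight("richards", [500, 2.0, 0.05, 1.5], 0.0)


class TestInitialEstimates:
    def test_a0_at_least_max_weight(self, brody_series):
        s, _ = brody_series
        for model in MODELS:
            p0 = initial_estimates(s, model)
            assert p0[0] >= s.weights.max()

    def test_noiseless_brody_grid_k_near_truth(self, brody_series):
        # the grid argmin compensates for the deliberately inflated A0, so it
        # lands near (not exactly on) the true K; what matters is that the
        # full fit started there converges to the truth
        s, truth = brody_series
        p0 = initial_estimates(s, "brody")
        assert abs(p0[2] - truth[2]) <= 0.02
        fit = fit_animal(s, "brody")
        np.testing.assert_allclose(fit.params, truth, atol=1e-6)

    def test_constant_weights_take_fallback_with_warning(self, flat_series):
        with pytest.warns(UserWarning, match="fallback"):
            p0 = initial_estimates(flat_series, "brody")
        assert p0[0] == 250.0 and p0[2] == 0.005


class TestFitAnimal:
    @pytest.mark.parametrize("model", sorted(MODELS))
    def test_noiseless_recovery(self, model):
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = _draw_params(model, rng)
            w = predict_weight(model, p, AGES)
            fit = fit_animal(WeightSeries("x", AGES, w), model)
            assert fit.converged
            np.testing.assert_allclose(fit.params, p, atol=1e-6)
            assert fit.diagnostics.r2_adj == pytest.approx(1.0)
            assert fit.diagnostics.mse == pytest.approx(0.0, abs=1e-12)

    def test_noisy_fit_stays_near_truth(self):
        rng = np.random.default_rng(12)
        p = np.array([500.0, 0.9, 0.07])
        w = predict_weight("brody", p, AGES) + rng.normal(0, 5, size=6)
        fit = fit_animal(WeightSeries("x", AGES, w), "brody")
        assert fit.converged and fit.diagnostics.mse > 0
        # loose sanity band (joint CI of a 3-parameter NLS on 6 points is wide)
        assert abs(fit.params[0] - 500) < 150
        assert abs(fit.params[2] - 0.07) < 0.05

    @pytest.mark.parametrize("model", ["richards", "brody"])
    def test_flat_data_fails_convergence_quietly(self, model, flat_series):
        fit = fit_animal(flat_series, model)
        assert not fit.converged
        assert fit.diagnostics is None


class TestGof:
    def test_hand_arithmetic(self):
        # residuals (1,-1,1,-1,1,-1), n=6, p=3: SSE=6, mse=2, mad1=mad2=1,
        # aic = 6 ln(1) + 2*4 = 8
        w_true = predict_weight("brody", [500, 0.9, 0.07], AGES)
        resid = np.array([1.0, -1, 1, -1, 1, -1])
        s = WeightSeries("x", AGES, w_true + resid)
        fit = GrowthFit("x", "brody", np.array([500.0, 0.9, 0.07]), True)
        d = gof_summary(s, fit)
        assert d.mse == pytest.approx(2.0)
        assert d.mad1 == pytest.approx(1.0) and d.mad2 == pytest.approx(1.0)
        assert d.aic == pytest.approx(8.0)

    def test_perfect_fit_hits_aic_floor(self, brody_series):
        s, p = brody_series
        d = gof_summary(s, GrowthFit("x", "brody", p, True))
        assert d.mse == pytest.approx(0.0, abs=1e-15)
        assert d.r2_adj == pytest.approx(1.0)
        assert d.aic == pytest.approx(6 * math.log(1e-12 / 6) + 8)

    def test_too_few_points_raises(self):
        s = WeightSeries("x", [0.0, 6.0, 12.0], [35.0, 200.0, 250.0])
        with pytest.raises(ValueError, match="n > p"):
            gof_summary(s, GrowthFit("x", "brody", np.array([500.0, 0.9, 0.07]), True))

    def test_diagnostics_invariant_to_record_order(self, tmp_path):
        # same records fed in shuffled long-format order give identical GOF
        from gcgwas import io_formats

        rng = np.random.default_rng(13)
        w = predict_weight("brody", [500, 0.9, 0.07], AGES) + rng.normal(0, 3, 6)
        rows = list(zip(AGES, w))
        text1 = "animal_id,age,weight\n" + "".join(f"a,{a},{x}\n" for a, x in rows)
        rng.shuffle(rows)
        text2 = "animal_id,age,weight\n" + "".join(f"a,{a},{x}\n" for a, x in rows)
        d = {}
        for name, text in (("f1", text1), ("f2", text2)):
            p = tmp_path / f"{name}.csv"
            p.write_text(text)
            (s,) = io_formats.read_phenotypes(p, layout="long")
            d[name] = fit_animal(s, "brody").diagnostics
        for attr in ("mse", "mad1", "mad2"):
            assert getattr(d["f1"], attr) == pytest.approx(getattr(d["f2"], attr))


class TestPreadjust:
    def _series(self, weights, factors):
        return [WeightSeries(f"a{i}", AGES, w, f)
                for i, (w, f) in enumerate(zip(weights, factors))]

    def test_single_level_factor_is_identity(self):
        rng = np.random.default_rng(14)
        base = predict_weight("brody", [500, 0.9, 0.07], AGES)
        phenos = self._series(
            [base + rng.normal(0, 5, 6) for _ in range(6)],
            [{"farm": "F1"}] * 6,
        )
        adj = preadjust_fixed_effects(phenos, ["farm"])
        for a, b in zip(adj, phenos):
            np.testing.assert_allclose(a.weights, b.weights, atol=1e-9)

    def test_planted_group_offsets_removed(self):
        rng = np.random.default_rng(15)
        base = predict_weight("brody", [500, 0.9, 0.07], AGES)
        weights, factors = [], []
        for i in range(40):
            grp = "G1" if i % 2 == 0 else "G2"
            off = 10.0 if grp == "G1" else -10.0
            weights.append(base + off + rng.normal(0, 2, 6))
            factors.append({"grp": grp})
        adj = preadjust_fixed_effects(self._series(weights, factors), ["grp"])
        W = np.array([s.weights for s in adj])
        g1 = W[::2].mean(axis=0)
        g2 = W[1::2].mean(axis=0)
        np.testing.assert_allclose(g1, g2, atol=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(16)
        base = predict_weight("brody", [500, 0.9, 0.07], AGES)
        levels = ["L1", "L2", "L3"]
        weights, factors = [], []
        for i in range(30):
            lev = levels[rng.integers(3)]
            weights.append(base + rng.normal(0, 4, 6))
            factors.append({"f": lev})
        phenos = self._series(weights, factors)
        adj = preadjust_fixed_effects(phenos, ["f"])
        # oracle: explicit normal equations with drop-first dummies, per age
        for j in range(len(AGES)):
            y = np.array([w[j] for w in weights])
            X = np.column_stack(
                [np.ones(30)]
                + [[1.0 if f["f"] == lev else 0.0 for f in factors]
                   for lev in levels[1:]]
            )
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            expected = y.mean() + (y - X @ beta)
            got = np.array([s.weights[j] for s in adj])
            np.testing.assert_allclose(got, expected, atol=1e-9)

    def test_grand_mean_preserved(self):
        rng = np.random.default_rng(17)
        base = predict_weight("brody", [500, 0.9, 0.07], AGES)
        phenos = self._series(
            [base + rng.normal(0, 5, 6) for _ in range(20)],
            [{"f": f"L{rng.integers(4)}"} for _ in range(20)],
        )
        adj = preadjust_fixed_effects(phenos, ["f"])
        for j in range(len(AGES)):
            before = np.mean([s.weights[j] for s in phenos])
            after = np.mean([s.weights[j] for s in adj])
            assert after == pytest.approx(before, abs=1e-9)

    def test_confounded_factor_raises(self):
        base = predict_weight("brody", [500, 0.9, 0.07], AGES)
        phenos = self._series([base, base + 5], [{"id": "a"}, {"id": "b"}])
        with pytest.raises(ValueError, match="confounded"):
            preadjust_fixed_effects(phenos, ["id"])


class TestPopulationAndSelection:
    def test_zero_noise_population(self):
        rng = np.random.default_rng(18)
        phenos = []
        for i in range(50):
            p = [rng.uniform(400, 600), 0.9, 0.07]
            phenos.append(WeightSeries(f"a{i}", AGES,
                                       predict_weight("brody", p, AGES)))
        fits, summary = fit_population(phenos, "brody")
        assert summary.c_pct == 100.0
        assert summary.param_means["b"] == pytest.approx(0.9, abs=1e-6)

    def test_flat_mixture_halves_convergence(self):
        good = [WeightSeries(f"g{i}", AGES,
                             predict_weight("brody", [500, 0.9, 0.07], AGES))
                for i in range(10)]
        flat = [WeightSeries(f"f{i}", AGES, np.full(6, 250.0)) for i in range(10)]
        _, summary = fit_population(good + flat, "brody")
        assert summary.c_pct == pytest.approx(50.0)

    @staticmethod
    def _summary(model, c_pct, r2, mse, mad1, mad2, aic):
        n = 1000
        return PopulationFitSummary(
            model, n, int(round(n * c_pct / 100)), {}, {},
            {"r2_adj": r2, "mse": mse, "mad1": mad1, "mad2": mad2, "aic": aic},
            {},
        )

    def test_published_style_gof_ranks_brody_first(self):
        # the four 3-parameter models' printed goodness-of-fit profile:
        # brody wins all five criteria
        summaries = [
            self._summary("gompertz", 100.0, 0.96, 604.91, 27.53, 10.95, 42.90),
            self._summary("logistic", 99.44, 0.95, 821.16, 32.83, 10.51, 44.81),
            self._summary("brody", 99.92, 0.98, 382.79, 18.94, 10.28, 40.01),
            self._summary("bertalanffy", 99.52, 0.87, 2071.96, 46.61, 11.87, 50.42),
            self._summary("richards", 9.0, 0.99, 100.0, 5.0, 5.0, 30.0),
        ]
        ranked = select_model(summaries)
        assert ranked.iloc[0]["model"] == "brody"
        assert ranked.iloc[0]["criteria_won"] == 5
        assert "richards" not in set(ranked["model"])  # C% < 50 excluded

    def test_single_model(self):
        ranked = select_model([self._summary("brody", 100, 0.98, 1, 1, 1, 10)])
        assert list(ranked["model"]) == ["brody"] and ranked.iloc[0]["rank"] == 1

    def test_tie_broken_by_aic(self):
        a = self._summary("m_a", 100, 0.9, 5.0, 2.0, 2.0, 20.0)
        b = self._summary("m_b", 100, 0.9, 6.0, 2.5, 2.5, 18.0)
        ranked = select_model([a, b])
        # each wins some criteria; m_b's lower AIC decides deterministically
        assert list(ranked["model"]) == sorted(
            ["m_a", "m_b"],
            key=lambda m: (-ranked.set_index("model").loc[m, "criteria_won"],
                           ranked.set_index("model").loc[m, "aic"]),
        )

    def test_all_excluded_raises(self):
        with pytest.raises(ValueError, match="excluded"):
            select_model([self._summary("richards", 5, 0.99, 1, 1, 1, 1)])
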