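"""Psychometric fits, cross-validated performance, ceilings, NNLS, unique
variance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from facesim.evaluation import (
    CVSpec,
    bootstrap_ci,
    compare_linear_vs_sigmoid,
    cross_validated_performance,
    fit_sigmoid,
    linear_fit_r2,
    logistic4,
    nnls_combination,
    noise_ceiling,
    pairwise_model_tests,
    unique_variance,
)
from facesim.synthetic_data import ObserverSpec, simulate_observer


TRUE = dict(lo=0.05, hi=0.9, x0=25.0, k=0.1)


class TestFitSigmoid:
    def test_exact_recovery_noiseless(self):
        x = np.linspace(0, 80, 100)
        y = logistic4(x, **TRUE)
        params, r2 = fit_sigmoid(x, y)
        np.testing.assert_allclose(
            params.as_array(), [TRUE["lo"], TRUE["hi"], TRUE["x0"], TRUE["k"]], atol=1e-4
        )
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_near_linear_data_fit_close_to_linear(self):
        x = np.linspace(0, 80, 60)
        y = x / 80.0
        _, r2_sig = fit_sigmoid(x, y)
        r2_lin = linear_fit_r2(x, y)
        # the bounded logistic only approximately nests a line
        assert r2_sig >= r2_lin - 0.02

    def test_beats_grid_search_oracle(self, rng):
        for _ in range(20):
            x = np.sort(rng.uniform(0, 80, 60))
            lo, hi = 0.05, 0.9
            x0 = rng.uniform(15, 50)
            k = rng.uniform(0.05, 0.3)
            y = np.clip(logistic4(x, lo, hi, x0, k) + rng.normal(0, 0.05, x.size), 0, 1)
            params, _ = fit_sigmoid(x, y)
            loss_fit = np.sum((params(x) - y) ** 2)
            # brute-force grid over (x0, k) at the true asymptotes
            best = np.inf
            for gx0 in np.linspace(0, 80, 81):
                for gk in np.geomspace(0.01, 1.0, 41):
                    loss = np.sum((logistic4(x, lo, hi, gx0, gk) - y) ** 2)
                    best = min(best, loss)
            assert loss_fit <= best * 1.01

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_sigmoid(np.ones(20), np.linspace(0, 1, 20))
        with pytest.raises(ValueError):
            fit_sigmoid(np.linspace(0, 1, 20), np.full(20, 0.3))
        with pytest.raises(ValueError):
            fit_sigmoid([0, 1, 2], [0, 0.5, 1])  # too few points


class TestCompareLinearVsSigmoid:
    def test_sigmoid_generated_data_prefers_sigmoid(self, distances232, trials232):
        hits = 0
        n_sims = 100
        rng = np.random.default_rng(5)
        for _ in range(n_sims):
            spec = ObserverSpec(noise_sd=0.05, participant_sd=0.0, n_participants=10,
                                n_sessions=1)
            ds = simulate_observer(spec, distances232, trials232, rng=rng)
            _, p = compare_linear_vs_sigmoid(ds, distances232)
            hits += p < 0.05
        assert hits >= 0.95 * n_sims

    def _linear_dataset(self, distances232, trials232):
        ds = simulate_observer(
            ObserverSpec(noise_sd=0.0, participant_sd=0.0, n_participants=6,
                         n_sessions=1, seed=0),
            distances232, trials232,
        )
        # overwrite judgments with an exactly linear response
        lin = distances232 / distances232.max()
        ds.frame["dissimilarity"] = lin.reindex(ds.frame.pair_id).to_numpy()
        ds.frame["same_identity"] = (
            ds.frame.dissimilarity < ds.frame.identity_line
        ).astype(int)
        return ds

    def test_linear_noiseless_data_gives_tiny_difference(self, distances232, trials232):
        ds = self._linear_dataset(distances232, trials232)
        table, _ = compare_linear_vs_sigmoid(ds, distances232)
        # the bounded logistic approximates a line to ~0.013 in R^2
        assert (table.sigmoid_r2 - table.linear_r2).abs().max() < 0.02

    def test_no_evidence_for_sigmoid_gives_p_one(self, distances232, trials232):
        # linear truth: every participant's sigmoid R^2 <= linear R^2, so
        # the one-sided test (zero differences dropped) returns p = 1
        ds = self._linear_dataset(distances232, trials232)
        _, p = compare_linear_vs_sigmoid(ds, distances232)
        assert p == 1.0

    def test_too_few_participants_rejected(self, distances232, trials232):
        spec = ObserverSpec(n_participants=3, n_sessions=1, seed=0)
        ds = simulate_observer(spec, distances232, trials232)
        with pytest.raises(ValueError):
            compare_linear_vs_sigmoid(ds, distances232)


class TestCrossValidatedPerformance:
    def test_generating_model_noiseless_reaches_r_one(self, distances232, trials232):
        spec = ObserverSpec(noise_sd=0.0, participant_sd=0.0, n_participants=8,
                            n_sessions=1, seed=3)
        ds = simulate_observer(spec, distances232, trials232)
        est = cross_validated_performance(
            distances232, ds, transform="sigmoid", cv=CVSpec(n_repeats=3), seed=0
        )
        assert est.mean_r == pytest.approx(1.0, abs=1e-6)

    def test_pure_noise_model_scores_near_zero(self, dataset232, distances232, rng):
        # a single random model carries chance correlation of SD ~1/sqrt(n)
        # with any fixed signal, so average the estimate over several draws
        rs = []
        for _ in range(10):
            noise_model = pd.Series(rng.uniform(0, 80, distances232.size),
                                    index=distances232.index)
            est = cross_validated_performance(
                noise_model, dataset232, transform="raw", cv=CVSpec(n_repeats=4), seed=1
            )
            rs.append(est.mean_r)
        assert abs(np.mean(rs)) < 0.05

    def test_monotone_transform_absorbed_by_sigmoid_fit(self, dataset232, distances232):
        warped = pd.Series(distances232**3, index=distances232.index)
        a = cross_validated_performance(
            distances232, dataset232, transform="sigmoid", cv=CVSpec(n_repeats=5), seed=2
        )
        b = cross_validated_performance(
            warped, dataset232, transform="sigmoid", cv=CVSpec(n_repeats=5), seed=2
        )
        assert a.mean_r == pytest.approx(b.mean_r, abs=0.02)

    def test_sigmoid_transform_does_not_hurt(self, dataset232, distances232):
        raw = cross_validated_performance(
            distances232, dataset232, transform="raw", cv=CVSpec(n_repeats=5), seed=4
        )
        sig = cross_validated_performance(
            distances232, dataset232, transform="sigmoid", cv=CVSpec(n_repeats=5), seed=4
        )
        assert sig.mean_r >= raw.mean_r - 0.02

    def test_small_test_split_rejected(self, dataset232, distances232):
        with pytest.raises(ValueError):
            cross_validated_performance(
                distances232, dataset232, cv=CVSpec(stimulus_train_frac=0.99), seed=0
            )


class TestNoiseCeiling:
    def test_identical_participants_reach_one(self, distances232, trials232):
        spec = ObserverSpec(noise_sd=0.0, participant_sd=0.0, n_participants=5,
                            n_sessions=1, seed=0)
        ds = simulate_observer(spec, distances232, trials232)
        nc = noise_ceiling(ds)
        assert nc.lower == pytest.approx(1.0, abs=1e-9)
        assert nc.upper == pytest.approx(1.0, abs=1e-9)

    def test_matches_analytic_attenuation(self, distances232, trials232):
        spec = ObserverSpec(noise_sd=0.1, participant_sd=0.0, n_participants=200,
                            n_sessions=1, seed=8, lo=0.1, hi=0.85)
        ds = simulate_observer(spec, distances232, trials232)
        true = spec.true_dissimilarity(distances232.to_numpy())
        s2, n2 = np.var(true), spec.noise_sd**2
        m = spec.n_participants
        expect_upper = np.sqrt((s2 + n2 / m) / (s2 + n2))
        expect_lower = s2 / np.sqrt((s2 + n2) * (s2 + n2 / (m - 1)))
        nc = noise_ceiling(ds)
        assert nc.upper == pytest.approx(expect_upper, abs=0.02)
        assert nc.lower == pytest.approx(expect_lower, abs=0.02)
        assert nc.lower <= nc.upper

    def test_too_few_participants_rejected(self, distances232, trials232):
        spec = ObserverSpec(n_participants=2, n_sessions=1, seed=0)
        ds = simulate_observer(spec, distances232, trials232)
        with pytest.raises(ValueError):
            noise_ceiling(ds)


class TestBootstrapCI:
    def test_constant_statistic_zero_width(self, rng):
        lo, hi = bootstrap_ci(np.ones(50), lambda d: 1.0, n_boot=200, seed=0)
        assert lo == hi == 1.0

    def test_width_matches_analytic_mean_ci(self, rng):
        x = rng.standard_normal(232)
        lo, hi = bootstrap_ci(x, np.mean, n_boot=2000, seed=1)
        expect = 2 * 1.96 / np.sqrt(232)
        assert (hi - lo) == pytest.approx(expect, rel=0.15)

    def test_nominal_coverage(self):
        rng = np.random.default_rng(7)
        hits = 0
        n_sims = 500
        for _ in range(n_sims):
            x = rng.standard_normal(100)
            idx = rng.integers(0, 100, (2000, 100))
            boots = x[idx].mean(axis=1)
            lo, hi = np.percentile(boots, [2.5, 97.5])
            hits += lo <= 0.0 <= hi
        assert 0.90 * n_sims <= hits <= 0.99 * n_sims

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.ones(1), np.mean)
        with pytest.raises(ValueError):
            bootstrap_ci(np.ones(10), np.mean, n_boot=10)


class TestPairwiseModelTests:
    def test_duplicated_model_gives_p_one(self, rng):
        r = rng.uniform(0.3, 0.9, 10)
        table = pd.DataFrame({"a": r, "b": r, "c": r + rng.normal(0, 0.05, 10)})
        p = pairwise_model_tests(table)
        assert p.loc["a", "b"] == 1.0

    def test_bonferroni_never_below_raw(self, rng):
        table = pd.DataFrame(rng.uniform(0, 1, (12, 4)), columns=list("abcd"))
        p = pairwise_model_tests(table)
        for a in "abc":
            for b in "bcd":
                if a == b or np.isnan(p.loc[a, b]):
                    continue
                raw = stats.wilcoxon(table[a] - table[b]).pvalue
                assert p.loc[a, b] >= raw - 1e-12

    def test_power_at_gap(self):
        rng = np.random.default_rng(3)
        hits = 0
        n_sims = 100
        for _ in range(n_sims):
            base = rng.normal(0.6, 0.05, 26)
            table = pd.DataFrame({"good": base + 0.2, "bad": base + rng.normal(0, 0.05, 26)})
            hits += pairwise_model_tests(table).loc["good", "bad"] < 0.05
        assert hits >= 0.95 * n_sims

    def test_too_few_inputs_rejected(self, rng):
        with pytest.raises(ValueError):
            pairwise_model_tests(pd.DataFrame({"a": rng.uniform(0, 1, 10)}))
        with pytest.raises(ValueError):
            pairwise_model_tests(pd.DataFrame(rng.uniform(0, 1, (4, 3))))


class TestNnlsCombination:
    def test_combined_recovers_generating_model_noiseless(self, distances232, trials232, rng):
        spec = ObserverSpec(noise_sd=0.0, participant_sd=0.0, n_participants=8,
                            n_sessions=1, seed=0)
        ds = simulate_observer(spec, distances232, trials232)
        y_true = spec.true_dissimilarity(distances232.to_numpy())
        preds = pd.DataFrame(
            {
                "generator": y_true,  # already on the response scale
                "noise1": rng.uniform(0, 1, distances232.size),
                "noise2": rng.uniform(0, 1, distances232.size),
            },
            index=distances232.index,
        )
        est = nnls_combination(preds, ds, cv=CVSpec(n_repeats=4), seed=1)
        assert est.mean_r == pytest.approx(1.0, abs=1e-6)
        w = est.weights.drop("intercept")
        assert w["generator"] > 0.9 * w.sum()
        assert (est.weights >= 0).all()

    def test_combination_beats_two_partial_models(self, rng):
        # two orthogonal half-informative predictors; their weighted sum
        # should outperform each alone on held-out data
        n = 232
        idx = pd.Index(np.arange(n), name="pair_id")
        wins = 0
        n_sims = 20
        for sim in range(n_sims):
            a = rng.normal(0, 1, n)
            b = rng.normal(0, 1, n)
            signal = 0.5 * a + 0.5 * b
            y01 = (signal - signal.min()) / np.ptp(signal)
            rows = []
            for p in range(8):
                noisy = np.clip(y01 + rng.normal(0, 0.1, n), 0, 1)
                rows.append(
                    pd.DataFrame(
                        {
                            "participant_id": f"p{p}",
                            "session": 1,
                            "set_label": "A",
                            "trial": np.arange(n) // 8,
                            "pair_id": idx,
                            "dissimilarity": noisy,
                            "same_identity": (noisy < 0.5).astype(int),
                            "identity_line": 0.5,
                        }
                    )
                )
            from facesim.synthetic_data import JudgmentDataset

            ds = JudgmentDataset(pd.concat(rows, ignore_index=True))
            shift = lambda v: v - v.min() + 0.01
            preds = pd.DataFrame({"a": shift(a), "b": shift(b)}, index=idx)
            combo = nnls_combination(preds, ds, cv=CVSpec(n_repeats=4), seed=sim)
            singles = [
                cross_validated_performance(
                    preds[m], ds, transform="raw", cv=CVSpec(n_repeats=4), seed=sim
                ).mean_r
                for m in preds.columns
            ]
            wins += combo.mean_r > max(singles)
        assert wins >= 0.9 * n_sims

    def test_constant_predictor_rejected(self, dataset232, distances232):
        preds = pd.DataFrame(
            {"a": distances232, "flat": np.ones(distances232.size)},
            index=distances232.index,
        )
        with pytest.raises(ValueError):
            nnls_combination(preds, dataset232, seed=0)


class TestUniqueVariance:
    def _noiseless_dataset(self, distances232, trials232):
        spec = ObserverSpec(noise_sd=0.0, participant_sd=0.0, n_participants=6,
                            n_sessions=1, seed=0)
        return simulate_observer(spec, distances232, trials232)

    def test_duplicated_model_has_no_unique_variance(self, distances232, trials232):
        ds = self._noiseless_dataset(distances232, trials232)
        preds = pd.DataFrame(
            {"m1": distances232, "m2": distances232}, index=distances232.index
        )
        res = unique_variance(preds, ds)
        assert (res.per_participant.abs() < 1e-6).all().all()

    def test_single_model_unique_variance_equals_full_r2(self, distances232, trials232):
        ds = self._noiseless_dataset(distances232, trials232)
        preds = pd.DataFrame({"m1": distances232}, index=distances232.index)
        res = unique_variance(preds, ds)
        from facesim.evaluation import _nnls_r2

        y = ds.pair_by_participant().iloc[:, 0].to_numpy()
        _, r2 = _nnls_r2(distances232.to_numpy()[:, None], y)
        assert res.per_participant.iloc[0, 0] == pytest.approx(r2, abs=1e-9)

    def test_orthogonal_predictors_partition_variance(self, rng):
        n = 400
        idx = pd.Index(np.arange(n), name="pair_id")
        a = np.concatenate([np.ones(n // 2), -np.ones(n // 2)])
        b = np.tile([1.0, -1.0], n // 2)
        y = np.sqrt(0.30) * a / a.std() + np.sqrt(0.20) * b / b.std()
        y += rng.normal(0, np.sqrt(0.50), n) * 0  # noiseless construction
        y01 = (y - y.min()) / np.ptp(y) * 0.9
        frame = pd.DataFrame(
            {
                "participant_id": "p0",
                "session": 1,
                "set_label": "A",
                "trial": np.arange(n) // 8,
                "pair_id": idx,
                "dissimilarity": y01,
                "same_identity": (y01 < 0.5).astype(int),
                "identity_line": 0.5,
            }
        )
        from facesim.synthetic_data import JudgmentDataset

        ds = JudgmentDataset(frame)
        preds = pd.DataFrame({"a": a - a.min(), "b": b - b.min()}, index=idx)
        res = unique_variance(preds, ds)
        total = 0.30 + 0.20
        assert res.per_participant.loc["p0", "a"] == pytest.approx(0.30 / total, abs=0.02)
        assert res.per_participant.loc["p0", "b"] == pytest.approx(0.20 / total, abs=0.02)

    def test_more_models_than_stimuli_rejected(self, rng):
        n = 5
        idx = pd.Index(np.arange(n), name="pair_id")
        frame = pd.DataFrame(
            {
                "participant_id": "p0",
                "session": 1,
                "set_label": "A",
                "trial": 0,
                "pair_id": idx,
                "dissimilarity": np.linspace(0.1, 0.9, n),
                "same_identity": 0,
                "identity_line": 0.05,
            }
        )
        from facesim.synthetic_data import JudgmentDataset

        ds = JudgmentDataset(frame)
        preds = pd.DataFrame(rng.uniform(0, 1, (n, 6)), index=idx,
                             columns=[f"m{i}" for i in range(6)])
        with pytest.raises(ValueError):
            unique_variance(preds, ds)
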