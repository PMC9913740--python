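import numpy as np
import pandas as pd
import pytest

from tspsig import (
    build_nomogram,
    calibration_curve,
    cox_table,
    fit_hazard_model,
    km_estimate,
    logrank_test,
    optimal_cutpoint,
    risk_stratify,
    signature_score,
    simulate_bulk_cohort,
    simulate_survival,
    time_dependent_auc,
)


def _sig(genes_up, genes_down=()):
    rows = [{"gene_id": g, "direction": "up", "cm1": 1.0} for g in genes_up]
    rows += [{"gene_id": g, "direction": "down", "cm1": -1.0} for g in genes_down]
    return pd.DataFrame(rows)


class TestSignatureScore:
    def test_single_up_gene_is_its_zscore(self, rng):
        expr = pd.DataFrame({"g1": rng.normal(3, 2, 30)})
        score = signature_score(expr, _sig(["g1"]))
        z = (expr["g1"] - expr["g1"].mean()) / expr["g1"].std(ddof=0)
        assert np.allclose(score, z)

    def test_constant_genes_score_zero(self):
        expr = pd.DataFrame({"g1": np.full(10, 2.0), "g2": np.full(10, 7.0)})
        assert (signature_score(expr, _sig(["g1"], ["g2"])) == 0).all()

    def test_signed_mean_matches_loop_oracle(self, rng):
        expr = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        score = signature_score(expr, _sig(["a", "c"], ["b", "d"]))
        for i in (0, 17, 39):
            acc = 0.0
            for g, s in [("a", 1), ("c", 1), ("b", -1), ("d", -1)]:
                v = expr[g]
                acc += s * (v.iloc[i] - v.mean()) / v.std(ddof=0)
            assert score.iloc[i] == pytest.approx(acc / 4)

    def test_missing_genes_warned_absent_all_errors(self, rng):
        expr = pd.DataFrame({"a": rng.normal(size=10)})
        with pytest.warns(RuntimeWarning, match="missing"):
            signature_score(expr, _sig(["a", "zzz"]))
        with pytest.raises(ValueError):
            signature_score(expr, _sig(["zzz"]))

    def test_pc1_correlates_with_signed_mean(self, rng):
        z = rng.normal(size=60)
        expr = pd.DataFrame({f"g{j}": z + rng.normal(0, 0.3, 60) for j in range(5)})
        sig = _sig([f"g{j}" for j in range(5)])
        pc1 = signature_score(expr, sig, mode="pc1")
        sm = signature_score(expr, sig, mode="signed_mean")
        assert np.corrcoef(pc1, sm)[0, 1] > 0.9


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        km = km_estimate([1, 2, 3], [0, 0, 0])[0.0]
        assert (km == 1.0).all()

    def test_four_subjects_one_event(self):
        km = km_estimate([2, 3, 4, 5], [1, 0, 0, 0])[0.0]
        assert km.loc[2.0] == pytest.approx(0.75)

    def test_matches_hand_product_limit_with_censoring(self):
        time = [1, 2, 2, 3, 4, 4, 5, 6, 7, 8]
        event = [1, 1, 0, 1, 0, 1, 0, 1, 0, 1]
        km = km_estimate(time, event)[0.0]
        # hand computation of the product-limit formula
        s, at_risk = 1.0, 10
        expected = {}
        for t in [1, 2, 3, 4, 5, 6, 7, 8]:
            d = sum(1 for ti, ei in zip(time, event) if ti == t and ei == 1)
            n = sum(1 for ti in time if ti >= t)
            if d:
                s *= 1 - d / n
            expected[t] = s
        for t, e in expected.items():
            assert km.loc[float(t)] == pytest.approx(e, abs=1e-12)

    def test_no_censoring_equals_empirical_survivor(self, rng):
        t = rng.exponential(5, 60)
        km = km_estimate(t, np.ones(60))[0.0]
        for q in (np.median(t), np.percentile(t, 80)):
            assert km[km.index <= q].iloc[-1] == pytest.approx((t > q).mean(), abs=1e-10)


class TestLogrank:
    def test_identical_groups_p_one(self):
        t = [1, 2, 3, 4, 1, 2, 3, 4]
        d = [1, 1, 0, 1, 1, 1, 0, 1]
        g = [0, 0, 0, 0, 1, 1, 1, 1]
        stat, p = logrank_test(t, d, g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_small_example_matches_hand_oe(self):
        # 3 vs 3, events at t=1 (grp1), t=2 (grp1), t=3 (grp0)
        t = [3, 4, 5, 1, 2, 6]
        d = [1, 0, 0, 1, 1, 0]
        g = [0, 0, 0, 1, 1, 1]
        stat, p = logrank_test(t, d, g)
        # hand observed-minus-expected for group 1
        O = 2
        E = 3 / 6 + 2 / 5 + 1 / 4
        V = (3 / 6) * (1 - 3 / 6) + (2 / 5) * (1 - 2 / 5) + (1 / 4) * (1 - 1 / 4)
        assert stat == pytest.approx((O - E) ** 2 / V, abs=1e-12)

    def test_matches_lifelines_on_random_data(self, rng):
        from lifelines.statistics import logrank_test as ll
        for _ in range(5):
            t = rng.exponential(10, 70)
            d = rng.binomial(1, 0.6, 70)
            g = rng.binomial(1, 0.4, 70)
            if d.sum() == 0 or len(np.unique(g)) < 2:
                continue
            stat, p = logrank_test(t, d, g)
            ref = ll(t[g == 0], t[g == 1], d[g == 0], d[g == 1])
            assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
            assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_group_relabeling_invariance(self, rng):
        t = rng.exponential(10, 50)
        d = rng.binomial(1, 0.7, 50)
        g = rng.binomial(1, 0.5, 50)
        assert logrank_test(t, d, g)[0] == pytest.approx(logrank_test(t, d, 1 - g)[0])

    def test_power_under_rate_ratio_three(self):
        hits = 0
        for s in range(40):
            r = np.random.default_rng(s)
            t = np.concatenate([r.exponential(3, 200), r.exponential(9, 200)])
            g = np.repeat([0, 1], 200)
            _, p = logrank_test(t, np.ones(400), g)
            hits += p < 0.001
        assert hits >= 38

    def test_single_group_errors(self):
        with pytest.raises(ValueError, match="2 groups"):
            logrank_test([1, 2], [1, 1], [0, 0])


class TestCutpoint:
    def test_binary_scores_single_admissible_split(self):
        r = np.random.default_rng(0)
        score = np.repeat([0.0, 1.0], 150)
        t = np.concatenate([r.exponential(9, 150), r.exponential(3, 150)])
        cut = optimal_cutpoint(score, t, np.ones(300), minprop=0.1)
        assert 0.0 <= cut.threshold < 1.0
        assert cut.n_high == cut.n_low == 150

    def test_minprop_respected(self, rng):
        score = rng.normal(size=100)
        t = rng.exponential(10, 100)
        cut = optimal_cutpoint(score, t, np.ones(100), minprop=0.2)
        assert min(cut.n_high, cut.n_low) >= 20

    def test_all_identical_scores_error(self):
        with pytest.raises(ValueError, match="identical"):
            optimal_cutpoint(np.ones(50), np.arange(1, 51), np.ones(50))

    def test_recovers_planted_median_changepoint(self):
        hits = 0
        for s in range(10):
            coh, _ = simulate_survival(
                n=300, betas={"score": np.log(3)}, score_effect="threshold",
                censoring=0.2, seed=s,
            )
            cut = optimal_cutpoint(coh["score"], coh["time"], coh["event"])
            pct = (coh["score"] <= cut.threshold).mean()
            hits += 0.40 <= pct <= 0.60
        assert hits >= 8


class TestHazardModel:
    def test_null_binary_covariate_hr_near_one(self):
        r = np.random.default_rng(1)
        df = pd.DataFrame({
            "time": r.exponential(10, 400), "event": r.binomial(1, 0.8, 400),
            "arm": np.repeat([0.0, 1.0], 200),
        })
        m = fit_hazard_model(df, ["arm"])
        assert abs(m.coefficients["arm"]) < 0.25
        assert m.p_values["arm"] > 0.05

    def test_optimum_beats_grid_scan_of_partial_likelihood(self):
        r = np.random.default_rng(2)
        x = r.normal(size=20)
        t = r.exponential(np.exp(-0.8 * x))
        df = pd.DataFrame({"time": t, "event": 1, "x": x})
        m = fit_hazard_model(df, ["x"])

        def loglik(b):  # Breslow form; no ties in continuous times
            order = np.argsort(t)
            ll, risk = 0.0, list(order)
            for i in order:
                ll += b * x[i] - np.log(np.sum(np.exp(b * x[t >= t[i]])))
            return ll

        bhat = m.coefficients["x"]
        grid = np.arange(-3, 3, 0.01)
        assert loglik(bhat) >= max(loglik(b) for b in grid) - 1e-6

    def test_baseline_cumulative_hazard_nondecreasing(self):
        coh, _ = simulate_survival(n=150, seed=4)
        m = fit_hazard_model(coh, ["score", "age"])
        assert (m.baseline_cumulative_hazard.diff().dropna() >= -1e-12).all()
        assert np.allclose(m.hazard_ratios, np.exp(m.coefficients))
        assert (m.conf_int["hr_lower"] <= m.hazard_ratios).all()
        assert (m.conf_int["hr_upper"] >= m.hazard_ratios).all()

    def test_closed_loop_recovery_within_mc_error(self):
        coh, _ = simulate_survival(n=800, betas={"score": 0.7}, seed=5)
        m = fit_hazard_model(coh, ["score"])
        assert m.coefficients["score"] == pytest.approx(0.7, abs=0.15)

    def test_cox_table_layout(self):
        coh, _ = simulate_survival(n=200, seed=6)
        tab = cox_table(coh, ["score", "age", "stage_iii"])
        assert list(tab.index) == ["score", "age", "stage_iii"]
        assert {"uni_hr", "uni_p", "multi_hr", "multi_p"} <= set(tab.columns)


class TestNomogram:
    @pytest.fixture
    def fitted(self):
        coh, _ = simulate_survival(
            n=400, betas={"score": 0.7, "age": 0.03, "stage_iii": 0.8}, seed=7
        )
        m = fit_hazard_model(coh, ["score", "age", "stage_iii", "tumor_size"])
        ranges = {c: (coh[c].min(), coh[c].max()) for c in m.coefficients.index}
        return coh, m, ranges, build_nomogram(m, ranges, [36, 60])

    def test_reference_value_zero_points(self, fitted):
        _, _, _, nom = fitted
        for cov in nom.coefficients.index:
            assert nom.points(cov, nom.references[cov]) == pytest.approx(0.0)

    def test_largest_covariate_spans_exactly_100(self, fitted):
        _, m, ranges, nom = fitted
        spans = {c: abs(m.coefficients[c]) * (ranges[c][1] - ranges[c][0]) for c in ranges}
        big = max(spans, key=spans.get)
        extreme = ranges[big][1] if m.coefficients[big] > 0 else ranges[big][0]
        assert nom.points(big, extreme) == pytest.approx(100.0)

    def test_mean_covariates_predict_baseline_survival(self, fitted):
        _, m, _, nom = fitted
        tp = nom.total_points(pd.DataFrame([m.covariate_means])).iloc[0]
        assert nom.survival_at(tp, 36) == pytest.approx(m.baseline_survival_at(36), abs=1e-9)

    def test_survival_monotone_in_total_points(self, fitted):
        _, _, _, nom = fitted
        tab = nom.to_table(step=25.0)
        for col in ("surv_36", "surv_60"):
            assert (tab[col].diff().dropna() <= 1e-12).all()
            assert tab[col].between(0, 1).all()

    def test_horizon_beyond_follow_up_warns(self, fitted):
        _, m, ranges, _ = fitted
        with pytest.warns(RuntimeWarning, match="beyond"):
            build_nomogram(m, ranges, [1e6])


class TestCalibration:
    def test_single_bin_equals_overall_summary(self):
        coh, _ = simulate_survival(n=120, seed=8)
        m = fit_hazard_model(coh, ["score"])
        cal = calibration_curve(m, coh, horizon=36, n_bins=1)
        assert len(cal) == 1
        km = km_estimate(coh["time"], coh["event"])[0.0]
        observed = km[km.index <= 36].iloc[-1]
        assert cal["km_observed"].iloc[0] == pytest.approx(observed, abs=1e-9)
        assert cal["mean_predicted"].iloc[0] == pytest.approx(
            m.predict_survival(coh, 36).mean()
        )

    def test_excess_bins_merge_without_error(self):
        coh, _ = simulate_survival(n=25, seed=9)
        m = fit_hazard_model(coh, ["score"])
        cal = calibration_curve(m, coh, horizon=24, n_bins=50)
        assert cal["n"].sum() == 25
        assert (cal["n"] >= 10).all()

    def test_self_consistency_on_model_generated_data(self):
        # the model's own predictions should track the observed KM per bin
        inside = total = 0
        for s in range(8):
            coh, _ = simulate_survival(n=400, betas={"score": 0.9}, seed=100 + s)
            m = fit_hazard_model(coh, ["score"])
            cal = calibration_curve(m, coh, horizon=36, n_bins=3)
            inside += (
                (cal["mean_predicted"] >= cal["km_ci_low"])
                & (cal["mean_predicted"] <= cal["km_ci_high"])
            ).sum()
            total += len(cal)
        assert inside / total >= 0.85


class TestTimeDependentAUC:
    def test_perfect_marker_no_censoring(self, rng):
        t = rng.exponential(10, 200)
        assert time_dependent_auc(-t, t, np.ones(200), np.median(t)) == pytest.approx(1.0)

    def test_no_censoring_reduces_to_binary_wilcoxon_auc(self, rng):
        from sklearn.metrics import roc_auc_score
        t = rng.exponential(10, 300)
        score = -t + rng.normal(0, 5, 300)
        h = np.median(t)
        got = time_dependent_auc(score, t, np.ones(300), h)
        expected = roc_auc_score((t <= h).astype(int), score)
        assert got == pytest.approx(expected, abs=1e-10)

    def test_requires_events_on_both_sides_of_horizon(self, rng):
        t = rng.exponential(10, 50)
        with pytest.raises(ValueError):
            time_dependent_auc(-t, t, np.ones(50), t.max() + 1)


def test_risk_stratification_pipeline_detects_planted_effect():
    from tspsig.synthetic_data import default_signature
    sig = default_signature().signatures["BL1"]
    hits = 0
    for s in range(20):
        expr, clinical, _ = simulate_bulk_cohort(sig, n=150, beta_score=1.1, seed=s)
        strat = risk_stratify(expr, clinical, sig)
        hits += strat.logrank_p < 0.05
    assert hits >= 18
    assert strat.groups.value_counts().min() >= 15  # minprop respected
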