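"""Survival statistics: C-index, KM, log-rank, Cox, cutpoints, stratification."""

import numpy as np
import pandas as pd
import pytest

from hypersurv.evaluate import (
    build_control_models,
    clinical_design,
    cox_fit,
    harrell_c,
    km_estimate,
    logrank,
    logrank_chi2,
    median_survival,
    quantile_stratify,
    response_auc,
    univariate_screen,
    xtile_cutpoints,
)
from hypersurv.hgnn import _breslow_neg_loglik
from hypersurv.simulate import SyntheticConfig, generate_cohort


def brute_force_cindex(scores, times, events):
    """O(n^2) comparable-pair count: higher score should mean longer survival."""
    conc = ties = total = 0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # comparable when the shorter observed time carries an event; at
            # tied times only event-vs-censored pairs compare (the censored
            # patient survived at least as long), both-event ties are excluded
            shorter_event = times[i] < times[j] and events[i]
            tied_mixed = times[i] == times[j] and events[i] and not events[j]
            if shorter_event or tied_mixed:
                total += 1
                if scores[i] < scores[j]:
                    conc += 1
                elif scores[i] == scores[j]:
                    ties += 1
    if total == 0:
        return None
    return (conc + 0.5 * ties) / total


class TestHarrellC:
    def test_perfect_and_reversed_concordance(self):
        t = np.array([10.0, 5.0, 1.0])
        e = np.ones(3, bool)
        assert harrell_c(np.array([3.0, 2.0, 1.0]), t, e, n_boot=0)[0] == 1.0
        assert harrell_c(np.array([1.0, 2.0, 3.0]), t, e, n_boot=0)[0] == 0.0

    def test_matches_brute_force_on_censored_data(self, rng):
        for _ in range(20):
            n = 15
            t = rng.uniform(1, 30, n).round(1)
            e = rng.random(n) < 0.7
            s = rng.normal(size=n).round(2)
            expected = brute_force_cindex(s, t, e)
            if expected is None:
                continue
            c, _ = harrell_c(s, t, e, n_boot=0)
            assert c == pytest.approx(expected, abs=1e-12)

    def test_invariant_to_monotone_score_transform(self, rng):
        t = rng.uniform(1, 30, 20)
        e = rng.random(20) < 0.7
        s = rng.normal(size=20)
        c1, _ = harrell_c(s, t, e, n_boot=0)
        c2, _ = harrell_c(np.exp(2 * s) + 7, t, e, n_boot=0)
        assert c1 == pytest.approx(c2)

    def test_bootstrap_ci_brackets_estimate(self, rng):
        t = rng.uniform(1, 30, 60)
        e = rng.random(60) < 0.8
        s = -t + rng.normal(0, 5, 60)  # noisy concordant scores
        c, (lo, hi) = harrell_c(-s, t, e, n_boot=200, seed=1)
        assert lo <= c <= hi
        assert 0 < lo < hi < 1

    def test_no_comparable_pairs_errors(self):
        with pytest.raises(ValueError):
            harrell_c(np.array([1.0, 2.0]), np.array([5.0, 5.0]), np.zeros(2, bool), n_boot=0)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        curve = km_estimate(np.array([1.0, 2.0, 3.0, 4.0]), np.ones(4, bool))
        np.testing.assert_allclose(curve.times, [1, 2, 3, 4])
        np.testing.assert_allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])
        assert median_survival(curve) == 2.0

    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate(np.array([1.0, 2.0]), np.zeros(2, bool))
        assert len(curve.times) == 0
        assert median_survival(curve) is None

    def test_time_scale_equivariance(self, rng):
        t = rng.uniform(1, 20, 30)
        e = rng.random(30) < 0.7
        if not e.any():
            e[0] = True
        c1 = km_estimate(t, e)
        c2 = km_estimate(2 * t, e)
        np.testing.assert_allclose(c2.times, 2 * c1.times)
        np.testing.assert_allclose(c2.survival, c1.survival)

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = np.sort(rng.uniform(1, 20, 25))
        curve = km_estimate(t, np.ones(25, bool))
        emp = [(t > ti).mean() for ti in curve.times]
        np.testing.assert_allclose(curve.survival, emp, atol=1e-12)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate(np.array([-1.0, 2.0]), np.ones(2, bool))


class TestLogrank:
    def test_identical_groups_give_zero(self):
        g = (np.array([1.0, 2.0, 3.0]), np.ones(3, bool))
        chi2, p = logrank([g, g])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_observed_minus_expected(self):
        # group A events at 1, 2; group B events at 10, 11; no overlap after t=2
        a = (np.array([1.0, 2.0]), np.ones(2, bool))
        b = (np.array([10.0, 11.0]), np.ones(2, bool))
        chi2, p = logrank([a, b])
        # hand O-E: t=1: O_A=1 E_A=1/2 V=1/4; t=2: O_A=1 E_A=1/3 V=2/9;
        # t=10,11: O_A=0=E_A. Z = (2 - 5/6)^2 / (1/4 + 2/9)
        expected = (2 - 5 / 6) ** 2 / (1 / 4 + 2 / 9)
        assert chi2 == pytest.approx(expected, abs=1e-9)

    def test_vectorized_chi2_matches_lifelines(self, rng):
        for _ in range(10):
            n = 40
            t = rng.uniform(1, 30, n).round(1)
            e = rng.random(n) < 0.7
            labels = rng.integers(0, 3, n)
            if len(np.unique(labels)) < 3 or e.sum() == 0:
                continue
            ours = logrank_chi2(t, e, labels)
            groups = [(t[labels == g], e[labels == g]) for g in range(3)]
            ref, _ = logrank(groups)
            assert ours == pytest.approx(ref, abs=1e-8)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            logrank([(np.array([1.0]), np.array([True])), (np.array([]), np.array([]))])


class TestCoxFit:
    def test_single_binary_covariate_matches_brute_force(self, rng):
        n = 40
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(10.0, n) * np.exp(-0.8 * x)
        t += rng.uniform(0, 1e-6, n)  # guarantee tie-free times
        e = np.ones(n, bool)
        fit = cox_fit(x, t, e)
        grid = np.linspace(-3, 3, 20001)
        lls = [-_breslow_neg_loglik(b * x, t, e)[0] for b in grid]
        beta_grid = grid[int(np.argmax(lls))]
        assert fit.converged
        assert abs(fit.coefs[0] - beta_grid) < 1e-4

    def test_null_covariate_not_significant(self):
        local = np.random.default_rng(2024)
        n = 500
        x = local.normal(size=n)
        t = local.exponential(10.0, n)
        e = local.random(n) < 0.9
        fit = cox_fit(x, t, e)
        assert abs(fit.coefs[0]) < 0.15
        assert fit.p_values[0] > 0.05

    def test_coefficient_recovery_on_proportional_hazards_data(self, big_cohort):
        cohort, truth = big_cohort
        times, events = cohort.pfs()
        fit = cox_fit(truth.risk, times, events)
        assert abs(fit.coefs[0] - 1.0) < 0.1

    def test_zero_variance_covariate_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            cox_fit(np.ones(10), np.arange(1.0, 11.0), np.ones(10, bool))

    def test_zero_events_errors(self):
        with pytest.raises(ValueError):
            cox_fit(np.arange(5.0), np.arange(1.0, 6.0), np.zeros(5, bool))


class TestControlModels:
    def test_clinical_driven_cohort_favours_clinical_model(self):
        # class fully drives risk; radiomics features carry (almost) no signal
        for seed in (1, 2, 3):
            cfg = SyntheticConfig(
                n=250, seed=seed, class_risk=1.2, radiomics_risk=0.1,
                informative_loading=0.05,
            )
            cohort, _ = generate_cohort(cfg)
            from hypersurv.radiomics import standardize_features

            feats, _ = standardize_features(cohort.radiomics)
            models = build_control_models(cohort, feats, penalizer=0.1)
            times, events = cohort.pfs()
            design = clinical_design(cohort).join(feats.to_frame().reset_index(drop=True))
            assert not models["clinical"].degenerate
            c_clin, _ = harrell_c(models["clinical"].scores(design), times, events, n_boot=0)
            if models["radiomics"].degenerate:
                continue  # nothing passed the screen: clinical trivially wins
            c_rad, _ = harrell_c(models["radiomics"].scores(design), times, events, n_boot=0)
            assert c_clin > c_rad

    def test_all_insignificant_screen_is_degenerate(self, rng):
        n = 60
        design = pd.DataFrame({"x": rng.normal(size=n)})
        t = rng.exponential(10, n)
        e = np.ones(n, bool)
        sel = univariate_screen(design, t, e, alpha=1e-12)
        assert sel == []

    def test_composite_pools_both_blocks(self, small_cohort):
        from hypersurv.radiomics import standardize_features

        cohort, _ = small_cohort
        feats, _ = standardize_features(cohort.radiomics)
        models = build_control_models(cohort, feats, penalizer=0.1)
        assert len(models["composite"].selected) == (
            len(models["clinical"].selected) + len(models["radiomics"].selected)
        )


def independent_cutpoint_enumerator(scores, times, events, min_frac):
    """Second, independently coded exhaustive search used as an oracle."""
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2
    n = len(scores)
    best = (-np.inf, None, None)
    for a in range(len(mids)):
        for b in range(a + 1, len(mids)):
            lab = np.zeros(n, int)
            lab[scores > mids[a]] = 1
            lab[scores > mids[b]] = 2
            if np.bincount(lab, minlength=3).min() < int(np.ceil(min_frac * n)):
                continue
            groups = [(times[lab == g], events[lab == g]) for g in range(3)]
            chi2, _ = logrank(groups)
            if chi2 > best[0] + 1e-12:
                best = (chi2, mids[a], mids[b])
    return best


class TestXtileCutpoints:
    def test_recovers_plateau_boundaries(self, rng):
        # three score plateaus with well-separated exponential survival
        n_per = 25
        scores = np.concatenate(
            [
                rng.uniform(0.0, 0.2, n_per),
                rng.uniform(0.4, 0.6, n_per),
                rng.uniform(0.8, 1.0, n_per),
            ]
        )
        times = np.concatenate(
            [
                rng.exponential(1.0, n_per),
                rng.exponential(15.0, n_per),
                rng.exponential(200.0, n_per),
            ]
        )
        events = np.ones(3 * n_per, bool)
        res = xtile_cutpoints(scores, times, events, min_frac=0.10)
        true_groups = np.repeat([0, 1, 2], n_per)
        # recovered grouping agrees with the plateau identity almost everywhere
        assert (res.labels == true_groups).mean() >= 0.9
        assert 0.2 <= res.cutpoints[0] <= 0.4

    def test_matches_independent_enumerator(self, rng):
        for _ in range(5):
            n = 30
            scores = rng.normal(size=n).round(2)
            times = rng.uniform(1, 30, n)
            events = rng.random(n) < 0.8
            if events.sum() < 3 or len(np.unique(scores)) < 3:
                continue
            try:
                res = xtile_cutpoints(scores, times, events, min_frac=0.10)
            except ValueError:
                continue
            chi2_ref, c1, c2 = independent_cutpoint_enumerator(
                scores, times, events, 0.10
            )
            assert res.chi2 == pytest.approx(chi2_ref, abs=1e-6)
            assert res.cutpoints == pytest.approx((c1, c2), abs=1e-12)

    def test_exact_minimum_split_is_only_feasible(self):
        scores = np.repeat([0.0, 1.0, 2.0], 3)
        times = np.arange(1.0, 10.0)
        events = np.ones(9, bool)
        res = xtile_cutpoints(scores, times, events, min_frac=1 / 3)
        np.testing.assert_array_equal(np.bincount(res.labels), [3, 3, 3])

    def test_constant_scores_error(self):
        with pytest.raises(ValueError):
            xtile_cutpoints(np.ones(10), np.arange(1.0, 11.0), np.ones(10, bool))


class TestQuantileStratify:
    def test_pdl1_ratio_sizes(self, rng):
        labels = quantile_stratify(rng.normal(size=100), [38.0, 35.5, 26.5])
        np.testing.assert_array_equal(np.bincount(labels), [38, 35, 27])

    def test_cumulative_floor_small_n(self, rng):
        labels = quantile_stratify(rng.normal(size=5), [50.0, 50.0])
        np.testing.assert_array_equal(np.bincount(labels), [2, 3])

    def test_single_group(self, rng):
        labels = quantile_stratify(rng.normal(size=7), [100.0])
        assert (labels == 0).all()

    def test_groups_are_score_ordered(self, rng):
        s = rng.normal(size=50)
        labels = quantile_stratify(s, [30.0, 40.0, 30.0])
        assert s[labels == 0].max() <= s[labels == 1].min() + 1e-12
        assert s[labels == 1].max() <= s[labels == 2].min() + 1e-12

    def test_bad_proportions_error(self):
        with pytest.raises(ValueError):
            quantile_stratify(np.arange(5.0), [50.0, 40.0])


class TestResponseAUC:
    def test_perfect_and_tied(self):
        assert response_auc(np.array([1, 2, 3, 4.0]), np.array([0, 0, 1, 1], bool)) == 1.0
        assert response_auc(np.ones(4), np.array([0, 0, 1, 1], bool)) == 0.5

    def test_matches_pair_counting(self, rng):
        s = rng.normal(size=30).round(1)
        y = rng.random(30) < 0.4
        if y.all() or not y.any():
            y[:2] = [True, False]
        wins = ties = 0
        pos, neg = s[y], s[~y]
        for a in pos:
            for b in neg:
                wins += a > b
                ties += a == b
        expected = (wins + 0.5 * ties) / (len(pos) * len(neg))
        assert response_auc(s, y) == pytest.approx(expected, abs=1e-12)

    def test_single_class_is_undefined(self):
        assert response_auc(np.arange(3.0), np.ones(3, bool)) is None
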