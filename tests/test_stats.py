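"""Group comparison machinery: curves, selection, permutation, BCa, correlations."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from lrtcpipe.errors import DataError, ParameterError
from lrtcpipe.stats import (
    DEFAULT_BANDS,
    SubjectSummary,
    bootstrap_bca_ci,
    clinical_correlations,
    compare_groups,
    median_difference_curves,
    permutation_test,
    posterior_channels,
    power_alpha_correlation,
    select_frequencies,
    summarize_subject,
)
from lrtcpipe.synthetic import layout_positions

FREQS = np.logspace(np.log10(4), np.log10(40), 40)


def _summary(sid, group, alpha_by_freq, n_channels=8, channel_offsets=None,
             relpower=None):
    """Build a SubjectSummary with a given frequency profile."""
    base = np.tile(np.asarray(alpha_by_freq, dtype=float), (n_channels, 1))
    if channel_offsets is not None:
        base = base + np.asarray(channel_offsets)[:, None]
    return SubjectSummary(
        subject_id=sid, group=group, alpha=base, frequencies=FREQS,
        channel_pos=layout_positions(n_channels),
        relpower=relpower if relpower is None else np.tile(
            np.asarray(relpower, dtype=float), (n_channels, 1)),
    )


def _cohort(rng, n_ctrl=10, n_clin=10, shift=0.0, spread=0.03):
    subs = []
    for i in range(n_ctrl):
        subs.append(_summary(f"C{i}", "CTRL",
                             0.7 + rng.normal(0, spread, FREQS.size)))
    for i in range(n_clin):
        subs.append(_summary(f"P{i}", "CLIN",
                             0.7 + shift + rng.normal(0, spread, FREQS.size)))
    return subs


class TestMedianDifferenceCurves:
    def test_identical_groups_zero_curve(self):
        subs = [_summary("a", "CTRL", np.full(40, 0.7)),
                _summary("b", "CLIN", np.full(40, 0.7))]
        curves = median_difference_curves(subs)
        assert np.allclose(curves["CLIN"], 0.0)

    def test_constant_shift_recovered(self):
        rng = np.random.default_rng(0)
        subs = _cohort(rng, shift=0.05)
        curves = median_difference_curves(subs)
        assert np.all(np.abs(curves["CLIN"] - 0.05) < 0.04)
        assert abs(curves["CLIN"].mean() - 0.05) < 0.01

    def test_band_limited_effect_peaks_in_band(self):
        rng = np.random.default_rng(1)
        bump = 0.08 * np.exp(-0.5 * ((FREQS - 20.0) / 2.0) ** 2)
        subs = [_summary(f"c{i}", "CTRL",
                         0.7 + rng.normal(0, 0.01, FREQS.size))
                for i in range(8)]
        subs += [_summary(f"p{i}", "CLIN",
                          0.7 + bump + rng.normal(0, 0.01, FREQS.size))
                 for i in range(8)]
        curves = median_difference_curves(subs)
        f_peak = curves["CLIN"].abs().idxmax()
        assert 12.0 <= f_peak <= 40.0

    def test_empty_group_rejected(self):
        with pytest.raises(DataError):
            median_difference_curves([_summary("a", "CTRL", np.full(40, 0.7))])


class TestSelectFrequencies:
    def _curves(self, values):
        return pd.DataFrame({"CLIN": values},
                            index=pd.Index(FREQS, name="frequency_hz"))

    def test_unique_max_selected_per_band(self):
        v = np.zeros(40)
        v[5] = 0.03   # theta member
        v[18] = -0.06  # alpha member (abs max)
        v[30] = 0.02
        sel = select_frequencies(self._curves(v))
        assert sel.selected["theta"]["frequency"] == pytest.approx(FREQS[5])
        assert sel.selected["alpha"]["frequency"] == pytest.approx(FREQS[18])
        assert sel.selected["beta"]["frequency"] == pytest.approx(FREQS[30])
        assert sel.selected["alpha"]["delta"] == pytest.approx(-0.06)

    def test_tie_breaks_to_lower_frequency(self):
        v = np.zeros(40)
        beta = (FREQS >= 12) & (FREQS <= 40)
        idx = np.flatnonzero(beta)[[2, 5]]
        v[idx] = 0.05
        sel = select_frequencies(self._curves(v))
        assert sel.selected["beta"]["frequency"] == pytest.approx(FREQS[idx[0]])

    def test_empty_band_rejected(self):
        curves = pd.DataFrame({"CLIN": [0.1]},
                              index=pd.Index([25.0], name="frequency_hz"))
        with pytest.raises(ParameterError):
            select_frequencies(curves, DEFAULT_BANDS)

    def test_simulated_beta_effect_located(self):
        rng = np.random.default_rng(2)
        bump = 0.08 * np.exp(-0.5 * ((FREQS - 21.0) / 1.5) ** 2)
        subs = [_summary(f"c{i}", "CTRL",
                         0.7 + rng.normal(0, 0.01, FREQS.size))
                for i in range(10)]
        subs += [_summary(f"p{i}", "CLIN",
                          0.7 + bump + rng.normal(0, 0.01, FREQS.size))
                 for i in range(10)]
        sel = select_frequencies(median_difference_curves(subs))
        f_sel = sel.selected["beta"]["frequency"]
        i_true = np.argmin(np.abs(FREQS - 21.0))
        assert abs(np.log10(f_sel) - np.log10(FREQS[i_true])) \
            <= 1.5 * (np.log10(FREQS[1]) - np.log10(FREQS[0]))


class TestPermutationTest:
    def test_identical_groups_p_is_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        assert permutation_test(a, a.copy(), n=999, seed=0).p == 1.0

    def test_complete_separation_attains_minimum_p(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 20)
        b = rng.normal(10, 1, 20)
        res = permutation_test(a, b, n=999, seed=1)
        assert res.p == pytest.approx(1.0 / 1000.0)

    def test_null_p_values_uniform(self):
        """Under exchangeability p is uniform (even group sizes: the median
        statistic is conservative for odd sizes)."""
        rng = np.random.default_rng(4)
        ps = [permutation_test(rng.normal(0, 1, 16), rng.normal(0, 1, 16),
                               n=499, seed=s).p for s in range(200)]
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01

    def test_t_statistic_variant(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 15), rng.normal(1.5, 1, 15)
        res = permutation_test(a, b, statistic="t", n=999, seed=2)
        assert res.p < 0.05

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
        r1 = permutation_test(a, b, n=500, seed=42)
        r2 = permutation_test(a, b, n=500, seed=42)
        assert r1.p == r2.p
        assert np.array_equal(r1.null_distribution, r2.null_distribution)


class TestBootstrapBca:
    def test_symmetric_case_matches_percentile(self):
        rng = np.random.default_rng(7)
        a = rng.normal(0.7, 0.05, 40)
        b = rng.normal(0.65, 0.05, 40)
        lo, hi, boot = bootstrap_bca_ci(a, b, n=4000, seed=1)
        plo, phi = np.quantile(boot, [0.025, 0.975])
        step = 3.0 * (np.quantile(boot, 0.05) - np.quantile(boot, 0.02))
        assert abs(lo - plo) <= abs(step)
        assert abs(hi - phi) <= abs(step)

    def test_bias_correction_definition(self):
        """z0 = 0 exactly when half the resamples fall below the observed
        statistic."""
        prop = 0.5
        assert scipy.stats.norm.ppf(prop) == 0.0

    def test_reproducible_and_ordered(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0.7, 0.1, 12), rng.normal(0.6, 0.1, 12)
        r1 = bootstrap_bca_ci(a, b, n=1000, seed=3)
        r2 = bootstrap_bca_ci(a, b, n=1000, seed=3)
        assert r1[:2] == r2[:2]
        assert r1[0] < r1[1]

    def test_degenerate_groups_rejected(self):
        with pytest.raises(DataError):
            bootstrap_bca_ci([1.0], [1.0, 2.0])

    def test_coverage_near_nominal(self):
        """95% BCa interval covers the true median difference at close to
        nominal rate over repeated two-group draws."""
        cover = 0
        n_rep = 150
        for i in range(n_rep):
            rng = np.random.default_rng(10_000 + i)
            a = rng.normal(0.75, 0.05, 25)
            b = rng.normal(0.70, 0.05, 47)
            lo, hi, _ = bootstrap_bca_ci(a, b, n=600, seed=i)
            cover += lo <= 0.05 <= hi
        assert 0.90 <= cover / n_rep <= 0.99


class TestCompareGroups:
    def test_null_cohort_behaviour(self):
        rng = np.random.default_rng(9)
        subs = _cohort(rng, 12, 12, shift=0.0)
        res = compare_groups(subs, 10.0, n_permutations=500, n_bootstrap=500,
                             seed=1)["CLIN"]
        assert abs(res.delta_median) < 0.05
        assert res.ci_low < 0.0 < res.ci_high
        assert res.p_perm > 0.05

    def test_injected_effect_recovered(self):
        rng = np.random.default_rng(10)
        subs = _cohort(rng, 25, 25, shift=0.05)
        res = compare_groups(subs, 20.0, n_permutations=1000,
                             n_bootstrap=1000, seed=2)["CLIN"]
        half_width = (res.ci_high - res.ci_low) / 2
        assert abs(res.delta_median - 0.05) < max(half_width, 0.02)
        assert res.p_perm < 0.05

    def test_posterior_subset_sharpens_local_effect(self):
        """A posterior-only effect is diluted in the all-channel median."""
        rng = np.random.default_rng(11)
        pos = layout_positions(8)
        posterior = posterior_channels(pos)
        offs = np.where(posterior, -0.08, 0.0)
        subs = [_summary(f"c{i}", "CTRL",
                         0.7 + rng.normal(0, 0.005, FREQS.size))
                for i in range(10)]
        subs += [_summary(f"p{i}", "CLIN",
                          0.7 + rng.normal(0, 0.005, FREQS.size),
                          channel_offsets=offs)
                 for i in range(10)]
        r_all = compare_groups(subs, 20.0, n_permutations=200,
                               n_bootstrap=200, seed=3)["CLIN"]
        r_post = compare_groups(subs, 20.0, channel_subset=posterior,
                                n_permutations=200, n_bootstrap=200,
                                seed=3)["CLIN"]
        assert abs(r_post.delta_median) > abs(r_all.delta_median)

    def test_bonferroni_flag(self):
        rng = np.random.default_rng(12)
        subs = _cohort(rng, 8, 8, shift=0.0)
        res = compare_groups(subs, 10.0, n_permutations=200, n_bootstrap=200,
                             seed=4, bonferroni_m=3)["CLIN"]
        assert res.p_bonferroni == pytest.approx(min(res.p_perm * 3, 1.0))


class TestPosteriorChannels:
    def test_median_and_zero_split(self):
        pos = layout_positions(32)
        m = posterior_channels(pos, "median")
        z = posterior_channels(pos, "zero")
        assert m.sum() == 16
        assert np.all(pos[z, 1] < 0)

    def test_missing_positions_rejected(self):
        with pytest.raises(DataError):
            posterior_channels(None)


class TestPowerAlphaCorrelation:
    def test_identical_vectors_give_r_one(self):
        vals = np.linspace(0.6, 0.8, 12)
        subs = [_summary(f"s{i}", "CTRL", np.full(40, v),
                         relpower=np.full(40, v)) for i, v in enumerate(vals)]
        r, p, r2 = power_alpha_correlation(subs, 10.0)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_independent_power_mostly_uncorrelated(self):
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            subs = [_summary(f"s{i}", "CTRL",
                             np.full(40, 0.7 + rng.normal(0, 0.03)),
                             relpower=np.full(40, abs(rng.normal(0.1, 0.02))))
                    for i in range(20)]
            _, p, _ = power_alpha_correlation(subs, 10.0)
            hits += p < 0.05
        assert hits <= 3

    def test_constant_input_rejected(self):
        subs = [_summary(f"s{i}", "CTRL", np.full(40, 0.7),
                         relpower=np.full(40, 0.1)) for i in range(5)]
        with pytest.raises(DataError):
            power_alpha_correlation(subs, 10.0)


class TestClinicalCorrelations:
    def _subs(self, alphas):
        return [_summary(f"s{i}", "CTRL", np.full(40, a))
                for i, a in enumerate(alphas)]

    def test_score_equal_to_alpha_gives_rho_one(self):
        alphas = np.linspace(0.6, 0.9, 10)
        subs = self._subs(alphas)
        table = pd.DataFrame({"score": alphas},
                             index=[s.subject_id for s in subs])
        out = clinical_correlations(subs, table, [10.0])
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        alphas = np.linspace(0.6, 0.9, 10)
        subs = self._subs(alphas)
        table = pd.DataFrame({"score": np.exp(5 * alphas)},
                             index=[s.subject_id for s in subs])
        out = clinical_correlations(subs, table, [10.0])
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_too_few_pairs_reported_missing(self):
        alphas = np.linspace(0.6, 0.9, 6)
        subs = self._subs(alphas)
        scores = [0.1, 0.2, np.nan, np.nan, np.nan, np.nan]
        table = pd.DataFrame({"score": scores},
                             index=[s.subject_id for s in subs])
        out = clinical_correlations(subs, table, [10.0])
        assert np.isnan(out.loc[0, "rho"])
        assert "fewer than 3" in out.loc[0, "note"]

    def test_independent_scores_null_p_distribution(self):
        ps = []
        for rep in range(60):
            rng = np.random.default_rng(200 + rep)
            alphas = 0.7 + rng.normal(0, 0.05, 14)
            subs = self._subs(alphas)
            table = pd.DataFrame({"score": rng.normal(0, 1, 14)},
                                 index=[s.subject_id for s in subs])
            out = clinical_correlations(subs, table, [10.0])
            ps.append(out.loc[0, "p"])
        assert scipy.stats.kstest(ps, "uniform").pvalue > 0.01


def test_summarize_subject_roundtrip():
    from lrtcpipe.dfa import ScalingExponentMap
    alpha = np.random.default_rng(0).uniform(0.5, 1.0, (4, 40))
    m = ScalingExponentMap(alpha=alpha, fit_r2=np.ones_like(alpha),
                           n_windows_used=np.ones_like(alpha, dtype=np.int64),
                           frequencies=FREQS,
                           channel_names=[f"CH{i}" for i in range(4)])
    s = summarize_subject(m, "sub-1", "CTRL")
    assert s.alpha_by_freq.shape == (40,)
    assert s.alpha_at(10.0) == pytest.approx(
        np.median(alpha[:, np.argmin(np.abs(FREQS - 10.0))]))
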