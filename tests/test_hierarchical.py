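"""Hierarchical model: structure, sampler contracts, inference, DIC, PPC."""

import math
import warnings
from dataclasses import replace

import numpy as np
import pytest
from scipy import stats as sps

from moralddm.hierarchical import (
    FitConfig,
    HierarchicalDDM,
    build_model,
    diff_distribution,
    dic,
    posterior_predict,
    sample_posterior,
)
from moralddm.wiener import Choice, DDMParams, fpt_density, _prob_before


class TestBuildModel:
    def test_structure_counts(self, small_cohort):
        spec = build_model(small_cohort, variant="bias")
        assert len(spec.groups) == 12
        # 12 groups x 3 families x (mean + spread) + shared starting point
        assert len(spec.free_group_parameters) == 12 * 6 + 2

    def test_no_bias_variant_drops_z(self, small_cohort):
        spec = build_model(small_cohort, variant="no_bias")
        assert not any(p.startswith("z") for p in spec.free_group_parameters)

    def test_degenerate_single_group_rejected(self, small_cohort):
        one_cell = small_cohort[small_cohort.group == "1V1M"]
        with pytest.raises(ValueError, match="12 valence groups"):
            build_model(one_cell)

    def test_unknown_group_label_rejected(self, small_cohort):
        bad = small_cohort.copy()
        moral_rows = bad.index[bad.task == "moral"][:50]
        bad.loc[moral_rows, "group"] = "9V9M"
        with pytest.raises(ValueError, match="unknown group"):
            build_model(bad)

    def test_single_participant_rejected(self, small_cohort):
        solo = small_cohort[small_cohort.participant_id == 0]
        with pytest.raises(ValueError, match="two participants"):
            build_model(solo)

    def test_unknown_variant_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="variant"):
            build_model(small_cohort, variant="magic")

    def test_invalid_fit_config(self):
        with pytest.raises(ValueError):
            FitConfig(n_samples=100, burn_in=100)
        with pytest.raises(ValueError):
            FitConfig(n_samples=100, burn_in=10, thinning=0)


class TestDiffDistribution:
    def test_identical_samples(self):
        x = np.random.default_rng(0).normal(size=500)
        d = diff_distribution(x, x)
        assert d.mean == 0.0
        assert not d.significant
        assert d.pct_below_zero == d.pct_above_zero == 50.0

    def test_unit_shift_is_significant(self):
        x = np.random.default_rng(1).normal(size=500)
        d = diff_distribution(x, x - 1.0)
        assert d.mean == pytest.approx(1.0)
        assert d.pct_below_zero == 0.0 and d.pct_above_zero == 100.0
        assert d.significant

    def test_normal_overlap_closed_form(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.5, 1.0, 100_000)
        b = rng.normal(0.0, 1.0, 100_000)
        d = diff_distribution(a, b)
        expected = sps.norm.cdf(0.5 / math.sqrt(2.0)) * 100
        assert d.pct_above_zero == pytest.approx(expected, abs=1.0)

    def test_percentages_sum_to_100_with_ties(self):
        d = diff_distribution(np.array([1.0, 2.0, 3.0]), np.array([1.0, 0.0, 5.0]))
        assert d.pct_below_zero + d.pct_above_zero == pytest.approx(100.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            diff_distribution(np.zeros(3), np.zeros(4))


class TestSampler:
    def test_fixed_seed_bit_identical(self, small_cohort):
        kw = dict(draws=250, burn_in=80, seed=5, include_errors=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m1 = HierarchicalDDM(**kw).fit(small_cohort)
            m2 = HierarchicalDDM(**kw).fit(small_cohort)
        for k in m1.chains_.draws:
            np.testing.assert_array_equal(m1.chains_.draws[k], m2.chains_.draws[k])
        assert m1.dic_ == m2.dic_

    def test_prior_only_recovers_prior_means(self, small_cohort):
        model = build_model(small_cohort, variant="bias")
        chains = sample_posterior(
            model, small_cohort, FitConfig(n_samples=6000, burn_in=1000, seed=9, prior_only=True)
        )
        v_means = np.array([chains.draws[f"v_mu[{g}]"].mean() for g in chains.groups])
        assert np.abs(v_means.mean()) < 0.15  # prior mean 0
        assert chains.draws["z_mu"].mean() == pytest.approx(0.5, abs=0.03)  # Beta(2,2)
        # boundary-mean prior: Gamma(1.5, rate 0.75) truncated above 0.3,
        # reference mean by direct Monte Carlo
        rng = np.random.default_rng(4)
        ref = rng.gamma(1.5, 1 / 0.75, 200_000)
        ref = ref[ref > 0.3].mean()
        a_means = np.array([chains.draws[f"a_mu[{g}]"].mean() for g in chains.groups])
        assert a_means.mean() == pytest.approx(ref, abs=0.2)

    def test_nonconvergence_is_flagged_not_silent(self, small_cohort):
        with pytest.warns(RuntimeWarning, match="non-convergence"):
            m = HierarchicalDDM(draws=60, burn_in=10, seed=1).fit(small_cohort)
        assert m.chains_.warnings

    def test_diagnostics_cover_every_group_parameter(self, small_fit):
        params = set(small_fit.diagnostics_["parameter"])
        assert params == set(small_fit.model_.free_group_parameters)
        assert small_fit.diagnostics_["rhat"].notna().all()

    def test_shrinkage_toward_group_mean(self, small_fit, small_cohort):
        """Participant-level posterior means sit between the raw per-cell
        moment estimates and the group mean for the bulk of cells."""
        from moralddm.hierarchical import _ez_init, _prepare

        prep = _prepare(small_cohort, "moral", True)
        ez_v, _, _ = _ez_init(prep)
        post_v = small_fit.chains_.participant_mean["v"]
        group_v = post_v.mean(axis=0, keepdims=True)
        closer = np.abs(post_v - group_v) <= np.abs(ez_v - group_v) + 0.05
        assert closer.mean() > 0.75


class TestDic:
    def test_zero_variance_chains_give_zero_pd(self, small_fit, small_cohort):
        chains = small_fit.chains_
        d_bar = chains.deviance.mean()
        d_hat = 2 * d_bar - small_fit.dic_
        degenerate = replace(chains, deviance=np.full_like(chains.deviance, d_hat))
        assert dic(small_fit.model_, degenerate, small_cohort) == pytest.approx(d_hat, rel=1e-12)

    def test_brute_force_two_pass_oracle(self, small_fit, small_cohort):
        """Stored deviance draws match a naive per-trial recomputation."""
        from moralddm.hierarchical import _prepare

        model = small_fit.model_
        chains = small_fit.chains_
        prep = _prepare(small_cohort, model.task, model.include_errors)
        n_store = max(1, len(chains) // 200)
        for i in (0, 3, 7):
            v = chains.participant_draws["v"][i]
            a = chains.participant_draws["a"][i]
            t = chains.participant_draws["t"][i]
            z = chains.participant_draws["z"][i]
            ll = 0.0
            for rt, up, p, g in zip(prep.rt, prep.upper, prep.p_idx, prep.g_idx):
                params = DDMParams(v[p, g], a[p, g], z[p], t[p, g])
                dens = fpt_density(rt - t[p, g], Choice.upper if up else Choice.lower, params)
                norm = _prob_before(
                    model.deadline_s - t[p, g], v[p, g], a[p, g], z[p], 1e-7
                )
                ll += math.log(dens) - math.log(norm)
            assert chains.deviance[i * n_store] == pytest.approx(-2 * ll, abs=1e-6)

    def test_invariant_to_post_hoc_thinning(self, small_fit, small_cohort):
        chains = small_fit.chains_
        thinned = replace(chains, deviance=chains.deviance[::2])
        d_full = dic(small_fit.model_, chains, small_cohort)
        d_thin = dic(small_fit.model_, thinned, small_cohort)
        assert abs(d_full - d_thin) < 0.5

    def test_nonfinite_deviance_rejected(self, small_fit, small_cohort):
        bad = replace(small_fit.chains_, deviance=np.r_[small_fit.chains_.deviance, np.inf])
        with pytest.raises(ValueError, match="non-finite"):
            dic(small_fit.model_, bad, small_cohort)


class TestPosteriorPredict:
    def test_deterministic_single_rep(self, small_fit, small_cohort):
        p1 = posterior_predict(small_fit.model_, small_fit.chains_, small_cohort, n_rep=1, seed=3)
        p2 = posterior_predict(small_fit.model_, small_fit.chains_, small_cohort, n_rep=1, seed=3)
        assert p1.equals(p2)

    def test_invalid_n_rep(self, small_fit, small_cohort):
        with pytest.raises(ValueError):
            posterior_predict(small_fit.model_, small_fit.chains_, small_cohort, n_rep=0)

    def test_self_consistency_coverage(self, small_fit, small_cohort):
        ppc = posterior_predict(small_fit.model_, small_fit.chains_, small_cohort, n_rep=40, seed=4)
        assert ppc["covered"].mean() >= 0.9

    def test_gross_misspecification_flagged(self, small_fit, small_cohort):
        chains = small_fit.chains_
        broken = replace(
            chains,
            participant_draws={
                **chains.participant_draws,
                "a": chains.participant_draws["a"] * 10.0,
            },
        )
        ppc = posterior_predict(small_fit.model_, broken, small_cohort, n_rep=25, seed=5)
        rt_rows = ppc[ppc.stat.str.startswith("rt_")]
        assert rt_rows["covered"].mean() < 0.5
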