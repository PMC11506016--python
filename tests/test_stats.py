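"""Behavioral statistics against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from moralddm.stats import (
    assign_valence_levels,
    cronbach_alpha,
    filter_trials,
    intensity,
    match_stimuli_ttests,
    paired_t_fdr,
    required_sample_size,
    rm_anova_2x2,
    select_words,
    simple_effects,
)


class TestIntensity:
    @pytest.mark.parametrize("score,expected", [(5, 0), (7, 2), (1, 4), (9, 4), (3.5, 1.5)])
    def test_distance_from_midpoint(self, score, expected):
        assert intensity(score) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            intensity(0.5)


class TestWordSelection:
    def _words(self, rows):
        return pd.DataFrame(rows, columns=["moral_rating", "emotional_rating"])

    def test_either_dimension_rule(self):
        # intensities (2.5, 1.0): kept because one dimension exceeds 2
        kept = select_words(self._words([(7.5, 6.0)]))
        assert len(kept) == 1

    def test_boundary_is_strict(self):
        # exactly 2 on both dimensions: dropped
        kept = select_words(self._words([(7.0, 3.0)]))
        assert len(kept) == 0

    def test_equal_width_bin_edges(self):
        # words spanning intensity [2, 4]: edges at 2.667 / 3.333,
        # an exact edge value goes to the upper bin
        w = pd.DataFrame(
            dict(
                moral_rating=[7.0, 7.0 + 2 / 3, 8.0, 9.0],
                emotional_rating=[7.0, 7.0 + 2 / 3, 8.0, 9.0],
            )
        )
        out, rejected = assign_valence_levels(w)
        both = pd.concat([out, rejected]).sort_values("moral_rating")
        assert list(both["moral_level"]) == [0, 1, 1, 2]

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            assign_valence_levels(pd.DataFrame(columns=["moral_rating", "emotional_rating"]))


class TestFilterTrials:
    def _table(self):
        return pd.DataFrame(
            dict(
                task=["moral"] * 10,
                rt_ms=[500] * 9 + [1700],
                timeout=[False] * 9 + [True],
                correct=[True] * 7 + [False, False, False],
            )
        )

    def test_counts_and_percentages(self):
        kept, report = filter_trials(self._table())
        assert len(kept) == 7
        row = report.iloc[0]
        assert row["n_timeout"] == 1 and row["pct_timeout"] == 10.0
        assert row["n_error"] == 2 and row["pct_error"] == 20.0
        assert row["n_kept"] == 7 and row["pct_kept"] == 70.0

    def test_all_correct_identity(self):
        t = self._table().assign(correct=True, timeout=False, rt_ms=500)
        kept, _ = filter_trials(t)
        pd.testing.assert_frame_equal(kept, t.reset_index(drop=True))

    def test_idempotent(self):
        kept1, _ = filter_trials(self._table())
        kept2, _ = filter_trials(kept1)
        pd.testing.assert_frame_equal(kept1, kept2)


def _anova_oracle(y):
    """Textbook within-subjects SS decomposition for a 2x2 design."""
    n = y.shape[0]
    cells = y.reshape(n, 2, 2)  # (subject, A, B)
    grand = cells.mean()
    sm = cells.mean(axis=(1, 2))
    out = {}
    for name, axis_keep in (("task", 1), ("word", 2)):
        m = cells.mean(axis=3 - axis_keep)  # (subject, level)
        lvl = m.mean(axis=0)
        ss_eff = 2 * n * np.sum((lvl - grand) ** 2)
        ss_err = 2 * np.sum((m - sm[:, None] - lvl[None, :] + grand) ** 2)
        out[name] = (ss_eff, ss_err)
    ma = cells.mean(axis=2).mean(axis=0)
    mb = cells.mean(axis=1).mean(axis=0)
    cell_m = cells.mean(axis=0)
    inter = cell_m - ma[:, None] - mb[None, :] + grand
    ss_ab = n * np.sum(inter**2)
    resid = (
        cells
        - cells.mean(axis=1, keepdims=True)
        - cells.mean(axis=2, keepdims=True)
        - cell_m[None, :, :]
        + sm[:, None, None]
        + ma[None, :, None]
        + mb[None, None, :]
        - grand
    )
    out["interaction"] = (ss_ab, np.sum(resid**2))
    res = {}
    for name, (ss_eff, ss_err) in out.items():
        F = (ss_eff / 1) / (ss_err / (n - 1))
        res[name] = (F, ss_eff / (ss_eff + ss_err))
    return res


class TestRmAnova:
    def test_zero_effects(self):
        y = np.tile(np.random.default_rng(0).normal(size=(10, 1)), (1, 4))
        res = rm_anova_2x2(y)
        for eff in ("task", "word", "interaction"):
            assert getattr(res, eff).F == pytest.approx(0.0, abs=1e-20)

    def test_matches_ss_decomposition_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            y = rng.normal(500, 60, size=(9, 4)) + rng.normal(0, 20, size=4)
            res = rm_anova_2x2(y)
            oracle = _anova_oracle(y)
            for eff in ("task", "word", "interaction"):
                assert getattr(res, eff).F == pytest.approx(oracle[eff][0], abs=1e-10)
                assert getattr(res, eff).partial_eta_sq == pytest.approx(
                    oracle[eff][1], abs=1e-10
                )

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        y = rng.normal(500, 50, size=(12, 4)) + np.array([0, 10, 5, 25])
        res = rm_anova_2x2(y)
        df = pd.DataFrame(
            dict(
                y=y.ravel(),
                subj=np.repeat(np.arange(12), 4),
                A=np.tile([0, 0, 1, 1], 12),
                B=np.tile([0, 1, 0, 1], 12),
            )
        )
        ref = pg.rm_anova(data=df, dv="y", within=["A", "B"], subject="subj", detailed=True,
                          effsize="np2")
        for eff, src in (("task", "A"), ("word", "B"), ("interaction", "A * B")):
            row = ref.loc[ref["Source"] == src].iloc[0]
            assert getattr(res, eff).F == pytest.approx(row["F"], rel=1e-9)
            assert getattr(res, eff).p == pytest.approx(row["p_unc"], rel=1e-9)
            assert getattr(res, eff).partial_eta_sq == pytest.approx(row["np2"], rel=1e-9)

    def test_location_invariance(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=(8, 4))
        r1, r2 = rm_anova_2x2(y), rm_anova_2x2(y + 1234.5)
        for eff in ("task", "word", "interaction"):
            assert getattr(r1, eff).F == pytest.approx(getattr(r2, eff).F, rel=1e-9)

    def test_missing_cells_error(self):
        y = np.random.default_rng(0).normal(size=(5, 4))
        y[0, 0] = np.nan
        with pytest.raises(ValueError):
            rm_anova_2x2(y)


class TestSimpleEffects:
    def test_identical_columns_zero_f(self):
        y = np.random.default_rng(1).normal(size=(6, 4))
        y[:, 3] = y[:, 2]
        assert simple_effects(y, "word", 1).F == pytest.approx(0.0, abs=1e-20)

    def test_equals_squared_paired_t(self):
        y = np.random.default_rng(2).normal(size=(10, 4))
        t, p = sps.ttest_rel(y[:, 0], y[:, 1])
        res = simple_effects(y, "word", 0)
        assert res.F == pytest.approx(t**2, rel=1e-10)
        assert res.p == pytest.approx(p, rel=1e-9)
        assert res.df1 == 1 and res.df2 == 9

    def test_unknown_level_error(self):
        with pytest.raises(ValueError):
            simple_effects(np.zeros((4, 4)), "word", 2)


def _bh_oracle(p):
    """Step-up Benjamini-Hochberg from the definition."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj


class TestPairedTFdr:
    def test_identical_vectors(self):
        x = np.arange(10.0)
        res = paired_t_fdr({"same": (x, x.copy())})
        assert res[0].t == 0.0 and res[0].p_raw == 1.0

    def test_bh_adjustment_matches_step_up_oracle(self):
        rng = np.random.default_rng(6)
        comparisons = {
            f"c{i}": (rng.normal(i * 0.2, 1, 15), rng.normal(0, 1, 15)) for i in range(6)
        }
        res = paired_t_fdr(comparisons)
        p_raw = np.array([r.p_raw for r in res])
        p_fdr = np.array([r.p_fdr for r in res])
        np.testing.assert_allclose(p_fdr, _bh_oracle(p_raw), atol=1e-12)

    def test_bh_known_example(self):
        # p = (.01, .02, .03, .04) with m = 4 all adjust to .04
        np.testing.assert_allclose(_bh_oracle([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_statsmodels_bh_equals_oracle_on_random_vectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        for _ in range(1000):
            p = rng.random(rng.integers(2, 12))
            _, adj, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(adj, _bh_oracle(p), atol=1e-12)

    def test_fdr_monotone_in_rank(self):
        rng = np.random.default_rng(8)
        comparisons = {f"c{i}": (rng.normal(0, 1, 10), rng.normal(0, 1, 10)) for i in range(8)}
        res = paired_t_fdr(comparisons)
        by_raw = sorted(res, key=lambda r: r.p_raw)
        fdr = [r.p_fdr for r in by_raw]
        assert all(a <= b + 1e-15 for a, b in zip(fdr, fdr[1:]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_t_fdr({"bad": (np.zeros(3), np.zeros(4))})


class TestCronbachAlpha:
    def test_duplicated_items(self):
        rng = np.random.default_rng(9)
        col = rng.normal(size=(20, 1))
        assert cronbach_alpha(np.tile(col, (1, 5))) == pytest.approx(1.0)

    def test_two_items_spearman_brown(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=200)
        y = 0.7 * x + rng.normal(size=200) * 0.5
        r = np.corrcoef(x, y)[0, 1]
        # standardize so the covariance identity is exact
        x, y = (x - x.mean()) / x.std(ddof=1), (y - y.mean()) / y.std(ddof=1)
        r = np.corrcoef(x, y)[0, 1]
        assert cronbach_alpha(np.c_[x, y]) == pytest.approx(2 * r / (1 + r), rel=1e-10)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(11)
        assert abs(cronbach_alpha(rng.normal(size=(500, 40)))) < 0.1

    def test_zero_variance_error(self):
        with pytest.raises(ValueError):
            cronbach_alpha(np.ones((5, 5)))


class TestSampleSize:
    def test_study_settings_give_26(self):
        assert required_sample_size(f=0.25, alpha=0.05, power=0.85, m=4, rho=0.5, eps=1.0) == 26

    def test_returned_n_is_minimal(self):
        from moralddm.stats import _rm_power

        n = required_sample_size(f=0.3, power=0.9)
        assert _rm_power(n, 0.3, 0.05, 4, 0.5, 1.0) >= 0.9
        assert _rm_power(n - 1, 0.3, 0.05, 4, 0.5, 1.0) < 0.9

    def test_power_monotone_in_n(self):
        from moralddm.stats import _rm_power

        powers = [_rm_power(n, 0.25, 0.05, 4, 0.5, 1.0) for n in range(5, 60, 5)]
        assert all(a < b for a, b in zip(powers, powers[1:]))

    def test_invalid_settings(self):
        with pytest.raises(ValueError):
            required_sample_size(f=-1)
        with pytest.raises(ValueError):
            required_sample_size(power=1.5)


class TestMatching:
    def _words(self, n1=48, n2=48, shift=0.0, seed=12):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            dict(
                word_type=["moral"] * n1 + ["immoral"] * n2,
                moral_intensity=np.r_[rng.normal(3, 0.5, n1), rng.normal(3 + shift, 0.5, n2)],
                emotional_intensity=rng.normal(3, 0.5, n1 + n2),
                strokes=rng.integers(8, 25, n1 + n2).astype(float),
                frequency=rng.lognormal(1.5, 0.8, n1 + n2),
            )
        )

    def test_identical_groups(self):
        w = self._words()
        w.loc[w.word_type == "immoral", w.columns[1:]] = w.loc[
            w.word_type == "moral", w.columns[1:]
        ].to_numpy()
        res = match_stimuli_ttests(w)
        assert np.allclose(res["t"], 0.0) and np.allclose(res["cohens_d"], 0.0)

    def test_df_is_94_for_full_design(self):
        res = match_stimuli_ttests(self._words())
        assert (res["df"] == 94).all()

    def test_direct_formula_oracle(self):
        w = self._words(shift=0.4, seed=13)
        res = match_stimuli_ttests(w, covariates=("moral_intensity",)).iloc[0]
        # groups are ordered alphabetically: immoral first
        x = w.loc[w.word_type == "immoral", "moral_intensity"].to_numpy()
        y = w.loc[w.word_type == "moral", "moral_intensity"].to_numpy()
        sp2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / (x.size + y.size - 2)
        t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / x.size + 1 / y.size))
        assert res["t"] == pytest.approx(t, abs=1e-12)
        assert res["cohens_d"] == pytest.approx((x.mean() - y.mean()) / np.sqrt(sp2), abs=1e-12)
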