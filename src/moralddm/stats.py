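"""Behavioral statistics for the valence-evaluation design.

Covers everything outside the diffusion model itself: the intensity
transform and word selection used to build the stimulus set, trial
filtering, the 2x2 repeated-measures ANOVA with partial eta squared and
simple effects, paired t-tests with Benjamini-Hochberg FDR control,
Cronbach's alpha, stimulus-matching t-tests, and the noncentral-F power
computation for the within-subjects sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AnovaResult",
    "PairedTestResult",
    "intensity",
    "select_words",
    "assign_valence_levels",
    "filter_trials",
    "rm_anova_2x2",
    "simple_effects",
    "paired_t_fdr",
    "cronbach_alpha",
    "required_sample_size",
    "match_stimuli_ttests",
]


@dataclass
class EffectResult:
    F: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float


@dataclass
class AnovaResult:
    """2x2 within-subjects ANOVA: one :class:`EffectResult` per effect."""

    task: EffectResult
    word: EffectResult
    interaction: EffectResult

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("task", "word", "interaction"):
            e: EffectResult = getattr(self, name)
            rows.append(
                dict(effect=name, F=e.F, df1=e.df1, df2=e.df2, p=e.p, partial_eta_sq=e.partial_eta_sq)
            )
        return pd.DataFrame(rows)


@dataclass
class PairedTestResult:
    label: str
    t: float
    df: int
    p_raw: float
    p_fdr: float
    cohens_d: float


# ---------------------------------------------------------------------------
# stimulus-side operations
# ---------------------------------------------------------------------------


def intensity(score):
    """Valence intensity: distance of a 1-9 rating from the neutral midpoint 5.

    Maps both poles onto a common 0-4 scale so moral and immoral words
    can be compared on how extreme they are rather than which side of
    neutral they fall on.
    """
    score = np.asarray(score, dtype=float)
    if np.any((score < 1) | (score > 9)):
        raise ValueError("ratings must lie in [1, 9]")
    out = np.abs(score - 5.0)
    return float(out) if out.ndim == 0 else out


def select_words(words: pd.DataFrame, threshold: float = 2.0) -> pd.DataFrame:
    """Keep words whose intensity exceeds ``threshold`` on either dimension.

    ``words`` needs ``moral_rating`` and ``emotional_rating`` columns on
    the 1-9 scale.  The inequality is strict: a word sitting exactly at
    the threshold on both dimensions is dropped.
    """
    mi = intensity(words["moral_rating"].to_numpy())
    ei = intensity(words["emotional_rating"].to_numpy())
    keep = (mi > threshold) | (ei > threshold)
    return words.loc[keep].reset_index(drop=True)


#: populated (emotional_level, moral_level) cells of the 2x3 valence grid;
#: within each word type no word is simultaneously neutral on both
#: dimensions, and the extreme-mismatch combinations do not occur.
POPULATED_CELLS = ((1, 0), (0, 1), (1, 1), (2, 1), (1, 2), (2, 2))


def assign_valence_levels(
    words: pd.DataFrame, binning: str = "width"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each selected word a valence-group label like ``2V1M``.

    Intensity on each dimension is split into three levels (0 = low,
    1 = medium, 2 = high).  ``binning='width'`` (default) uses three
    equal-width bins over the observed intensity range of that
    dimension; ``binning='frequency'`` uses tertiles.  A word on an
    exact bin edge goes to the upper bin.

    Returns ``(labelled words, rejected words)`` where the second frame
    holds words whose level combination is not a populated cell of the
    design grid.
    """
    if len(words) == 0:
        raise ValueError("no words to assign")
    if binning not in ("width", "frequency"):
        raise ValueError(f"unknown binning {binning!r}")
    out = words.copy()
    levels = {}
    for dim, col in (("emotional", "emotional_rating"), ("moral", "moral_rating")):
        x = intensity(out[col].to_numpy())
        if binning == "width":
            lo, hi = float(np.min(x)), float(np.max(x))
            edges = np.array([lo + (hi - lo) / 3.0, lo + 2.0 * (hi - lo) / 3.0])
        else:
            edges = np.quantile(x, [1 / 3, 2 / 3])
        levels[dim] = np.searchsorted(edges, x, side="right")  # edge -> upper bin
    out["emotional_level"] = levels["emotional"]
    out["moral_level"] = levels["moral"]
    out["group"] = [f"{e}V{m}M" for e, m in zip(out["emotional_level"], out["moral_level"])]
    ok = np.array(
        [(e, m) in POPULATED_CELLS for e, m in zip(out["emotional_level"], out["moral_level"])]
    )
    return out.loc[ok].reset_index(drop=True), out.loc[~ok].reset_index(drop=True)


# ---------------------------------------------------------------------------
# trial filtering
# ---------------------------------------------------------------------------


def filter_trials(
    trials: pd.DataFrame, deadline_ms: float = 1600.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove timeout trials, then incorrect trials.

    A trial is a timeout if its ``timeout`` flag is set or its ``rt_ms``
    exceeds the deadline.  The exclusion report gives counts and
    percentages per task, with timeout percentages taken over all trials
    and error percentages over all trials (matching the convention of
    reporting each exclusion relative to the task's full trial count).
    The operation is idempotent: filtering a filtered table changes
    nothing.
    """
    t = trials.copy()
    is_timeout = t["timeout"].astype(bool) | (t["rt_ms"] > deadline_ms)
    after_to = t.loc[~is_timeout]
    is_error = ~after_to["correct"].astype(bool)
    kept = after_to.loc[~is_error].reset_index(drop=True)

    rows = []
    for task, sub in t.groupby("task", sort=True):
        n = len(sub)
        n_to = int((sub["timeout"].astype(bool) | (sub["rt_ms"] > deadline_ms)).sum())
        sub_ok = sub.loc[~(sub["timeout"].astype(bool) | (sub["rt_ms"] > deadline_ms))]
        n_err = int((~sub_ok["correct"].astype(bool)).sum())
        n_kept = n - n_to - n_err
        rows.append(
            dict(
                task=task,
                n_trials=n,
                n_timeout=n_to,
                pct_timeout=100.0 * n_to / n if n else 0.0,
                n_error=n_err,
                pct_error=100.0 * n_err / n if n else 0.0,
                n_kept=n_kept,
                pct_kept=100.0 * n_kept / n if n else 0.0,
            )
        )
    return kept, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------


def _cells_to_array(cell_means) -> np.ndarray:
    """participants x 4 array ordered (A1B1, A1B2, A2B1, A2B2)."""
    y = np.asarray(cell_means, dtype=float)
    if y.ndim != 2 or y.shape[1] != 4:
        raise ValueError("cell means must be participants x 4 (A1B1, A1B2, A2B1, A2B2)")
    if y.shape[0] < 2:
        raise ValueError("need at least two participants")
    if not np.all(np.isfinite(y)):
        raise ValueError("missing cells")
    return y


def rm_anova_2x2(cell_means) -> AnovaResult:
    """Two-way (2x2) fully within-subjects ANOVA with partial eta squared.

    ``cell_means`` is a participants x 4 array with columns ordered
    (A1B1, A1B2, A2B1, A2B2); factor A is the task, factor B the word
    type.  Each effect has one degree of freedom so sphericity is moot.
    Effects are tested against their own effect-by-subject interaction,
    and ``partial_eta_sq = SS_effect / (SS_effect + SS_error)``.
    """
    y = _cells_to_array(cell_means)
    n = y.shape[0]
    # contrast scores per participant: each 1-df within effect reduces to a
    # paired difference, F = t^2 against the matching subject interaction
    ca = (y[:, 0] + y[:, 1] - y[:, 2] - y[:, 3]) / 2.0  # A main effect
    cb = (y[:, 0] - y[:, 1] + y[:, 2] - y[:, 3]) / 2.0  # B main effect
    ci = (y[:, 0] - y[:, 1] - y[:, 2] + y[:, 3]) / 2.0  # A x B
    effects = {}
    for name, c in (("task", ca), ("word", cb), ("interaction", ci)):
        ss_eff = n * np.mean(c) ** 2
        ss_err = np.sum((c - np.mean(c)) ** 2)
        df1, df2 = 1, n - 1
        F = (ss_eff / df1) / (ss_err / df2) if ss_err > 0 else (0.0 if ss_eff == 0 else np.inf)
        p = float(sps.f.sf(F, df1, df2))
        pes = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        effects[name] = EffectResult(float(F), df1, df2, p, float(pes))
    return AnovaResult(**effects)


def simple_effects(cell_means, within: str, at: int) -> EffectResult:
    """One-way within-subject F for one factor at a fixed level of the other.

    ``within`` is ``'task'`` (factor A) or ``'word'`` (factor B);
    ``at`` is the level (0 or 1) of the other factor at which the effect
    is evaluated.  With two levels this equals the squared paired t.
    """
    y = _cells_to_array(cell_means)
    n = y.shape[0]
    cols = {
        ("word", 0): (0, 1),  # word effect within task level 0
        ("word", 1): (2, 3),
        ("task", 0): (0, 2),  # task effect within word level 0
        ("task", 1): (1, 3),
    }
    if (within, at) not in cols:
        raise ValueError(f"unknown simple effect ({within!r}, {at!r})")
    i, j = cols[(within, at)]
    d = y[:, i] - y[:, j]
    ss_eff = n * np.mean(d) ** 2
    ss_err = np.sum((d - np.mean(d)) ** 2)
    df1, df2 = 1, n - 1
    F = (ss_eff / df1) / (ss_err / df2) if ss_err > 0 else (0.0 if ss_eff == 0 else np.inf)
    p = float(sps.f.sf(F, df1, df2))
    pes = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
    return EffectResult(float(F), df1, df2, p, float(pes))


# ---------------------------------------------------------------------------
# paired t-tests with FDR
# ---------------------------------------------------------------------------


def paired_t_fdr(comparisons: dict[str, tuple[np.ndarray, np.ndarray]]) -> list[PairedTestResult]:
    """Two-sided paired t-tests with Benjamini-Hochberg FDR across the family.

    ``comparisons`` maps a label to a pair of equal-length vectors.
    Cohen's d is the mean difference over the SD of the differences.
    """
    labels, ts, dfs, ps, ds = [], [], [], [], []
    for label, (x, yv) in comparisons.items():
        x = np.asarray(x, dtype=float)
        yv = np.asarray(yv, dtype=float)
        if x.shape != yv.shape:
            raise ValueError(f"{label}: length mismatch {x.shape} vs {yv.shape}")
        if x.size < 2:
            raise ValueError(f"{label}: need at least two pairs")
        d = x - yv
        sd = np.std(d, ddof=1)
        if sd == 0:
            t, p = 0.0, 1.0
        else:
            t, p = sps.ttest_rel(x, yv)
        labels.append(label)
        ts.append(float(t))
        dfs.append(x.size - 1)
        ps.append(float(p))
        ds.append(float(np.mean(d) / sd) if sd > 0 else 0.0)
    _, p_fdr, _, _ = multipletests(ps, method="fdr_bh")
    return [
        PairedTestResult(label, t, df, p, float(pf), d)
        for label, t, df, p, pf, d in zip(labels, ts, dfs, ps, p_fdr, ds)
    ]


# ---------------------------------------------------------------------------
# reliability, power, matching
# ---------------------------------------------------------------------------


def cronbach_alpha(ratings) -> float:
    """Cronbach's alpha of a cases x items matrix.

    ``alpha = k/(k-1) * (1 - sum(item variances) / var(total score))``
    with ``k`` items (columns) and cases in rows.  For norming data the
    words are the items and the raters the cases.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 cases and 2 items")
    k = x.shape[1]
    item_var = np.var(x, axis=0, ddof=1)
    total_var = np.var(x.sum(axis=1), ddof=1)
    if total_var == 0:
        raise ValueError("zero total-score variance")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


def _rm_power(n: int, f: float, alpha: float, m: int, rho: float, eps: float) -> float:
    lam = f * f * n * m / (1.0 - rho)
    df1 = (m - 1) * eps
    df2 = (n - 1) * (m - 1) * eps
    crit = sps.f.isf(alpha, df1, df2)
    return float(sps.ncf.sf(crit, df1, df2, lam))


def required_sample_size(
    f: float = 0.25,
    alpha: float = 0.05,
    power: float = 0.85,
    m: int = 4,
    rho: float = 0.5,
    eps: float = 1.0,
) -> int:
    """Smallest n reaching the target power for a within-subjects RM ANOVA.

    Follows the repeated-measures, within-factors convention: the
    noncentrality is ``lambda = f^2 * n * m / (1 - rho)`` with ``m``
    repeated measurements, correlation ``rho`` among them and
    nonsphericity correction ``eps``; degrees of freedom are
    ``(m-1)*eps`` and ``(n-1)*(m-1)*eps``.
    """
    if f <= 0:
        raise ValueError("effect size must be positive")
    if not 0 < power < 1:
        raise ValueError("power must lie in (0, 1)")
    if m < 2:
        raise ValueError("need at least two measurements")
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    for n in range(2, 10001):
        if _rm_power(n, f, alpha, m, rho, eps) >= power:
            return n
    raise ValueError("infeasible settings: no n <= 10000 reaches the target power")


def match_stimuli_ttests(
    words: pd.DataFrame,
    covariates: tuple[str, ...] = ("moral_intensity", "emotional_intensity", "strokes", "frequency"),
    group_col: str = "word_type",
) -> pd.DataFrame:
    """Independent (pooled-variance) t-tests comparing word groups on covariates.

    With 48 + 48 words this yields df = 94.  Cohen's d uses the pooled
    standard deviation.
    """
    groups = sorted(words[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two word groups, got {groups}")
    g1 = words.loc[words[group_col] == groups[0]]
    g2 = words.loc[words[group_col] == groups[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least two words")
    rows = []
    for cov in covariates:
        x, yv = g1[cov].to_numpy(float), g2[cov].to_numpy(float)
        t, p = sps.ttest_ind(x, yv, equal_var=True)
        n1, n2 = x.size, yv.size
        sp = np.sqrt(((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(yv, ddof=1)) / (n1 + n2 - 2))
        d = (np.mean(x) - np.mean(yv)) / sp if sp > 0 else 0.0
        rows.append(dict(covariate=cov, t=float(t), df=n1 + n2 - 2, p=float(p), cohens_d=float(d)))
    return pd.DataFrame(rows)
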