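"""Hierarchical Bayesian estimation of the 12-group drift-diffusion model.

The generative model mirrors the study's parameter structure: each of
the 12 valence groups (2 word types x 6 populated valence cells) has its
own drift rate ``v``, boundary separation ``a`` and non-decision time
``tau`` at both group and participant level, while the relative starting
point ``z`` is shared across groups — one value per participant drawn
from a single group-level distribution.  The upper boundary codes the
"moral" response, so moral-word groups carry positive drift and
immoral-word groups negative drift.  The ``no_bias`` variant fixes
``z = 0.5`` everywhere, which is the comparison model for testing a
prior response bias.

Inference is blocked Metropolis-within-Gibbs: all participant-by-group
parameters of one family are proposed jointly and accepted cell-wise
(their full conditionals are independent given the group level), the
drift group means are conjugate Gibbs draws, and the remaining group
means and spreads use adaptive random-walk steps tuned during burn-in
only.  The contract is distributional correctness plus seeded
determinism, not a named algorithm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from .stats import POPULATED_CELLS
from .wiener import (
    DDMParams,
    _log_prob_before_cells,
    _loglik_batch,
    _loglik_batch_truncated,
    sample_trials_arrays,
)

__all__ = [
    "ModelSpec",
    "FitConfig",
    "Priors",
    "PosteriorChains",
    "DifferenceSummary",
    "HierarchicalDDM",
    "build_model",
    "sample_posterior",
    "diff_distribution",
    "dic",
    "posterior_predict",
]

#: canonical order of the 12 valence groups
GROUP_LABELS = tuple(
    f"{wt}_{e}V{m}M" for wt in ("moral", "immoral") for e, m in sorted(POPULATED_CELLS)
)

FAMILIES = ("v", "a", "t")  # participant x group parameter families


@dataclass(frozen=True)
class Priors:
    """Weakly-informative group-level priors.

    Defaults follow common hierarchical-DDM conventions so that fits are
    comparable with published ones: drift means are Normal(0, 2);
    boundary means Gamma(shape 1.5, rate 0.75) truncated above 0.3;
    non-decision means Uniform(0.05, deadline) — participant-level values
    are additionally bounded by each cell's fastest trial through the
    likelihood; the starting-point mean Beta(2, 2); all group spreads
    Half-Normal(1).
    """

    v_mu_sd: float = 2.0
    a_shape: float = 1.5
    a_rate: float = 0.75
    a_min: float = 0.3
    tau_lo: float = 0.05
    z_alpha: float = 2.0
    z_beta: float = 2.0
    sd_scale: float = 1.0


@dataclass
class FitConfig:
    """MCMC run configuration.

    Defaults are the full-scale profile (60,000 draws, 5,000 burn-in);
    the desk-scale test profile is 3,000 / 500.
    """

    n_samples: int = 60_000
    burn_in: int = 5_000
    seed: int = 0
    thinning: int = 1
    #: drop the likelihood entirely and sample the prior (validation aid)
    prior_only: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.burn_in < self.n_samples:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_samples")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class ModelSpec:
    """Structural description of the hierarchical model for one dataset."""

    groups: tuple[str, ...]
    participants: tuple
    variant: str
    priors: Priors
    task: str = "moral"
    include_errors: bool = False
    #: response deadline in seconds; when set, the likelihood of each kept
    #: trial is conditioned on absorption before the deadline (the data are
    #: truncated there), None disables the correction
    deadline_s: float | None = 1.6

    @property
    def free_group_parameters(self) -> list[str]:
        names = []
        for fam in FAMILIES:
            names += [f"{fam}_mu[{g}]" for g in self.groups]
            names += [f"{fam}_sd[{g}]" for g in self.groups]
        if self.variant == "bias":
            names += ["z_mu", "z_sd"]
        return names


@dataclass
class DifferenceSummary:
    """Summary of a posterior difference distribution (a - b).

    ``significant`` follows the decision rule that at least 95% of the
    difference mass must fall on one side of zero; draws exactly at zero
    are split half to each side.
    """

    mean: float
    pct_below_zero: float
    pct_above_zero: float
    significant: bool

    def __str__(self) -> str:
        star = " *" if self.significant else ""
        return (
            f"M = {self.mean:.2f}, {self.pct_below_zero:.1f}% < 0 < "
            f"{self.pct_above_zero:.1f}%{star}"
        )


@dataclass
class PosteriorChains:
    """Post-burn-in MCMC draws plus convergence diagnostics."""

    draws: dict[str, np.ndarray]
    deviance: np.ndarray
    diagnostics: pd.DataFrame
    burn_in: int
    thinning: int
    seed: int
    groups: tuple[str, ...]
    participants: tuple
    variant: str
    participant_mean: dict[str, np.ndarray]
    participant_draws: dict[str, np.ndarray]
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return next(iter(self.draws.values())).size

    def to_frame(self) -> pd.DataFrame:
        """Long-format draws (parameter, chain, iteration, value)."""
        frames = []
        for name, x in self.draws.items():
            frames.append(
                pd.DataFrame(
                    dict(parameter=name, chain=0, iteration=np.arange(x.size), value=x)
                )
            )
        return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


@dataclass
class _Prepared:
    rt: np.ndarray          # seconds
    upper: np.ndarray       # bool
    p_idx: np.ndarray
    g_idx: np.ndarray
    pg_idx: np.ndarray
    participants: tuple
    groups: tuple[str, ...]
    rt_min: float

    @property
    def n_participants(self) -> int:
        return len(self.participants)

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def _prepare(dataset: pd.DataFrame, task: str, include_errors: bool) -> _Prepared:
    d = dataset
    if "task" in d.columns:
        d = d.loc[d["task"] == task]
    d = d.loc[~d["timeout"].astype(bool)] if "timeout" in d.columns else d
    if not include_errors and "correct" in d.columns:
        d = d.loc[d["correct"].astype(bool)]
    if len(d) == 0:
        raise ValueError(f"no usable trials for task {task!r}")
    labels = d["word_type"].astype(str) + "_" + d["group"].astype(str)
    unknown = set(labels) - set(GROUP_LABELS)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    missing = set(GROUP_LABELS) - set(labels)
    if missing:
        raise ValueError(
            f"dataset must populate all 12 valence groups; missing {sorted(missing)}"
        )
    participants = tuple(sorted(d["participant_id"].unique()))
    if len(participants) < 2:
        raise ValueError("need at least two participants for a hierarchical fit")
    p_map = {p: i for i, p in enumerate(participants)}
    g_map = {g: i for i, g in enumerate(GROUP_LABELS)}
    p_idx = d["participant_id"].map(p_map).to_numpy(np.int64)
    g_idx = labels.map(g_map).to_numpy(np.int64)
    rt = d["rt_ms"].to_numpy(float) / 1000.0
    upper = (d["response"] == "upper").to_numpy(bool)
    return _Prepared(
        rt=rt,
        upper=upper,
        p_idx=p_idx,
        g_idx=g_idx,
        pg_idx=p_idx * len(GROUP_LABELS) + g_idx,
        participants=participants,
        groups=GROUP_LABELS,
        rt_min=float(rt.min()),
    )


def build_model(
    dataset: pd.DataFrame,
    variant: str = "bias",
    task: str = "moral",
    include_errors: bool = False,
    priors: Priors | None = None,
    deadline_ms: float | None = 1600.0,
) -> ModelSpec:
    """Build the hierarchical specification for a trial table.

    Participant-level (v, a, tau) per group are drawn from group-level
    distributions; the likelihood of each trial is the defective
    first-passage density of its response boundary.  ``variant='bias'``
    estimates the shared starting point, ``'no_bias'`` fixes it at 0.5.
    """
    if variant not in ("bias", "no_bias"):
        raise ValueError(f"variant must be 'bias' or 'no_bias', got {variant!r}")
    prep = _prepare(dataset, task, include_errors)
    return ModelSpec(
        groups=prep.groups,
        participants=prep.participants,
        variant=variant,
        priors=priors or Priors(),
        task=task,
        include_errors=include_errors,
        deadline_s=deadline_ms / 1000.0 if deadline_ms else None,
    )


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _log_normal(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd) - _LOG_SQRT_2PI


def _ez_init(prep: _Prepared) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Method-of-moments (EZ-style) start values per participant and group.

    Maps each cell's accuracy, RT mean and RT variance to closed-form
    (v, a, tau) for an unbiased two-boundary diffusion; the drift sign
    follows the word type.  Used only to start the chains near the bulk
    of the posterior — the estimates themselves are never reported.
    """
    P, G = prep.n_participants, prep.n_groups
    v = np.zeros((P, G))
    a = np.full((P, G), 1.5)
    t = np.zeros((P, G))
    sign = np.array([1.0 if g.startswith("moral") else -1.0 for g in prep.groups])
    for p in range(P):
        for j in range(G):
            sel = (prep.p_idx == p) & (prep.g_idx == j)
            n = int(sel.sum())
            rt = prep.rt[sel]
            if n < 2 or rt.var() <= 0:
                v[p, j] = sign[j] * 2.0
                t[p, j] = max(0.05, (rt.min() if n else prep.rt_min) - 0.15)
                continue
            corr = prep.upper[sel] == (sign[j] > 0)
            pc = np.clip(corr.mean(), 0.5 + 1.0 / (2 * n), 1.0 - 1.0 / (2 * n))
            L = math.log(pc / (1.0 - pc))
            x = L * (L * pc * pc - L * pc + pc - 0.5) / rt.var()
            vv = max(x, 1e-6) ** 0.25
            aa = float(np.clip(L / vv, 0.5, 4.0))
            vv = float(np.clip(vv, 0.3, 6.0))
            mdt = (aa / (2.0 * vv)) * (1.0 - math.exp(-vv * aa)) / (1.0 + math.exp(-vv * aa))
            v[p, j] = sign[j] * vv
            a[p, j] = aa
            t[p, j] = float(np.clip(rt.mean() - mdt, 0.05, rt.min() - 0.01))
    return v, a, t


class _Sampler:
    """Internal MCMC engine; one instance per fit."""

    # initial random-walk scales, adapted during burn-in; keys ending in a
    # family letter are per-group vectors, the z-related ones scalars
    _INIT_SCALES = dict(
        v=0.35, a=0.12, t=0.02, mu_a=0.06, mu_t=0.015,
        loc_v=0.15, loc_a=0.08, loc_t=0.01,
        scl_v=0.25, scl_a=0.25, scl_t=0.25,
        lsd_v=0.35, lsd_a=0.35, lsd_t=0.35,
        z=0.04, mu_z=0.03, loc_z=0.03, scl_z=0.25, lsd_z=0.35,
    )
    _SCALAR_KEYS = ("z", "mu_z", "loc_z", "scl_z", "lsd_z")

    def __init__(self, model: ModelSpec, prep: _Prepared, config: FitConfig):
        self.model = model
        self.prep = prep
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.P, self.G = prep.n_participants, prep.n_groups
        # upper support of the non-decision group-mean prior: the deadline.
        # Bounding it by the fastest single trial instead would clamp the
        # group mean below every participant's non-decision time and bias
        # tau (and through it a) downward; participant-level tau is already
        # bounded by each cell's fastest RT through the likelihood.
        self.tau_hi = model.deadline_s if model.deadline_s is not None else float(np.max(prep.rt))
        self.tol = 1e-7
        self._init_state()

    # -- state ------------------------------------------------------------

    def _init_state(self):
        P, G = self.P, self.G
        prep = self.prep
        self.v, self.a, self.t = _ez_init(prep)
        self.z = np.full(P, 0.5)
        self.mu = {
            "v": self.v.mean(axis=0),
            "a": self.a.mean(axis=0),
            "t": self.t.mean(axis=0),
        }
        self.sd = {
            f: np.clip(getattr(self, f).std(axis=0), 0.05, 1.0) for f in FAMILIES
        }
        self.mu_z, self.sd_z = 0.5, 0.1
        self.scales = {
            k: (v0 if k in self._SCALAR_KEYS else np.full(G, v0))
            for k, v0 in self._INIT_SCALES.items()
        }
        self.acc = {
            k: [0.0 if k in self._SCALAR_KEYS else np.zeros(G), 0]
            for k in self._INIT_SCALES
        }
        self.counts_pg = np.bincount(prep.pg_idx, minlength=P * G).reshape(P, G).astype(float)
        self.ll_pg = self._cell_loglik(self.v, self.a, self.t, self.z)

    def _cell_loglik(self, v, a, t, z):
        """Summed trial log-density per (participant, group) cell.

        The deadline-truncation normalizer depends only on the cell's
        parameters, so it is evaluated once per cell and weighted by the
        cell's trial count rather than per trial.
        """
        if self.config.prior_only:
            return np.zeros((self.P, self.G))
        prep = self.prep
        pg, p = prep.pg_idx, prep.p_idx
        ll = _loglik_batch(
            prep.rt, prep.upper, v.ravel()[pg], a.ravel()[pg], z[p], t.ravel()[pg], self.tol
        )
        out = np.bincount(pg, weights=ll, minlength=self.P * self.G).reshape(self.P, self.G)
        dl = self.model.deadline_s
        if dl is not None:
            w_cell = np.repeat(z, self.G)
            lpb = _log_prob_before_cells(
                v.ravel(), a.ravel(), w_cell, t.ravel(), dl, self.tol
            ).reshape(self.P, self.G)
            out -= self.counts_pg * lpb
        return out

    # -- update blocks ----------------------------------------------------

    def _update_family(self, fam: str):
        """Joint proposal over all participant-by-group values of one family."""
        cur = getattr(self, fam)
        prop = cur + self.scales[fam][None, :] * self.rng.standard_normal(cur.shape)
        args = {f: getattr(self, f) for f in FAMILIES}
        args[fam] = prop
        ll_prop = self._cell_loglik(args["v"], args["a"], args["t"], self.z)
        mu, sd = self.mu[fam], self.sd[fam]
        logr = (
            ll_prop
            - self.ll_pg
            + _log_normal(prop, mu[None, :], sd[None, :])
            - _log_normal(cur, mu[None, :], sd[None, :])
        )
        acc = np.log(self.rng.random(cur.shape)) < logr
        cur[acc] = prop[acc]
        self.ll_pg[acc] = ll_prop[acc]
        self.acc[fam][0] += acc.sum(axis=0)
        self.acc[fam][1] += acc.shape[0]

    def _update_z(self):
        prop = self.z + self.scales["z"] * self.rng.standard_normal(self.P)
        ok = (prop > 0.02) & (prop < 0.98)
        ll_prop_pg = self._cell_loglik(self.v, self.a, self.t, prop)
        ll_prop = ll_prop_pg.sum(axis=1)
        ll_cur = self.ll_pg.sum(axis=1)
        logr = (
            ll_prop
            - ll_cur
            + _log_normal(prop, self.mu_z, self.sd_z)
            - _log_normal(self.z, self.mu_z, self.sd_z)
        )
        logr[~ok] = -np.inf
        acc = np.log(self.rng.random(self.P)) < logr
        self.z[acc] = prop[acc]
        self.ll_pg[acc, :] = ll_prop_pg[acc, :]
        self.acc["z"][0] += float(acc.mean())
        self.acc["z"][1] += 1

    def _update_location(self, fam: str):
        """Shift a whole group (participant values + group mean) jointly.

        The participant-level prior is translation invariant, so the
        ratio reduces to the likelihood change times the group-mean
        prior ratio; this moves the hierarchy through directions the
        single-site updates mix slowly along.
        """
        key = f"loc_{fam}"
        x = getattr(self, fam)
        mu = self.mu[fam]
        delta = self.scales[key] * self.rng.standard_normal(self.G)
        prop_x = x + delta[None, :]
        prop_mu = mu + delta
        args = {f: getattr(self, f) for f in FAMILIES}
        args[fam] = prop_x
        ll_prop_pg = self._cell_loglik(args["v"], args["a"], args["t"], self.z)
        if fam == "v":
            pr_ratio = _log_normal(prop_mu, 0.0, self.model.priors.v_mu_sd) - _log_normal(
                mu, 0.0, self.model.priors.v_mu_sd
            )
        else:
            pr_ratio = self._log_prior_mu(fam, prop_mu) - self._log_prior_mu(fam, mu)
        logr = ll_prop_pg.sum(axis=0) - self.ll_pg.sum(axis=0) + pr_ratio
        acc = np.log(self.rng.random(self.G)) < logr
        x[:, acc] = prop_x[:, acc]
        mu[acc] = prop_mu[acc]
        self.ll_pg[:, acc] = ll_prop_pg[:, acc]
        self.acc[key][0] += acc.astype(float)
        self.acc[key][1] += 1

    def _update_scale(self, fam: str):
        """Rescale a group's deviations and spread jointly (funnel move).

        With x' = mu + c (x - mu) and sd' = c sd, the participant-prior
        terms cancel against the Jacobian except for a single factor c,
        so the ratio is the likelihood change times c times the spread-
        prior ratio.  This lets the chain escape the sd -> 0 funnel that
        traps centered hierarchical samplers.
        """
        key = f"scl_{fam}"
        x = getattr(self, fam)
        mu, sd = self.mu[fam], self.sd[fam]
        eps = self.scales[key] * self.rng.standard_normal(self.G)
        c = np.exp(eps)
        prop_x = mu[None, :] + c[None, :] * (x - mu[None, :])
        prop_sd = c * sd
        args = {f: getattr(self, f) for f in FAMILIES}
        args[fam] = prop_x
        ll_prop_pg = self._cell_loglik(args["v"], args["a"], args["t"], self.z)
        pr = self.model.priors
        logr = (
            ll_prop_pg.sum(axis=0)
            - self.ll_pg.sum(axis=0)
            + eps
            - 0.5 * (prop_sd**2 - sd**2) / pr.sd_scale**2
        )
        acc = np.log(self.rng.random(self.G)) < logr
        x[:, acc] = prop_x[:, acc]
        sd[acc] = prop_sd[acc]
        self.ll_pg[:, acc] = ll_prop_pg[:, acc]
        self.acc[key][0] += acc.astype(float)
        self.acc[key][1] += 1

    def _update_z_joint(self):
        """Location and scale moves for the shared starting point."""
        pr = self.model.priors
        # location: shift all z and mu_z
        delta = self.scales["loc_z"] * self.rng.standard_normal()
        prop_z = self.z + delta
        prop_mu = self.mu_z + delta
        if 0.0 < prop_mu < 1.0 and np.all((prop_z > 0.02) & (prop_z < 0.98)):
            ll_prop_pg = self._cell_loglik(self.v, self.a, self.t, prop_z)
            logr = (
                ll_prop_pg.sum()
                - self.ll_pg.sum()
                + (pr.z_alpha - 1.0) * (math.log(prop_mu) - math.log(self.mu_z))
                + (pr.z_beta - 1.0) * (math.log1p(-prop_mu) - math.log1p(-self.mu_z))
            )
            if math.log(self.rng.random()) < logr:
                self.z = prop_z
                self.mu_z = prop_mu
                self.ll_pg = ll_prop_pg
                self.acc["loc_z"][0] += 1.0
        self.acc["loc_z"][1] += 1
        # scale: rescale deviations and sd_z
        eps = self.scales["scl_z"] * self.rng.standard_normal()
        c = math.exp(eps)
        prop_z = self.mu_z + c * (self.z - self.mu_z)
        prop_sd = c * self.sd_z
        if np.all((prop_z > 0.02) & (prop_z < 0.98)):
            ll_prop_pg = self._cell_loglik(self.v, self.a, self.t, prop_z)
            logr = (
                ll_prop_pg.sum()
                - self.ll_pg.sum()
                + eps
                - 0.5 * (prop_sd**2 - self.sd_z**2) / pr.sd_scale**2
            )
            if math.log(self.rng.random()) < logr:
                self.z = prop_z
                self.sd_z = prop_sd
                self.ll_pg = ll_prop_pg
                self.acc["scl_z"][0] += 1.0
        self.acc["scl_z"][1] += 1

    def _log_prior_mu(self, fam: str, x: np.ndarray) -> np.ndarray:
        pr = self.model.priors
        if fam == "a":
            out = np.where(
                x > pr.a_min, (pr.a_shape - 1.0) * np.log(np.maximum(x, 1e-12)) - pr.a_rate * x, -np.inf
            )
            return out
        if fam == "t":
            return np.where((x > pr.tau_lo) & (x < self.tau_hi), 0.0, -np.inf)
        raise KeyError(fam)

    def _update_group_level(self):
        P = self.P
        pr = self.model.priors
        # drift means: Normal-Normal conjugate Gibbs
        prec = P / self.sd["v"] ** 2 + 1.0 / pr.v_mu_sd**2
        mean = (self.v.sum(axis=0) / self.sd["v"] ** 2) / prec
        self.mu["v"] = mean + self.rng.standard_normal(self.G) / np.sqrt(prec)
        # boundary / non-decision means: vectorized random walk
        for fam, key in (("a", "mu_a"), ("t", "mu_t")):
            cur = self.mu[fam]
            prop = cur + self.scales[key] * self.rng.standard_normal(self.G)
            x = getattr(self, fam)
            logr = (
                _log_normal(x, prop[None, :], self.sd[fam][None, :]).sum(axis=0)
                - _log_normal(x, cur[None, :], self.sd[fam][None, :]).sum(axis=0)
                + self._log_prior_mu(fam, prop)
                - self._log_prior_mu(fam, cur)
            )
            acc = np.log(self.rng.random(self.G)) < logr
            cur[acc] = prop[acc]
            self.acc[key][0] += acc.astype(float)
            self.acc[key][1] += 1
        # spreads: random walk on log sd, Half-Normal prior + Jacobian
        for fam in FAMILIES:
            cur = self.sd[fam]
            prop = cur * np.exp(self.scales[f"lsd_{fam}"] * self.rng.standard_normal(self.G))
            x = getattr(self, fam)
            mu = self.mu[fam]
            logr = (
                _log_normal(x, mu[None, :], prop[None, :]).sum(axis=0)
                - _log_normal(x, mu[None, :], cur[None, :]).sum(axis=0)
                - 0.5 * (prop**2 - cur**2) / pr.sd_scale**2
                + np.log(prop / cur)
            )
            acc = np.log(self.rng.random(self.G)) < logr
            cur[acc] = prop[acc]
            self.acc[f"lsd_{fam}"][0] += acc.astype(float)
            self.acc[f"lsd_{fam}"][1] += 1
        if self.model.variant == "bias":
            self._update_z_group()

    def _update_z_group(self):
        pr = self.model.priors
        # z group mean (Beta prior)
        cur = self.mu_z
        prop = cur + self.scales["mu_z"] * self.rng.standard_normal()
        if 0.0 < prop < 1.0:
            logr = (
                _log_normal(self.z, prop, self.sd_z).sum()
                - _log_normal(self.z, cur, self.sd_z).sum()
                + (pr.z_alpha - 1.0) * (math.log(prop) - math.log(cur))
                + (pr.z_beta - 1.0) * (math.log1p(-prop) - math.log1p(-cur))
            )
            if math.log(self.rng.random()) < logr:
                self.mu_z = prop
                self.acc["mu_z"][0] += 1.0
        self.acc["mu_z"][1] += 1
        # z group spread
        cur = self.sd_z
        prop = cur * math.exp(self.scales["lsd_z"] * self.rng.standard_normal())
        logr = (
            _log_normal(self.z, self.mu_z, prop).sum()
            - _log_normal(self.z, self.mu_z, cur).sum()
            - 0.5 * (prop**2 - cur**2) / pr.sd_scale**2
            + math.log(prop / cur)
        )
        if math.log(self.rng.random()) < logr:
            self.sd_z = prop

    def _adapt(self):
        for key, (na, nt) in self.acc.items():
            if nt == 0:
                continue
            rate = na / nt
            init = self._INIT_SCALES[key]
            self.scales[key] = np.clip(
                self.scales[key] * np.exp(rate - 0.35), init / 100.0, init * 30.0
            )
            self.acc[key] = [0.0 if key in self._SCALAR_KEYS else np.zeros(self.G), 0]

    # -- main loop ---------------------------------------------------------

    def run(self) -> PosteriorChains:
        cfg = self.config
        kept = (cfg.n_samples - cfg.burn_in + cfg.thinning - 1) // cfg.thinning
        rec = {}
        for fam in FAMILIES:
            for g in self.prep.groups:
                rec[f"{fam}_mu[{g}]"] = np.empty(kept)
                rec[f"{fam}_sd[{g}]"] = np.empty(kept)
        if self.model.variant == "bias":
            rec["z_mu"] = np.empty(kept)
            rec["z_sd"] = np.empty(kept)
        deviance = np.empty(kept)
        pmean = {f: np.zeros((self.P, self.G)) for f in FAMILIES}
        pmean["z"] = np.zeros(self.P)
        n_mean = 0
        n_store = max(1, kept // 200)
        pdraws = {f: [] for f in ("v", "a", "t", "z")}

        k = 0
        for it in range(cfg.n_samples):
            for fam in FAMILIES:
                self._update_family(fam)
                self._update_location(fam)
                self._update_scale(fam)
            if self.model.variant == "bias":
                self._update_z()
                self._update_z_joint()
            # group-level conditionals cost no likelihood passes; iterating
            # them decorrelates the hierarchy faster than one pass per sweep
            for _ in range(3):
                self._update_group_level()
            if it < cfg.burn_in:
                if (it + 1) % 25 == 0:
                    self._adapt()
                continue
            # running means over every post-burn-in sweep
            for f in FAMILIES:
                pmean[f] += getattr(self, f)
            pmean["z"] += self.z
            n_mean += 1
            if (it - cfg.burn_in) % cfg.thinning:
                continue
            for fam in FAMILIES:
                for j, g in enumerate(self.prep.groups):
                    rec[f"{fam}_mu[{g}]"][k] = self.mu[fam][j]
                    rec[f"{fam}_sd[{g}]"][k] = self.sd[fam][j]
            if self.model.variant == "bias":
                rec["z_mu"][k] = self.mu_z
                rec["z_sd"][k] = self.sd_z
            deviance[k] = -2.0 * self.ll_pg.sum()
            if k % n_store == 0:
                for f in FAMILIES:
                    pdraws[f].append(getattr(self, f).copy())
                pdraws["z"].append(self.z.copy())
            k += 1

        for f in pmean:
            pmean[f] /= n_mean
        chains = PosteriorChains(
            draws=rec,
            deviance=deviance,
            diagnostics=_diagnose(rec),
            burn_in=cfg.burn_in,
            thinning=cfg.thinning,
            seed=cfg.seed,
            groups=self.prep.groups,
            participants=self.prep.participants,
            variant=self.model.variant,
            participant_mean=pmean,
            participant_draws={f: np.array(v) for f, v in pdraws.items()},
        )
        bad = chains.diagnostics.loc[chains.diagnostics["rhat"] > 1.1, "parameter"].tolist()
        if bad:
            msg = f"possible non-convergence (R-hat > 1.1): {', '.join(bad[:8])}"
            chains.warnings.append(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
        return chains


def _diagnose(rec: dict[str, np.ndarray], n_segments: int = 4) -> pd.DataFrame:
    """Split-chain R-hat, effective sample size and autocorrelation."""
    rows = []
    for name, x in rec.items():
        L = (x.size // n_segments) * n_segments
        seg = x[:L].reshape(n_segments, -1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat = float(az.rhat(seg))
            ess = float(az.ess(seg))
            ac1 = float(az.autocorr(x)[1]) if x.size > 1 else np.nan
        if not np.isfinite(rhat):  # a frozen chain segment: flag, don't hide
            rhat, ess = np.inf, 0.0
        rows.append(dict(parameter=name, rhat=rhat, ess=ess, autocorr_lag1=ac1))
    return pd.DataFrame(rows)


def sample_posterior(
    model: ModelSpec, data: pd.DataFrame, config: FitConfig
) -> PosteriorChains:
    """Draw from the joint posterior of the hierarchical model.

    Deterministic under a fixed ``config.seed``; burn-in is discarded
    and diagnostics (split R-hat, ESS, autocorrelation) are attached.
    Non-convergence (R-hat > 1.1 on a group-level parameter) is flagged
    in ``chains.warnings`` and as a ``RuntimeWarning``, never silent.
    """
    prep = _prepare(data, model.task, model.include_errors)
    if tuple(prep.participants) != tuple(model.participants):
        raise ValueError("dataset participants do not match the model specification")
    return _Sampler(model, prep, config).run()


# ---------------------------------------------------------------------------
# posterior inference
# ---------------------------------------------------------------------------


def diff_distribution(samples_a: np.ndarray, samples_b: np.ndarray) -> DifferenceSummary:
    """Summarize the element-wise posterior difference ``a - b``.

    Reports the mean and the percentages of the difference distribution
    below and above zero; the comparison is significant when at least
    95% of the mass falls on one side.
    """
    a = np.asarray(samples_a, float)
    b = np.asarray(samples_b, float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    d = a - b
    ties = float(np.mean(d == 0.0))
    below = float(np.mean(d < 0.0)) + 0.5 * ties
    above = 1.0 - below
    return DifferenceSummary(
        mean=float(d.mean()),
        pct_below_zero=100.0 * below,
        pct_above_zero=100.0 * above,
        significant=max(below, above) >= 0.95,
    )


def dic(model: ModelSpec, chains: PosteriorChains, data: pd.DataFrame) -> float:
    """Deviance information criterion, DIC = D-bar + p_D (lower is better).

    ``D-bar`` is the posterior mean deviance over the stored draws and
    ``p_D = D-bar - D(theta-bar)`` the effective number of parameters,
    with the deviance evaluated at the posterior mean of all
    participant-level parameters.
    """
    if not np.all(np.isfinite(chains.deviance)):
        raise ValueError("non-finite deviance draw in chains")
    prep = _prepare(data, model.task, model.include_errors)
    d_bar = float(chains.deviance.mean())
    pm = chains.participant_mean
    pg, p = prep.pg_idx, prep.p_idx
    args = (
        prep.rt,
        prep.upper,
        pm["v"].ravel()[pg],
        pm["a"].ravel()[pg],
        pm["z"][p],
        pm["t"].ravel()[pg],
    )
    if model.deadline_s is not None:
        ll = _loglik_batch_truncated(*args, model.deadline_s, 1e-7)
    else:
        ll = _loglik_batch(*args, 1e-7)
    d_hat = -2.0 * float(ll.sum())
    return d_bar + (d_bar - d_hat)


def posterior_predict(
    model: ModelSpec,
    chains: PosteriorChains,
    data: pd.DataFrame,
    n_rep: int = 100,
    seed: int = 0,
    dt: float = 1e-3,
    quantiles: tuple[float, ...] = (0.1, 0.3, 0.5, 0.7, 0.9),
) -> pd.DataFrame:
    """Posterior predictive check of RT quantiles and choice proportions.

    Simulates ``n_rep`` replicate datasets (matching the observed trial
    counts per participant and group) from stored posterior draws,
    summarizes each group by its correct-response RT quantiles and
    upper-boundary choice proportion, and reports 95% predictive
    intervals together with flags marking whether the observed
    statistics are covered.
    """
    if n_rep <= 0:
        raise ValueError("n_rep must be positive")
    prep = _prepare(data, model.task, model.include_errors)
    rng = np.random.default_rng(seed)
    P, G = prep.n_participants, prep.n_groups
    counts = np.bincount(prep.pg_idx, minlength=P * G).reshape(P, G)
    n_draws = chains.participant_draws["v"].shape[0]

    def summarize(rt_by_g, upper_by_g):
        rows = {}
        for j, g in enumerate(prep.groups):
            rts = np.asarray(rt_by_g[j])
            ups = np.asarray(upper_by_g[j])
            corr = ups if g.startswith("moral") else ~ups
            q = (
                np.quantile(rts[corr], quantiles)
                if corr.any()
                else np.full(len(quantiles), np.nan)
            )
            rows[g] = (q, float(ups.mean()) if ups.size else np.nan)
        return rows

    obs_rt = [prep.rt[prep.g_idx == j] for j in range(G)]
    obs_up = [prep.upper[prep.g_idx == j] for j in range(G)]
    obs = summarize(obs_rt, obs_up)

    sims = {g: [] for g in prep.groups}
    for r in range(n_rep):
        di = int(rng.integers(0, n_draws))
        v = chains.participant_draws["v"][di]
        a = chains.participant_draws["a"][di]
        t = chains.participant_draws["t"][di]
        z = chains.participant_draws["z"][di]
        rt_by_g = [[] for _ in range(G)]
        up_by_g = [[] for _ in range(G)]
        for p in range(P):
            for j in range(G):
                n = int(counts[p, j])
                if n == 0:
                    continue
                params = DDMParams(v=v[p, j], a=a[p, j], z_rel=float(np.clip(z[p], 0.02, 0.98)), tau=t[p, j])
                up, rt = sample_trials_arrays(params, n, seed=int(rng.integers(0, 2**31 - 1)), dt=dt)
                if model.deadline_s is not None:
                    keep = rt <= model.deadline_s
                    up, rt = up[keep], rt[keep]
                rt_by_g[j].append(rt)
                up_by_g[j].append(up)
        rep = summarize(
            [np.concatenate(x) if x else np.empty(0) for x in rt_by_g],
            [np.concatenate(x) if x else np.empty(0, bool) for x in up_by_g],
        )
        for g in prep.groups:
            sims[g].append(rep[g])

    rows = []
    for g in prep.groups:
        qs = np.array([s[0] for s in sims[g]])  # n_rep x n_quantiles
        ps = np.array([s[1] for s in sims[g]])
        q_lo, q_hi = np.nanquantile(qs, 0.025, axis=0), np.nanquantile(qs, 0.975, axis=0)
        p_lo, p_hi = np.nanquantile(ps, 0.025), np.nanquantile(ps, 0.975)
        oq, op = obs[g]
        for qi, qq in enumerate(quantiles):
            rows.append(
                dict(
                    group=g,
                    stat=f"rt_q{int(qq * 100)}",
                    observed=oq[qi],
                    pred_lo=q_lo[qi],
                    pred_hi=q_hi[qi],
                    covered=bool(q_lo[qi] <= oq[qi] <= q_hi[qi]),
                )
            )
        rows.append(
            dict(group=g, stat="p_upper", observed=op, pred_lo=p_lo, pred_hi=p_hi,
                 covered=bool(p_lo <= op <= p_hi))
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sklearn-style estimator
# ---------------------------------------------------------------------------

from sklearn.base import BaseEstimator  # noqa: E402


class HierarchicalDDM(BaseEstimator):
    """Hierarchical Bayesian drift-diffusion estimator (sklearn-style).

    Fits the 12-group model to a canonical trial table.  Defaults use
    the desk-scale MCMC profile (3,000 draws / 500 burn-in); pass
    ``draws=60000, burn_in=5000`` for the full-scale profile.

    Parameters
    ----------
    variant : {'bias', 'no_bias'}
        Whether the shared starting point is estimated or fixed at 0.5.
    draws, burn_in, thinning : int
        MCMC schedule.
    seed : int
        Sampler seed; fits are bit-identical under a fixed seed.
    task : str
        Which task's trials to fit (default the moral-evaluation task).
    include_errors : bool
        Fit all response trials instead of correct responses only.

    Attributes
    ----------
    chains_ : PosteriorChains
    diagnostics_ : pandas.DataFrame
    dic_ : float
    groups_ : tuple of the 12 group labels
    """

    def __init__(
        self,
        variant: str = "bias",
        draws: int = 3000,
        burn_in: int = 500,
        thinning: int = 1,
        seed: int = 0,
        task: str = "moral",
        include_errors: bool = False,
        deadline_ms: float | None = 1600.0,
    ):
        self.variant = variant
        self.draws = draws
        self.burn_in = burn_in
        self.thinning = thinning
        self.seed = seed
        self.task = task
        self.include_errors = include_errors
        self.deadline_ms = deadline_ms

    def fit(self, X: pd.DataFrame, y=None) -> "HierarchicalDDM":
        self.model_ = build_model(
            X,
            variant=self.variant,
            task=self.task,
            include_errors=self.include_errors,
            deadline_ms=self.deadline_ms,
        )
        config = FitConfig(
            n_samples=self.draws, burn_in=self.burn_in, seed=self.seed, thinning=self.thinning
        )
        self.chains_ = sample_posterior(self.model_, X, config)
        self.diagnostics_ = self.chains_.diagnostics
        self.dic_ = dic(self.model_, self.chains_, X)
        self.groups_ = self.chains_.groups
        return self

    def group_posterior_mean(self, family: str = "v") -> pd.Series:
        """Posterior mean of a group-level mean parameter per group."""
        self._check_fitted()
        return pd.Series(
            {g: float(self.chains_.draws[f"{family}_mu[{g}]"].mean()) for g in self.groups_}
        )

    def diff(self, family: str, group_a: str, group_b: str) -> DifferenceSummary:
        """Posterior difference of a group-level mean between two groups."""
        self._check_fitted()
        return diff_distribution(
            self.chains_.draws[f"{family}_mu[{group_a}]"],
            self.chains_.draws[f"{family}_mu[{group_b}]"],
        )

    def predictive_check(self, X: pd.DataFrame, n_rep: int = 100, seed: int = 0) -> pd.DataFrame:
        self._check_fitted()
        return posterior_predict(self.model_, self.chains_, X, n_rep=n_rep, seed=seed)

    def _check_fitted(self):
        if not hasattr(self, "chains_"):
            raise AttributeError("estimator is not fitted; call fit() first")
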