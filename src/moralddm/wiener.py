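"""Two-boundary Wiener diffusion: first-passage densities, absorption
probabilities, forward simulation and trial likelihoods.

The decision process is a Brownian motion with drift ``v`` and unit
diffusion coefficient started at ``z = z_rel * a`` between absorbing
boundaries at 0 (lower) and ``a`` (upper).  A response is emitted when
the process is absorbed; the observed response time is the absorption
time plus a non-decision offset ``tau``.

The first-passage density at one boundary is *defective*: it integrates
to that boundary's choice probability, not to one.  Two series
expansions of the density exist — one that converges quickly for large
scaled time and one for small scaled time — and the evaluator switches
between them by comparing the number of terms each needs to reach the
requested truncation error (the standard small-/large-time selection
rule for this density).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from numba import njit

__all__ = [
    "DDMParams",
    "Choice",
    "prob_upper",
    "fpt_density",
    "fpt_cdf",
    "sample_trials",
    "loglik_trials",
]


class Choice(Enum):
    """Absorbing boundary of a response.

    In the moral-evaluation task the upper boundary codes a "moral"
    response and the lower boundary an "immoral" response; in the
    emotional task the same geometry codes "positive" vs "negative".
    """

    upper = "upper"
    lower = "lower"


@dataclass(frozen=True)
class DDMParams:
    """Parameters of one diffusion process.

    Attributes
    ----------
    v : float
        Drift rate (evidence units per second, signed; positive drives
        toward the upper boundary).
    a : float
        Boundary separation (upper boundary at ``a``, lower at 0).
    z_rel : float
        Relative starting point in (0, 1); absolute start ``z = z_rel * a``.
    tau : float
        Non-decision time in seconds (encoding + motor latency).

    The diffusion coefficient is fixed at ``s = 1``, the convention of
    hierarchical DDM software; it is not configurable.
    """

    v: float
    a: float
    z_rel: float
    tau: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.v, self.a, self.z_rel, self.tau)
        if not all(math.isfinite(x) for x in vals):
            raise ValueError(f"non-finite DDM parameters: {vals}")
        if self.a <= 0:
            raise ValueError(f"boundary separation must be positive, got a={self.a}")
        if not 0.0 < self.z_rel < 1.0:
            raise ValueError(f"relative start must lie in (0, 1), got z_rel={self.z_rel}")
        if self.tau < 0:
            raise ValueError(f"non-decision time must be >= 0, got tau={self.tau}")


def prob_upper(params: DDMParams) -> float:
    """Probability of absorption at the upper boundary.

    Closed form (gambler's ruin for drifted Brownian motion, s = 1)::

        P_upper = (1 - exp(-2 v z)) / (1 - exp(-2 v a)),  z = z_rel * a

    with the analytic limit ``P_upper = z_rel`` at ``v = 0``.
    """
    v, a, z = params.v, params.a, params.z_rel * params.a
    if v == 0.0:
        return params.z_rel
    # Work with u = |v|; for v < 0 use the reflected process.
    if v < 0:
        return 1.0 - prob_upper(DDMParams(-v, a, 1.0 - params.z_rel, params.tau))
    # v > 0: both expm1 arguments are negative, no overflow.
    return math.expm1(-2.0 * v * z) / math.expm1(-2.0 * v * a)


# ---------------------------------------------------------------------------
# Density evaluation (scalar core compiled with numba)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fpt_std_lower(tt: float, w: float, err: float) -> float:
    """Standardized (v=0, a=1) first-passage density at the lower boundary.

    ``tt`` is time scaled by ``a**2``; ``w`` the relative start.  Chooses
    the series (small- vs large-time) that needs fewer terms for absolute
    truncation error below ``err``.
    """
    # terms needed by the small-time expansion
    if 2.0 * math.sqrt(2.0 * math.pi * tt) * err < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * tt * math.log(2.0 * err * math.sqrt(2.0 * math.pi * tt)))
        ks = max(ks, math.sqrt(tt) + 1.0)
    else:
        ks = 2.0
    # terms needed by the large-time expansion
    if math.pi * tt * err < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * tt * err) / (math.pi * math.pi * tt))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(tt)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(tt))

    p = 0.0
    if ks < kl:  # small-time expansion
        K = int(math.ceil(ks))
        lo = -((K - 1) // 2)
        hi = K // 2
        for k in range(lo, hi + 1):
            x = w + 2.0 * k
            p += x * math.exp(-x * x / (2.0 * tt))
        p /= math.sqrt(2.0 * math.pi * tt * tt * tt)
    else:  # large-time expansion
        K = int(math.ceil(kl))
        for k in range(1, K + 1):
            p += k * math.exp(-k * k * math.pi * math.pi * tt / 2.0) * math.sin(k * math.pi * w)
        p *= math.pi
    if p < 0.0:  # truncation can leave a tiny negative residue
        p = 0.0
    return p


@njit(cache=True)
def _fpt_pdf_lower(t: float, v: float, a: float, w: float, err: float) -> float:
    """Defective density of lower-boundary absorption at decision time t."""
    tt = t / (a * a)
    p = _fpt_std_lower(tt, w, err)
    return p * math.exp(-v * a * w - v * v * t / 2.0) / (a * a)


@njit(cache=True)
def _fpt_pdf(t: float, upper: bool, v: float, a: float, w: float, err: float) -> float:
    if upper:
        # reflection: upper-boundary density = lower-boundary density of
        # the mirrored process (v -> -v, w -> 1 - w)
        return _fpt_pdf_lower(t, -v, a, 1.0 - w, err)
    return _fpt_pdf_lower(t, v, a, w, err)


def fpt_density(t: float, choice: Choice, params: DDMParams, tol: float = 1e-7) -> float:
    """Defective first-passage density at decision time ``t`` (seconds).

    ``t`` is decision time, i.e. response time minus ``tau``.  The
    result integrates over t to the probability of the requested
    boundary (< 1), not to one.

    Parameters
    ----------
    t : float
        Decision time, > 0.
    choice : Choice
        Which boundary's defective density to evaluate.
    params : DDMParams
    tol : float
        Absolute truncation tolerance of the series (default 1e-7).
    """
    if t <= 0:
        raise ValueError(f"decision time must be positive, got t={t}")
    if tol <= 0:
        raise ValueError(f"tolerance must be positive, got tol={tol}")
    return float(_fpt_pdf(float(t), choice is Choice.upper, params.v, params.a, params.z_rel, tol))


def fpt_cdf(t: np.ndarray, choice: Choice, params: DDMParams, tol: float = 1e-9, n_grid: int = 4096) -> np.ndarray:
    """Defective first-passage CDF at decision times ``t`` (vectorized).

    Computed by dense trapezoidal integration of :func:`fpt_density`;
    intended for distributional checks (e.g. KS statistics), not as a
    likelihood.
    """
    t = np.asarray(t, dtype=float)
    tmax = max(float(np.max(t)), 1e-3) * 1.0 + 1e-9
    grid = np.linspace(0.0, tmax, n_grid)
    dens = np.empty_like(grid)
    dens[0] = 0.0
    up = choice is Choice.upper
    for i in range(1, n_grid):
        dens[i] = _fpt_pdf(grid[i], up, params.v, params.a, params.z_rel, tol)
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) * 0.5 * np.diff(grid))])
    return np.interp(t, grid, cdf)


@njit(cache=True)
def _survival_one(t: float, v: float, a: float, w: float, err: float) -> float:
    """P(first passage at the *lower* boundary occurs after time t).

    Term-wise integral of the large-time series; each term decays like
    exp(-lambda_k t) with lambda_k = (v^2 + pi^2 k^2 / a^2) / 2.  The
    truncation test uses the sin-free envelope of the terms — the sine
    factor vanishes at periodic k, so testing the term itself would stop
    the series far too early.
    """
    s = 0.0
    log_pref = -v * a * w
    for k in range(1, 512):
        lam = 0.5 * (v * v + math.pi * math.pi * k * k / (a * a))
        ex = log_pref - lam * t
        if ex < -745.0:
            break
        envelope = (math.pi / (a * a)) * k * math.exp(ex) / lam
        s += envelope * math.sin(k * math.pi * w)
        # the envelope is only guaranteed monotone decreasing past k = |v| a / pi
        if envelope < err and k * math.pi >= abs(v) * a:
            break
    return s


@njit(cache=True)
def _prob_before(t: float, v: float, a: float, w: float, err: float) -> float:
    """P(absorption at either boundary before time t)."""
    s = _survival_one(t, v, a, w, err) + _survival_one(t, -v, a, 1.0 - w, err)
    p = 1.0 - s
    if p < 1e-300:
        p = 1e-300
    if p > 1.0:
        p = 1.0
    return p


@njit(cache=True)
def _log_prob_before_cells(
    v: np.ndarray, a: np.ndarray, w: np.ndarray, tau: np.ndarray, deadline: float, err: float
) -> np.ndarray:
    """log P(absorption before the deadline) per parameter cell (flattened)."""
    n = v.size
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        if a[i] <= 0.0 or w[i] <= 0.0 or w[i] >= 1.0 or tau[i] < 0.0 or tau[i] >= deadline:
            out[i] = 0.0  # invalid cells are rejected by the density term
            continue
        out[i] = math.log(_prob_before(deadline - tau[i], v[i], a[i], w[i], err))
    return out


@njit(cache=True)
def _loglik_batch_truncated(
    rt: np.ndarray,
    upper: np.ndarray,
    v: np.ndarray,
    a: np.ndarray,
    w: np.ndarray,
    tau: np.ndarray,
    deadline: float,
    err: float,
) -> np.ndarray:
    """Per-trial log density conditioned on absorption before the deadline."""
    n = rt.size
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        t = rt[i] - tau[i]
        if t <= 0.0 or tau[i] < 0.0 or a[i] <= 0.0 or w[i] <= 0.0 or w[i] >= 1.0:
            out[i] = -np.inf
            continue
        p = _fpt_pdf(t, upper[i], v[i], a[i], w[i], err)
        if p <= 0.0:
            out[i] = -np.inf
            continue
        tmax = deadline - tau[i]
        out[i] = math.log(p) - math.log(_prob_before(tmax, v[i], a[i], w[i], err))
    return out


# ---------------------------------------------------------------------------
# Forward simulation (Euler-Maruyama)
# ---------------------------------------------------------------------------


_EM_BETA = 0.5826  # -zeta(1/2)/sqrt(2*pi): discrete-monitoring boundary correction


@njit(cache=True)
def _em_paths(v: float, a: float, z: float, n: int, dt: float, seed: int):
    np.random.seed(seed)
    sq = math.sqrt(dt)
    # A discretely monitored path overshoots a continuously monitored
    # boundary; pulling both boundaries inward by beta*sigma*sqrt(dt)
    # cancels the leading O(sqrt(dt)) bias in absorption time and choice
    # probability (continuity correction for barrier crossing).
    c = _EM_BETA * sq
    lo = min(c, 0.49 * z)
    hi = a - min(c, 0.49 * (a - z))
    upper = np.empty(n, dtype=np.bool_)
    dt_dec = np.empty(n, dtype=np.float64)
    for i in range(n):
        x = z
        t = 0.0
        while lo < x < hi:
            x += v * dt + sq * np.random.normal()
            t += dt
        upper[i] = x >= hi
        dt_dec[i] = t
    return upper, dt_dec


def sample_trials(
    params: DDMParams, n: int, seed: int, dt: float = 1e-4
) -> list[tuple[Choice, float]]:
    """Simulate ``n`` trials by Euler-Maruyama integration of the diffusion.

    Each path starts at ``z_rel * a`` and runs with step ``dt`` until
    absorption at 0 or ``a``; the reported response time is the
    absorption time plus ``tau``.  Identical seeds give identical output.

    Note that a finite step overshoots the boundary slightly, biasing
    absorption times upward by O(sqrt(dt)); dt <= 1e-3 is recommended and
    dt = 1e-4 (the default) keeps the bias negligible for the parameter
    ranges of word-evaluation experiments.
    """
    if n <= 0:
        raise ValueError(f"need at least one trial, got n={n}")
    if dt <= 0:
        raise ValueError(f"step must be positive, got dt={dt}")
    upper, t_dec = _em_paths(params.v, params.a, params.z_rel * params.a, int(n), float(dt), int(seed))
    return [
        (Choice.upper if u else Choice.lower, float(t + params.tau))
        for u, t in zip(upper, t_dec)
    ]


def sample_trials_arrays(
    params: DDMParams, n: int, seed: int, dt: float = 1e-4
) -> tuple[np.ndarray, np.ndarray]:
    """Like :func:`sample_trials` but returning (upper: bool array, rt: float array)."""
    if n <= 0:
        raise ValueError(f"need at least one trial, got n={n}")
    upper, t_dec = _em_paths(params.v, params.a, params.z_rel * params.a, int(n), float(dt), int(seed))
    return upper, t_dec + params.tau


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


@njit(cache=True)
def _loglik_batch(
    rt: np.ndarray,
    upper: np.ndarray,
    v: np.ndarray,
    a: np.ndarray,
    w: np.ndarray,
    tau: np.ndarray,
    err: float,
) -> np.ndarray:
    """Per-trial log defective density with per-trial parameters."""
    n = rt.size
    out = np.empty(n, dtype=np.float64)
    for i in range(n):
        t = rt[i] - tau[i]
        if t <= 0.0 or tau[i] < 0.0 or a[i] <= 0.0 or w[i] <= 0.0 or w[i] >= 1.0:
            out[i] = -np.inf
            continue
        p = _fpt_pdf(t, upper[i], v[i], a[i], w[i], err)
        out[i] = math.log(p) if p > 0.0 else -np.inf
    return out


def loglik_trials(
    trials: list[tuple[Choice, float]], params: DDMParams, tol: float = 1e-7
) -> float:
    """Summed log-likelihood of (choice, rt-seconds) trials.

    Each trial contributes ``log fpt_density(rt - tau, choice)``; a trial
    with ``rt <= tau`` is impossible under the model and drives the sum
    to ``-inf`` (returned, not raised).
    """
    if len(trials) == 0:
        raise ValueError("empty trial list")
    rt = np.array([r for _, r in trials], dtype=float)
    upper = np.array([c is Choice.upper for c, _ in trials])
    k = np.full(rt.size, 0.0)
    ll = _loglik_batch(
        rt,
        upper,
        k + params.v,
        k + params.a,
        k + params.z_rel,
        k + params.tau,
        tol,
    )
    return float(np.sum(ll))
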