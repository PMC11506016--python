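"""Synthetic study generator.

Emulates the full valence-evaluation experiment at desk scale with known
ground truth: a norming questionnaire (raters x words on two 1-9
scales), the 12-cell valence design (2 word types x populated cells of
the emotional-level x moral-level grid, 8 words per cell), per-
participant trial schedules with counterbalancing, and diffusion-
generated responses under a 1600 ms deadline.

Study conditions emulated by the defaults: 30 participants, 2 tasks
(emotional and moral evaluation), 96 words presented twice per task
(192 trials/task), ~4-6% error trials, <1% timeouts, and a group-level
parameter pattern in which drift rate rises with emotional valence for
moral words, boundary separation falls with emotional valence for
immoral words, and moral valence has no effect.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .stats import POPULATED_CELLS
from .wiener import DDMParams, sample_trials_arrays

__all__ = [
    "TruthScenario",
    "SCENARIOS",
    "generate_ratings",
    "generate_design",
    "generate_true_params",
    "simulate_dataset",
]

#: intensity-scale centers (distance from the neutral midpoint 5) of the
#: low/medium/high valence levels used for synthetic word construction.
LEVEL_CENTERS = (2.3, 3.0, 3.7)

DEADLINE_MS = 1600.0
TASKS = ("emotional", "moral")
WORD_TYPES = ("moral", "immoral")


# ---------------------------------------------------------------------------
# ground-truth scenarios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TruthScenario:
    """Group-level ground truth for one simulated cohort.

    Drift magnitudes and boundaries are indexed by emotional level
    (0 = low, 1 = medium, 2 = high); moral level has no effect, matching
    the pattern the design is built to detect.  Immoral-word drift is
    negative (toward the lower / "immoral" boundary).
    """

    name: str = "emotional-dominance"
    v_moral: tuple[float, float, float] = (1.5, 2.2, 2.9)
    v_immoral: tuple[float, float, float] = (2.2, 2.2, 2.2)  # magnitude; sign applied
    a_moral: tuple[float, float, float] = (1.5, 1.5, 1.5)
    a_immoral: tuple[float, float, float] = (1.8, 1.5, 1.2)
    tau: float = 0.33
    z_rel: float = 0.45
    sd_v: float = 0.25
    sd_a: float = 0.12
    sd_tau: float = 0.04
    sd_z: float = 0.04
    #: non-decision offsets (s) applied in the emotional task per word type,
    #: reproducing the small task-by-word RT shifts of the behavioral means
    tau_offset_emotional: tuple[float, float] = (0.007, -0.016)  # (moral, immoral)

    def cell_params(self, word_type: str, e_level: int, m_level: int) -> tuple[float, float, float]:
        """Group-level (v, a, tau) for one design cell of the moral task."""
        if word_type == "moral":
            return self.v_moral[e_level], self.a_moral[e_level], self.tau
        return -self.v_immoral[e_level], self.a_immoral[e_level], self.tau

    def group_table(self) -> pd.DataFrame:
        rows = []
        for wt in WORD_TYPES:
            for e, m in POPULATED_CELLS:
                v, a, tau = self.cell_params(wt, e, m)
                rows.append(
                    dict(word_type=wt, group=f"{e}V{m}M", emotional_level=e, moral_level=m,
                         v=v, a=a, tau=tau, z_rel=self.z_rel)
                )
        return pd.DataFrame(rows)


SCENARIOS: dict[str, TruthScenario] = {
    "emotional-dominance": TruthScenario(),
    "no-bias": replace(TruthScenario(), name="no-bias", z_rel=0.5),
    "strong-bias": replace(TruthScenario(), name="strong-bias", z_rel=0.35),
    "null": TruthScenario(
        name="null",
        v_moral=(2.2, 2.2, 2.2),
        v_immoral=(2.2, 2.2, 2.2),
        a_moral=(1.5, 1.5, 1.5),
        a_immoral=(1.5, 1.5, 1.5),
        z_rel=0.5,
        tau_offset_emotional=(0.0, 0.0),
    ),
}


# ---------------------------------------------------------------------------
# stimuli and norming ratings
# ---------------------------------------------------------------------------


def _true_words(rng: np.random.Generator, n_words: int = 230) -> pd.DataFrame:
    """Latent word inventory: 96 design words filling the 12 cells plus fillers.

    True ratings place each design word comfortably inside its intensity
    level so that noisy norming means still select and bin correctly;
    fillers are near-neutral (intensity <= ~1.7 on both dimensions) and
    are meant to be discarded by the selection rule.
    """
    if n_words < 96:
        raise ValueError("need at least 96 words to fill the design")
    rows = []
    wid = 0
    for wt in WORD_TYPES:
        sign = 1.0 if wt == "moral" else -1.0
        for e, m in POPULATED_CELLS:
            for _ in range(8):
                ei = np.clip(rng.normal(LEVEL_CENTERS[e], 0.10), LEVEL_CENTERS[e] - 0.25, LEVEL_CENTERS[e] + 0.25)
                mi = np.clip(rng.normal(LEVEL_CENTERS[m], 0.10), LEVEL_CENTERS[m] - 0.25, LEVEL_CENTERS[m] + 0.25)
                rows.append(
                    dict(word_id=f"w{wid:03d}", word_type=wt, design_cell=f"{e}V{m}M",
                         emotional_rating=5.0 + sign * ei, moral_rating=5.0 + sign * mi)
                )
                wid += 1
    for _ in range(n_words - 96):
        s1, s2 = rng.choice([-1.0, 1.0], size=2)
        rows.append(
            dict(word_id=f"w{wid:03d}", word_type="filler", design_cell="",
                 emotional_rating=5.0 + s1 * rng.uniform(0.3, 1.7),
                 moral_rating=5.0 + s2 * rng.uniform(0.3, 1.7))
        )
        wid += 1
    df = pd.DataFrame(rows)
    # matched surface covariates: same distributions for both word types
    df["strokes"] = rng.integers(8, 25, size=len(df))
    df["frequency"] = np.round(rng.lognormal(1.5, 0.8, size=len(df)), 2)
    return df


def generate_ratings(
    n_raters: int = 31,
    n_words: int = 230,
    seed: int = 0,
    rater_noise_sd: float = 0.5,
    leniency_sd: float = 0.18,
    discrete: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the norming questionnaire.

    Each rater scores every word on the emotional and the moral 1-9
    scale.  A rating is the word's true value plus a per-rater leniency
    shift (shared across the rater's answers on that scale) plus
    independent noise, rounded to the integer scale when ``discrete``.
    The default noise/leniency mix is tuned so Cronbach's alpha of the
    resulting 230-item matrix lands near 0.94-0.95 on both dimensions.

    Returns ``(ratings, words)`` where ``ratings`` is long-format
    (rater, word_id, scale, value) and ``words`` the latent inventory
    with true ratings.
    """
    if n_raters < 2:
        raise ValueError("need at least two raters")
    rng = np.random.default_rng(seed)
    words = _true_words(rng, n_words)
    recs = []
    for scale, col in (("emotional", "emotional_rating"), ("moral", "moral_rating")):
        true = words[col].to_numpy()
        lenien = rng.normal(0.0, leniency_sd, size=n_raters)
        noise = rng.normal(0.0, rater_noise_sd, size=(n_raters, len(words)))
        vals = true[None, :] + lenien[:, None] + noise
        if discrete:
            vals = np.round(vals)
        vals = np.clip(vals, 1.0, 9.0)
        for r in range(n_raters):
            recs.append(
                pd.DataFrame(
                    dict(rater=r, word_id=words["word_id"], scale=scale, value=vals[r])
                )
            )
    return pd.concat(recs, ignore_index=True), words


def ratings_matrix(ratings: pd.DataFrame, scale: str) -> np.ndarray:
    """Pivot long-format ratings to a rater x word matrix for one scale."""
    sub = ratings.loc[ratings["scale"] == scale]
    return sub.pivot(index="rater", columns="word_id", values="value").to_numpy()


# ---------------------------------------------------------------------------
# design / schedule
# ---------------------------------------------------------------------------


def generate_design(seed: int = 0, n_participants: int = 30) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the stimulus list and per-participant trial schedules.

    The stimulus list holds the 96 design words (8 per populated cell and
    word type).  Each participant runs both tasks, 192 trials per task
    (each word twice, shuffled), with task order and response-key mapping
    counterbalanced across participants.
    """
    rng = np.random.default_rng(seed)
    words = _true_words(rng, 230)
    stimuli = words.loc[words["word_type"] != "filler"].reset_index(drop=True).copy()
    stimuli["group"] = stimuli["design_cell"]

    rows = []
    for p in range(n_participants):
        task_order = TASKS if p % 2 == 0 else TASKS[::-1]
        key_map = "FJ" if (p // 2) % 2 == 0 else "JF"
        for block, task in enumerate(task_order):
            idx = np.repeat(np.arange(len(stimuli)), 2)
            rng.shuffle(idx)
            for trial, i in enumerate(idx):
                rows.append(
                    dict(participant_id=p, task=task, block=block, trial=trial,
                         word_id=stimuli.at[i, "word_id"], group=stimuli.at[i, "group"],
                         word_type=stimuli.at[i, "word_type"], key_map=key_map)
                )
    return stimuli, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# participant-level truth
# ---------------------------------------------------------------------------

_VALID = dict(a_min=0.3, tau_min=0.05, z_min=0.05, z_max=0.95)


def generate_true_params(
    scenario: TruthScenario, n_participants: int = 30, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw participant-level parameters around the scenario's group levels.

    Participant values are the group-level cell values plus Normal
    between-participant deviations, truncated to the valid parameter
    region; if more than 5% of raw draws fall outside it the scenario is
    rejected.  The starting point is drawn once per participant and
    shared across all cells.

    Returns ``(cell_params, participant_z)``.
    """
    rng = np.random.default_rng(seed)
    group = scenario.group_table()
    n_bad = 0
    n_tot = 0
    rows = []
    z_raw = rng.normal(scenario.z_rel, scenario.sd_z, size=n_participants)
    n_bad += int(np.sum((z_raw < _VALID["z_min"]) | (z_raw > _VALID["z_max"])))
    n_tot += n_participants
    z = np.clip(z_raw, _VALID["z_min"], _VALID["z_max"])
    for p in range(n_participants):
        for _, g in group.iterrows():
            v = rng.normal(g["v"], scenario.sd_v)
            a = rng.normal(g["a"], scenario.sd_a)
            tau = rng.normal(g["tau"], scenario.sd_tau)
            n_tot += 3
            n_bad += int(a < _VALID["a_min"]) + int(tau < _VALID["tau_min"])
            rows.append(
                dict(participant_id=p, word_type=g["word_type"], group=g["group"],
                     v=v, a=max(a, _VALID["a_min"]), tau=max(tau, _VALID["tau_min"]),
                     z_rel=z[p])
            )
    if n_bad > 0.05 * n_tot:
        raise ValueError(
            f"scenario produces {100 * n_bad / n_tot:.1f}% invalid draws after truncation"
        )
    zdf = pd.DataFrame(dict(participant_id=np.arange(n_participants), z_rel=z))
    return pd.DataFrame(rows), zdf


# ---------------------------------------------------------------------------
# dataset simulation
# ---------------------------------------------------------------------------


def simulate_dataset(
    design: tuple[pd.DataFrame, pd.DataFrame],
    truth: tuple[pd.DataFrame, pd.DataFrame],
    seed: int = 0,
    scenario: TruthScenario | None = None,
    dt: float = 1e-3,
    deadline_ms: float = DEADLINE_MS,
) -> pd.DataFrame:
    """Simulate responses for every scheduled trial.

    Each (participant, task, cell) block is sampled from that
    participant's diffusion parameters; in the emotional task the
    boundaries are re-labelled (upper = "positive") and the scenario's
    per-word-type non-decision offsets are applied.  A response slower
    than the deadline is recorded as a timeout with no choice.
    Correctness is the agreement of the absorbing boundary with the word
    type.  Deterministic under a fixed seed.
    """
    scenario = scenario or TruthScenario()
    stimuli, schedule = design
    cell_params, _ = truth
    pidx = cell_params.set_index(["participant_id", "word_type", "group"])

    off_moral, off_immoral = scenario.tau_offset_emotional
    out = schedule.copy()
    rng = np.random.default_rng(seed)
    rt_ms = np.empty(len(out))
    response = np.empty(len(out), dtype=object)
    correct = np.zeros(len(out), dtype=bool)
    timeout = np.zeros(len(out), dtype=bool)

    for (p, task, wt, grp), block in out.groupby(
        ["participant_id", "task", "word_type", "group"], sort=True
    ):
        try:
            row = pidx.loc[(p, wt, grp)]
        except KeyError:
            raise KeyError(f"missing parameters for participant {p}, cell {wt}/{grp}") from None
        tau = float(row["tau"])
        if task == "emotional":
            tau = max(tau + (off_moral if wt == "moral" else off_immoral), 0.01)
        params = DDMParams(v=float(row["v"]), a=float(row["a"]), z_rel=float(row["z_rel"]), tau=tau)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        up, rt = sample_trials_arrays(params, len(block), seed=sub_seed, dt=dt)
        loc = block.index
        rt_ms[loc] = rt * 1000.0
        is_to = rt * 1000.0 > deadline_ms
        timeout[loc] = is_to
        resp = np.where(up, "upper", "lower").astype(object)
        resp[is_to] = "timeout"
        response[loc] = resp
        correct[loc] = np.where(is_to, False, up == (wt == "moral"))

    out["response"] = response
    out["rt_ms"] = np.round(np.minimum(rt_ms, deadline_ms), 1)
    out["timeout"] = timeout
    out["correct"] = correct
    return out
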