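"""Report assembly and open-format persistence for the pipeline.

Every artifact is CSV or JSON: posterior draws as a long-format CSV
(parameter, chain, iteration, value), behavioral statistics and fit
summaries as JSON, and a human-readable markdown summary that mirrors
the field's reporting style for posterior differences
("M = ..., x% < 0 < y%", starred when the 95% rule is met).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as bstats
from .hierarchical import DifferenceSummary, PosteriorChains, diff_distribution

__all__ = [
    "save_chains",
    "load_chains",
    "behavior_report",
    "fit_report",
    "difference_table",
    "render_markdown",
]

#: functional-separation contrasts reported for the group-level means:
#: (label, family, group_a, group_b).  Emotional-valence effects hold the
#: moral level fixed (0V1M vs 2V1M); moral-valence effects hold the
#: emotional level fixed (1V0M vs 1V2M).
CONTRASTS = [
    ("v: emotional effect, moral words (2V1M - 0V1M)", "v", "moral_2V1M", "moral_0V1M"),
    ("v: emotional effect, immoral words (2V1M - 0V1M)", "v", "immoral_2V1M", "immoral_0V1M"),
    ("v: moral effect, moral words (1V2M - 1V0M)", "v", "moral_1V2M", "moral_1V0M"),
    ("v: moral effect, immoral words (1V2M - 1V0M)", "v", "immoral_1V2M", "immoral_1V0M"),
    ("a: emotional effect, moral words (2V1M - 0V1M)", "a", "moral_2V1M", "moral_0V1M"),
    ("a: emotional effect, immoral words (2V1M - 0V1M)", "a", "immoral_2V1M", "immoral_0V1M"),
    ("a: moral effect, moral words (1V2M - 1V0M)", "a", "moral_1V2M", "moral_1V0M"),
    ("a: moral effect, immoral words (1V2M - 1V0M)", "a", "immoral_1V2M", "immoral_1V0M"),
    ("v: immoral vs moral evaluation at 0V1M (|v| difference)", "abs_v", "immoral_0V1M", "moral_0V1M"),
]


def save_chains(chains: PosteriorChains, path: str | Path) -> None:
    chains.to_frame().to_csv(path, index=False)


def load_chains(path: str | Path) -> dict[str, np.ndarray]:
    """Load a long-format chains CSV back into a parameter -> draws dict."""
    df = pd.read_csv(path)
    return {
        name: sub.sort_values("iteration")["value"].to_numpy()
        for name, sub in df.groupby("parameter", sort=True)
    }


# ---------------------------------------------------------------------------
# behavioral report
# ---------------------------------------------------------------------------


def _cell_means(trials: pd.DataFrame, value: str) -> np.ndarray:
    """participants x 4 means ordered (emo/moral-word, emo/immoral, moral/moral, moral/immoral)."""
    pivot = trials.pivot_table(
        index="participant_id", columns=["task", "word_type"], values=value, aggfunc="mean"
    )
    cols = [("emotional", "moral"), ("emotional", "immoral"), ("moral", "moral"), ("moral", "immoral")]
    return pivot[cols].to_numpy()


def behavior_report(trials: pd.DataFrame, deadline_ms: float = 1600.0) -> dict:
    """Full behavioral analysis of a trial table.

    Accuracy is analyzed over all trials; reaction times over the
    filtered (timeout- and error-free) trials.  Returns a JSON-ready
    dict with the exclusion report, both 2x2 ANOVAs, the four simple
    effects of the RT analysis, and the FDR-corrected paired t-tests of
    the 12-group moral-task reaction times.
    """
    kept, excl = bstats.filter_trials(trials, deadline_ms)

    acc = _cell_means(trials.assign(acc=trials["correct"].astype(float)), "acc")
    rt = _cell_means(kept, "rt_ms")
    out: dict = {"exclusions": excl.to_dict(orient="records")}
    for name, y in (("accuracy", acc), ("rt", rt)):
        an = bstats.rm_anova_2x2(y)
        out[f"anova_{name}"] = {
            eff: vars(getattr(an, eff)) for eff in ("task", "word", "interaction")
        }
    out["simple_effects_rt"] = {
        "word_within_emotional_task": vars(bstats.simple_effects(rt, "word", 0)),
        "word_within_moral_task": vars(bstats.simple_effects(rt, "word", 1)),
        "task_within_moral_words": vars(bstats.simple_effects(rt, "task", 0)),
        "task_within_immoral_words": vars(bstats.simple_effects(rt, "task", 1)),
    }
    out["cell_means_rt"] = {
        "emotional_moral": float(np.mean(rt[:, 0])),
        "emotional_immoral": float(np.mean(rt[:, 1])),
        "moral_moral": float(np.mean(rt[:, 2])),
        "moral_immoral": float(np.mean(rt[:, 3])),
    }

    # 12-group paired comparisons in the moral task
    moral = kept.loc[kept["task"] == "moral"]
    g = moral.pivot_table(
        index="participant_id", columns=["word_type", "group"], values="rt_ms", aggfunc="mean"
    )
    comparisons = {}
    for cell in sorted({c[1] for c in g.columns}):
        if ("moral", cell) in g.columns and ("immoral", cell) in g.columns:
            comparisons[f"immoral_vs_moral_{cell}"] = (
                g[("immoral", cell)].to_numpy(),
                g[("moral", cell)].to_numpy(),
            )
    for wt in ("immoral", "moral"):
        comparisons[f"{wt}_0V1M_vs_2V1M"] = (g[(wt, "0V1M")].to_numpy(), g[(wt, "2V1M")].to_numpy())
        comparisons[f"{wt}_1V0M_vs_1V2M"] = (g[(wt, "1V0M")].to_numpy(), g[(wt, "1V2M")].to_numpy())
    out["paired_t_fdr"] = [vars(r) for r in bstats.paired_t_fdr(comparisons)]
    return out


# ---------------------------------------------------------------------------
# fit report
# ---------------------------------------------------------------------------


def difference_table(draws: dict[str, np.ndarray]) -> list[dict]:
    """Posterior-difference summaries for the canonical contrasts."""
    rows = []
    for label, fam, ga, gb in CONTRASTS:
        if fam == "abs_v":
            da = np.abs(draws[f"v_mu[{ga}]"])
            db = np.abs(draws[f"v_mu[{gb}]"])
        else:
            da = draws[f"{fam}_mu[{ga}]"]
            db = draws[f"{fam}_mu[{gb}]"]
        s = diff_distribution(da, db)
        rows.append(dict(label=label, **vars(s)))
    return rows


def fit_report(
    chains_by_variant: dict[str, PosteriorChains],
    dics: dict[str, float],
) -> dict:
    """JSON-ready summary of one or both model variants."""
    out: dict = {"variants": {}}
    for variant, chains in chains_by_variant.items():
        out["variants"][variant] = {
            "n_draws": len(chains),
            "burn_in": chains.burn_in,
            "seed": chains.seed,
            "dic": dics[variant],
            "diagnostics": chains.diagnostics.to_dict(orient="records"),
            "max_rhat": float(chains.diagnostics["rhat"].max()),
            "warnings": chains.warnings,
            "group_posterior_means": {
                name: float(x.mean())
                for name, x in chains.draws.items()
            },
            "differences": difference_table(chains.draws),
        }
    if {"bias", "no_bias"} <= set(dics):
        out["dic_comparison"] = {
            "bias": dics["bias"],
            "no_bias": dics["no_bias"],
            "preferred": "bias" if dics["bias"] < dics["no_bias"] else "no_bias",
        }
    return out


def _fmt_diff(d: dict) -> str:
    star = " *" if d["significant"] else ""
    return (
        f"M = {d['mean']:.2f}, {d['pct_below_zero']:.1f}% < 0 < "
        f"{d['pct_above_zero']:.1f}%{star}"
    )


def render_markdown(report: dict) -> str:
    """Markdown summary of a fit report (regenerable from persisted JSON)."""
    lines = ["# Hierarchical DDM fit summary", ""]
    if "dic_comparison" in report:
        c = report["dic_comparison"]
        lines += [
            "## Model comparison (DIC, lower is better)",
            "",
            f"- bias variant: {c['bias']:.3f}",
            f"- no-bias variant: {c['no_bias']:.3f}",
            f"- preferred: **{c['preferred']}**",
            "",
        ]
    for variant, v in report["variants"].items():
        lines += [f"## Variant: {variant}", ""]
        lines += [f"- draws: {v['n_draws']} (burn-in {v['burn_in']}, seed {v['seed']})"]
        lines += [f"- DIC: {v['dic']:.3f}", f"- max R-hat: {v['max_rhat']:.3f}", ""]
        if v["warnings"]:
            lines += [f"- warnings: {'; '.join(v['warnings'])}", ""]
        lines += ["### Posterior differences (group-level means)", ""]
        for d in v["differences"]:
            lines.append(f"- {d['label']}: {_fmt_diff(d)}")
        lines.append("")
    return "\n".join(lines)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float))
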