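"""Repeated-measures statistics on zone summaries, plus report output.

The study design is reproduced structurally: 2 × 4 (zone × condition) and
one-way repeated-measures ANOVAs on participant×condition mean rates,
post hoc pairwise paired t-tests with Holm correction and compact
letter-display grouping, and paired t-tests for kinematic contrasts.

The uncorrected within-subject F is reported by default (a
Greenhouse–Geisser-corrected p is available); the post hoc correction is
configurable (holm or none) since different conventions exist.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import BalanceError, DomainError, EmptyReportError

__all__ = [
    "AnovaResult",
    "PairwiseComparison",
    "rm_anova",
    "paired_t",
    "posthoc_pairwise",
    "letter_groups",
    "build_report",
]


@dataclass
class AnovaResult:
    """One within-subject effect: F, degrees of freedom, p, cell means/SEs."""

    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    p_gg: Optional[float] = None
    means: dict = field(default_factory=dict)
    ses: dict = field(default_factory=dict)


@dataclass
class PairwiseComparison:
    level_a: str
    level_b: str
    t: float
    df: int
    p_raw: float
    p_adj: float


def _check_balance(table: pd.DataFrame, subject: str, factors: Sequence[str]):
    counts = table.groupby([subject, *factors], observed=True).size()
    if (counts != 1).any():
        raise BalanceError("table is not a complete balanced subject x cell design")
    per_subject = table.groupby(subject, observed=True).size()
    if per_subject.nunique() != 1:
        raise BalanceError("subjects have unequal numbers of cells")


def _level_stats(table: pd.DataFrame, subject: str, factor: str, dv: str):
    """Mean and SE per factor level, over per-subject means."""
    cell = table.groupby([subject, factor], observed=True)[dv].mean().unstack(factor)
    means = cell.mean(axis=0)
    ses = cell.std(axis=0, ddof=1) / np.sqrt(cell.shape[0])
    return means.to_dict(), ses.to_dict()


def rm_anova(
    table: pd.DataFrame,
    dv: str = "mean_rate",
    subject: str = "participant",
    within: Sequence[str] = ("condition",),
) -> list[AnovaResult]:
    """Within-subject ANOVA with one or two factors.

    The input is a long table with one row per subject×cell; it must be
    complete and balanced.  Returns one :class:`AnovaResult` per effect (and
    the interaction for two factors).  A zero-variance effect (all cell
    values identical) is reported as F = 0, p = 1.
    """
    import warnings as _warnings

    within = list(within)
    if not 1 <= len(within) <= 2:
        raise DomainError("within must name one or two factors")
    _check_balance(table, subject, within)
    with _warnings.catch_warnings():
        # degenerate (zero-variance) tables trigger 0/0 inside the fit;
        # they are mapped to F = 0, p = 1 below
        _warnings.simplefilter("ignore", RuntimeWarning)
        aov = pg.rm_anova(
            data=table, dv=dv, within=within if len(within) > 1 else within[0],
            subject=subject, detailed=True, effsize="ng2",
        )
    error_df = None
    if "DF" in aov.columns:
        err_rows = aov[aov["Source"].str.lower() == "error"]
        if len(err_rows):
            error_df = int(err_rows["DF"].iloc[0])
    results = []
    for _, row in aov.iterrows():
        effect = str(row["Source"])
        if effect.lower() == "error":
            continue
        F = row["F"] if "F" in row else np.nan
        p = row["p_unc"] if "p_unc" in row else np.nan
        if not np.isfinite(F):  # 0/0: no effect variance and no error variance
            F, p = 0.0, 1.0
        p_gg = row.get("p_GG_corr")
        means, ses = {}, {}
        if effect in within:
            means, ses = _level_stats(table, subject, effect, dv)
        results.append(
            AnovaResult(
                effect=effect,
                F=float(F),
                df_num=int(row["ddof1"]) if "ddof1" in row else int(row["DF"]),
                df_den=int(row["ddof2"]) if "ddof2" in row else (error_df or 0),
                p=float(p),
                p_gg=float(p_gg) if p_gg is not None and np.isfinite(p_gg) else None,
                means=means,
                ses=ses,
            )
        )
    return results


def paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, int, float]:
    """Classical paired t-test on per-participant values; (t, df, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise DomainError("x and y must be equal-length 1-D arrays with n >= 2")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        raise DomainError("zero-variance differences: paired t is degenerate")
    res = sps.ttest_rel(x, y)
    return float(res.statistic), int(x.size - 1), float(res.pvalue)


def letter_groups(
    levels: Sequence[str],
    not_different: set[tuple[str, str]],
    means: Optional[dict] = None,
) -> dict[str, str]:
    """Compact letter display: levels sharing a letter are not significantly
    different.  Letters are the maximal cliques of the non-significance
    graph, ordered by descending clique mean."""
    g = nx.Graph()
    g.add_nodes_from(levels)
    g.add_edges_from(not_different)
    cliques = list(nx.find_cliques(g))
    if means:
        cliques.sort(key=lambda c: -np.mean([means[l] for l in c]))
    letters = {lvl: "" for lvl in levels}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for lvl in clique:
            letters[lvl] += letter
    return {lvl: "".join(sorted(s)) for lvl, s in letters.items()}


def posthoc_pairwise(
    table: pd.DataFrame,
    dv: str = "mean_rate",
    subject: str = "participant",
    factor: str = "condition",
    correction: str = "holm",
    alpha: float = 0.05,
) -> tuple[list[PairwiseComparison], dict[str, str]]:
    """All pairwise within-subject comparisons of one factor's levels, with
    Holm-adjusted p-values (or none) and letter groupings.

    A zero-variance pair (identical values) is treated as not different
    (p = 1) rather than an error, so degenerate toy tables still group.
    """
    if correction not in ("holm", "none"):
        raise DomainError("correction must be 'holm' or 'none'")
    _check_balance(table, subject, [factor])
    wide = table.groupby([subject, factor], observed=True)[dv].mean().unstack(factor)
    levels = list(wide.columns)
    if len(levels) < 2:
        raise DomainError("need at least two levels")
    pairs = list(itertools.combinations(levels, 2))
    raw = []
    stats_ = []
    for a, b in pairs:
        try:
            t, df, p = paired_t(wide[a].to_numpy(), wide[b].to_numpy())
        except DomainError:
            t, df, p = 0.0, wide.shape[0] - 1, 1.0
        raw.append(p)
        stats_.append((t, df))
    if correction == "holm":
        adj = multipletests(raw, method="holm")[1]
    else:
        adj = np.asarray(raw)
    comparisons = [
        PairwiseComparison(a, b, t=stats_[i][0], df=stats_[i][1],
                           p_raw=raw[i], p_adj=float(adj[i]))
        for i, (a, b) in enumerate(pairs)
    ]
    not_diff = {
        (c.level_a, c.level_b) for c in comparisons if c.p_adj >= alpha
    }
    means = wide.mean(axis=0).to_dict()
    return comparisons, letter_groups(levels, not_diff, means)


# ---------------------------------------------------------------------------
# report generation
# ---------------------------------------------------------------------------

def _anova_frame(results: list[AnovaResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "effect": r.effect,
                "F": r.F,
                "df_num": r.df_num,
                "df_den": r.df_den,
                "p": r.p,
                "p_gg": r.p_gg,
            }
            for r in results
        ]
    )


def build_report(
    zone_table: pd.DataFrame,
    rate_curves: dict[str, "object"],
    outdir,
    alpha: float = 0.05,
    correction: str = "holm",
) -> dict:
    """Emit tables, figures, and a structured run log for one analysis run.

    ``zone_table`` is the long participant×condition×zone table;
    ``rate_curves`` maps condition name → pooled :class:`~msreach.rates.RateSeries`.
    Writes zone_summary.csv, anova_*.csv, posthoc_*.csv, rate_curves.png,
    zone_bars.png and stats.json into ``outdir`` and returns the log dict.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if zone_table is None or len(zone_table) == 0:
        raise EmptyReportError("no zone summaries to report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    zone_table = zone_table.sort_values(
        ["participant", "condition", "zone"]
    ).reset_index(drop=True)
    zone_table.to_csv(outdir / "zone_summary.csv", index=False)

    log: dict = {"alpha": alpha, "correction": correction, "anovas": {},
                 "posthoc": {}}

    # within-subject F (and sphericity) needs a handful of participants
    enough_subjects = zone_table["participant"].nunique() >= 3

    # 2 x 4 zone x condition ANOVA (initial fixation vs pre-cue)
    two_way = zone_table[
        zone_table["zone"].isin(["initial_fixation", "pre_cue_250"])
    ]
    complete = (
        two_way.groupby("participant", observed=True).size() == 8
    )
    if (enough_subjects and complete.any() and complete.all()
            and two_way["condition"].nunique() == 4):
        res = rm_anova(two_way, within=("zone", "condition"))
        _anova_frame(res).to_csv(outdir / "anova_zone_by_condition.csv", index=False)
        log["anovas"]["zone_by_condition"] = [r.__dict__ for r in res]

    # one-way condition ANOVA + post hoc letters per zone
    letters_by_zone = {}
    for zone in sorted(zone_table["zone"].unique()) if enough_subjects else []:
        sub = zone_table[zone_table["zone"] == zone]
        cells = sub.groupby("participant", observed=True).size()
        if sub["condition"].nunique() < 2 or cells.nunique() != 1:
            continue
        res = rm_anova(sub, within=("condition",))
        _anova_frame(res).to_csv(outdir / f"anova_{zone}.csv", index=False)
        comps, letters = posthoc_pairwise(sub, correction=correction, alpha=alpha)
        pd.DataFrame([c.__dict__ for c in comps]).to_csv(
            outdir / f"posthoc_{zone}.csv", index=False
        )
        letters_by_zone[zone] = letters
        log["anovas"][zone] = [r.__dict__ for r in res]
        log["posthoc"][zone] = {
            "comparisons": [c.__dict__ for c in comps],
            "letters": letters,
        }

    # figures: pooled rate curves and zone bars
    if rate_curves:
        fig, ax = plt.subplots(figsize=(7, 4))
        for cond, series in sorted(rate_curves.items()):
            ax.plot(series.t, series.rate, label=cond, lw=1.2)
        ax.axvline(0.0, color="k", ls="--", lw=0.8)
        ax.set_xlabel("time relative to go cue (s)")
        ax.set_ylabel("microsaccade rate (Hz)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(outdir / "rate_curves.png", dpi=150)
        plt.close(fig)

    bar_zones = [z for z in
                 ("initial_fixation", "pre_cue_250", "post_inhibition", "movement")
                 if z in set(zone_table["zone"])]
    if bar_zones:
        fig, axes = plt.subplots(1, len(bar_zones), figsize=(3 * len(bar_zones), 3.2),
                                 sharey=True)
        axes = np.atleast_1d(axes)
        for ax, zone in zip(axes, bar_zones):
            sub = zone_table[zone_table["zone"] == zone]
            agg = sub.groupby("condition", observed=True)["mean_rate"]
            means, ses = agg.mean(), agg.sem()
            ax.bar(range(len(means)), means.to_numpy(), yerr=ses.to_numpy(),
                   capsize=3)
            letters = letters_by_zone.get(zone, {})
            for i, cond in enumerate(means.index):
                ax.text(i, means[cond] + (ses[cond] or 0) + 0.02,
                        letters.get(cond, ""), ha="center", fontsize=9)
            ax.set_xticks(range(len(means)))
            ax.set_xticklabels(means.index, rotation=45, ha="right", fontsize=7)
            ax.set_title(zone, fontsize=9)
        axes[0].set_ylabel("rate (Hz)")
        fig.tight_layout()
        fig.savefig(outdir / "zone_bars.png", dpi=150)
        plt.close(fig)

    with open(outdir / "stats.json", "w") as fh:
        json.dump(log, fh, indent=2, default=float)
    return log
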