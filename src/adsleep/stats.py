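"""Longitudinal condition/hemisphere comparisons of sleep-EEG features.

Builds the long-format study table — one row per (time point, channel,
variable) with the condition grouping pre / active / post and the
hemisphere derived from the channel label — and runs the comparisons:

* a two-way fixed-effects ANOVA (condition × hemisphere) per variable,
  Type II sums of squares by default (robust for unbalanced crossed
  designs without interaction emphasis; Type I/III switchable);
* a one-way ANOVA across the active-condition time points;
* Tukey HSD post-hoc comparisons (studentized range, Tukey–Kramer
  harmonic-mean correction for unbalanced groups) at α = 0.05.

Channel-level values are treated as replicates, following the original
analysis convention; this is pseudo-replication in the strict sense (the
six channels come from one head) and is documented as such.  Missing
spindle-frequency cells ("no value recorded" when no spectral peak
exists) are dropped listwise, never imputed; a condition in which most
channels lack a spindle peak is excluded from the spindle-frequency
analysis altogether.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import studentized_range

from .recording import hemisphere_of

__all__ = [
    "VARIABLES",
    "AnovaResult",
    "TukeyComparison",
    "TukeyComparisons",
    "build_study_table",
    "anova_two_way",
    "anova_one_way",
    "tukey_hsd",
    "run_paper_analysis",
]

VARIABLES = ("spindle_power", "spindle_freq", "delta_power", "alpha_power")


@dataclass
class Effect:
    F: float
    df_num: int
    df_den: int
    p: float

    def to_dict(self) -> dict:
        return {"F": self.F, "df_num": self.df_num, "df_den": self.df_den, "p": self.p}


@dataclass
class AnovaResult:
    """Fixed-effects ANOVA table: one entry per main effect / interaction."""

    effects: dict[str, Effect]
    residual_df: int
    ss_type: int
    dropped: list[str] = field(default_factory=list)  # factors/interaction dropped

    def to_dict(self) -> dict:
        return {
            "effects": {k: v.to_dict() for k, v in self.effects.items()},
            "residual_df": self.residual_df,
            "ss_type": self.ss_type,
            "dropped": list(self.dropped),
        }


@dataclass
class TukeyComparison:
    level_a: str
    level_b: str
    mean_diff: float  # mean(a) - mean(b)
    q: float
    p_adj: float
    significant: bool

    def to_dict(self) -> dict:
        return {
            "level_a": self.level_a,
            "level_b": self.level_b,
            "mean_diff": self.mean_diff,
            "q": self.q,
            "p_adj": self.p_adj,
            "significant": self.significant,
        }


@dataclass
class TukeyComparisons:
    factor: str
    alpha: float
    mse: float
    df: int
    comparisons: list[TukeyComparison]

    def lookup(self, a: str, b: str) -> TukeyComparison:
        for c in self.comparisons:
            if {c.level_a, c.level_b} == {a, b}:
                return c
        raise KeyError(f"no comparison {a} vs {b}")

    def to_dict(self) -> dict:
        return {
            "factor": self.factor,
            "alpha": self.alpha,
            "mse": self.mse,
            "df": self.df,
            "comparisons": [c.to_dict() for c in self.comparisons],
        }


# ---------------------------------------------------------------------------
# Study table
# ---------------------------------------------------------------------------

def build_study_table(
    features: pd.DataFrame, condition_map: Mapping[str, str]
) -> pd.DataFrame:
    """Attach condition and hemisphere to a tidy feature table.

    ``features`` needs columns ``time_point, channel, variable, value``;
    rows for absent values (e.g. spindle frequency with no peak) must
    simply be omitted upstream, not encoded as zero.
    """
    required = {"time_point", "channel", "variable", "value"}
    if not required <= set(features.columns):
        raise ValueError(f"feature table needs columns {sorted(required)}")
    missing = set(features["time_point"]) - set(condition_map)
    if missing:
        raise ValueError(f"condition_map missing time points: {sorted(missing)}")
    table = features.copy()
    table["channel"] = table["channel"].str.upper()
    table["condition"] = table["time_point"].map(dict(condition_map))
    table["hemisphere"] = table["channel"].map(hemisphere_of)  # raises on bad label
    cols = ["time_point", "condition", "channel", "hemisphere", "variable", "value"]
    return table[cols].reset_index(drop=True)


def _subset(table: pd.DataFrame, variable: str) -> pd.DataFrame:
    sub = table[table["variable"] == variable].dropna(subset=["value"])
    if sub.empty:
        raise ValueError(f"no observations for variable {variable!r}")
    return sub.copy()


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def anova_two_way(
    table: pd.DataFrame,
    variable: str,
    factors: tuple[str, str] = ("condition", "hemisphere"),
    ss_type: int = 2,
) -> AnovaResult:
    """Crossed fixed-effects ANOVA of one variable on two factors.

    Factors with fewer than two observed levels are dropped with a
    warning; the interaction is dropped when empty cells make it
    inestimable.  Type II sums of squares by default.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    sub = _subset(table, variable)
    dropped: list[str] = []
    use: list[str] = []
    for f in dict.fromkeys(factors):  # dedupe, keep order
        if sub[f].nunique() >= 2:
            use.append(f)
        else:
            warnings.warn(f"factor {f!r} has fewer than 2 levels; dropped", stacklevel=2)
            dropped.append(f)
    if not use:
        raise ValueError("no factor has at least two levels")

    with_interaction = len(use) == 2
    if with_interaction:
        cells = sub.groupby(list(use), observed=True).size()
        n_expected = int(np.prod([sub[f].nunique() for f in use]))
        if len(cells) < n_expected:
            warnings.warn(
                "empty cells make the interaction inestimable; interaction dropped",
                stacklevel=2,
            )
            dropped.append(":".join(use))
            with_interaction = False

    terms = [f"C({f})" for f in use]
    if with_interaction:
        terms.append(f"C({use[0]}):C({use[1]})")
    model = smf.ols("value ~ " + " + ".join(terms), data=sub).fit()
    tab = sm.stats.anova_lm(model, typ=ss_type)

    resid_df = int(tab.loc["Residual", "df"])
    effects: dict[str, Effect] = {}
    for row_name in tab.index:
        if row_name == "Residual":
            continue
        name = row_name.replace("C(", "").replace(")", "")
        effects[name] = Effect(
            F=float(tab.loc[row_name, "F"]),
            df_num=int(tab.loc[row_name, "df"]),
            df_den=resid_df,
            p=float(tab.loc[row_name, "PR(>F)"]),
        )
    return AnovaResult(effects=effects, residual_df=resid_df, ss_type=ss_type, dropped=dropped)


def anova_one_way(table: pd.DataFrame, variable: str, factor: str) -> AnovaResult:
    """One-way fixed-effects ANOVA (used within the active condition)."""
    return anova_two_way(table, variable, factors=(factor, factor), ss_type=1)


# ---------------------------------------------------------------------------
# Tukey HSD
# ---------------------------------------------------------------------------

def tukey_hsd(
    table: pd.DataFrame, variable: str, factor: str, alpha: float = 0.05
) -> TukeyComparisons:
    """All-pairs Tukey HSD on the levels of ``factor``.

    Uses the one-way residual mean square of the factor's groups and the
    studentized-range distribution; unbalanced groups use the
    Tukey–Kramer harmonic-mean standard error.
    """
    sub = _subset(table, variable)
    groups = {lvl: g["value"].to_numpy(float) for lvl, g in sub.groupby(factor, observed=True)}
    levels = sorted(groups)
    k = len(levels)
    if k < 2:
        raise ValueError(f"factor {factor!r} has a single level")
    ns = {lvl: len(v) for lvl, v in groups.items()}
    N = sum(ns.values())
    df = N - k
    if df < 1:
        raise ValueError("residual degrees of freedom < 1")
    mse = sum(((v - v.mean()) ** 2).sum() for v in groups.values()) / df
    means = {lvl: float(v.mean()) for lvl, v in groups.items()}

    comparisons = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            diff = means[a] - means[b]
            se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            if diff == 0.0:
                q = 0.0
            elif se == 0.0:
                q = np.inf
            else:
                q = abs(diff) / se
            p = float(studentized_range.sf(q, k, df)) if np.isfinite(q) else 0.0
            p = min(max(p, 0.0), 1.0)
            comparisons.append(
                TukeyComparison(
                    level_a=a,
                    level_b=b,
                    mean_diff=diff,
                    q=float(q),
                    p_adj=p,
                    significant=bool(p < alpha),
                )
            )
    return TukeyComparisons(
        factor=factor, alpha=alpha, mse=float(mse), df=int(df), comparisons=comparisons
    )


# ---------------------------------------------------------------------------
# Full analysis
# ---------------------------------------------------------------------------

def run_paper_analysis(
    study_table: pd.DataFrame,
    alpha: float = 0.05,
    ss_type: int = 2,
    min_channel_frac: float = 0.5,
) -> dict:
    """Per-variable condition × hemisphere ANOVA with Tukey post-hocs.

    For the spindle-frequency variable, any condition in which fewer than
    ``min_channel_frac`` of the channels report a peak is excluded from
    the analysis (mirroring the removal of the post-stimulation condition
    when the spindle peak is absent in most channels).  Also runs the
    within-active one-way ANOVA across active time points.
    """
    n_channels = study_table["channel"].nunique()
    report: dict = {"alpha": alpha, "ss_type": ss_type, "variables": {}}
    for variable in sorted(study_table["variable"].unique()):
        sub = study_table[study_table["variable"] == variable].dropna(subset=["value"])
        dropped_conditions: list[str] = []
        if variable == "spindle_freq":
            for cond, g in sub.groupby("condition", observed=True):
                if g["channel"].nunique() < min_channel_frac * n_channels:
                    dropped_conditions.append(str(cond))
            sub = sub[~sub["condition"].isin(dropped_conditions)]
        entry: dict = {"dropped_conditions": sorted(dropped_conditions)}

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            anova = anova_two_way(sub, variable, ss_type=ss_type)
            entry["anova"] = anova.to_dict()
            if sub["condition"].nunique() >= 2:
                entry["tukey_condition"] = tukey_hsd(sub, variable, "condition", alpha).to_dict()
            if sub["hemisphere"].nunique() >= 2:
                entry["tukey_hemisphere"] = tukey_hsd(sub, variable, "hemisphere", alpha).to_dict()

            active = sub[sub["condition"] == "active"]
            if not active.empty and active["time_point"].nunique() >= 2:
                entry["within_active"] = {
                    "anova": anova_one_way(active, variable, "time_point").to_dict(),
                    "tukey_time_point": tukey_hsd(active, variable, "time_point", alpha).to_dict(),
                }
        report["variables"][variable] = entry
    return report
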