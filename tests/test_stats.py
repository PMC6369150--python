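"""ANOVA and Tukey HSD against hand computation and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from adsleep.stats import (
    anova_one_way,
    anova_two_way,
    build_study_table,
    run_paper_analysis,
    tukey_hsd,
)
from adsleep.synthetic import DEFAULT_CONDITION_MAP


def _table(rows):
    df = pd.DataFrame(rows, columns=["condition", "hemisphere", "value"])
    df["variable"] = "v"
    df["time_point"] = "TP1"
    df["channel"] = "C3"
    return df


def _balanced_fixture():
    # 2 hemispheres x 3 conditions x 2 replicates, small integers
    data = {
        ("pre", "left"): [3.0, 5.0],
        ("pre", "right"): [2.0, 4.0],
        ("active", "left"): [6.0, 8.0],
        ("active", "right"): [5.0, 9.0],
        ("post", "left"): [1.0, 3.0],
        ("post", "right"): [2.0, 2.0],
    }
    rows = [(c, h, v) for (c, h), vals in data.items() for v in vals]
    return _table(rows)


def _balanced_two_way_oracle(df):
    """Textbook balanced two-way ANOVA from cell/marginal means."""
    y = df["value"].to_numpy()
    grand = y.mean()
    a_levels = sorted(df["condition"].unique())
    b_levels = sorted(df["hemisphere"].unique())
    n = len(df) // (len(a_levels) * len(b_levels))
    ss_a = sum(
        len(df[df.condition == a]) * (df[df.condition == a]["value"].mean() - grand) ** 2
        for a in a_levels
    )
    ss_b = sum(
        len(df[df.hemisphere == b]) * (df[df.hemisphere == b]["value"].mean() - grand) ** 2
        for b in b_levels
    )
    ss_cells = 0.0
    ss_e = 0.0
    for a in a_levels:
        for b in b_levels:
            cell = df[(df.condition == a) & (df.hemisphere == b)]["value"]
            ss_cells += n * (cell.mean() - grand) ** 2
            ss_e += ((cell - cell.mean()) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    df_a, df_b = len(a_levels) - 1, len(b_levels) - 1
    df_ab = df_a * df_b
    df_e = len(df) - len(a_levels) * len(b_levels)
    mse = ss_e / df_e
    return {
        "condition": (ss_a / df_a / mse, df_a, df_e),
        "hemisphere": (ss_b / df_b / mse, df_b, df_e),
        "condition:hemisphere": (ss_ab / df_ab / mse, df_ab, df_e),
    }


def test_balanced_two_way_matches_hand_computed_sums_of_squares():
    df = _balanced_fixture()
    res = anova_two_way(df, "v")
    oracle = _balanced_two_way_oracle(df)
    for effect, (F, dfn, dfd) in oracle.items():
        got = res.effects[effect]
        assert got.F == pytest.approx(F, abs=1e-10)
        assert (got.df_num, got.df_den) == (dfn, dfd)
        assert got.p == pytest.approx(sps.f.sf(F, dfn, dfd), abs=1e-12)


def _type2_oracle(df):
    """Brute-force Type II F statistics from nested least-squares fits."""
    def rss(terms):
        X = [np.ones(len(df))]
        for t in terms:
            if ":" in t:
                a, b = t.split(":")
                d = pd.get_dummies(df[a].astype(str) + "|" + df[b].astype(str), drop_first=False)
            else:
                d = pd.get_dummies(df[t], drop_first=False)
            X.append(d.to_numpy(float))
        X = np.column_stack(X)
        y = df["value"].to_numpy(float)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r), int(np.linalg.matrix_rank(X))

    rss_full, rank_full = rss(["condition", "hemisphere", "condition:hemisphere"])
    df_e = len(df) - rank_full
    mse = rss_full / df_e
    out = {}
    rss_ab, _ = rss(["condition", "hemisphere"])
    rss_a, _ = rss(["condition"])
    rss_b, _ = rss(["hemisphere"])
    ss = {
        "condition": rss_b - rss_ab,
        "hemisphere": rss_a - rss_ab,
        "condition:hemisphere": rss_ab - rss_full,
    }
    dfs = {
        "condition": df["condition"].nunique() - 1,
        "hemisphere": df["hemisphere"].nunique() - 1,
    }
    dfs["condition:hemisphere"] = dfs["condition"] * dfs["hemisphere"]
    for k, v in ss.items():
        out[k] = (v / dfs[k] / mse, dfs[k], df_e)
    return out


def test_unbalanced_type2_matches_nested_least_squares_oracle():
    rng = np.random.default_rng(3)
    rows = []
    sizes = {("pre", "left"): 4, ("pre", "right"): 2, ("active", "left"): 6,
             ("active", "right"): 5, ("post", "left"): 3, ("post", "right"): 7}
    for (c, h), n in sizes.items():
        for v in rng.normal(loc={"pre": 0, "active": 1, "post": 0.5}[c], size=n):
            rows.append((c, h, v))
    df = _table(rows)
    res = anova_two_way(df, "v", ss_type=2)
    oracle = _type2_oracle(df)
    for effect, (F, dfn, dfd) in oracle.items():
        got = res.effects[effect]
        assert got.F == pytest.approx(F, rel=1e-8)
        assert (got.df_num, got.df_den) == (dfn, dfd)


def test_identical_cell_means_give_zero_F():
    rows = []
    for c in ("pre", "active", "post"):
        for h in ("left", "right"):
            rows += [(c, h, 1.0), (c, h, 3.0)]  # every cell mean = 2
    res = anova_two_way(_table(rows), "v")
    for eff in res.effects.values():
        assert eff.F == pytest.approx(0.0, abs=1e-10)


def test_single_level_factor_dropped_with_warning():
    rows = [("pre", "left", v) for v in (1.0, 2.0)] + [
        ("active", "left", v) for v in (3.0, 4.0)
    ]
    with pytest.warns(UserWarning, match="hemisphere.*dropped"):
        res = anova_two_way(_table(rows), "v")
    assert "hemisphere" in res.dropped
    assert set(res.effects) == {"condition"}


def test_empty_cell_drops_interaction_with_warning():
    rows = [
        ("pre", "left", 1.0), ("pre", "left", 2.0),
        ("pre", "right", 2.0), ("pre", "right", 1.5),
        ("active", "left", 3.0), ("active", "left", 4.0),
        # no (active, right) cell
    ]
    with pytest.warns(UserWarning, match="interaction"):
        res = anova_two_way(_table(rows), "v")
    assert not any(":" in k for k in res.effects)


# ---------------------------------------------------------------------------
# Tukey HSD
# ---------------------------------------------------------------------------

def test_two_group_tukey_equals_pooled_t_test():
    rng = np.random.default_rng(9)
    a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 17)
    rows = [("pre", "left", v) for v in a] + [("active", "left", v) for v in b]
    tk = tukey_hsd(_table(rows), "v", "condition")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    (cmp_,) = tk.comparisons
    assert cmp_.q == pytest.approx(np.sqrt(2) * abs(t), rel=1e-10)
    assert cmp_.p_adj == pytest.approx(p, abs=1e-6)


def test_identical_groups_give_p_one():
    rows = [("pre", "left", 2.0)] * 3 + [("active", "left", 2.0)] * 3
    tk = tukey_hsd(_table(rows), "v", "condition")
    (cmp_,) = tk.comparisons
    assert cmp_.mean_diff == 0.0 and cmp_.p_adj == 1.0 and not cmp_.significant


def test_only_shifted_group_is_significant():
    rng = np.random.default_rng(4)
    rows = []
    for cond, mu in (("pre", 0.0), ("active", 0.0), ("post", 3.0)):  # 3 SD shift
        rows += [(cond, "left", v) for v in rng.normal(mu, 1.0, 30)]
    tk = tukey_hsd(_table(rows), "v", "condition")
    sig = {frozenset((c.level_a, c.level_b)): c.significant for c in tk.comparisons}
    assert sig[frozenset(("post", "pre"))]
    assert sig[frozenset(("active", "post"))]
    assert not sig[frozenset(("active", "pre"))]


def test_tukey_matches_statsmodels_on_unbalanced_groups():
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    rng = np.random.default_rng(11)
    groups = {"pre": 8, "active": 14, "post": 5}
    rows, flat_vals, flat_groups = [], [], []
    for g, n in groups.items():
        vals = rng.normal({"pre": 0, "active": 1.0, "post": 0.3}[g], 1.0, n)
        rows += [(g, "left", v) for v in vals]
        flat_vals += list(vals)
        flat_groups += [g] * n
    tk = tukey_hsd(_table(rows), "v", "condition")
    sm = pairwise_tukeyhsd(np.array(flat_vals), np.array(flat_groups))
    sm_p = {frozenset(pair): p for pair, p in
            zip(zip(sm.groupsunique[sm._multicomp.pairindices[0]],
                    sm.groupsunique[sm._multicomp.pairindices[1]]), sm.pvalues)}
    for c in tk.comparisons:
        assert c.p_adj == pytest.approx(sm_p[frozenset((c.level_a, c.level_b))], abs=1e-6)


def test_tukey_single_level_errors():
    rows = [("pre", "left", 1.0), ("pre", "left", 2.0)]
    with pytest.raises(ValueError, match="single level"):
        tukey_hsd(_table(rows), "v", "condition")


# ---------------------------------------------------------------------------
# study table and full analysis
# ---------------------------------------------------------------------------

def _features(n_tp=5, channels=("F3", "F4", "FC5", "FC6", "C3", "C4")):
    rows = []
    rng = np.random.default_rng(0)
    for tp in [f"TP{i+1}" for i in range(n_tp)]:
        for ch in channels:
            for var in ("spindle_power", "spindle_freq", "delta_power", "alpha_power"):
                rows.append(dict(time_point=tp, channel=ch, variable=var,
                                 value=float(rng.normal(10, 1))))
    return pd.DataFrame(rows)


def test_build_study_table_counts_and_hemispheres():
    table = build_study_table(_features(), DEFAULT_CONDITION_MAP)
    assert len(table) == 5 * 6 * 4
    assert set(table.loc[table.channel.isin(["F3", "FC5", "C3"]), "hemisphere"]) == {"left"}
    assert set(table.loc[table.channel.isin(["F4", "FC6", "C4"]), "hemisphere"]) == {"right"}


def test_build_study_table_errors():
    feats = _features()
    with pytest.raises(ValueError, match="condition_map"):
        build_study_table(feats, {"TP1": "pre"})
    bad = feats.copy()
    bad.loc[0, "channel"] = "CZ"  # midline: no hemisphere
    with pytest.raises(ValueError):
        build_study_table(bad, DEFAULT_CONDITION_MAP)


def test_spindle_freq_condition_dropped_when_mostly_peakless():
    feats = _features()
    # post condition (TP5): spindle_freq present in C3 only
    drop = (feats.time_point == "TP5") & (feats.variable == "spindle_freq") & (
        feats.channel != "C3"
    )
    feats = feats[~drop]
    table = build_study_table(feats, DEFAULT_CONDITION_MAP)
    report = run_paper_analysis(table)
    entry = report["variables"]["spindle_freq"]
    assert entry["dropped_conditions"] == ["post"]
    levels = {c["level_a"] for c in entry["tukey_condition"]["comparisons"]} | {
        c["level_b"] for c in entry["tukey_condition"]["comparisons"]
    }
    assert "post" not in levels


def test_one_way_within_active():
    feats = _features()
    table = build_study_table(feats, DEFAULT_CONDITION_MAP)
    active = table[table.condition == "active"]
    res = anova_one_way(active, "delta_power", "time_point")
    assert set(res.effects) == {"time_point"}
    assert res.effects["time_point"].df_num == 2
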