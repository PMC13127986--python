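import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from neurocarousel import (analyze_metric, anova_tukey, correlate,
                           groups_from_table, kw_dunn, mean_sem,
                           normality_gate, rm_anova_balanced)


# ---------------------------------------------------------------------------
# independent brute-force oracles (defining formulas, no library calls)

def brute_force_f(arrays):
    k = len(arrays)
    n = sum(len(a) for a in arrays)
    grand = np.concatenate(arrays).mean()
    ssb = sum(len(a) * (np.mean(a) - grand) ** 2 for a in arrays)
    ssw = sum(np.sum((np.asarray(a) - np.mean(a)) ** 2) for a in arrays)
    return (ssb / (k - 1)) / (ssw / (n - k))


def brute_force_h(arrays):
    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    offset = 0
    h = 0.0
    for a in arrays:
        r = ranks[offset:offset + len(a)]
        h += len(a) * (r.mean() - (n + 1) / 2) ** 2
        offset += len(a)
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


def brute_force_mixed_anova(table):
    """Balanced two-way mixed ANOVA from sums of squares."""
    piv = table.pivot_table(index=["group", "animal"], columns="day",
                            values="value")
    groups = piv.index.get_level_values("group")
    a = groups.nunique()
    n = len(piv) // a
    b = piv.shape[1]
    grand = piv.values.mean()
    subj_means = piv.values.mean(axis=1)
    group_means = piv.groupby("group").mean().mean(axis=1)
    day_means = piv.values.mean(axis=0)
    cell = piv.groupby("group").mean().values  # a x b
    ss_group = n * b * np.sum((group_means.values - grand) ** 2)
    ss_subj = b * np.sum((subj_means - grand) ** 2)
    ss_subj_err = ss_subj - ss_group
    ss_day = a * n * np.sum((day_means - grand) ** 2)
    ss_inter = n * np.sum((cell - group_means.values[:, None]
                           - day_means[None, :] + grand) ** 2)
    ss_total = np.sum((piv.values - grand) ** 2)
    ss_err = ss_total - ss_subj - ss_day - ss_inter
    df_err = (a * n - a) * (b - 1)
    return {
        "group": ss_group / (a - 1) / (ss_subj_err / (a * n - a)),
        "day": ss_day / (b - 1) / (ss_err / df_err),
        "interaction": ss_inter / ((a - 1) * (b - 1)) / (ss_err / df_err),
    }


# ---------------------------------------------------------------------------
# omnibus tests vs oracles

def test_anova_hand_case():
    # groups (0,0) and (1,3): SSB=4, SSW=2, F = (4/1)/(2/2) = 4
    rep = anova_tukey({"A": [0.0, 0.0], "B": [1.0, 3.0]})
    assert rep.statistic == pytest.approx(4.0, abs=1e-12)
    assert rep.df == (1, 2)


def test_kruskal_hand_case():
    # groups (1,2) and (3,4): ranks 1..4, H = 2.4
    rep = kw_dunn({"A": [1.0, 2.0], "B": [3.0, 4.0]})
    assert rep.statistic == pytest.approx(2.4, abs=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_f_and_h_match_brute_force_on_random_tables(rng, seed):
    r = np.random.default_rng(seed)
    arrays = [r.normal(size=r.integers(3, 9)) for _ in range(r.integers(2, 5))]
    groups = {f"g{i}": a for i, a in enumerate(arrays)}
    assert anova_tukey(groups).statistic == pytest.approx(
        brute_force_f(arrays), abs=1e-10)
    # include ties to exercise the correction
    tied = [np.round(a, 1) for a in arrays]
    assert kw_dunn({f"g{i}": a for i, a in enumerate(tied)}).statistic == \
        pytest.approx(brute_force_h(tied), abs=1e-10)


def test_identical_groups_give_zero_statistics():
    rep = anova_tukey({"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0]})
    assert rep.statistic == pytest.approx(0.0)
    rep = kw_dunn({"A": [5.0, 5.0], "B": [5.0, 5.0]})
    assert rep.statistic == 0.0 and rep.p == 1.0


def test_zero_within_variance_unequal_means_flagged_infinite():
    rep = anova_tukey({"A": [1.0, 1.0], "B": [2.0, 2.0]})
    assert np.isinf(rep.statistic)
    assert rep.p == 0.0


def test_tukey_null_contrast_p_near_one(rng):
    base = rng.normal(size=8)
    rep = anova_tukey({"A": base, "B": base.copy(), "C": base + 10},
                      alpha=0.05)
    assert rep.significant()
    pair = next(p for p in rep.posthoc if set(p["pair"]) == {"A", "B"})
    assert pair["p_adj"] > 0.95


def test_dunn_adjustment_monotone_in_raw_p(rng):
    groups = {"A": rng.normal(size=10), "B": rng.normal(loc=3, size=10),
              "C": rng.normal(loc=6, size=10)}
    for adjust in ("bonferroni", "holm"):
        rep = kw_dunn(groups, adjust=adjust)
        assert rep.posthoc, "omnibus should be significant"
        raws = [p["p_raw"] for p in rep.posthoc]
        adjs = [p["p_adj"] for p in rep.posthoc]
        order = np.argsort(raws)
        assert np.all(np.diff(np.array(adjs)[order]) >= -1e-12)
        assert all(a >= r - 1e-12 for a, r in zip(adjs, raws))


# ---------------------------------------------------------------------------
# normality gate

def test_gate_accepts_normal_groups_at_nominal_level():
    # per-group Shapiro-Wilk false-positive rate ~ alpha = 0.05, so the
    # joint all-groups-pass rate for k groups is ~ 0.95**k
    per_group_pass = 0
    joint = 0
    n_sims = 200
    for seed in range(n_sims):
        r = np.random.default_rng(seed)
        groups = {g: r.normal(size=10) for g in "ABC"}
        route, outcomes = normality_gate(groups)
        per_group_pass += sum(o["normal"] for o in outcomes.values())
        joint += route == "parametric"
    assert per_group_pass / (3 * n_sims) == pytest.approx(0.95, abs=0.03)
    assert joint / n_sims == pytest.approx(0.95**3, abs=0.07)


def test_gate_flags_bimodal_group():
    hits = 0
    for seed in range(50):
        r = np.random.default_rng(seed)
        bimodal = np.concatenate([r.normal(-5, 0.5, 25), r.normal(5, 0.5, 25)])
        groups = {"A": r.normal(size=50), "B": bimodal}
        route, _ = normality_gate(groups)
        hits += route == "nonparametric"
    assert hits >= 48  # >= 95 %


def test_gate_input_guards():
    with pytest.raises(ValueError, match="n=2"):
        normality_gate({"A": [1.0, 2.0], "B": [1.0, 2.0, 3.0]})
    with pytest.raises(ValueError, match="zero variance"):
        normality_gate({"A": [1.0, 1.0, 1.0], "B": [1.0, 2.0, 3.0]})


def test_kruskal_type_one_error_at_nominal_level():
    # three groups from one distribution, n=8: rejection rate ~ alpha
    rejections = 0
    n_sims = 1000
    for seed in range(n_sims):
        r = np.random.default_rng(seed)
        groups = {g: r.normal(size=8) for g in "ABC"}
        rejections += kw_dunn(groups).p < 0.05
    assert 0.03 <= rejections / n_sims <= 0.07


# ---------------------------------------------------------------------------
# mixed ANOVA

def _make_table(values):
    """values: dict group -> 2-D array (subjects x days)."""
    rows = []
    for g, mat in values.items():
        for s, row in enumerate(mat):
            for d, v in enumerate(row):
                rows.append({"animal": f"{g}{s}", "group": g, "day": d,
                             "value": float(v)})
    return pd.DataFrame(rows)


def test_rm_anova_constant_days_group_shift():
    tbl = _make_table({
        "A": np.tile([1.0, 1.0, 1.0], (4, 1)) + np.arange(4)[:, None] * 0.01,
        "B": np.tile([2.0, 2.0, 2.0], (4, 1)) + np.arange(4)[:, None] * 0.01,
    })
    rep = rm_anova_balanced(tbl)
    assert rep.effects["day"]["F"] == pytest.approx(0.0, abs=1e-9)
    assert rep.effects["group"]["F"] > 100


def test_rm_anova_day_trend_no_group_effect():
    base = np.tile(np.arange(3.0), (4, 1))
    tbl = _make_table({"A": base + np.random.default_rng(0).normal(0, 1e-3, base.shape),
                       "B": base + np.random.default_rng(1).normal(0, 1e-3, base.shape)})
    rep = rm_anova_balanced(tbl)
    assert rep.effects["day"]["F"] > 1e4
    assert rep.effects["group"]["p"] > 0.05


@pytest.mark.parametrize("seed", range(3))
def test_rm_anova_matches_brute_force(seed):
    r = np.random.default_rng(seed)
    tbl = _make_table({"A": r.normal(size=(5, 4)), "B": r.normal(size=(5, 4)),
                       "C": r.normal(size=(5, 4))})
    rep = rm_anova_balanced(tbl)
    oracle = brute_force_mixed_anova(tbl)
    for effect in ("group", "day", "interaction"):
        assert rep.effects[effect]["F"] == pytest.approx(oracle[effect],
                                                         rel=1e-9)


def test_rm_anova_matches_pingouin_with_unequal_groups():
    # independent library cross-check, including unequal group sizes
    pg = pytest.importorskip("pingouin")
    r = np.random.default_rng(10)
    tbl = _make_table({"A": r.normal(size=(7, 5)), "B": r.normal(size=(5, 5)),
                       "C": r.normal(size=(5, 5))})
    rep = rm_anova_balanced(tbl)
    aov = pg.mixed_anova(data=tbl, dv="value", within="day",
                         subject="animal", between="group")
    ref = {{"Interaction": "interaction"}.get(s, s): f
           for s, f in zip(aov["Source"], aov["F"])}
    for effect in ("group", "day", "interaction"):
        assert rep.effects[effect]["F"] == pytest.approx(ref[effect], rel=1e-9)


def test_rm_anova_rejects_missing_cells():
    tbl = _make_table({"A": np.ones((3, 3)), "B": np.ones((3, 3))})
    tbl = tbl[~((tbl.animal == "A0") & (tbl.day == 2))]
    with pytest.raises(ValueError, match="mixed-effects"):
        rm_anova_balanced(tbl)


def test_rm_anova_detects_programmed_interaction():
    # group B drifts across days; detection at the programmed effect size
    hits = 0
    n_sims = 50
    for seed in range(n_sims):
        r = np.random.default_rng(seed)
        a = r.normal(0, 1, size=(6, 4))
        b = r.normal(0, 1, size=(6, 4)) + np.arange(4) * 1.0
        rep = rm_anova_balanced(_make_table({"A": a, "B": b}))
        hits += rep.effects["interaction"]["p"] < 0.05
    assert hits >= 0.8 * n_sims


# ---------------------------------------------------------------------------
# correlation, summaries, chain

def test_correlation_identity_and_reflection(rng):
    x = rng.normal(size=10)
    assert correlate(x, x)[0] == pytest.approx(1.0)
    assert correlate(x, -x)[0] == pytest.approx(-1.0)
    assert correlate(x, x, method="spearman")[0] == pytest.approx(1.0)


def test_correlation_null_behaviour():
    rs, rejections = [], 0
    n_sims = 500
    for seed in range(n_sims):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=20), r.normal(size=20)
        cr, p = correlate(x, y)
        rs.append(abs(cr))
        rejections += p < 0.05
    assert np.mean(rs) == pytest.approx(0.18, abs=0.03)
    assert 0.02 <= rejections / n_sims <= 0.08


def test_correlation_guards(rng):
    with pytest.raises(ValueError):
        correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(ValueError):
        correlate([1.0, 2.0], [1.0, 2.0])


def test_mean_sem_values():
    m, s = mean_sem([1.0, 2.0, 3.0])
    assert m == pytest.approx(2.0)
    assert s == pytest.approx(1.0 / np.sqrt(3))
    assert mean_sem([4.0, 4.0, 4.0])[1] == 0.0
    m1, s1 = mean_sem([7.0])
    assert m1 == 7.0 and np.isnan(s1)


def test_analyze_metric_records_gate_and_route(rng):
    groups = {"A": rng.normal(size=8), "B": rng.normal(loc=5, size=8)}
    rep = analyze_metric(groups)
    assert rep.gate["route"] in ("parametric", "nonparametric")
    assert set(rep.gate["shapiro"]) == {"A", "B"}


def test_groups_from_table_slices_one_metric():
    tbl = pd.DataFrame({
        "animal": ["a", "b", "c", "d"],
        "group": ["G1", "G1", "G2", "G2"],
        "metric": ["m", "m", "m", "m"],
        "value": [1.0, 2.0, 3.0, 4.0],
    })
    groups = groups_from_table(tbl, "m")
    np.testing.assert_array_equal(groups["G2"], [3.0, 4.0])
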