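import itertools

import numpy as np
import pandas as pd
import pytest

import fpvs
from fpvs.stats import effect_p


def _mixed_table(n_per_group=(8, 8), k_a=3, k_b=2, seed=0,
                 effects=None):
    """Balanced-or-not split-plot data: group x A(condition) x
    B(stimulus_type)."""
    rng = np.random.default_rng(seed)
    effects = effects or {}
    rows = []
    for g, n in zip(("NT", "autism"), n_per_group):
        for i in range(n):
            s = f"{g}{i:02d}"
            subj = rng.normal(0, 1)
            for a in range(k_a):
                for b in range(k_b):
                    mu = (effects.get(("a", a), 0)
                          + effects.get(("g", g), 0)
                          + effects.get(("ga", (g, a)), 0))
                    rows.append((s, g, f"A{a}", f"B{b}",
                                 mu + subj + rng.normal(0, 1)))
    return pd.DataFrame(rows, columns=["subject", "group", "condition",
                                       "stimulus_type", "value"])


# ---------------------------------------------------------------------------
# brute-force cell-means oracle (balanced designs)
# ---------------------------------------------------------------------------

def _brute_force_ss(table):
    """Classical cell-means decomposition for a balanced group x A x B
    split-plot design, computed with explicit marginal means."""
    subjects = list(pd.unique(table["subject"]))
    A = list(pd.unique(table["condition"]))
    B = list(pd.unique(table["stimulus_type"]))
    g_of = table.groupby("subject")["group"].first()
    groups = list(pd.unique(table["group"]))
    Y = {}
    for _, r in table.iterrows():
        Y[(r["subject"], r["condition"], r["stimulus_type"])] = r["value"]

    def mean(subj=None, a=None, b=None, group=None):
        vals = [Y[(s, x, y)] for s in subjects for x in A for y in B
                if (subj is None or s == subj)
                and (a is None or x == a) and (b is None or y == b)
                and (group is None or g_of[s] == group)]
        return np.mean(vals)

    N = len(subjects)
    nA, nB = len(A), len(B)
    m = nA * nB
    mu = mean()
    n_g = {g: sum(g_of[s] == g for s in subjects) for g in groups}

    ss = {}
    ss["group"] = m * sum(n_g[g] * (mean(group=g) - mu) ** 2
                          for g in groups)
    ss["subj(group)"] = m * sum(
        (mean(subj=s) - mean(group=g_of[s])) ** 2 for s in subjects)
    ss["condition"] = N * nB * sum((mean(a=a) - mu) ** 2 for a in A)
    ss["condition * group"] = nB * sum(
        n_g[g] * (mean(a=a, group=g) - mean(group=g) - mean(a=a) + mu) ** 2
        for g in groups for a in A)
    ss["condition_err"] = nB * sum(
        (mean(subj=s, a=a) - mean(subj=s)
         - mean(a=a, group=g_of[s]) + mean(group=g_of[s])) ** 2
        for s in subjects for a in A)
    ss["stimulus_type"] = N * nA * sum((mean(b=b) - mu) ** 2 for b in B)
    ss["stimulus_type * group"] = nA * sum(
        n_g[g] * (mean(b=b, group=g) - mean(group=g) - mean(b=b) + mu) ** 2
        for g in groups for b in B)
    ss["stimulus_type_err"] = nA * sum(
        (mean(subj=s, b=b) - mean(subj=s)
         - mean(b=b, group=g_of[s]) + mean(group=g_of[s])) ** 2
        for s in subjects for b in B)
    ss["condition * stimulus_type"] = N * sum(
        (mean(a=a, b=b) - mean(a=a) - mean(b=b) + mu) ** 2
        for a in A for b in B)
    ss["condition * stimulus_type * group"] = sum(
        n_g[g] * (mean(a=a, b=b, group=g) - mean(a=a, group=g)
                  - mean(b=b, group=g) - mean(a=a, b=b)
                  + mean(a=a) + mean(b=b) + mean(group=g) - mu) ** 2
        for g in groups for a in A for b in B)
    ss["condition * stimulus_type_err"] = sum(
        (Y[(s, a, b)] - mean(subj=s, a=a) - mean(subj=s, b=b)
         - mean(a=a, b=b, group=g_of[s]) + mean(subj=s)
         + mean(a=a, group=g_of[s]) + mean(b=b, group=g_of[s])
         - mean(group=g_of[s])) ** 2
        for s in subjects for a in A for b in B)
    return ss


def test_anova_matches_brute_force_cell_means_oracle():
    table = _mixed_table(n_per_group=(6, 6), seed=12)
    got = fpvs.mixed_anova(table, within=("condition", "stimulus_type"))
    oracle = _brute_force_ss(table)
    by_name = got.set_index("effect")
    for eff in ("group", "condition", "stimulus_type",
                "condition * group", "stimulus_type * group",
                "condition * stimulus_type",
                "condition * stimulus_type * group"):
        assert by_name.loc[eff, "ss_effect"] == pytest.approx(
            oracle[eff], rel=1e-8), eff
    assert by_name.loc["group", "ss_error"] == pytest.approx(
        oracle["subj(group)"], rel=1e-8)
    assert by_name.loc["condition", "ss_error"] == pytest.approx(
        oracle["condition_err"], rel=1e-8)
    assert by_name.loc["condition * stimulus_type", "ss_error"] == \
        pytest.approx(oracle["condition * stimulus_type_err"], rel=1e-8)


def test_ss_decomposition_adds_to_total():
    # balanced design: effect and error SS partition the total exactly
    # (with unequal n, Type III SS are deliberately non-additive)
    bal = _mixed_table(n_per_group=(6, 6), seed=4)
    got_b = fpvs.mixed_anova(bal, within=("condition", "stimulus_type"))
    by_b = got_b.set_index("effect")
    total_b = float(((bal["value"] - bal["value"].mean()) ** 2).sum())
    acc_b = (by_b.loc["group", "ss_effect"]
             + by_b.loc["group", "ss_error"])
    for eff in ("condition", "stimulus_type",
                "condition * stimulus_type"):
        acc_b += (by_b.loc[eff, "ss_effect"]
                  + by_b.loc[f"{eff} * group", "ss_effect"]
                  + by_b.loc[eff, "ss_error"])
    assert acc_b == pytest.approx(total_b, rel=1e-8)


def test_printed_degrees_of_freedom_for_study_sample_sizes():
    """Groups of 19 and 23 give (2, 80) for a 3-level within factor and
    (1, 40) for a 2-level within factor; the between-group t has df 40."""
    table = _mixed_table(n_per_group=(19, 23), seed=1)
    a3 = fpvs.mixed_anova(table[table["stimulus_type"] == "B0"],
                          within=("condition",))
    row = a3.set_index("effect").loc["condition"]
    assert (row["df_num"], row["df_den"]) == (2, 80)
    sub2 = table[(table["condition"] != "A2")
                 & (table["stimulus_type"] == "B0")]
    a2 = fpvs.mixed_anova(sub2, within=("condition",))
    row2 = a2.set_index("effect").loc["condition"]
    assert (row2["df_num"], row2["df_den"]) == (1, 40)
    t = fpvs.independent_t(np.random.default_rng(0).normal(size=19),
                           np.random.default_rng(1).normal(size=23))
    assert t.df == 40


def test_anova_group_terms_match_pingouin_balanced():
    pg = pytest.importorskip("pingouin")
    table = _mixed_table(n_per_group=(9, 9), seed=7)
    sub = table[table["stimulus_type"] == "B0"]
    mine = fpvs.mixed_anova(sub, within=("condition",)).set_index(
        "effect")
    theirs = pg.mixed_anova(data=sub, dv="value", within="condition",
                            subject="subject", between="group")
    theirs = theirs.set_index("Source")
    assert mine.loc["group", "F"] == pytest.approx(
        theirs.loc["group", "F"], rel=1e-9)
    assert mine.loc["condition", "F"] == pytest.approx(
        theirs.loc["condition", "F"], rel=1e-9)
    assert mine.loc["condition * group", "F"] == pytest.approx(
        theirs.loc["Interaction", "F"], rel=1e-9)
    assert mine.loc["condition", "p"] == pytest.approx(
        theirs.loc["condition", "p_unc"], rel=1e-9)


def test_eta_squared_definition_and_range():
    table = _mixed_table(n_per_group=(6, 6), seed=3,
                         effects={("a", 0): 1.0})
    out = fpvs.mixed_anova(table, within=("condition", "stimulus_type"))
    for _, r in out.iterrows():
        assert 0 <= r["partial_eta_sq"] <= 1
        assert r["partial_eta_sq"] == pytest.approx(
            r["ss_effect"] / (r["ss_effect"] + r["ss_error"]))


class TestSphericity:
    def _one_group(self, cov, n=40, seed=0):
        rng = np.random.default_rng(seed)
        Y = rng.multivariate_normal(np.zeros(cov.shape[0]), cov, size=n)
        rows = [(f"s{i}", f"A{j}", Y[i, j]) for i in range(n)
                for j in range(cov.shape[0])]
        return pd.DataFrame(rows, columns=["subject", "condition",
                                           "value"])

    def test_compound_symmetry_satisfies_sphericity(self):
        cov = np.full((3, 3), 0.7) + np.eye(3) * 1.0
        t = self._one_group(cov, n=2000, seed=5)
        res = fpvs.mauchly(t, "condition", between=None)
        assert res.W > 0.99
        assert res.p > 0.05
        assert res.df == 2  # k(k-1)/2 - 1 for k = 3
        assert fpvs.gg_epsilon(t, "condition", between=None) > 0.99

    def test_rank_one_contrast_covariance_hits_lower_bound(self):
        # all within-level differences proportional: eps = 1/(k-1) = 0.5
        rng = np.random.default_rng(6)
        rows = []
        for i in range(25):
            base, slope = rng.normal(size=2)
            for j, lev in enumerate(("A0", "A1", "A2")):
                rows.append((f"s{i}", lev, base + slope * j))
        t = pd.DataFrame(rows, columns=["subject", "condition", "value"])
        assert fpvs.gg_epsilon(t, "condition", between=None) == \
            pytest.approx(0.5, abs=1e-9)

    def test_matches_eigenvalue_formula_oracle(self):
        cov = np.array([[2.0, 0.5, 0.1], [0.5, 1.0, 0.3],
                        [0.1, 0.3, 0.7]])
        t = self._one_group(cov, n=30, seed=9)
        # oracle: eigenvalues of the orthonormal-contrast covariance
        piv = t.pivot_table(index="subject", columns="condition",
                            values="value")
        C = np.linalg.qr(
            np.array([[1.0, 1.0], [-1.0, 0.0], [0.0, -1.0]]))[0]
        Z = piv.to_numpy() @ C
        S = np.cov(Z.T, ddof=1)
        lam = np.linalg.eigvalsh(S)
        eps_oracle = lam.sum() ** 2 / (len(lam) * (lam ** 2).sum())
        W_oracle = np.prod(lam) / (lam.mean() ** len(lam))
        assert fpvs.gg_epsilon(t, "condition", between=None) == \
            pytest.approx(eps_oracle, abs=1e-10)
        assert fpvs.mauchly(t, "condition", between=None).W == \
            pytest.approx(W_oracle, abs=1e-10)

    def test_two_levels_rejected(self):
        t = self._one_group(np.eye(2), n=10)
        with pytest.raises(ValueError):
            fpvs.mauchly(t, "condition", between=None)

    def test_matches_pingouin_single_group(self):
        pg = pytest.importorskip("pingouin")
        t = self._one_group(np.array([[2.0, 0.5, 0.1], [0.5, 1.0, 0.3],
                                      [0.1, 0.3, 0.7]]), n=25, seed=2)
        res = fpvs.mauchly(t, "condition", between=None)
        sph = pg.sphericity(t, dv="value", within="condition",
                            subject="subject")
        assert res.W == pytest.approx(sph.W, rel=1e-9)
        assert res.p == pytest.approx(sph.pval, rel=1e-6)
        eps = pg.epsilon(t, dv="value", within="condition",
                         subject="subject", correction="gg")
        assert fpvs.gg_epsilon(t, "condition", between=None) == \
            pytest.approx(eps, rel=1e-9)


class TestTTests:
    def test_paired_matches_scipy(self):
        from scipy import stats as spstats

        rng = np.random.default_rng(0)
        x, y = rng.normal(size=15), rng.normal(size=15)
        mine = fpvs.paired_t(x, y)
        ref = spstats.ttest_rel(x, y)
        assert mine.t == pytest.approx(ref.statistic)
        assert mine.p == pytest.approx(ref.pvalue)
        assert mine.df == 14
        d = x - y
        assert mine.effect == pytest.approx(d.mean() / d.std(ddof=1))

    def test_independent_matches_scipy(self):
        from scipy import stats as spstats

        rng = np.random.default_rng(1)
        x, y = rng.normal(size=19), rng.normal(1, 1, size=23)
        mine = fpvs.independent_t(x, y)
        ref = spstats.ttest_ind(x, y)
        assert mine.t == pytest.approx(ref.statistic)
        assert mine.p == pytest.approx(ref.pvalue)
        sp = np.sqrt(((19 - 1) * x.var(ddof=1) + (23 - 1) * y.var(ddof=1))
                     / 40)
        assert mine.effect == pytest.approx((x.mean() - y.mean()) / sp)

    def test_identical_vectors_are_a_true_null(self):
        x = np.array([1.0, 2.0, 3.0])
        res = fpvs.paired_t(x, x)
        assert (res.t, res.effect, res.p) == (0.0, 0.0, 1.0)

    def test_constant_nonzero_difference_is_degenerate(self):
        with pytest.raises(ValueError):
            fpvs.paired_t(np.array([1.0, 2.0, 3.0]),
                          np.array([2.0, 3.0, 4.0]))

    def test_f_equals_squared_paired_t_for_two_levels(self):
        rng = np.random.default_rng(8)
        rows = []
        for i in range(12):
            base = rng.normal()
            rows.append((f"s{i}", "A0", base + rng.normal()))
            rows.append((f"s{i}", "A1", base + 0.5 + rng.normal()))
        t = pd.DataFrame(rows, columns=["subject", "condition", "value"])
        a = fpvs.mixed_anova(t, within=("condition",), between=None)
        piv = t.pivot_table(index="subject", columns="condition",
                            values="value")
        tt = fpvs.paired_t(piv["A0"], piv["A1"])
        row = a.set_index("effect").loc["condition"]
        assert row["F"] == pytest.approx(tt.t ** 2, rel=1e-9)
        assert row["p"] == pytest.approx(tt.p, rel=1e-9)


class TestBonferroni:
    def test_examples(self):
        assert fpvs.bonferroni([0.01], m=3)[0] == pytest.approx(0.03)
        assert fpvs.bonferroni([0.6], m=3)[0] == 1.0
        assert list(fpvs.bonferroni([0.2, 0.04], m=2)) == \
            pytest.approx([0.4, 0.08])
        assert fpvs.bonferroni([0.2], m=1)[0] == pytest.approx(0.2)

    def test_m_smaller_than_count_rejected(self):
        with pytest.raises(ValueError):
            fpvs.bonferroni([0.1, 0.2, 0.3], m=2)


class TestAnovaValidation:
    def test_missing_cell_rejected(self):
        table = _mixed_table(n_per_group=(4, 4))
        broken = table.drop(table.index[0])
        with pytest.raises(ValueError):
            fpvs.mixed_anova(broken, within=("condition",
                                             "stimulus_type"))

    def test_duplicate_observation_rejected(self):
        table = _mixed_table(n_per_group=(4, 4))
        dup = pd.concat([table, table.iloc[:1]], ignore_index=True)
        with pytest.raises(ValueError):
            fpvs.mixed_anova(dup, within=("condition", "stimulus_type"))

    def test_single_subject_group_rejected(self):
        table = _mixed_table(n_per_group=(1, 5))
        with pytest.raises(ValueError):
            fpvs.mixed_anova(table, within=("condition",))

    def test_gg_correction_is_conservative_for_f_above_one(self):
        # reducing both dfs by epsilon raises the tail probability
        # whenever F >= 1 (for F << 1 the inequality can reverse, which
        # is immaterial: such effects are never significant)
        table = _mixed_table(n_per_group=(8, 8), seed=2,
                             effects={("a", 0): 0.8})
        out = fpvs.mixed_anova(table, within=("condition",
                                              "stimulus_type"))
        for _, r in out.iterrows():
            if np.isfinite(r["p_gg"]) and r["F"] >= 1.0:
                assert r["p_gg"] >= r["p"] - 1e-12


class TestRunPaperContrasts:
    def test_detects_designed_group_interaction_for_faces_only(self):
        cfg = fpvs.SimulationConfig(n_per_group={"NT": 24, "autism": 20})
        table = fpvs.simulate_subject_table(cfg, seed=5)
        rep = fpvs.run_study_contrasts(table)
        assert rep.detects_condition_group_interaction("Faces")
        assert not rep.detects_condition_group_interaction("Names")
        assert not rep.reversed_self_close_group_difference()
        assert {"parieto-occipital", "frontocentral",
                "parieto-occipital/Faces", "parieto-occipital/Names",
                "frontocentral/Faces", "frontocentral/Names"} <= set(
            rep.anovas)
        assert (rep.ttests["p_adj"] >= rep.ttests["p"] - 1e-12).all()
        assert "t(" in rep.to_text() or "t-tests" in rep.to_text()

    def test_single_group_skips_group_terms(self):
        cfg = fpvs.SimulationConfig(n_per_group={"NT": 6, "autism": 0})
        table = fpvs.simulate_subject_table(cfg, seed=1)
        rep = fpvs.run_study_contrasts(table)
        assert any("single group" in n for n in rep.notes)
        assert "group" not in set(rep.anovas["parieto-occipital"]
                                  ["effect"])
        assert (rep.ttests["kind"] == "paired").all()


def test_effect_p_uses_gg_only_when_mauchly_significant():
    table = _mixed_table(n_per_group=(8, 8), seed=2)
    out = fpvs.mixed_anova(table[table["stimulus_type"] == "B0"],
                          within=("condition",))
    row = out.set_index("effect").loc["condition"]
    expected = row["p_gg"] if row["mauchly_p"] < 0.05 else row["p"]
    assert effect_p(out, "condition") == pytest.approx(expected)
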