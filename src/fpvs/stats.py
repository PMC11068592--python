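"""Mixed repeated-measures ANOVA and follow-up tests, from first principles.

The design handled here is the split-plot layout of the study: one
between-subjects factor (group, possibly with unequal group sizes) fully
crossed with up to three within-subjects factors, every subject observed in
every within-cell exactly once.

Each within effect is evaluated on the projection of the per-subject cell
vectors onto an orthonormal contrast basis (Kronecker products of
per-factor Helmert contrasts and unit vectors).  Sums of squares are Type
III via model comparison on effect-coded group regressors, which for this
balanced-within design reproduces the classical univariate mixed-model
decomposition (and, for equal group sizes, the textbook cell-means
formulas).  Sphericity (Mauchly) and the Greenhouse-Geisser epsilon are
computed from the pooled within-group covariance of the same contrast
scores.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _helmert(k: int) -> np.ndarray:
    """Orthonormal contrast matrix, k x (k-1), columns orthogonal to 1."""
    h = np.zeros((k, k - 1))
    for j in range(1, k):
        h[:j, j - 1] = 1.0
        h[j, j - 1] = -j
        h[:, j - 1] /= np.linalg.norm(h[:, j - 1])
    return h


def _rss(X: np.ndarray, Y: np.ndarray) -> float:
    """Residual sum of squares of Y on X (columns summed)."""
    if X.shape[1] == 0:
        return float((Y ** 2).sum())
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return float(((Y - X @ beta) ** 2).sum())


def _effect_coding(groups: np.ndarray, levels: list) -> np.ndarray:
    """n x (G-1) effect-coded (sum-to-zero) group regressors."""
    out = np.zeros((len(groups), len(levels) - 1))
    for j, lev in enumerate(levels[:-1]):
        out[groups == lev, j] = 1.0
    out[groups == levels[-1], :] = -1.0
    return out


def _pivot(table: pd.DataFrame, dv: str, within: tuple[str, ...],
           subject: str, between: str | None):
    """Return (wide ndarray, group labels, within level lists, cell index)."""
    levels = [list(pd.unique(table[f])) for f in within]
    cells = list(itertools.product(*levels))
    agg = table.groupby([subject, *within], sort=False)[dv]
    counts = agg.count()
    if (counts != 1).any():
        bad = counts[counts != 1]
        raise ValueError(
            f"design must have exactly one observation per subject x cell; "
            f"offending cells: {bad.index.tolist()[:5]}")
    piv = table.pivot_table(index=subject, columns=list(within), values=dv,
                            sort=False)
    piv = piv.reindex(columns=(cells if len(within) > 1
                               else [c[0] for c in cells]))
    if piv.isna().any().any():
        raise ValueError("incomplete design: missing subject x cell values")
    if between is not None:
        gmap = table.groupby(subject)[between].agg(pd.unique)
        if any(len(g) != 1 for g in gmap):
            raise ValueError("a subject appears in more than one group")
        groups = np.array([gmap[s][0] for s in piv.index])
    else:
        groups = np.array(["all"] * len(piv))
    return piv.to_numpy(dtype=float), groups, levels


def _contrast_basis(within: tuple[str, ...], levels: list[list],
                    effect: tuple[str, ...]) -> np.ndarray:
    """Kronecker contrast basis for a within effect (m cells x q)."""
    mats = []
    for f, lev in zip(within, levels):
        k = len(lev)
        mats.append(_helmert(k) if f in effect
                    else np.full((k, 1), 1.0 / np.sqrt(k)))
    C = mats[0]
    for m in mats[1:]:
        C = np.kron(C, m)
    return C


# ---------------------------------------------------------------------------
# sphericity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SphericityResult:
    W: float
    chi_sq: float
    df: int
    p: float


def _pooled_contrast_cov(Z: np.ndarray, groups: np.ndarray
                         ) -> tuple[np.ndarray, int]:
    """Pooled within-group covariance of contrast scores; (S, df)."""
    levels = list(pd.unique(groups))
    resid = Z.copy()
    for g in levels:
        resid[groups == g] -= Z[groups == g].mean(axis=0)
    df = len(Z) - len(levels)
    return resid.T @ resid / df, df


def _gg_epsilon_from_cov(S: np.ndarray) -> float:
    q = S.shape[0]
    tr = np.trace(S)
    denom = q * float((S * S).sum())
    if denom <= 0:
        return 1.0
    return float(min(1.0, max(tr * tr / denom, 1.0 / q)))


def _mauchly_from_cov(S: np.ndarray, df_resid: int) -> SphericityResult:
    q = S.shape[0]
    det = float(np.linalg.det(S))
    tr = float(np.trace(S))
    W = det / (tr / q) ** q if tr > 0 and det > 0 else np.finfo(float).tiny
    W = min(W, 1.0)
    d = q * (q + 1) // 2 - 1
    f = 1.0 - (2 * q * q + q + 2) / (6.0 * q * df_resid)
    chi2 = -f * df_resid * np.log(W)
    p = float(spstats.chi2.sf(chi2, d))
    return SphericityResult(W=float(W), chi_sq=float(chi2), df=d, p=p)


def _within_scores(table, factor_or_effect, dv, subject, between):
    effect = ((factor_or_effect,) if isinstance(factor_or_effect, str)
              else tuple(factor_or_effect))
    wide, groups, levels = _pivot(table, dv, effect, subject, between)
    C = _contrast_basis(effect, levels, effect)
    return wide @ C, groups


def mauchly(table: pd.DataFrame, factor, dv: str = "value",
            subject: str = "subject", between: str | None = "group"
            ) -> SphericityResult:
    """Mauchly's sphericity test for a within factor (k >= 3 levels)."""
    Z, groups = _within_scores(table, factor, dv, subject, between)
    if Z.shape[1] < 2:
        raise ValueError("sphericity is trivial for fewer than 3 levels")
    S, df_resid = _pooled_contrast_cov(Z, groups)
    return _mauchly_from_cov(S, df_resid)


def gg_epsilon(table: pd.DataFrame, factor, dv: str = "value",
               subject: str = "subject", between: str | None = "group"
               ) -> float:
    """Greenhouse-Geisser (Box) epsilon for a within factor."""
    Z, groups = _within_scores(table, factor, dv, subject, between)
    if Z.shape[1] < 2:
        raise ValueError("epsilon is undefined for fewer than 3 levels")
    S, _ = _pooled_contrast_cov(Z, groups)
    return _gg_epsilon_from_cov(S)


# ---------------------------------------------------------------------------
# the mixed ANOVA
# ---------------------------------------------------------------------------

ANOVA_COLUMNS = ["effect", "ss_effect", "ss_error", "df_num", "df_den",
                 "F", "p", "partial_eta_sq", "epsilon_gg", "p_gg",
                 "mauchly_w", "mauchly_p"]


def mixed_anova(table: pd.DataFrame, within, dv: str = "value",
                subject: str = "subject", between: str | None = "group"
                ) -> pd.DataFrame:
    """Univariate mixed (split-plot) ANOVA.

    Returns one row per effect with F, p, partial eta squared and — for
    within effects with more than one numerator df — the
    Greenhouse-Geisser epsilon, GG-corrected p and Mauchly statistics.
    """
    within = (within,) if isinstance(within, str) else tuple(within)
    wide, groups, levels = _pivot(table, dv, within, subject, between)
    n = len(wide)
    group_levels = list(pd.unique(groups))
    G = len(group_levels)
    if between is not None and G < 2:
        raise ValueError("between factor needs at least two groups "
                         "(pass between=None for a single group)")
    if min((groups == g).sum() for g in group_levels) < 2:
        raise ValueError("need at least two subjects per group")

    Xg = _effect_coding(groups, group_levels) if between else \
        np.empty((n, 0))
    ones = np.ones((n, 1))
    X_full = np.hstack([ones, Xg])
    X_no_int = Xg
    X_no_grp = ones

    rows = []

    def _row(name, ss_e, ss_err, df1, df2, eps=None, mau=None):
        F = (ss_e / df1) / (ss_err / df2) if ss_err > 0 else np.inf
        p = float(spstats.f.sf(F, df1, df2))
        etap = ss_e / (ss_e + ss_err) if ss_e + ss_err > 0 else 0.0
        if eps is not None:
            p_gg = float(spstats.f.sf(F, eps * df1, eps * df2))
        else:
            p_gg = p if df1 == 1 else np.nan
        rows.append({
            "effect": name, "ss_effect": ss_e, "ss_error": ss_err,
            "df_num": df1, "df_den": df2, "F": float(F), "p": p,
            "partial_eta_sq": float(etap),
            "epsilon_gg": eps if eps is not None else
            (1.0 if df1 == 1 else np.nan),
            "p_gg": p_gg,
            "mauchly_w": mau.W if mau else np.nan,
            "mauchly_p": mau.p if mau else np.nan,
        })

    # between-subjects part: subject means (scaled by the unit contrast)
    m = wide.shape[1]
    z0 = wide @ np.full((m, 1), 1.0 / np.sqrt(m))
    if between is not None:
        ss_grp = _rss(X_no_grp, z0) - _rss(X_full, z0)
        ss_sub = _rss(X_full, z0)
        _row(between, ss_grp, ss_sub, G - 1, n - G)

    # within-subject effects and their group interactions
    for r in range(1, len(within) + 1):
        for effect in itertools.combinations(within, r):
            C = _contrast_basis(within, levels, effect)
            q = C.shape[1]
            Z = wide @ C
            rss_full = _rss(X_full, Z)
            ss_eff = _rss(X_no_int, Z) - rss_full
            eps = mau = None
            if q > 1:
                S, df_resid = _pooled_contrast_cov(Z, groups)
                eps = _gg_epsilon_from_cov(S)
                mau = _mauchly_from_cov(S, df_resid)
            name = " * ".join(effect)
            _row(name, ss_eff, rss_full, q, q * (n - G), eps, mau)
            if between is not None:
                ss_int = _rss(X_no_grp, Z) - rss_full
                _row(f"{name} * {between}", ss_int, rss_full,
                     q * (G - 1), q * (n - G), eps, mau)

    return pd.DataFrame(rows, columns=ANOVA_COLUMNS)


def effect_p(anova: pd.DataFrame, effect: str, gg_alpha: float = 0.05
             ) -> float:
    """The reported p for an effect: GG-corrected when the effect has more
    than one numerator df and Mauchly's test is significant."""
    row = anova[anova["effect"] == effect]
    if row.empty:
        raise KeyError(f"no effect {effect!r} in table")
    row = row.iloc[0]
    if row["df_num"] > 1 and np.isfinite(row["mauchly_p"]) \
            and row["mauchly_p"] < gg_alpha:
        return float(row["p_gg"])
    return float(row["p"])


# ---------------------------------------------------------------------------
# t-tests and multiplicity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TTestResult:
    kind: str                 # "paired" | "independent"
    t: float
    df: int
    p: float
    effect: float             # Cohen's dz (paired) or d (independent)
    bonferroni_m: int | None = None
    p_adj: float | None = None

    def with_bonferroni(self, m: int) -> "TTestResult":
        return TTestResult(self.kind, self.t, self.df, self.p, self.effect,
                           bonferroni_m=m, p_adj=min(1.0, m * self.p))


def paired_t(x, y) -> TTestResult:
    """Two-tailed paired t-test with Cohen's dz = mean(d)/sd(d)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("paired test needs two equal-length vectors, n>=2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        if np.all(d == 0):  # identical vectors: a true null, not an error
            return TTestResult("paired", 0.0, len(d) - 1, 1.0, 0.0)
        raise ValueError("zero variance of differences; t undefined")
    n = len(d)
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * spstats.t.sf(abs(t), n - 1)
    return TTestResult("paired", float(t), n - 1, float(p),
                       float(d.mean() / sd))


def independent_t(x, y) -> TTestResult:
    """Two-tailed independent t-test (pooled SD) with Cohen's d."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("independent test needs n >= 2 per group")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance; t undefined")
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    p = 2 * spstats.t.sf(abs(t), df)
    return TTestResult("independent", float(t), df, float(p),
                       float((x.mean() - y.mean()) / np.sqrt(sp2)))


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """p_adj = min(1, m*p), order preserved; m defaults to len(p)."""
    p = np.asarray(list(p_values), dtype=float)
    m = len(p) if m is None else m
    if m < len(p):
        raise ValueError("m must be at least the number of p-values")
    return np.minimum(1.0, m * p)


# ---------------------------------------------------------------------------
# the full analysis plan
# ---------------------------------------------------------------------------

_PAIRS = (("Self", "CloseOther"), ("Self", "Stranger"),
          ("CloseOther", "Stranger"))


@dataclass
class ContrastReport:
    """Structured output of the omnibus + follow-up analysis plan."""

    anovas: dict[str, pd.DataFrame]
    ttests: pd.DataFrame
    notes: list[str] = field(default_factory=list)
    alpha: float = 0.05

    def condition_group_p(self, stimulus_type: str) -> float:
        key = f"parieto-occipital/{stimulus_type}"
        return effect_p(self.anovas[key], "condition * group")

    def detects_condition_group_interaction(self, stimulus_type: str
                                            ) -> bool:
        return self.condition_group_p(stimulus_type) < self.alpha

    def group_difference_tests(self, stimulus_type: str) -> pd.DataFrame:
        t = self.ttests
        return t[(t["stimulus_type"] == stimulus_type)
                 & (t["kind"] == "independent")]

    def reversed_self_close_group_difference(self) -> bool:
        """True if the Faces Self-CloseOther group comparison came out
        significant in the wrong direction (autism > NT)."""
        t = self.group_difference_tests("Faces")
        row = t[t["contrast"] == "Self-CloseOther"]
        if row.empty:
            return False
        row = row.iloc[0]
        return bool(row["p"] < self.alpha and row["t"] < 0)

    def to_text(self) -> str:
        lines = []
        for name, tab in self.anovas.items():
            lines.append(f"== ANOVA: {name} ==")
            for _, r in tab.iterrows():
                extra = ""
                if r["df_num"] > 1 and np.isfinite(r["mauchly_p"]):
                    extra = (f", eps_GG={r['epsilon_gg']:.3f},"
                             f" p_GG={r['p_gg']:.4g}"
                             f" (Mauchly p={r['mauchly_p']:.3g})")
                lines.append(
                    f"  {r['effect']}: F({r['df_num']:g},{r['df_den']:g})"
                    f" = {r['F']:.2f}, p = {r['p']:.4g}, "
                    f"eta_p^2 = {r['partial_eta_sq']:.3f}{extra}")
        lines.append("== t-tests ==")
        for _, r in self.ttests.iterrows():
            lines.append(
                f"  [{r['stimulus_type']}] {r['contrast']} ({r['kind']}): "
                f"t({r['df']}) = {r['t']:.2f}, p = {r['p']:.4g}, "
                f"{r['effect_kind']} = {r['effect_size']:.2f}, "
                f"p_bonf = {r['p_adj']:.4g}")
        for n in self.notes:
            lines.append(f"note: {n}")
        return "\n".join(lines)


def _po_condition_means(table: pd.DataFrame) -> pd.DataFrame:
    """Per-subject condition means over the two PO clusters (per stim)."""
    po = table[table["roi"].isin(["left-PO", "right-PO"])]
    return (po.groupby(["subject", "group", "stimulus_type", "condition"],
                       sort=False)["value"].mean().reset_index())


def run_study_contrasts(table: pd.DataFrame, alpha: float = 0.05
                        ) -> ContrastReport:
    """Execute the omnibus + follow-up analysis plan on a ROI table.

    Omnibus mixed ANOVAs for the parieto-occipital clusters (with a
    laterality factor) and the frontocentral cluster; per-stimulus-type
    follow-up ANOVAs; pairwise condition paired t-tests; and between-group
    t-tests on condition difference scores.  Raw and Bonferroni-adjusted
    p-values are both reported.
    """
    notes: list[str] = []
    groups = list(pd.unique(table["group"]))
    between = "group" if len(groups) >= 2 else None
    if between is None:
        notes.append("single group supplied; group terms skipped")

    po = table[table["roi"].isin(["left-PO", "right-PO"])].copy()
    fc = table[table["roi"] == "frontocentral"]
    anovas: dict[str, pd.DataFrame] = {}
    anovas["parieto-occipital"] = mixed_anova(
        po, within=("stimulus_type", "condition", "laterality"),
        between=between)
    anovas["frontocentral"] = mixed_anova(
        fc, within=("stimulus_type", "condition"), between=between)

    stim_types = list(pd.unique(table["stimulus_type"]))
    for stim in stim_types:
        anovas[f"parieto-occipital/{stim}"] = mixed_anova(
            po[po["stimulus_type"] == stim],
            within=("condition", "laterality"), between=between)
        anovas[f"frontocentral/{stim}"] = mixed_anova(
            fc[fc["stimulus_type"] == stim], within=("condition",),
            between=between)

    if between is not None:
        p3 = effect_p(anovas["parieto-occipital"],
                      "stimulus_type * condition * group")
        notes.append("stimulus_type * condition * group omnibus p = "
                     f"{p3:.4g}; follow-ups reported per stimulus type")

    means = _po_condition_means(table)
    trows = []
    for stim in stim_types:
        sub = means[means["stimulus_type"] == stim]
        piv = sub.pivot_table(index=["subject", "group"],
                              columns="condition", values="value")
        for a, b in _PAIRS:
            res = paired_t(piv[a], piv[b]).with_bonferroni(len(_PAIRS))
            trows.append((stim, f"{a}-{b}", res))
        if between is not None:
            g1 = piv.index.get_level_values("group") == groups[0]
            for a, b in _PAIRS:
                diff = piv[a] - piv[b]
                res = independent_t(diff[g1], diff[~g1]) \
                    .with_bonferroni(len(_PAIRS))
                trows.append((stim, f"{a}-{b}", res))

    ttests = pd.DataFrame(
        [(stim, contrast, r.kind, r.t, r.df, r.p,
          r.effect, "dz" if r.kind == "paired" else "d",
          r.bonferroni_m, r.p_adj)
         for stim, contrast, r in trows],
        columns=["stimulus_type", "contrast", "kind", "t", "df", "p",
                 "effect_size", "effect_kind", "m", "p_adj"])
    if between is not None:
        notes.append(f"group order for independent tests: {groups[0]} "
                     f"minus {groups[1]}")
    return ContrastReport(anovas=anovas, ttests=ttests, notes=notes,
                          alpha=alpha)
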