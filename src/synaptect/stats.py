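"""Genotype group statistics: normality-gated two-group tests, two-way ANOVA
with Bonferroni post hoc comparisons, and a PCA outlier screen.

The decision procedure mirrors common slice-physiology practice: Shapiro–Wilk
on each group at α = 0.05 decides between an unpaired two-sided t-test
(reporting DF = n₁ + n₂ − 2) and a Mann–Whitney U test (exact for small
samples).  Within-group factorial designs use a two-factor fixed-effect ANOVA
(Type III sums of squares, sum-to-zero contrasts) followed by per-level
Bonferroni-adjusted comparisons.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

SHAPIRO_ALPHA = 0.05


def normality_gate(a, b, alpha: float = SHAPIRO_ALPHA) -> str:
    """Shapiro–Wilk gate: ``"parametric"`` iff both groups pass at ``alpha``."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    for g in (a, b):
        if len(g) < 3:
            raise ValueError("Shapiro–Wilk needs at least 3 observations per group")
    for g in (a, b):
        if np.ptp(g) == 0:
            return "nonparametric"  # degenerate (constant) sample: not normal
        if sps.shapiro(g).pvalue < alpha:
            return "nonparametric"
    return "parametric"


@dataclasses.dataclass
class GroupComparison:
    """Two-group comparison with the gated test and reporting fields."""

    test_used: str            # "unpaired_t" or "mann_whitney"
    statistic: float          # t or U
    df_or_u: float            # DF (t-test) or U (Mann–Whitney)
    p_value: float
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    n_a: int
    n_b: int

    def report(self) -> str:
        """Figure-legend style string, e.g. ``unpaired t-test, p = 0.0278; DF = 11``."""
        if self.test_used == "unpaired_t":
            return f"unpaired t-test, p = {self.p_value:.4f}; DF = {int(self.df_or_u)}"
        return f"Mann–Whitney test, p = {self.p_value:.4f}; U = {self.df_or_u:g}"


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else float("nan")


def compare_groups(a, b, force: str | None = None) -> GroupComparison:
    """Two-sided between-group comparison behind the normality gate.

    ``force`` overrides the gate with ``"parametric"`` or ``"nonparametric"``.
    The t-test is the classic equal-variance unpaired test, so
    DF = n₁ + n₂ − 2; Mann–Whitney uses the exact null distribution when
    sample sizes permit.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    branch = force or normality_gate(a, b)
    if branch == "parametric":
        res = sps.ttest_ind(a, b, equal_var=True)
        test, stat, aux = "unpaired_t", float(res.statistic), float(len(a) + len(b) - 2)
        p = float(res.pvalue)
        if np.isnan(stat):  # identical constant groups
            stat, p = 0.0, 1.0
    else:
        method = "exact" if (len(a) <= 20 and len(b) <= 20) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        test, stat, aux = "mann_whitney", float(res.statistic), float(res.statistic)
        p = float(res.pvalue)
    return GroupComparison(
        test_used=test,
        statistic=stat,
        df_or_u=aux,
        p_value=min(p, 1.0),
        mean_a=float(np.mean(a)),
        sem_a=_sem(a),
        mean_b=float(np.mean(b)),
        sem_b=_sem(b),
        n_a=len(a),
        n_b=len(b),
    )


@dataclasses.dataclass
class AnovaResult:
    """Two-factor ANOVA with per-level Bonferroni post hoc comparisons.

    ``effects`` maps effect name (genotype, level, interaction) to
    ``(F, dfn, dfd, p)``; ``posthoc`` maps level to
    ``(t, raw_p, bonferroni_p)`` for the genotype contrast at that level.
    """

    effects: dict[str, tuple[float, float, float, float]]
    posthoc: dict[object, tuple[float, float, float]]

    def genotype_p(self) -> float:
        return self.effects["genotype"][3]


def two_way_anova_bonferroni(
    table: pd.DataFrame,
    value: str = "value",
    genotype: str = "genotype",
    level: str = "level",
) -> AnovaResult:
    """Two-factor fixed-effect ANOVA (genotype × level) with interaction.

    Type III sums of squares with sum-to-zero contrasts (the convention of
    common GraphPad-style analyses); repeated factors are treated as fixed on
    cell means — an approximation, documented in the package methods note.
    Post hoc: per-level equal-variance t-tests with Bonferroni adjustment
    (adjusted p = min(1, raw p × number of levels)).  A single-level table
    degenerates to the one-way case, where F = t².
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table.rename(columns={value: "y", genotype: "g", level: "lvl"}).copy()
    if df["g"].nunique() != 2:
        raise ValueError("exactly two genotype groups required")
    levels = sorted(df["lvl"].unique())

    if len(levels) == 1:
        groups = [grp["y"].to_numpy() for _, grp in df.groupby("g")]
        res = sps.ttest_ind(groups[0], groups[1], equal_var=True)
        dfd = len(df) - 2
        effects = {"genotype": (float(res.statistic) ** 2, 1.0, float(dfd), float(res.pvalue))}
        posthoc = {levels[0]: (float(res.statistic), float(res.pvalue), float(min(1.0, res.pvalue)))}
        return AnovaResult(effects=effects, posthoc=posthoc)

    model = smf.ols("y ~ C(g, Sum) * C(lvl, Sum)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=3)

    def row(name: str) -> tuple[float, float, float, float]:
        r = aov.loc[name]
        dfd = float(aov.loc["Residual", "df"])
        return float(r["F"]), float(r["df"]), dfd, float(r["PR(>F)"])

    effects = {
        "genotype": row("C(g, Sum)"),
        "level": row("C(lvl, Sum)"),
        "interaction": row("C(g, Sum):C(lvl, Sum)"),
    }
    k = len(levels)
    posthoc = {}
    g_names = sorted(df["g"].unique())
    for lvl in levels:
        sub = df[df["lvl"] == lvl]
        x = sub[sub["g"] == g_names[0]]["y"].to_numpy()
        y = sub[sub["g"] == g_names[1]]["y"].to_numpy()
        res = sps.ttest_ind(x, y, equal_var=True)
        raw = float(res.pvalue)
        posthoc[lvl] = (float(res.statistic), raw, float(min(1.0, raw * k)))
    return AnovaResult(effects=effects, posthoc=posthoc)


def pca_outlier_screen(
    matrix: pd.DataFrame | np.ndarray,
    k_components: int = 2,
    threshold_sd: float = 3.0,
    labels: pd.Series | np.ndarray | None = None,
) -> list:
    """Flag samples far from their group centroid in PC-score space.

    ``matrix`` is genes × samples (or features × samples).  Samples whose
    robust z-score (median / 1.4826·MAD) exceeds ``threshold_sd`` on any of
    the first ``k_components`` PC scores, within their own group, are flagged.
    Flagging only — exclusion is the caller's decision.  The flag set is
    invariant to sample order.
    """
    if isinstance(matrix, pd.DataFrame):
        sample_names = list(matrix.columns)
        x = matrix.to_numpy(dtype=float).T  # samples × features
    else:
        x = np.asarray(matrix, dtype=float).T
        sample_names = list(range(x.shape[0]))
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    k = min(k_components, n - 1, x.shape[1])
    xc = x - x.mean(axis=0, keepdims=True)
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    scores = xc @ vt[:k].T  # samples × k

    if labels is None:
        groups = {None: np.arange(n)}
    else:
        lab = np.asarray(labels)
        groups = {g: np.nonzero(lab == g)[0] for g in np.unique(lab)}

    flagged = []
    for idx in groups.values():
        s = scores[idx]
        med = np.median(s, axis=0)
        mad = np.median(np.abs(s - med), axis=0) * 1.4826
        mad[mad == 0] = np.finfo(float).eps
        z = np.abs(s - med) / mad
        for i_local, i_global in enumerate(idx):
            if np.any(z[i_local] > threshold_sd):
                flagged.append(sample_names[i_global])
    return sorted(flagged, key=lambda s: str(s))
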