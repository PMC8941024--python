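"""Two-environment comparison battery.

The analysis compares response variables between environments (sunny vs
shaded) and collection months in a completely randomized two-way factorial
scheme:

* mortality proportions — Pearson chi-square test of equal proportions on
  the 2x2 table, with or without Yates continuity correction;
* a Shapiro-Wilk normality gate routing each variable to the parametric or
  the nonparametric branch;
* parametric branch — two-way ANOVA with Tukey HSD multiple comparisons
  and a compact letter display;
* nonparametric branch — the Scheirer-Ray-Hare rank test (the two-factor
  extension of Kruskal-Wallis: factorial sums of squares are computed on
  the pooled mid-ranks and each effect's H = SS_effect / MS_total is
  referred to a chi-square distribution), followed by Dunn's pairwise
  z-tests on mean ranks with Benjamini-Hochberg false-discovery-rate
  adjustment.

Shapiro-Wilk, ANOVA/Tukey and the BH step are delegated to scipy and
statsmodels; the Scheirer-Ray-Hare decomposition, Dunn's z with tie
correction, the 2x2 closed form and the letter display are implemented
here.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "MortalityTable",
    "equal_proportions_test",
    "normality_gate",
    "two_way_anova_tukey",
    "scheirer_ray_hare",
    "dunn_test",
    "compact_letter_display",
]

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    method: str
    adjustment: str | None = None

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class MortalityTable:
    """Queen deaths out of founded nests, per environment."""

    deaths_sunny: int
    n_sunny: int
    deaths_shaded: int
    n_shaded: int

    def __post_init__(self) -> None:
        if not (0 <= self.deaths_sunny <= self.n_sunny):
            raise ValueError("sunny deaths must lie in [0, n_sunny]")
        if not (0 <= self.deaths_shaded <= self.n_shaded):
            raise ValueError("shaded deaths must lie in [0, n_shaded]")

    @property
    def proportions(self) -> tuple[float, float]:
        return self.deaths_sunny / self.n_sunny, self.deaths_shaded / self.n_shaded


def equal_proportions_test(
    table: MortalityTable, continuity_correction: bool = False
) -> TestResult:
    """Pearson chi-square test that two proportions are equal (1 df).

    Closed form on the 2x2 table: X^2 = N (ad - bc)^2 / (R1 R2 C1 C2),
    with Yates' correction subtracting N/2 from |ad - bc| when requested.
    """
    a, b = table.deaths_sunny, table.n_sunny - table.deaths_sunny
    c, d = table.deaths_shaded, table.n_shaded - table.deaths_shaded
    n = a + b + c + d
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        raise ValueError("a zero marginal total leaves the test undefined")
    cross = abs(a * d - b * c)
    if continuity_correction:
        cross = max(cross - n / 2.0, 0.0)
    chi2 = n * cross**2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return TestResult(
        statistic=float(chi2),
        df=1.0,
        p_value=float(sps.chi2.sf(chi2, 1)),
        method="equal proportions chi-square"
        + (" (Yates)" if continuity_correction else ""),
    )


def normality_gate(
    values, alpha: float = DEFAULT_ALPHA
) -> tuple[str, TestResult]:
    """Route a sample to the parametric or nonparametric branch.

    Shapiro-Wilk at significance ``alpha``: p >= alpha keeps the parametric
    route.  A constant sample (W undefined) routes nonparametric, as no
    normal model can be asserted for it.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError("Shapiro-Wilk needs at least 3 observations")
    if np.ptp(x) == 0.0:
        res = TestResult(float("nan"), float(x.size), float("nan"), "Shapiro-Wilk")
        return "nonparametric", res
    w, p = sps.shapiro(x)
    res = TestResult(float(w), float(x.size), float(p), "Shapiro-Wilk")
    return ("parametric" if p >= alpha else "nonparametric"), res


# ---------------------------------------------------------------------------
# compact letter display


def compact_letter_display(
    ordered_levels, significant_pairs
) -> dict[str, str]:
    """Insert-and-absorb letter display from a pairwise significance set.

    ``ordered_levels`` lists the group labels from best to worst (the
    caller orders by mean or mean rank, breaking ties by label);
    ``significant_pairs`` is an iterable of 2-tuples of labels that differ
    significantly.  Groups sharing a letter do not differ.
    """
    levels = list(ordered_levels)
    pos = {g: i for i, g in enumerate(levels)}
    columns: list[set] = [set(levels)]
    for i, j in sorted(tuple(sorted(p, key=lambda g: pos[g])) for p in significant_pairs):
        new_cols: list[set] = []
        for col in columns:
            if i in col and j in col:
                new_cols.append(col - {i})
                new_cols.append(col - {j})
            else:
                new_cols.append(col)
        # absorb: drop duplicates and strict subsets
        columns = []
        for c in new_cols:
            if any(c < o for o in new_cols):
                continue
            if c not in columns and c:
                columns.append(c)
    columns.sort(key=lambda c: min(pos[g] for g in c))
    letters = {g: "" for g in levels}
    for letter_idx, col in enumerate(columns):
        ch = chr(ord("a") + letter_idx)
        for g in col:
            letters[g] += ch
    return {g: "".join(sorted(s)) for g, s in letters.items()}


# ---------------------------------------------------------------------------
# parametric branch


def two_way_anova_tukey(
    data: pd.DataFrame,
    response: str,
    factor_env: str = "environment",
    factor_month: str = "month",
    alpha: float = DEFAULT_ALPHA,
) -> dict:
    """Two-way factorial ANOVA with Tukey HSD letters per factor.

    Uses type-II sums of squares.  Every cell of the env x month grid must
    be occupied.  Returns a dict with ``anova`` (TestResult per term),
    ``tukey`` (per-factor pairwise frames) and ``letters`` (per-factor
    compact letter display at ``alpha``).
    """
    df = pd.DataFrame(
        {
            "y": data[response].to_numpy(dtype=float),
            "env": data[factor_env].astype(str).to_numpy(),
            "mon": data[factor_month].astype(str).to_numpy(),
        }
    )
    counts = df.groupby(["env", "mon"]).size()
    n_env, n_mon = df["env"].nunique(), df["mon"].nunique()
    if n_env < 2 or n_mon < 2:
        raise ValueError("each factor needs at least 2 levels")
    if len(counts) < n_env * n_mon:
        raise ValueError("empty factorial cell(s); ANOVA grid must be complete")

    model = ols("y ~ C(env) * C(mon)", data=df).fit()
    table = anova_lm(model, typ=2)
    term_map = {
        factor_env: "C(env)",
        factor_month: "C(mon)",
        "interaction": "C(env):C(mon)",
    }
    anova_results = {
        name: TestResult(
            statistic=float(table.loc[key, "F"]),
            df=float(table.loc[key, "df"]),
            p_value=float(table.loc[key, "PR(>F)"]),
            method="two-way ANOVA (type II)",
        )
        for name, key in term_map.items()
    }

    tukey_frames: dict[str, pd.DataFrame] = {}
    letters: dict[str, dict[str, str]] = {}
    for name, col in ((factor_env, "env"), (factor_month, "mon")):
        hsd = pairwise_tukeyhsd(df["y"], df[col], alpha=alpha)
        frame = pd.DataFrame(
            hsd.summary().data[1:], columns=hsd.summary().data[0]
        )
        tukey_frames[name] = frame
        means = df.groupby(col)["y"].mean()
        ordered = sorted(means.index, key=lambda g: (-means[g], g))
        sig = {
            (row["group1"], row["group2"])
            for _, row in frame.iterrows()
            if bool(row["reject"])
        }
        letters[name] = compact_letter_display(ordered, sig)
    return {"anova": anova_results, "tukey": tukey_frames, "letters": letters}


# ---------------------------------------------------------------------------
# nonparametric branch


def _rank_ss_balanced(df: pd.DataFrame) -> dict[str, float]:
    grand = df["r"].mean()
    ss = {}
    for term, cols in (("a", ["a"]), ("b", ["b"]), ("cells", ["a", "b"])):
        grp = df.groupby(cols)["r"]
        ss[term] = float((grp.count() * (grp.mean() - grand) ** 2).sum())
    ss["ab"] = ss.pop("cells") - ss["a"] - ss["b"]
    return ss


def _rank_ss_type2(df: pd.DataFrame) -> dict[str, float]:
    model = ols("r ~ C(a) * C(b)", data=df).fit()
    table = anova_lm(model, typ=2)
    return {
        "a": float(table.loc["C(a)", "sum_sq"]),
        "b": float(table.loc["C(b)", "sum_sq"]),
        "ab": float(table.loc["C(a):C(b)", "sum_sq"]),
    }


def scheirer_ray_hare(
    data: pd.DataFrame,
    response: str,
    factor_a: str = "environment",
    factor_b: str = "month",
) -> pd.DataFrame:
    """Scheirer-Ray-Hare rank test for a two-way factorial design.

    The pooled response is ranked with mid-ranks for ties; factorial sums
    of squares are computed on the ranks and each effect's statistic
    H = SS_effect / MS_total, with MS_total = SS_total / (N - 1), is
    referred to a chi-square law with the effect's df.  Mid-ranking makes
    MS_total the tie-adjusted variance, so no separate tie factor is
    needed.  Balanced designs use the exact factorial decomposition;
    unbalanced designs fall back to type-II rank sums of squares.

    A factor held at a single level is allowed: its SS is zero, its rows
    (and the interaction) carry 0 df with NaN H and p, and the remaining
    factor's H reduces exactly to the tie-corrected Kruskal-Wallis
    statistic.

    Returns a tidy frame with one row per term (factor_a, factor_b,
    interaction, residual, total) and columns term, ss, df, H, p_value.
    """
    y = data[response].to_numpy(dtype=float)
    if np.ptp(y) == 0.0:
        raise ValueError("all responses tied: rank variance is zero")
    df = pd.DataFrame(
        {
            "r": sps.rankdata(y),
            "a": data[factor_a].astype(str).to_numpy(),
            "b": data[factor_b].astype(str).to_numpy(),
        }
    )
    n = len(df)
    ka, kb = df["a"].nunique(), df["b"].nunique()
    if max(ka, kb) < 2:
        raise ValueError("at least one factor needs 2 or more levels")
    ss_total = float(((df["r"] - df["r"].mean()) ** 2).sum())
    ms_total = ss_total / (n - 1)

    counts = df.groupby(["a", "b"]).size()
    balanced = len(counts) == ka * kb and counts.nunique() == 1
    if balanced or min(ka, kb) == 1:
        ss = _rank_ss_balanced(df)
    else:
        ss = _rank_ss_type2(df)

    dfs = {"a": ka - 1, "b": kb - 1, "ab": (ka - 1) * (kb - 1)}
    rows = []
    for term, label in (("a", factor_a), ("b", factor_b), ("ab", "interaction")):
        if dfs[term] == 0:
            rows.append({"term": label, "ss": ss[term], "df": 0, "H": np.nan, "p_value": np.nan})
            continue
        h = ss[term] / ms_total
        rows.append(
            {
                "term": label,
                "ss": ss[term],
                "df": dfs[term],
                "H": h,
                "p_value": float(sps.chi2.sf(h, dfs[term])),
            }
        )
    ss_model = ss["a"] + ss["b"] + ss["ab"]
    rows.append(
        {
            "term": "residual",
            "ss": ss_total - ss_model,
            "df": n - 1 - sum(dfs.values()),
            "H": np.nan,
            "p_value": np.nan,
        }
    )
    rows.append({"term": "total", "ss": ss_total, "df": n - 1, "H": np.nan, "p_value": np.nan})
    return pd.DataFrame(rows)


def dunn_test(
    values,
    groups,
    p_adjust: str = "fdr",
    alpha: float = DEFAULT_ALPHA,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Dunn's pairwise rank comparisons after a Kruskal-Wallis-type omnibus.

    Pooled mid-ranks; for groups i, j the statistic is

        z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)),

    with tie term T = sum over tied sets of (t^3 - t).  Two-sided p per
    pair; Benjamini-Hochberg adjustment when ``p_adjust="fdr"``.  Returns
    the pairwise table and a compact letter display from the adjusted
    p-values at ``alpha`` (groups ordered by mean rank, descending, ties
    broken by label).
    """
    if p_adjust not in ("fdr", "none"):
        raise ValueError("p_adjust must be 'fdr' or 'none'")
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if y.shape != g.shape:
        raise ValueError("values and groups must have equal length")
    labels = sorted(pd.unique(g).tolist())
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    sizes = {lab: int((g == lab).sum()) for lab in labels}
    if any(s == 0 for s in sizes.values()):
        raise ValueError("every group needs at least one observation")

    n = y.size
    ranks = sps.rankdata(y)
    mean_rank = {lab: float(ranks[g == lab].mean()) for lab in labels}
    _, tie_counts = np.unique(y, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    base_var = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))

    rows = []
    for g1, g2 in combinations(labels, 2):
        se = np.sqrt(base_var * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_rank[g1] - mean_rank[g2]) / se if se > 0 else 0.0
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "z": float(z),
                "p_value": float(2.0 * sps.norm.sf(abs(z))),
            }
        )
    table = pd.DataFrame(rows)
    if p_adjust == "fdr":
        table["p_adjusted"] = multipletests(table["p_value"], method="fdr_bh")[1]
        adjustment = "benjamini-hochberg"
    else:
        table["p_adjusted"] = table["p_value"]
        adjustment = None
    table.attrs["adjustment"] = adjustment

    ordered = sorted(labels, key=lambda lab: (-mean_rank[lab], lab))
    sig = {
        (row["group1"], row["group2"])
        for _, row in table.iterrows()
        if row["p_adjusted"] < alpha
    }
    letters = compact_letter_display(ordered, sig)
    return table, letters
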