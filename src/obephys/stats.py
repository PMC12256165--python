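"""The group-comparison statistical ladder and exact contingency tests.

The ladder mirrors standard practice for intrinsic-property datasets:
normality is assessed with the D'Agostino-Pearson omnibus test for larger
samples and Shapiro-Wilk otherwise; data failing the battery are screened
by the fraction of variance a fitted normal fails to explain (Q-Q R^2
surrogate); if more than 10% is unexplained a ladder of standard
transforms (log10, sqrt(x+1), 1/x, x+1) is tried, and when none renders
the data normal the factorial ANOVA is run on mid-ranks (the Akritas
rank-transform approach).  Proportions are compared with Fisher's exact
test, extended to 2xk tables by Freeman-Halton enumeration, with
Bonferroni-corrected alpha for pairwise batteries.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .core import InputError

DAGOSTINO_MIN_N = 8   # below this, Shapiro-Wilk is used
ALPHA = 0.05
UNEXPLAINED_LIMIT = 0.10
TRANSFORMS = ("log10", "sqrt_plus1", "reciprocal", "plus1")


@dataclass
class StatResult:
    """Outcome of one comparison: test, transform, statistic(s), p, post hocs."""

    test: str
    transform: str
    statistic: Optional[float]
    df: Optional[tuple]
    p: Optional[float]
    alpha: float = ALPHA
    post_hoc: list = field(default_factory=list)   # (label, adjusted p)
    terms: dict = field(default_factory=dict)      # per-factor results for ANOVAs
    notes: str = ""

    def summary(self) -> str:
        lines = [f"{self.test} (transform: {self.transform}, alpha={self.alpha:g})"]
        if self.terms:
            for name, d in self.terms.items():
                lines.append(
                    f"  {name}: F={d['F']:.4g}, df=({d['df_num']:g},{d['df_den']:g}), p={d['p']:.4g}"
                )
        elif self.p is not None:
            stat = f"{self.statistic:.4g}" if self.statistic is not None else "-"
            lines.append(f"  statistic={stat}, df={self.df}, p={self.p:.4g}")
        for label, p in self.post_hoc:
            lines.append(f"  post hoc {label}: p_adj={p:.4g}")
        if self.notes:
            lines.append(f"  note: {self.notes}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "test": self.test, "transform": self.transform,
            "statistic": self.statistic, "df": self.df, "p": self.p,
            "alpha": self.alpha, "post_hoc": list(self.post_hoc),
            "terms": self.terms, "notes": self.notes,
        }


# ---------------------------------------------------------------------------
# Normality battery and transform ladder
# ---------------------------------------------------------------------------

def normality_battery(values: Sequence[float], alpha: float = ALPHA) -> dict:
    """Normality decision: D'Agostino-Pearson for n >= 8, else Shapiro-Wilk."""
    x = np.asarray(list(values), dtype=float)
    if x.size < 3:
        raise InputError("normality assessment needs n >= 3")
    if np.ptp(x) == 0:
        return {"normal": False, "test": "degenerate", "statistic": np.nan,
                "p": 0.0, "n": int(x.size)}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if x.size >= DAGOSTINO_MIN_N:
            stat, p = sps.normaltest(x)
            test = "dagostino_pearson"
        else:
            stat, p = sps.shapiro(x)
            test = "shapiro_wilk"
    return {"normal": bool(p > alpha), "test": test,
            "statistic": float(stat), "p": float(p), "n": int(x.size)}


def variance_explained_normal_fit(values: Sequence[float]) -> float:
    """Fraction of dataset variance NOT explained by a fitted normal (Q-Q R^2).

    A normal distribution is fitted by mean/SD; the ordered data are
    regressed against the fitted-normal quantiles and the unexplained
    fraction is 1 - R^2.  Values above 0.10 flag a transform as needed.
    """
    x = np.sort(np.asarray(list(values), dtype=float))
    if x.size < DAGOSTINO_MIN_N:
        raise InputError(f"variance-explained screen needs n >= {DAGOSTINO_MIN_N}")
    if np.ptp(x) == 0:
        raise InputError("zero-variance data")
    n = x.size
    probs = (np.arange(1, n + 1) - 0.5) / n
    q = sps.norm.ppf(probs, loc=x.mean(), scale=x.std(ddof=1))
    r = np.corrcoef(x, q)[0, 1]
    return float(1.0 - r * r)


def _apply_transform(name: str, x: np.ndarray) -> Optional[np.ndarray]:
    if name == "log10":
        return np.log10(x) if np.all(x > 0) else (np.log10(x + 1) if np.all(x > -1) else None)
    if name == "sqrt_plus1":
        return np.sqrt(x + 1) if np.all(x >= -1) else None
    if name == "reciprocal":
        return 1.0 / x if np.all(x > 0) else None
    if name == "plus1":
        return x + 1.0
    raise InputError(f"unknown transform {name!r}")


def transform_ladder(
    values: Sequence[float],
    candidates: Sequence[str] = TRANSFORMS,
    alpha: float = ALPHA,
) -> Tuple[str, np.ndarray]:
    """Pick the treatment that renders the data normal, or fall back to ranks.

    Returns ``("none", x)`` when the data already pass the battery (or when
    a fitted normal leaves <= 10% of the variance unexplained), else the
    first candidate transform that passes, else ``("rank", midranks)``.
    """
    x = np.asarray(list(values), dtype=float)
    if not np.all(np.isfinite(x)):
        raise InputError("values must be finite")
    if normality_battery(x, alpha)["normal"]:
        return "none", x
    if x.size >= DAGOSTINO_MIN_N and variance_explained_normal_fit(x) <= UNEXPLAINED_LIMIT:
        return "none", x
    for name in candidates:
        tx = _apply_transform(name, x)
        if tx is None or not np.all(np.isfinite(tx)):
            continue
        if normality_battery(tx, alpha)["normal"]:
            return name, tx
    return "rank", sps.rankdata(x, method="average")


# ---------------------------------------------------------------------------
# One- and two-factor families
# ---------------------------------------------------------------------------

def _dunn_posthoc(groups: Dict[str, np.ndarray]) -> List[Tuple[str, float]]:
    """Dunn's test on pooled mid-ranks, tie-corrected, Bonferroni-adjusted."""
    labels = list(groups)
    pooled = np.concatenate([groups[k] for k in labels])
    n_tot = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie = np.sum(counts**3 - counts) / (12.0 * (n_tot - 1))
    offsets = np.cumsum([0] + [groups[k].size for k in labels])
    mean_rank = {
        k: ranks[offsets[i]: offsets[i + 1]].mean() for i, k in enumerate(labels)
    }
    m = len(labels) * (len(labels) - 1) // 2
    out = []
    for a, b in itertools.combinations(labels, 2):
        se = math.sqrt(
            (n_tot * (n_tot + 1) / 12.0 - tie) * (1.0 / groups[a].size + 1.0 / groups[b].size)
        )
        z = abs(mean_rank[a] - mean_rank[b]) / se
        p = min(1.0, 2.0 * sps.norm.sf(z) * m)
        out.append((f"{a} vs {b}", float(p)))
    return out


def one_way_family(groups: Dict[str, Sequence[float]], alpha: float = ALPHA) -> StatResult:
    """One-way ANOVA + Tukey when every group is normal; Kruskal-Wallis + Dunn otherwise."""
    gs = {k: np.asarray(list(v), dtype=float) for k, v in groups.items()}
    if len(gs) < 2:
        raise InputError("need at least two groups")
    for k, v in gs.items():
        if v.size < 2:
            raise InputError(f"group {k!r} has fewer than 2 values")
    parametric = all(
        v.size >= 3 and np.ptp(v) > 0 and normality_battery(v, alpha)["normal"]
        for v in gs.values()
    )
    labels = list(gs)
    if parametric:
        f, p = sps.f_oneway(*[gs[k] for k in labels])
        df = (len(gs) - 1, sum(v.size for v in gs.values()) - len(gs))
        values = np.concatenate([gs[k] for k in labels])
        codes = np.concatenate([[k] * gs[k].size for k in labels])
        tk = pairwise_tukeyhsd(values, codes, alpha=alpha)
        pairs = list(itertools.combinations(sorted(labels), 2))
        post = [
            (f"{g1} vs {g2}", float(padj))
            for (g1, g2), padj in zip(pairs, tk.pvalues)
        ]
        return StatResult("one_way_anova+tukey", "none", float(f), df, float(p),
                          alpha, post)
    h, p = sps.kruskal(*[gs[k] for k in labels])
    df = (len(gs) - 1, None)
    post = _dunn_posthoc(gs)
    return StatResult("kruskal_wallis+dunn", "rank", float(h), df, float(p),
                      alpha, post)


def sidak_adjust(p: float, m: int = 3) -> float:
    """Sidak multiple-comparison adjustment: 1 - (1 - p)^m.

    Evaluated as -expm1(m*log1p(-p)) so tiny p do not underflow to 0.
    """
    if p >= 1.0:
        return 1.0
    return float(-math.expm1(m * math.log1p(-p)))


def two_way_family(
    data: pd.DataFrame,
    value: str = "value",
    factor_a: str = "group",
    factor_b: str = "treatment",
    alpha: float = ALPHA,
    use_ladder: bool = True,
) -> StatResult:
    """Two-factor ANOVA (Type II SS) on raw, transformed or rank data.

    The normality->transform->rank ladder decides the data treatment
    (``use_ladder=False`` forces raw data).  Post hoc sham-vs-occluded
    contrasts within each level of ``factor_a`` use the ANOVA residual
    variance with Sidak adjustment for the three comparisons.
    """
    df = data[[value, factor_a, factor_b]].dropna().copy()
    levels_a = sorted(df[factor_a].unique())
    levels_b = sorted(df[factor_b].unique())
    for a in levels_a:
        for b in levels_b:
            if ((df[factor_a] == a) & (df[factor_b] == b)).sum() == 0:
                raise InputError(f"empty design cell: {a} x {b}")
    if use_ladder:
        transform, tx = transform_ladder(df[value].to_numpy())
    else:
        transform, tx = "none", df[value].to_numpy()
    df["_y"] = tx
    model = smf.ols(f"_y ~ C({factor_a}) * C({factor_b})", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = anova_lm(model, typ=2)
    terms = {}
    name_map = {
        f"C({factor_a})": factor_a,
        f"C({factor_b})": factor_b,
        f"C({factor_a}):C({factor_b})": "interaction",
    }
    resid_df = float(table.loc["Residual", "df"])
    for row, label in name_map.items():
        terms[label] = {
            "F": float(table.loc[row, "F"]),
            "df_num": float(table.loc[row, "df"]),
            "df_den": resid_df,
            "p": float(table.loc[row, "PR(>F)"]),
        }
    # Sidak post hocs: factor_b contrast within each level of factor_a,
    # pooled error variance from the ANOVA residual.
    mse = float(table.loc["Residual", "sum_sq"] / resid_df)
    post = []
    if len(levels_b) == 2:
        m = len(levels_a)
        for a in levels_a:
            sub = df[df[factor_a] == a]
            y1 = sub[sub[factor_b] == levels_b[0]]["_y"]
            y2 = sub[sub[factor_b] == levels_b[1]]["_y"]
            se = math.sqrt(mse * (1.0 / len(y1) + 1.0 / len(y2)))
            tstat = (y1.mean() - y2.mean()) / se
            p_raw = 2.0 * sps.t.sf(abs(tstat), resid_df)
            post.append((f"{a}: {levels_b[0]} vs {levels_b[1]}", sidak_adjust(p_raw, m)))
    return StatResult(
        "two_way_anova_type2", transform, None, None, None, alpha, post, terms,
        notes="Type II sums of squares; rank transform = Akritas-style rank ANOVA"
        if transform == "rank" else "Type II sums of squares",
    )


# ---------------------------------------------------------------------------
# Exact tests on counts
# ---------------------------------------------------------------------------

def fisher_2x2(a: int, n1: int, b: int, n2: int) -> float:
    """Two-sided Fisher exact p for a/n1 vs b/n2 (minimum-likelihood method)."""
    for v in (a, n1, b, n2):
        if v < 0 or int(v) != v:
            raise InputError("counts must be non-negative integers")
    if a > n1 or b > n2:
        raise InputError("successes cannot exceed totals")
    table = [[a, n1 - a], [b, n2 - b]]
    s = a + b
    if s == 0 or s == n1 + n2 or n1 == 0 or n2 == 0:
        return 1.0  # degenerate margin: only one table possible
    return float(sps.fisher_exact(table, alternative="two-sided")[1])


def fisher_2xk(
    successes: Sequence[int],
    totals: Sequence[int],
    max_tables: int = 5_000_000,
) -> float:
    """Freeman-Halton exact test for a 2xk table of proportions.

    Sums the probabilities of every margin-fixed table whose hypergeometric
    probability does not exceed that of the observed table.  Reduces
    exactly to :func:`fisher_2x2` for k = 2.  Raises when the margin space
    exceeds ``max_tables`` candidate tables.
    """
    succ = [int(s) for s in successes]
    tot = [int(t) for t in totals]
    if len(succ) != len(tot) or len(succ) < 2:
        raise InputError("need k >= 2 aligned count columns")
    for s, t in zip(succ, tot):
        if s < 0 or t < 0 or s > t:
            raise InputError("require 0 <= successes <= totals")
    k = len(succ)
    s_tot = sum(succ)
    n_tot = sum(tot)
    if s_tot == 0 or s_tot == n_tot:
        return 1.0
    bound = 1
    for t in tot:
        bound *= min(t, s_tot) + 1
    if bound > max_tables:
        raise InputError(f"margin space too large for enumeration ({bound} tables)")
    log_denom = math.lgamma(n_tot + 1) - math.lgamma(s_tot + 1) - math.lgamma(n_tot - s_tot + 1)

    def log_prob(cells: tuple) -> float:
        lp = -log_denom
        for c, t in zip(cells, tot):
            lp += (
                math.lgamma(t + 1)
                - math.lgamma(c + 1)
                - math.lgamma(t - c + 1)
            )
        return lp

    lp_obs = log_prob(tuple(succ))
    tol = 1e-9 * abs(lp_obs) + 1e-12
    total_p = 0.0

    def recurse(col: int, remaining: int, cells: list) -> None:
        nonlocal total_p
        if col == k - 1:
            if remaining <= tot[col]:
                lp = log_prob(tuple(cells + [remaining]))
                if lp <= lp_obs + tol:
                    total_p += math.exp(lp)
            return
        tail_capacity = sum(tot[col + 1:])
        lo = max(0, remaining - tail_capacity)
        hi = min(tot[col], remaining)
        for c in range(lo, hi + 1):
            recurse(col + 1, remaining - c, cells + [c])

    recurse(0, s_tot, [])
    return float(min(1.0, total_p))


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-test alpha after Bonferroni correction, rounded to 3 decimals for display."""
    if m < 1:
        raise InputError("m must be >= 1")
    return round(family_alpha / m, 3)


def bonferroni_alpha_exact(family_alpha: float, m: int) -> float:
    if m < 1:
        raise InputError("m must be >= 1")
    return family_alpha / m


# ---------------------------------------------------------------------------
# t test and Spearman
# ---------------------------------------------------------------------------

def student_t(
    a: Optional[Sequence[float]] = None,
    b: Optional[Sequence[float]] = None,
    summary: Optional[dict] = None,
) -> Tuple[float, int, float]:
    """Pooled-variance two-sample t test: (t, df, two-sided p).

    Either two samples, or ``summary={'mean': (m1, m2), 'sem': (s1, s2),
    'n': (n1, n2)}`` reconstructed from printed group statistics.
    """
    if summary is not None:
        (m1, m2), (s1, s2), (n1, n2) = summary["mean"], summary["sem"], summary["n"]
        sd1, sd2 = s1 * math.sqrt(n1), s2 * math.sqrt(n2)
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
        if sp2 <= 0:
            raise InputError("zero pooled variance")
        t = (m1 - m2) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
        return float(t), int(df), float(2 * sps.t.sf(abs(t), df))
    x = np.asarray(list(a), dtype=float)
    y = np.asarray(list(b), dtype=float)
    if x.size < 2 or y.size < 2:
        raise InputError("need n >= 2 per group")
    if np.ptp(np.concatenate([x, y])) == 0:
        return 0.0, int(x.size + y.size - 2), 1.0
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return float(t), int(x.size + y.size - 2), float(p)


def t_pvalue(t: float, df: int) -> float:
    """Two-sided p for a printed t statistic and its degrees of freedom."""
    return float(2.0 * sps.t.sf(abs(t), df))


def spearman(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Mid-rank Spearman correlation; exact permutation p for n <= 9."""
    xv = np.asarray(list(x), dtype=float)
    yv = np.asarray(list(y), dtype=float)
    if xv.size != yv.size or xv.size < 4:
        raise InputError("need paired samples with n >= 4")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise InputError("constant vector: correlation undefined")
    if xv.size <= 9:
        rx = sps.rankdata(xv)
        ry = sps.rankdata(yv)
        r_obs = float(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            if abs(r) >= abs(r_obs) - 1e-12:
                count += 1
            total += 1
        return r_obs, count / total
    r, p = sps.spearmanr(xv, yv)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Model-style interface over the ladder
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """Fitted group comparison: per-feature StatResults with a summary table."""

    results: Dict[str, StatResult]

    def summary(self) -> str:
        return "\n\n".join(
            f"== {name} ==\n{res.summary()}" for name, res in self.results.items()
        )

    def to_dict(self) -> dict:
        return {name: res.to_dict() for name, res in self.results.items()}


class GroupComparison:
    """Group-comparison model over a feature table.

    Built from a tidy DataFrame of per-cell features; ``fit`` runs the
    appropriate family (one-way across maturation groups, or two-way
    maturation x treatment) per feature and returns a
    :class:`ComparisonResult`.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        features: Sequence[str],
        group_col: str = "group",
        treatment_col: str = "treatment",
    ):
        self.data = data
        self.features = list(features)
        self.group_col = group_col
        self.treatment_col = treatment_col

    @classmethod
    def from_records(cls, records, features):
        from .io import feature_table_frame

        return cls(feature_table_frame(records), features)

    def fit(self, design: str = "auto", alpha: float = ALPHA) -> ComparisonResult:
        """Run the ladder per feature.

        ``design='one_way'`` compares maturation groups only (sham data);
        ``'two_way'`` crosses maturation with treatment; ``'auto'`` picks
        two-way when more than one treatment level is present.
        """
        results = {}
        for feat in self.features:
            cols = [feat, self.group_col, self.treatment_col]
            sub = self.data[[c for c in cols if c in self.data.columns]].dropna(subset=[feat])
            n_treat = sub[self.treatment_col].nunique() if self.treatment_col in sub else 1
            use_two_way = design == "two_way" or (design == "auto" and n_treat > 1)
            try:
                if use_two_way:
                    results[feat] = two_way_family(
                        sub.rename(columns={feat: "value"}),
                        factor_a=self.group_col, factor_b=self.treatment_col,
                        alpha=alpha,
                    )
                else:
                    groups = {
                        g: sub.loc[sub[self.group_col] == g, feat].to_numpy()
                        for g in sorted(sub[self.group_col].dropna().unique())
                    }
                    results[feat] = one_way_family(groups, alpha=alpha)
            except InputError as exc:
                results[feat] = StatResult(
                    "skipped", "none", None, None, None, alpha, notes=str(exc)
                )
        return ComparisonResult(results)
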