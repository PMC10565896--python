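"""Statistical comparisons between cooperative, private and background genes.

Two omnibus families are provided, chosen per variable by explicit
configuration (never by an automatic normality decision): Welch's ANOVA
with Games-Howell post hocs for approximately normal variables, and
Kruskal-Wallis with Dunn post hocs for skewed ones.  A paired mode
aggregates per trait-group medians and applies the exact Wilcoxon
signed-rank test for the few-category comparison.

The omnibus statistics are implemented from the published formulas
(Welch 1951; Games & Howell 1976; Kruskal & Wallis 1952 with tie
correction; Dunn 1964) on top of scipy distribution functions, so that
the p-value machinery stays in one auditable place.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

# documented defaults mirroring which variables are treated as normal
DEFAULT_FAMILY = {
    "pi": "welch_anova",
    "pi_S": "welch_anova",
    "Ks": "welch_anova",
    "pi_N": "kruskal_wallis",
    "Ka": "kruskal_wallis",
    "pi_N_over_pi_S": "kruskal_wallis",
    "Ka_over_Ks": "kruskal_wallis",
}


@dataclass
class ComparisonResult:
    variable: str
    family: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    posthoc: pd.DataFrame | None
    group_summaries: pd.DataFrame
    n_dropped_missing: int = 0


def _check_groups(groups: Sequence[np.ndarray], need_variance: bool = True) -> list[np.ndarray]:
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(gs):
        if len(g) < 2:
            raise ValueError(f"group {i} has fewer than 2 observations")
        if need_variance and np.var(g, ddof=1) == 0:
            raise ValueError(f"group {i} has zero variance")
    return gs


def welch_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float, float, float]:
    """Welch's heteroscedastic one-way ANOVA: returns (F, df1, df2, p)."""
    gs = _check_groups(groups)
    k = len(gs)
    n = np.array([len(g) for g in gs], dtype=float)
    m = np.array([np.mean(g) for g in gs])
    v = np.array([np.var(g, ddof=1) for g in gs])
    w = n / v
    W = w.sum()
    mw = (w * m).sum() / W
    num = ((w * (m - mw) ** 2).sum()) / (k - 1)
    lam = (((1 - w / W) ** 2) / (n - 1)).sum()
    den = 1 + 2 * (k - 2) / (k**2 - 1) * lam
    F = num / den
    df1 = k - 1.0
    df2 = (k**2 - 1) / (3 * lam)
    p = float(sps.f.sf(F, df1, df2))
    return float(F), df1, float(df2), p


def games_howell(groups: Sequence[Sequence[float]], labels=None) -> pd.DataFrame:
    """Games-Howell pairwise comparisons (studentized-range p-values).

    For each pair: Welch's t on the pair, q = t*sqrt(2), p from the
    studentized range distribution with k groups and the pairwise Welch
    degrees of freedom.
    """
    gs = _check_groups(groups)
    k = len(gs)
    labels = list(labels) if labels is not None else list(range(k))
    n = np.array([len(g) for g in gs], dtype=float)
    m = np.array([np.mean(g) for g in gs])
    v = np.array([np.var(g, ddof=1) for g in gs])
    rows = []
    for i, j in combinations(range(k), 2):
        se2 = v[i] / n[i] + v[j] / n[j]
        t = (m[i] - m[j]) / np.sqrt(se2)
        df = se2**2 / (
            (v[i] / n[i]) ** 2 / (n[i] - 1) + (v[j] / n[j]) ** 2 / (n[j] - 1)
        )
        q = abs(t) * np.sqrt(2.0)
        p = float(sps.studentized_range.sf(q, k, df))
        rows.append(
            {"group_1": labels[i], "group_2": labels[j], "statistic": float(t),
             "df": float(df), "p_adjusted": min(1.0, p)}
        )
    return pd.DataFrame(rows)


def _rank_with_ties(values: np.ndarray) -> tuple[np.ndarray, float]:
    ranks = sps.rankdata(values)
    _, counts = np.unique(values, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    return ranks, tie_sum


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Kruskal-Wallis rank test with tie correction: returns (H, df, p)."""
    gs = _check_groups(groups, need_variance=False)
    k = len(gs)
    allv = np.concatenate(gs)
    N = len(allv)
    if N < k + 1:
        raise ValueError("need N >= k + 1 observations")
    ranks, tie_sum = _rank_with_ties(allv)
    H = 0.0
    start = 0
    for g in gs:
        r = ranks[start : start + len(g)]
        H += r.sum() ** 2 / len(g)
        start += len(g)
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    correction = 1.0 - tie_sum / (N**3 - N)
    if correction <= 0:  # every value tied
        import warnings

        warnings.warn("all values tied; H = 0", stacklevel=2)
        return 0.0, k - 1, 1.0
    H /= correction
    p = float(sps.chi2.sf(H, k - 1))
    return float(H), k - 1, p


def dunn_test(
    groups: Sequence[Sequence[float]], labels=None, adjustment: str = "none"
) -> pd.DataFrame:
    """Dunn's rank-based post hoc z tests with tie correction.

    ``adjustment`` in {none, bonferroni, holm}; unadjusted by default
    (single pairwise contrasts are reported as-is).
    """
    gs = _check_groups(groups, need_variance=False)
    k = len(gs)
    labels = list(labels) if labels is not None else list(range(k))
    allv = np.concatenate(gs)
    N = len(allv)
    ranks, tie_sum = _rank_with_ties(allv)
    mean_ranks = []
    start = 0
    for g in gs:
        mean_ranks.append(ranks[start : start + len(g)].mean())
        start += len(g)
    var_base = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))
    rows = []
    for i, j in combinations(range(k), 2):
        se = np.sqrt(var_base * (1.0 / len(gs[i]) + 1.0 / len(gs[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * float(sps.norm.sf(abs(z)))
        rows.append({"group_1": labels[i], "group_2": labels[j],
                     "statistic": float(z), "p_raw": min(1.0, p)})
    df = pd.DataFrame(rows)
    if adjustment == "none":
        df["p_adjusted"] = df["p_raw"]
    elif adjustment in ("bonferroni", "holm"):
        from statsmodels.stats.multitest import multipletests

        df["p_adjusted"] = multipletests(df["p_raw"], method=adjustment)[1]
    else:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    return df


def wilcoxon_signed_rank(paired_differences: Sequence[float]) -> tuple[float, float, int]:
    """Exact Wilcoxon signed-rank test on paired differences.

    Returns (V, two-sided p, n_zero_dropped).  V is the sum of ranks of
    positive differences after dropping zero differences.  For n <= 25
    the p-value is exact over all 2^n sign assignments (computed by
    convolution, equivalent to full enumeration); above that, a normal
    approximation with tie and continuity corrections is used.
    """
    d = np.asarray(paired_differences, dtype=float)
    nz = d[d != 0]
    n_zero = int(len(d) - len(nz))
    if len(nz) == 0:
        return float("nan"), float("nan"), n_zero
    n = len(nz)
    ranks = sps.rankdata(np.abs(nz))
    V = float(ranks[nz > 0].sum())
    if n <= 25:
        # distribution of V over independent signs; scale ranks x2 so that
        # average ranks (halves) become integers
        scaled = np.rint(2 * ranks).astype(int)
        total = scaled.sum()
        pmf = np.zeros(total + 1)
        pmf[0] = 1.0
        for r in scaled:
            nxt = pmf.copy()
            nxt[r:] += pmf[: total + 1 - r]
            pmf = nxt / 2.0
        v2 = int(np.rint(2 * V))
        cdf = pmf[: v2 + 1].sum()
        sf = pmf[v2:].sum()
        p = min(1.0, 2.0 * min(cdf, sf))
    else:
        mu = n * (n + 1) / 4.0
        _, counts = np.unique(np.abs(nz), return_counts=True)
        tie_term = float(np.sum(counts**3 - counts)) / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = (V - mu - 0.5 * np.sign(V - mu)) / sigma
        p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))
    return V, p, n_zero


def compare_classes(
    gene_stats: pd.DataFrame,
    variable: str,
    classes: Sequence[str] = ("cooperative", "private", "background"),
    family: str | None = None,
    posthoc_adjustment: str = "none",
) -> ComparisonResult:
    """Omnibus + post hoc comparison of a statistic across gene classes.

    Flagged-missing (NaN) values are dropped listwise.  ``family`` is one
    of welch_anova, kruskal_wallis, wilcoxon_signed_rank; when None the
    documented per-variable default is used.  The paired family
    aggregates the per-trait-group medians of the first two classes and
    tests the within-group differences.
    """
    family = family or DEFAULT_FAMILY.get(variable, "kruskal_wallis")
    sub = gene_stats[gene_stats["category"].isin(classes)][
        ["category", variable]
        + (["trait_group"] if "trait_group" in gene_stats.columns else [])
    ]
    n_total = len(sub)
    sub = sub.dropna(subset=[variable])
    dropped = n_total - len(sub)

    if family == "wilcoxon_signed_rank":
        if "trait_group" not in sub.columns:
            raise ValueError("paired mode needs a trait_group column")
        if len(classes) < 2:
            raise ValueError("paired mode compares the first two classes")
        a, b = classes[0], classes[1]
        med = sub.groupby(["trait_group", "category"])[variable].median().unstack()
        if a not in med.columns or b not in med.columns:
            raise ValueError("paired mode: classes absent after dropping missing")
        med = med.dropna(subset=[a, b])
        diffs = (med[a] - med[b]).to_numpy()
        V, p, n_zero = wilcoxon_signed_rank(diffs)
        summaries = pd.DataFrame(
            {"n": [len(diffs)], "n_zero_dropped": [n_zero]}, index=["pairs"]
        )
        return ComparisonResult(variable, family, V, (float(len(diffs)),), p,
                                None, summaries, dropped)

    present = [c for c in classes if (sub["category"] == c).sum() >= 2]
    if len(present) < 2:
        raise ValueError("need at least 2 non-empty classes after dropping missing")
    groups = [sub.loc[sub["category"] == c, variable].to_numpy() for c in present]
    summaries = pd.DataFrame(
        {
            "n": [len(g) for g in groups],
            "mean": [float(np.mean(g)) for g in groups],
            "median": [float(np.median(g)) for g in groups],
            "variance": [float(np.var(g, ddof=1)) for g in groups],
        },
        index=present,
    )
    if family == "welch_anova":
        F, df1, df2, p = welch_anova(groups)
        posthoc = games_howell(groups, labels=present)
        return ComparisonResult(variable, family, F, (df1, df2), p, posthoc,
                                summaries, dropped)
    if family == "kruskal_wallis":
        H, df, p = kruskal_wallis(groups)
        posthoc = dunn_test(groups, labels=present, adjustment=posthoc_adjustment)
        return ComparisonResult(variable, family, H, (float(df),), p, posthoc,
                                summaries, dropped)
    raise ValueError(f"unknown test family {family!r}")
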