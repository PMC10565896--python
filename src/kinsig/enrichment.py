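"""Are loss-of-function mutations over-represented in cooperative genes?

Given per-gene deleterious-mutation annotations and a sociality
categorization, this module compares (a) the percentage of
deleterious-mutation-bearing genes that are cooperative against (b) the
percentage of categorized genes that are cooperative, with a one-sided
exact binomial test (the directional prediction is over-representation
under relaxed selection).  The same contrast can be run on total
mutation counts instead of gene presence/absence, and a 2x2 chi-square
is available for direct cooperative-vs-private contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats as sps

from .genome_io import GeneModel


@dataclass
class EnrichmentResult:
    mode: str  # gene_presence | mutation_count
    k: int  # focal-set hits
    n: int  # total hits
    f: float  # focal-set fraction of the categorized genome
    observed_percent: float
    expected_percent: float
    p_value: float
    chi2: float | None = None
    chi2_df: int | None = None
    chi2_p: float | None = None


def binomial_enrichment(k: int, n: int, f: float, mode: str = "gene_presence") -> EnrichmentResult:
    """One-sided upper-tail exact binomial test of over-representation.

    p = P(X >= k) for X ~ Binomial(n, f): the probability of at least the
    observed number of focal-category hits if hits landed on genes at the
    focal category's genomic frequency.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < f < 1:
        raise ValueError("focal fraction f must be in (0, 1)")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    p = float(sps.binomtest(k, n, f, alternative="greater").pvalue)
    return EnrichmentResult(
        mode=mode,
        k=k,
        n=n,
        f=f,
        observed_percent=100.0 * k / n,
        expected_percent=100.0 * f,
        p_value=p,
    )


def count_hits(
    deleterious: pd.DataFrame,
    genes: Sequence[GeneModel],
    focal_category: str = "cooperative",
    mode: str = "gene_presence",
) -> tuple[int, int, float]:
    """Hit counts (k, n) and genome fraction f for the enrichment test.

    ``gene_presence`` mode: n = genes with at least one deleterious
    mutation, k = those in the focal category.  ``mutation_count`` mode:
    n = total deleterious mutations, k = those in focal-category genes.
    f is the focal category's share of genes with a known category
    (uncategorized genes are removed, mirroring the removal of genes with
    unknown localization).
    """
    if mode not in ("gene_presence", "mutation_count"):
        raise ValueError(f"unknown mode {mode!r}")
    cat = {g.gene_id: g.category for g in genes}
    known = [g for g in genes if g.category != "uncategorized"]
    focal = [g for g in known if g.category == focal_category]
    if not focal:
        raise ValueError(f"no genes in focal category {focal_category!r}")
    f = len(focal) / len(known)
    df = deleterious.loc[[g for g in deleterious.index if g in cat]]
    if mode == "gene_presence":
        hits = df[df["total"] > 0]
        n = len(hits)
        k = sum(cat[g] == focal_category for g in hits.index)
    else:
        n = int(df["total"].sum())
        k = int(df.loc[[g for g in df.index if cat[g] == focal_category], "total"].sum())
    return k, n, f


def enrichment_test(
    deleterious: pd.DataFrame,
    genes: Sequence[GeneModel],
    focal_category: str = "cooperative",
    mode: str = "gene_presence",
) -> EnrichmentResult:
    """count_hits + binomial_enrichment in one call."""
    k, n, f = count_hits(deleterious, genes, focal_category, mode)
    return binomial_enrichment(k, n, f, mode=mode)


def cooperative_vs_private_chisq(
    hits_coop: int, n_coop: int, hits_priv: int, n_priv: int
) -> tuple[float, int, float]:
    """2x2 chi-square (with continuity correction) for the direct contrast
    between cooperative and private genes on (hit, no-hit) counts."""
    table = [[hits_coop, n_coop - hits_coop], [hits_priv, n_priv - hits_priv]]
    res = sps.chi2_contingency(table, correction=True)
    return float(res.statistic), int(res.dof), float(res.pvalue)
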