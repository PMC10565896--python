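"""Co-expression test: is a candidate gene set more co-regulated than chance?

A set of genes proposed as "expressed under the same conditions" (for
example, all quorum-sensing-controlled genes) is scored by the mean
pairwise Spearman correlation of its members' expression profiles across
timepoints.  The null is built by drawing random same-size sets from the
full measured gene universe and recomputing the statistic B times
(bootstrap over gene sets), giving an empirical percentile and an
add-one empirical p-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger("kinsig.coexpression")


@dataclass
class ExpressionMatrix:
    """Gene x timepoint expression levels.

    ``data`` is a DataFrame indexed by gene id with one column per
    timepoint.  ``normalized`` records whether rows have been divided by
    their median.
    """

    data: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.data.shape[1] < 3:
            raise ValueError("need at least 3 timepoints for rank correlations")
        if self.data.isna().all(axis=1).any():
            raise ValueError("all-missing gene rows are not allowed")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def timepoints(self) -> list[str]:
        return list(self.data.columns)


def _as_matrix(matrix) -> ExpressionMatrix:
    if isinstance(matrix, ExpressionMatrix):
        return matrix
    return ExpressionMatrix(pd.DataFrame(matrix))


def read_expression(path) -> ExpressionMatrix:
    """Read a TSV (rows = genes, columns = timepoints, first column = id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(df, normalized=False)


def median_normalize(matrix) -> ExpressionMatrix:
    """Divide each gene row by its median across timepoints.

    Rows with median 0 cannot be scaled and are excluded with a warning.
    Rank-based statistics are invariant to this monotone rescaling; it is
    applied so that levels of different genes live on the same scale, as
    in the expression data set this emulates.
    """
    m = _as_matrix(matrix)
    med = m.data.median(axis=1)
    bad = med == 0
    if bad.any():
        logger.warning("excluding %d gene rows with zero median", int(bad.sum()))
    data = m.data.loc[~bad].div(med[~bad], axis=0)
    return ExpressionMatrix(data, normalized=True)


def _rank_rows(data: pd.DataFrame) -> np.ndarray:
    """Rows rank-transformed, centered and scaled to unit norm.

    Pairwise dot products of these rows are Spearman correlations with
    average-rank tie handling. Constant rows give NaN rows.
    """
    r = rankdata(data.to_numpy(dtype=float), axis=1)
    r = r - r.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(r, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(norm > 0, r / norm, np.nan)


def mean_pairwise_spearman(matrix, gene_set) -> tuple[float, int]:
    """Mean Spearman correlation over all unordered pairs in the gene set.

    Returns (rho_bar, num_pairs) with num_pairs = k(k-1)/2.
    """
    m = _as_matrix(matrix)
    gene_set = list(gene_set)
    if len(gene_set) < 2:
        raise ValueError("gene_set must contain at least 2 genes")
    missing = [g for g in gene_set if g not in m.data.index]
    if missing:
        raise KeyError(f"genes absent from matrix: {missing[:10]}")
    z = _rank_rows(m.data.loc[gene_set])
    gram = z @ z.T
    k = len(gene_set)
    iu = np.triu_indices(k, 1)
    return float(np.mean(gram[iu])), k * (k - 1) // 2


@dataclass
class BootstrapNullResult:
    """Observed set-mean correlation against its random-set null."""

    rho_obs: float
    B: int
    null_means: np.ndarray = field(repr=False)
    percentile: float = 0.0
    p_value: float = 1.0

    def __post_init__(self) -> None:
        null = np.asarray(self.null_means, dtype=float)
        self.percentile = 100.0 * float(np.sum(null < self.rho_obs)) / len(null)
        self.p_value = (1.0 + float(np.sum(null >= self.rho_obs))) / (1.0 + len(null))


def bootstrap_null(
    matrix, observed_set, B: int = 10_000, seed: int | None = None
) -> BootstrapNullResult:
    """Bootstrap null for set co-expression.

    Draws B random sets of the same size (uniform, without replacement
    within a draw) from the full universe of measured genes — including
    the candidate set's own members — and records each null set's mean
    pairwise Spearman correlation.  Genes whose profiles are constant
    after normalization have no defined correlation and are excluded from
    the universe.

    The empirical p is add-one: p = (1 + #{null >= observed}) / (1 + B),
    so it is never exactly zero.
    """
    m = _as_matrix(matrix)
    observed_set = list(observed_set)
    k = len(observed_set)
    if B < 100:
        logger.warning("B=%d bootstrap draws gives an unstable tail", B)
    rho_obs, _ = mean_pairwise_spearman(m, observed_set)
    z = _rank_rows(m.data)
    defined = ~np.isnan(z[:, 0])
    n_dropped = int((~defined).sum())
    if n_dropped:
        logger.info("excluding %d constant-profile genes from the null universe",
                    n_dropped)
    z = z[defined]
    universe = z.shape[0]
    if universe <= k:
        raise ValueError("gene universe must exceed the set size")
    rng = np.random.default_rng(seed)
    null = np.empty(B)
    for b in range(B):
        rows = rng.choice(universe, size=k, replace=False)
        zs = z[rows]
        tot = zs.sum(axis=0)
        # sum over pairs of dot products, via the Gram identity
        null[b] = (tot @ tot - k) / (k * (k - 1))
    return BootstrapNullResult(rho_obs=rho_obs, B=B, null_means=null)
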