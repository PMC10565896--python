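"""Per-gene molecular population-genetic statistics.

Implements the statistic battery used to detect relaxed selection on
cooperative genes: nucleotide diversity (total, synonymous and
nonsynonymous, per NG86 fractional site counts), the frequency-spectrum
tests of Tajima (1989) and Fu & Li (1993), the McDonald-Kreitman table
with Fisher's exact test, Neutrality Index and Direction of Selection,
and NG86 Ka/Ks with Jukes-Cantor correction against an outgroup.

Missing data are handled by pairwise deletion within sites; undefined
statistics are reported as NaN ("flagged missing"), never coerced to 0.
All per-site quantities are scaled to the effective (mapped) length of
the gene.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._codon import (
    BASES,
    N_BASE,
    ng86_site_counts,
    pathway_diff_counts,
    translate_codon,
)
from .genome_io import GeneModel, HaplotypeAlignment

logger = logging.getLogger("kinsig.popgen")

NAN = float("nan")


# ---------------------------------------------------------------------------
# column-level bookkeeping


class _SiteSummary(NamedTuple):
    counts: np.ndarray        # (4, L) allele counts per column (A,C,G,T)
    called: np.ndarray        # (L,) number of called rows per column
    n_alleles: np.ndarray     # (L,) distinct alleles per column
    pair_diffs: np.ndarray    # (L,) pairs of rows differing at the column


def _site_summary(seqs: np.ndarray) -> _SiteSummary:
    counts = np.stack([(seqs == b).sum(axis=0) for b in BASES]).astype(np.int64)
    called = counts.sum(axis=0)
    n_alleles = (counts > 0).sum(axis=0)
    pair_diffs = (called.astype(np.int64) ** 2 - (counts**2).sum(axis=0)) // 2
    return _SiteSummary(counts, called, n_alleles, pair_diffs)


def _consensus(seqs: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Majority base per column (ties broken by A<C<G<T); N where uncalled."""
    cons = np.frombuffer(bytes(BASES), dtype=np.uint8)[counts.argmax(axis=0)].copy()
    cons[counts.sum(axis=0) == 0] = N_BASE
    return cons


# ---------------------------------------------------------------------------
# diversity


def nucleotide_diversity(alignment: HaplotypeAlignment) -> tuple[float, float]:
    """Nucleotide diversity: returns (pi per site, raw pi).

    Raw pi is the mean number of pairwise differences per sequence pair
    (pairwise deletion over missing data, every pair weighted equally);
    per-site pi divides by the effective length.
    """
    n = alignment.n_samples
    if n < 2:
        return NAN, NAN
    summ = _site_summary(alignment.seqs)
    npairs = n * (n - 1) // 2
    pi_raw = float(summ.pair_diffs.sum()) / npairs
    if alignment.effective_length <= 0:
        return NAN, pi_raw
    return pi_raw / alignment.effective_length, pi_raw


# ---------------------------------------------------------------------------
# synonymous / nonsynonymous classification


@dataclass
class SiteClassification:
    """NG86 site counts plus per-column synonymous weights for a CDS alignment."""

    syn_sites: float
    nonsyn_sites: float
    # column index -> fraction of that column's mutations that are synonymous
    syn_weight: dict[int, float]


def classify_sites(alignment: HaplotypeAlignment) -> SiteClassification:
    """Classify segregating columns as synonymous/nonsynonymous.

    Site counts follow NG86 fractional counting on the reference codon.
    A column is labeled by comparing the reference codon with the codon
    carrying the column's alternate allele; codons with more than one
    segregating position are resolved by pathway averaging over
    substitution orderings, and each of their columns receives the codon's
    mean synonymous fraction.  Codons containing an ambiguous reference
    base are excluded from numerator and denominator.
    """
    ref = alignment.ref_seq
    if len(ref) % 3:
        raise ValueError(f"{alignment.gene_id}: CDS length not divisible by 3")
    syn_sites, nonsyn_sites = ng86_site_counts(ref)
    summ = _site_summary(alignment.seqs)
    poly = np.nonzero(summ.n_alleles >= 2)[0]
    by_codon: dict[int, list[int]] = {}
    for col in poly:
        by_codon.setdefault(col // 3, []).append(col)
    weights: dict[int, float] = {}
    for codon_idx, cols in by_codon.items():
        codon = ref[3 * codon_idx : 3 * codon_idx + 3].tobytes().decode()
        if translate_codon(codon) == "X":
            logger.info("%s: ambiguous codon %d excluded", alignment.gene_id, codon_idx)
            continue
        derived = list(codon)
        for col in cols:
            p = col % 3
            # alternate allele = most common non-reference base in the column
            cnts = summ.counts[:, col].copy()
            ref_b = codon[p]
            if ref_b in "ACGT":
                cnts["ACGT".index(ref_b)] = 0
            alt_b = "ACGT"[int(cnts.argmax())]
            derived[p] = alt_b
        sd, nd = pathway_diff_counts(codon, "".join(derived))
        tot = sd + nd
        w = sd / tot if tot > 0 else 0.0
        for col in cols:
            weights[int(col)] = w
    return SiteClassification(syn_sites, nonsyn_sites, weights)


# ---------------------------------------------------------------------------
# frequency-spectrum statistics


def _harmonics(n: int) -> tuple[float, float]:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    return a1, a2


def tajimas_d(S: int, pi_raw: float, n: int) -> float:
    """Tajima's D from segregating sites, raw pi, and sample size.

    Uses the constants of Tajima (1989).  Undefined (NaN) when S = 0.
    """
    if S <= 0 or n < 2:
        return NAN
    a1, a2 = _harmonics(n)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return NAN
    return (pi_raw - S / a1) / math.sqrt(var)


@dataclass
class FuLiResult:
    D_star: float
    F_star: float
    D: float = NAN
    F: float = NAN


def fu_li_from_counts(
    n: int,
    eta: int,
    eta_s: int,
    pi_raw: float,
    eta_e: int | None = None,
) -> FuLiResult:
    """Fu & Li (1993) statistics from mutation counts.

    ``eta`` is the total number of mutations, ``eta_s`` the number of
    singletons (any allele carried by exactly one sequence), ``pi_raw``
    the mean pairwise difference count, and ``eta_e`` the number of
    *derived* singletons (requires outgroup polarization; when None, only
    the starred, sample-only statistics are computed).  Variance constants
    follow the corrected versions in Simonsen, Churchill & Aquadro (1995).
    """
    if eta <= 0 or n < 3:
        return FuLiResult(NAN, NAN, NAN, NAN)
    a1, a2 = _harmonics(n)
    a1n1 = a1 + 1.0 / n  # a_{n+1}
    cn = 2 * (n * a1 - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = cn + (n - 2) / (n - 1) ** 2 + (2 / (n - 1)) * (
        1.5 - (2 * a1n1 - 3) / (n - 2) - 1.0 / n
    )
    # D* / F* (within-sample)
    nn = n / (n - 1)
    v_Ds = (nn**2 * a2 + a1**2 * dn - 2 * n * a1 * (a1 + 1) / (n - 1) ** 2) / (
        a1**2 + a2
    )
    u_Ds = nn * (a1 - nn) - v_Ds
    num_Ds = nn * eta - a1 * eta_s
    var_Ds = u_Ds * eta + v_Ds * eta**2
    D_star = num_Ds / math.sqrt(var_Ds) if var_Ds > 0 else NAN

    v_Fs = (
        dn
        + 2 * (n**2 + n + 3) / (9 * n * (n - 1))
        - (2.0 / n) * (4 * a2 - 6 + 8.0 / n)
    ) / (a1**2 + a2)
    u_Fs = (
        (4 * n**2 + 19 * n + 3 - 12 * (n + 1) * a1n1) / (3 * n * (n - 1))
    ) / a1 - v_Fs
    num_Fs = pi_raw - ((n - 1) / n) * eta_s
    var_Fs = u_Fs * eta + v_Fs * eta**2
    F_star = num_Fs / math.sqrt(var_Fs) if var_Fs > 0 else NAN

    D = F = NAN
    if eta_e is not None:
        v_D = 1 + (a1**2 / (a2 + a1**2)) * (cn - (n + 1) / (n - 1))
        u_D = a1 - 1 - v_D
        var_D = u_D * eta + v_D * eta**2
        D = (eta - a1 * eta_e) / math.sqrt(var_D) if var_D > 0 else NAN
        v_F = (cn + 2 * (n**2 + n + 3) / (9 * n * (n - 1)) - 2 / (n - 1)) / (
            a1**2 + a2
        )
        u_F = (
            1
            + (n + 1) / (3 * (n - 1))
            - 4 * ((n + 1) / (n - 1) ** 2) * (a1n1 - 2 * n / (n + 1))
        ) / a1 - v_F
        var_F = u_F * eta + v_F * eta**2
        F = (pi_raw - eta_e) / math.sqrt(var_F) if var_F > 0 else NAN
    return FuLiResult(D_star, F_star, D, F)


def _mutation_counts(alignment: HaplotypeAlignment) -> tuple[int, int, int | None]:
    """(eta, eta_s, eta_e) for an alignment; eta_e None without outgroup."""
    summ = _site_summary(alignment.seqs)
    poly = np.nonzero(summ.n_alleles >= 2)[0]
    eta = int((summ.n_alleles[poly] - 1).sum())
    eta_s = 0
    for col in poly:
        eta_s += int((summ.counts[:, col] == 1).sum())
    eta_e: int | None = None
    og = alignment.outgroup_seq
    if og is not None:
        eta_e = 0
        for col in poly:
            cnts = summ.counts[:, col]
            og_b = og[col]
            if og_b not in BASES:
                continue
            og_i = bytes(BASES).index(og_b)
            if cnts[og_i] == 0:
                continue  # outgroup allele absent from the sample: unpolarizable
            for b_i in range(4):
                if b_i != og_i and cnts[b_i] == 1:
                    eta_e += 1
    return eta, eta_s, eta_e


def fu_li_statistics(alignment: HaplotypeAlignment) -> FuLiResult:
    """Fu & Li D*, F* (always) and D, F (when an outgroup row is present).

    Singletons are polarized as derived when the outgroup carries the
    other allele; sites where the outgroup allele is missing or absent
    from the sample are left unpolarized.
    """
    _, pi_raw = nucleotide_diversity(alignment)
    eta, eta_s, eta_e = _mutation_counts(alignment)
    return fu_li_from_counts(alignment.n_samples, eta, eta_s, pi_raw, eta_e)


# ---------------------------------------------------------------------------
# McDonald-Kreitman


@dataclass
class MKResult:
    Pn: float
    Ps: float
    Dn: float
    Ds: float
    fisher_p: float
    NI: float
    DoS: float


def _mk_counts(
    alignment: HaplotypeAlignment, min_minor_freq: float = 0.0
) -> tuple[float, float, float, float]:
    if alignment.outgroup_seq is None:
        raise ValueError("McDonald-Kreitman requires an outgroup row")
    ref = alignment.ref_seq
    if len(ref) % 3:
        raise ValueError(f"{alignment.gene_id}: CDS length not divisible by 3")
    summ = _site_summary(alignment.seqs)
    cons = _consensus(alignment.seqs, summ.counts)
    og = alignment.outgroup_seq
    poly_mask = summ.n_alleles >= 2
    if min_minor_freq > 0:
        minor = summ.called - summ.counts.max(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            maf = np.where(summ.called > 0, minor / np.maximum(summ.called, 1), 0.0)
        poly_mask = poly_mask & (maf >= min_minor_freq)
    Pn = Ps = Dn = Ds = 0.0
    ncod = len(ref) // 3
    for ci in range(ncod):
        cols = range(3 * ci, 3 * ci + 3)
        codon = ref[3 * ci : 3 * ci + 3].tobytes().decode()
        if translate_codon(codon) == "X":
            continue
        pcols = [c for c in cols if poly_mask[c]]
        # polymorphism: reference codon vs codon carrying the alternate alleles
        if pcols:
            derived = list(codon)
            for col in pcols:
                p = col % 3
                cnts = summ.counts[:, col].copy()
                if codon[p] in "ACGT":
                    cnts["ACGT".index(codon[p])] = 0
                derived[p] = "ACGT"[int(cnts.argmax())]
            sd, nd = pathway_diff_counts(codon, "".join(derived))
            Ps += sd
            Pn += nd
        # divergence: monomorphic columns differing from the outgroup.
        # Columns polymorphic in-sample are polymorphism only, never divergence.
        dcols = [
            c
            for c in cols
            if summ.n_alleles[c] == 1
            and og[c] in BASES
            and cons[c] in BASES
            and og[c] != cons[c]
        ]
        if dcols:
            samp = list(codon)
            outg = list(codon)
            for col in cols:
                p = col % 3
                if cons[col] in BASES:
                    samp[p] = chr(cons[col])
                    outg[p] = chr(cons[col])
            for col in dcols:
                outg[col % 3] = chr(og[col])
            sd, nd = pathway_diff_counts("".join(samp), "".join(outg))
            Ds += sd
            Dn += nd
    return Pn, Ps, Dn, Ds


def mk_from_table(Pn: float, Ps: float, Dn: float, Ds: float) -> MKResult:
    table = np.rint([[Pn, Ps], [Dn, Ds]]).astype(int)
    if table.sum() == 0:
        fisher_p = NAN
    else:
        fisher_p = float(sps.fisher_exact(table, alternative="two-sided")[1])
    NI = (Pn / Ps) / (Dn / Ds) if (Ps > 0 and Dn > 0 and Ds > 0) else NAN
    if (Dn + Ds) > 0 and (Pn + Ps) > 0:
        DoS = Dn / (Dn + Ds) - Pn / (Pn + Ps)
    else:
        DoS = NAN
    return MKResult(Pn, Ps, Dn, Ds, fisher_p, NI, DoS)


def mcdonald_kreitman(alignment: HaplotypeAlignment) -> MKResult:
    """McDonald-Kreitman 2x2 contrast with Fisher's exact p, NI and DoS.

    Polymorphism = segregating within the sample; divergence = fixed in
    the sample and differing from the outgroup.  Both are labeled
    synonymous/nonsynonymous on the codon, with pathway averaging for
    multi-hit codons (fractional counts are rounded for the Fisher test
    but kept fractional for NI and DoS).
    """
    return mk_from_table(*_mk_counts(alignment))


def mk_conservative(
    alignment: HaplotypeAlignment, min_derived_freq: float = 0.15
) -> MKResult:
    """McDonald-Kreitman after removing low-frequency polymorphisms.

    Polymorphic sites with minor-allele frequency below
    ``min_derived_freq`` are excluded from the polymorphism cells (they do
    not move to divergence), which guards against segregating slightly
    deleterious variants inflating Pn.
    """
    return mk_from_table(*_mk_counts(alignment, min_minor_freq=min_derived_freq))


# ---------------------------------------------------------------------------
# Ka/Ks


class KaKsResult(NamedTuple):
    Ka: float
    Ks: float
    ratio: float


def jukes_cantor(p: float) -> float:
    """JC69 distance correction; NaN when p >= 3/4 (correction undefined)."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return NAN
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ka_ks(reference_cds: np.ndarray, outgroup_cds: np.ndarray) -> KaKsResult:
    """NG86 Ka/Ks between two codon-aligned CDS sequences.

    Fractional site counts are averaged over the two sequences,
    differences are pathway-averaged per codon, and the proportions are
    Jukes-Cantor corrected.  Codons containing an ambiguous base or a
    premature internal stop in either sequence are skipped.
    """
    if len(reference_cds) != len(outgroup_cds):
        raise ValueError("sequences must be the same length")
    if len(reference_cds) % 3:
        raise ValueError("CDS length must be divisible by 3")
    ncod = len(reference_cds) // 3
    S = Nn = sd = nd = 0.0
    skipped = 0
    for ci in range(ncod):
        c1 = reference_cds[3 * ci : 3 * ci + 3].tobytes().decode()
        c2 = outgroup_cds[3 * ci : 3 * ci + 3].tobytes().decode()
        aa1, aa2 = translate_codon(c1), translate_codon(c2)
        if aa1 == "X" or aa2 == "X":
            skipped += 1
            continue
        if ci < ncod - 1 and ("*" in (aa1, aa2)):
            skipped += 1
            continue  # premature internal stop
        s1, n1 = ng86_site_counts(np.frombuffer(c1.encode(), dtype=np.uint8))
        s2, n2 = ng86_site_counts(np.frombuffer(c2.encode(), dtype=np.uint8))
        S += (s1 + s2) / 2
        Nn += (n1 + n2) / 2
        ds_, dn_ = pathway_diff_counts(c1, c2)
        sd += ds_
        nd += dn_
    if skipped:
        logger.info("ka_ks: skipped %d ambiguous/stop codons", skipped)
    if S <= 0 or Nn <= 0:
        return KaKsResult(NAN, NAN, NAN)
    Ks = jukes_cantor(sd / S)
    Ka = jukes_cantor(nd / Nn)
    ratio = Ka / Ks if (Ks == Ks and Ka == Ka and Ks > 0) else NAN
    return KaKsResult(Ka, Ks, ratio)


# ---------------------------------------------------------------------------
# assembled per-gene statistics


@dataclass
class GeneStats:
    """The full per-gene statistic vector; NaN marks an undefined value."""

    gene_id: str
    n_samples: int
    effective_length: int
    S: int = 0
    singletons: int = 0
    pi: float = NAN
    pi_N: float = NAN
    pi_S: float = NAN
    pi_N_over_pi_S: float = NAN
    tajimas_D: float = NAN
    fu_li_D_star: float = NAN
    fu_li_F_star: float = NAN
    fu_li_D: float = NAN
    fu_li_F: float = NAN
    Pn: float = NAN
    Ps: float = NAN
    Dn: float = NAN
    Ds: float = NAN
    mk_p: float = NAN
    NI: float = NAN
    DoS: float = NAN
    Ka: float = NAN
    Ks: float = NAN
    Ka_over_Ks: float = NAN
    category: str = "uncategorized"
    trait_group: str | None = None

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def compute_gene_stats(
    alignment: HaplotypeAlignment,
    gene: GeneModel | None = None,
) -> GeneStats:
    """Assemble the full statistic vector for one gene.

    Per-site quantities divide by the relevant effective site count:
    total effective length for pi, and the NG86 synonymous/nonsynonymous
    site counts scaled by the mapped fraction for pi_S / pi_N.  Statistics
    whose preconditions fail (no outgroup, S = 0, zero denominators)
    propagate as NaN.
    """
    n = alignment.n_samples
    eff = int(alignment.effective_length)
    gs = GeneStats(alignment.gene_id, n, eff)
    if gene is not None:
        gs.category = gene.category
        gs.trait_group = gene.trait_group
    if n < 2:
        return gs
    summ = _site_summary(alignment.seqs)
    npairs = n * (n - 1) // 2
    pi_raw = float(summ.pair_diffs.sum()) / npairs
    gs.S = int((summ.n_alleles >= 2).sum())
    eta, eta_s, eta_e = _mutation_counts(alignment)
    gs.singletons = eta_s
    gs.pi = pi_raw / eff if eff > 0 else NAN
    cls = classify_sites(alignment)
    scale = eff / alignment.length if alignment.length else 0.0
    pi_raw_syn = (
        sum(cls.syn_weight.get(int(c), 0.0) * summ.pair_diffs[c]
            for c in np.nonzero(summ.n_alleles >= 2)[0])
        / npairs
    )
    pi_raw_non = pi_raw - pi_raw_syn
    if cls.syn_sites > 0 and scale > 0:
        gs.pi_S = pi_raw_syn / (cls.syn_sites * scale)
    if cls.nonsyn_sites > 0 and scale > 0:
        gs.pi_N = pi_raw_non / (cls.nonsyn_sites * scale)
    if gs.pi_S == gs.pi_S and gs.pi_S > 0:
        gs.pi_N_over_pi_S = gs.pi_N / gs.pi_S
    gs.tajimas_D = tajimas_d(gs.S, pi_raw, n)
    fl = fu_li_from_counts(n, eta, eta_s, pi_raw, eta_e)
    gs.fu_li_D_star, gs.fu_li_F_star = fl.D_star, fl.F_star
    gs.fu_li_D, gs.fu_li_F = fl.D, fl.F
    if alignment.outgroup_seq is not None:
        mk = mcdonald_kreitman(alignment)
        gs.Pn, gs.Ps, gs.Dn, gs.Ds = mk.Pn, mk.Ps, mk.Dn, mk.Ds
        gs.mk_p, gs.NI, gs.DoS = mk.fisher_p, mk.NI, mk.DoS
        kk = ka_ks(alignment.ref_seq, alignment.outgroup_seq)
        gs.Ka, gs.Ks, gs.Ka_over_Ks = kk.Ka, kk.Ks, kk.ratio
    return gs


def compute_stats_table(
    alignments: Iterable[HaplotypeAlignment],
    genes: Sequence[GeneModel] | None = None,
) -> pd.DataFrame:
    """Per-gene statistics as a DataFrame, one row per alignment."""
    lut = {g.gene_id: g for g in genes} if genes is not None else {}
    rows = [
        compute_gene_stats(a, lut.get(a.gene_id)).to_dict() for a in alignments
    ]
    return pd.DataFrame(rows)
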