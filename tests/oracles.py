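"""Independent brute-force oracles used to validate the statistics layer.

Everything here is deliberately written from scratch (direct enumeration,
closed forms, or the published formulas retyped independently) and never
imports from kinsig, so agreement between the two routes is evidence of
correctness rather than tautology.
"""

from __future__ import annotations

import itertools
from math import comb, log, sqrt

import numpy as np
from Bio.Seq import Seq

MISSING = ord("N")


def brute_pi_raw(seqs: np.ndarray) -> float:
    """Mean pairwise differences by an O(n^2 L) double loop (pairwise deletion)."""
    n = seqs.shape[0]
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            for col in range(seqs.shape[1]):
                a, b = seqs[i, col], seqs[j, col]
                if a != MISSING and b != MISSING and a != b:
                    total += 1
    return total / comb(n, 2)


def brute_segregating(seqs: np.ndarray) -> int:
    S = 0
    for col in range(seqs.shape[1]):
        alleles = {int(b) for b in seqs[:, col] if b != MISSING}
        if len(alleles) >= 2:
            S += 1
    return S


def tajima_d_oracle(S: int, pi_raw: float, n: int) -> float:
    """Tajima (1989), retyped independently."""
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i / i for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (pi_raw - S / a1) / sqrt(e1 * S + e2 * S * (S - 1))


def fu_li_star_oracle(n: int, eta: int, eta_s: int, pi_raw: float):
    """Fu & Li (1993) D*/F* with the Simonsen et al. (1995) constants."""
    an = sum(1 / i for i in range(1, n))
    bn = sum(1 / i / i for i in range(1, n))
    an1 = an + 1 / n
    cn = 2 * (n * an - 2 * (n - 1)) / ((n - 1) * (n - 2))
    dn = cn + (n - 2) / (n - 1) ** 2 + 2 / (n - 1) * (3 / 2 - (2 * an1 - 3) / (n - 2) - 1 / n)
    vD = ((n / (n - 1)) ** 2 * bn + an**2 * dn - 2 * (n * an * (an + 1)) / (n - 1) ** 2) / (an**2 + bn)
    uD = n / (n - 1) * (an - n / (n - 1)) - vD
    Dstar = (n / (n - 1) * eta - an * eta_s) / sqrt(uD * eta + vD * eta**2)
    vF = (dn + 2 * (n**2 + n + 3) / (9 * n * (n - 1)) - 2 / n * (4 * bn - 6 + 8 / n)) / (an**2 + bn)
    uF = ((4 * n**2 + 19 * n + 3 - 12 * (n + 1) * an1) / (3 * n * (n - 1))) / an - vF
    Fstar = (pi_raw - (n - 1) / n * eta_s) / sqrt(uF * eta + vF * eta**2)
    return Dstar, Fstar


def fisher_exact_oracle(table) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return comb(r1, x) * comb(r2, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    return sum(prob(x) for x in range(0, c1 + 1) if prob(x) <= p_obs * (1 + 1e-9))


def wilcoxon_exact_oracle(diffs) -> tuple[float, float]:
    """Exact signed-rank V and two-sided p by enumerating all 2^n signs."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    i = 0
    pos = 1
    while i < n:
        j = i
        while j < n and sorted_abs[j] == sorted_abs[i]:
            j += 1
        avg = (pos + pos + (j - i) - 1) / 2
        for k in range(i, j):
            ranks[order[k]] = avg
        pos += j - i
        i = j
    V = float(ranks[d > 0].sum())
    vs = []
    for signs in itertools.product([0, 1], repeat=n):
        vs.append(sum(r for r, s in zip(ranks, signs) if s))
    vs = np.asarray(vs)
    cdf = np.mean(vs <= V + 1e-9)
    sf = np.mean(vs >= V - 1e-9)
    return V, min(1.0, 2 * min(cdf, sf))


def spearman_set_mean_oracle(data: np.ndarray) -> float:
    """Mean pairwise Spearman rho via scipy, pair by pair."""
    from scipy.stats import spearmanr

    k = data.shape[0]
    vals = []
    for i in range(k):
        for j in range(i + 1, k):
            vals.append(spearmanr(data[i], data[j]).statistic)
    return float(np.mean(vals))


def binom_upper_tail_oracle(k: int, n: int, f: float) -> float:
    """P(X >= k) by direct term-by-term summation."""
    return sum(comb(n, x) * f**x * (1 - f) ** (n - x) for x in range(k, n + 1))


def translate(codon: str) -> str:
    return str(Seq(codon).translate(table=11))


def ng86_sites_oracle(seq: str) -> tuple[float, float]:
    """NG86 site counts using Biopython translation, coded independently."""
    s_tot = n_tot = 0.0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        aa = translate(codon)
        for p in range(3):
            syn = 0
            for b in "ACGT":
                if b == codon[p]:
                    continue
                if translate(codon[:p] + b + codon[p + 1 :]) == aa:
                    syn += 1
            s_tot += syn / 3
            n_tot += 1 - syn / 3
    return s_tot, n_tot


def jc_oracle(p: float) -> float:
    return -3 / 4 * log(1 - 4 * p / 3)


def codon_pathways_oracle(c1: str, c2: str):
    """All substitution orderings between two codons with per-step labels."""
    diff = [p for p in range(3) if c1[p] != c2[p]]
    out = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        stops = False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if translate(nxt) == translate(cur):
                sd += 1
            else:
                nd += 1
            if translate(nxt) == "*" and nxt != c2:
                stops = True
            cur = nxt
        out.append((sd, nd, stops))
    return out
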