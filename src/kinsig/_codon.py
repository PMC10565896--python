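"""Codon-level helpers shared by the simulator and the statistics layer.

Everything here works on the bacterial genetic code (NCBI translation
table 11) and on nucleotide arrays encoded as uint8 ASCII (b"ACGTN").
Site counting follows Nei & Gojobori (1986): each codon position carries a
fractional synonymous site count equal to the fraction of its three
possible single-base changes that leave the amino acid unchanged, and
multi-hit codons are resolved by averaging over mutational pathways.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

BASES = b"ACGT"
A, C, G, T = BASES
N_BASE = ord("N")

_TABLE = CodonTable.unambiguous_dna_by_id[11]

# codon string -> amino acid, '*' for stop
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = frozenset(_TABLE.stop_codons)

_COMP = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b
    # lowercase tolerated on input
    _COMP[_a + 32] = _b


def seq_to_arr(seq: str | bytes) -> np.ndarray:
    """Encode a nucleotide string as an upper-case uint8 array."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    arr = np.frombuffer(bytes(seq), dtype=np.uint8).copy()
    lower = (arr >= ord("a")) & (arr <= ord("z"))
    arr[lower] -= 32
    return arr


def arr_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp(arr: np.ndarray) -> np.ndarray:
    return _COMP[arr][::-1]


def translate_codon(codon: str) -> str:
    """Amino acid for a codon under table 11 ('*' = stop, 'X' = ambiguous)."""
    return CODON_TO_AA.get(codon, "X")


def _codon_str(arr: np.ndarray, codon_idx: int) -> str:
    return arr[3 * codon_idx : 3 * codon_idx + 3].tobytes().decode("ascii")


@lru_cache(maxsize=None)
def syn_fraction(codon: str, pos: int) -> float:
    """Fraction of the 3 single-base changes at `pos` that are synonymous.

    Changes to or from a stop codon count as nonsynonymous, following the
    usual NG86 convention; a stop-to-stop change counts as synonymous.
    """
    aa0 = translate_codon(codon)
    if aa0 == "X":
        return 0.0
    syn = 0
    for b in "ACGT":
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1 :]
        if translate_codon(alt) == aa0:
            syn += 1
    return syn / 3.0


@lru_cache(maxsize=None)
def codon_site_counts(codon: str) -> tuple[float, float]:
    """NG86 (synonymous, nonsynonymous) site counts for one codon."""
    if translate_codon(codon) == "X":
        return 0.0, 0.0
    s = sum(syn_fraction(codon, p) for p in range(3))
    return s, 3.0 - s


def ng86_site_counts(arr: np.ndarray) -> tuple[float, float]:
    """Total NG86 synonymous / nonsynonymous site counts for a CDS array.

    Codons containing an ambiguous base contribute to neither class.
    """
    if len(arr) % 3:
        raise ValueError("CDS length must be divisible by 3")
    s_tot = n_tot = 0.0
    for i in range(len(arr) // 3):
        s, n = codon_site_counts(_codon_str(arr, i))
        s_tot += s
        n_tot += n
    return s_tot, n_tot


@lru_cache(maxsize=None)
def is_synonymous_change(codon: str, pos: int, alt_base: str) -> bool:
    """Whether replacing `codon[pos]` by `alt_base` preserves the amino acid."""
    aa0 = translate_codon(codon)
    alt = codon[:pos] + alt_base + codon[pos + 1 :]
    return translate_codon(alt) == aa0 and aa0 != "X"


@lru_cache(maxsize=None)
def pathway_diff_counts(c1: str, c2: str) -> tuple[float, float]:
    """NG86 pathway-averaged (synonymous, nonsynonymous) difference counts.

    Enumerates all orderings of the differing positions between the two
    codons; pathways passing through an intermediate stop codon are
    discarded unless every pathway does.  Codons with an ambiguous base
    return (0, 0).
    """
    if translate_codon(c1) == "X" or translate_codon(c2) == "X":
        return 0.0, 0.0
    diff = [p for p in range(3) if c1[p] != c2[p]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0.0
        through_stop = False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1 :]
            if translate_codon(nxt) == translate_codon(cur) and translate_codon(cur) != "*":
                sd += 1
            elif translate_codon(nxt) == "*" == translate_codon(cur):
                sd += 1
            else:
                nd += 1
            if translate_codon(nxt) == "*" and nxt != c2:
                through_stop = True
            cur = nxt
        paths.append((sd, nd, through_stop))
    kept = [(s, n) for s, n, ts in paths if not ts]
    if not kept:
        kept = [(s, n) for s, n, _ in paths]
    sd = float(np.mean([s for s, _ in kept]))
    nd = float(np.mean([n for _, n in kept]))
    return sd, nd


def mutation_masks(ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-position flags: can a single-base change here be synonymous /
    nonsynonymous?  Used by the simulator to place mutations of a chosen
    functional class."""
    L = len(ref)
    can_syn = np.zeros(L, dtype=np.uint8)
    can_non = np.zeros(L, dtype=np.uint8)
    for i in range(L // 3):
        codon = _codon_str(ref, i)
        if translate_codon(codon) == "X":
            continue
        for p in range(3):
            f = syn_fraction(codon, p)
            if f > 0:
                can_syn[3 * i + p] = 1
            if f < 1:
                can_non[3 * i + p] = 1
    return can_syn, can_non


@lru_cache(maxsize=None)
def compatible_alt_bases(codon: str, pos: int, synonymous: bool) -> list[str]:
    """Alternative bases at `pos` whose change matches the requested class."""
    out = []
    for b in "ACGT":
        if b == codon[pos]:
            continue
        if is_synonymous_change(codon, pos, b) == synonymous:
            out.append(b)
    return out


def random_cds(rng: np.random.Generator, length: int) -> np.ndarray:
    """Random protein-coding sequence: ATG start, no internal stops, TAA end."""
    if length % 3:
        raise ValueError("CDS length must be divisible by 3")
    ncod = length // 3
    sense = sorted(c for c in CODON_TO_AA if CODON_TO_AA[c] not in ("*",) and c != "ATG")
    body = rng.choice(sense, size=max(ncod - 2, 0))
    parts = ["ATG", *body, "TAA"][:ncod]
    return seq_to_arr("".join(parts))
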