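"""Input formats, filtering rules, haplotype alignments, deleterious variants.

This module is the boundary between the standard file formats (VCF 4.2,
GFF3, FASTA) and the in-memory objects the statistics layer consumes.
Coordinates are 1-based inclusive at the file boundary (VCF/GFF
convention) and 0-based half-open internally.

Filtering mirrors the study design this package implements: SNP sites must
be called in at least 80% of strains, indels are excluded from the
population-genetic statistics but kept aside for loss-of-function
annotation, and genes with less than half their length mapped (or no
polymorphism data at all) are dropped. Per-site statistics downstream are
scaled by the mapped (effective) length, not the annotated length.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import gffutils
import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from ._codon import N_BASE, revcomp, seq_to_arr, translate_codon

logger = logging.getLogger("kinsig.genome_io")

CATEGORIES = ("cooperative", "private", "background", "uncategorized")


@dataclass
class GeneModel:
    """A protein-coding gene with its sociality annotation.

    `start`/`end` are 1-based inclusive genomic coordinates.
    `mapped_fraction` is the fraction of the gene length covered by the
    upstream read mapping; per-site statistics divide by
    ``mapped_fraction * length``.
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    category: str = "uncategorized"
    trait_group: str | None = None
    operon_id: str | None = None
    mapped_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if not 0.0 <= self.mapped_fraction <= 1.0:
            raise ValueError(f"{self.gene_id}: mapped_fraction outside [0, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def effective_length(self) -> int:
        return int(round(self.mapped_fraction * self.length))


@dataclass
class VariantRecord:
    """One decomposed (single-alt) variant with per-strain haploid calls.

    `calls` holds one int8 per strain: 0 = reference allele, 1 = this alt,
    -1 = missing (uncalled, or carrying a different alt of a multi-allelic
    site).
    """

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    calls: np.ndarray
    variant_class: str = "SNP"  # SNP | insertion | deletion

    @property
    def call_rate(self) -> float:
        return float(np.mean(self.calls >= 0))

    @property
    def is_snp(self) -> bool:
        return self.variant_class == "SNP"


@dataclass
class HaplotypeAlignment:
    """Per-gene matrix of sampled strain sequences in CDS orientation.

    Rows are strains, columns are gene positions; minus-strand genes are
    reverse-complemented so codon position 1 is column 0.  Missing calls
    are encoded as ``N``.  The optional outgroup row is never counted in
    the sample size.
    """

    gene_id: str
    strain_ids: list[str]
    seqs: np.ndarray  # uint8, shape (n, L)
    ref_seq: np.ndarray  # uint8, shape (L,)
    outgroup_seq: np.ndarray | None = None
    effective_length: int | None = None

    def __post_init__(self) -> None:
        if self.seqs.ndim != 2 or self.seqs.shape[0] != len(self.strain_ids):
            raise ValueError("seqs must be (n_strains, L)")
        if self.seqs.shape[1] != len(self.ref_seq):
            raise ValueError("ref_seq length must match alignment width")
        if self.outgroup_seq is not None and len(self.outgroup_seq) != self.length:
            raise ValueError("outgroup row must match alignment width")
        if self.effective_length is None:
            self.effective_length = self.length
        if self.effective_length > self.length:
            raise ValueError("effective_length cannot exceed gene length")

    @property
    def n_samples(self) -> int:
        return self.seqs.shape[0]

    @property
    def length(self) -> int:
        return self.seqs.shape[1]


class VcfData(NamedTuple):
    samples: list[str]
    records: list[VariantRecord]


def read_vcf(path: str | Path) -> VcfData:
    """Read a VCF into decomposed per-alt `VariantRecord`s.

    Multi-allelic rows are split into one record per alternate allele;
    strains carrying a different alternate allele are marked missing for
    that record.
    """
    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            if rec.alts is None:
                continue
            gts = []
            for s in samples:
                gt = rec.samples[s]["GT"]
                gts.append(gt[0] if gt and gt[0] is not None else None)
            for k, alt in enumerate(rec.alts, start=1):
                calls = np.full(len(samples), -1, dtype=np.int8)
                for i, a in enumerate(gts):
                    if a == 0:
                        calls[i] = 0
                    elif a == k:
                        calls[i] = 1
                if len(rec.ref) == 1 and len(alt) == 1:
                    vclass = "SNP"
                elif len(alt) > len(rec.ref):
                    vclass = "insertion"
                else:
                    vclass = "deletion"
                records.append(
                    VariantRecord(rec.contig, rec.pos, rec.ref, alt, calls, vclass)
                )
    return VcfData(samples, records)


def read_gff(path: str | Path, contigs: Iterable[str] | None = None) -> list[GeneModel]:
    """Read CDS features with sociality annotations from a GFF3 file."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    known = set(contigs) if contigs is not None else None
    genes = []
    for f in db.features_of_type("CDS"):
        if known is not None and f.seqid not in known:
            raise ValueError(f"GFF feature on unknown contig {f.seqid!r}")
        attrs = f.attributes
        gid = attrs["ID"][0]
        genes.append(
            GeneModel(
                gene_id=gid,
                contig=f.seqid,
                start=f.start,
                end=f.end,
                strand=f.strand,
                category=attrs.get("sociality", ["uncategorized"])[0],
                trait_group=(attrs.get("trait_group") or [None])[0],
                operon_id=(attrs.get("operon_id") or [None])[0],
                mapped_fraction=float(attrs.get("mapped_fraction", ["1.0"])[0]),
            )
        )
    return genes


def read_fasta(path: str | Path) -> dict[str, np.ndarray]:
    """Read a FASTA file into a contig -> uint8 sequence mapping."""
    return {rec.id: seq_to_arr(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}


def read_categories(path: str | Path) -> pd.DataFrame:
    """Read a sociality annotation table (gene_id, category[, trait_group])."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns or "category" not in df.columns:
        raise ValueError("category table needs gene_id and category columns")
    return df


def apply_categories(genes: Sequence[GeneModel], table: pd.DataFrame) -> list[GeneModel]:
    """Override gene categories/trait groups from an annotation table."""
    lut = table.set_index("gene_id")
    for g in genes:
        if g.gene_id in lut.index:
            row = lut.loc[g.gene_id]
            g.category = str(row["category"])
            if "trait_group" in lut.columns and not pd.isna(row.get("trait_group")):
                g.trait_group = str(row["trait_group"])
    return list(genes)


class FilteredVariants(NamedTuple):
    snps: list[VariantRecord]
    indels: list[VariantRecord]
    n_dropped_low_call: int


def filter_variants(
    records: Iterable[VariantRecord],
    min_call_rate: float = 0.8,
    drop_indels: bool = True,
) -> FilteredVariants:
    """Apply the site-level filters.

    SNPs with call rate >= `min_call_rate` (ties retained) are kept for the
    population-genetic statistics; indels are routed to a side collection
    used only for loss-of-function annotation.  `drop_indels` must stay
    True: the statistics layer is defined on SNPs only.
    """
    if not drop_indels:
        raise ValueError(
            "drop_indels=False is not supported: indels are excluded from all "
            "population-genetic statistics and kept only for deleterious "
            "annotation"
        )
    snps: list[VariantRecord] = []
    indels: list[VariantRecord] = []
    dropped = 0
    for rec in records:
        if not rec.is_snp:
            indels.append(rec)
        elif rec.call_rate >= min_call_rate:
            snps.append(rec)
        else:
            dropped += 1
    return FilteredVariants(snps, indels, dropped)


def filter_genes(
    genes: Iterable[GeneModel],
    min_mapped_fraction: float = 0.5,
    require_polymorphism_data: bool = True,
) -> list[GeneModel]:
    """Drop genes with mapped length below threshold or with no mapped sites.

    Ties at the threshold are retained ("at least" semantics).
    """
    out = []
    for g in genes:
        if g.mapped_fraction < min_mapped_fraction:
            continue
        if require_polymorphism_data and g.effective_length <= 0:
            continue
        out.append(g)
    return out


def build_alignment(
    gene: GeneModel,
    variants: Iterable[VariantRecord],
    reference: dict[str, np.ndarray],
    strains: Sequence[str],
    outgroup: dict[str, np.ndarray] | None = None,
) -> HaplotypeAlignment:
    """Realize per-strain haplotype sequences for one gene.

    Each strain row is the reference slice with that strain's alternate
    alleles substituted; missing calls become ``N`` (pairwise deletion
    downstream).  Minus-strand genes are returned reverse-complemented.
    """
    if gene.contig not in reference:
        raise ValueError(f"gene {gene.gene_id} on unknown contig {gene.contig!r}")
    ref_slice = reference[gene.contig][gene.start - 1 : gene.end].copy()
    n = len(strains)
    seqs = np.tile(ref_slice, (n, 1))
    for rec in variants:
        if rec.contig != gene.contig or not (gene.start <= rec.pos <= gene.end):
            continue
        if not rec.is_snp:
            continue
        off = rec.pos - gene.start
        if ref_slice[off] != ord(rec.ref):
            raise ValueError(
                f"variant {rec.contig}:{rec.pos} ref allele {rec.ref!r} does not "
                f"match reference base {chr(ref_slice[off])!r}"
            )
        alt = ord(rec.alt)
        seqs[rec.calls == 1, off] = alt
        seqs[rec.calls == -1, off] = N_BASE
    out_row = None
    if outgroup is not None:
        if gene.contig not in outgroup:
            raise ValueError(f"outgroup lacks contig {gene.contig!r}")
        out_row = outgroup[gene.contig][gene.start - 1 : gene.end].copy()
    ref_oriented = ref_slice
    if gene.strand == "-":
        seqs = np.stack([revcomp(row) for row in seqs])
        ref_oriented = revcomp(ref_slice)
        if out_row is not None:
            out_row = revcomp(out_row)
    return HaplotypeAlignment(
        gene_id=gene.gene_id,
        strain_ids=list(strains),
        seqs=seqs,
        ref_seq=ref_oriented,
        outgroup_seq=out_row,
        effective_length=gene.effective_length,
    )


def build_outgroup_pseudogenome(
    reference: dict[str, np.ndarray],
    outgroup_records: Iterable[VariantRecord],
) -> dict[str, np.ndarray]:
    """Substitute the outgroup's SNP alleles into the reference sequence.

    Length is preserved: indels in the outgroup VCF are skipped with a
    warning.  Where the outgroup VCF has per-sample calls, the first
    sample's called allele is used; records without samples substitute the
    alternate allele.
    """
    pseudo = {c: seq.copy() for c, seq in reference.items()}
    n_sub = n_skipped = 0
    for rec in outgroup_records:
        if rec.contig not in pseudo:
            raise ValueError(f"outgroup variant on unknown contig {rec.contig!r}")
        if not rec.is_snp:
            n_skipped += 1
            continue
        if len(rec.calls) and rec.calls[0] != 1:
            continue  # outgroup carries the reference (or is uncalled) here
        off = rec.pos - 1
        if pseudo[rec.contig][off] != ord(rec.ref):
            raise ValueError(
                f"outgroup variant {rec.contig}:{rec.pos} inconsistent with reference"
            )
        pseudo[rec.contig][off] = ord(rec.alt)
        n_sub += 1
    if n_skipped:
        logger.warning("skipped %d outgroup indels (length preservation)", n_skipped)
    logger.info("outgroup pseudogenome: %d substitutions", n_sub)
    return pseudo


def _gene_index(genes: Sequence[GeneModel]) -> dict[str, tuple[list[int], list[GeneModel]]]:
    by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_contig.setdefault(g.contig, []).append(g)
    out = {}
    for contig, gl in by_contig.items():
        gl.sort(key=lambda g: g.start)
        out[contig] = ([g.start for g in gl], gl)
    return out


def _find_gene(index, contig: str, pos: int) -> GeneModel | None:
    if contig not in index:
        return None
    starts, gl = index[contig]
    i = bisect_right(starts, pos) - 1
    if i >= 0 and gl[i].start <= pos <= gl[i].end:
        return gl[i]
    return None


def annotate_deleterious(
    variants: Iterable[VariantRecord],
    genes: Sequence[GeneModel],
    reference: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Count putative loss-of-function variants per gene.

    Two classes are annotated, from first principles on translation
    table 11:

    * stop gain — a SNP whose alternate codon is a stop (TAA/TAG/TGA on
      the coding strand) while the reference codon is not, excluding the
      annotated terminal stop codon;
    * frameshift — an indel anchored inside the CDS whose length change is
      not a multiple of 3.

    Returns a DataFrame indexed by gene_id with columns ``stop_gain``,
    ``frameshift``, ``total`` and ``has_deleterious``; every input gene is
    present (zero counts included).
    """
    index = _gene_index(genes)
    rows = {g.gene_id: {"stop_gain": 0, "frameshift": 0} for g in genes}
    for rec in variants:
        gene = _find_gene(index, rec.contig, rec.pos)
        if gene is None:
            continue
        if rec.pos + max(len(rec.ref), len(rec.alt)) - 1 > gene.end:
            logger.warning(
                "variant %s:%d spans the boundary of %s; counted by anchor",
                rec.contig, rec.pos, gene.gene_id,
            )
        if rec.is_snp:
            if gene.length % 3:
                continue
            if gene.strand == "+":
                cds_off = rec.pos - gene.start
                alt_b = rec.alt
            else:
                cds_off = gene.end - rec.pos
                alt_b = chr(revcomp(seq_to_arr(rec.alt))[0])
            codon_idx = cds_off // 3
            if codon_idx == gene.length // 3 - 1:
                continue  # annotated terminal stop
            gslice = reference[gene.contig][gene.start - 1 : gene.end]
            cds = revcomp(gslice) if gene.strand == "-" else gslice
            codon = cds[3 * codon_idx : 3 * codon_idx + 3].tobytes().decode()
            p = cds_off % 3
            alt_codon = codon[:p] + alt_b + codon[p + 1 :]
            if translate_codon(alt_codon) == "*" and translate_codon(codon) != "*":
                rows[gene.gene_id]["stop_gain"] += 1
        else:
            if abs(len(rec.ref) - len(rec.alt)) % 3 != 0:
                rows[gene.gene_id]["frameshift"] += 1
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene_id"
    df["total"] = df["stop_gain"] + df["frameshift"]
    df["has_deleterious"] = df["total"] > 0
    return df
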