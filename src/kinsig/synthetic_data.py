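"""Relaxed-selection simulator and fixture writer.

Generates complete synthetic inputs (multi-strain SNP VCF, GFF3 with
sociality annotations, reference + outgroup FASTA, expression TSV, truth
table) under an explicit relaxed-selection model, so that every
downstream stage of the pipeline can be exercised and validated without
any external data.

The model: each gene evolves as an independent haploid Wright-Fisher
population (free recombination between genes, full linkage within).
Mutations at nonsynonymous sites are deleterious with selection
coefficient ``s_eff``; synonymous-site mutations are neutral.  For
cooperative genes the effective coefficient is reduced to ``s_eff = r*s``
— the first-order inclusive-fitness reduction when the benefits of a
cooperative gene product fall on neighbors of relatedness ``r`` — while
private and background genes keep ``s_eff = s``.  Relatedness r = 1
therefore makes cooperative and private genes statistically identical,
and r < 1 elevates polymorphism (and, through the outgroup model,
divergence) at cooperative genes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._codon import (
    arr_to_seq,
    compatible_alt_bases,
    is_synonymous_change,
    mutation_masks,
    random_cds,
    revcomp,
    translate_codon,
)
from ._wf import wf_simulate
from .genome_io import GeneModel, HaplotypeAlignment

logger = logging.getLogger("kinsig.synthetic_data")

CLASSES = ("cooperative", "private", "background")
CLASS_PREFIX = {"cooperative": "coop", "private": "priv", "background": "bg"}


@dataclass
class SimulationConfig:
    """Study conditions for the relaxed-selection simulator.

    Defaults emulate the real study's post-variant-calling products: 31
    sampled strains, a quorum-sensing-sized gene panel (25 cooperative,
    153 private) plus cytoplasmic background genes, per-site diversity on
    the order of 1%, an outgroup diverged at roughly Ks = 0.3, 5% missing
    genotype calls, and a true relatedness defaulting to the study's
    estimated r = 0.79.
    """

    population_size: int = 1000
    sample_size: int = 31
    num_genes_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"cooperative": 25, "private": 153, "background": 100}
    )
    gene_length_bp: int = 900
    per_site_mutation_rate: float = 5e-6
    selection_coefficient: float = 0.01
    true_relatedness: float = 0.79
    fraction_sites_nonsynonymous: float = 0.75
    burn_in_generations: int | None = None  # default 10 * population_size
    outgroup_expected_Ks: float = 0.3
    outgroup_omega: float = 0.2
    outgroup_omega_relaxed: bool = True
    missingness_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in_generations is None:
            self.burn_in_generations = 10 * self.population_size
        if self.sample_size > self.population_size:
            raise ValueError("sample_size must not exceed population_size")
        if not 0 < self.true_relatedness <= 1:
            raise ValueError("true_relatedness must be in (0, 1]")
        if self.gene_length_bp % 3:
            raise ValueError("gene_length_bp must be divisible by 3")
        for name in ("per_site_mutation_rate", "fraction_sites_nonsynonymous",
                     "missingness_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.selection_coefficient < 0:
            raise ValueError("selection_coefficient must be >= 0")
        # infinite-sites feasibility: expected population-level segregating
        # sites (~ 2NuL * H_N) must stay well below the gene length
        n_seg = (
            2 * self.population_size * self.per_site_mutation_rate
            * self.gene_length_bp
            * (math.log(max(self.population_size, 2)) + 0.5772)
        )
        if n_seg > 0.5 * self.gene_length_bp:
            raise ValueError(
                "u*L*N too large: expected segregating sites would exceed the "
                "gene length (infinite-sites assumption violated)"
            )

    def s_eff(self, category: str) -> float:
        if category == "cooperative":
            return self.true_relatedness * self.selection_coefficient
        return self.selection_coefficient


@dataclass
class SimulationResult:
    """Alignments plus ground truth from one simulated cohort."""

    alignments: list[HaplotypeAlignment]
    truth: pd.DataFrame  # gene_id, category, s_eff, true_r, segregating_sites
    config: SimulationConfig

    def alignment(self, gene_id: str) -> HaplotypeAlignment:
        for a in self.alignments:
            if a.gene_id == gene_id:
                return a
        raise KeyError(gene_id)


def _strain_ids(n: int) -> list[str]:
    return [f"strain_{i:02d}" for i in range(1, n + 1)]


def simulate_population(config: SimulationConfig) -> SimulationResult:
    """Forward-simulate every gene and sample n strains per gene.

    Each gene runs a haploid Wright-Fisher population of size N for the
    burn-in, with multiplicative selection against deleterious
    (nonsynonymous-site) mutations at the class's effective coefficient;
    after burn-in, ``sample_size`` haplotypes are drawn without
    replacement.  Identical seeds give bit-identical results.
    """
    rng = np.random.default_rng(config.seed)
    core_seeds_root = np.random.SeedSequence(config.seed)
    N, n, L = config.population_size, config.sample_size, config.gene_length_bp
    u = config.per_site_mutation_rate
    strains = _strain_ids(n)
    cap = int(min(L, max(128, 8 * 2 * N * u * L * (math.log(max(N, 2)) + 1))))
    alignments: list[HaplotypeAlignment] = []
    truth_rows = []
    gene_idx = 0
    n_genes_total = sum(config.num_genes_per_class.get(c, 0) for c in CLASSES)
    core_seeds = core_seeds_root.generate_state(n_genes_total, dtype=np.uint32)
    for category in CLASSES:
        count = config.num_genes_per_class.get(category, 0)
        s_eff = config.s_eff(category)
        for k in range(count):
            gene_id = f"{CLASS_PREFIX[category]}_{k + 1:04d}"
            ref = random_cds(rng, L)
            can_syn, can_non = mutation_masks(ref)
            geno, pos, is_del, status = wf_simulate(
                N, L, u, s_eff, config.fraction_sites_nonsynonymous,
                can_syn, can_non, int(config.burn_in_generations),
                int(core_seeds[gene_idx]), cap,
            )
            if status < 0:
                raise RuntimeError(
                    f"{gene_id}: segregating sites exceeded capacity "
                    "(u*L*N too large)"
                )
            sample_rows = rng.choice(N, size=n, replace=False)
            sub = geno[np.sort(sample_rows)]
            seg_mask = (sub.sum(axis=0) > 0) & (sub.sum(axis=0) < n)
            sub = sub[:, seg_mask]
            spos = pos[seg_mask]
            sdel = is_del[seg_mask]
            order = np.argsort(spos)
            sub, spos, sdel = sub[:, order], spos[order], sdel[order]
            seqs = np.tile(ref, (n, 1))
            for j, p in enumerate(spos):
                codon_idx = int(p) // 3
                codon = arr_to_seq(ref[3 * codon_idx : 3 * codon_idx + 3])
                alts = compatible_alt_bases(codon, int(p) % 3, synonymous=not sdel[j])
                alt = alts[int(rng.integers(len(alts)))] if alts else None
                if alt is None:  # cannot happen given the mutation masks
                    continue
                seqs[sub[:, j] == 1, int(p)] = ord(alt)
            alignments.append(
                HaplotypeAlignment(
                    gene_id=gene_id,
                    strain_ids=strains,
                    seqs=seqs,
                    ref_seq=ref.copy(),
                    effective_length=L,
                )
            )
            truth_rows.append(
                {
                    "gene_id": gene_id,
                    "category": category,
                    "s_eff": s_eff,
                    "true_r": config.true_relatedness,
                    "segregating_sites": int(seg_mask.sum()),
                }
            )
            gene_idx += 1
    truth = pd.DataFrame(truth_rows)
    return SimulationResult(alignments, truth, config)


def simulate_outgroup(
    config: SimulationConfig,
    reference_seqs: Mapping[str, np.ndarray],
    categories: Mapping[str, str],
) -> dict[str, np.ndarray]:
    """Evolve an outgroup sequence for each gene along a single branch.

    Substitution events arrive as a Poisson process at ``expected_Ks``
    proposals per site; each proposes one of the 3 alternative bases
    uniformly and is accepted with probability 1 if synonymous and
    omega_class if nonsynonymous (Jukes-Cantor multiple-hit behavior:
    a site may substitute repeatedly).  When ``outgroup_omega_relaxed``
    is on, cooperative genes use omega/r (capped at 1), so divergence as
    well as polymorphism is elevated under relaxed selection.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    out: dict[str, np.ndarray] = {}
    for gene_id, ref in reference_seqs.items():
        omega = config.outgroup_omega
        if config.outgroup_omega_relaxed and categories.get(gene_id) == "cooperative":
            omega = min(1.0, omega / config.true_relatedness)
        seq = ref.copy()
        L = len(seq)
        n_events = rng.poisson(config.outgroup_expected_Ks * L)
        for _ in range(n_events):
            p = int(rng.integers(L))
            codon_idx = p // 3
            codon = arr_to_seq(seq[3 * codon_idx : 3 * codon_idx + 3])
            if translate_codon(codon) == "X":
                continue
            cur_b = codon[p % 3]
            alt = "ACGT"[int(rng.integers(4))]
            while alt == cur_b:
                alt = "ACGT"[int(rng.integers(4))]
            if is_synonymous_change(codon, p % 3, alt):
                seq[p] = ord(alt)
            elif rng.random() < omega:
                seq[p] = ord(alt)
        out[gene_id] = seq
    return out


# ---------------------------------------------------------------------------
# expression


def generate_expression(
    gene_ids: Sequence[str] | int,
    num_timepoints: int,
    coexpressed_sets: Sequence[Sequence[str]] = (),
    target_rho: float = 0.3,
    noise_sd: float | None = None,
    seed: int = 0,
):
    """Gene x timepoint expression matrix with planted co-expressed blocks.

    Each co-expressed set shares a smooth latent temporal profile; member
    levels are gene-specific monotone affine transforms of the profile
    plus independent Gaussian noise on the log scale.  When ``noise_sd``
    is None the noise is calibrated by bisection so the realized mean
    pairwise Spearman correlation within each set is close to
    ``target_rho``.  Non-member genes follow independent profiles.  The
    returned matrix is median-normalized per gene.
    """
    from .coexpression import ExpressionMatrix, median_normalize

    if isinstance(gene_ids, int):
        gene_ids = [f"gene_{i + 1:05d}" for i in range(gene_ids)]
    if num_timepoints < 3:
        raise ValueError("num_timepoints must be >= 3")
    if noise_sd is None and not 0 < target_rho < 1:
        raise ValueError("target_rho must be in (0, 1)")
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    idx = {g: i for i, g in enumerate(gene_ids)}
    T = num_timepoints
    G = len(gene_ids)

    def smooth_profile(r):
        z = np.cumsum(r.standard_normal(T))
        z = (z - z.mean()) / max(z.std(), 1e-12)
        return z

    log_level = np.empty((G, T))
    for i in range(G):
        log_level[i] = 0.6 * smooth_profile(rng) + 0.3 * rng.standard_normal(T)
    for members in coexpressed_sets:
        missing = [g for g in members if g not in idx]
        if missing:
            raise ValueError(f"co-expressed set members not in universe: {missing[:5]}")
        rows = np.array([idx[g] for g in members])
        z = smooth_profile(rng)
        a = rng.normal(0.0, 0.5, size=len(rows))
        b = np.exp(rng.normal(0.0, 0.3, size=len(rows)))  # positive: monotone
        eps = rng.standard_normal((len(rows), T))
        if noise_sd is not None:
            sd = noise_sd
        else:
            sd = _calibrate_noise(z, a, b, eps, target_rho)
        log_level[rows] = a[:, None] + b[:, None] * z[None, :] + sd * eps
    levels = np.exp(log_level)
    df = pd.DataFrame(
        levels, index=pd.Index(gene_ids, name="gene_id"),
        columns=[f"t{j + 1:02d}" for j in range(T)],
    )
    return median_normalize(ExpressionMatrix(df, normalized=False))


def _mean_pairwise_spearman_rows(x: np.ndarray) -> float:
    from scipy.stats import rankdata

    r = rankdata(x, axis=1).astype(float)
    r -= r.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(r, axis=1, keepdims=True)
    z = r / np.where(norm > 0, norm, np.nan)
    gram = z @ z.T
    k = x.shape[0]
    iu = np.triu_indices(k, 1)
    return float(np.nanmean(gram[iu]))


def _calibrate_noise(z, a, b, eps, target_rho: float, iters: int = 20) -> float:
    """Bisection on the noise SD against the realized set-mean Spearman rho."""
    lo, hi = 0.0, 8.0
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        x = a[:, None] + b[:, None] * z[None, :] + mid * eps
        rho = _mean_pairwise_spearman_rows(x)
        if rho > target_rho:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


# ---------------------------------------------------------------------------
# fixture writing


SPACER = 100  # intergenic bases between consecutive genes


def _layout(
    alignments: Sequence[HaplotypeAlignment],
    truth: pd.DataFrame,
    rng: np.random.Generator,
    mapped_fractions: Mapping[str, float] | None,
) -> tuple[np.ndarray, list[GeneModel]]:
    """Place genes head-to-tail on one contig, alternating strands."""
    cat = dict(zip(truth["gene_id"], truth["category"]))
    parts: list[np.ndarray] = []
    genes: list[GeneModel] = []
    cursor = 0
    for i, aln in enumerate(alignments):
        spacer = rng.integers(0, 4, size=SPACER).astype(np.uint8)
        spacer = np.frombuffer(b"ACGT", dtype=np.uint8)[spacer]
        parts.append(spacer)
        cursor += SPACER
        strand = "+" if i % 2 == 0 else "-"
        cds = aln.ref_seq
        genomic = cds if strand == "+" else revcomp(cds)
        parts.append(genomic)
        mf = 1.0 if mapped_fractions is None else mapped_fractions.get(aln.gene_id, 1.0)
        genes.append(
            GeneModel(
                gene_id=aln.gene_id,
                contig="sim_contig",
                start=cursor + 1,
                end=cursor + len(cds),
                strand=strand,
                category=cat.get(aln.gene_id, "uncategorized"),
                mapped_fraction=mf,
            )
        )
        cursor += len(cds)
    parts.append(np.frombuffer(b"ACGT", dtype=np.uint8)[
        rng.integers(0, 4, size=SPACER).astype(np.uint8)])
    return np.concatenate(parts), genes


def _genomic_variants(
    aln: HaplotypeAlignment, gene: GeneModel, contig_ref: np.ndarray
) -> list[tuple[int, str, str, np.ndarray]]:
    """Per-gene polymorphic columns as (pos1, ref, alt, carrier mask)."""
    out = []
    n = aln.n_samples
    for col in range(aln.length):
        column = aln.seqs[:, col]
        alleles = sorted(set(int(b) for b in column))
        if len(alleles) < 2:
            continue
        ref_b = int(aln.ref_seq[col])
        alt_bs = [b for b in alleles if b != ref_b]
        for alt_b in alt_bs:
            if gene.strand == "+":
                pos1 = gene.start + col
                g_ref, g_alt = ref_b, alt_b
            else:
                pos1 = gene.end - col
                comp = dict(zip(b"ACGT", b"TGCA"))
                g_ref, g_alt = comp[ref_b], comp[alt_b]
            assert contig_ref[pos1 - 1] == g_ref
            out.append((pos1, chr(g_ref), chr(g_alt), column == alt_b))
    return out


def _find_stop_gain_site(aln: HaplotypeAlignment) -> tuple[int, str, str] | None:
    """A CDS position where a single change creates a premature stop."""
    ref = aln.ref_seq
    ncod = len(ref) // 3
    for ci in range(1, ncod - 1):
        codon = arr_to_seq(ref[3 * ci : 3 * ci + 3])
        if translate_codon(codon) == "*":
            continue
        for p in range(3):
            col = 3 * ci + p
            if len(set(int(b) for b in aln.seqs[:, col])) > 1:
                continue  # keep spikes off already-polymorphic columns
            for b in "ACGT":
                if b == codon[p]:
                    continue
                alt = codon[:p] + b + codon[p + 1 :]
                if translate_codon(alt) == "*":
                    return col, codon[p], b
    return None


def write_fixture(
    output_dir: str | Path,
    alignments: Sequence[HaplotypeAlignment],
    truth: pd.DataFrame,
    expression=None,
    *,
    outgroup_seqs: Mapping[str, np.ndarray] | None = None,
    missingness_rate: float = 0.0,
    seed: int = 0,
    mapped_fractions: Mapping[str, float] | None = None,
    spike_stop_gain: Iterable[str] = (),
    spike_frameshift: Iterable[str] = (),
    force: bool = False,
) -> dict[str, Path]:
    """Write VCF + GFF3 + FASTA(s) + TSVs for a simulated cohort.

    The VCF holds one row per site segregating in the sample, with
    haploid genotypes and MCAR missingness at ``missingness_rate``.
    Optional spikes add a premature-stop SNP and/or a 1-bp frameshift
    insertion to named genes so loss-of-function annotation can be tested
    against a known answer.  Refuses to overwrite without ``force``.
    """
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "strains.vcf",
        "gff": outdir / "genes.gff3",
        "fasta": outdir / "reference.fasta",
        "outgroup_fasta": outdir / "outgroup_pseudogenome.fasta",
        "truth": outdir / "truth.tsv",
        "expression": outdir / "expression.tsv",
        "categories": outdir / "categories.tsv",
    }
    for key, p in paths.items():
        if p.exists() and not force:
            raise FileExistsError(f"{p} exists; pass force=True to overwrite")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    contig_ref, genes = _layout(alignments, truth, rng, mapped_fractions)
    aln_by_id = {a.gene_id: a for a in alignments}
    gene_by_id = {g.gene_id: g for g in genes}
    strains = alignments[0].strain_ids if alignments else []

    # --- variant rows (position-sorted)
    rows: list[tuple[int, str, str, np.ndarray | None, str]] = []
    for g in genes:
        aln = aln_by_id[g.gene_id]
        for pos1, ref_a, alt_a, mask in _genomic_variants(aln, g, contig_ref):
            rows.append((pos1, ref_a, alt_a, mask, "snp"))
    n = len(strains)
    for gene_id in spike_stop_gain:
        aln, g = aln_by_id[gene_id], gene_by_id[gene_id]
        found = _find_stop_gain_site(aln)
        if found is None:
            raise ValueError(f"no spikable stop-gain site in {gene_id}")
        col, ref_b, alt_b = found
        mask = np.zeros(n, dtype=bool)
        mask[: max(1, n // 10)] = True
        if g.strand == "+":
            pos1 = g.start + col
            g_ref, g_alt = ref_b, alt_b
        else:
            pos1 = g.end - col
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            g_ref, g_alt = comp[ref_b], comp[alt_b]
        rows.append((pos1, g_ref, g_alt, mask, "snp"))
    for gene_id in spike_frameshift:
        g = gene_by_id[gene_id]
        pos1 = g.start + 4  # inside the CDS, away from boundaries
        ref_b = chr(contig_ref[pos1 - 1])
        mask = np.zeros(n, dtype=bool)
        mask[: max(1, n // 15)] = True
        rows.append((pos1, ref_b, ref_b + "A", mask, "indel"))
    rows.sort(key=lambda r: (r[0], r[2]))

    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID=sim_contig,length={len(contig_ref)}>")
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for s in strains:
        header.add_sample(s)
    miss = rng.random((len(rows), n)) < missingness_rate
    with pysam.VariantFile(str(paths["vcf"]), "w", header=header) as vf:
        for ridx, (pos1, ref_a, alt_a, mask, _kind) in enumerate(rows):
            rec = vf.new_record(
                contig="sim_contig", start=pos1 - 1,
                stop=pos1 - 1 + len(ref_a), alleles=(ref_a, alt_a),
            )
            for si, s in enumerate(strains):
                if miss[ridx, si]:
                    rec.samples[s]["GT"] = (None,)
                else:
                    rec.samples[s]["GT"] = (1,) if mask[si] else (0,)
            vf.write(rec)

    with open(paths["gff"], "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region sim_contig 1 {len(contig_ref)}\n")
        for g in genes:
            attrs = (
                f"ID={g.gene_id};gene_biotype=protein_coding;"
                f"sociality={g.category};mapped_fraction={g.mapped_fraction:g}"
            )
            fh.write(
                f"sim_contig\tkinsig\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t{attrs}\n"
            )

    SeqIO.write(
        [SeqRecord(Seq(arr_to_seq(contig_ref)), id="sim_contig", description="")],
        str(paths["fasta"]), "fasta",
    )
    if outgroup_seqs is not None:
        out_contig = contig_ref.copy()
        for g in genes:
            og = outgroup_seqs[g.gene_id]
            genomic = og if g.strand == "+" else revcomp(og)
            out_contig[g.start - 1 : g.end] = genomic
        SeqIO.write(
            [SeqRecord(Seq(arr_to_seq(out_contig)), id="sim_contig", description="")],
            str(paths["outgroup_fasta"]), "fasta",
        )
    else:
        paths.pop("outgroup_fasta")

    truth.to_csv(paths["truth"], sep="\t", index=False)
    cats = truth[["gene_id", "category"]]
    cats.to_csv(paths["categories"], sep="\t", index=False)
    if expression is not None:
        df = getattr(expression, "data", expression)
        df.to_csv(paths["expression"], sep="\t")
    else:
        paths.pop("expression")
    logger.info("fixture written to %s (%d genes, %d variant rows)",
                outdir, len(genes), len(rows))
    return paths
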