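"""File formats, filters, alignments, pseudogenome, deleterious annotation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from kinsig._codon import revcomp, seq_to_arr
from kinsig.genome_io import (
    GeneModel,
    VariantRecord,
    annotate_deleterious,
    build_alignment,
    build_outgroup_pseudogenome,
    filter_genes,
    filter_variants,
    read_fasta,
    read_gff,
    read_vcf,
)
from kinsig.popgen import nucleotide_diversity


def _rec(pos, ref, alt, calls, contig="sim_contig"):
    return VariantRecord(contig, pos, ref, alt, np.asarray(calls, dtype=np.int8))


class TestFilterVariants:
    def test_call_rate_threshold_arithmetic(self):
        # 31 strains: 24 called (77.4%) dropped, 25 called (80.6%) kept
        kept = _rec(5, "A", "C", [1] * 25 + [-1] * 6)
        dropped = _rec(6, "A", "C", [1] * 24 + [-1] * 7)
        res = filter_variants([kept, dropped])
        assert [r.pos for r in res.snps] == [5]
        assert res.n_dropped_low_call == 1

    def test_exact_boundary_retained(self):
        # 8/10 called is exactly 0.8: "at least 80%" is inclusive
        rec = _rec(1, "A", "C", [1] * 8 + [-1] * 2)
        assert filter_variants([rec]).snps == [rec]

    def test_indels_routed_to_side_channel(self):
        indel = VariantRecord("c", 1, "A", "AT", np.array([1, 0], dtype=np.int8),
                              "insertion")
        res = filter_variants([indel] * 3)
        assert res.snps == [] and len(res.indels) == 3

    def test_drop_indels_false_rejected(self):
        with pytest.raises(ValueError, match="drop_indels"):
            filter_variants([], drop_indels=False)

    def test_retention_matches_binomial_tail(self):
        # MCAR missingness 0.3 on 31 strains: P(kept) = P(Bin(31,.7) >= 25)
        rng = np.random.default_rng(0)
        n_rec, n_strains = 4000, 31
        recs = []
        for i in range(n_rec):
            calls = np.where(rng.random(n_strains) < 0.3, -1, 1).astype(np.int8)
            recs.append(_rec(i + 1, "A", "C", calls))
        kept = len(filter_variants(recs).snps)
        expect = 1 - sps.binom.cdf(24, 31, 0.7)  # P(calls >= ceil(0.8 * 31))
        se = np.sqrt(expect * (1 - expect) / n_rec)
        assert kept / n_rec == pytest.approx(expect, abs=4 * se)

    @given(st.lists(st.integers(0, 31), max_size=40))
    def test_idempotent(self, called_counts):
        recs = [
            _rec(i + 1, "A", "C", [1] * c + [-1] * (31 - c))
            for i, c in enumerate(called_counts)
        ]
        once = filter_variants(recs)
        twice = filter_variants(once.snps)
        assert twice.snps == once.snps


class TestFilterGenes:
    def _gene(self, mf, gid="g"):
        return GeneModel(gid, "c", 1, 300, "+", mapped_fraction=mf)

    def test_boundary_ties_retained(self):
        kept = filter_genes([self._gene(0.49, "a"), self._gene(0.50, "b")])
        assert [g.gene_id for g in kept] == ["b"]

    def test_zero_coverage_removed(self):
        assert filter_genes([self._gene(0.0)]) == []

    def test_flagged_fraction_survival(self):
        genes = [self._gene(0.3 if i % 10 == 0 else 1.0, f"g{i}") for i in range(100)]
        assert len(filter_genes(genes)) == 90


class TestBuildAlignment:
    REF = {"c": seq_to_arr("AAATTTGGGCCCAAATTTGGG")}

    def test_no_variants_rows_equal_reference(self):
        gene = GeneModel("g", "c", 4, 12, "+")
        aln = build_alignment(gene, [], self.REF, ["s1", "s2"])
        assert aln.seqs.tobytes() == b"TTTGGGCCC" * 2

    def test_single_snp_split(self):
        gene = GeneModel("g", "c", 4, 12, "+")
        rec = _rec(7, "G", "A", [1] * 15 + [0] * 16, contig="c")
        aln = build_alignment(gene, [rec], self.REF, [f"s{i}" for i in range(31)])
        col = aln.seqs[:, 3]
        assert (col == ord("A")).sum() == 15 and (col == ord("G")).sum() == 16
        assert (aln.seqs[:, [0, 1, 2, 4]] == aln.ref_seq[[0, 1, 2, 4]]).all()

    def test_minus_strand_reverse_complement(self):
        # 9-bp gene on the minus strand: rows are the revcomp of the + slice
        gene = GeneModel("g", "c", 4, 12, "-")
        aln = build_alignment(gene, [], self.REF, ["s1"])
        assert aln.seqs[0].tobytes() == b"GGGCCCAAA"
        assert aln.ref_seq.tobytes() == b"GGGCCCAAA"

    def test_missing_call_becomes_n(self):
        gene = GeneModel("g", "c", 4, 12, "+")
        rec = _rec(7, "G", "A", [1, -1, 0], contig="c")
        aln = build_alignment(gene, [rec], self.REF, ["a", "b", "c"])
        assert aln.seqs[1, 3] == ord("N")

    def test_inconsistent_reference_allele_raises(self):
        gene = GeneModel("g", "c", 4, 12, "+")
        rec = _rec(7, "T", "A", [1, 0], contig="c")
        with pytest.raises(ValueError, match="does not match reference"):
            build_alignment(gene, [rec], self.REF, ["a", "b"])


class TestOutgroupPseudogenome:
    def test_empty_vcf_identity(self):
        ref = {"c": seq_to_arr("ACGT" * 25)}
        pseudo = build_outgroup_pseudogenome(ref, [])
        assert np.array_equal(pseudo["c"], ref["c"])

    def test_three_snps_three_mismatches(self):
        ref = {"c": seq_to_arr("A" * 100)}
        recs = [_rec(p, "A", "G", [1], contig="c") for p in (10, 50, 90)]
        pseudo = build_outgroup_pseudogenome(ref, recs)
        assert int((pseudo["c"] != ref["c"]).sum()) == 3
        assert len(pseudo["c"]) == 100

    def test_indel_skipped_with_warning(self, caplog):
        ref = {"c": seq_to_arr("A" * 10)}
        indel = VariantRecord("c", 2, "A", "AT", np.array([1], dtype=np.int8),
                              "insertion")
        with caplog.at_level("WARNING", logger="kinsig.genome_io"):
            pseudo = build_outgroup_pseudogenome(ref, [indel])
        assert np.array_equal(pseudo["c"], ref["c"])
        assert "indel" in caplog.text


class TestAnnotateDeleterious:
    REF = {"c": seq_to_arr("ATG" + "TCG" * 8 + "TAA" + "ATG" + "GAA" * 8 + "TAA")}
    GENES = [
        GeneModel("plus", "c", 1, 30, "+"),
        GeneModel("minus_like", "c", 31, 60, "+"),
    ]

    def test_stop_gain_from_tcg_to_tag(self):
        # codon 5 of the + strand gene: TCG -> TAG (premature stop)
        pos = 3 * 4 + 2  # 1-based position of the codon's middle base
        rec = _rec(pos, "C", "A", [1, 0, 0], contig="c")
        df = annotate_deleterious([rec], self.GENES, self.REF)
        assert df.loc["plus", "stop_gain"] == 1
        assert df.loc["minus_like", "total"] == 0

    def test_in_frame_deletion_not_frameshift(self):
        rec = VariantRecord("c", 5, "CGTC", "C", np.array([1], dtype=np.int8),
                            "deletion")
        df = annotate_deleterious([rec], self.GENES, self.REF)
        assert df.loc["plus", "frameshift"] == 0

    def test_one_bp_insertion_is_frameshift(self):
        rec = VariantRecord("c", 5, "C", "CT", np.array([1], dtype=np.int8),
                            "insertion")
        df = annotate_deleterious([rec], self.GENES, self.REF)
        assert df.loc["plus", "frameshift"] == 1

    def test_terminal_stop_excluded(self):
        rec = _rec(29, "A", "G", [1], contig="c")  # inside the annotated stop
        df = annotate_deleterious([rec], self.GENES, self.REF)
        assert df.loc["plus", "stop_gain"] == 0

    def test_minus_strand_stop_gain(self):
        # minus-strand gene with CDS = revcomp(genomic) = ATG TCA CCC TAA;
        # genomic pos 8 G->T reads as codon 2 TCA -> TAA on the coding strand
        ref = {"m": seq_to_arr("TTAGGGTGACAT")}
        gene = GeneModel("g", "m", 1, 12, "-")
        assert revcomp(ref["m"]).tobytes() == b"ATGTCACCCTAA"
        df = annotate_deleterious([_rec(8, "G", "T", [1], contig="m")], [gene], ref)
        assert df.loc["g", "stop_gain"] == 1


class TestRoundTrip:
    def test_fixture_round_trip_preserves_pi(self, fixture_dir):
        paths = fixture_dir["paths"]
        sim = fixture_dir["sim"]
        reference = read_fasta(paths["fasta"])
        outgroup = read_fasta(paths["outgroup_fasta"])
        samples, records = read_vcf(paths["vcf"])
        genes = read_gff(paths["gff"], contigs=reference.keys())
        assert samples == sim.alignments[0].strain_ids
        filt = filter_variants(records, min_call_rate=0.0)
        by_id = {g.gene_id: g for g in genes}
        spiked = {"coop_0001", "priv_0002"}
        for aln0 in sim.alignments:
            gene = by_id[aln0.gene_id]
            aln = build_alignment(gene, filt.snps, reference, samples, outgroup)
            assert aln.ref_seq.tobytes() == aln0.ref_seq.tobytes()
            # outgroup row round-trips exactly
            assert aln.outgroup_seq.tobytes() == \
                fixture_dir["outgroup"][aln0.gene_id].tobytes()
            # at fully called sites the matrix matches the in-memory one
            called = aln.seqs != ord("N")
            if aln0.gene_id in spiked:
                continue  # spiked variants intentionally differ
            assert (aln.seqs[called] == aln0.seqs[called]).all()

    def test_round_trip_pi_identity_without_missingness(self, tmp_path):
        from kinsig.synthetic_data import SimulationConfig, simulate_population, write_fixture

        cfg = SimulationConfig(
            population_size=120, sample_size=15, gene_length_bp=300,
            per_site_mutation_rate=5e-5, selection_coefficient=0.0,
            missingness_rate=0.0,
            num_genes_per_class={"cooperative": 2, "private": 2, "background": 0},
            seed=21,
        )
        sim = simulate_population(cfg)
        paths = write_fixture(tmp_path / "fx", sim.alignments, sim.truth,
                              missingness_rate=0.0, seed=1)
        reference = read_fasta(paths["fasta"])
        samples, records = read_vcf(paths["vcf"])
        genes = read_gff(paths["gff"])
        filt = filter_variants(records)
        for aln0 in sim.alignments:
            gene = next(g for g in genes if g.gene_id == aln0.gene_id)
            aln = build_alignment(gene, filt.snps, reference, samples)
            assert nucleotide_diversity(aln) == nucleotide_diversity(aln0)

    def test_record_count_matches_truth(self, fixture_dir):
        _, records = read_vcf(fixture_dir["paths"]["vcf"])
        snps = [r for r in records if r.is_snp]
        indels = [r for r in records if not r.is_snp]
        # 2 spiked stop SNPs on top of the segregating sites; 1 spiked indel
        assert len(snps) == int(fixture_dir["sim"].truth["segregating_sites"].sum()) + 2
        assert len(indels) == 1

    def test_spiked_deleterious_recovered_exactly(self, fixture_dir):
        paths = fixture_dir["paths"]
        reference = read_fasta(paths["fasta"])
        genes = read_gff(paths["gff"])
        _, records = read_vcf(paths["vcf"])
        df = annotate_deleterious(records, genes, reference)
        assert df.loc["coop_0001", "stop_gain"] >= 1
        assert df.loc["priv_0002", "stop_gain"] >= 1
        assert df.loc["coop_0002", "frameshift"] == 1

    def test_gff_unknown_contig_raises(self, fixture_dir):
        with pytest.raises(ValueError, match="unknown contig"):
            read_gff(fixture_dir["paths"]["gff"], contigs=["other"])

    def test_gff_attributes_round_trip(self, fixture_dir):
        genes = read_gff(fixture_dir["paths"]["gff"])
        cats = {g.gene_id: g.category for g in genes}
        truth = fixture_dir["sim"].truth
        assert cats == dict(zip(truth["gene_id"], truth["category"]))
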