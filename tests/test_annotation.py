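import numpy as np
import pytest

from sweepscan.annotation import (
    GeneRecord,
    coding_effect_report,
    distance_null_test,
    filter_by_gene_distance,
    gene_scores,
    nearest_gene,
    read_genes,
    write_genes_bed,
)
from sweepscan.outliers import CandidateLocus
from sweepscan.sweep_stats import ScoreTrack
from conftest import matrix_from_calls
from reference import naive_nearest_gene


def cand(chrom, pos, rank=1, score=1.0, radius=50_000):
    return CandidateLocus(
        rank=rank, chromosome=chrom, focal_position=pos, score=score,
        masked_start=max(1, pos - radius), masked_end=pos + radius,
        statistic_name="G12",
    )


GFF3 = """##gff-version 3
chr1\ttest\tgene\t1000\t5000\t.\t+\t.\tID=geneA
chr1\ttest\tmRNA\t1000\t5000\t.\t+\t.\tID=geneA.t1;Parent=geneA
chr1\ttest\tCDS\t1200\t1399\t.\t+\t0\tID=geneA.c1;Parent=geneA.t1
chr1\ttest\tCDS\t2000\t2099\t.\t+\t0\tID=geneA.c2;Parent=geneA.t1
chr1\ttest\tmRNA\t1000\t4500\t.\t+\t.\tID=geneA.t2;Parent=geneA
chr1\ttest\tCDS\t1200\t1399\t.\t+\t0\tID=geneA.c3;Parent=geneA.t2
chr2\ttest\tgene\t100\t400\t.\t-\t.\tID=geneB
"""


class TestReadGenes:
    def test_bed_coordinate_convention(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t999\t2000\tgeneA\t0\t+\n")
        genes = read_genes(p)
        assert genes[0].start == 1000 and genes[0].end == 2000

    def test_gff3_merges_transcripts_into_one_gene(self, tmp_path):
        p = tmp_path / "genes.gff3"
        p.write_text(GFF3)
        genes = read_genes(p)
        ids = [g.gene_id for g in genes]
        assert ids == ["geneA", "geneB"]
        gene_a = genes[0]
        assert (gene_a.start, gene_a.end) == (1000, 5000)
        assert gene_a.cds_segments == ((1200, 1399), (2000, 2099))
        assert genes[1].strand == "-"

    def test_bed_roundtrip(self, tmp_path):
        genes = [
            GeneRecord("g1", "chr1", 500, 1500, "+"),
            GeneRecord("g2", "chr2", 100, 900, "-"),
        ]
        p = tmp_path / "out.bed"
        write_genes_bed(genes, p)
        assert read_genes(p) == genes

    def test_malformed_bed_reports_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t10\n")
        with pytest.raises(ValueError, match="bad.bed:1"):
            read_genes(p)

    def test_empty_annotation_is_an_error(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("# nothing\n")
        with pytest.raises(ValueError, match="no genes"):
            read_genes(p)


class TestNearestGene:
    GENES = [
        GeneRecord("g1", "chr1", 10_000, 20_000),
        GeneRecord("g2", "chr1", 50_000, 60_000),
        GeneRecord("g3", "chr2", 1_000, 2_000),
    ]

    def test_inside_gene_distance_zero(self):
        gid, d = nearest_gene(cand("chr1", 15_000), self.GENES)
        assert (gid, d) == ("g1", 0)

    def test_downstream_distance(self):
        gid, d = nearest_gene(cand("chr1", 35_000), self.GENES)
        assert (gid, d) == ("g1", 15_000)

    def test_no_gene_on_chromosome(self):
        gid, d = nearest_gene(cand("chrX", 100), self.GENES)
        assert gid is None and np.isinf(d)

    def test_matches_exhaustive_search(self, rng):
        genes = [
            GeneRecord(f"g{i}", f"chr{rng.integers(1, 4)}",
                       int(s), int(s) + int(rng.integers(100, 5000)))
            for i, s in enumerate(rng.integers(1, 1_000_000, size=100))
        ]
        for _ in range(200):
            chrom = f"chr{rng.integers(1, 4)}"
            pos = int(rng.integers(1, 1_000_000))
            assert nearest_gene((chrom, pos), genes) == naive_nearest_gene(
                chrom, pos, genes
            )


class TestDistanceFilter:
    GENES = [GeneRecord("g1", "chr1", 100_000, 110_000)]

    def test_boundary_inclusive_at_max_distance(self):
        kept = filter_by_gene_distance(
            [cand("chr1", 130_000)], self.GENES, max_distance=20_000
        )
        assert len(kept) == 1 and kept[0].gene_distance == 20_000

    def test_just_past_boundary_dropped(self):
        kept = filter_by_gene_distance(
            [cand("chr1", 130_001)], self.GENES, max_distance=20_000
        )
        assert kept == []

    def test_constructed_subset_retained(self, rng):
        genes = [GeneRecord(f"g{i}", "chr1", p, p + 5_000)
                 for i, p in enumerate(range(100_000, 2_000_000, 400_000))]
        near = [cand("chr1", g.start - 10_000, rank=i + 1)
                for i, g in enumerate(genes[:4])]
        far = [cand("chr1", g.start - 150_000, rank=i + 5)
               for i, g in enumerate(genes[:6])]
        kept = filter_by_gene_distance(near + far, genes, max_distance=20_000)
        assert {c.rank for c in kept} == {1, 2, 3, 4}
        assert all(c.gene_id is not None for c in kept)


def flat_track(chrom, positions):
    rng = np.random.default_rng(0)
    return ScoreTrack(
        chromosome=chrom,
        focal_positions=np.asarray(positions),
        values=rng.uniform(size=len(positions)),
        statistic_name="G12",
    )


class TestDistanceNull:
    def test_deterministic_given_seed(self):
        positions = np.arange(1, 2001) * 1_000
        tracks = [flat_track("chr1", positions)]
        genes = [GeneRecord("g1", "chr1", 500_000, 600_000)]
        cands = [cand("chr1", int(p), rank=i + 1, radius=10_000)
                 for i, p in enumerate(positions[::400][:5])]
        r1 = distance_null_test(cands, genes, tracks, n_permutations=100, seed=9)
        r2 = distance_null_test(cands, genes, tracks, n_permutations=100, seed=9)
        assert r1["p_value"] == r2["p_value"]
        assert np.array_equal(r1["null_distances"], r2["null_distances"])

    def test_gene_desert_candidates_are_detected(self):
        # genes tile the left half of the chromosome; candidates sit in
        # the gene desert on the right
        positions = np.arange(1, 4001) * 1_000
        tracks = [flat_track("chr1", positions)]
        genes = [GeneRecord(f"g{i}", "chr1", s, s + 20_000)
                 for i, s in enumerate(range(1, 2_000_000, 50_000))]
        cands = [cand("chr1", 3_200_000 + i * 150_000, rank=i + 1, radius=50_000)
                 for i in range(5)]
        res = distance_null_test(cands, genes, tracks, n_permutations=200, seed=1)
        assert res["observed_median"] > res["null_median"]
        assert res["p_value"] < 0.05

    def test_self_null_is_not_significant(self):
        rng = np.random.default_rng(5)
        positions = np.arange(1, 3001) * 1_000
        tracks = [flat_track("chr1", positions)]
        genes = [GeneRecord(f"g{i}", "chr1", int(s), int(s) + 10_000)
                 for i, s in enumerate(np.sort(rng.choice(2_900_000, 40, replace=False)))]
        # candidates drawn from the null itself
        from sweepscan.annotation import sample_spaced_positions

        draws = sample_spaced_positions(
            rng, {"chr1": positions}, 10, mask_radius_bp=20_000
        )
        cands = [cand(c, p, rank=i + 1, radius=20_000)
                 for i, (c, p) in enumerate(draws)]
        res = distance_null_test(cands, genes, tracks, n_permutations=100, seed=2)
        assert res["p_value"] > 0.01

    def test_bp_uniform_scheme_available_and_deterministic(self):
        positions = np.arange(1, 2001) * 1_000
        tracks = [flat_track("chr1", positions)]
        genes = [GeneRecord("g1", "chr1", 500_000, 600_000)]
        cands = [cand("chr1", int(p), rank=i + 1, radius=10_000)
                 for i, p in enumerate(positions[::400][:5])]
        r1 = distance_null_test(cands, genes, tracks, n_permutations=100,
                                seed=3, scheme="bp")
        r2 = distance_null_test(cands, genes, tracks, n_permutations=100,
                                seed=3, scheme="bp")
        assert r1["p_value"] == r2["p_value"]
        with pytest.raises(ValueError, match="scheme"):
            distance_null_test(cands, genes, tracks, n_permutations=100,
                               seed=3, scheme="nope")

    def test_minimum_permutations_enforced(self):
        with pytest.raises(ValueError):
            distance_null_test([cand("chr1", 5)], [], [], n_permutations=10)


class TestGeneScores:
    def test_max_score_per_gene_and_ranking(self):
        track = ScoreTrack(
            chromosome="chr1",
            focal_positions=np.array([100, 200, 300, 5_000]),
            values=np.array([0.2, 0.9, 0.4, 0.5]),
            statistic_name="G12",
        )
        genes = [
            GeneRecord("inner", "chr1", 50, 400),
            GeneRecord("other", "chr1", 4_900, 5_100),
            GeneRecord("empty", "chr1", 10_000, 11_000),
        ]
        scores = gene_scores([track], genes)
        assert [(s.gene_id, s.max_statistic, s.rank) for s in scores] == [
            ("inner", 0.9, 1), ("other", 0.5, 2),
        ]

    def test_planted_ranking_recovered(self, rng):
        positions = np.arange(1, 2001) * 500
        values = rng.uniform(0, 0.5, size=2000)
        genes = []
        planted = {}
        for i in range(20):
            start = 1 + i * 50_000
            genes.append(GeneRecord(f"g{i:02d}", "chr1", start, start + 10_000))
            in_gene = np.flatnonzero((positions >= start) & (positions <= start + 10_000))
            peak = 0.5 + (20 - i) * 0.02
            values[in_gene[0]] = peak
            planted[f"g{i:02d}"] = i + 1
        track = ScoreTrack("chr1", positions, values, "G12")
        scores = gene_scores([track], genes)
        assert {s.gene_id: s.rank for s in scores} == planted


def make_cds_fixture(strand="+"):
    """Gene with two CDS segments and planted coding variants.

    Reference layout (1-based positions 1..60), CDS = [11, 22] + [31, 36]
    (18 bases, 6 codons).
    """
    ref = "A" * 10 + "ATGCACGGATTCAAGTAG".replace("", "")[:12] + "A" * 8 + "CATCAC" + "A" * 24
    # positions 11-22: ATGCACGGATTC ; positions 31-36: CATCAC
    gene = GeneRecord(
        "geneX", "chr1", 5, 40, strand=strand,
        cds_segments=((11, 22), (31, 36)),
    )
    return ref, gene


class TestCodingEffects:
    def test_third_position_his_codon_synonymous(self):
        # CDS codon 2 is CAC (histidine, positions 14-16); C->T at the
        # third position gives CAT, still histidine
        ref, gene = make_cds_fixture()
        m = matrix_from_calls(
            np.array([[0], [1]], dtype=np.int8), positions=[16]
        )
        m.ref_alleles[0], m.alt_alleles[0] = "C", "T"
        report = coding_effect_report(gene, m, ref)
        assert report[0]["classification"] == "synonymous"
        assert report[0]["codon_number"] == 2
        assert report[0]["ref_aa"] == "H" and report[0]["alt_aa"] == "H"

    def test_first_position_change_nonsynonymous(self):
        # codon 1 ATG -> CTG (M -> L)
        ref, gene = make_cds_fixture()
        m = matrix_from_calls(np.array([[1]], dtype=np.int8), positions=[11])
        m.ref_alleles[0], m.alt_alleles[0] = "A", "C"
        report = coding_effect_report(gene, m, ref)
        assert report[0]["classification"] == "nonsynonymous"
        assert report[0]["ref_aa"] == "M" and report[0]["alt_aa"] == "L"

    def test_between_cds_segments_is_intronic(self):
        ref, gene = make_cds_fixture()
        m = matrix_from_calls(np.array([[1]], dtype=np.int8), positions=[25])
        m.ref_alleles[0], m.alt_alleles[0] = "A", "G"
        report = coding_effect_report(gene, m, ref)
        assert report[0]["classification"] == "intronic"
        assert report[0]["codon_number"] is None

    def test_minus_strand_equals_reverse_complement_construction(self):
        # classifying on the minus strand must match classifying the
        # reverse-complemented plus-strand construction
        from Bio.Seq import Seq

        rng = np.random.default_rng(12)
        bases = np.array(list("ACGT"))
        core = "".join(rng.choice(bases, size=30))
        ref_plus = "AAAAA" + core + "AAAAA"
        # 30-base CDS on the plus strand at positions 6..35
        gene_plus = GeneRecord("gp", "chr1", 1, 40, "+", ((6, 35),))
        ref_minus = str(Seq(ref_plus).reverse_complement())
        gene_minus = GeneRecord("gm", "chr1", 1, 40, "-", ((6, 35),))
        for pos in (7, 14, 23, 31):
            ref_base = ref_plus[pos - 1]
            alt_base = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref_base]
            m_plus = matrix_from_calls(np.array([[1]], dtype=np.int8), positions=[pos])
            m_plus.ref_alleles[0], m_plus.alt_alleles[0] = ref_base, alt_base
            rep_plus = coding_effect_report(gene_plus, m_plus, ref_plus)
            mirror_pos = len(ref_plus) - pos + 1
            mref = ref_minus[mirror_pos - 1]
            malt = str(Seq(alt_base).reverse_complement())
            m_minus = matrix_from_calls(
                np.array([[1]], dtype=np.int8), positions=[mirror_pos]
            )
            m_minus.ref_alleles[0], m_minus.alt_alleles[0] = mref, malt
            rep_minus = coding_effect_report(gene_minus, m_minus, ref_minus)
            assert rep_plus[0]["classification"] == rep_minus[0]["classification"]
            assert rep_plus[0]["ref_aa"] == rep_minus[0]["ref_aa"]
            assert rep_plus[0]["alt_aa"] == rep_minus[0]["alt_aa"]

    def test_reference_mismatch_raises(self):
        ref, gene = make_cds_fixture()
        m = matrix_from_calls(np.array([[1]], dtype=np.int8), positions=[16])
        m.ref_alleles[0], m.alt_alleles[0] = "G", "T"  # reference has C
        with pytest.raises(ValueError, match="!= reference"):
            coding_effect_report(gene, m, ref)

    def test_cds_length_must_be_codon_multiple(self):
        gene = GeneRecord("bad", "chr1", 1, 50, "+", ((10, 20),))  # 11 bases
        m = matrix_from_calls(np.array([[1]], dtype=np.int8), positions=[15])
        with pytest.raises(ValueError, match="divisible by 3"):
            coding_effect_report(gene, m, "A" * 50)
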