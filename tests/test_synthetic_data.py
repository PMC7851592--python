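import numpy as np
import pytest

from sweepscan.genotype_io import read_vcf
from sweepscan.sweep_stats import g12_scan, h_scan
from sweepscan.synthetic_data import (
    SimulationConfig,
    SweepSpec,
    TwoPopConfig,
    make_category_fixture,
    make_gene_fixture,
    simulate_neutral,
    simulate_two_pops,
    write_vcf,
)
from sweepscan.differentiation import wc_fst_per_snp


class TestDeterminism:
    def test_identical_config_gives_bit_identical_cohorts(self):
        cfg = SimulationConfig(
            n_individuals=12, n_snps=800, seed=21,
            sweeps=(SweepSpec("chr1", 400, 101, 0.5),),
        )
        a = simulate_neutral(cfg)
        b = simulate_neutral(cfg)
        assert a.matrix == b.matrix
        assert a.truth == b.truth

    def test_two_pop_determinism(self):
        cfg = SimulationConfig(
            n_individuals=10, n_snps=600, seed=8,
            two_pop=TwoPopConfig(drift=0.3, n_individuals_b=6),
        )
        a = simulate_two_pops(cfg)
        b = simulate_two_pops(cfg)
        assert a.matrices[0] == b.matrices[0]
        assert a.matrices[1] == b.matrices[1]

    def test_different_seeds_differ(self):
        cfg1 = SimulationConfig(n_individuals=8, n_snps=500, seed=1)
        cfg2 = SimulationConfig(n_individuals=8, n_snps=500, seed=2)
        assert simulate_neutral(cfg1).matrix != simulate_neutral(cfg2).matrix

    def test_vcf_writing_is_deterministic(self, tmp_path):
        cfg = SimulationConfig(n_individuals=6, n_snps=300, seed=3)
        p1, p2 = tmp_path / "a.vcf", tmp_path / "b.vcf"
        write_vcf(simulate_neutral(cfg).matrix, p1)
        write_vcf(simulate_neutral(cfg).matrix, p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestDegenerateLimits:
    def test_single_founder_no_switching_all_identical(self):
        cfg = SimulationConfig(
            n_individuals=8, n_snps=200, founder_pool_size=1,
            switch_probability=0.0, seed=5,
        )
        cohort = simulate_neutral(cfg)
        g = g12_scan(cohort.matrix, window_snps=51)[0]
        h = h_scan(cohort.matrix)[0]
        assert np.all(g.values == 1.0)
        assert np.all(h.values == 200.0)

    def test_many_founders_no_switching_near_singleton_floor(self):
        n = 12
        cfg = SimulationConfig(
            n_individuals=n, n_snps=400, founder_pool_size=2 * n,
            switch_probability=0.0, seed=6,
        )
        cohort = simulate_neutral(cfg)
        g = g12_scan(cohort.matrix, window_snps=101)[0]
        floor = (n + 2) / n**2
        assert np.median(g.values) < 2.5 * floor

    def test_default_config_baseline_properties(self):
        cfg = SimulationConfig(seed=13)
        cohort = simulate_neutral(cfg)
        g = g12_scan(cohort.matrix)[0]
        assert np.median(g.values) < 0.2
        assert g.values.max() < 1.0


class TestSweepInjection:
    def test_truth_table_records_every_sweep(self):
        sweeps = (
            SweepSpec("chr1", 300, 101, 0.5),
            SweepSpec("chr2", 700, 151, 0.4, n_sweep_haplotypes=3),
        )
        cfg = SimulationConfig(
            n_individuals=10, n_snps=1000, n_chromosomes=2, seed=7, sweeps=sweeps
        )
        cohort = simulate_neutral(cfg)
        assert len(cohort.truth) == 2
        for spec, t in zip(sweeps, cohort.truth):
            assert t["chromosome"] == spec.chromosome
            assert t["span_snps"] == spec.span_snps
            assert t["n_sweep_haplotypes"] == spec.n_sweep_haplotypes
            assert len(t["carrier_haplotypes"]) == int(
                np.ceil(spec.carrier_frequency * 20)
            )

    def test_hard_sweep_carrier_class_size(self):
        cfg = SimulationConfig(
            n_individuals=29, n_snps=1500, seed=10,
            sweeps=(SweepSpec("chr1", 750, 201, 11 / 29, whole_individuals=True),),
        )
        cohort = simulate_neutral(cfg)
        t = cohort.truth[0]
        lo = t["center_index"] - 100
        window = cohort.matrix.calls[:, lo : lo + 201]
        rows = [tuple(r) for r in window]
        counts = sorted((rows.count(q) for q in set(rows)), reverse=True)
        assert counts[0] == 11

    def test_soft_sweep_has_multiple_frequent_classes(self):
        cfg = SimulationConfig(
            n_individuals=24, n_snps=1500, seed=11,
            sweeps=(
                SweepSpec("chr1", 750, 201, 0.75, n_sweep_haplotypes=3,
                          whole_individuals=True),
            ),
        )
        cohort = simulate_neutral(cfg)
        t = cohort.truth[0]
        lo = t["center_index"] - 100
        window = cohort.matrix.calls[:, lo : lo + 201]
        rows = [tuple(r) for r in window]
        counts = sorted((rows.count(q) for q in set(rows)), reverse=True)
        assert sum(1 for c in counts if c >= 3) >= 3

    def test_singleton_carrier_indistinguishable_from_neutral(self):
        base = SimulationConfig(n_individuals=10, n_snps=800, seed=12)
        neutral = simulate_neutral(base)
        swept = simulate_neutral(
            SimulationConfig(
                n_individuals=10, n_snps=800, seed=12,
                sweeps=(SweepSpec("chr1", 400, 101, 1 / 20),),
            )
        )
        g_neutral = g12_scan(neutral.matrix, 101)[0].values
        g_swept = g12_scan(swept.matrix, 101)[0].values
        # one replaced haplotype cannot create a shared genotype class
        assert g_swept.max() <= g_neutral.max() + 0.05

    def test_span_exceeding_chromosome_rejected(self):
        cfg = SimulationConfig(
            n_individuals=5, n_snps=100, seed=1,
            sweeps=(SweepSpec("chr1", 50, 301, 0.5),),
        )
        with pytest.raises(ValueError, match="span exceeds"):
            simulate_neutral(cfg)


class TestTwoPopulations:
    def test_zero_drift_gives_near_zero_fst(self):
        cfg = SimulationConfig(
            n_individuals=15, n_snps=2000, seed=14,
            two_pop=TwoPopConfig(drift=0.0, n_individuals_b=15),
        )
        cohort = simulate_two_pops(cfg)
        fst = wc_fst_per_snp(*cohort.matrices)["fst"]
        assert abs(np.nanmean(fst)) < 0.02

    def test_drift_elevates_baseline_fst(self):
        means = {}
        for drift in (0.05, 0.8):
            cfg = SimulationConfig(
                n_individuals=15, n_snps=2000, seed=15,
                two_pop=TwoPopConfig(drift=drift, n_individuals_b=15),
            )
            cohort = simulate_two_pops(cfg)
            means[drift] = float(np.nanmean(wc_fst_per_snp(*cohort.matrices)["fst"]))
        assert means[0.8] > means[0.05] + 0.02

    def test_population_b_size_and_sweep_targeting(self):
        cfg = SimulationConfig(
            n_individuals=20, n_snps=1000, seed=16,
            two_pop=TwoPopConfig(drift=0.2, n_individuals_b=9),
            sweeps=(SweepSpec("chr1", 500, 101, 0.6, population=1),),
        )
        cohort = simulate_two_pops(cfg)
        assert cohort.matrices[1].n_samples == 9
        assert cohort.truth[0]["population"] == 1


class TestFixtures:
    def test_gene_fixture_deterministic_and_clustered(self):
        spec = [{"chromosome": "chr1", "start": 500_000, "n": 3,
                 "spacing_bp": 8_000, "prefix": "CYP"}]
        g1, _ = make_gene_fixture(20, {"chr1": 2_000_000}, cluster_spec=spec, seed=4)
        g2, _ = make_gene_fixture(20, {"chr1": 2_000_000}, cluster_spec=spec, seed=4)
        assert g1 == g2
        cyps = [g for g in g1 if g.gene_id.startswith("CYP")]
        assert len(cyps) == 3
        assert cyps[1].start - cyps[0].start == 8_000

    def test_gene_fixture_cds_and_sequence(self):
        genes, seqs = make_gene_fixture(5, {"chr1": 200_000}, seed=2, cds=True)
        assert set(seqs) == {"chr1"} and len(seqs["chr1"]) == 200_000
        for g in genes:
            assert g.cds_length % 3 == 0

    def test_category_fixture_deterministic(self):
        genes, _ = make_gene_fixture(30, {"chr1": 3_000_000}, seed=1)
        c1 = make_category_fixture(genes, 5, seed=9)
        c2 = make_category_fixture(genes, 5, seed=9)
        assert c1.category_to_genes == c2.category_to_genes
        forced = make_category_fixture(
            genes, 2, seed=9,
            forced_assignments={"GO:CLUSTER": [genes[0].gene_id, genes[1].gene_id]},
        )
        assert genes[0].gene_id in forced.category_to_genes["GO:CLUSTER"]

    def test_vcf_roundtrip_identity(self, tmp_path):
        cfg = SimulationConfig(n_individuals=7, n_snps=400, n_chromosomes=2, seed=19)
        cohort = simulate_neutral(cfg)
        p = tmp_path / "cohort.vcf"
        write_vcf(cohort.matrix, p)
        assert read_vcf(p) == cohort.matrix


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_individuals=0),
            dict(switch_probability=1.5),
            dict(mean_spacing_bp=0),
        ],
    )
    def test_bad_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_bad_sweep_rejected(self):
        with pytest.raises(ValueError):
            SweepSpec("chr1", 10, 5, 0.0)
        with pytest.raises(ValueError):
            SweepSpec("chr1", 10, 5, 0.5, n_sweep_haplotypes=0)

    def test_two_pop_requires_config(self):
        with pytest.raises(ValueError):
            simulate_two_pops(SimulationConfig(n_individuals=5, n_snps=100))

    def test_neutral_no_systematic_peak(self):
        # across seeds the argmax should wander, not stick to one locus
        peaks = []
        for seed in range(8):
            cfg = SimulationConfig(n_individuals=10, n_snps=1500, seed=seed)
            h = h_scan(simulate_neutral(cfg).matrix)[0]
            peaks.append(int(np.argmax(h.values)))
        assert len(set(p // 300 for p in peaks)) >= 3
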