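import numpy as np
import pytest

from mendelprior.enrichment import (
    EnrichmentConfig,
    EnrichmentEngine,
    Genome,
    PlacementSampler,
    empirical_pvalues,
    observed_statistic,
    placement_segments,
    relocate_interval,
    run_enrichment,
)
from mendelprior.errors import DataError, ValidationError
from mendelprior.intervals import GenomicInterval
from mendelprior.ontology import GeneSetAnnotation
from mendelprior.overlap import GeneRegion


def annotation(term_to_genes, background=None):
    if background is None:
        background = set().union(*term_to_genes.values()) if term_to_genes else set()
    return GeneSetAnnotation(
        ontology_label="X",
        term_to_genes={t: frozenset(g) for t, g in term_to_genes.items()},
        genome_background=frozenset(background),
    )


def region(gid, start, end, chrom="1"):
    return GeneRegion(gene_id=gid, chrom=chrom, region_start=start, region_end=end)


class TestObservedStatistic:
    def test_gene_vs_interval_mode(self):
        ann = annotation({"T": {"g1", "g2", "g3"}})
        sets = [{"g1", "g2"}, {"g3"}]
        assert observed_statistic(sets, ann, "T", "gene") == 3
        assert observed_statistic(sets, ann, "T", "interval") == 2

    def test_no_annotated_genes(self):
        ann = annotation({"T": {"g9"}}, background={"g9", "g1", "g2"})
        assert observed_statistic([{"g1"}, {"g2"}], ann, "T", "gene") == 0
        assert observed_statistic([{"g1"}, {"g2"}], ann, "T", "interval") == 0

    def test_shared_gene_counted_once_in_gene_mode(self):
        ann = annotation({"T": {"g1"}})
        assert observed_statistic([{"g1"}, {"g1"}], ann, "T", "gene") == 1
        assert observed_statistic([{"g1"}, {"g1"}], ann, "T", "interval") == 2

    def test_unknown_term_errors(self):
        with pytest.raises(DataError):
            observed_statistic([{"g1"}], annotation({"T": {"g1"}}), "NOPE", "gene")

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_nested_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(30)]
        terms = {
            f"T{t}": {genes[int(i)] for i in rng.choice(30, 6, replace=False)}
            for t in range(5)
        }
        ann = annotation(terms, background=genes)
        sets = [
            {genes[int(i)] for i in rng.choice(30, rng.integers(0, 8), replace=False)}
            for _ in range(6)
        ]
        for tid, members in terms.items():
            gene_oracle = len({g for s in sets for g in s if g in members})
            iv_oracle = sum(1 for s in sets if any(g in members for g in s))
            assert observed_statistic(sets, ann, tid, "gene") == gene_oracle
            assert observed_statistic(sets, ann, tid, "interval") == iv_oracle
            # with no gene shared between intervals, each counted interval
            # contributes >= 1 distinct gene
            if sum(len(s) for s in sets) == len(set().union(*sets) if sets else set()):
                assert gene_oracle >= iv_oracle


def toy_genome(gene_spans, size=20_000, chrom="1"):
    regions = [region(f"g{i}", s, e, chrom=chrom) for i, (s, e) in enumerate(gene_spans)]
    return Genome(chrom_sizes={chrom: size}, regions=regions)


class TestPlacementSegments:
    @pytest.mark.parametrize("seed", range(10))
    def test_segments_match_per_position_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        spans = []
        for _ in range(6):
            s = int(rng.integers(1, 1_800))
            spans.append((s, s + int(rng.integers(10, 300))))
        genome = toy_genome(spans, size=2_000)
        length = int(rng.integers(50, 400))
        k = int(rng.integers(0, 4))
        segs = placement_segments(
            length, genome.chrom_sizes, genome.clusters_by_chrom(), k, k
        )
        got = set()
        for _, start, seg_len in segs:
            got.update(range(start, start + seg_len))
        brute = set()
        for s in range(1, 2_000 - length + 2):
            e = s + length - 1
            count = sum(
                1 for c in genome.clusters if c.span_start <= e and c.span_end >= s
            )
            if count == k:
                brute.add(s)
        assert got == brute


class TestRelocateInterval:
    def test_forced_placement_keeps_cluster_count(self):
        genome = toy_genome([(1_000, 1_500), (1_600, 2_100), (2_200, 2_700)],
                            size=100_000)
        iv = GenomicInterval("1", 900, 2_800, label="x")  # covers all 3 clusters
        rng = np.random.default_rng(0)
        for _ in range(20):
            new = relocate_interval(iv, genome, rng)
            assert new.length == iv.length
            assert genome.cluster_count(new) == 3

    def test_k0_interval_lands_in_gene_deserts(self):
        genome = toy_genome([(10_000, 12_000)], size=50_000)
        iv = GenomicInterval("1", 30_000, 30_999, label="desert")
        rng = np.random.default_rng(1)
        for _ in range(50):
            new = relocate_interval(iv, genome, rng)
            assert genome.cluster_count(new) == 0

    def test_tolerance_auto_relaxes_when_exact_match_impossible(self):
        # single cluster; a k=1 interval longer than any k=1 placement window
        genome = toy_genome([(50, 60)], size=200)
        iv = GenomicInterval("1", 1, 200, label="whole")
        rng = np.random.default_rng(2)
        new = relocate_interval(iv, genome, rng)  # every placement has k=1; fine
        assert new.length == 200

    def test_impossible_relocation_errors(self):
        genome = Genome(chrom_sizes={"1": 100}, regions=[])
        iv = GenomicInterval("1", 1, 150, label="toolong")
        # interval longer than every chromosome: no placement at any tolerance
        with pytest.raises(DataError, match="toolong"):
            relocate_interval(iv, genome, np.random.default_rng(0))

    def test_uniform_over_valid_positions_chi_square(self):
        from scipy import stats

        genome = toy_genome([(60, 90), (140, 160)], size=200)
        iv = GenomicInterval("1", 50, 99, label="x")
        k = genome.cluster_count(iv)
        sampler = PlacementSampler(iv.length, k, genome)
        valid = sampler.valid_positions()
        assert len(valid) > 1
        rng = np.random.default_rng(7)
        codes, starts = sampler.sample(20_000, rng)
        counts = {pos: 0 for _, pos in valid}
        for s in starts:
            counts[int(s)] += 1
        observed = np.array(list(counts.values()))
        res = stats.chisquare(observed)
        assert res.pvalue > 1e-3


def simple_setup(seed=0, n_terms=5, n_genes=30, n_intervals=4):
    rng = np.random.default_rng(seed)
    spans = []
    pos = 1_000
    for _ in range(n_genes):
        length = int(rng.integers(500, 2_000))
        spans.append((pos, pos + length))
        pos += length + int(rng.integers(2_000, 6_000))
    genome = toy_genome(spans, size=pos + 10_000)
    genes = [f"g{i}" for i in range(n_genes)]
    terms = {
        f"T{t}": {genes[int(i)] for i in rng.choice(n_genes, 5, replace=False)}
        for t in range(n_terms)
    }
    ann = annotation(terms, background=genes)
    intervals = []
    for j in range(n_intervals):
        s = int(rng.integers(1, genome.chrom_sizes["1"] - 5_000))
        intervals.append(GenomicInterval("1", s, s + 4_999, label=f"iv{j}"))
    return intervals, ann, genome


class TestEmpiricalPvalues:
    def test_config_validation(self):
        with pytest.raises(ValidationError):
            EnrichmentConfig(n_perm=0)
        with pytest.raises(ValidationError):
            EnrichmentConfig(n_boot=0)
        with pytest.raises(ValidationError):
            EnrichmentConfig(mode="banana")

    def test_p_range_and_observed_zero_gives_p1(self):
        intervals, ann, genome = simple_setup(seed=3)
        cfg = EnrichmentConfig(n_perm=99, n_boot=10, seed=1)
        first = empirical_pvalues(intervals, ann, genome, cfg)
        for tid in first.term_ids:
            p = first.pvalues[tid]
            assert 1 / 100 <= p <= 1.0
            if first.observed[tid] == 0:
                assert p == 1.0

    def test_term_size_bounds_exclude_terms(self):
        intervals, ann, genome = simple_setup()
        cfg = EnrichmentConfig(n_perm=19, n_boot=5, seed=1, min_term_size=6)
        first = empirical_pvalues(intervals, ann, genome, cfg)
        assert first.term_ids == []  # all terms have 5 genes

    def test_deterministic_given_seed(self):
        intervals, ann, genome = simple_setup(seed=4)
        cfg = EnrichmentConfig(n_perm=200, n_boot=50, seed=9)
        a = run_enrichment(intervals, ann, genome, cfg)
        b = run_enrichment(intervals, ann, genome, cfg)
        assert [(r.term_id, r.empirical_p, r.corrected_p) for r in a] == [
            (r.term_id, r.empirical_p, r.corrected_p) for r in b
        ]

    def test_observed_matches_simple_statistic(self):
        from mendelprior.overlap import interval_gene_sets

        intervals, ann, genome = simple_setup(seed=5)
        sets = interval_gene_sets(intervals, genome.regions)
        for mode in ("gene", "interval"):
            cfg = EnrichmentConfig(mode=mode, n_perm=9, n_boot=2, seed=1)
            first = empirical_pvalues(intervals, ann, genome, cfg)
            for tid in first.term_ids:
                assert first.observed[tid] == observed_statistic(sets, ann, tid, mode)

    def test_gene_mode_observed_ge_interval_mode_when_genes_unshared(self):
        from mendelprior.overlap import interval_gene_sets

        for seed in range(5):
            intervals, ann, genome = simple_setup(seed=seed)
            sets = interval_gene_sets(intervals, genome.regions)
            if sum(len(s) for s in sets) != len(set().union(*sets)):
                continue  # shared genes void the comparison
            g = empirical_pvalues(
                intervals, ann, genome, EnrichmentConfig(mode="gene", n_perm=9,
                                                         n_boot=2, seed=1)
            )
            i = empirical_pvalues(
                intervals, ann, genome, EnrichmentConfig(mode="interval", n_perm=9,
                                                         n_boot=2, seed=1)
            )
            for tid in g.term_ids:
                assert g.observed[tid] >= i.observed[tid]


class TestCorrectedPvalues:
    def test_single_term_corrected_close_to_empirical(self):
        rng = np.random.default_rng(11)
        spans = []
        pos = 500
        for _ in range(12):
            spans.append((pos, pos + 800))
            pos += 4_000
        genome = toy_genome(spans, size=pos + 5_000)
        ann = annotation({"T0": {f"g{i}" for i in range(4)}},
                         background=[f"g{i}" for i in range(12)])
        intervals = [GenomicInterval("1", 400, 2_400, label="a"),
                     GenomicInterval("1", 9_000, 11_000, label="b")]
        cfg = EnrichmentConfig(n_perm=2_000, n_boot=2_000, seed=5)
        (res,) = run_enrichment(intervals, ann, genome, cfg)
        se = np.sqrt(res.empirical_p * (1 - res.empirical_p) / cfg.n_boot)
        assert abs(res.corrected_p - res.empirical_p) <= 4 * se + 2 / cfg.n_boot

    def test_empirical_p_one_gives_corrected_one(self):
        intervals, ann, genome = simple_setup(seed=6)
        cfg = EnrichmentConfig(n_perm=99, n_boot=49, seed=2)
        results = run_enrichment(intervals, ann, genome, cfg)
        for r in results:
            assert 0 < r.corrected_p <= 1
            if r.empirical_p == 1.0:
                assert r.corrected_p == 1.0

    def test_multiplicity_makes_corrected_dominate_empirical(self):
        intervals, ann, genome = simple_setup(seed=7, n_terms=10)
        cfg = EnrichmentConfig(n_perm=300, n_boot=300, seed=3)
        results = run_enrichment(intervals, ann, genome, cfg)
        # stochastic dominance on a 10-term null: corrected at least as large
        # on average
        emp = np.array([r.empirical_p for r in results])
        corr = np.array([r.corrected_p for r in results])
        assert corr.mean() >= emp.mean()


class TestRunEnrichment:
    def test_sorted_by_p_then_gene_count_then_id(self):
        intervals, ann, genome = simple_setup(seed=8, n_terms=8)
        cfg = EnrichmentConfig(n_perm=150, n_boot=30, seed=4)
        results = run_enrichment(intervals, ann, genome, cfg)
        keys = [(r.empirical_p, -r.n_genes_in_intervals, r.term_id) for r in results]
        assert keys == sorted(keys)

    def test_gene_ratio_definition(self):
        intervals, ann, genome = simple_setup(seed=9)
        cfg = EnrichmentConfig(n_perm=19, n_boot=5, seed=1)
        for r in run_enrichment(intervals, ann, genome, cfg):
            assert r.gene_ratio == pytest.approx(
                r.n_genes_in_intervals / r.n_genome_annotated
            )

    def test_empty_annotation_returns_empty_with_warning(self):
        from mendelprior.runlog import RunLog

        intervals, _, genome = simple_setup()
        log = RunLog()
        ann = annotation({}, background={"g0"})
        out = run_enrichment(intervals, ann, genome,
                             EnrichmentConfig(n_perm=9, n_boot=2, seed=1), log=log)
        assert out == []
        assert log.counters["empty_annotations"] == 1

    def test_root_terms_excluded_by_default(self):
        intervals, ann, genome = simple_setup(seed=10)
        rooted = GeneSetAnnotation(
            ontology_label="X",
            term_to_genes=dict(ann.term_to_genes) | {
                "ROOT": frozenset(ann.genome_background)
            },
            genome_background=ann.genome_background,
            root_ids=frozenset({"ROOT"}),
        )
        cfg = EnrichmentConfig(n_perm=9, n_boot=2, seed=1, max_term_size=2_000)
        results = run_enrichment(intervals, rooted, genome, cfg)
        assert all(r.term_id != "ROOT" for r in results)


class TestExactNullAgreement:
    def test_mc_p_matches_exhaustive_enumeration(self):
        """Fully enumerable toy genome: joint placement distribution is a
        product over per-interval gene-coverage signatures."""
        spans = [(1 + 6_000 * i, 2_000 + 6_000 * i) for i in range(10)]
        genome = toy_genome(spans, size=62_000)
        genes = [f"g{i}" for i in range(10)]
        ann = annotation(
            {"TA": {"g0", "g1", "g2"}, "TB": {"g3", "g7"},
             "TC": {"g4", "g5", "g6", "g9"}},
            background=genes,
        )
        intervals = [
            GenomicInterval("1", 500, 5_499, label="a"),
            GenomicInterval("1", 24_000, 28_999, label="b"),
        ]
        r1 = 2_000
        cfg = EnrichmentConfig(n_perm=r1, n_boot=10, seed=13)
        first = empirical_pvalues(intervals, ann, genome, cfg)

        # oracle: per-interval signature distribution by per-position scan
        def signatures(iv):
            k = genome.cluster_count(iv)
            sig_weight = {}
            size = genome.chrom_sizes["1"]
            for s in range(1, size - iv.length + 2):
                e = s + iv.length - 1
                covered = frozenset(
                    r.gene_id for r in genome.regions
                    if r.region_start <= e and r.region_end >= s
                )
                if len([c for c in genome.clusters
                        if c.span_start <= e and c.span_end >= s]) == k:
                    sig_weight[covered] = sig_weight.get(covered, 0) + 1
            return sig_weight

        sig_a = signatures(intervals[0])
        sig_b = signatures(intervals[1])
        total = sum(sig_a.values()) * sum(sig_b.values())
        for tid in first.term_ids:
            members = ann.term_to_genes[tid]
            obs = first.observed[tid]
            mass = 0
            for ga, wa in sig_a.items():
                for gb, wb in sig_b.items():
                    stat = len((ga | gb) & members)
                    if stat >= obs:
                        mass += wa * wb
            p_exact = mass / total
            expected = (1 + r1 * p_exact) / (r1 + 1)
            tol = 3 * np.sqrt(p_exact * (1 - p_exact) / r1) + 1e-12
            assert abs(first.pvalues[tid] - expected) <= tol, tid
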