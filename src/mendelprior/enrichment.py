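"""Interval-permutation enrichment of term -> gene sets.

The null relocates every test interval, keeping its exact bp length and
matching the number of background gene clusters it covers (the dominant
genomic confounders for gene-set statistics), by sampling uniformly over all
placements genome-wide whose cluster count lies within the configured
tolerance. Empirical p-values use the (1 + exceedances) / (1 + replicates)
estimator; family-wise correction bootstraps the minimum p across terms
against the first-level null.

Placement sampling is exact, not rejection-based: the cluster count covered
by a placement is piecewise-constant in the start coordinate, so the set of
valid placements decomposes into integer segments that are enumerated once
per interval length and sampled by weighted index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import DataError, ValidationError
from .intervals import GenomicInterval
from .ontology import GeneSetAnnotation
from .overlap import GeneRegion, collapse_genes, interval_gene_sets
from .runlog import RunLog

MODES = ("gene", "interval")


@dataclass
class EnrichmentConfig:
    mode: str = "gene"
    n_perm: int = 5000
    n_boot: int = 1000
    alpha_report: float = 0.05
    seed: int = 0
    min_term_size: int = 2
    max_term_size: int = 2000
    match_tolerance: int = 0
    exclude_root: bool = True

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}", code="bad_mode")
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1", code="bad_config")
        if self.n_boot < 1:
            raise ValidationError("n_boot must be >= 1", code="bad_config")
        if self.min_term_size < 1 or self.max_term_size < self.min_term_size:
            raise ValidationError("invalid term-size bounds", code="bad_config")
        if self.match_tolerance < 0:
            raise ValidationError("match_tolerance must be >= 0", code="bad_config")


@dataclass
class Genome:
    """Background geometry for relocation: chromosome sizes plus the regions
    of all background (Mendelian) genes; clusters are derived once."""

    chrom_sizes: dict  # chrom -> size bp
    regions: list  # of GeneRegion (background genes only)
    clusters: list = field(default_factory=list)

    def __post_init__(self):
        if not self.clusters:
            self.clusters = collapse_genes(self.regions)
        self._clusters_by_chrom: dict[str, list] = {}
        for c in self.clusters:
            self._clusters_by_chrom.setdefault(c.chrom, []).append(c)

    def clusters_by_chrom(self) -> dict:
        return self._clusters_by_chrom

    def cluster_count(self, interval: GenomicInterval) -> int:
        return sum(
            1
            for c in self._clusters_by_chrom.get(interval.chrom, ())
            if c.span_start <= interval.end and c.span_end >= interval.start
        )


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    observed: int
    n_genes_in_intervals: int
    n_genome_annotated: int
    gene_ratio: float
    empirical_p: float
    corrected_p: float
    overlap_genes: list


def observed_statistic(
    interval_gene_sets_: Sequence[set],
    annotation: GeneSetAnnotation,
    term_id: str,
    mode: str,
) -> int:
    """Gene mode: distinct annotated genes across all intervals.
    Interval mode: intervals containing at least one annotated gene."""
    if mode not in MODES:
        raise ValidationError(f"mode must be one of {MODES}", code="bad_mode")
    if term_id not in annotation.term_to_genes:
        raise DataError(f"term {term_id} not in annotation", code="unknown_term")
    members = annotation.term_to_genes[term_id]
    if mode == "gene":
        hit: set = set()
        for genes in interval_gene_sets_:
            hit |= genes & members
        return len(hit)
    return sum(1 for genes in interval_gene_sets_ if genes & members)


# ---------------------------------------------------------------------------
# placement segments

def placement_segments(
    length: int,
    chrom_sizes: Mapping[str, int],
    clusters_by_chrom: Mapping[str, list],
    k_min: int,
    k_max: int,
) -> list:
    """Maximal segments of start positions where an interval of the given
    length covers between k_min and k_max gene clusters (inclusive).

    Returns (chrom, seg_start, seg_len) triples. The cluster count of a
    placement [s, s+L-1] is piecewise-constant in s with breakpoints at
    cluster entry/exit, so a sorted event sweep enumerates it exactly.
    """
    segments = []
    for chrom, size in chrom_sizes.items():
        n_pos = size - length + 1
        if n_pos < 1:
            continue
        events: list[tuple[int, int]] = []
        for c in clusters_by_chrom.get(chrom, ()):
            a = max(1, c.span_start - length + 1)
            b = min(c.span_end, n_pos)
            if a <= b:
                events.append((a, 1))
                events.append((b + 1, -1))
        events.sort()
        count = 0
        pos = 1
        i = 0
        while pos <= n_pos:
            while i < len(events) and events[i][0] <= pos:
                count += events[i][1]
                i += 1
            nxt = events[i][0] if i < len(events) else n_pos + 1
            seg_end = min(nxt - 1, n_pos)
            if k_min <= count <= k_max:
                segments.append((chrom, pos, seg_end - pos + 1))
            pos = seg_end + 1
    return segments


class PlacementSampler:
    """Uniform sampler over the valid placements of one interval length."""

    def __init__(
        self,
        length: int,
        k: int,
        genome: Genome,
        tolerance: int = 0,
        log: RunLog | None = None,
        context: str = "",
    ):
        log = log if log is not None else RunLog()
        self.length = length
        self.k = k
        max_k = len(genome.clusters)
        tol = tolerance
        segments: list = []
        while True:
            segments = placement_segments(
                length,
                genome.chrom_sizes,
                genome.clusters_by_chrom(),
                max(0, k - tol),
                k + tol,
            )
            if segments:
                break
            if max(0, k - tol) == 0 and k + tol >= max_k:
                raise DataError(
                    f"no valid relocation for interval {context or '?'} "
                    f"(length {length}, cluster count {k}) at any tolerance",
                    code="no_valid_placement",
                )
            tol += 1
            log.note(
                f"relocation tolerance for {context or 'interval'} "
                f"(length {length}, k={k}) relaxed to +/-{tol}"
            )
        self.tolerance = tol
        self.chroms = [s[0] for s in segments]
        self.seg_start = np.array([s[1] for s in segments], dtype=np.int64)
        seg_len = np.array([s[2] for s in segments], dtype=np.int64)
        self.cum = np.cumsum(seg_len)
        self.total = int(self.cum[-1])
        uniq = sorted(set(self.chroms))
        self._chrom_code = {c: i for i, c in enumerate(uniq)}
        self.chrom_names = uniq
        self.seg_chrom = np.array(
            [self._chrom_code[c] for c in self.chroms], dtype=np.int64
        )

    def sample(self, n: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """n placements -> (chrom code array, start position array)."""
        u = rng.integers(0, self.total, size=n)
        idx = np.searchsorted(self.cum, u, side="right")
        prev = np.where(idx > 0, self.cum[idx - 1], 0)
        starts = self.seg_start[idx] + (u - prev)
        return self.seg_chrom[idx], starts

    def valid_positions(self) -> list:
        """(chrom, start) of every valid placement — exhaustive enumeration."""
        out = []
        for code, s0, s1 in zip(
            self.seg_chrom, self.seg_start, np.append(self.cum[:1], np.diff(self.cum))
        ):
            for s in range(int(s0), int(s0 + s1)):
                out.append((self.chrom_names[int(code)], s))
        return out


def relocate_interval(
    interval: GenomicInterval,
    genome: Genome,
    rng: np.random.Generator,
    match_tolerance: int = 0,
    log: RunLog | None = None,
) -> GenomicInterval:
    """One confounder-matched relocation of an interval (same length, same
    cluster count within tolerance, uniform over valid placements)."""
    k = genome.cluster_count(interval)
    sampler = PlacementSampler(
        interval.length, k, genome, match_tolerance, log=log, context=interval.label
    )
    codes, starts = sampler.sample(1, rng)
    chrom = sampler.chrom_names[int(codes[0])]
    start = int(starts[0])
    return GenomicInterval(
        chrom, start, start + interval.length - 1,
        label=interval.label, origin=interval.origin,
    )


# ---------------------------------------------------------------------------
# engine

class _GeneIndex:
    """Per-chromosome arrays of background gene regions for mask building."""

    def __init__(self, regions: Sequence[GeneRegion], gene_order: Sequence[str]):
        gene_pos = {g: i for i, g in enumerate(gene_order)}
        self.n_genes = len(gene_order)
        by_chrom: dict[str, list[GeneRegion]] = {}
        for r in regions:
            if r.gene_id in gene_pos:
                by_chrom.setdefault(r.chrom, []).append(r)
        self.per_chrom = {
            chrom: (
                np.array([r.region_start for r in rs], dtype=np.int64),
                np.array([r.region_end for r in rs], dtype=np.int64),
                np.array([gene_pos[r.gene_id] for r in rs], dtype=np.int64),
            )
            for chrom, rs in by_chrom.items()
        }

    def masks(
        self, chrom_names: Sequence[str], codes: np.ndarray, starts: np.ndarray,
        length: int,
    ) -> np.ndarray:
        """(n_placements x n_genes) boolean overlap matrix."""
        n = len(starts)
        out = np.zeros((n, self.n_genes), dtype=bool)
        ends = starts + length - 1
        for code, chrom in enumerate(chrom_names):
            arrays = self.per_chrom.get(chrom)
            if arrays is None:
                continue
            rows = np.nonzero(codes == code)[0]
            if rows.size == 0:
                continue
            gs, ge, gi = arrays
            hit = (gs[None, :] <= ends[rows, None]) & (ge[None, :] >= starts[rows, None])
            out[np.ix_(rows, gi)] |= hit
        return out


@dataclass
class FirstLevel:
    """First-level permutation results plus the null needed for correction."""

    observed: dict  # term_id -> observed statistic (configured mode)
    pvalues: dict  # term_id -> empirical p
    term_ids: list
    null_stats: np.ndarray  # (n_perm x n_terms)
    gene_counts: dict  # term_id -> distinct annotated genes in intervals
    overlap_genes: dict  # term_id -> sorted gene ids in intervals
    genome_counts: dict  # term_id -> background genes annotated with term

    def __getitem__(self, term_id):
        return (self.observed[term_id], self.pvalues[term_id])

    def items(self):
        return {t: self[t] for t in self.term_ids}.items()


class EnrichmentEngine:
    """Shared machinery for the first-level permutation null and the
    bootstrap correction over one annotation."""

    def __init__(
        self,
        intervals: Sequence[GenomicInterval],
        annotation: GeneSetAnnotation,
        genome: Genome,
        config: EnrichmentConfig,
        log: RunLog | None = None,
    ):
        self.log = log if log is not None else RunLog()
        self.intervals = list(intervals)
        self.annotation = annotation
        self.genome = genome
        self.config = config

        background = set(annotation.genome_background)
        self.gene_order = sorted(
            {r.gene_id for r in genome.regions} & background
        )
        self.gene_index = _GeneIndex(genome.regions, self.gene_order)
        gene_pos = {g: i for i, g in enumerate(self.gene_order)}

        self.term_ids = []
        rows = []
        for tid in sorted(annotation.term_to_genes):
            if config.exclude_root and tid in annotation.root_ids:
                continue
            members = [g for g in annotation.term_to_genes[tid] if g in gene_pos]
            if not config.min_term_size <= len(members) <= config.max_term_size:
                continue
            row = np.zeros(len(self.gene_order), dtype=np.uint8)
            row[[gene_pos[g] for g in members]] = 1
            self.term_ids.append(tid)
            rows.append(row)
        self.term_matrix = (
            np.array(rows, dtype=np.uint8)
            if rows
            else np.zeros((0, len(self.gene_order)), dtype=np.uint8)
        )

        self.samplers = [
            PlacementSampler(
                iv.length,
                genome.cluster_count(iv),
                genome,
                config.match_tolerance,
                log=self.log,
                context=iv.label,
            )
            for iv in self.intervals
        ]
        self._null_cache: tuple[np.ndarray, np.ndarray] | None = None

    # -- statistics ---------------------------------------------------------

    def _stats(self, masks_per_interval: list) -> tuple[np.ndarray, np.ndarray]:
        """Gene-mode and interval-mode statistics for stacked placements.

        masks_per_interval: list of (n x n_genes) boolean matrices, one per
        interval, row r being replicate r's placement of that interval.
        """
        n = masks_per_interval[0].shape[0] if masks_per_interval else 0
        t = len(self.term_ids)
        union = np.zeros((n, len(self.gene_order)), dtype=bool)
        interval_hits = np.zeros((n, t), dtype=np.int32)
        for m in masks_per_interval:
            union |= m
            if t:
                interval_hits += (m.astype(np.uint8) @ self.term_matrix.T) > 0
        gene_stats = (
            union.astype(np.uint8) @ self.term_matrix.T
            if t
            else np.zeros((n, 0), dtype=np.int32)
        ).astype(np.int32)
        return gene_stats, interval_hits

    def observed_masks(self) -> list:
        masks = []
        for iv in self.intervals:
            m = np.zeros((1, len(self.gene_order)), dtype=bool)
            arrays = self.gene_index.per_chrom.get(iv.chrom)
            if arrays is not None:
                gs, ge, gi = arrays
                hit = (gs <= iv.end) & (ge >= iv.start)
                m[0, gi[hit]] = True
            masks.append(m)
        return masks

    def _null_masks(self, n_total: int) -> list[list]:
        """Per-interval placement masks for n_total replicates, each interval
        driven by its own deterministic substream."""
        children = np.random.SeedSequence(self.config.seed).spawn(len(self.intervals))
        per_interval = []
        for sampler, child, iv in zip(self.samplers, children, self.intervals):
            rng = np.random.default_rng(child)
            codes, starts = sampler.sample(n_total, rng)
            per_interval.append(
                self.gene_index.masks(sampler.chrom_names, codes, starts, iv.length)
            )
        return per_interval

    def _null_stats(self) -> tuple[np.ndarray, np.ndarray]:
        """(n_perm x T) first-level and (n_boot x T) bootstrap statistics in
        the configured mode."""
        if self._null_cache is None:
            n_total = self.config.n_perm + self.config.n_boot
            masks = self._null_masks(n_total)
            gene_stats, interval_stats = self._stats(masks)
            stats = gene_stats if self.config.mode == "gene" else interval_stats
            self._null_cache = (
                stats[: self.config.n_perm], stats[self.config.n_perm:],
            )
        return self._null_cache

    # -- public levels ------------------------------------------------------

    def first_level(self) -> FirstLevel:
        obs_masks = self.observed_masks()
        gene_obs, interval_obs = self._stats(obs_masks)
        obs = gene_obs[0] if self.config.mode == "gene" else interval_obs[0]
        null_stats, _ = self._null_stats()
        r1 = self.config.n_perm
        exceed = (null_stats >= obs[None, :]).sum(axis=0)
        pvals = (1.0 + exceed) / (r1 + 1.0)

        union = np.zeros(len(self.gene_order), dtype=bool)
        for m in obs_masks:
            union |= m[0]
        overlap_genes = {}
        gene_counts = {}
        genome_counts = {}
        for j, tid in enumerate(self.term_ids):
            members = self.term_matrix[j].astype(bool)
            hits = np.nonzero(members & union)[0]
            overlap_genes[tid] = [self.gene_order[i] for i in hits]
            gene_counts[tid] = int(gene_obs[0, j])
            genome_counts[tid] = int(members.sum())
        return FirstLevel(
            observed={t: int(obs[j]) for j, t in enumerate(self.term_ids)},
            pvalues={t: float(pvals[j]) for j, t in enumerate(self.term_ids)},
            term_ids=list(self.term_ids),
            null_stats=null_stats,
            gene_counts=gene_counts,
            overlap_genes=overlap_genes,
            genome_counts=genome_counts,
        )

    def corrected(self, first: FirstLevel) -> dict:
        """Min-p bootstrap family-wise correction.

        Each bootstrap pseudo-experiment relocates all intervals afresh; its
        per-term empirical p is evaluated against the first-level null, and
        the minimum across terms forms the reference distribution.
        """
        if not first.term_ids:
            return {}
        _, boot_stats = self._null_stats()
        r1 = self.config.n_perm
        r2 = self.config.n_boot
        null = first.null_stats
        t = len(first.term_ids)
        pseudo_p = np.empty((r2, t))
        for j in range(t):
            col = np.sort(null[:, j])
            ge = r1 - np.searchsorted(col, boot_stats[:, j], side="left")
            pseudo_p[:, j] = (1.0 + ge) / (r1 + 1.0)
        min_p = pseudo_p.min(axis=1)
        out = {}
        for j, tid in enumerate(first.term_ids):
            emp = first.pvalues[tid]
            out[tid] = float((1.0 + (min_p <= emp).sum()) / (r2 + 1.0))
        return out


def empirical_pvalues(
    intervals: Sequence[GenomicInterval],
    annotation: GeneSetAnnotation,
    genome: Genome,
    config: EnrichmentConfig,
    log: RunLog | None = None,
) -> FirstLevel:
    """First-level relocation-permutation p-values for every tested term."""
    return EnrichmentEngine(intervals, annotation, genome, config, log).first_level()


def corrected_pvalues(
    first_level: FirstLevel,
    intervals: Sequence[GenomicInterval],
    annotation: GeneSetAnnotation,
    genome: Genome,
    config: EnrichmentConfig,
    log: RunLog | None = None,
) -> dict:
    engine = EnrichmentEngine(intervals, annotation, genome, config, log)
    return engine.corrected(first_level)


def run_enrichment(
    intervals: Sequence[GenomicInterval],
    annotation: GeneSetAnnotation,
    genome: Genome,
    config: EnrichmentConfig,
    log: RunLog | None = None,
) -> list:
    """Full two-level enrichment for one annotation, sorted for reporting:
    empirical p ascending, then overlap gene count descending, then term id."""
    log = log if log is not None else RunLog()
    if not annotation.term_to_genes:
        log.warn(
            f"annotation {annotation.ontology_label} has no term sets; "
            "empty enrichment result",
            count_key="empty_annotations",
        )
        return []
    engine = EnrichmentEngine(intervals, annotation, genome, config, log)
    first = engine.first_level()
    corrected = engine.corrected(first)
    results = []
    for tid in first.term_ids:
        n_genome = first.genome_counts[tid]
        results.append(
            EnrichmentResult(
                term_id=tid,
                term_name=annotation.term_names.get(tid, tid),
                observed=first.observed[tid],
                n_genes_in_intervals=first.gene_counts[tid],
                n_genome_annotated=n_genome,
                gene_ratio=first.gene_counts[tid] / n_genome if n_genome else 0.0,
                empirical_p=first.pvalues[tid],
                corrected_p=corrected[tid],
                overlap_genes=sorted(first.overlap_genes[tid]),
            )
        )
    results.sort(key=lambda r: (r.empirical_p, -r.n_genes_in_intervals, r.term_id))
    return results


def run_enrichment_suite(
    intervals: Sequence[GenomicInterval],
    annotations: Mapping[str, GeneSetAnnotation],
    genome: Genome,
    config: EnrichmentConfig,
    log: RunLog | None = None,
) -> dict:
    """Run every annotation (HPO, DO, slims, pathway sets, ...) in turn."""
    return {
        label: run_enrichment(intervals, ann, genome, config, log)
        for label, ann in annotations.items()
    }
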