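"""Interval x gene-region and interval x variant intersection, plus gene
collapsing into overlap clusters.

All arithmetic is 1-based inclusive; two features overlap iff they share at
least one base. A sorted sweep replaces an external overlap engine — exact
agreement with a brute-force all-pairs scan is the contract.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .data_model import PATHOGENIC_SIGNIFICANCE, GeneRecord, KnowledgeBase, VariantRecord
from .errors import DataError, ValidationError
from .intervals import GenomicInterval

#: Maximum per-side gene-region extension.
MAX_GENE_EXTENSION_BP = 20_000


@dataclass(frozen=True)
class GeneRegion:
    gene_id: str
    chrom: str
    region_start: int
    region_end: int

    def __post_init__(self):
        if self.region_start > self.region_end:
            raise ValidationError(
                f"gene region {self.gene_id}: start > end", code="bad_coordinates"
            )


@dataclass(frozen=True)
class GeneCluster:
    cluster_id: str
    member_gene_ids: frozenset
    chrom: str
    span_start: int
    span_end: int


def build_gene_regions(
    genes: Sequence[GeneRecord],
    upstream: int = 0,
    downstream: int = 0,
    strand_aware: bool = True,
) -> list:
    """Extend canonical transcript spans by up/downstream flanks.

    Upstream/downstream are transcription-relative when ``strand_aware``
    (extensions swap ends on the minus strand); clipped at position 1.
    """
    for ext, side in ((upstream, "upstream"), (downstream, "downstream")):
        if not 0 <= ext <= MAX_GENE_EXTENSION_BP:
            raise ValidationError(
                f"{side} extension {ext} bp outside [0, {MAX_GENE_EXTENSION_BP}]",
                code="gene_extension_too_large",
            )
    regions = []
    for g in genes:
        if strand_aware and g.strand == "-":
            left, right = downstream, upstream
        else:
            left, right = upstream, downstream
        regions.append(
            GeneRegion(
                gene_id=g.gene_id,
                chrom=g.chrom,
                region_start=max(1, g.tx_start - left),
                region_end=g.tx_end + right,
            )
        )
    return regions


def _check_chrom_conventions(interval_chroms: set, region_chroms: set) -> None:
    if not interval_chroms or not region_chroms:
        return
    if interval_chroms & region_chroms:
        return
    stripped_iv = {c.removeprefix("chr") for c in interval_chroms}
    stripped_rg = {c.removeprefix("chr") for c in region_chroms}
    if stripped_iv & stripped_rg:
        raise DataError(
            "no shared chromosome names between intervals and gene regions, "
            "but names match after stripping a 'chr' prefix — use one naming "
            "convention ('chr1' vs '1') consistently",
            code="chrom_convention_mismatch",
        )


@dataclass
class _ChromIndex:
    """Regions of one chromosome sorted by start, for a sweep query."""

    starts: np.ndarray
    ends: np.ndarray
    order: list  # indices into the original region list


def _index_regions(regions: Sequence[GeneRegion]) -> dict:
    by_chrom: dict[str, list[int]] = {}
    for i, r in enumerate(regions):
        by_chrom.setdefault(r.chrom, []).append(i)
    index = {}
    for chrom, idxs in by_chrom.items():
        idxs.sort(key=lambda i: (regions[i].region_start, regions[i].region_end))
        index[chrom] = _ChromIndex(
            starts=np.array([regions[i].region_start for i in idxs], dtype=np.int64),
            ends=np.array([regions[i].region_end for i in idxs], dtype=np.int64),
            order=idxs,
        )
    return index


def find_gene_overlaps(
    intervals: Sequence[GenomicInterval], regions: Sequence[GeneRegion]
) -> list:
    """All (interval_index, GeneRegion) pairs sharing >= 1 bp."""
    _check_chrom_conventions({iv.chrom for iv in intervals}, {r.chrom for r in regions})
    index = _index_regions(regions)
    rows = []
    for i, iv in enumerate(intervals):
        ci = index.get(iv.chrom)
        if ci is None:
            continue
        hi = int(np.searchsorted(ci.starts, iv.end, side="right"))
        hit = np.nonzero(ci.ends[:hi] >= iv.start)[0]
        for j in hit:
            rows.append((i, regions[ci.order[j]]))
    return rows


def find_variant_overlaps(
    intervals: Sequence[GenomicInterval],
    variants: Sequence[VariantRecord],
    significance_filter: Iterable[str] = PATHOGENIC_SIGNIFICANCE,
) -> list:
    """All (interval_index, VariantRecord) pairs with the variant position
    inside the interval and a qualifying clinical significance."""
    keep = set(significance_filter)
    by_chrom: dict[str, list[VariantRecord]] = {}
    for v in variants:
        if v.clinical_significance in keep:
            by_chrom.setdefault(v.chrom, []).append(v)
    for vs in by_chrom.values():
        vs.sort(key=lambda v: v.pos)
    rows = []
    for i, iv in enumerate(intervals):
        vs = by_chrom.get(iv.chrom)
        if not vs:
            continue
        positions = [v.pos for v in vs]
        lo = int(np.searchsorted(positions, iv.start, side="left"))
        hi = int(np.searchsorted(positions, iv.end, side="right"))
        for v in vs[lo:hi]:
            rows.append((i, v))
    return rows


def collapse_genes(regions: Sequence[GeneRegion], prefix: str = "C") -> list:
    """Merge chains of pairwise-overlapping regions into maximal clusters.

    Touching-but-not-overlapping regions (end + 1 == next start) stay apart.
    Cluster span is [min start, max end] of its members.
    """
    ordered = sorted(regions, key=lambda r: (r.chrom, r.region_start, r.region_end))
    clusters = []
    current: list[GeneRegion] = []
    cur_chrom, cur_end = None, -1

    def flush():
        if current:
            clusters.append(
                GeneCluster(
                    cluster_id=f"{prefix}{len(clusters) + 1:05d}",
                    member_gene_ids=frozenset(r.gene_id for r in current),
                    chrom=current[0].chrom,
                    span_start=min(r.region_start for r in current),
                    span_end=max(r.region_end for r in current),
                )
            )

    for r in ordered:
        if current and r.chrom == cur_chrom and r.region_start <= cur_end:
            current.append(r)
            cur_end = max(cur_end, r.region_end)
        else:
            flush()
            current = [r]
            cur_chrom, cur_end = r.chrom, r.region_end
    flush()
    return clusters


def interval_gene_sets(
    intervals: Sequence[GenomicInterval], regions: Sequence[GeneRegion]
) -> list:
    """Per-interval sets of overlapping gene ids, in interval input order."""
    sets: list[set] = [set() for _ in intervals]
    for i, region in find_gene_overlaps(intervals, regions):
        sets[i].add(region.gene_id)
    return sets


@dataclass
class OverlapTable:
    """Joined interval/gene/disease rows plus interval/variant rows."""

    gene_rows: list  # (GenomicInterval, GeneRecord, DiseaseGeneAssociation)
    variant_rows: list  # (GenomicInterval, VariantRecord)


def build_overlap_table(
    intervals: Sequence[GenomicInterval],
    kb: KnowledgeBase,
    regions: Sequence[GeneRegion],
    significance_filter: Iterable[str] = PATHOGENIC_SIGNIFICANCE,
) -> OverlapTable:
    """Intersect intervals with gene regions and variants, joining each gene
    hit with all its disease associations."""
    by_gene = kb.associations_by_gene()
    gene_rows = []
    for i, region in find_gene_overlaps(intervals, regions):
        gene = kb.genes[region.gene_id]
        for assoc in by_gene.get(region.gene_id, []):
            gene_rows.append((intervals[i], gene, assoc))
    variant_rows = [
        (intervals[i], v)
        for i, v in find_variant_overlaps(intervals, kb.variants, significance_filter)
    ]
    return OverlapTable(gene_rows=gene_rows, variant_rows=variant_rows)
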