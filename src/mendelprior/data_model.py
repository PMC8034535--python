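"""Knowledge-base schema: genes, gene-disease associations, variants.

Gene-disease tables from several curated sources are merged on
``(gene_id, disease_id)`` with per-source provenance, then decorated with
disease descriptions and ontology terms according to fixed source-priority
orders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping

import pandas as pd

from .errors import DataError, ValidationError
from .runlog import RunLog

if TYPE_CHECKING:  # pragma: no cover
    from .ontology import Ontology

#: Association sources, in priority order (first wins naming conflicts).
SOURCES = ("OMIM", "ORPHANET", "DECIPHER", "GE")

#: Disease-description sources, in priority order.
DESCRIPTION_PRIORITY = ("OMIM", "ORPHANET", "UNIPROT", "DO")

#: Default source orders for ontology-term collection, primary source first.
HPO_TERM_SOURCE_ORDER = ("OMIM", "ORPHANET", "DECIPHER", "HPO_OFFICIAL")
DO_TERM_SOURCE_ORDER = ("OMIM", "ORPHANET", "DO_OFFICIAL")

CLINICAL_SIGNIFICANCE = frozenset(
    {
        "pathogenic",
        "likely pathogenic",
        "uncertain significance",
        "likely benign",
        "benign",
    }
)

PATHOGENIC_SIGNIFICANCE = frozenset({"pathogenic", "likely pathogenic"})


@dataclass(frozen=True)
class GeneRecord:
    """One transcript of a gene; the canonical transcript stands for the gene."""

    gene_id: str
    symbol: str
    chrom: str
    tx_start: int
    tx_end: int
    strand: str
    transcript_id: str
    appris_principal: bool
    transcript_length: int = 0

    def __post_init__(self):
        if self.tx_start > self.tx_end:
            raise ValidationError(
                f"gene {self.gene_id} transcript {self.transcript_id}: "
                f"tx_start {self.tx_start} > tx_end {self.tx_end}",
                code="bad_coordinates",
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}",
                code="bad_strand",
            )
        if self.transcript_length == 0:
            object.__setattr__(
                self, "transcript_length", self.tx_end - self.tx_start + 1
            )
        if self.transcript_length < 1:
            raise ValidationError(
                f"gene {self.gene_id}: transcript_length must be >= 1",
                code="bad_coordinates",
            )


@dataclass
class DiseaseGeneAssociation:
    """One gene-disease link with provenance, description and ontology terms."""

    gene_id: str
    disease_id: str
    disease_name: str
    sources: frozenset = frozenset()
    description: str | None = None
    description_source: str | None = None
    hpo_terms: set = field(default_factory=set)
    do_terms: set = field(default_factory=set)
    link_url: str = ""

    def __post_init__(self):
        self.sources = frozenset(self.sources)
        if not self.sources:
            raise ValidationError(
                f"association ({self.gene_id}, {self.disease_id}) has no sources",
                code="empty_sources",
            )
        unknown = self.sources - set(SOURCES)
        if unknown:
            raise ValidationError(
                f"unknown association sources: {sorted(unknown)}",
                code="unknown_source",
            )


@dataclass(frozen=True)
class VariantRecord:
    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    clinical_significance: str
    gene_id: str | None = None
    disease_name: str | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(
                f"variant {self.variant_id}: pos must be >= 1", code="bad_coordinates"
            )
        if self.clinical_significance not in CLINICAL_SIGNIFICANCE:
            raise ValidationError(
                f"variant {self.variant_id}: unknown clinical significance "
                f"{self.clinical_significance!r}",
                code="bad_significance",
            )


@dataclass
class KnowledgeBase:
    """Integrated reference: canonical genes, associations, variants."""

    genes: dict  # gene_id -> canonical GeneRecord
    associations: list  # of DiseaseGeneAssociation
    variants: list  # of VariantRecord
    build_label: str = "GRCh38"

    def validate(self) -> None:
        for assoc in self.associations:
            if assoc.gene_id not in self.genes:
                raise DataError(
                    f"association gene {assoc.gene_id} has no gene record",
                    code="unresolved_gene",
                )
        for var in self.variants:
            if var.gene_id is not None and var.gene_id not in self.genes:
                raise DataError(
                    f"variant {var.variant_id} gene {var.gene_id} has no gene record",
                    code="unresolved_gene",
                )

    def associations_by_gene(self) -> dict:
        by_gene: dict[str, list] = {}
        for assoc in self.associations:
            by_gene.setdefault(assoc.gene_id, []).append(assoc)
        return by_gene


def _link_url(disease_id: str) -> str:
    ns, _, ident = disease_id.partition(":")
    if ns == "OMIM":
        return f"https://www.omim.org/entry/{ident}"
    if ns == "ORPHA":
        return (
            "https://www.orpha.net/consor/cgi-bin/OC_Exp.php?"
            f"Expert={ident}"
        )
    return ""


def integrate_sources(
    per_source_tables: Mapping[str, pd.DataFrame],
    known_gene_ids: Iterable[str] | None = None,
    disease_alias: Mapping[str, str] | None = None,
    log: RunLog | None = None,
) -> list[DiseaseGeneAssociation]:
    """Merge per-source association tables into unique (gene, disease) records.

    ``disease_alias`` optionally maps member disease ids to a shared series id
    so that near-duplicate entries merge; merging then happens on the aliased
    key. Rows with gene ids absent from ``known_gene_ids`` (when supplied) are
    excluded with a logged warning. Duplicate rows within one source are
    silently dropped.
    """
    log = log if log is not None else RunLog()
    known = set(known_gene_ids) if known_gene_ids is not None else None
    alias = dict(disease_alias) if disease_alias else {}

    for source in per_source_tables:
        if source not in SOURCES:
            raise ValidationError(
                f"unknown source label {source!r}; expected one of {SOURCES}",
                code="unknown_source",
            )

    merged: dict[tuple[str, str], DiseaseGeneAssociation] = {}
    # iterate in fixed priority order so disease_name comes from the
    # first-priority source holding the pair
    for source in SOURCES:
        table = per_source_tables.get(source)
        if table is None:
            continue
        seen_in_source: set[tuple[str, str]] = set()
        for row in table.itertuples(index=False):
            gene_id = str(row.gene_id)
            disease_id = alias.get(str(row.disease_id), str(row.disease_id))
            key = (gene_id, disease_id)
            if key in seen_in_source:
                continue  # intra-source duplicate
            seen_in_source.add(key)
            if known is not None and gene_id not in known:
                log.warn(
                    f"{source}: gene {gene_id} not in gene table; "
                    f"association with {disease_id} excluded",
                    count_key="unresolved_gene_associations",
                )
                continue
            if key in merged:
                assoc = merged[key]
                assoc.sources = assoc.sources | {source}
            else:
                merged[key] = DiseaseGeneAssociation(
                    gene_id=gene_id,
                    disease_id=disease_id,
                    disease_name=str(row.disease_name),
                    sources=frozenset({source}),
                    link_url=_link_url(disease_id),
                )
    return list(merged.values())


def attach_descriptions(
    associations: list,
    description_tables: Mapping[str, Mapping[str, str]],
    log: RunLog | None = None,
) -> list:
    """Attach the first available description in fixed source-priority order."""
    log = log if log is not None else RunLog()
    for source in description_tables:
        if source not in DESCRIPTION_PRIORITY:
            raise ValidationError(
                f"unknown description source {source!r}", code="unknown_source"
            )
    n_described = 0
    for assoc in associations:
        for source in DESCRIPTION_PRIORITY:
            table = description_tables.get(source)
            if table is not None and assoc.disease_id in table:
                assoc.description = table[assoc.disease_id]
                assoc.description_source = source
                n_described += 1
                break
    log.note(f"descriptions attached to {n_described}/{len(associations)} associations")
    return associations


def attach_ontology_terms(
    associations: list,
    per_source_term_tables: Mapping[str, Mapping[str, Iterable[str]]],
    ontology: "Ontology",
    ontology_kind: str,
    source_order: tuple[str, ...] | None = None,
    log: RunLog | None = None,
) -> list:
    """Attach the union of per-source ontology terms to every association.

    Sources are scanned in ``source_order`` (primary first) purely for
    bookkeeping: the final term set is the order-invariant union, but the log
    reports how many diseases gained terms only from non-primary sources.
    Unknown or obsolete term ids are dropped with a warning.
    """
    log = log if log is not None else RunLog()
    if ontology_kind not in ("HPO", "DO"):
        raise ValidationError(
            f"ontology_kind must be HPO or DO, got {ontology_kind!r}",
            code="bad_ontology_kind",
        )
    if source_order is None:
        source_order = (
            HPO_TERM_SOURCE_ORDER if ontology_kind == "HPO" else DO_TERM_SOURCE_ORDER
        )
    attr = "hpo_terms" if ontology_kind == "HPO" else "do_terms"

    disease_terms: dict[str, set] = {}
    first_source: dict[str, str] = {}
    extra_sources = [s for s in per_source_term_tables if s not in source_order]
    for source in tuple(source_order) + tuple(extra_sources):
        table = per_source_term_tables.get(source)
        if table is None:
            continue
        for disease_id, term_ids in table.items():
            kept = set()
            for tid in term_ids:
                term = ontology.terms.get(tid)
                if term is None:
                    log.warn(
                        f"{source}: unknown {ontology_kind} term {tid} for "
                        f"{disease_id} dropped",
                        count_key=f"unknown_{ontology_kind.lower()}_terms",
                    )
                elif term.obsolete:
                    log.warn(
                        f"{source}: obsolete {ontology_kind} term {tid} for "
                        f"{disease_id} dropped",
                        count_key=f"obsolete_{ontology_kind.lower()}_terms",
                    )
                else:
                    kept.add(tid)
            if kept:
                if disease_id not in disease_terms:
                    disease_terms[disease_id] = set()
                    first_source[disease_id] = source
                disease_terms[disease_id] |= kept

    primary = source_order[0]
    n_non_primary_only = sum(1 for s in first_source.values() if s != primary)
    log.note(
        f"{ontology_kind}: {n_non_primary_only} diseases with no previous terms "
        f"gained terms only from non-{primary} sources"
    )
    for assoc in associations:
        terms = disease_terms.get(assoc.disease_id)
        if terms:
            setattr(assoc, attr, set(getattr(assoc, attr)) | terms)
    return associations


def select_canonical_transcript(transcripts: list) -> GeneRecord:
    """Pick the canonical transcript of one gene.

    The unique principal-isoform transcript wins; otherwise the longest
    transcript, ties broken by lexicographically smallest transcript_id.
    """
    if not transcripts:
        raise DataError("gene has no transcripts", code="no_transcripts")
    gene_ids = {t.gene_id for t in transcripts}
    if len(gene_ids) != 1:
        raise DataError(
            f"transcripts span multiple genes: {sorted(gene_ids)}",
            code="mixed_genes",
        )
    principal = [t for t in transcripts if t.appris_principal]
    if len(principal) == 1:
        return principal[0]
    return min(transcripts, key=lambda t: (-t.transcript_length, t.transcript_id))


def canonical_genes(transcripts: Iterable[GeneRecord]) -> dict:
    """Collapse a transcript table to one canonical GeneRecord per gene."""
    by_gene: dict[str, list] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    return {g: select_canonical_transcript(ts) for g, ts in by_gene.items()}


# ---------------------------------------------------------------------------
# readers (tab-delimited external interfaces)

def read_association_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "disease_id", "disease_name"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(
            f"{path}: association table missing columns {sorted(missing)}",
            code="bad_table",
        )
    return df


def read_gene_table(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {
        "gene_id", "symbol", "chrom", "tx_start", "tx_end",
        "strand", "transcript_id", "appris_principal",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(
            f"{path}: gene table missing columns {sorted(missing)}",
            code="bad_table",
        )
    records = []
    for row in df.itertuples(index=False):
        records.append(
            GeneRecord(
                gene_id=row.gene_id,
                symbol=row.symbol,
                chrom=row.chrom,
                tx_start=int(row.tx_start),
                tx_end=int(row.tx_end),
                strand=row.strand,
                transcript_id=row.transcript_id,
                appris_principal=str(row.appris_principal) in ("1", "True", "true"),
            )
        )
    return records


def read_variant_table(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype=str)
    records = []
    for row in df.itertuples(index=False):
        gene_id = getattr(row, "gene_id", None)
        if gene_id is not None and pd.isna(gene_id):
            gene_id = None
        disease_name = getattr(row, "disease_name", None)
        if disease_name is not None and pd.isna(disease_name):
            disease_name = None
        records.append(
            VariantRecord(
                variant_id=row.variant_id,
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                clinical_significance=row.clinical_significance,
                gene_id=gene_id,
                disease_name=disease_name,
            )
        )
    return records


def read_description_table(path) -> dict:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"disease_id", "description"} <= set(df.columns):
        raise ValidationError(
            f"{path}: description table needs disease_id + description columns",
            code="bad_table",
        )
    return dict(zip(df["disease_id"], df["description"]))


def read_term_table(path) -> dict:
    """disease_id<TAB>term_id rows -> {disease_id: set of term ids}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"disease_id", "term_id"} <= set(df.columns):
        raise ValidationError(
            f"{path}: term table needs disease_id + term_id columns",
            code="bad_table",
        )
    out: dict[str, set] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.disease_id, set()).add(row.term_id)
    return out
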