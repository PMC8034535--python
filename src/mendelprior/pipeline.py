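"""Single-command pipeline: inputs -> intervals -> overlap -> enrichment ->
output bundle (log, BED echo, overlap tables, per-ontology enrichment files,
summary figures).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import data_model as dm
from . import intervals as iv
from . import ontology as onto
from . import overlap as ov
from .enrichment import EnrichmentConfig, Genome, run_enrichment_suite
from .errors import ValidationError
from .report import render_top_terms
from .runlog import RunLog

ROUTES = ("flank", "ld", "intervals")

OVERLAP_COLUMNS = [
    "ID", "Interval_tested", "Gene_name", "Gene_ID", "Chrom", "Gene_start",
    "Gene_end", "Strand", "Transcript_ID", "Disease_ID", "Disease_name",
    "Link", "Sources", "Description", "Description_source", "HPO_terms",
    "DO_terms", "N_HPO_terms", "N_DO_terms", "Origin",
]


_PATH_KEYS = (
    "positions_file", "intervals_file", "chrom_sizes", "gene_table",
    "variant_table", "ld_source_dir", "recomb_map", "out_dir",
)
_PATH_DICT_KEYS = ("association_tables", "description_tables", "gmt_annotations")


def _resolve_paths(cfg: dict, base_dir: Path | None) -> dict:
    """Resolve relative paths against the config file's directory."""
    if base_dir is None:
        return dict(cfg)
    out = dict(cfg)

    def resolve(value):
        return str(base_dir / value) if not Path(value).is_absolute() else value

    for key in _PATH_KEYS:
        if key in out and out[key] is not None:
            out[key] = resolve(out[key])
    for key in _PATH_DICT_KEYS:
        if key in out and out[key]:
            out[key] = {k: resolve(v) for k, v in out[key].items()}
    if out.get("ontologies"):
        ontologies = {}
        for label, spec in out["ontologies"].items():
            spec = dict(spec)
            if "obo" in spec:
                spec["obo"] = resolve(spec["obo"])
            if spec.get("slim") and spec["slim"] != "auto":
                spec["slim"] = resolve(spec["slim"])
            if spec.get("term_tables"):
                spec["term_tables"] = {
                    k: resolve(v) for k, v in spec["term_tables"].items()
                }
            ontologies[label] = spec
        out["ontologies"] = ontologies
    return out


@dataclass
class RunConfig:
    raw: dict
    route: str
    out_dir: Path
    build_label: str = "GRCh38"
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)

    @classmethod
    def from_mapping(
        cls, cfg: Mapping[str, Any], base_dir: Path | None = None
    ) -> "RunConfig":
        cfg = _resolve_paths(dict(cfg), base_dir)
        route = cfg.get("route")
        if route not in ROUTES:
            raise ValidationError(
                f"route must be one of {ROUTES}, got {route!r}", code="bad_route"
            )
        if "out_dir" not in cfg:
            raise ValidationError("config needs out_dir", code="bad_config")
        enr = EnrichmentConfig(**cfg.get("enrichment", {}))
        needed = {"chrom_sizes", "gene_table"}
        if route == "flank":
            needed |= {"positions_file"}
        elif route == "ld":
            needed |= {"positions_file", "ld_source_dir"}
        else:
            needed |= {"intervals_file"}
        for key in sorted(needed):
            if key not in cfg:
                raise ValidationError(
                    f"config route {route!r} needs key {key!r}", code="bad_config"
                )
            if not Path(cfg[key]).exists():
                raise ValidationError(
                    f"config path {key}={cfg[key]} does not exist", code="missing_path"
                )
        return cls(
            raw=dict(cfg),
            route=route,
            out_dir=Path(cfg["out_dir"]),
            build_label=cfg.get("build", "GRCh38"),
            enrichment=enr,
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh), base_dir=path.parent)


def _build_intervals(cfg: RunConfig, chrom_sizes: dict, log: RunLog) -> list:
    raw = cfg.raw
    if cfg.route == "intervals":
        out = iv.read_intervals_file(raw["intervals_file"])
    elif cfg.route == "flank":
        positions = iv.read_positions_file(raw["positions_file"])
        out = iv.make_flank_intervals(
            positions,
            int(raw.get("flank_left", 0)),
            int(raw.get("flank_right", 0)),
            chrom_sizes,
            log=log,
        )
    else:
        source = iv.LDSource(
            raw["ld_source_dir"], population=raw.get("population"), log=log
        )
        positions = iv.read_positions_file(raw["positions_file"], ld_source=source)
        stat = raw.get("ld_stat", "r2")
        threshold = float(raw.get("ld_threshold", 0.8))
        out = [
            iv.make_ld_interval(
                (chrom, pos, label),
                source.get(label, chrom, pos),
                stat=stat,
                threshold=threshold,
                log=log,
            )
            for chrom, pos, label in positions
        ]
        if raw.get("extend_to_hotspot"):
            rmap = iv.read_recomb_map(raw["recomb_map"])
            rate = float(raw.get("hotspot_rate", iv.DEFAULT_HOTSPOT_RATE))
            out = [iv.extend_to_hotspot(interval, rmap, rate) for interval in out]
            log.note(f"intervals extended to hotspots with rate > {rate} cM/Mb")
    return iv.validate_intervals(out)


def _load_knowledge_base(cfg: RunConfig, log: RunLog):
    raw = cfg.raw
    transcripts = dm.read_gene_table(raw["gene_table"])
    genes = dm.canonical_genes(transcripts)
    tables = {
        source: dm.read_association_table(path)
        for source, path in raw.get("association_tables", {}).items()
    }
    associations = dm.integrate_sources(tables, known_gene_ids=genes, log=log)
    desc_tables = {
        source: dm.read_description_table(path)
        for source, path in raw.get("description_tables", {}).items()
    }
    if desc_tables:
        dm.attach_descriptions(associations, desc_tables, log=log)
    variants = (
        dm.read_variant_table(raw["variant_table"]) if raw.get("variant_table") else []
    )
    kb = dm.KnowledgeBase(
        genes=genes, associations=associations, variants=variants,
        build_label=cfg.build_label,
    )
    kb.validate()
    return kb


def _load_annotations(cfg: RunConfig, kb, log: RunLog) -> dict:
    annotations: dict[str, onto.GeneSetAnnotation] = {}
    for label, spec in cfg.raw.get("ontologies", {}).items():
        kind = spec.get("kind", label)
        ontology = onto.load_obo(spec["obo"])
        term_tables = {
            source: dm.read_term_table(path)
            for source, path in spec.get("term_tables", {}).items()
        }
        dm.attach_ontology_terms(
            kb.associations, term_tables, ontology, kind, log=log
        )
        annotation = onto.annotate_genes(kb.associations, ontology, kind, label=label)
        annotations[label] = annotation
        slim_cfg = spec.get("slim")
        if slim_cfg:
            if slim_cfg == "auto":
                roots = sorted(ontology.root_ids)
                slim = onto.build_slim(ontology, roots[0])
            else:
                slim = onto.read_slim_file(slim_cfg)
            annotations[f"{label}_slim"] = onto.slim_annotation(
                annotation, slim, ontology
            )
    background = {a.gene_id for a in kb.associations}
    for label, path in cfg.raw.get("gmt_annotations", {}).items():
        annotations[label] = onto.read_gmt(path, label, background=background)
    return annotations


def _write_disease_overlap(table: ov.OverlapTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(OVERLAP_COLUMNS) + "\n")
        for interval, gene, assoc in table.gene_rows:
            row = [
                interval.label,
                interval.region_string(),
                gene.symbol,
                gene.gene_id,
                gene.chrom,
                str(gene.tx_start),
                str(gene.tx_end),
                gene.strand,
                gene.transcript_id,
                assoc.disease_id,
                assoc.disease_name,
                assoc.link_url,
                ";".join(sorted(assoc.sources)),
                assoc.description or "",
                assoc.description_source or "",
                ";".join(sorted(assoc.hpo_terms)),
                ";".join(sorted(assoc.do_terms)),
                str(len(assoc.hpo_terms)),
                str(len(assoc.do_terms)),
                interval.origin,
            ]
            fh.write("\t".join(row) + "\n")


def _write_variant_overlap(table: ov.OverlapTable, path) -> None:
    header = [
        "ID", "Interval_tested", "Variant_ID", "Chrom", "Pos", "Ref", "Alt",
        "Clinical_significance", "Gene_ID", "Disease_name",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for interval, var in table.variant_rows:
            row = [
                interval.label,
                interval.region_string(),
                var.variant_id,
                var.chrom,
                str(var.pos),
                var.ref,
                var.alt,
                var.clinical_significance,
                var.gene_id or "",
                var.disease_name or "",
            ]
            fh.write("\t".join(row) + "\n")


def _write_enrichment(results: list, label: str, out_dir: Path) -> None:
    raw_path = out_dir / f"{label}.out.inrich"
    with open(raw_path, "w") as fh:
        fh.write("term_id\tobserved\tempirical_p\tcorrected_p\tgenes\n")
        for r in results:
            fh.write(
                f"{r.term_id}\t{r.observed}\t{r.empirical_p:.6g}\t"
                f"{r.corrected_p:.6g}\t{';'.join(r.overlap_genes)}\n"
            )
    parsed_path = out_dir / f"{label}.out.inrich.parsed"
    with open(parsed_path, "w") as fh:
        fh.write(
            "term_id\tterm_name\tobserved\tn_genes_in_intervals\t"
            "n_genome_annotated\tgene_ratio\tempirical_p\tcorrected_p\tgenes\n"
        )
        for r in results:
            fh.write(
                f"{r.term_id}\t{r.term_name}\t{r.observed}\t"
                f"{r.n_genes_in_intervals}\t{r.n_genome_annotated}\t"
                f"{r.gene_ratio:.6g}\t{r.empirical_p:.6g}\t{r.corrected_p:.6g}\t"
                f"{';'.join(r.overlap_genes)}\n"
            )


def _config_lines(cfg: Mapping[str, Any], prefix: str = "") -> list:
    lines = []
    for key in sorted(cfg):
        value = cfg[key]
        if isinstance(value, Mapping):
            lines.append(f"{prefix}{key}:")
            lines.extend(_config_lines(value, prefix + "  "))
        else:
            lines.append(f"{prefix}{key}: {value}")
    return lines


def run_pipeline(config) -> dict:
    """Execute the full pipeline; returns {stage: artifact} including output
    paths and in-memory results."""
    if isinstance(config, (str, Path)):
        cfg = RunConfig.from_yaml(config)
    elif isinstance(config, RunConfig):
        cfg = config
    else:
        cfg = RunConfig.from_mapping(config)
    log = RunLog()
    out_dir = cfg.out_dir
    out_dir.mkdir(parents=True, exist_ok=True)

    chrom_sizes = iv.read_chrom_sizes(cfg.raw["chrom_sizes"])
    kb = _load_knowledge_base(cfg, log)
    log.note(
        f"knowledge base: {len(kb.genes)} genes, {len(kb.associations)} "
        f"associations, {len(kb.variants)} variants ({cfg.build_label})"
    )

    test_intervals = _build_intervals(cfg, chrom_sizes, log)
    log.note(f"{len(test_intervals)} test intervals via route '{cfg.route}'")
    iv.write_bed(test_intervals, out_dir / "input_file.bed")

    ext = cfg.raw.get("gene_extension", {})
    background_genes = {a.gene_id for a in kb.associations}
    regions = ov.build_gene_regions(
        [kb.genes[g] for g in sorted(background_genes)],
        upstream=int(ext.get("upstream", 0)),
        downstream=int(ext.get("downstream", 0)),
        strand_aware=bool(ext.get("strand_aware", True)),
    )
    table = ov.build_overlap_table(test_intervals, kb, regions)
    _write_disease_overlap(table, out_dir / "disease_overlap.txt")
    _write_variant_overlap(table, out_dir / "variant_overlap.txt")
    log.note(
        f"overlap: {len(table.gene_rows)} gene-disease rows, "
        f"{len(table.variant_rows)} variant rows"
    )

    annotations = _load_annotations(cfg, kb, log)
    genome = Genome(chrom_sizes=chrom_sizes, regions=regions)
    suite = run_enrichment_suite(
        test_intervals, annotations, genome, cfg.enrichment, log=log
    )
    for label, results in suite.items():
        _write_enrichment(results, label, out_dir)
        render_top_terms(
            results,
            k=50,
            table_path=out_dir / f"{label}.top_terms.tsv",
            figure_path=out_dir / f"{label}.png",
        )

    log_path = out_dir / "mendelvar.log"
    with open(log_path, "w") as fh:
        fh.write("# run parameters\n")
        for line in _config_lines(cfg.raw):
            fh.write(line + "\n")
        fh.write("# events\n")
        for line in log.lines():
            fh.write(line + "\n")
    return {
        "config": cfg,
        "knowledge_base": kb,
        "intervals": test_intervals,
        "overlap": table,
        "enrichment": suite,
        "out_dir": out_dir,
        "log": log,
    }
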