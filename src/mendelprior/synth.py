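"""Seeded synthetic fixtures: toy genome, transcripts, multi-source
associations, ontologies, LD tables, recombination map, variants — with an
optional planted enrichment signal. Everything another module reads can be
generated here, so the whole pipeline is testable offline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import SOURCES
from .errors import ValidationError
from .intervals import GenomicInterval, LD_WINDOW_HALF_BP

HPO_SOURCES = ("OMIM", "ORPHANET", "DECIPHER", "HPO_OFFICIAL")
DO_SOURCES = ("OMIM", "ORPHANET", "DO_OFFICIAL")
DESC_SOURCES = ("OMIM", "ORPHANET", "UNIPROT", "DO")


@dataclass
class FixtureSpec:
    n_chrom: int = 1
    chrom_length: int = 10_000_000
    n_genes: int = 60
    n_diseases: int = 40
    n_terms: int = 10
    ontology_depth: int = 3
    ontology_branching: int = 3
    frac_termless_diseases: float = 0.1
    planted_term: tuple | None = None  # (term_id or None, n_target_loci, effect)
    ld_decay_bp: int = 100_000
    hotspot_spacing_bp: int = 1_000_000
    seed: int = 0
    # artifact extras (not part of the core parameter set)
    n_intervals: int = 8
    interval_length: int = 100_000
    n_variants: int = 60
    term_size_min: int = 4
    term_size_max: int = 8

    def __post_init__(self):
        for name in (
            "n_chrom", "chrom_length", "n_genes", "n_diseases", "n_terms",
            "ontology_depth", "ontology_branching", "ld_decay_bp",
            "hotspot_spacing_bp", "n_intervals", "interval_length",
        ):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive", code="bad_spec")
        if not 0.0 <= self.frac_termless_diseases <= 1.0:
            raise ValidationError(
                "frac_termless_diseases must be in [0, 1]", code="bad_spec"
            )
        if self.planted_term is not None:
            _, n_loci, effect = self.planted_term
            if not 0.0 <= effect <= 1.0:
                raise ValidationError("planted effect must be in [0, 1]", code="bad_spec")
            if n_loci > self.n_intervals:
                raise ValidationError(
                    "planted target loci exceed interval count", code="bad_spec"
                )


@dataclass
class Fixture:
    spec: FixtureSpec
    chrom_sizes: dict
    gene_table: pd.DataFrame  # transcript-level rows
    association_tables: dict  # source -> DataFrame
    description_tables: dict  # source -> {disease_id: text}
    hpo_obo: str
    do_obo: str
    hpo_term_tables: dict  # source -> {disease_id: set}
    do_term_tables: dict
    variants: pd.DataFrame
    positions: list  # (chrom, pos, label)
    intervals: list  # GenomicInterval
    ld_tables: dict  # label -> DataFrame
    recomb_map: pd.DataFrame
    manifest: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# component generators

def _make_ontology(prefix: str, n_terms: int, depth: int, branching: int,
                   rng: np.random.Generator):
    """Random is_a DAG: a root, ``n_terms`` live terms, one obsolete term.

    Returns (obo_text, root_id, term_levels dict, edge_count).
    """
    root = f"{prefix}:0000000"
    term_ids = [f"{prefix}:{i:07d}" for i in range(1, n_terms + 1)]
    level = {root: 0}
    parents: dict[str, list] = {root: []}
    for i, tid in enumerate(term_ids):
        if i < branching or depth <= 1:
            parents[tid] = [root]
            level[tid] = 1
        else:
            shallow = [t for t in term_ids[:i] if level[t] < depth]
            pool = shallow if shallow else [root]
            p1 = pool[int(rng.integers(0, len(pool)))]
            ps = [p1]
            if len(pool) > 1 and rng.random() < 0.2:
                same = [t for t in pool if level[t] == level[p1] and t != p1]
                if same:
                    ps.append(same[int(rng.integers(0, len(same)))])
            parents[tid] = ps
            level[tid] = level[p1] + 1

    lines = ["format-version: 1.2", ""]
    lines += ["[Term]", f"id: {root}", f"name: {prefix} root", ""]
    n_edges = 0
    for tid in term_ids:
        lines += ["[Term]", f"id: {tid}", f"name: term {tid}"]
        for p in parents[tid]:
            lines.append(f"is_a: {p} ! {p}")
            n_edges += 1
        lines.append("")
    obsolete = f"{prefix}:9999999"
    lines += ["[Term]", f"id: {obsolete}", f"name: retired term",
              "is_obsolete: true", ""]
    return "\n".join(lines), root, level, n_edges


def _place_genes(spec: FixtureSpec, rng: np.random.Generator):
    """Non-overlapping gene spans, round-robin across chromosomes."""
    chroms = [str(i + 1) for i in range(spec.n_chrom)]
    per_chrom = [spec.n_genes // spec.n_chrom + (1 if i < spec.n_genes % spec.n_chrom else 0)
                 for i in range(spec.n_chrom)]
    genes = []
    gi = 0
    for ci, chrom in enumerate(chroms):
        n_here = per_chrom[ci]
        if n_here == 0:
            continue
        slot = spec.chrom_length // n_here
        if slot < 40_000:
            raise ValidationError(
                "chromosome too short for the requested gene count",
                code="bad_spec",
            )
        for s in range(n_here):
            gi += 1
            length = int(rng.integers(5_000, 30_001))
            lo = s * slot + 1
            hi = (s + 1) * slot - length - 1_000
            start = int(rng.integers(lo, max(lo + 1, hi)))
            genes.append(
                {
                    "gene_id": f"G{gi:04d}",
                    "symbol": f"GENE{gi}",
                    "chrom": chrom,
                    "start": start,
                    "end": start + length - 1,
                    "strand": "+" if rng.random() < 0.5 else "-",
                }
            )
    return chroms, genes


def _transcript_table(genes: list, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for g in genes:
        principal = rng.random() < 0.7
        n_tx = int(rng.integers(1, 4))
        span = g["end"] - g["start"] + 1
        for t in range(n_tx):
            if t == 0:
                s, e = g["start"], g["end"]
            else:
                # strict sub-span so the full-span transcript stays longest
                cut = int(rng.integers(1, max(2, span // 3)))
                s, e = g["start"] + cut, g["end"] - int(rng.integers(0, cut + 1))
                if s > e:
                    s, e = g["start"] + 1, g["end"]
            rows.append(
                {
                    "gene_id": g["gene_id"],
                    "symbol": g["symbol"],
                    "chrom": g["chrom"],
                    "tx_start": s,
                    "tx_end": e,
                    "strand": g["strand"],
                    "transcript_id": f'{g["gene_id"]}.t{t + 1}',
                    "appris_principal": 1 if (t == 0 and principal) else 0,
                }
            )
    return pd.DataFrame(rows)


def generate_ld_table(
    index_id: str,
    chrom: str,
    index_pos: int,
    ld_decay_bp: int,
    rng: np.random.Generator,
    n_proxies: int = 40,
) -> pd.DataFrame:
    """LDproxy-style export: r2 decays exponentially with distance (noisy),
    D' >= r2 row-wise, index row at r2 = D' = 1."""
    if ld_decay_bp <= 0:
        raise ValidationError("ld_decay_bp must be > 0", code="bad_spec")
    offsets = rng.integers(-LD_WINDOW_HALF_BP, LD_WINDOW_HALF_BP + 1, size=n_proxies)
    rows = [
        {"variant_id": index_id, "chrom": chrom, "pos": index_pos,
         "r2": 1.0, "dprime": 1.0}
    ]
    for i, off in enumerate(sorted(int(o) for o in offsets if o != 0)):
        pos = index_pos + off
        if pos < 1:
            continue
        r2 = float(
            np.clip(np.exp(-abs(off) / ld_decay_bp) * rng.uniform(0.7, 1.0), 0.0, 1.0)
        )
        dprime = float(min(1.0, r2 + rng.uniform(0.0, 1.0 - r2)))
        rows.append(
            {"variant_id": f"{index_id}_p{i + 1}", "chrom": chrom, "pos": pos,
             "r2": round(r2, 6), "dprime": round(dprime, 6)}
        )
    return pd.DataFrame(rows)


def _recomb_map(
    chroms: list, chrom_length: int, hotspot_spacing_bp: int, rng: np.random.Generator
) -> pd.DataFrame:
    rows = []
    step = 50_000
    for chrom in chroms:
        for pos in range(step, chrom_length + 1, step):
            if pos % hotspot_spacing_bp == 0:
                rate = round(float(rng.uniform(4.0, 10.0)), 4)
            else:
                rate = round(float(rng.uniform(0.1, 2.5)), 4)
            rows.append({"chrom": chrom, "pos": pos, "rate_cM_per_Mb": rate})
    return pd.DataFrame(rows)


def _closure_from_levels(term: str, parents_of: dict) -> set:
    out = {term}
    stack = [term]
    while stack:
        t = stack.pop()
        for p in parents_of.get(t, ()):
            if p not in out:
                out.add(p)
                stack.append(p)
    return out


def _parse_obo_parents(obo_text: str) -> dict:
    """Minimal parent map straight from the generated text (bookkeeping)."""
    parents: dict[str, list] = {}
    cur = None
    for line in obo_text.splitlines():
        if line.startswith("id: "):
            cur = line[4:].strip()
            parents.setdefault(cur, [])
        elif line.startswith("is_a: ") and cur:
            parents[cur].append(line[6:].split("!")[0].strip())
    return parents


# ---------------------------------------------------------------------------
# full fixture

def generate_fixture(spec: FixtureSpec) -> Fixture:
    """Deterministic full input bundle with manifest ground truth."""
    rng = np.random.default_rng(spec.seed)
    chroms, genes = _place_genes(spec, rng)
    chrom_sizes = {c: spec.chrom_length for c in chroms}
    gene_table = _transcript_table(genes, rng)
    gene_ids = [g["gene_id"] for g in genes]
    gene_by_id = {g["gene_id"]: g for g in genes}

    hpo_obo, hpo_root, _, hpo_edges = _make_ontology(
        "HP", spec.n_terms, spec.ontology_depth, spec.ontology_branching, rng
    )
    do_obo, do_root, _, do_edges = _make_ontology(
        "DO", max(2, spec.n_terms // 2), spec.ontology_depth,
        spec.ontology_branching, rng
    )
    hpo_terms = [f"HP:{i:07d}" for i in range(1, spec.n_terms + 1)]
    do_terms = [f"DO:{i:07d}" for i in range(1, max(2, spec.n_terms // 2) + 1)]

    # diseases: 1-2 causal genes, 1-3 sources, direct ontology terms
    assoc_rows: dict[str, list] = {s: [] for s in SOURCES}
    hpo_tables: dict[str, dict] = {s: {} for s in HPO_SOURCES}
    do_tables: dict[str, dict] = {s: {} for s in DO_SOURCES}
    desc_tables: dict[str, dict] = {s: {} for s in DESC_SOURCES}
    disease_truth: dict[str, dict] = {}
    for d in range(1, spec.n_diseases + 1):
        disease_id = f"DIS:{d:04d}"
        n_g = int(rng.integers(1, 3))
        d_genes = [gene_ids[int(i)] for i in rng.choice(len(gene_ids), n_g, replace=False)]
        n_src = int(rng.integers(1, 4))
        src_idx = rng.choice(len(SOURCES), n_src, replace=False)
        d_sources = sorted(SOURCES[int(i)] for i in src_idx)
        for source in d_sources:
            for g in d_genes:
                assoc_rows[source].append(
                    {"gene_id": g, "disease_id": disease_id,
                     "disease_name": f"Disease {d}"}
                )
        d_hpo, d_do = set(), set()
        if rng.random() >= spec.frac_termless_diseases:
            n_hpo = min(int(rng.integers(1, 4)), len(hpo_terms))
            n_do = min(int(rng.integers(1, 3)), len(do_terms))
            d_hpo = {
                hpo_terms[int(i)]
                for i in rng.choice(len(hpo_terms), n_hpo, replace=False)
            }
            d_do = {
                do_terms[int(i)]
                for i in rng.choice(len(do_terms), n_do, replace=False)
            }
            for t in sorted(d_hpo):
                src = HPO_SOURCES[int(rng.integers(0, len(HPO_SOURCES)))]
                hpo_tables[src].setdefault(disease_id, set()).add(t)
            for t in sorted(d_do):
                src = DO_SOURCES[int(rng.integers(0, len(DO_SOURCES)))]
                do_tables[src].setdefault(disease_id, set()).add(t)
        if rng.random() < 0.8:
            src = DESC_SOURCES[int(rng.integers(0, len(DESC_SOURCES)))]
            desc_tables[src][disease_id] = f"Synthetic description of disease {d}."
        disease_truth[disease_id] = {
            "genes": sorted(d_genes),
            "sources": d_sources,
            "hpo": sorted(d_hpo),
            "do": sorted(d_do),
        }

    # ground truth: per-gene direct + closed HPO term sets
    hpo_parents = _parse_obo_parents(hpo_obo)
    gene_hpo_direct: dict[str, set] = {}
    for disease_id, info in disease_truth.items():
        for g in info["genes"]:
            gene_hpo_direct.setdefault(g, set()).update(info["hpo"])
    term_genes_closure: dict[str, set] = {}
    for g, direct in gene_hpo_direct.items():
        closed = set()
        for t in direct:
            closed |= _closure_from_levels(t, hpo_parents)
        for t in closed:
            term_genes_closure.setdefault(t, set()).add(g)

    # variants
    var_rows = []
    sig_pool = ["pathogenic", "likely pathogenic", "benign", "uncertain significance"]
    sig_w = [0.45, 0.2, 0.25, 0.1]
    for v in range(1, spec.n_variants + 1):
        g = gene_by_id[gene_ids[int(rng.integers(0, len(gene_ids)))]]
        pos = int(rng.integers(g["start"], g["end"] + 1))
        var_rows.append(
            {
                "variant_id": f"var{v:05d}",
                "chrom": g["chrom"],
                "pos": pos,
                "ref": "ACGT"[int(rng.integers(0, 4))],
                "alt": "ACGT"[int(rng.integers(0, 4))],
                "clinical_significance": sig_pool[
                    int(rng.choice(len(sig_pool), p=sig_w))
                ],
                "gene_id": g["gene_id"],
                "disease_name": "",
            }
        )

    # test loci: planted ones centred on member genes of the planted term
    planted_info = None
    planted_targets = []
    if spec.planted_term is not None:
        term_id, n_loci, effect = spec.planted_term
        if term_id is None:
            # smallest term that still has enough members to fill the target
            # loci: specific terms separate cleanly from their ancestors
            candidates = sorted(
                (t for t in term_genes_closure
                 if t != hpo_root and len(term_genes_closure[t]) >= n_loci),
                key=lambda t: (len(term_genes_closure[t]), t),
            )
            if not candidates:
                candidates = sorted(
                    (t for t in term_genes_closure if t != hpo_root),
                    key=lambda t: (-len(term_genes_closure[t]), t),
                )
            if not candidates:
                raise ValidationError("no annotated terms to plant", code="bad_spec")
            term_id = candidates[0]
        members = sorted(term_genes_closure.get(term_id, ()))
        if n_loci > len(members):
            raise ValidationError(
                f"planted term {term_id} has {len(members)} member genes, "
                f"fewer than {n_loci} target loci",
                code="infeasible_plant",
            )
        member_order = list(rng.permutation(members))
        planted_info = {"term_id": term_id, "effect": effect,
                        "member_genes": members}
    positions, intervals = [], []
    half = spec.interval_length // 2
    for j in range(spec.n_intervals):
        label = f"rs{1000 + j}"
        planted_here = False
        if spec.planted_term is not None and j < spec.planted_term[1]:
            if rng.random() < spec.planted_term[2]:
                planted_here = True
        if planted_here:
            g = gene_by_id[member_order[j % len(member_order)]]
            chrom = g["chrom"]
            pos = (g["start"] + g["end"]) // 2
            planted_targets.append(label)
        else:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            pos = int(rng.integers(half + 1, spec.chrom_length - half))
        start = max(1, pos - half)
        end = min(spec.chrom_length, pos + (spec.interval_length - 1 - half))
        positions.append((chrom, pos, label))
        intervals.append(GenomicInterval(chrom, start, end, label=label, origin="user"))
    if planted_info is not None:
        planted_info["target_labels"] = planted_targets

    ld_tables = {
        label: generate_ld_table(label, chrom, pos, spec.ld_decay_bp, rng)
        for chrom, pos, label in positions
    }
    recomb = _recomb_map(chroms, spec.chrom_length, spec.hotspot_spacing_bp, rng)

    manifest = {
        "seed": spec.seed,
        "chrom_sizes": chrom_sizes,
        "genes": {
            g["gene_id"]: {"chrom": g["chrom"], "start": g["start"], "end": g["end"]}
            for g in genes
        },
        "diseases": disease_truth,
        "hpo_root": hpo_root,
        "do_root": do_root,
        "hpo_term_count": spec.n_terms + 2,  # live terms + root + obsolete
        "hpo_edge_count": hpo_edges,
        "do_edge_count": do_edges,
        "term_genes_closure": {
            t: sorted(g) for t, g in sorted(term_genes_closure.items())
        },
        "planted": planted_info,
        "interval_labels": [iv.label for iv in intervals],
    }
    return Fixture(
        spec=spec,
        chrom_sizes=chrom_sizes,
        gene_table=gene_table,
        association_tables={
            s: pd.DataFrame(rows) for s, rows in assoc_rows.items() if rows
        },
        description_tables=desc_tables,
        hpo_obo=hpo_obo,
        do_obo=do_obo,
        hpo_term_tables=hpo_tables,
        do_term_tables=do_tables,
        variants=pd.DataFrame(var_rows),
        positions=positions,
        intervals=intervals,
        ld_tables=ld_tables,
        recomb_map=recomb,
        manifest=manifest,
    )


def generate_null_dataset(spec: FixtureSpec) -> Fixture:
    """Bundle in which every term's enrichment null holds by construction.

    Each gene carries its own disease; term membership is a uniform random
    gene subset (labels permuted independently of position); test intervals
    are placed uniformly at random.
    """
    if spec.planted_term is not None:
        raise ValidationError(
            "null dataset cannot carry a planted term", code="bad_spec"
        )
    base = FixtureSpec(
        n_chrom=spec.n_chrom,
        chrom_length=spec.chrom_length,
        n_genes=spec.n_genes,
        n_diseases=spec.n_genes,
        n_terms=spec.n_terms,
        ontology_depth=1,
        ontology_branching=spec.n_terms,
        frac_termless_diseases=0.0,
        ld_decay_bp=spec.ld_decay_bp,
        hotspot_spacing_bp=spec.hotspot_spacing_bp,
        seed=spec.seed,
        n_intervals=spec.n_intervals,
        interval_length=spec.interval_length,
        n_variants=spec.n_variants,
        term_size_min=spec.term_size_min,
        term_size_max=spec.term_size_max,
    )
    rng = np.random.default_rng(spec.seed)
    chroms, genes = _place_genes(base, rng)
    chrom_sizes = {c: base.chrom_length for c in chroms}
    gene_table = _transcript_table(genes, rng)
    gene_ids = [g["gene_id"] for g in genes]

    hpo_obo, hpo_root, _, hpo_edges = _make_ontology(
        "HP", base.n_terms, 1, base.n_terms, rng
    )
    hpo_terms = [f"HP:{i:07d}" for i in range(1, base.n_terms + 1)]

    # one disease per gene; term -> random gene subset, independent of position
    assoc_rows = []
    disease_of = {}
    for i, g in enumerate(gene_ids, start=1):
        disease_id = f"DIS:{i:04d}"
        disease_of[g] = disease_id
        assoc_rows.append(
            {"gene_id": g, "disease_id": disease_id, "disease_name": f"Disease {i}"}
        )
    hpo_table: dict[str, set] = {}
    term_genes = {}
    for t in hpo_terms:
        size = int(rng.integers(spec.term_size_min, spec.term_size_max + 1))
        size = min(size, len(gene_ids))
        members = sorted(
            gene_ids[int(i)] for i in rng.choice(len(gene_ids), size, replace=False)
        )
        term_genes[t] = members
        for g in members:
            hpo_table.setdefault(disease_of[g], set()).add(t)

    positions, intervals = [], []
    half = base.interval_length // 2
    for j in range(base.n_intervals):
        label = f"rs{1000 + j}"
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos = int(rng.integers(half + 1, base.chrom_length - half))
        start = max(1, pos - half)
        end = min(base.chrom_length, pos + (base.interval_length - 1 - half))
        positions.append((chrom, pos, label))
        intervals.append(GenomicInterval(chrom, start, end, label=label, origin="user"))

    ld_tables = {
        label: generate_ld_table(label, chrom, pos, base.ld_decay_bp, rng)
        for chrom, pos, label in positions
    }
    recomb = _recomb_map(chroms, base.chrom_length, base.hotspot_spacing_bp, rng)

    manifest = {
        "seed": spec.seed,
        "null": True,
        "chrom_sizes": chrom_sizes,
        "genes": {
            g["gene_id"]: {"chrom": g["chrom"], "start": g["start"], "end": g["end"]}
            for g in genes
        },
        "hpo_root": hpo_root,
        "hpo_edge_count": hpo_edges,
        "term_genes_closure": {t: list(g) for t, g in sorted(term_genes.items())},
        "interval_labels": [iv.label for iv in intervals],
        "planted": None,
    }
    return Fixture(
        spec=base,
        chrom_sizes=chrom_sizes,
        gene_table=gene_table,
        association_tables={"OMIM": pd.DataFrame(assoc_rows)},
        description_tables={s: {} for s in DESC_SOURCES},
        hpo_obo=hpo_obo,
        do_obo=hpo_obo,  # schema completeness; DO mirrors HPO in null bundles
        hpo_term_tables={"OMIM": hpo_table, "ORPHANET": {}, "DECIPHER": {},
                         "HPO_OFFICIAL": {}},
        do_term_tables={s: {} for s in DO_SOURCES},
        variants=pd.DataFrame(
            columns=["variant_id", "chrom", "pos", "ref", "alt",
                     "clinical_significance", "gene_id", "disease_name"]
        ),
        positions=positions,
        intervals=intervals,
        ld_tables=ld_tables,
        recomb_map=recomb,
        manifest=manifest,
    )


def enrichment_inputs(fixture: Fixture):
    """In-memory pipeline objects for a bundle: (intervals, HPO annotation,
    genome). Runs the same integration/annotation code paths as the file
    route, without serialization."""
    from .data_model import attach_ontology_terms, canonical_genes, integrate_sources
    from .enrichment import Genome
    from .ontology import annotate_genes, parse_obo
    from .overlap import build_gene_regions

    transcripts = []
    from .data_model import GeneRecord

    for row in fixture.gene_table.itertuples(index=False):
        transcripts.append(
            GeneRecord(
                gene_id=row.gene_id, symbol=row.symbol, chrom=str(row.chrom),
                tx_start=int(row.tx_start), tx_end=int(row.tx_end),
                strand=row.strand, transcript_id=row.transcript_id,
                appris_principal=bool(row.appris_principal),
            )
        )
    genes = canonical_genes(transcripts)
    associations = integrate_sources(
        fixture.association_tables, known_gene_ids=genes
    )
    ontology = parse_obo(fixture.hpo_obo)
    attach_ontology_terms(associations, fixture.hpo_term_tables, ontology, "HPO")
    annotation = annotate_genes(associations, ontology, "HPO", label="HPO")
    background = {a.gene_id for a in associations}
    regions = build_gene_regions([genes[g] for g in sorted(background)])
    genome = Genome(chrom_sizes=dict(fixture.chrom_sizes), regions=regions)
    return list(fixture.intervals), annotation, genome


# ---------------------------------------------------------------------------
# serialization

def write_fixture(fixture: Fixture, outdir) -> Path:
    """Serialize the bundle; same spec/seed -> byte-identical files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    with open(out / "chrom_sizes.tsv", "w") as fh:
        for chrom, size in fixture.chrom_sizes.items():
            fh.write(f"{chrom}\t{size}\n")

    fixture.gene_table.to_csv(out / "genes.tsv", sep="\t", index=False)
    for source, df in sorted(fixture.association_tables.items()):
        df.to_csv(out / f"{source.lower()}.tsv", sep="\t", index=False)
    for source, table in sorted(fixture.description_tables.items()):
        with open(out / f"descriptions_{source.lower()}.tsv", "w") as fh:
            fh.write("disease_id\tdescription\n")
            for did in sorted(table):
                fh.write(f"{did}\t{table[did]}\n")
    (out / "hpo.obo").write_text(fixture.hpo_obo + "\n")
    (out / "do.obo").write_text(fixture.do_obo + "\n")
    for kind, tables in (("hpo", fixture.hpo_term_tables),
                         ("do", fixture.do_term_tables)):
        for source, table in sorted(tables.items()):
            with open(out / f"{kind}_terms_{source.lower()}.tsv", "w") as fh:
                fh.write("disease_id\tterm_id\n")
                for did in sorted(table):
                    for t in sorted(table[did]):
                        fh.write(f"{did}\t{t}\n")
    fixture.variants.to_csv(out / "variants.tsv", sep="\t", index=False)

    with open(out / "positions.txt", "w") as fh:
        for chrom, pos, label in fixture.positions:
            fh.write(f"{chrom}\t{pos}\t{label}\n")
    with open(out / "intervals.bed", "w") as fh:
        for iv in fixture.intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.label}\n")

    ld_dir = out / "ld"
    ld_dir.mkdir(exist_ok=True)
    for label, df in sorted(fixture.ld_tables.items()):
        df.to_csv(ld_dir / f"{label}.tsv", sep="\t", index=False)
    fixture.recomb_map.to_csv(out / "recomb_map.tsv", sep="\t", index=False)

    with open(out / "manifest.json", "w") as fh:
        json.dump(fixture.manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")

    config = _run_config(fixture, out)
    with open(out / "run_config.yaml", "w") as fh:
        fh.write(config)
    return out


def _run_config(fixture: Fixture, out: Path) -> str:
    """Ready-to-run pipeline config for the serialized bundle.

    Paths are relative to the bundle directory (the pipeline resolves them
    against the config file's location), so bundles are location-independent
    and byte-identical across runs.
    """
    lines = [
        "build: GRCh38",
        "route: intervals",
        "intervals_file: intervals.bed",
        "positions_file: positions.txt",
        "chrom_sizes: chrom_sizes.tsv",
        "gene_table: genes.tsv",
        "variant_table: variants.tsv",
        "ld_source_dir: ld",
        "recomb_map: recomb_map.tsv",
        "flank_left: 50000",
        "flank_right: 50000",
        "ld_stat: r2",
        "ld_threshold: 0.8",
        "extend_to_hotspot: false",
        "association_tables:",
    ]
    for source in sorted(fixture.association_tables):
        lines.append(f"  {source}: {source.lower()}.tsv")
    lines.append("description_tables:")
    for source in sorted(fixture.description_tables):
        lines.append(f"  {source}: descriptions_{source.lower()}.tsv")
    lines.append("ontologies:")
    lines += [
        "  HPO:",
        "    obo: hpo.obo",
        "    term_tables:",
    ]
    for source in sorted(fixture.hpo_term_tables):
        lines.append(f"      {source}: hpo_terms_{source.lower()}.tsv")
    lines += [
        "  DO:",
        "    obo: do.obo",
        "    term_tables:",
    ]
    for source in sorted(fixture.do_term_tables):
        lines.append(f"      {source}: do_terms_{source.lower()}.tsv")
    lines += [
        "gene_extension:",
        "  upstream: 0",
        "  downstream: 0",
        "  strand_aware: true",
        "enrichment:",
        "  mode: gene",
        "  n_perm: 200",
        "  n_boot: 100",
        "  seed: 1",
        "out_dir: results",
    ]
    return "\n".join(lines) + "\n"
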