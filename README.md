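# mendelprior

Gene prioritization at GWAS loci using Mendelian disease knowledge, as a
desk-scale library + CLI. The pipeline:

1. **Intervals** — turn lead positions into test intervals via fixed flanks,
   LD-proxy boundaries (optionally extended to the nearest recombination
   hotspot with rate > 3 cM/Mb), or accept user intervals (BED /
   `chrom:start-end`). Limits: ≤ 10 000 inputs, ≤ 20 Mbp per interval,
   flanks ≤ 10 Mbp, LD proxies within a 1 Mbp window around the index variant.
2. **Knowledge base** — merge gene–disease association tables from up to four
   sources (OMIM / Orphanet / DECIPHER / Genomics England schemas) on
   `(gene, disease)` with provenance, attach disease descriptions
   (OMIM > Orphanet > Uniprot > DO priority) and HPO/DO terms (union across
   sources), and pick each gene's canonical transcript (principal isoform,
   else longest).
3. **Overlap** — intersect intervals with (optionally up/downstream-extended,
   ≤ 20 kbp) canonical gene regions and with pathogenic / likely-pathogenic
   variants; collapse overlapping genes into clusters.
4. **Enrichment** — interval-permutation test of term → gene sets against the
   background of all Mendelian genes. Every permutation relocates each
   interval to a uniformly random placement of identical length covering the
   same number of gene clusters (confounder matching), in `gene` or
   `interval` mode. Empirical p = (1 + exceedances)/(1 + R1); family-wise
   correction bootstraps the minimum p across terms (R2 replicates).
5. **Report** — tab-delimited outputs (`mendelvar.log`, `input_file.bed`,
   `disease_overlap.txt`, `variant_overlap.txt`, `<ontology>.out.inrich`,
   `<ontology>.out.inrich.parsed`, `<ontology>.top_terms.tsv`) plus a
   best-effort ranked-term dot plot per ontology.

A first-class synthetic-data module generates complete seeded input bundles
(toy genome, transcripts, associations, OBO ontologies, LD tables,
recombination map, variants) with optional planted enrichment, so everything
runs offline.

## CLI

```sh
# generate a synthetic bundle (add --null for a no-signal bundle)
mendelprior synth --out bundle/ --seed 1

# full pipeline from the bundle's ready-made config
mendelprior run --config bundle/run_config.yaml

# intervals stage only
mendelprior intervals --config bundle/run_config.yaml --out intervals.bed

# run + print top enriched terms
mendelprior enrich --config bundle/run_config.yaml
```

The run config is YAML; relative paths resolve against the config file's
directory. Key sections: the input route (`route: flank|ld|intervals` plus
`positions_file`/`intervals_file`, `flank_left/right`, `ld_stat`,
`ld_threshold`, `population`, `extend_to_hotspot`, `hotspot_rate`),
knowledge-base paths (`gene_table`, `association_tables`,
`description_tables`, `variant_table`), `ontologies` (OBO files + per-source
term tables, `slim: auto` for direct root children or a term-list file),
optional GMT `gmt_annotations` for pathway sets, `gene_extension`, and
`enrichment` (`mode`, `n_perm`, `n_boot`, `seed`, term-size bounds,
`match_tolerance`). Exit codes: 0 ok, 2 validation error, 3 data error,
4 internal error.

## Layout

- `src/mendelprior/data_model.py` — knowledge-base schema, source
  integration, descriptions, ontology-term attachment, canonical transcripts
- `src/mendelprior/ontology.py` — OBO parsing, ancestor closure, slims,
  gene annotation
- `src/mendelprior/intervals.py` — flank/LD/user interval construction and
  validation
- `src/mendelprior/overlap.py` — interval×gene / interval×variant
  intersection, gene collapsing
- `src/mendelprior/enrichment.py` — relocation-matched permutation test and
  min-p bootstrap correction
- `src/mendelprior/synth.py` — synthetic fixture generator (planted and
  null bundles)
- `src/mendelprior/pipeline.py`, `report.py`, `cli.py` — driver, ranked-term
  report, command line
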