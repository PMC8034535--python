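import itertools

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mendelprior.data_model import (
    DiseaseGeneAssociation,
    GeneRecord,
    attach_descriptions,
    attach_ontology_terms,
    integrate_sources,
    select_canonical_transcript,
)
from mendelprior.errors import DataError, ValidationError
from mendelprior.runlog import RunLog


def table(pairs, name="Disease"):
    return pd.DataFrame(
        [
            {"gene_id": g, "disease_id": d, "disease_name": f"{name} {d}"}
            for g, d in pairs
        ]
    )


class TestIntegrateSources:
    def test_set_union_by_key(self):
        out = integrate_sources(
            {
                "OMIM": table([("g1", "D1")]),
                "ORPHANET": table([("g1", "D1"), ("g2", "D2")]),
            }
        )
        assert len(out) == 2
        by_key = {(a.gene_id, a.disease_id): a for a in out}
        assert by_key[("g1", "D1")].sources == {"OMIM", "ORPHANET"}
        assert by_key[("g2", "D2")].sources == {"ORPHANET"}

    def test_all_sources_empty(self):
        out = integrate_sources({s: table([]) for s in ("OMIM", "ORPHANET")})
        assert out == []

    def test_intra_source_duplicates_dropped_silently(self):
        log = RunLog()
        out = integrate_sources({"OMIM": table([("g1", "D1"), ("g1", "D1")])}, log=log)
        assert len(out) == 1
        assert log.counters == {}

    def test_unresolvable_gene_excluded_with_warning(self):
        log = RunLog()
        out = integrate_sources(
            {"OMIM": table([("g1", "D1"), ("gX", "D2")])},
            known_gene_ids={"g1"},
            log=log,
        )
        assert [(a.gene_id, a.disease_id) for a in out] == [("g1", "D1")]
        assert log.counters["unresolved_gene_associations"] == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_count_matches_brute_force_pair_enumeration(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        sources = ("OMIM", "ORPHANET", "DECIPHER", "GE")
        per_source = {}
        all_pairs = set()
        for s in sources:
            pairs = [
                (f"g{rng.integers(0, 12)}", f"D{rng.integers(0, 15)}")
                for _ in range(30)
            ]
            per_source[s] = table(pairs)
            all_pairs.update(pairs)
        out = integrate_sources(per_source)
        assert len(out) == len(all_pairs)
        # provenance: a pair's sources are exactly the tables containing it
        for a in out:
            expected = {
                s
                for s in sources
                if (a.gene_id, a.disease_id)
                in set(zip(per_source[s]["gene_id"], per_source[s]["disease_id"]))
            }
            assert a.sources == expected

    def test_idempotent_reintegration(self):
        first = integrate_sources(
            {
                "OMIM": table([("g1", "D1"), ("g2", "D2")]),
                "GE": table([("g1", "D1"), ("g3", "D3")]),
            }
        )
        # split the integrated set back into per-source tables and re-integrate
        per_source = {}
        for a in first:
            for s in a.sources:
                per_source.setdefault(s, []).append((a.gene_id, a.disease_id))
        second = integrate_sources({s: table(p) for s, p in per_source.items()})
        assert {(a.gene_id, a.disease_id, a.sources) for a in second} == {
            (a.gene_id, a.disease_id, a.sources) for a in first
        }

    def test_disease_alias_merges_series_members(self):
        out = integrate_sources(
            {
                "OMIM": table([("g1", "D1a")]),
                "ORPHANET": table([("g1", "D1b")]),
            },
            disease_alias={"D1a": "SER1", "D1b": "SER1"},
        )
        assert len(out) == 1
        assert out[0].disease_id == "SER1"
        assert out[0].sources == {"OMIM", "ORPHANET"}

    def test_disease_name_from_first_priority_source(self):
        out = integrate_sources(
            {
                "ORPHANET": table([("g1", "D1")], name="OrphaName"),
                "OMIM": table([("g1", "D1")], name="OmimName"),
            }
        )
        assert out[0].disease_name == "OmimName D1"

    def test_unknown_source_rejected(self):
        with pytest.raises(ValidationError):
            integrate_sources({"FOO": table([("g1", "D1")])})

    def test_omim_link_url(self):
        out = integrate_sources({"OMIM": table([("g1", "OMIM:125853")])})
        assert out[0].link_url == "https://www.omim.org/entry/125853"


def assoc(gene, disease):
    return DiseaseGeneAssociation(
        gene_id=gene, disease_id=disease, disease_name=disease,
        sources=frozenset({"OMIM"}),
    )


class TestAttachDescriptions:
    def test_priority_order(self):
        a = assoc("g1", "D1")
        attach_descriptions(
            [a],
            {"DO": {"D1": "do text"}, "ORPHANET": {"D1": "orpha text"}},
        )
        assert a.description == "orpha text"
        assert a.description_source == "ORPHANET"

    def test_absent_everywhere(self):
        a = assoc("g1", "D2")
        attach_descriptions([a], {"OMIM": {"D1": "x"}})
        assert a.description is None
        assert a.description_source is None

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_priority_scan_oracle(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        order = ("OMIM", "ORPHANET", "UNIPROT", "DO")
        diseases = [f"D{i}" for i in range(20)]
        tables = {
            s: {d: f"{s}:{d}" for d in diseases if rng.random() < 0.4} for s in order
        }
        assocs = [assoc(f"g{i}", d) for i, d in enumerate(diseases)]
        attach_descriptions(assocs, tables)
        for a in assocs:
            winner = next((s for s in order if a.disease_id in tables[s]), None)
            if winner is None:
                assert a.description is None
            else:
                assert a.description_source == winner
                assert a.description == tables[winner][a.disease_id]


class TestAttachOntologyTerms:
    def test_union_across_sources(self, chain_ontology):
        a = assoc("g1", "D1")
        attach_ontology_terms(
            [a],
            {"OMIM": {"D1": {"T:C"}}, "ORPHANET": {"D1": {"T:C", "T:B"}}},
            chain_ontology,
            "HPO",
            source_order=("OMIM", "ORPHANET"),
        )
        assert a.hpo_terms == {"T:C", "T:B"}

    def test_non_primary_only_counted(self, chain_ontology):
        log = RunLog()
        a = assoc("g1", "D1")
        attach_ontology_terms(
            [a],
            {"OMIM": {}, "ORPHANET": {"D1": {"T:B"}}},
            chain_ontology,
            "HPO",
            source_order=("OMIM", "ORPHANET"),
            log=log,
        )
        assert a.hpo_terms == {"T:B"}
        assert any("1 diseases" in msg for _, msg in log.events)

    def test_unknown_and_obsolete_terms_dropped(self, chain_ontology):
        log = RunLog()
        a = assoc("g1", "D1")
        attach_ontology_terms(
            [a],
            {"OMIM": {"D1": {"T:C", "T:NOPE", "T:OBS"}}},
            chain_ontology,
            "HPO",
            source_order=("OMIM",),
            log=log,
        )
        assert a.hpo_terms == {"T:C"}
        assert log.counters["unknown_hpo_terms"] == 1
        assert log.counters["obsolete_hpo_terms"] == 1

    def test_source_order_never_changes_term_sets(self, chain_ontology):
        tables = {"OMIM": {"D1": {"T:C"}}, "ORPHANET": {"D1": {"T:B"}}}
        results = []
        for order in itertools.permutations(("OMIM", "ORPHANET")):
            a = assoc("g1", "D1")
            attach_ontology_terms(
                [a], tables, chain_ontology, "HPO", source_order=order
            )
            results.append(frozenset(a.hpo_terms))
        assert len(set(results)) == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_set_union_oracle(self, seed, chain_ontology):
        import numpy as np

        rng = np.random.default_rng(seed)
        valid = ["T:A", "T:B", "T:C"]
        diseases = [f"D{i}" for i in range(10)]
        tables = {
            s: {
                d: {valid[int(i)] for i in rng.integers(0, 3, rng.integers(1, 3))}
                for d in diseases
                if rng.random() < 0.6
            }
            for s in ("OMIM", "ORPHANET", "DECIPHER", "HPO_OFFICIAL")
        }
        assocs = [assoc(f"g{i}", d) for i, d in enumerate(diseases)]
        attach_ontology_terms(assocs, tables, chain_ontology, "HPO")
        for a in assocs:
            expected = set()
            for t in tables.values():
                expected |= set(t.get(a.disease_id, ()))
            assert a.hpo_terms == expected


def tx(tid, length, principal=False, gene="g1"):
    return GeneRecord(
        gene_id=gene, symbol="G", chrom="1", tx_start=1000, tx_end=1000 + length - 1,
        strand="+", transcript_id=tid, appris_principal=principal,
    )


class TestSelectCanonicalTranscript:
    def test_principal_beats_longer(self):
        assert (
            select_canonical_transcript(
                [tx("tA", 1000, principal=True), tx("tB", 5000)]
            ).transcript_id
            == "tA"
        )

    def test_length_tie_broken_by_transcript_id(self):
        assert (
            select_canonical_transcript(
                [tx("ENST02", 2000), tx("ENST01", 2000)]
            ).transcript_id
            == "ENST01"
        )

    def test_multiple_principals_fall_back_to_length(self):
        got = select_canonical_transcript(
            [tx("tA", 1000, principal=True), tx("tB", 5000, principal=True)]
        )
        assert got.transcript_id == "tB"

    def test_empty_list_errors(self):
        with pytest.raises(DataError, match="no transcripts"):
            select_canonical_transcript([])

    def test_mixed_genes_rejected(self):
        with pytest.raises(DataError):
            select_canonical_transcript([tx("a", 10, gene="g1"), tx("b", 10, gene="g2")])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_argmax_oracle_on_50_transcripts(self, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        txs = [
            tx(f"t{int(i):03d}", int(rng.integers(100, 5000)),
               principal=bool(rng.random() < 0.05))
            for i in rng.permutation(50)
        ]
        got = select_canonical_transcript(txs)
        principals = [t for t in txs if t.appris_principal]
        if len(principals) == 1:
            assert got is principals[0]
        else:
            best = max(
                txs, key=lambda t: (t.transcript_length, [-ord(c) for c in t.transcript_id])
            )
            assert got.transcript_length == best.transcript_length
            assert got.transcript_id == min(
                t.transcript_id for t in txs
                if t.transcript_length == best.transcript_length
            )

    @settings(max_examples=30, deadline=None)
    @given(st.permutations(list(range(8))))
    def test_pure_function_under_permutation(self, perm):
        txs = [tx(f"t{i}", 100 * (1 + i % 4)) for i in range(8)]
        baseline = select_canonical_transcript(txs).transcript_id
        shuffled = [txs[i] for i in perm]
        assert select_canonical_transcript(shuffled).transcript_id == baseline
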