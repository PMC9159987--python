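"""Parental classification, maternal-lineage inference, hybrid formulas,
the reticulogram, and summary bookkeeping."""

import pytest

from reticulator.genotypes import parse_genotype_string
from reticulator.parentage import (
    HYBRID,
    PARENTAL,
    UNRESOLVED,
    GenotypeRecord,
    build_cooccurrence,
    build_parental_registry,
    build_reticulogram,
    identify_parental_genotypes,
    infer_all,
    infer_maternal_group,
    is_unknown,
    records_from_fixture,
    summarize,
)


def make_record(record_id, taxon, knox3, cp, ploidy=2, mode="apogamous"):
    genotypes = {}
    g = parse_genotype_string(knox3, record_id, "Knox3")
    if g is not None:
        genotypes["Knox3"] = g
    return GenotypeRecord(
        record_id=record_id, taxon=taxon, sample_ids=(record_id,),
        genotypes=genotypes, cp_haplotype=cp, ploidy=ploidy, mode=mode,
    )


class TestParentalClassification:
    def test_homozygote_is_parental_even_when_apogamous(self):
        records = [make_record("r1", "P. biaurita", "G1G1", "ci")]
        statuses = identify_parental_genotypes(records)
        assert statuses["r1"] == PARENTAL

    def test_sexual_same_group_heterozygote_is_parental(self):
        records = [make_record("r1", "P. minor", "A1A6", "cf'", mode="sexual")]
        assert identify_parental_genotypes(records)["r1"] == PARENTAL

    def test_two_group_diploid_is_hybrid(self):
        records = [make_record("r1", "P. cf. fauriei", "A4D7", "cf")]
        assert identify_parental_genotypes(records)["r1"] == HYBRID

    def test_apogamous_same_group_needs_homozygous_diploid_anchor(self):
        anchored = [
            make_record("anchor", "P. biaurita", "G1G1", "ci", ploidy=2),
            make_record("het", "P. biaurita", "G1G4", "ci"),
        ]
        statuses = identify_parental_genotypes(anchored)
        assert statuses["het"] == PARENTAL

        unanchored = [make_record("het", "P. biaurita", "G1G4", "ci")]
        assert identify_parental_genotypes(unanchored)["het"] == HYBRID

    def test_anchor_must_share_haplotype(self):
        records = [
            make_record("anchor", "P. wulaiensis", "D4D4", "cy", ploidy=2),
            make_record("het", "P. wulaiensis", "D2D4", "cd"),
        ]
        assert identify_parental_genotypes(records)["het"] == HYBRID

    def test_no_cp_haplotype_blocks_parental_status(self):
        records = [make_record("r1", "P. aff. confusa", "F1F1", None, ploidy=None)]
        assert identify_parental_genotypes(records)["r1"] == HYBRID

    def test_partition_into_parental_plus_hybrid(self, fixture_records,
                                                 fixture_inference):
        statuses = fixture_inference[0]
        assert set(statuses.values()) <= {PARENTAL, HYBRID}
        assert len(statuses) == len(fixture_records)


class TestCooccurrence:
    def test_fixture_headline_cooccurrences(self, fixture_inference):
        matrix = fixture_inference[1]
        assert matrix.counts["cf"]["A"] > 0
        assert matrix.counts["cb"]["A"] > 0
        assert matrix.counts["ca"]["D"] > 0

    def test_single_sample_single_cell(self):
        records = [make_record("r1", "t", "A7A7", "cb")]
        statuses = identify_parental_genotypes(records)
        matrix = build_cooccurrence(records, statuses)
        assert matrix.counts == {"cb": {"A": 1}}
        assert matrix.parental_counts == {"cb": {"A": 1}}

    def test_parental_counts_bounded_by_counts(self, fixture_inference):
        matrix = fixture_inference[1]
        for cp, groups in matrix.parental_counts.items():
            for group, n in groups.items():
                assert n <= matrix.counts[cp].get(group, 0)


class TestMaternalInference:
    def test_parental_carrier_rule_on_fixture(self, fixture_inference):
        matrix = fixture_inference[1]
        assert infer_maternal_group("cf", matrix).groups == {"A"}
        assert infer_maternal_group("cb", matrix).groups == {"A"}
        assert infer_maternal_group("ca", matrix).groups == {"D"}

    def test_universal_cooccurrence_fallback(self, fixture_inference):
        # ck has no parental carrier; H is present in every ck carrier.
        matrix = fixture_inference[1]
        call = infer_maternal_group("ck", matrix)
        assert call.groups == {"H"}
        assert call.basis == "universal"

    def test_ambiguity_fallthrough(self):
        records = [
            make_record("h1", "t1", "A1B1", "cz"),
            make_record("h2", "t2", "C1D1", "cz"),
        ]
        statuses = {r.record_id: HYBRID for r in records}
        matrix = build_cooccurrence(records, statuses)
        call = infer_maternal_group("cz", matrix)
        assert call.basis == "ambiguous"
        assert call.groups == {"A", "B", "C", "D"}

    def test_absent_haplotype_rejected(self, fixture_inference):
        with pytest.raises(KeyError, match="nope"):
            infer_maternal_group("nope", fixture_inference[1])


class TestHybridFormulas:
    def _formula_for(self, fixture_records, fixture_inference, record_id):
        formulas = fixture_inference[4]
        return {f.record_id: f for f in formulas}[record_id]

    def test_fauriei_formula_minor_x_latipinna(self, fixture_records,
                                               fixture_inference):
        f = self._formula_for(fixture_records, fixture_inference, "Chao2082")
        assert f.maternal_taxa == {"P. minor"}
        assert f.paternal_taxa == {"P. latipinna"}
        assert f.maternal_alleles == {"A1", "A6"}
        assert f.formula_string == "P. minor x P. latipinna"

    def test_arisanensis_maternal_of_F16G1(self, fixture_records,
                                           fixture_inference):
        f = self._formula_for(fixture_records, fixture_inference, "Chao2478")
        assert f.maternal_taxa == {"P. arisanensis"}
        assert f.paternal_taxa == {"P. biaurita"}

    def test_unknown_paternal_lineage_placeholder(self, fixture_records,
                                                  fixture_inference):
        f = self._formula_for(fixture_records, fixture_inference, "Chao1818")
        # cb's parental carrier is homozygous A7, pinning the maternal allele
        assert f.maternal_taxa == {"P. boninensis"}
        assert f.maternal_alleles == {"A7"}
        assert any(is_unknown(t) for t in f.paternal_taxa)
        assert f.formula_string.endswith("unknown")

    def test_intra_group_hybrid_sided_by_parental_carriers(
            self, fixture_records, fixture_inference):
        """D4D7 on a cy haplotype: both alleles are group D, but cy's
        parental carrier is the D4 homozygote, so D4 is maternal."""
        f = self._formula_for(fixture_records, fixture_inference, "Chao2035")
        assert f.maternal_taxa == {"P. wulaiensis"}
        assert f.paternal_taxa == {"P. latipinna"}
        assert f.formula_string == "P. wulaiensis x P. latipinna"

    def test_maternal_group_always_in_genotype(self, fixture_records,
                                               fixture_inference):
        from reticulator.io import allele_group

        by_id = {r.record_id: r for r in fixture_records}
        for f in fixture_inference[4]:
            if f.status != HYBRID:
                continue
            groups = {allele_group(a)
                      for a in by_id[f.record_id].distinct_alleles("Knox3")}
            assert f.maternal_groups & groups

    def test_no_nuclear_data_unresolved(self, fixture_records, fixture_inference):
        f = self._formula_for(fixture_records, fixture_inference, "Lu32448")
        assert f.status == UNRESOLVED


class TestReticulogram:
    def test_minimal_triangle(self):
        records = [
            make_record("m", "mat", "A1A1", "c1"),
            make_record("p", "pat", "B1B1", "c2"),
            make_record("h", "hyb", "A1B1", "c1"),
        ]
        statuses, matrix, maternal, registry, formulas = infer_all(records)
        graph = build_reticulogram(formulas, records, statuses)
        assert graph.number_of_nodes() == 3
        types = sorted(d["type"] for _, _, d in graph.edges(data=True))
        assert types == ["maternal", "paternal"]
        maternal_edge = [
            (u, v) for u, v, d in graph.edges(data=True) if d["type"] == "maternal"
        ]
        assert maternal_edge == [("mat|A1A1", "hyb|A1B1")]

    def test_latipinna_out_degree_dominates(self, fixture_records,
                                            fixture_inference):
        statuses, _, _, _, formulas = fixture_inference
        graph = build_reticulogram(formulas, fixture_records, statuses)
        out_deg = {
            n: graph.out_degree(n) for n, d in graph.nodes(data=True)
            if d.get("status") == PARENTAL and not d.get("dashed")
        }
        top = max(out_deg, key=out_deg.get)
        assert top == "P. latipinna|D7D7"

    def test_degree_dominance_is_data_driven(self, fixture_records):
        """Removing the D7-carrying hybrids dethrones the D7 lineage."""
        pruned = [
            r for r in fixture_records
            if "D7" not in r.distinct_alleles("Knox3")
            or len(set(r.distinct_alleles("Knox3"))) == 1
        ]
        statuses, _, _, _, formulas = infer_all(pruned)
        graph = build_reticulogram(formulas, pruned, statuses)
        out_deg = {
            n: graph.out_degree(n) for n, d in graph.nodes(data=True)
            if d.get("status") == PARENTAL and not d.get("dashed")
        }
        assert max(out_deg, key=out_deg.get) != "P. latipinna|D7D7"

    def test_parental_nodes_have_no_in_edges(self, fixture_records,
                                             fixture_inference):
        statuses, _, _, _, formulas = fixture_inference
        graph = build_reticulogram(formulas, fixture_records, statuses)
        for node, data in graph.nodes(data=True):
            if data.get("status") == PARENTAL:
                assert graph.in_degree(node) == 0

    def test_incomplete_flag_when_a_side_is_missing(self, fixture_records,
                                                    fixture_inference):
        statuses, _, _, _, formulas = fixture_inference
        graph = build_reticulogram(formulas, fixture_records, statuses)
        # P. confusa has no nuclear data at all: both sides missing.
        assert graph.nodes["P. confusa|-"]["incomplete"] is True

    def test_exports_are_writable(self, tmp_path, fixture_records,
                                  fixture_inference):
        from reticulator.parentage import write_dot, write_gml

        statuses, _, _, _, formulas = fixture_inference
        graph = build_reticulogram(formulas, fixture_records, statuses)
        write_gml(graph, tmp_path / "net.gml")
        write_dot(graph, tmp_path / "net.dot")
        dot = (tmp_path / "net.dot").read_text()
        assert "color=red" in dot and "color=blue" in dot
        assert (tmp_path / "net.gml").stat().st_size > 0


class TestSummary:
    def test_empty_input_all_zero(self):
        summary = summarize([], {}, [])
        assert summary.total_genotypes == 0
        assert summary.parental_genotypes == 0
        assert summary.hybrid_genotypes == 0
        assert summary.hybrids_per_parental_taxon == {}

    def test_constructed_three_parent_four_hybrid(self):
        records = [
            make_record("p1", "t1", "A1A1", "c1"),
            make_record("p2", "t2", "B1B1", "c2"),
            make_record("p3", "t3", "C1C1", "c3"),
            make_record("h1", "x1", "A1B1", "c1"),
            make_record("h2", "x2", "A1C1", "c1"),
            make_record("h3", "x3", "B1C1", "c2"),
            make_record("h4", "x4", "A1B1", "c2", ploidy=3),
        ]
        statuses, _, _, _, formulas = infer_all(records)
        summary = summarize(records, statuses, formulas)
        assert summary.total_genotypes == 7
        assert summary.parental_genotypes == 3
        assert summary.hybrid_genotypes == 4
        assert summary.hybrids_per_parental_taxon["t1"]["either"] == 3
        assert summary.hybrids_per_parental_taxon["t1"]["maternal"] == 2

    def test_role_counts_nest(self, fixture_inference, fixture_records):
        statuses, _, _, _, formulas = fixture_inference
        summary = summarize(fixture_records, statuses, formulas)
        for taxon, roles in summary.hybrids_per_parental_taxon.items():
            assert roles["either"] <= roles["maternal"] + roles["paternal"]
            assert roles["either"] >= max(roles["maternal"], roles["paternal"])
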