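"""Catalog ingestion: validation, deduplication, merge semantics."""

import pandas as pd
import pytest

from snvprofiler.catalogs import (
    IngestionError,
    classify_origin,
    load_proteome,
    load_site_sources,
    load_variant_sources,
    total_length,
    VariantRecord,
)


def write_fasta(path, entries):
    path.write_text("".join(f">{h}\n{s}\n" for h, s in entries))


def vrow(**kw):
    row = {
        "accession": "P1", "position": 2, "ref_aa": "K", "alt_aa": "R",
        "sources": "COSMIC", "in_dbsnp": 0, "do_terms": "", "pmids": "",
        "sample_id": "",
    }
    row.update(kw)
    return row


class TestLoadProteome:
    def test_three_records_and_total_length(self, tmp_path):
        f = tmp_path / "p.fa"
        write_fasta(f, [("A1", "MKT"), ("A2", "GGSS"), ("A3", "WYYYY")])
        prot = load_proteome(f)
        assert [p.accession for p in prot] == ["A1", "A2", "A3"]
        assert total_length(prot) == 12

    def test_lowercase_residues_uppercased(self, tmp_path):
        f = tmp_path / "p.fa"
        write_fasta(f, [("A1", "mktay")])
        assert load_proteome(f)[0].sequence == "MKTAY"

    def test_duplicate_accession_names_offender(self, tmp_path):
        f = tmp_path / "p.fa"
        write_fasta(f, [("A1", "MKT"), ("A1", "GGG")])
        with pytest.raises(IngestionError, match="A1"):
            load_proteome(f)

    def test_empty_file_rejected(self, tmp_path):
        f = tmp_path / "p.fa"
        f.write_text("")
        with pytest.raises(IngestionError):
            load_proteome(f)


class TestVariantMerge:
    def test_same_variant_from_two_sources_merges(self, toy_proteome):
        a = pd.DataFrame([vrow(sources="COSMIC")])
        b = pd.DataFrame([vrow(sources="TCGA", in_dbsnp=1)])
        variants, report = load_variant_sources([a, b], toy_proteome)
        assert len(variants) == 1
        v = variants[0]
        assert v.sources == {"COSMIC", "TCGA"}
        assert v.in_dbsnp  # OR semantics
        assert report["merged_duplicates"] == 1

    def test_wild_type_mismatch_dropped_and_counted(self, toy_proteome):
        bad = pd.DataFrame([vrow(ref_aa="R", alt_aa="Q")])  # proteome has K at P1:2
        variants, report = load_variant_sources([bad], toy_proteome)
        assert variants == []
        assert report["dropped_ref_mismatch"] == 1

    @pytest.mark.parametrize(
        "row,counter",
        [
            (vrow(accession="NOPE"), "dropped_unknown_accession"),
            (vrow(position="x"), "dropped_bad_position"),
            (vrow(position=999), "dropped_bad_position"),
            (vrow(alt_aa="K"), "dropped_bad_residue"),  # ref == alt
        ],
    )
    def test_malformed_rows_reported(self, toy_proteome, row, counter):
        variants, report = load_variant_sources([pd.DataFrame([row])], toy_proteome)
        assert variants == []
        assert report[counter] == 1

    def test_empty_input_gives_empty_catalog(self, toy_proteome):
        variants, report = load_variant_sources([], toy_proteome)
        assert variants == [] and report["rows_read"] == 0

    def test_merge_is_idempotent(self, toy_proteome):
        table = pd.DataFrame([vrow(), vrow(position=5, ref_aa="Y", alt_aa="F")])
        once, _ = load_variant_sources([table], toy_proteome)
        twice, _ = load_variant_sources([table, table], toy_proteome)
        assert once == twice

    def test_input_order_does_not_matter(self, toy_proteome):
        a = pd.DataFrame([vrow(sources="COSMIC")])
        b = pd.DataFrame([vrow(sources="TCGA"), vrow(position=5, ref_aa="Y", alt_aa="F")])
        ab, _ = load_variant_sources([a, b], toy_proteome)
        ba, _ = load_variant_sources([b, a], toy_proteome)
        assert ab == ba

    def test_provenance_is_conserved_across_merge(self, toy_proteome):
        tables = [
            pd.DataFrame([vrow(sources="COSMIC;TCGA")]),
            pd.DataFrame([vrow(sources="ICGC"), vrow(position=5, ref_aa="Y", alt_aa="F", sources="dbSNP")]),
        ]
        variants, _ = load_variant_sources(tables, toy_proteome)
        merged_tags = set().union(*(v.sources for v in variants))
        assert merged_tags == {"COSMIC", "TCGA", "ICGC", "dbSNP"}


class TestOrigin:
    def test_dbsnp_membership_is_germline_even_from_cosmic(self):
        v = VariantRecord("P1", 2, "K", "R", sources=frozenset({"COSMIC"}), in_dbsnp=True)
        assert classify_origin(v) == "germline"

    def test_not_in_dbsnp_is_somatic(self):
        v = VariantRecord("P1", 2, "K", "R", in_dbsnp=False)
        assert classify_origin(v) == "somatic"


class TestSiteLoading:
    def srow(self, **kw):
        row = {"accession": "P3", "position": 1, "end": 1,
               "subtype": "Active site", "source": "CDD"}
        row.update(kw)
        return row

    def test_span_of_six_excluded(self, toy_proteome):
        t = pd.DataFrame([self.srow(position=1, end=6)])
        sites, report = load_site_sources([t], toy_proteome)
        assert sites == [] and report["dropped_long_span"] == 1

    def test_span_of_five_expanded_per_residue(self, toy_proteome):
        t = pd.DataFrame([self.srow(position=3, end=7)])
        sites, _ = load_site_sources([t], toy_proteome)
        assert [s.position for s in sites] == [3, 4, 5, 6, 7]
        assert all(s.category == "Active site" for s in sites)

    def test_phosphoserine_maps_to_phosphorylation(self, toy_proteome):
        t = pd.DataFrame([{"accession": "P3", "position": 4,
                           "subtype": "Phosphoserine", "source": "UniProt"}])
        sites, _ = load_site_sources([t], toy_proteome, {"Phosphoserine": "Phosphorylation"})
        assert len(sites) == 1 and sites[0].category == "Phosphorylation"

    def test_unmapped_subtype_warned_not_fatal(self, toy_proteome):
        t = pd.DataFrame([{"accession": "P3", "position": 4,
                           "subtype": "Mystery mark", "source": "x"}])
        sites, report = load_site_sources([t], toy_proteome, {})
        assert sites == [] and report["unmapped_subtype"] == 1

    def test_out_of_range_position_reported(self, toy_proteome):
        t = pd.DataFrame([self.srow(position=99, end=99)])
        sites, report = load_site_sources([t], toy_proteome)
        assert sites == [] and report["dropped_out_of_range"] == 1

    def test_duplicate_sites_merge_sources(self, toy_proteome):
        a = pd.DataFrame([self.srow(source="CDD")])
        b = pd.DataFrame([self.srow(source="UniProt")])
        sites, report = load_site_sources([a, b], toy_proteome)
        assert len(sites) == 1
        assert sites[0].sources == {"CDD", "UniProt"}
        assert report["merged_duplicates"] == 1
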