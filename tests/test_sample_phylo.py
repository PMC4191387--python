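"""SNV condensation, p-distances, neighbor joining, sample profiles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from snvprofiler.catalogs import ProteinRecord, VariantRecord
from snvprofiler.disruption import scan
from snvprofiler.sample_phylo import (
    PhyloInputError,
    condense,
    distance_matrix,
    nj_tree,
    sample_profiles,
)


def var(acc, pos, ref, alt, sid):
    return VariantRecord(acc, pos, ref, alt, sample_ids=frozenset({sid}))


class TestCondense:
    ref = {"chr": "TACGG"}

    def test_single_locus_no_flank(self):
        aln = condense(
            {"s1": [var("chr", 2, "A", "G", "s1")], "s2": []}, self.ref, k=0
        )
        assert aln.sequences == {"s1": "G", "s2": "A"}

    def test_single_locus_with_flank(self):
        aln = condense(
            {"s1": [var("chr", 2, "A", "G", "s1")], "s2": []}, self.ref, k=1
        )
        assert aln.sequences == {"s1": "TGC", "s2": "TAC"}

    def test_boundary_truncation_keeps_lengths_equal(self):
        aln = condense(
            {"s1": [var("chr", 1, "T", "A", "s1")], "s2": [var("chr", 5, "G", "C", "s2")]},
            self.ref, k=2,
        )
        lengths = {len(s) for s in aln.sequences.values()}
        assert len(lengths) == 1
        # locus 1 truncates the left flank (3 chars), locus 5 the right (3 chars)
        assert lengths == {6}

    def test_interior_length_formula(self):
        samples = {"s1": [var("chr", 3, "C", "A", "s1")], "s2": []}
        for k in range(3):
            aln = condense(samples, self.ref, k=k)
            assert all(len(s) == 2 * k + 1 for s in aln.sequences.values())

    def test_reference_mismatch_names_locus(self):
        with pytest.raises(PhyloInputError, match="chr:2"):
            condense({"s1": [var("chr", 2, "C", "G", "s1")]}, self.ref, k=0)

    def test_flank_bound_enforced(self):
        with pytest.raises(PhyloInputError):
            condense({"s1": []}, self.ref, k=4)


class TestDistances:
    def test_identical_samples_zero(self):
        aln = condense(
            {"s1": [var("chr", 2, "A", "G", "s1")], "s2": [var("chr", 2, "A", "G", "s2")]},
            {"chr": "TACGG"}, k=1,
        )
        assert distance_matrix(aln).loc["s1", "s2"] == 0.0

    def test_all_columns_differ(self):
        aln = condense(
            {"s1": [var("chr", 2, "A", "G", "s1")], "s2": [var("chr", 2, "A", "C", "s2")]},
            {"chr": "TACGG"}, k=0,
        )
        assert distance_matrix(aln).loc["s1", "s2"] == 1.0

    def test_three_sample_hand_computation(self):
        ref = {"chr": "AAAAA"}
        samples = {
            "s1": [var("chr", 1, "A", "C", "s1"), var("chr", 3, "A", "G", "s1")],
            "s2": [var("chr", 1, "A", "C", "s2")],
            "s3": [],
        }
        d = distance_matrix(condense(samples, ref, k=0))
        assert d.loc["s1", "s2"] == pytest.approx(1 / 2)
        assert d.loc["s1", "s3"] == pytest.approx(2 / 2)
        assert d.loc["s2", "s3"] == pytest.approx(1 / 2)

    def test_metric_on_cohort(self, small_bundle):
        aln = condense(small_bundle.cohort, small_bundle.proteome, k=0)
        d = distance_matrix(aln).values
        n = d.shape[0]
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)
        for i, j, k in itertools.permutations(range(n), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


def patristic(newick):
    import dendropy

    tree = dendropy.Tree.get(data=newick, schema="newick")
    dm = tree.phylogenetic_distance_matrix()
    out = {}
    for t1, t2 in itertools.combinations(tree.taxon_namespace, 2):
        out[frozenset({t1.label, t2.label})] = dm.distance(t1, t2)
    return out


class TestNeighborJoining:
    def test_additive_four_taxon_distances_recovered_exactly(self):
        # tree ((A:2,B:3):1,C:4,D:5) -> additive distance matrix
        dist = pd.DataFrame(
            [[0, 5, 7, 8], [5, 0, 8, 9], [7, 8, 0, 9], [8, 9, 9, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        newick = nj_tree(dist)
        got = patristic(newick)
        for pair, expected in {
            frozenset("AB"): 5, frozenset("AC"): 7, frozenset("AD"): 8,
            frozenset("BC"): 8, frozenset("BD"): 9, frozenset("CD"): 9,
        }.items():
            assert got[pair] == pytest.approx(expected, abs=1e-9)

    def test_fewer_than_three_taxa_rejected(self):
        d = pd.DataFrame([[0, 1], [1, 0]], index=["a", "b"], columns=["a", "b"], dtype=float)
        with pytest.raises(PhyloInputError):
            nj_tree(d)

    def test_all_equal_distances_deterministic(self):
        ids = list("abcde")
        d = pd.DataFrame(1.0, index=ids, columns=ids)
        np.fill_diagonal(d.values, 0.0)
        assert nj_tree(d) == nj_tree(d.copy())

    def test_duplicate_sample_forms_zero_length_cherry(self, small_bundle):
        cohort = dict(small_bundle.cohort)
        first = next(iter(cohort))
        twin = [
            VariantRecord(v.accession, v.position, v.ref_aa, v.alt_aa,
                          sample_ids=frozenset({"TWIN"}))
            for v in cohort[first]
        ]
        cohort["TWIN"] = twin
        aln = condense(cohort, small_bundle.proteome, k=0)
        newick = nj_tree(distance_matrix(aln))
        assert patristic(newick)[frozenset({first, "TWIN"})] == pytest.approx(0.0, abs=1e-12)

    def test_topology_matches_scikit_bio(self, small_bundle):
        import dendropy
        from skbio import DistanceMatrix
        from skbio.tree import nj

        aln = condense(small_bundle.cohort, small_bundle.proteome, k=0)
        d = distance_matrix(aln)
        import io

        ours = nj_tree(d)
        buf = io.StringIO()
        nj(DistanceMatrix(d.values, ids=list(d.index))).write(buf)
        theirs = buf.getvalue()
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=ours, schema="newick", taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=theirs, schema="newick", taxon_namespace=tns)
        t1.encode_bipartitions(), t2.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0


class TestSampleProfiles:
    def test_untouched_category_dropped_and_overlay_consistent(self, small_bundle):
        cohort_variants = [v for recs in small_bundle.cohort.values() for v in recs]
        calls, _ = scan(cohort_variants, small_bundle.sites, small_bundle.proteome)
        results, profile, presence = sample_profiles(
            calls, cohort_variants, small_bundle.sites, small_bundle.proteome
        )
        observed = {}
        for r in results:
            observed[r.category] = observed.get(r.category, 0) + r.n_O
        for cat, total in observed.items():
            assert (cat in profile.values.columns) == (total > 0)
        assert set(presence.columns) == set(profile.values.columns)
        assert presence.values.max() <= 1

    def test_single_sample_skips_clustering(self):
        prot = [ProteinRecord("P1", "AAKAA")]
        from snvprofiler.catalogs import FunctionalSite

        sites = [FunctionalSite("P1", 3, "Acetylation")]
        v = var("P1", 3, "K", "E", "only")
        calls, _ = scan([v], sites, prot)
        results, profile, presence = sample_profiles(calls, [v], sites, prot)
        assert profile.row_newick is None
        assert list(profile.values.index) == ["only"]
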