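"""Binomial observed/expected statistics and profile clustering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import poisson

from snvprofiler.catalogs import FunctionalSite, ProteinRecord, VariantRecord
from snvprofiler.disruption import scan
from snvprofiler.enrichment import (
    EnrichmentInputError,
    benjamini_hochberg,
    binomial_tail_pvalue,
    category_profile,
    cluster_profile,
    expected_count,
    results_to_matrix,
    term_enrichment,
)

N_PROTEOME = 1_705_285  # distinct nsSNVs in the reference survey


def brute_force_tail(n_O, N, p, direction):
    """Direct pmf summation oracle (exact rational-ish via log terms)."""
    ks = range(n_O, N + 1) if direction == "over" else range(0, n_O + 1)
    return sum(math.comb(N, k) * p**k * (1 - p) ** (N - k) for k in ks)


class TestExpectedCount:
    def test_arithmetic(self):
        assert expected_count(10, 5, 50) == 1.0

    def test_zero_sites(self):
        assert expected_count(10, 0, 50) == 0.0

    def test_zero_length_rejected(self):
        with pytest.raises(EnrichmentInputError):
            expected_count(10, 5, 0)

    def test_acetylation_expectation_from_inferred_proteome_length(self):
        # proteome length recovered by inverting the phosphorylation row
        L = N_PROTEOME * 77_734 / 11_706.50734
        assert expected_count(N_PROTEOME, 8_253, int(round(L))) == pytest.approx(
            1242.877056, rel=1e-4
        )


class TestBinomialTail:
    def test_all_successes_closed_form(self):
        p, direction = binomial_tail_pvalue(10, 10, 0.5)
        assert direction == "over"
        assert p == pytest.approx(0.5**10, rel=1e-12)

    @pytest.mark.parametrize(
        "n_O,N,p,direction",
        [(3, 20, 0.3, "under"), (9, 20, 0.3, "over"), (0, 15, 0.1, "under"), (7, 7, 0.9, "over")],
    )
    def test_matches_direct_summation(self, n_O, N, p, direction):
        got, d = binomial_tail_pvalue(n_O, N, p)
        assert d == direction
        assert got == pytest.approx(brute_force_tail(n_O, N, p, direction), rel=1e-12)

    def test_printed_underrepresented_row(self):
        # C-linked glycosylation: observed 4 against expectation 10.84
        p, d = binomial_tail_pvalue(4, N_PROTEOME, 10.84298413 / N_PROTEOME)
        assert d == "under" and p == pytest.approx(1.68e-2, rel=0.05)

    def test_printed_overrepresented_row(self):
        # amidation: observed 9 against expectation 5.57
        p, d = binomial_tail_pvalue(9, N_PROTEOME, 5.572089069 / N_PROTEOME)
        assert d == "over" and p == pytest.approx(1.12e-1, rel=0.05)

    def test_tail_complementarity(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            N = int(rng.integers(10, 10_000))
            p = float(rng.uniform(0.001, 0.999))
            n_O = int(rng.integers(0, N + 1))
            lower, _ = binomial_tail_pvalue(n_O, N, p, alternative="under")
            upper, _ = binomial_tail_pvalue(n_O, N, p, alternative="over")
            pmf = math.exp(
                math.lgamma(N + 1) - math.lgamma(n_O + 1) - math.lgamma(N - n_O + 1)
                + n_O * math.log(p) + (N - n_O) * math.log1p(-p)
            )
            assert lower + upper == pytest.approx(1 + pmf, rel=1e-12)

    def test_poisson_limit(self):
        N = 200_000
        for mu in (1.0, 10.0, 50.0):
            pF = mu / N
            for n_O in (int(mu * 0.5), int(mu), int(mu * 2) + 1):
                b, d = binomial_tail_pvalue(n_O, N, pF)
                if d == "over":
                    pp = poisson.sf(n_O - 1, mu)
                else:
                    pp = poisson.cdf(n_O, mu)
                assert b == pytest.approx(pp, rel=0.01)

    @settings(derandomize=True, max_examples=50)
    @given(
        N=st.integers(20, 2000),
        pF=st.floats(0.01, 0.5),
        n=st.integers(0, 1999),
    )
    def test_upper_tail_monotone_in_observed_count(self, N, pF, n):
        n = n % N
        hi, _ = binomial_tail_pvalue(n, N, pF, alternative="over")
        hi2, _ = binomial_tail_pvalue(n + 1, N, pF, alternative="over")
        assert hi2 <= hi + 1e-15

    @pytest.mark.parametrize("bad_p", [0.0, 1.0, -0.1, 1.5])
    def test_degenerate_probability_rejected(self, bad_p):
        with pytest.raises(EnrichmentInputError):
            binomial_tail_pvalue(1, 10, bad_p)


class TestCategoryProfile:
    def _toy(self):
        prot = [ProteinRecord("P1", "AAKAASAAKA")]
        sites = [
            FunctionalSite("P1", 3, "Acetylation"),
            FunctionalSite("P1", 6, "Phosphorylation"),
        ]
        variants = [
            VariantRecord("P1", 3, "K", "E", sources=frozenset({"COSMIC"})),
            VariantRecord("P1", 6, "S", "L", sources=frozenset({"TCGA"}), in_dbsnp=True),
        ]
        calls, _ = scan(variants, sites, prot)
        return calls, variants, sites, prot

    def test_difference_and_expectation_semantics(self):
        calls, variants, sites, prot = self._toy()
        res = {r.category: r for r in category_profile(calls, variants, sites, prot)}
        r = res["Acetylation"]
        assert r.N == 2 and r.n_F == 1 and r.L == 10
        assert r.n_E == pytest.approx(2 * 1 / 10)
        assert r.difference == pytest.approx(1 - 0.2)
        assert r.direction == "over"

    def test_empty_stratum_is_degenerate(self):
        calls, variants, sites, prot = self._toy()
        res = category_profile(calls, [], sites, prot)
        assert all(r.degenerate and r.p_value == 1.0 and r.N == 0 for r in res)

    def test_origin_strata_partition_variants(self):
        calls, variants, sites, prot = self._toy()
        res = category_profile(calls, variants, sites, prot, ("origin",))
        by = {(r.stratum, r.category): r for r in res}
        assert by[("origin:germline", "Phosphorylation")].n_O == 1
        assert by[("origin:somatic", "Acetylation")].n_O == 1
        assert by[("origin:somatic", "Phosphorylation")].n_O == 0


class TestTermEnrichment:
    term_map = {
        "g1": {"kinase"}, "g2": {"kinase"}, "g3": {"kinase", "binding"},
        "g4": {"binding"}, "g5": set(), "g6": {"kinase"},
        "g7": {"binding"}, "g8": set(), "g9": {"kinase"}, "g10": {"ubiquitous"},
    }
    background = set(term_map)

    def test_toy_universe_matches_brute_force(self):
        affected = {"g1", "g2", "g3", "g6"}
        res = {r.category: r for r in term_enrichment(affected, self.background, self.term_map)}
        kin = res["kinase"]
        assert kin.n_O == 4
        expect = brute_force_tail(4, 4, 5 / 10, "over")
        assert kin.p_value == pytest.approx(expect, rel=1e-9)
        assert kin.direction == "over"

    def test_universal_term_degenerate(self):
        term_map = {g: {"everywhere"} for g in "abc"}
        res = term_enrichment({"a"}, {"a", "b", "c"}, term_map)
        assert res[0].degenerate and res[0].p_value == 1.0

    def test_saturated_affected_set_not_significant(self):
        res = term_enrichment(self.background, self.background, self.term_map)
        assert all(r.p_value > 0.05 for r in res)

    def test_affected_must_be_subset(self):
        with pytest.raises(EnrichmentInputError):
            term_enrichment({"zz"}, self.background, self.term_map)


class TestClustering:
    def test_identical_rows_join_at_zero_distance(self):
        import pandas as pd

        mat = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [5.0, 9.0]],
                           index=["a", "b", "c"], columns=["x", "y"])
        prof = cluster_profile(mat)
        assert "(a:0,b:0)" in prof.row_newick.replace(" ", "")

    def test_constant_matrix_keeps_input_order(self):
        import pandas as pd

        mat = pd.DataFrame(0.0, index=["r1", "r2", "r3"], columns=["c1", "c2"])
        prof = cluster_profile(mat)
        assert prof.row_order == ["r1", "r2", "r3"]

    def test_sign_convention_matches_direction(self):
        prot = [ProteinRecord("P1", "AAKAASAAKA")]
        sites = [FunctionalSite("P1", 3, "Acetylation")]
        variants = [VariantRecord("P1", 3, "K", "E", sources=frozenset({"s"}))]
        calls, _ = scan(variants, sites, prot)
        res = category_profile(calls, variants, sites, prot)
        mat = results_to_matrix(res)
        assert mat.loc["total", "Acetylation"] > 0  # overrepresented => positive


def test_benjamini_hochberg_against_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(1)
    p = rng.uniform(0, 1, 40)
    ours = benjamini_hochberg(p)
    theirs = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(ours, theirs)
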