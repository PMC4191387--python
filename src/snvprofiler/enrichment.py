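"""Observed-vs-expected disruption statistics.

The null model: if nsSNVs fell uniformly along the proteome, the chance
that one lands on a site of category F is p(F) = n(F)/L, where n(F) is the
number of annotated positions of that category and L the total proteome
length.  Among N variants the expected number hitting the category is
n(E) = N*p(F), and the observed count n(O) is referred to an exact
Binomial(N, p(F)) tail, one-sided and inclusive of the observed value, in
the direction of deviation: P(X >= n(O)) when n(O) >= n(E), else
P(X <= n(O)).  Tails are computed through the regularised incomplete beta
function, so values far below double-precision log-precision thresholds
(e.g. 1e-273) are exact rather than normal approximations.

Raw P-values are reported (no multiple-testing correction by default);
``benjamini_hochberg`` adds an optional FDR column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import binom

from .catalogs import (
    FunctionalSite,
    ProteinRecord,
    VariantRecord,
    total_length,
)
from .disruption import DisruptionCall


class EnrichmentInputError(ValueError):
    pass


@dataclass(frozen=True)
class EnrichmentResult:
    """One (category, stratum) cell of the enrichment profile."""

    category: str
    stratum: str
    n_O: int
    n_F: int
    N: int
    L: int
    p_value: float
    direction: str
    degenerate: bool = False

    @property
    def p_F(self) -> float:
        return self.n_F / self.L if self.L else float("nan")

    @property
    def n_E(self) -> float:
        return expected_count(self.N, self.n_F, self.L)

    @property
    def difference(self) -> float:
        return self.n_O - self.n_E


def expected_count(N: int, n_F: int, L: int) -> float:
    """Expected disrupted count n(E) = N * n(F) / L (no rounding)."""
    if L <= 0:
        raise EnrichmentInputError("proteome length L must be positive")
    if not 0 <= n_F <= L:
        raise EnrichmentInputError("n_F must satisfy 0 <= n_F <= L")
    return N * n_F / L


def binomial_tail_pvalue(
    n_O: int, N: int, p_F: float, alternative: str = "auto"
) -> tuple[float, str]:
    """Exact one-sided inclusive binomial tail and its direction.

    ``alternative='auto'`` tests in the direction of deviation from the
    expectation N*p_F; ``'over'``/``'under'`` force the tail.
    """
    if not 0 < p_F < 1:
        raise EnrichmentInputError(f"p_F must lie in (0, 1), got {p_F}")
    if not 0 <= n_O <= N:
        raise EnrichmentInputError(f"n_O={n_O} outside [0, N={N}]")
    if alternative == "auto":
        alternative = "over" if n_O >= N * p_F else "under"
    if alternative == "over":
        # inclusive upper tail P(X >= n_O)
        p = float(binom.sf(n_O - 1, N, p_F))
    elif alternative == "under":
        p = float(binom.cdf(n_O, N, p_F))
    else:
        raise EnrichmentInputError(f"unknown alternative {alternative!r}")
    return min(p, 1.0), alternative


# ---------------------------------------------------------------------------
# stratified category profiles

_STRATA_AXES = ("total", "source", "origin", "do_term", "sample")


def _stratum_members(
    variants: Sequence[VariantRecord], axis: str
) -> dict[str, set[tuple]]:
    """Map stratum label -> set of variant keys belonging to it."""
    out: dict[str, set[tuple]] = {}
    if axis == "total":
        out["total"] = {v.key for v in variants}
        return out
    for v in variants:
        if axis == "source":
            labels = v.sources
        elif axis == "origin":
            labels = {v.origin}
        elif axis == "do_term":
            labels = v.do_terms
        elif axis == "sample":
            labels = v.sample_ids
        else:
            raise EnrichmentInputError(f"unknown stratum axis {axis!r}")
        for label in labels:
            out.setdefault(label, set()).add(v.key)
    return out


def category_profile(
    calls: Sequence[DisruptionCall],
    variants: Sequence[VariantRecord],
    sites: Sequence[FunctionalSite],
    proteome: Sequence[ProteinRecord],
    strata_spec: Sequence[str] = ("total",),
) -> list[EnrichmentResult]:
    """Enrichment of disrupted counts per category within each stratum.

    N counts distinct variant keys in the stratum; n(O) counts distinct
    disrupted (variant, site) pairs of the category among those variants.
    Empty or saturated cells are emitted with p=1 and flagged degenerate.
    """
    L = total_length(proteome)
    n_F: dict[str, int] = {}
    for s in sites:
        n_F[s.category] = n_F.get(s.category, 0) + 1
    categories = sorted(n_F)

    disrupted_pairs: dict[str, set[tuple]] = {c: set() for c in categories}
    pairs_by_variant: dict[tuple, list[tuple[str, tuple]]] = {}
    for call in calls:
        if call.disrupted and call.category in disrupted_pairs:
            pairs_by_variant.setdefault(call.variant_key, []).append(
                (call.category, call.site_key)
            )

    results: list[EnrichmentResult] = []
    for axis in strata_spec:
        for label, members in sorted(_stratum_members(variants, axis).items()):
            stratum = label if axis == "total" else f"{axis}:{label}"
            for cat in categories:
                n_O = sum(
                    1
                    for key in members
                    for c, _ in pairs_by_variant.get(key, ())
                    if c == cat
                )
                N = len(members)
                p_F = n_F[cat] / L
                if N == 0 or not 0 < p_F < 1:
                    results.append(
                        EnrichmentResult(cat, stratum, n_O, n_F[cat], N, L, 1.0, "over", True)
                    )
                    continue
                p, direction = binomial_tail_pvalue(n_O, N, p_F)
                results.append(
                    EnrichmentResult(cat, stratum, n_O, n_F[cat], N, L, p, direction)
                )
    return results


def term_enrichment(
    affected_genes: set[str],
    background_genes: set[str],
    term_map: Mapping[str, Iterable[str]],
) -> list[EnrichmentResult]:
    """Annotation-term (GO/pathway-style) enrichment among affected genes.

    Per term: N = number of affected genes, p_F = fraction of background
    genes carrying the term, n_O = affected genes carrying it; same
    binomial tail as the site profiles.  Terms carried by every background
    gene are degenerate (p = 1).
    """
    if not background_genes:
        raise EnrichmentInputError("background gene set is empty")
    if not affected_genes <= background_genes:
        raise EnrichmentInputError("affected genes must be a subset of background")
    terms = sorted({t for g in background_genes for t in term_map.get(g, ())})
    N = len(affected_genes)
    L = len(background_genes)
    results = []
    for term in terms:
        n_bg = sum(1 for g in background_genes if term in term_map.get(g, ()))
        n_O = sum(1 for g in affected_genes if term in term_map.get(g, ()))
        p_F = n_bg / L
        if N == 0 or not 0 < p_F < 1:
            results.append(EnrichmentResult(term, "genes", n_O, n_bg, L, L, 1.0, "over", True))
            continue
        p, direction = binomial_tail_pvalue(n_O, N, p_F)
        results.append(EnrichmentResult(term, "genes", n_O, n_bg, N, L, p, direction))
    return results


def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted P-values (step-up FDR)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.clip(ranked, 0, 1)
    return out


# ---------------------------------------------------------------------------
# signed significance matrix and clustering

@dataclass
class ProfileMatrix:
    """Signed -log10(P) matrix (+over / -under) with clustering results."""

    values: pd.DataFrame
    row_order: list[str]
    col_order: list[str]
    row_newick: str | None = None
    col_newick: str | None = None


MAX_NEGLOG10 = 320.0  # cap for p-values that underflow double precision


def signed_significance(result: EnrichmentResult) -> float:
    if result.degenerate or result.p_value >= 1.0:
        return 0.0
    mag = -np.log10(result.p_value) if result.p_value > 0 else MAX_NEGLOG10
    return mag if result.direction == "over" else -mag


def results_to_matrix(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    """Pivot results into a stratum x category signed -log10(P) matrix."""
    strata = list(dict.fromkeys(r.stratum for r in results))
    cats = list(dict.fromkeys(r.category for r in results))
    mat = pd.DataFrame(0.0, index=strata, columns=cats)
    for r in results:
        mat.loc[r.stratum, r.category] = signed_significance(r)
    return mat


def _linkage_to_newick(link: np.ndarray, labels: Sequence[str]) -> str:
    tree = hierarchy.to_tree(link)

    def render(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left, right = node.get_left(), node.get_right()
        bl_l = max(node.dist - left.dist, 0.0)
        bl_r = max(node.dist - right.dist, 0.0)
        return f"({render(left)}:{bl_l:g},{render(right)}:{bl_r:g})"

    return render(tree) + ";"


def cluster_profile(results_or_matrix) -> ProfileMatrix:
    """Agglomerative clustering (average linkage, Euclidean) of the profile.

    Accepts either EnrichmentResult sequences or a prebuilt matrix.  With a
    single row or column that axis is left in input order (no clustering).
    Ties (e.g. a constant matrix) resolve deterministically to input order
    via scipy's index-based merging.
    """
    if isinstance(results_or_matrix, pd.DataFrame):
        mat = results_or_matrix.copy()
    else:
        mat = results_to_matrix(results_or_matrix)

    def cluster_axis(frame: pd.DataFrame):
        if frame.shape[0] < 2:
            return list(frame.index), None
        dists = pdist(frame.values)
        link = hierarchy.linkage(dists, method="average")
        if np.allclose(dists, dists[0]):  # fully tied: keep input order
            order = range(frame.shape[0])
        else:
            order = hierarchy.leaves_list(link)
        return [frame.index[i] for i in order], _linkage_to_newick(link, list(frame.index))

    row_order, row_newick = cluster_axis(mat)
    col_order, col_newick = cluster_axis(mat.T)
    return ProfileMatrix(mat, row_order, col_order, row_newick, col_newick)


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "category": r.category,
            "stratum": r.stratum,
            "n_O": r.n_O,
            "n_F": r.n_F,
            "N": r.N,
            "L": r.L,
            "p_F": r.p_F,
            "n_E": r.n_E,
            "difference": r.difference,
            "direction": r.direction,
            "p_value": r.p_value,
            "degenerate": int(r.degenerate),
        }
        for r in results
    ]
    return pd.DataFrame(rows)
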