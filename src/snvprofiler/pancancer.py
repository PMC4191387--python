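"""Pan-cancer recurrence analysis over disrupted functional sites.

Fine-grained Disease Ontology (DO) cancer labels are collapsed through a
many-to-one slim map to a small pan-cancer analysis set; cancer-stratified
enrichment delegates to the category-profile machinery; recurrence ranking
keys each disrupted amino-acid change at (gene, site position, category,
alternate residue) and counts the distinct cancer types it appears in;
literature support filters variants by unique PubMed-ID counts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import pandas as pd

from .catalogs import (
    FunctionalSite,
    ProteinRecord,
    VariantRecord,
    proteome_index,
)
from .disruption import DisruptionCall
from .enrichment import (
    EnrichmentResult,
    ProfileMatrix,
    category_profile,
    cluster_profile,
    results_to_matrix,
)


@dataclass(frozen=True)
class DOSlimMap:
    """Many-to-one DO term collapsing; collapsed terms map to themselves."""

    mapping: Mapping[str, str]
    unmapped_policy: str = "keep"  # or "drop"

    def __post_init__(self):
        for term, target in self.mapping.items():
            if self.mapping.get(target, target) != target:
                raise ValueError(f"slim map is not idempotent at {term} -> {target}")
        if self.unmapped_policy not in ("keep", "drop"):
            raise ValueError("unmapped_policy must be 'keep' or 'drop'")

    def collapse(self, term: str) -> str | None:
        if term in self.mapping:
            return self.mapping[term]
        return term if self.unmapped_policy == "keep" else None

    @classmethod
    def from_tsv(cls, path, unmapped_policy: str = "keep") -> "DOSlimMap":
        """Read a two-column (term, collapsed_term) TSV; '#' starts a comment.

        The slim shipped in ``data/do_slim.tsv`` is a best-effort
        reconstruction covering the DO identifiers used in the analyses,
        not an authoritative ontology slim.
        """
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
        return cls(dict(zip(df["term"], df["collapsed_term"])), unmapped_policy)


def collapse_terms(
    variants: Sequence[VariantRecord], slim: DOSlimMap
) -> tuple[list[VariantRecord], dict]:
    """Relabel each variant's DO terms through the slim map."""
    report = {"terms_seen": 0, "terms_collapsed": 0, "terms_dropped": 0}
    out = []
    for v in variants:
        new_terms = set()
        for t in v.do_terms:
            report["terms_seen"] += 1
            collapsed = slim.collapse(t)
            if collapsed is None:
                report["terms_dropped"] += 1
                continue
            if collapsed != t:
                report["terms_collapsed"] += 1
            new_terms.add(collapsed)
        out.append(replace(v, do_terms=frozenset(new_terms)))
    return out, report


def cancer_profile(
    calls: Sequence[DisruptionCall],
    variants: Sequence[VariantRecord],
    sites: Sequence[FunctionalSite],
    proteome: Sequence[ProteinRecord],
) -> tuple[list[EnrichmentResult], ProfileMatrix]:
    """Per-cancer-term enrichment; rows = cancer terms, cols = categories."""
    results = category_profile(calls, variants, sites, proteome, strata_spec=("do_term",))
    matrix = results_to_matrix(results)
    if matrix.shape[0] >= 2 and matrix.shape[1] >= 2:
        return results, cluster_profile(matrix)
    return results, ProfileMatrix(
        matrix, list(matrix.index), list(matrix.columns)
    )


@dataclass(frozen=True)
class RecurrenceRecord:
    gene: str
    accession: str
    site_position: int
    category: str
    alt_aa: str
    cancer_terms: frozenset[str]
    pmid_count: int

    @property
    def n_cancers(self) -> int:
        return len(self.cancer_terms)


def recurrent_sites(
    calls: Sequence[DisruptionCall],
    variants: Sequence[VariantRecord],
    proteome: Sequence[ProteinRecord],
    k_min: int = 2,
) -> list[RecurrenceRecord]:
    """Disrupted amino-acid changes recurring in >= k_min cancer types.

    Records are keyed at (gene, site position, category, alt residue) and
    sorted by descending cancer count then gene.
    """
    if k_min < 1:
        raise ValueError("k_min must be >= 1")
    proteins = proteome_index(proteome)
    by_key = {v.key: v for v in variants}
    agg: dict[tuple, dict] = {}
    for c in calls:
        if not c.disrupted:
            continue
        v = by_key.get(c.variant_key)
        if v is None or not v.do_terms:
            continue
        gene = proteins[c.site_key[0]].gene or c.site_key[0]
        key = (gene, c.site_key[0], c.site_key[1], c.category, v.alt_aa)
        slot = agg.setdefault(key, {"terms": set(), "pmids": set()})
        slot["terms"] |= v.do_terms
        slot["pmids"] |= v.pmids
    records = [
        RecurrenceRecord(
            gene=k[0], accession=k[1], site_position=k[2], category=k[3],
            alt_aa=k[4], cancer_terms=frozenset(v["terms"]),
            pmid_count=len(v["pmids"]),
        )
        for k, v in agg.items()
    ]
    records = [r for r in records if r.n_cancers >= k_min]
    records.sort(key=lambda r: (-r.n_cancers, r.gene, r.accession, r.site_position, r.alt_aa))
    return records


def literature_support(
    variants: Sequence[VariantRecord], min_pmids: int = 2
) -> tuple[list[VariantRecord], dict]:
    """Variants supported by at least *min_pmids* unique PubMed IDs."""
    if min_pmids < 1:
        raise ValueError("min_pmids must be >= 1")
    kept = [v for v in variants if len(v.pmids) >= min_pmids]
    return kept, {"input": len(variants), "retained": len(kept)}


def export_gene_cancer_matrix(
    calls: Sequence[DisruptionCall],
    variants: Sequence[VariantRecord],
    proteome: Sequence[ProteinRecord],
) -> pd.DataFrame:
    """Long-format gene x cancer counts of disrupted site mutations.

    Cell (gene, cancer) counts the distinct disrupted variants of the gene
    labelled with that cancer term; a variant with several terms
    contributes to each of its terms.  Suitable as input for circular-plot
    tools.
    """
    proteins = proteome_index(proteome)
    by_key = {v.key: v for v in variants}
    cells: dict[tuple[str, str], set[tuple]] = {}
    for c in calls:
        if not c.disrupted:
            continue
        v = by_key.get(c.variant_key)
        if v is None:
            continue
        gene = proteins[c.site_key[0]].gene or c.site_key[0]
        for term in v.do_terms:
            cells.setdefault((gene, term), set()).add(v.key)
    rows = [
        {"gene": g, "cancer": t, "count": len(keys)}
        for (g, t), keys in sorted(cells.items())
    ]
    return pd.DataFrame(rows, columns=["gene", "cancer", "count"])


def intersect_gene_list(
    records: Sequence[RecurrenceRecord], gene_list: set[str]
) -> list[RecurrenceRecord]:
    """Restrict recurrence records to an external gene list (e.g. SMGs)."""
    return [r for r in records if r.gene in gene_list]
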