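"""Ingestion, validation and deduplication of variant and site catalogs.

All coordinates are 1-based, inclusive, in protein space (UniProt feature
convention).  Variant rows whose reference amino acid disagrees with the
reference proteome are dropped and counted; rows sharing the key
(accession, position, alt_aa) are merged into one non-redundant record with
the union of their provenance.  Site features spanning more than five
consecutive residues (domains, repeats, long motifs) are excluded; shorter
spans are expanded to one site per residue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .categories import AMINO_ACIDS, CATEGORIES

MAX_SITE_SPAN = 5

VARIANT_COLUMNS = [
    "accession", "position", "ref_aa", "alt_aa", "sources",
    "in_dbsnp", "do_terms", "pmids", "sample_id",
]
SITE_COLUMNS = ["accession", "position", "category", "subtype", "source"]


class IngestionError(ValueError):
    """Raised on unrecoverable catalog input problems."""


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    sequence: str
    gene: str = ""
    terms: frozenset[str] = frozenset()

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class VariantRecord:
    """One non-redundant nsSNV, keyed by (accession, position, alt_aa)."""

    accession: str
    position: int  # 1-based
    ref_aa: str
    alt_aa: str
    sources: frozenset[str] = frozenset()
    in_dbsnp: bool = False
    do_terms: frozenset[str] = frozenset()
    pmids: frozenset[str] = frozenset()
    sample_ids: frozenset[str] = frozenset()

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.accession, self.position, self.alt_aa)

    @property
    def origin(self) -> str:
        return classify_origin(self)


@dataclass(frozen=True)
class FunctionalSite:
    """One annotated residue (or sequon anchor for N-glycosylation)."""

    accession: str
    position: int  # 1-based; anchor N for sequon categories
    category: str
    subtype: str = ""
    sources: frozenset[str] = frozenset()
    span_length: int = 1

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.accession, self.position, self.category)


def classify_origin(variant: VariantRecord) -> str:
    """Operational germline/somatic call: dbSNP membership means germline."""
    return "germline" if variant.in_dbsnp else "somatic"


# ---------------------------------------------------------------------------
# proteome

def load_proteome(fasta) -> list[ProteinRecord]:
    """Read a FASTA proteome into ProteinRecords.

    Header format ``>ACCESSION [GENE=symbol]``; residues are uppercased.
    Duplicate accessions and empty files are ingestion errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(fasta), "fasta"):
        acc = rec.id
        if acc in seen:
            raise IngestionError(f"duplicate accession in proteome: {acc}")
        seen.add(acc)
        gene = ""
        for tok in rec.description.split():
            if tok.startswith("GENE="):
                gene = tok[5:]
        seq = str(rec.seq).upper()
        if not seq:
            raise IngestionError(f"empty sequence for accession {acc}")
        records.append(ProteinRecord(accession=acc, sequence=seq, gene=gene))
    if not records:
        raise IngestionError("no records in proteome FASTA")
    return records


def proteome_index(proteome: Iterable[ProteinRecord]) -> dict[str, ProteinRecord]:
    return {p.accession: p for p in proteome}


def total_length(proteome: Iterable[ProteinRecord]) -> int:
    """Total proteome length L = sum of per-protein lengths."""
    return sum(p.length for p in proteome)


# ---------------------------------------------------------------------------
# variants

def _split_set(value) -> frozenset[str]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return frozenset()
    text = str(value).strip()
    if not text:
        return frozenset()
    return frozenset(t for t in text.split(";") if t)


def _as_bool(value) -> bool:
    return str(value).strip().lower() in {"1", "true", "yes"}


def load_variant_sources(
    tables: Iterable, proteome: Iterable[ProteinRecord]
) -> tuple[list[VariantRecord], dict]:
    """Merge one or more variant tables into a non-redundant catalog.

    Each table is a TSV path or DataFrame with columns
    accession, position, ref_aa, alt_aa, sources (;-separated),
    in_dbsnp (0/1), do_terms, pmids, sample_id (the last three optional,
    ;-separated).  Rows failing wild-type validation against the proteome
    (unknown accession, malformed/out-of-range position, reference residue
    mismatch) are dropped and tallied in the report.  Surviving rows with
    the same (accession, position, alt_aa) key are merged with set-union
    provenance and OR of the dbSNP flag.
    """
    index = proteome_index(proteome)
    report = {
        "rows_read": 0,
        "dropped_unknown_accession": 0,
        "dropped_bad_position": 0,
        "dropped_ref_mismatch": 0,
        "dropped_bad_residue": 0,
        "merged_duplicates": 0,
        "variants": 0,
    }
    merged: dict[tuple[str, int, str], VariantRecord] = {}
    for table in tables:
        df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table, sep="\t", dtype=str)
        for row in df.itertuples(index=False):
            report["rows_read"] += 1
            acc = str(row.accession)
            protein = index.get(acc)
            if protein is None:
                report["dropped_unknown_accession"] += 1
                continue
            try:
                pos = int(row.position)
            except (TypeError, ValueError):
                report["dropped_bad_position"] += 1
                continue
            if not 1 <= pos <= protein.length:
                report["dropped_bad_position"] += 1
                continue
            ref = str(row.ref_aa).upper()
            alt = str(row.alt_aa).upper()
            if len(ref) != 1 or len(alt) != 1 or alt not in AMINO_ACIDS or ref == alt:
                report["dropped_bad_residue"] += 1
                continue
            if protein.sequence[pos - 1] != ref:
                report["dropped_ref_mismatch"] += 1
                continue
            rec = VariantRecord(
                accession=acc,
                position=pos,
                ref_aa=ref,
                alt_aa=alt,
                sources=_split_set(getattr(row, "sources", "")),
                in_dbsnp=_as_bool(getattr(row, "in_dbsnp", "0")),
                do_terms=_split_set(getattr(row, "do_terms", "")),
                pmids=_split_set(getattr(row, "pmids", "")),
                sample_ids=_split_set(getattr(row, "sample_id", "")),
            )
            prev = merged.get(rec.key)
            if prev is None:
                merged[rec.key] = rec
            else:
                report["merged_duplicates"] += 1
                merged[rec.key] = VariantRecord(
                    accession=prev.accession,
                    position=prev.position,
                    ref_aa=prev.ref_aa,
                    alt_aa=prev.alt_aa,
                    sources=prev.sources | rec.sources,
                    in_dbsnp=prev.in_dbsnp or rec.in_dbsnp,
                    do_terms=prev.do_terms | rec.do_terms,
                    pmids=prev.pmids | rec.pmids,
                    sample_ids=prev.sample_ids | rec.sample_ids,
                )
    variants = sorted(merged.values(), key=lambda v: v.key)
    report["variants"] = len(variants)
    return variants, report


# ---------------------------------------------------------------------------
# sites

def load_category_map(path) -> dict[str, str]:
    """Read a subtype -> category TSV (columns: subtype, category)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    mapping = dict(zip(df["subtype"], df["category"]))
    bad = sorted(set(mapping.values()) - set(CATEGORIES))
    if bad:
        raise IngestionError(f"category map targets outside controlled list: {bad}")
    return mapping


def load_site_sources(
    tables: Iterable,
    proteome: Iterable[ProteinRecord],
    category_map: Mapping[str, str] | None = None,
) -> tuple[list[FunctionalSite], dict]:
    """Merge site feature tables into per-residue FunctionalSites.

    Tables carry accession, position, subtype and source, plus an optional
    ``end`` column for multi-residue features.  Features longer than five
    consecutive residues are excluded outright; spans of 2-5 are expanded
    into one site per residue.  A ``category`` column is honoured directly;
    otherwise the subtype is looked up in *category_map* and unmapped
    subtypes are skipped with a warning count (they cannot be analysed
    without a category).  Duplicates (accession, position, category) merge
    with source union.
    """
    index = proteome_index(proteome)
    category_map = dict(category_map or {})
    report = {
        "rows_read": 0,
        "dropped_long_span": 0,
        "dropped_out_of_range": 0,
        "dropped_unknown_accession": 0,
        "unmapped_subtype": 0,
        "merged_duplicates": 0,
        "sites": 0,
    }
    merged: dict[tuple[str, int, str], FunctionalSite] = {}
    for table in tables:
        df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table, sep="\t", dtype=str)
        has_cat = "category" in df.columns
        has_end = "end" in df.columns
        for row in df.itertuples(index=False):
            report["rows_read"] += 1
            acc = str(row.accession)
            protein = index.get(acc)
            if protein is None:
                report["dropped_unknown_accession"] += 1
                continue
            subtype = str(getattr(row, "subtype", "") or "")
            if has_cat and str(row.category) in CATEGORIES:
                category = str(row.category)
            elif subtype in category_map:
                category = category_map[subtype]
            elif subtype in CATEGORIES:  # subtype already a canonical category
                category = subtype
            else:
                report["unmapped_subtype"] += 1
                continue
            try:
                start = int(row.position)
                end = int(getattr(row, "end", start) or start) if has_end else start
            except (TypeError, ValueError):
                report["dropped_out_of_range"] += 1
                continue
            span = end - start + 1
            if span < 1 or not (1 <= start and end <= protein.length):
                report["dropped_out_of_range"] += 1
                continue
            if span > MAX_SITE_SPAN:
                report["dropped_long_span"] += 1
                continue
            source = frozenset({str(getattr(row, "source", "") or "")} - {""})
            for pos in range(start, end + 1):
                site = FunctionalSite(
                    accession=acc, position=pos, category=category,
                    subtype=subtype, sources=source, span_length=span,
                )
                prev = merged.get(site.key)
                if prev is None:
                    merged[site.key] = site
                else:
                    report["merged_duplicates"] += 1
                    merged[site.key] = replace(prev, sources=prev.sources | site.sources)
    sites = sorted(merged.values(), key=lambda s: s.key)
    report["sites"] = len(sites)
    return sites, report


# ---------------------------------------------------------------------------
# writers

def variants_to_frame(variants: Iterable[VariantRecord]) -> pd.DataFrame:
    rows = [
        {
            "accession": v.accession,
            "position": v.position,
            "ref_aa": v.ref_aa,
            "alt_aa": v.alt_aa,
            "sources": ";".join(sorted(v.sources)),
            "in_dbsnp": int(v.in_dbsnp),
            "origin": v.origin,
            "do_terms": ";".join(sorted(v.do_terms)),
            "pmids": ";".join(sorted(v.pmids)),
            "sample_id": ";".join(sorted(v.sample_ids)),
        }
        for v in variants
    ]
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS[:5] + ["origin"] + VARIANT_COLUMNS[6:])


def sites_to_frame(sites: Iterable[FunctionalSite]) -> pd.DataFrame:
    rows = [
        {
            "accession": s.accession,
            "position": s.position,
            "category": s.category,
            "subtype": s.subtype,
            "source": ";".join(sorted(s.sources)),
        }
        for s in sites
    ]
    return pd.DataFrame(rows, columns=SITE_COLUMNS)


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
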