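"""Cross-species conservation of variant-impacted residues.

A residue's conservation count is the number of species whose best homolog
carries the identical amino acid at the aligned position; a residue is
"conserved" only when all configured species agree (five mammals in the
reference setting).  A species with no homolog, or an alignment gap at the
position, contributes zero.  The conservation ratio of a set of positions
is the fraction that are conserved, and enrichment of conserved positions
among site-impacted variants uses the same exact binomial tail as the
category profiles, with success probability equal to the global conserved
fraction.

Inputs are either ortholog FASTA sets with a 1:1 positional map (the
synthetic no-indel case) or precomputed pairwise homology hit tables in
12-column tabular format (qseqid sseqid pident length mismatch gapopen
qstart qend sstart send evalue bitscore) plus a species column.  For
desk-scale runs without external search binaries a built-in pairwise
aligner (affine-gap local alignment under BLOSUM62 with Karlin-Altschul
bit scores and E-values) can produce the hit table; its position map uses
ungapped coordinate arithmetic, exact for indel-free homologs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .catalogs import ProteinRecord, VariantRecord
from .disruption import DisruptionCall
from .enrichment import EnrichmentResult, binomial_tail_pvalue

E_VALUE_THRESHOLD = 1e-5

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore", "species",
]


@dataclass(frozen=True)
class HomologHit:
    query: str
    species: str
    subject: str
    evalue: float
    bitscore: float
    qstart: int
    qend: int
    sstart: int
    send: int

    def map_position(self, qpos: int) -> int | None:
        """Query -> subject position by ungapped coordinate arithmetic."""
        if self.qstart <= qpos <= self.qend:
            return self.sstart + (qpos - self.qstart)
        return None


def read_hits(path_or_frame) -> pd.DataFrame:
    """Read a tabular homology hit table with a trailing species column."""
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame.copy()
    else:
        df = pd.read_csv(path_or_frame, sep="\t", header=None, comment="#")
        df.columns = HIT_COLUMNS[: df.shape[1]]
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    return df


def best_hits(
    hits: pd.DataFrame, e_threshold: float = E_VALUE_THRESHOLD
) -> list[HomologHit]:
    """Retain one best hit per (query, species).

    Minimal E-value wins; ties break to higher bit score, then to the
    lexicographically smallest subject accession.  Hits at or above the
    threshold are discarded.
    """
    kept: dict[tuple[str, str], HomologHit] = {}
    for row in hits.itertuples(index=False):
        try:
            hit = HomologHit(
                query=str(row.qseqid), species=str(row.species),
                subject=str(row.sseqid),
                evalue=float(row.evalue), bitscore=float(row.bitscore),
                qstart=int(row.qstart), qend=int(row.qend),
                sstart=int(row.sstart), send=int(row.send),
            )
        except (TypeError, ValueError):
            continue
        if hit.evalue >= e_threshold:
            continue
        key = (hit.query, hit.species)
        prev = kept.get(key)
        if (
            prev is None
            or hit.evalue < prev.evalue
            or (hit.evalue == prev.evalue and hit.bitscore > prev.bitscore)
            or (
                hit.evalue == prev.evalue
                and hit.bitscore == prev.bitscore
                and hit.subject < prev.subject
            )
        ):
            kept[key] = hit
    return sorted(kept.values(), key=lambda h: (h.query, h.species))


def conservation_profile(
    proteome: Sequence[ProteinRecord],
    orthologs: Mapping[str, Mapping[str, str]] | None = None,
    hits: Sequence[HomologHit] | None = None,
    n_species: int | None = None,
) -> tuple[dict[tuple[str, int], int], int]:
    """Per-position conservation counts across species.

    With *orthologs* (species -> accession -> sequence) the map is
    positional 1:1 (the ortholog set is indel-free); a missing accession in
    a species contributes zero everywhere.  With *hits* plus *orthologs*
    sequences, positions map through each best hit's coordinates.  Returns
    (counts, n_species).
    """
    if orthologs is None:
        raise ValueError("ortholog sequences are required")
    species = sorted(orthologs)
    n_species = n_species or len(species)
    counts = {
        (p.accession, pos): 0 for p in proteome for pos in range(1, p.length + 1)
    }
    if hits is None:
        for sp in species:
            seqs = orthologs[sp]
            for p in proteome:
                other = seqs.get(p.accession)
                if other is None:
                    continue
                upto = min(p.length, len(other))
                for pos in range(1, upto + 1):
                    if p.sequence[pos - 1] == other[pos - 1]:
                        counts[(p.accession, pos)] += 1
    else:
        by_query: dict[str, list[HomologHit]] = {}
        for h in hits:
            by_query.setdefault(h.query, []).append(h)
        for p in proteome:
            for h in by_query.get(p.accession, ()):
                subject = orthologs.get(h.species, {}).get(h.subject)
                if subject is None:
                    continue
                for pos in range(1, p.length + 1):
                    spos = h.map_position(pos)
                    if spos is None or not 1 <= spos <= len(subject):
                        continue
                    if p.sequence[pos - 1] == subject[spos - 1]:
                        counts[(p.accession, pos)] += 1
    return counts, n_species


def is_conserved(count: int, n_species: int) -> bool:
    return count == n_species


def conservation_ratio(
    positions: Iterable[tuple[str, int]],
    profile: Mapping[tuple[str, int], int],
    n_species: int,
) -> float:
    """Fraction of the positions conserved in all species."""
    positions = list(positions)
    if not positions:
        return float("nan")
    hit = sum(1 for key in positions if is_conserved(profile.get(key, 0), n_species))
    return hit / len(positions)


def grouped_ratios(
    variants: Sequence[VariantRecord],
    calls: Sequence[DisruptionCall],
    proteome: Sequence[ProteinRecord],
    profile: Mapping[tuple[str, int], int],
    n_species: int,
) -> pd.DataFrame:
    """Conservation ratios per (group, residue, category).

    Groups: germline (G), somatic (S) and total (T); category "All" pools
    every variant position regardless of site annotation, and each site
    category covers the positions of its disrupted sites.
    """
    seqs = {p.accession: p.sequence for p in proteome}
    groups: dict[tuple[str, str, str], set[tuple[str, int]]] = {}

    def add(group: str, residue: str, category: str, key: tuple[str, int]):
        groups.setdefault((group, residue, category), set()).add(key)

    origin_of = {v.key: ("G" if v.in_dbsnp else "S") for v in variants}
    for v in variants:
        key = (v.accession, v.position)
        res = seqs[v.accession][v.position - 1]
        add("T", res, "All", key)
        add(origin_of[v.key], res, "All", key)
    for c in calls:
        if not c.disrupted:
            continue
        key = (c.site_key[0], c.site_key[1])
        res = seqs[c.site_key[0]][c.site_key[1] - 1]
        grp = origin_of.get(c.variant_key, "S")
        add("T", res, c.category, key)
        add(grp, res, c.category, key)

    rows = [
        {
            "group": g,
            "residue": res,
            "category": cat,
            "ratio": conservation_ratio(keys, profile, n_species),
            "n": len(keys),
        }
        for (g, res, cat), keys in sorted(groups.items())
    ]
    return pd.DataFrame(rows, columns=["group", "residue", "category", "ratio", "n"])


def conserved_enrichment(
    n_conserved_total: int,
    n_total: int,
    n_site_impacted: int,
    n_site_conserved: int,
) -> EnrichmentResult:
    """Are site-impacted positions more conserved than variants at large?

    Expected conserved site-impacted count is the global conserved fraction
    times the number of site-impacted variants; the observed count is
    referred to Binomial(n_site_impacted, global fraction).
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    p = n_conserved_total / n_total
    if not 0 < p < 1 or n_site_impacted == 0:
        return EnrichmentResult(
            "conserved", "sites", n_site_conserved, n_conserved_total,
            n_site_impacted, n_total, 1.0, "over", True,
        )
    pval, direction = binomial_tail_pvalue(n_site_conserved, n_site_impacted, p)
    return EnrichmentResult(
        "conserved", "sites", n_site_conserved, n_conserved_total,
        n_site_impacted, n_total, pval, direction,
    )


# ---------------------------------------------------------------------------
# built-in pairwise aligner (desk-scale substitute for an external search)

# Karlin-Altschul parameters for gapped BLOSUM62 (open 11 / extend 1)
_KA_LAMBDA = 0.267
_KA_K = 0.041


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def align_pair(
    query_id: str,
    query: str,
    subject_id: str,
    subject: str,
    species: str,
    search_space: int | None = None,
) -> dict:
    """Local pairwise alignment reported as one tabular hit row.

    Bit score b = (lambda*S - ln K)/ln 2 and E = m*n*2^-b with the default
    gapped BLOSUM62 Karlin-Altschul parameters; m*n defaults to the product
    of the two sequence lengths.
    """
    aligner = _make_aligner()
    aln = aligner.align(query, subject)[0]
    score = aln.score
    bit = (_KA_LAMBDA * score - math.log(_KA_K)) / math.log(2)
    mn = search_space or len(query) * len(subject)
    evalue = mn * 2.0 ** (-bit)
    qstart = int(aln.aligned[0][0][0]) + 1
    qend = int(aln.aligned[0][-1][1])
    sstart = int(aln.aligned[1][0][0]) + 1
    send = int(aln.aligned[1][-1][1])
    matches = sum(
        1
        for (qs, qe), (ss, _) in zip(aln.aligned[0], aln.aligned[1])
        for k in range(qe - qs)
        if query[qs + k] == subject[ss + k]
    )
    length = qend - qstart + 1
    return {
        "qseqid": query_id,
        "sseqid": subject_id,
        "pident": 100.0 * matches / max(length, 1),
        "length": length,
        "mismatch": length - matches,
        "gapopen": max(len(aln.aligned[0]) - 1, 0),
        "qstart": qstart,
        "qend": qend,
        "sstart": sstart,
        "send": send,
        "evalue": evalue,
        "bitscore": bit,
        "species": species,
    }


def search_orthologs(
    proteome: Sequence[ProteinRecord],
    orthologs: Mapping[str, Mapping[str, str]],
) -> pd.DataFrame:
    """All-pairs same-accession alignment producing a hit table."""
    rows = []
    for sp, seqs in sorted(orthologs.items()):
        for p in proteome:
            subject = seqs.get(p.accession)
            if subject:
                rows.append(
                    align_pair(p.accession, p.sequence, p.accession, subject, sp)
                )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)
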