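"""SNV-condensation phylogenetics and per-sample functional profiles.

Instead of aligning whole sequences, each sample is condensed to the
concatenation of its alleles at the union of variant loci across the
cohort, each locus padded with 0-3 flanking reference characters.  With a
fixed locus set the condensed sequences are positionally homologous by
construction, so a p-distance matrix and a neighbor-joining tree follow
directly.  Per-sample enrichment profiles over functional-site categories
reuse the binomial machinery, and samples are clustered on the signed
-log10(P) matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalogs import FunctionalSite, ProteinRecord, VariantRecord
from .disruption import DisruptionCall
from .enrichment import (
    EnrichmentResult,
    ProfileMatrix,
    category_profile,
    cluster_profile,
    results_to_matrix,
)

MAX_FLANK = 3


class PhyloInputError(ValueError):
    pass


@dataclass
class CondensedAlignment:
    loci: list[tuple[str, int, str]]  # (sequence id, position, ref allele)
    flank: int
    sequences: dict[str, str]  # sample id -> condensed string

    @property
    def sample_ids(self) -> list[str]:
        return list(self.sequences)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, seq in self.sequences.items():
                fh.write(f">{sid}\n{seq}\n")


def condense(
    sample_variants: Mapping[str, Sequence[VariantRecord]],
    reference: Mapping[str, str] | Sequence[ProteinRecord],
    k: int = 1,
) -> CondensedAlignment:
    """Build equal-length condensed sequences over the cohort's loci.

    The locus set is the union of variant positions across samples, sorted
    by (sequence id, position).  Per locus a sample contributes its
    alternate allele if it carries a variant there (else the reference),
    flanked by k reference characters on each side; flanks truncate at
    sequence boundaries identically for every sample.  Overlapping windows
    of nearby loci are kept independent.  A variant whose reference allele
    disagrees with the reference sequence is an input error.
    """
    if not 0 <= k <= MAX_FLANK:
        raise PhyloInputError(f"flank k must lie in 0..{MAX_FLANK}, got {k}")
    if not isinstance(reference, Mapping):
        reference = {p.accession: p.sequence for p in reference}

    alleles: dict[str, dict[tuple[str, int], str]] = {}
    loci_set: set[tuple[str, int]] = set()
    for sid, variants in sample_variants.items():
        table = {}
        for v in variants:
            seq = reference.get(v.accession)
            if seq is None:
                raise PhyloInputError(f"unknown reference sequence {v.accession}")
            if not 1 <= v.position <= len(seq):
                raise PhyloInputError(f"position {v.position} outside {v.accession}")
            if seq[v.position - 1] != v.ref_aa:
                raise PhyloInputError(
                    f"reference mismatch at {v.accession}:{v.position} "
                    f"(catalog {v.ref_aa}, reference {seq[v.position - 1]})"
                )
            table[(v.accession, v.position)] = v.alt_aa
            loci_set.add((v.accession, v.position))
        alleles[sid] = table

    loci = sorted(loci_set)
    loci_with_ref = [(acc, pos, reference[acc][pos - 1]) for acc, pos in loci]
    sequences = {}
    for sid in sample_variants:
        chunks = []
        for acc, pos, ref in loci_with_ref:
            seq = reference[acc]
            left = seq[max(pos - 1 - k, 0) : pos - 1]
            right = seq[pos : pos + k]
            centre = alleles[sid].get((acc, pos), ref)
            chunks.append(left + centre + right)
        sequences[sid] = "".join(chunks)
    return CondensedAlignment(loci=loci_with_ref, flank=k, sequences=sequences)


def distance_matrix(alignment: CondensedAlignment) -> pd.DataFrame:
    """Pairwise p-distance (Hamming / length) between condensed samples."""
    ids = alignment.sample_ids
    if len(ids) < 2:
        raise PhyloInputError("need at least 2 samples for a distance matrix")
    arrs = {}
    length = None
    for sid, seq in alignment.sequences.items():
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise RuntimeError("condensed sequences differ in length")
        arrs[sid] = np.frombuffer(seq.encode(), dtype=np.uint8)
    if length == 0:
        raise PhyloInputError("empty condensed alignment")
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            d = float(np.mean(arrs[a] != arrs[b]))
            mat.loc[a, b] = mat.loc[b, a] = d
    return mat


def nj_tree(distances: pd.DataFrame) -> str:
    """Neighbor-joining tree in newick text.

    Classic Saitou-Nei agglomeration with the Q criterion; ties break to
    the lowest index pair, negative branch lengths clamp to zero, and the
    final tree is unrooted (trifurcating root when possible).
    """
    ids = list(distances.index)
    n = len(ids)
    if n < 3:
        raise PhyloInputError("neighbor joining needs at least 3 taxa")
    D = distances.values.astype(float).copy()
    nodes = [str(i) for i in ids]  # newick fragments
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        totals = sub.sum(axis=1)
        Q = (m - 2) * sub - totals[:, None] - totals[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = np.argmin(Q)  # first minimum = lowest index pair
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        ai, aj = active[i], active[j]
        d_ij = sub[i, j]
        li = 0.5 * d_ij + (totals[i] - totals[j]) / (2 * (m - 2))
        lj = d_ij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        # distances from new node u to the rest
        du = 0.5 * (D[ai, :] + D[aj, :] - d_ij)
        new = f"({nodes[ai]}:{li:.10g},{nodes[aj]}:{lj:.10g})"
        D = np.vstack([D, du[None, :]])
        D = np.hstack([D, np.append(du, 0.0)[:, None]])
        nodes.append(new)
        active = [a for a in active if a not in (ai, aj)] + [len(nodes) - 1]

    a, b, c = active
    # three-way join: branch lengths from the three pairwise distances
    la = max(0.5 * (D[a, b] + D[a, c] - D[b, c]), 0.0)
    lb = max(0.5 * (D[a, b] + D[b, c] - D[a, c]), 0.0)
    lc = max(0.5 * (D[a, c] + D[b, c] - D[a, b]), 0.0)
    return f"({nodes[a]}:{la:.10g},{nodes[b]}:{lb:.10g},{nodes[c]}:{lc:.10g});"


def sample_profiles(
    calls: Sequence[DisruptionCall],
    variants: Sequence[VariantRecord],
    sites: Sequence[FunctionalSite],
    proteome: Sequence[ProteinRecord],
) -> tuple[list[EnrichmentResult], ProfileMatrix, pd.DataFrame]:
    """Per-sample category enrichment, clustered, plus a presence overlay.

    N for a sample is its own variant count.  Categories with zero
    disrupted calls across every sample are dropped from the matrix; with
    a single sample no clustering is performed.  The overlay is a 0/1
    sample x category table of disrupted-site presence.
    """
    results = category_profile(calls, variants, sites, proteome, strata_spec=("sample",))
    matrix = results_to_matrix(results)
    matrix.index = [s.split(":", 1)[1] for s in matrix.index]

    observed = {}
    for r in results:
        observed[r.category] = observed.get(r.category, 0) + r.n_O
    keep = [c for c in matrix.columns if observed.get(c, 0) > 0]
    matrix = matrix[keep]

    presence = pd.DataFrame(0, index=matrix.index, columns=keep)
    for r in results:
        if r.category in keep and r.n_O > 0:
            presence.loc[r.stratum.split(":", 1)[1], r.category] = 1

    if matrix.shape[0] >= 2 and matrix.shape[1] >= 2:
        profile = cluster_profile(matrix)
    else:
        profile = ProfileMatrix(matrix, list(matrix.index), list(matrix.columns))
    return results, profile, presence
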