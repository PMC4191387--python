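"""Seeded synthetic proteome / variant / ortholog / cohort generator.

Emulates, at desk scale, the statistical structure of the real inputs: a
reference proteome with planted PTM/active/binding sites (including valid
N-X-S/T sequons for N-linked glycosylation), multi-source variant catalogs
whose per-residue rate on category-c sites is a controlled multiple
``lambda_c`` of the background rate, germline/somatic mixtures via a dbSNP
flag, cancer-type labels, ortholog proteomes with tunable per-site
conservation, and multi-sample cohorts dropped along a known random binary
tree.  Every generated entity is recorded in a TruthBundle so downstream
stages can be tested against planted ground truth.

Background amino-acid composition is uniform over the 20 residues and
alternate alleles are drawn uniformly from the 19 non-reference residues;
single-nucleotide reachability of a substitution is not enforced.  All
randomness derives from the single config seed via fixed per-stage streams,
so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .catalogs import (
    FunctionalSite,
    ProteinRecord,
    VariantRecord,
    sites_to_frame,
    variants_to_frame,
)
from .categories import AMINO_ACIDS, CATEGORIES, SEQUON_CATEGORIES, compatible_residues


class SynthConfigError(ValueError):
    pass


SOURCE_TAGS = ("COSMIC", "TCGA", "ICGC", "IntOGen", "dbSNP", "UniProt")

#: Collapsed Disease Ontology cancer terms used as synthetic labels.
DEFAULT_CANCER_TERMS = (
    "DOID:1324",   # lung cancer
    "DOID:1612",   # breast cancer
    "DOID:11054",  # urinary bladder cancer
    "DOID:5746",   # ovarian serous cystadenocarcinoma
    "DOID:1996",   # rectum adenocarcinoma
    "DOID:9460",   # uterine corpus cancer
    "DOID:8923",   # skin melanoma
    "DOID:4467",   # renal clear cell carcinoma
    "DOID:2871",   # endometrial carcinoma
    "DOID:234",    # colon adenocarcinoma
    "DOID:8557",   # oropharynx cancer
    "DOID:9119",   # acute myeloid leukemia
)

DEFAULT_SITE_DENSITY = {
    "Phosphorylation": 12.0,
    "Acetylation": 8.0,
    "Ubiquitylation": 8.0,
    "Methylation": 5.0,
    "N-linked glycosylation": 5.0,
    "O-linked glycosylation": 3.0,
    "Active site": 3.0,
    "Binding site": 10.0,
}

# fixed stream ids so stage outputs are independent of call order
_STREAM_PROTEOME = 1
_STREAM_SITES = 2
_STREAM_VARIANTS = 3
_STREAM_ORTHOLOGS = 4
_STREAM_COHORT = 5


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic data set.

    ``site_density`` is sites per 1000 residues per category;
    ``enrichment_factor`` maps category -> lambda_c, the variant-rate
    multiplier on that category's sites relative to background.
    """

    seed: int = 0
    n_proteins: int = 30
    mean_length: int = 200
    site_density: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SITE_DENSITY)
    )
    enrichment_factor: Mapping[str, float] = field(default_factory=dict)
    n_variants: int = 4000
    germline_fraction: float = 0.5
    cancer_terms: Sequence[str] = DEFAULT_CANCER_TERMS
    cancer_rate: float = 0.6
    n_species: int = 5
    per_species_identity: float = 0.9
    n_samples: int = 8
    mutations_per_branch: int = 25
    flankable: bool = True

    def __post_init__(self):
        if self.n_proteins < 1:
            raise SynthConfigError("n_proteins must be >= 1")
        if self.mean_length < 20:
            raise SynthConfigError("mean_length must be >= 20")
        if not 0 <= self.germline_fraction <= 1:
            raise SynthConfigError("germline_fraction must lie in [0, 1]")
        if not 0 < self.per_species_identity <= 1:
            raise SynthConfigError("per_species_identity must lie in (0, 1]")
        if self.n_species < 1:
            raise SynthConfigError("n_species must be >= 1")
        for cat, lam in self.enrichment_factor.items():
            if lam <= 0:
                raise SynthConfigError(f"enrichment factor for {cat} must be > 0")
        for cat, dens in self.site_density.items():
            if cat not in CATEGORIES:
                raise SynthConfigError(f"unknown site category {cat!r}")
            if dens < 0:
                raise SynthConfigError("site densities must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([stream, self.seed])


@dataclass
class TruthBundle:
    planted_sites: list[FunctionalSite] = field(default_factory=list)
    planted_enrichment: dict[str, float] = field(default_factory=dict)
    conservation_truth: dict[tuple[str, int], int] = field(default_factory=dict)
    true_tree: str | None = None


# ---------------------------------------------------------------------------
# proteome

def gen_proteome(cfg: SynthConfig) -> list[ProteinRecord]:
    """Uniform-composition proteome; lengths ~ Poisson(mean), floor 20."""
    rng = cfg.rng(_STREAM_PROTEOME)
    lengths = np.maximum(rng.poisson(cfg.mean_length, cfg.n_proteins), 20)
    alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    records = []
    for i, n in enumerate(lengths):
        seq = alphabet[rng.integers(0, 20, int(n))].tobytes().decode()
        records.append(
            ProteinRecord(accession=f"SYN{i + 1:05d}", sequence=seq, gene=f"GENE{i + 1}")
        )
    return records


# ---------------------------------------------------------------------------
# sites

def gen_site_catalog(
    proteome: Sequence[ProteinRecord], cfg: SynthConfig
) -> tuple[list[ProteinRecord], list[FunctionalSite], TruthBundle]:
    """Plant sites and edit sequences so every site is rule-compatible.

    Direct-residue sites get a compatible residue written at the position;
    N-glycosylation sites get a full valid sequon (N, X != P, S/T) written
    at anchor..anchor+2.  Site footprints never overlap, so planted truth
    is unambiguous.  Returns the edited proteome, the site table and the
    truth fragment.
    """
    if not proteome:
        raise SynthConfigError("proteome is empty")
    rng = cfg.rng(_STREAM_SITES)
    seqs = {p.accession: bytearray(p.sequence.encode()) for p in proteome}
    lengths = {p.accession: p.length for p in proteome}
    total = sum(lengths.values())
    occupied: set[tuple[str, int]] = set()
    sites: list[FunctionalSite] = []

    flat = [(p.accession, pos) for p in proteome for pos in range(1, p.length + 1)]
    order = rng.permutation(len(flat))

    demand = sum(
        int(round(d / 1000.0 * total)) * (3 if c in SEQUON_CATEGORIES else 1)
        for c, d in cfg.site_density.items()
    )
    if demand > total:
        raise SynthConfigError(
            f"site densities demand {demand} residues but proteome has {total}"
        )

    non_p = [a for a in AMINO_ACIDS if a != "P"]
    cursor = 0
    for category in sorted(cfg.site_density):
        wanted = int(round(cfg.site_density[category] / 1000.0 * total))
        placed = 0
        sequon = category in SEQUON_CATEGORIES
        while placed < wanted and cursor < len(order):
            acc, pos = flat[order[cursor]]
            cursor += 1
            footprint = [(acc, pos + k) for k in range(3)] if sequon else [(acc, pos)]
            if sequon and pos + 2 > lengths[acc]:
                continue
            if any(cell in occupied for cell in footprint):
                continue
            seq = seqs[acc]
            if sequon:
                seq[pos - 1] = ord("N")
                seq[pos] = ord(non_p[rng.integers(0, len(non_p))])
                seq[pos + 1] = ord("ST"[rng.integers(0, 2)])
            else:
                residues = compatible_residues(category)
                seq[pos - 1] = ord(residues[rng.integers(0, len(residues))])
            occupied.update(footprint)
            sites.append(
                FunctionalSite(
                    accession=acc, position=pos, category=category,
                    subtype=category, sources=frozenset({"synthetic"}),
                )
            )
            placed += 1
        if placed < wanted:
            raise SynthConfigError(
                f"could not place {wanted} sites of {category}; proteome too crowded"
            )

    edited = [
        ProteinRecord(p.accession, seqs[p.accession].decode(), p.gene, p.terms)
        for p in proteome
    ]
    sites.sort(key=lambda s: s.key)
    truth = TruthBundle(planted_sites=list(sites))
    return edited, sites, truth


# ---------------------------------------------------------------------------
# variants

def _weighted_sample_without_replacement(
    weights: np.ndarray, k: int, rng: np.random.Generator
) -> np.ndarray:
    """Efraimidis-Spirakis via Gumbel keys: top-k indices by log(w)+Gumbel."""
    keys = np.log(weights) + rng.gumbel(size=weights.size)
    top = np.argpartition(keys, weights.size - k)[-k:]
    return top[np.argsort(-keys[top])]


def gen_variant_catalog(
    proteome: Sequence[ProteinRecord],
    sites: Sequence[FunctionalSite],
    cfg: SynthConfig,
    truth: TruthBundle | None = None,
) -> tuple[list[VariantRecord], TruthBundle]:
    """Draw distinct (position, alt) variants with per-category rate boosts.

    Each of the 19 alternate-residue cells of a position carries weight 1,
    multiplied by lambda_c when the position hosts a category-c site (the
    sequon anchor for N-glycosylation).  Cells are sampled without
    replacement, so all variant keys are distinct.  Provenance: 1-3 source
    tags, a dbSNP flag with probability ``germline_fraction``, cancer terms
    with probability ``cancer_rate`` and Poisson-count PubMed IDs.
    """
    rng = cfg.rng(_STREAM_VARIANTS)
    accs = [p.accession for p in proteome]
    seq_concat = "".join(p.sequence for p in proteome)
    lengths = np.array([p.length for p in proteome])
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    R = int(offsets[-1])
    if cfg.n_variants > R * 19:
        raise SynthConfigError(
            f"n_variants={cfg.n_variants} exceeds the {R * 19} available substitutions"
        )

    pos_weight = np.ones(R)
    site_pos = {}
    for s in sites:
        acc_i = accs.index(s.accession)
        g = int(offsets[acc_i]) + s.position - 1
        site_pos[g] = s.category
    for g, cat in site_pos.items():
        pos_weight[g] = cfg.enrichment_factor.get(cat, 1.0)
    cell_weights = np.repeat(pos_weight, 19)

    chosen = _weighted_sample_without_replacement(cell_weights, cfg.n_variants, rng)
    chosen.sort()
    g_idx = chosen // 19
    alt_idx = chosen % 19

    acc_i = np.searchsorted(offsets, g_idx, side="right") - 1
    local_pos = g_idx - offsets[acc_i] + 1

    n = cfg.n_variants
    in_dbsnp = rng.random(n) < cfg.germline_fraction
    primary_src = rng.integers(0, len(SOURCE_TAGS), n)
    extra_src = rng.random((n, len(SOURCE_TAGS))) < 0.15
    cancer_hit = rng.random(n) < cfg.cancer_rate
    terms = list(cfg.cancer_terms)
    term_mask = rng.random((n, len(terms))) < 0.12
    term_force = rng.integers(0, max(len(terms), 1), n)
    pmid_counts = rng.poisson(1.0, n)
    pmid_draws = rng.integers(0, 500, (n, max(int(pmid_counts.max()), 1) if n else 1))

    variants: list[VariantRecord] = []
    for i in range(n):
        ref = seq_concat[g_idx[i]]
        alts = [a for a in AMINO_ACIDS if a != ref]
        alt = alts[alt_idx[i]]
        srcs = {SOURCE_TAGS[primary_src[i]]} | {
            SOURCE_TAGS[j] for j in np.nonzero(extra_src[i])[0]
        }
        do_terms: frozenset[str] = frozenset()
        if cancer_hit[i] and terms:
            picked = {terms[j] for j in np.nonzero(term_mask[i])[0]}
            picked.add(terms[term_force[i]])
            do_terms = frozenset(picked)
        pmids = frozenset(f"PM{pmid_draws[i, j]}" for j in range(pmid_counts[i]))
        variants.append(
            VariantRecord(
                accession=accs[acc_i[i]],
                position=int(local_pos[i]),
                ref_aa=ref,
                alt_aa=alt,
                sources=frozenset(srcs),
                in_dbsnp=bool(in_dbsnp[i]),
                do_terms=do_terms,
                pmids=pmids,
            )
        )

    truth = truth or TruthBundle()
    truth.planted_enrichment = {
        c: cfg.enrichment_factor.get(c, 1.0) for c in sorted(cfg.site_density)
    }
    return variants, truth


# ---------------------------------------------------------------------------
# orthologs

def gen_ortholog_set(
    proteome: Sequence[ProteinRecord],
    cfg: SynthConfig,
    truth: TruthBundle | None = None,
) -> tuple[dict[str, dict[str, str]], TruthBundle]:
    """Per-species orthologs by site-independent substitution, no indels.

    Each ortholog copies the human sequence and replaces each residue with
    probability (1 - identity) by a uniformly drawn different residue; the
    per-position conservation count (species with the residue unchanged) is
    recorded as truth.
    """
    rng = cfg.rng(_STREAM_ORTHOLOGS)
    species = [f"species{s + 1}" for s in range(cfg.n_species)]
    orthologs: dict[str, dict[str, str]] = {s: {} for s in species}
    truth = truth or TruthBundle()
    counts = {
        (p.accession, pos): 0 for p in proteome for pos in range(1, p.length + 1)
    }
    for sp in species:
        for p in proteome:
            seq = bytearray(p.sequence.encode())
            hits = np.nonzero(rng.random(p.length) < 1 - cfg.per_species_identity)[0]
            for j in hits:
                current = chr(seq[j])
                others = [a for a in AMINO_ACIDS if a != current]
                seq[j] = ord(others[rng.integers(0, 19)])
            for pos in range(1, p.length + 1):
                if chr(seq[pos - 1]) == p.sequence[pos - 1]:
                    counts[(p.accession, pos)] += 1
            orthologs[sp][p.accession] = seq.decode()
    truth.conservation_truth = counts
    return orthologs, truth


# ---------------------------------------------------------------------------
# cohort

def genomic_offsets(proteome: Sequence[ProteinRecord]) -> dict[str, int]:
    """Pseudo-genomic coordinate base per protein (cumulative offsets)."""
    offsets = {}
    acc = 0
    for p in proteome:
        offsets[p.accession] = acc
        acc += p.length
    return offsets


def gen_cohort(
    proteome: Sequence[ProteinRecord],
    cfg: SynthConfig,
    truth: TruthBundle | None = None,
) -> tuple[dict[str, list[VariantRecord]], TruthBundle]:
    """Drop mutations along a random binary tree over the samples.

    Leaves join in random pairs into a rooted binary tree; every edge
    receives 1 + Poisson(mutations_per_branch - 1) mutations at globally
    distinct positions (no recurrent mutation), and each sample inherits
    the union of mutations on its root-to-leaf path.  Branch lengths in the
    recorded newick are mutation counts.
    """
    if cfg.n_samples < 3:
        raise SynthConfigError("n_samples must be >= 3")
    rng = cfg.rng(_STREAM_COHORT)
    accs = [p.accession for p in proteome]
    seqs = {p.accession: p.sequence for p in proteome}
    lengths = np.array([p.length for p in proteome])
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    R = int(offsets[-1])

    n_edges = 2 * cfg.n_samples - 2
    edge_counts = 1 + rng.poisson(max(cfg.mutations_per_branch - 1, 0), n_edges)
    total_mut = int(edge_counts.sum())
    if total_mut > R:
        raise SynthConfigError("tree requires more mutation loci than proteome positions")
    loci = rng.choice(R, size=total_mut, replace=False)

    sample_ids = [f"S{i + 1:02d}" for i in range(cfg.n_samples)]
    clusters: list[dict] = [
        {"newick": sid, "leaves": {sid}} for sid in sample_ids
    ]
    mutations: dict[str, list[int]] = {sid: [] for sid in sample_ids}
    pool = iter(loci)
    edge = 0
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        right = clusters.pop(j)
        left = clusters.pop(i)
        parts = []
        for child in (left, right):
            m = int(edge_counts[edge])
            edge += 1
            muts = [int(next(pool)) for _ in range(m)]
            for sid in child["leaves"]:
                mutations[sid].extend(muts)
            parts.append(f"{child['newick']}:{m}")
        clusters.append(
            {"newick": f"({parts[0]},{parts[1]})", "leaves": left["leaves"] | right["leaves"]}
        )
    tree = clusters[0]["newick"] + ";"

    # one fixed alternate residue per locus
    alt_choice = rng.integers(0, 19, total_mut)
    alt_by_locus = dict(zip((int(x) for x in loci), alt_choice))

    cohort: dict[str, list[VariantRecord]] = {}
    for sid in sample_ids:
        recs = []
        for g in sorted(set(mutations[sid])):
            acc_i = int(np.searchsorted(offsets, g, side="right") - 1)
            pos = g - int(offsets[acc_i]) + 1
            ref = seqs[accs[acc_i]][pos - 1]
            alts = [a for a in AMINO_ACIDS if a != ref]
            recs.append(
                VariantRecord(
                    accession=accs[acc_i], position=pos, ref_aa=ref,
                    alt_aa=alts[alt_by_locus[g]],
                    sources=frozenset({"cohort"}),
                    sample_ids=frozenset({sid}),
                )
            )
        cohort[sid] = recs

    truth = truth or TruthBundle()
    truth.true_tree = tree
    return cohort, truth


# ---------------------------------------------------------------------------
# bundle

@dataclass
class SynthBundle:
    config: SynthConfig
    proteome: list[ProteinRecord]
    sites: list[FunctionalSite]
    variants: list[VariantRecord]
    orthologs: dict[str, dict[str, str]]
    cohort: dict[str, list[VariantRecord]]
    truth: TruthBundle


def generate_bundle(cfg: SynthConfig) -> SynthBundle:
    """Run all generator stages under one config."""
    raw = gen_proteome(cfg)
    proteome, sites, truth = gen_site_catalog(raw, cfg)
    variants, truth = gen_variant_catalog(proteome, sites, cfg, truth)
    orthologs, truth = gen_ortholog_set(proteome, cfg, truth)
    cohort, truth = gen_cohort(proteome, cfg, truth)
    return SynthBundle(cfg, proteome, sites, variants, orthologs, cohort, truth)


def write_fasta(records: Mapping[str, str] | Sequence[ProteinRecord], path) -> None:
    with open(path, "w") as fh:
        if isinstance(records, Mapping):
            items = records.items()
        else:
            items = ((f"{r.accession} GENE={r.gene}", r.sequence) for r in records)
        for header, seq in items:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def write_bundle(bundle: SynthBundle, outdir) -> dict[str, str]:
    """Write the bundle as plain-text files; returns name -> path map."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    write_fasta(bundle.proteome, out / "proteome.fasta")
    paths["proteome"] = str(out / "proteome.fasta")

    sites_to_frame(bundle.sites).to_csv(out / "sites.tsv", sep="\t", index=False)
    paths["sites"] = str(out / "sites.tsv")

    variants_to_frame(bundle.variants).to_csv(out / "variants.tsv", sep="\t", index=False)
    paths["variants"] = str(out / "variants.tsv")

    for sp, seqs in bundle.orthologs.items():
        p = out / f"orthologs_{sp}.fasta"
        write_fasta(seqs, p)
        paths[f"orthologs_{sp}"] = str(p)

    cohort_frames = [
        variants_to_frame(recs) for recs in bundle.cohort.values() if recs
    ]
    if cohort_frames:
        import pandas as pd

        pd.concat(cohort_frames).to_csv(out / "cohort.tsv", sep="\t", index=False)
        paths["cohort"] = str(out / "cohort.tsv")

    truth = {
        "planted_enrichment": bundle.truth.planted_enrichment,
        "conservation_truth": {
            f"{acc}:{pos}": c for (acc, pos), c in bundle.truth.conservation_truth.items()
        },
        "true_tree": bundle.truth.true_tree,
        "genomic_offsets": genomic_offsets(bundle.proteome) if bundle.config.flankable else {},
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    paths["truth"] = str(out / "truth.json")
    if bundle.truth.true_tree:
        (out / "true_tree.nwk").write_text(bundle.truth.true_tree + "\n")
        paths["true_tree"] = str(out / "true_tree.nwk")
    return paths
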