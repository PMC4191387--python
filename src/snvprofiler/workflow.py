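"""End-to-end orchestration with reproducible run manifests.

A single YAML config drives the stages in dependency order::

    synth? -> catalogs -> disruption -> enrichment -> conservation
           -> pancancer -> phylo

Every file a stage writes is recorded in the manifest with its SHA-256
checksum, so a rerun under the same config and inputs can be verified
byte-for-byte.  A stage failure is recorded and downstream stages are
skipped.  All randomness flows from the single top-level seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .catalogs import (
    load_category_map,
    load_proteome,
    load_site_sources,
    load_variant_sources,
    sites_to_frame,
    variants_to_frame,
    write_report,
)
from .conservation import conservation_profile, grouped_ratios
from .disruption import ToleranceRules, calls_to_frame, scan
from .enrichment import category_profile, cluster_profile, results_to_frame
from .pancancer import (
    DOSlimMap,
    cancer_profile,
    collapse_terms,
    export_gene_cancer_matrix,
    recurrent_sites,
)
from .sample_phylo import MAX_FLANK, condense, distance_matrix, nj_tree, sample_profiles
from .synthetic_data import SynthConfig, generate_bundle, write_bundle

log = logging.getLogger("snvprofiler")

STAGES = ("synth", "catalogs", "disruption", "enrichment", "conservation", "pancancer", "phylo")


@dataclass
class RunConfig:
    outdir: str = "profiler_out"
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    synth: dict[str, Any] = field(default_factory=dict)
    proteome: str | None = None
    variants: list[str] = field(default_factory=list)
    sites: list[str] = field(default_factory=list)
    rules_file: str | None = None
    category_map: str | None = None
    slim_file: str | None = None
    strata: list[str] = field(default_factory=lambda: ["total", "source", "origin"])
    k_min: int = 2
    flank: int = 1
    version: str = __version__

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(open(path)) or {}
        cfg = cls()
        for key, value in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if key == "stages":
                cfg.stages.update(value)
            else:
                setattr(cfg, key, value)
        return cfg

    def to_dict(self) -> dict:
        return {
            "outdir": self.outdir, "seed": self.seed, "stages": dict(self.stages),
            "synth": dict(self.synth), "proteome": self.proteome,
            "variants": list(self.variants), "sites": list(self.sites),
            "rules_file": self.rules_file, "category_map": self.category_map,
            "slim_file": self.slim_file, "strata": list(self.strata),
            "k_min": self.k_min, "flank": self.flank, "version": self.version,
        }


def validate_config(config: RunConfig) -> list[str]:
    """Return all violations (empty list = ok)."""
    violations = []
    if config.seed < 0:
        violations.append("seed must be non-negative")
    if not 0 <= config.flank <= MAX_FLANK:
        violations.append(f"flank must lie in 0..{MAX_FLANK}, got {config.flank}")
    if config.k_min < 1:
        violations.append("k_min must be >= 1")
    unknown = set(config.stages) - set(STAGES)
    if unknown:
        violations.append(f"unknown stages: {sorted(unknown)}")
    synth_on = config.stages.get("synth", False)
    if not synth_on:
        if config.stages.get("catalogs", False):
            if not config.proteome:
                violations.append("catalogs stage enabled but no proteome path given")
            elif not Path(config.proteome).exists():
                violations.append(f"proteome file not found: {config.proteome}")
            for path in list(config.variants) + list(config.sites):
                if not Path(path).exists():
                    violations.append(f"input file not found: {path}")
    for opt in ("rules_file", "category_map", "slim_file"):
        path = getattr(config, opt)
        if path and not Path(path).exists():
            violations.append(f"{opt} not found: {path}")
    return violations


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute enabled stages in order; return the run manifest."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"version": config.version, "seed": config.seed, "stages": {}}

    def record(stage: str, status: str, outputs: dict[str, str] | None = None, error: str = ""):
        entry: dict[str, Any] = {"status": status}
        if outputs:
            entry["outputs"] = {name: _sha256(Path(p)) for name, p in outputs.items()}
            entry["paths"] = outputs
        if error:
            entry["error"] = error
        manifest["stages"][stage] = entry

    state: dict[str, Any] = {}
    failed = False
    for stage in STAGES:
        if not config.stages.get(stage, False):
            record(stage, "skipped")
            continue
        if failed:
            record(stage, "skipped_downstream")
            continue
        try:
            outputs = _run_stage(stage, config, state, out)
            record(stage, "ok", outputs)
            log.info("stage %s ok (%d outputs)", stage, len(outputs))
        except Exception as exc:  # noqa: BLE001 - manifest records any failure
            log.error("stage %s failed: %s", stage, exc)
            record(stage, "failed", error=str(exc))
            failed = True

    manifest["config"] = config.to_dict()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    if failed:
        raise RuntimeError("one or more stages failed; see manifest")
    return manifest


def _run_stage(stage: str, config: RunConfig, state: dict, out: Path) -> dict[str, str]:
    if stage == "synth":
        cfg = SynthConfig(seed=config.seed, **config.synth)
        bundle = generate_bundle(cfg)
        synth_dir = out / "synth"
        paths = write_bundle(bundle, synth_dir)
        state["bundle"] = bundle
        config.proteome = paths["proteome"]
        config.variants = [paths["variants"]]
        config.sites = [paths["sites"]]
        return paths

    if stage == "catalogs":
        proteome = load_proteome(config.proteome)
        cat_map = load_category_map(config.category_map) if config.category_map else {}
        variants, vreport = load_variant_sources(config.variants, proteome)
        sites, sreport = load_site_sources(config.sites, proteome, cat_map)
        state.update(proteome=proteome, variants=variants, sites=sites)
        paths = {
            "variants": str(out / "catalog_variants.tsv"),
            "sites": str(out / "catalog_sites.tsv"),
            "report": str(out / "ingestion_report.json"),
        }
        variants_to_frame(variants).to_csv(paths["variants"], sep="\t", index=False)
        sites_to_frame(sites).to_csv(paths["sites"], sep="\t", index=False)
        write_report({"variants": vreport, "sites": sreport}, paths["report"])
        return paths

    if stage == "disruption":
        rules = (
            ToleranceRules.from_yaml(config.rules_file)
            if config.rules_file
            else ToleranceRules()
        )
        calls, cube = scan(state["variants"], state["sites"], state["proteome"], rules)
        state["calls"] = calls
        paths = {
            "calls": str(out / "calls.tsv"),
            "cube_by_source": str(out / "counts_by_source.tsv"),
            "cube_by_origin": str(out / "counts_by_origin.tsv"),
        }
        calls_to_frame(calls).to_csv(paths["calls"], sep="\t", index=False)
        cube["by_source"].to_csv(paths["cube_by_source"], sep="\t")
        cube["by_origin"].to_csv(paths["cube_by_origin"], sep="\t")
        return paths

    if stage == "enrichment":
        results = category_profile(
            state["calls"], state["variants"], state["sites"], state["proteome"],
            strata_spec=tuple(config.strata),
        )
        state["enrichment"] = results
        profile = cluster_profile(results)
        paths = {
            "results": str(out / "enrichment.tsv"),
            "matrix": str(out / "profile_matrix.tsv"),
        }
        results_to_frame(results).to_csv(paths["results"], sep="\t", index=False)
        profile.values.to_csv(paths["matrix"], sep="\t")
        if profile.row_newick:
            (out / "profile_rows.nwk").write_text(profile.row_newick + "\n")
            paths["row_dendrogram"] = str(out / "profile_rows.nwk")
        if profile.col_newick:
            (out / "profile_cols.nwk").write_text(profile.col_newick + "\n")
            paths["col_dendrogram"] = str(out / "profile_cols.nwk")
        return paths

    if stage == "conservation":
        bundle = state.get("bundle")
        if bundle is None:
            raise ValueError("conservation stage currently requires the synth stage")
        profile, n_species = conservation_profile(
            state["proteome"], orthologs=bundle.orthologs
        )
        table = grouped_ratios(
            state["variants"], state["calls"], state["proteome"], profile, n_species
        )
        paths = {"ratios": str(out / "conservation_ratios.tsv")}
        table.to_csv(paths["ratios"], sep="\t", index=False)
        return paths

    if stage == "pancancer":
        variants = state["variants"]
        if config.slim_file:
            slim = DOSlimMap.from_tsv(config.slim_file)
            variants, _ = collapse_terms(variants, slim)
        results, profile = cancer_profile(
            state["calls"], variants, state["sites"], state["proteome"]
        )
        recs = recurrent_sites(state["calls"], variants, state["proteome"], config.k_min)
        matrix = export_gene_cancer_matrix(state["calls"], variants, state["proteome"])
        paths = {
            "cancer_enrichment": str(out / "pancancer_enrichment.tsv"),
            "recurrence": str(out / "recurrence.tsv"),
            "gene_cancer_matrix": str(out / "gene_cancer_matrix.tsv"),
        }
        results_to_frame(results).to_csv(paths["cancer_enrichment"], sep="\t", index=False)
        import pandas as pd

        pd.DataFrame(
            [
                {
                    "gene": r.gene, "accession": r.accession,
                    "site_position": r.site_position, "category": r.category,
                    "alt_aa": r.alt_aa, "n_cancers": r.n_cancers,
                    "cancer_terms": ";".join(sorted(r.cancer_terms)),
                    "pmid_count": r.pmid_count,
                }
                for r in recs
            ],
            columns=[
                "gene", "accession", "site_position", "category", "alt_aa",
                "n_cancers", "cancer_terms", "pmid_count",
            ],
        ).to_csv(paths["recurrence"], sep="\t", index=False)
        matrix.to_csv(paths["gene_cancer_matrix"], sep="\t", index=False)
        return paths

    if stage == "phylo":
        bundle = state.get("bundle")
        if bundle is None:
            raise ValueError("phylo stage currently requires the synth stage")
        alignment = condense(bundle.cohort, state["proteome"], k=config.flank)
        dist = distance_matrix(alignment)
        tree = nj_tree(dist)
        cohort_variants = [v for recs in bundle.cohort.values() for v in recs]
        calls, _ = scan(cohort_variants, state["sites"], state["proteome"])
        results, profile, presence = sample_profiles(
            calls, cohort_variants, state["sites"], state["proteome"]
        )
        paths = {
            "alignment": str(out / "condensed.fasta"),
            "distances": str(out / "distances.tsv"),
            "tree": str(out / "nj_tree.nwk"),
            "sample_matrix": str(out / "sample_profile_matrix.tsv"),
            "overlay": str(out / "sample_overlay.tsv"),
        }
        alignment.to_fasta(paths["alignment"])
        dist.to_csv(paths["distances"], sep="\t")
        Path(paths["tree"]).write_text(tree + "\n")
        profile.values.to_csv(paths["sample_matrix"], sep="\t")
        presence.to_csv(paths["overlay"], sep="\t")
        return paths

    raise ValueError(f"unknown stage {stage!r}")
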