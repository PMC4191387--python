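"""Disruption calling: does a variant abolish a functional site?

For direct-residue categories a substitution at the annotated position
disrupts the site unless the alternate residue is in the category's
tolerated set (empty by default -- every replacement of the modified
residue is treated as disrupting; the rules file makes this configurable).

N-linked glycosylation is evaluated as a motif.  The sequon N-X-S/T is
anchored at the modified asparagine; X is any residue except proline.  A
variant can break the motif at three offsets from the anchor:

* offset 0: the asparagine itself is replaced (always disrupting);
* offset 1: disrupting only if the new residue is proline;
* offset 2: disrupting if the new residue is neither serine nor threonine
  (the T<->S exchange preserves the sequon and is tolerated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .catalogs import FunctionalSite, ProteinRecord, VariantRecord, proteome_index
from .categories import SEQUON_CATEGORIES


class DisruptionInputError(ValueError):
    pass


RULE_DIRECT = "direct_replacement"
RULE_MOTIF_N = "motif_break_N"
RULE_MOTIF_ST = "motif_break_ST"
RULE_MOTIF_PRO = "motif_break_proline"
RULE_TOLERATED = "tolerated"


@dataclass(frozen=True)
class ToleranceRules:
    """Per-category tolerated substitutions.

    ``tolerated[category][site_residue]`` is the set of alternate residues
    that keep the site functional.  Sequon categories are handled by the
    motif logic and need no entries here.
    """

    tolerated: Mapping[str, Mapping[str, frozenset[str]]] = field(default_factory=dict)

    def is_tolerated(self, category: str, site_residue: str, alt_aa: str) -> bool:
        return alt_aa in self.tolerated.get(category, {}).get(site_residue, frozenset())

    @classmethod
    def from_yaml(cls, path) -> "ToleranceRules":
        raw = yaml.safe_load(open(path)) or {}
        tol = {
            cat: {res: frozenset(alts) - {res} for res, alts in (rules or {}).items()}
            for cat, rules in (raw.get("tolerated") or {}).items()
        }
        return cls(tolerated=tol)


DEFAULT_RULES = ToleranceRules()


@dataclass(frozen=True)
class DisruptionCall:
    variant_key: tuple[str, int, str]
    site_key: tuple[str, int, str]
    disrupted: bool
    rule: str
    motif_offset: int | None = None

    @property
    def category(self) -> str:
        return self.site_key[2]


def sequon_status(sequence: str, n_pos: int) -> str:
    """Check the N-glycosylation sequon anchored at 1-based *n_pos*.

    Valid iff sequence[n_pos] is N, the next residue exists and is not P,
    and the residue after that exists and is S or T.
    """
    if not 1 <= n_pos <= len(sequence):
        raise DisruptionInputError(f"position {n_pos} outside sequence of length {len(sequence)}")
    if sequence[n_pos - 1] != "N":
        return "invalid"
    if n_pos + 2 > len(sequence):
        return "invalid"
    if sequence[n_pos] == "P":
        return "invalid"
    if sequence[n_pos + 1] not in "ST":
        return "invalid"
    return "valid"


def evaluate_site(
    variant: VariantRecord,
    site: FunctionalSite,
    sequence: str,
    rules: ToleranceRules = DEFAULT_RULES,
) -> DisruptionCall:
    """Decide whether *variant* disrupts *site* on the same protein."""
    if variant.accession != site.accession:
        raise DisruptionInputError(
            f"variant {variant.key} and site {site.key} are on different proteins"
        )
    if site.category in SEQUON_CATEGORIES:
        offset = variant.position - site.position
        if offset not in (0, 1, 2):
            raise DisruptionInputError(
                f"variant at offset {offset} from sequon anchor {site.key}"
            )
        alt = variant.alt_aa
        if offset == 0:
            disrupted, rule = (alt != "N", RULE_MOTIF_N if alt != "N" else RULE_TOLERATED)
        elif offset == 1:
            disrupted, rule = (alt == "P", RULE_MOTIF_PRO if alt == "P" else RULE_TOLERATED)
        else:
            disrupted, rule = (alt not in "ST", RULE_MOTIF_ST if alt not in "ST" else RULE_TOLERATED)
        return DisruptionCall(variant.key, site.key, disrupted, rule, motif_offset=offset)
    if variant.position != site.position:
        raise DisruptionInputError(
            f"variant position {variant.position} does not match site {site.key}"
        )
    site_residue = sequence[site.position - 1]
    if rules.is_tolerated(site.category, site_residue, variant.alt_aa):
        return DisruptionCall(variant.key, site.key, False, RULE_TOLERATED)
    return DisruptionCall(variant.key, site.key, True, RULE_DIRECT)


def _site_index(sites: Iterable[FunctionalSite]) -> dict[tuple[str, int], list[FunctionalSite]]:
    """Map (accession, variant position) -> sites the position can touch.

    A sequon site is reachable from its anchor and the two following
    positions; direct sites only from their own position.
    """
    index: dict[tuple[str, int], list[FunctionalSite]] = {}
    for site in sites:
        offsets = (0, 1, 2) if site.category in SEQUON_CATEGORIES else (0,)
        for off in offsets:
            index.setdefault((site.accession, site.position + off), []).append(site)
    return index


def scan(
    variants: Iterable[VariantRecord],
    sites: Iterable[FunctionalSite],
    proteome: Iterable[ProteinRecord],
    rules: ToleranceRules = DEFAULT_RULES,
) -> tuple[list[DisruptionCall], dict[str, pd.DataFrame]]:
    """Evaluate every co-located (variant, site) pair.

    Returns all calls plus a count cube of DISRUPTED calls: one table per
    axis (``by_source``, ``by_origin``), rows = categories, a distinct
    variant counted once per (category, source) and once per
    (category, origin), plus a ``Total`` column of distinct variants per
    category.
    """
    proteins = proteome_index(proteome)
    index = _site_index(sites)
    calls: list[DisruptionCall] = []
    variants = list(variants)
    variant_by_key = {v.key: v for v in variants}
    for variant in variants:
        for site in index.get((variant.accession, variant.position), ()):
            seq = proteins[variant.accession].sequence
            calls.append(evaluate_site(variant, site, seq, rules))

    # count cube over disrupted calls
    src_cells: set[tuple[str, str, tuple]] = set()
    ori_cells: set[tuple[str, str, tuple]] = set()
    tot_cells: set[tuple[str, tuple]] = set()
    for call in calls:
        if not call.disrupted:
            continue
        variant = variant_by_key[call.variant_key]
        tot_cells.add((call.category, call.variant_key))
        for src in variant.sources:
            src_cells.add((call.category, src, call.variant_key))
        ori_cells.add((call.category, variant.origin, call.variant_key))

    def tabulate(cells, columns):
        table = pd.DataFrame(0, index=sorted({c[0] for c in tot_cells}), columns=columns)
        for cat, col, _ in cells:
            table.loc[cat, col] += 1
        table["Total"] = pd.Series(
            {cat: sum(1 for c, _ in tot_cells if c == cat) for cat in table.index},
            dtype=int,
        )
        return table

    sources = sorted({s for v in variants for s in v.sources})
    cube = {
        "by_source": tabulate(src_cells, sources),
        "by_origin": tabulate(ori_cells, ["germline", "somatic"]),
    }
    return calls, cube


def calls_to_frame(calls: Iterable[DisruptionCall]) -> pd.DataFrame:
    rows = [
        {
            "accession": c.variant_key[0],
            "position": c.variant_key[1],
            "alt_aa": c.variant_key[2],
            "site_position": c.site_key[1],
            "category": c.site_key[2],
            "disrupted": int(c.disrupted),
            "rule": c.rule,
            "motif_offset": "" if c.motif_offset is None else c.motif_offset,
        }
        for c in calls
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "accession", "position", "alt_aa", "site_position",
            "category", "disrupted", "rule", "motif_offset",
        ],
    )
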