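"""Controlled vocabulary for functional-site categories.

The analysis recognises a closed list of site categories: the common PTM
types plus enzyme active sites and binding sites.  Each category carries a
residue-compatibility set (which amino acids can host the modification);
``None`` means any residue (active/binding sites are not residue-specific).
N-linked glycosylation is the one motif-based category: the modified
asparagine must sit in an N-X-S/T sequon where X is any residue except
proline.
"""

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

CATEGORIES = (
    "Acetylation",
    "Active site",
    "Amidation",
    "Binding site",
    "C-linked glycosylation",
    "Crotonylation",
    "Gamma-carboxyglutamic acid",
    "Hydroxylation",
    "Methylation",
    "Myristation",
    "N-linked glycosylation",
    "O-linked glycosylation",
    "Other lipid modification",
    "Other modified residue",
    "Palmitoylation",
    "Phosphorylation",
    "Prenylation",
    "S-nitrosylation",
    "Sulfation",
    "Sumoylation",
    "Ubiquitylation",
)

#: Categories whose site is a motif anchored at the modified residue rather
#: than a single residue (currently only the N-glycosylation sequon).
SEQUON_CATEGORIES = frozenset({"N-linked glycosylation"})

#: Residues that can host each modification.  None = unrestricted.
MODIFIABLE_RESIDUES: dict[str, str | None] = {
    "Acetylation": "KA",
    "Active site": None,
    "Amidation": "G",
    "Binding site": None,
    "C-linked glycosylation": "W",
    "Crotonylation": "K",
    "Gamma-carboxyglutamic acid": "E",
    "Hydroxylation": "PK",
    "Methylation": "KR",
    "Myristation": "G",
    "N-linked glycosylation": "N",
    "O-linked glycosylation": "ST",
    "Other lipid modification": "C",
    "Other modified residue": None,
    "Palmitoylation": "C",
    "Phosphorylation": "STY",
    "Prenylation": "C",
    "S-nitrosylation": "C",
    "Sulfation": "Y",
    "Sumoylation": "K",
    "Ubiquitylation": "K",
}


def compatible_residues(category: str) -> str:
    """Residues a site of *category* may occupy (all 20 if unrestricted)."""
    res = MODIFIABLE_RESIDUES.get(category)
    return AMINO_ACIDS if res is None else res


def is_compatible(category: str, residue: str) -> bool:
    return residue in compatible_residues(category)
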