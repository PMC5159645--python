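"""Element radii, nucleotide atom inventories and modified-base mappings.

Van der Waals radii follow Bondi's compilation (element-keyed, Å).  The
inventories list the heavy atoms expected for a complete ribonucleotide in
standard PDB nomenclature; hydrogens are never expected (crystallographic
inputs rarely resolve them and the accessibility calculation is
heavy-atom only).
"""

from __future__ import annotations

# Bondi van der Waals radii, Å.  P uses Bondi's 1.80; metals absent on purpose
# (an unknown element is an input error, not a silent default).
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "P": 1.80,
    "S": 1.80,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}

# Ribose + phosphate backbone heavy atoms (PDB v3 names).
BACKBONE_ATOMS: tuple[str, ...] = (
    "P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'",
    "C3'", "O3'", "C2'", "O2'", "C1'",
)

# 5'-terminal residues commonly lack the phosphate group in crystal models;
# these atoms are not required of the first residue in a chain.
TERMINAL_5P_OPTIONAL: frozenset[str] = frozenset({"P", "OP1", "OP2"})

BASE_ATOMS: dict[str, tuple[str, ...]] = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"),
    "C": ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"),
    "U": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C6"),
}


def expected_inventory(base: str, *, include_backbone: bool = True) -> frozenset[str]:
    """Full heavy-atom inventory expected for a complete residue of ``base``.

    Returns an empty set for unknown bases (callers treat that as
    "no inventory known" and mark the residue invalid).
    """
    base = base.upper().replace("T", "U")
    if base not in BASE_ATOMS:
        return frozenset()
    atoms = BASE_ATOMS[base]
    if include_backbone:
        atoms = BACKBONE_ATOMS + atoms
    return frozenset(atoms)


# Modified nucleotides mapped to their parent base (small, editable).  Only
# residues listed here are kept when reading structures; other heteroatoms
# (ions, ligands, water) are skipped.
MODIFIED_BASE_PARENT: dict[str, str] = {
    "PSU": "U", "H2U": "U", "4SU": "U", "OMU": "U", "5MU": "U", "UR3": "U",
    "1MA": "A", "2MA": "A", "OMA": "A", "A2M": "A", "MA6": "A",
    "5MC": "C", "OMC": "C", "4OC": "C",
    "1MG": "G", "2MG": "G", "M2G": "G", "7MG": "G", "OMG": "G", "YG": "G",
    "I": "G",  # inosine read as guanosine-like
}

STANDARD_RESIDUES: dict[str, str] = {"A": "A", "C": "C", "G": "G", "U": "U"}


def parent_base(res_name: str) -> str | None:
    """Canonical base letter for a residue name, or None if not a nucleotide."""
    res_name = res_name.strip().upper()
    if res_name in STANDARD_RESIDUES:
        return STANDARD_RESIDUES[res_name]
    return MODIFIED_BASE_PARENT.get(res_name)
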