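"""Per-nucleotide solvent-accessible surface area from RNA 3D coordinates.

Accessible surface area (ASA) is computed with the Shrake–Rupley method:
each atom's van der Waals sphere is inflated by the solvent probe radius,
covered with a deterministic quasi-uniform point lattice, and the fraction
of points not buried inside any neighbouring inflated sphere gives the
exposed area.  Residue ASA is the sum over the residue's atoms.

Ground-truth values feed the regression on a normalized scale: asa / 400 Å²,
a single constant for all four bases (their maximal accessible areas are
similar).  A completeness filter marks a residue usable only when it and its
immediate sequence neighbours have no missing heavy atoms, so that local
accessibility is computed from complete geometry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .chemdata import (
    TERMINAL_5P_OPTIONAL,
    VDW_RADII,
    expected_inventory,
    parent_base,
)

logger = logging.getLogger(__name__)

DEFAULT_PROBE_RADIUS = 0.75  # Å: half the 1.5 Å solvent probe diameter
DEFAULT_NORM_CONSTANT = 400.0  # Å², shared across bases
MIN_SPHERE_POINTS = 24


@dataclass(frozen=True)
class AsaConfig:
    """Parameters of the accessibility calculation.

    probe_radius : solvent probe radius in Å.  Default 0.75 Å (probe
        *diameter* 1.5 Å); set 1.4 Å for the conventional water probe.
    n_sphere_points : quadrature points per atom (Fibonacci lattice).
    norm_constant : divisor mapping areas to the model's target scale.
    """

    probe_radius: float = DEFAULT_PROBE_RADIUS
    n_sphere_points: int = 960
    norm_constant: float = DEFAULT_NORM_CONSTANT

    def __post_init__(self) -> None:
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be >= 0")
        if self.n_sphere_points < MIN_SPHERE_POINTS:
            raise ValueError(
                f"n_sphere_points must be >= {MIN_SPHERE_POINTS}, "
                f"got {self.n_sphere_points}"
            )
        if self.norm_constant <= 0:
            raise ValueError("norm_constant must be > 0")


@dataclass
class AtomSet:
    """Named heavy atoms with coordinates and radii, grouped into residues.

    Parallel arrays, one entry per atom.  ``residue_index`` is 0-based and
    non-decreasing along the chain; gaps are allowed.  ``residue_base``
    holds the canonical base letter (A/C/G/U) or another string for
    unknown residue types.
    """

    names: list[str]
    elements: list[str]
    radii: np.ndarray
    coords: np.ndarray
    residue_index: np.ndarray
    residue_base: list[str]

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        n = len(self.names)
        if not (
            len(self.elements) == n
            and self.radii.shape == (n,)
            and self.coords.shape == (n, 3)
            and self.residue_index.shape == (n,)
            and len(self.residue_base) == n
        ):
            raise ValueError("AtomSet arrays have inconsistent lengths")
        if n == 0:
            raise ValueError("AtomSet must contain at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite atom coordinate")
        if np.any(self.radii <= 0):
            raise ValueError("all van der Waals radii must be > 0")
        if np.any(np.diff(self.residue_index) < 0):
            raise ValueError("residue_index must be non-decreasing")

    def __len__(self) -> int:
        return len(self.names)

    @property
    def residue_ids(self) -> np.ndarray:
        """Distinct residue indices in chain order."""
        return np.unique(self.residue_index)

    def residue_bases(self) -> dict[int, str]:
        out: dict[int, str] = {}
        for idx, base in zip(self.residue_index, self.residue_base):
            out.setdefault(int(idx), base)
        return out

    @classmethod
    def from_atoms(
        cls,
        atoms: Iterable[tuple[str, str, float, float, float, float, int, str]],
    ) -> "AtomSet":
        """Build from (name, element, vdw_radius, x, y, z, residue_index, base)."""
        names, elements, radii, coords, ridx, rbase = [], [], [], [], [], []
        for name, element, r, x, y, z, i, b in atoms:
            names.append(name)
            elements.append(element)
            radii.append(r)
            coords.append((x, y, z))
            ridx.append(i)
            rbase.append(b)
        return cls(names, elements, np.array(radii), np.array(coords),
                   np.array(ridx), rbase)


@dataclass
class ResidueAsa:
    """Accessibility of one nucleotide: raw Å², normalized, and validity."""

    residue_index: int
    base: str
    asa: float
    asa_norm: float
    valid: bool = True


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit vectors on the sphere (deterministic lattice)."""
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    theta = np.pi * (3.0 - np.sqrt(5.0)) * k
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack((rho * np.cos(theta), rho * np.sin(theta), z))


def compute_atom_asa(atoms: AtomSet, cfg: AsaConfig | None = None) -> np.ndarray:
    """Shrake–Rupley accessible area of every atom, Å².

    For atom i, points on the sphere of radius ``r_i + probe`` are buried if
    they fall inside any other atom's probe-inflated sphere; the exposed
    fraction times the sphere area is the atom's ASA.
    """
    cfg = cfg or AsaConfig()
    unit = fibonacci_sphere(cfg.n_sphere_points)
    radii_exp = atoms.radii + cfg.probe_radius
    coords = atoms.coords
    n_atoms = len(atoms)
    areas = np.empty(n_atoms)

    # Neighbour search: atoms j can bury points of i only within
    # r_i + r_j + 2*probe of i's center.
    tree = cKDTree(coords)
    max_reach = 2.0 * radii_exp.max()

    for i in range(n_atoms):
        pts = coords[i] + radii_exp[i] * unit
        exposed = np.ones(cfg.n_sphere_points, dtype=bool)
        for j in tree.query_ball_point(coords[i], radii_exp[i] + max_reach):
            if j == i:
                continue
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            exposed &= d2 >= radii_exp[j] ** 2
        areas[i] = 4.0 * np.pi * radii_exp[i] ** 2 * exposed.mean()
    return areas


def aggregate_residue_asa(
    atom_areas: np.ndarray,
    atoms: AtomSet,
    cfg: AsaConfig | None = None,
) -> list[ResidueAsa]:
    """Sum per-atom areas into per-residue ASA (Å² and normalized)."""
    cfg = cfg or AsaConfig()
    atom_areas = np.asarray(atom_areas, dtype=float)
    if atom_areas.shape != (len(atoms),):
        raise ValueError(
            f"need one area per atom: {atom_areas.shape[0]} areas, "
            f"{len(atoms)} atoms"
        )
    bases = atoms.residue_bases()
    out = []
    for rid in atoms.residue_ids:
        total = float(atom_areas[atoms.residue_index == rid].sum())
        out.append(
            ResidueAsa(
                residue_index=int(rid),
                base=bases[int(rid)],
                asa=total,
                asa_norm=total / cfg.norm_constant,
            )
        )
    return out


def completeness_mask(
    observed: Sequence[Iterable[str]],
    expected: Sequence[Iterable[str]],
) -> np.ndarray:
    """Validity of each residue under the missing-atom rule.

    ``observed[i]`` are the atom names present in residue i; ``expected[i]``
    the full inventory of a complete residue (empty → unknown base, always
    invalid).  Residue i is valid iff residues i−1, i, i+1 — those that
    exist — each contain their complete inventory.
    """
    if len(observed) != len(expected):
        raise ValueError("observed and expected must have equal length")
    n = len(observed)
    complete = np.empty(n, dtype=bool)
    for i in range(n):
        exp = frozenset(expected[i])
        if not exp:
            logger.warning("residue %d has no expected inventory; marked incomplete", i)
            complete[i] = False
        else:
            complete[i] = exp <= set(observed[i])
    valid = complete.copy()
    for i in range(n):
        if i > 0:
            valid[i] &= complete[i - 1]
        if i < n - 1:
            valid[i] &= complete[i + 1]
    return valid


def normalize_asa(asa: float | np.ndarray, cfg: AsaConfig | None = None):
    """Map Å² to the dimensionless training scale (division by 400 Å²)."""
    cfg = cfg or AsaConfig()
    arr = np.asarray(asa, dtype=float)
    if np.any(arr < 0):
        raise ValueError("ASA must be non-negative")
    out = arr / cfg.norm_constant
    return float(out) if np.isscalar(asa) else out


def denormalize_asa(asa_norm: float | np.ndarray, cfg: AsaConfig | None = None):
    """Inverse of :func:`normalize_asa`."""
    cfg = cfg or AsaConfig()
    arr = np.asarray(asa_norm, dtype=float)
    out = arr * cfg.norm_constant
    return float(out) if np.isscalar(asa_norm) else out


def chain_residue_asa(
    atoms: AtomSet,
    cfg: AsaConfig | None = None,
    *,
    inventory: dict[str, frozenset[str]] | None = None,
    first_residue_lacks_phosphate_ok: bool = True,
) -> list[ResidueAsa]:
    """Full pipeline for one chain: atom ASA → residue ASA → completeness.

    The completeness filter compares each residue's observed heavy atoms
    against the full nucleotide inventory for its base (or a caller-supplied
    base-keyed ``inventory``); the chain's first residue may lack the
    5'-phosphate group without penalty.
    """
    cfg = cfg or AsaConfig()
    areas = compute_atom_asa(atoms, cfg)
    residues = aggregate_residue_asa(areas, atoms, cfg)

    observed: list[set[str]] = []
    expected: list[frozenset[str]] = []
    for pos, res in enumerate(residues):
        obs = {
            atoms.names[k]
            for k in np.flatnonzero(atoms.residue_index == res.residue_index)
        }
        if inventory is not None:
            exp = frozenset(inventory.get(res.base, ()))
        else:
            exp = expected_inventory(res.base)
        if exp and pos == 0 and first_residue_lacks_phosphate_ok:
            exp = exp - TERMINAL_5P_OPTIONAL
        observed.append(obs)
        expected.append(exp)
    mask = completeness_mask(observed, expected)
    for res, ok in zip(residues, mask):
        res.valid = bool(ok)
    return residues


# ---------------------------------------------------------------------------
# Structure file I/O


def load_chain(path: str, chain_id: str) -> AtomSet:
    """Read one RNA chain from a PDB or mmCIF file as an :class:`AtomSet`.

    Keeps heavy atoms of standard and mapped modified nucleotides only;
    hydrogens, waters, ions and other heteroatoms are dropped.  Residue
    indices are renumbered 0-based in chain order.
    """
    import biotite.structure as struc

    if path.endswith((".cif", ".mmcif", ".pdbx")):
        import biotite.structure.io.pdbx as pdbx

        f = pdbx.CIFFile.read(path)
        arr = pdbx.get_structure(f, model=1)
    else:
        import biotite.structure.io.pdb as pdb

        f = pdb.PDBFile.read(path)
        arr = f.get_structure(model=1)

    arr = arr[arr.chain_id == chain_id]
    if arr.array_length() == 0:
        raise ValueError(f"chain {chain_id!r} not found in {path}")
    arr = arr[arr.element != "H"]

    names, elements, radii, coords, ridx, rbase = [], [], [], [], [], []
    res_counter = -1
    last_res = None
    for i in range(arr.array_length()):
        base = parent_base(arr.res_name[i])
        if base is None:
            continue
        element = arr.element[i].upper()
        if element not in VDW_RADII:
            raise ValueError(f"no van der Waals radius for element {element!r}")
        key = (arr.res_id[i], arr.res_name[i])
        if key != last_res:
            res_counter += 1
            last_res = key
        names.append(arr.atom_name[i])
        elements.append(element)
        radii.append(VDW_RADII[element])
        coords.append(tuple(arr.coord[i]))
        ridx.append(res_counter)
        rbase.append(base)
    if not names:
        raise ValueError(f"chain {chain_id!r} in {path} contains no nucleotides")
    return AtomSet(names, elements, np.array(radii), np.array(coords),
                   np.array(ridx), rbase)


def write_residue_asa_tsv(path: str, chain_id: str, residues: list[ResidueAsa]) -> None:
    """Write per-residue ASA as TSV: chain, residue_index, base, asa_A2, asa_norm, valid."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "chain": chain_id,
            "residue_index": [r.residue_index for r in residues],
            "base": [r.base for r in residues],
            "asa_A2": [r.asa for r in residues],
            "asa_norm": [r.asa_norm for r in residues],
            "valid": [int(r.valid) for r in residues],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")
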