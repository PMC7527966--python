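"""Crystal-structure model, CIF I/O and the CaCO3 candidate catalog.

The central object is :class:`CrystalStructure`: a unit cell given by six
lattice parameters, a list of symmetry operators as coordinate triplets
("x,y,z", "-y,x-y,z+1/3", ...), and the asymmetric-unit atom sites in
fractional coordinates.  Symmetry expansion, unit-cell volume and mass
density are the utilities everything downstream (pattern simulation,
candidate ranking) builds on.

The module also ships a 14-entry catalog of CaCO3 polymorphs (Materials
Project entries: identifier, space group, formation energy, band gap, cell
volume, site count, density) used to weight candidate phases during powder
pattern matching.

CIF support is deliberately a core-tag subset: cell parameters, a space-group
label, an explicit symmetry-operator loop and an atom-site loop with
fractional coordinates.  Files without an operator loop are treated as P1.
Parsing is backed by :mod:`gemmi`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

__all__ = [
    "AtomSite",
    "CrystalStructure",
    "CandidatePhase",
    "CifFormatError",
    "InvalidLatticeError",
    "StoichiometryError",
    "read_cif",
    "write_cif",
    "cell_volume",
    "lattice_vectors",
    "mass_density",
    "expand_sites",
    "load_candidate_catalog",
    "CACO3_MOLAR_MASS",
    "CACO3_ATOMS_PER_FORMULA",
    "AVOGADRO",
    "MERGE_TOL",
]

# IUPAC 2021 atomic weights (g/mol) and the CODATA Avogadro constant.
MOLAR_MASSES = {"Ca": 40.078, "C": 12.011, "O": 15.999}
AVOGADRO = 6.02214076e23
CACO3_MOLAR_MASS = MOLAR_MASSES["Ca"] + MOLAR_MASSES["C"] + 3 * MOLAR_MASSES["O"]
CACO3_ATOMS_PER_FORMULA = 5

#: duplicate-site merge tolerance after symmetry expansion, fractional units
MERGE_TOL = 1e-3


class CifFormatError(ValueError):
    """Raised when a CIF file lacks a required tag or contains a bad value."""


class InvalidLatticeError(ValueError):
    """Raised for degenerate lattices (non-positive cell volume)."""


class StoichiometryError(ValueError):
    """Raised when a site count is incompatible with the formula unit."""


@dataclass(frozen=True)
class AtomSite:
    """One atom of the asymmetric unit.

    ``frac_coords`` are reduced into [0, 1) on construction; ``b_iso`` is the
    isotropic Debye-Waller parameter B in A^2.
    """

    element: str
    frac_coords: tuple[float, float, float]
    occupancy: float = 1.0
    b_iso: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.occupancy <= 1.0:
            raise ValueError(f"occupancy must be in (0, 1], got {self.occupancy}")
        reduced = tuple(float(x) % 1.0 for x in self.frac_coords)
        object.__setattr__(self, "frac_coords", reduced)


@dataclass
class CrystalStructure:
    """Unit cell + symmetry operators + asymmetric-unit sites.

    ``lattice`` is (a, b, c, alpha, beta, gamma) in angstroms / degrees.
    ``symmetry_ops`` are coordinate-triplet strings; an empty list means P1
    (identity only).  ``formula_units`` is Z, the number of formula units in
    the cell described by the operators.
    """

    lattice: tuple[float, float, float, float, float, float]
    space_group_symbol: str = "P1"
    symmetry_ops: list[str] = field(default_factory=lambda: ["x,y,z"])
    sites: list[AtomSite] = field(default_factory=list)
    formula_units: int = 1

    def __post_init__(self) -> None:
        a, b, c, al, be, ga = self.lattice
        if min(a, b, c) <= 0:
            raise InvalidLatticeError(f"cell lengths must be positive: {self.lattice}")
        for ang in (al, be, ga):
            if not 0.0 < ang < 180.0:
                raise InvalidLatticeError(f"cell angles must lie in (0, 180): {self.lattice}")
        cell_volume(self.lattice)  # raises if degenerate

    @property
    def volume(self) -> float:
        return cell_volume(self.lattice)

    def expanded_sites(self) -> list[AtomSite]:
        return expand_sites(self)


@dataclass
class CandidatePhase:
    """One catalog entry: a CaCO3 polymorph with its stability metadata.

    ``formation_energy`` is in eV/atom; more negative means more stable and
    hence a higher prior probability of forming.  ``structure`` is attached
    when an atomic model is available for pattern simulation.
    """

    materials_id: str
    space_group: str
    formation_energy: float
    band_gap: float
    volume: float
    n_sites: int
    density: float
    structure: CrystalStructure | None = None

    def recomputed_density(self) -> float:
        return mass_density(self.volume, self.n_sites)


# ---------------------------------------------------------------------------
# lattice geometry


def cell_volume(lattice) -> float:
    """Unit-cell volume (A^3) from six lattice parameters.

    V = abc * sqrt(1 - cos^2 a - cos^2 b - cos^2 g + 2 cos a cos b cos g)
    """
    if isinstance(lattice, CrystalStructure):
        lattice = lattice.lattice
    a, b, c, al, be, ga = lattice
    ca, cb, cg = (math.cos(math.radians(x)) for x in (al, be, ga))
    arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if arg <= 0.0 or min(a, b, c) <= 0:
        raise InvalidLatticeError(f"degenerate lattice {lattice}")
    return a * b * c * math.sqrt(arg)


def lattice_vectors(lattice) -> np.ndarray:
    """Row matrix of lattice vectors (crystallographic convention).

    a along x, b in the xy plane.  Rows are a, b, c in cartesian angstroms.
    """
    if isinstance(lattice, CrystalStructure):
        lattice = lattice.lattice
    a, b, c, al, be, ga = lattice
    ca, cb, cg = (math.cos(math.radians(x)) for x in (al, be, ga))
    sg = math.sin(math.radians(ga))
    cz_sq = 1.0 - cb * cb - ((ca - cb * cg) / sg) ** 2
    if cz_sq <= 0:
        raise InvalidLatticeError(f"degenerate lattice {lattice}")
    return np.array(
        [
            [a, 0.0, 0.0],
            [b * cg, b * sg, 0.0],
            [c * cb, c * (ca - cb * cg) / sg, c * math.sqrt(cz_sq)],
        ]
    )


def mass_density(
    volume: float,
    n_sites: int,
    molar_mass: float = CACO3_MOLAR_MASS,
    atoms_per_formula: int = CACO3_ATOMS_PER_FORMULA,
) -> float:
    """Density in g/cc from cell volume (A^3) and the number of atoms."""
    if volume <= 0:
        raise InvalidLatticeError(f"volume must be positive, got {volume}")
    if n_sites % atoms_per_formula != 0:
        raise StoichiometryError(
            f"{n_sites} sites not divisible by {atoms_per_formula} atoms per formula"
        )
    n_formula = n_sites // atoms_per_formula
    mass_g = n_formula * molar_mass / AVOGADRO
    return mass_g / (volume * 1e-24)


# ---------------------------------------------------------------------------
# symmetry operators


def parse_symop(triplet: str) -> tuple[np.ndarray, np.ndarray]:
    """Parse a coordinate triplet into (3x3 rotation, translation) arrays."""
    try:
        op = gemmi.Op(triplet)
    except Exception as exc:  # gemmi raises RuntimeError on bad strings
        raise CifFormatError(f"unparsable symmetry operator {triplet!r}") from exc
    rot = np.array(op.rot, dtype=float) / gemmi.Op.DEN
    tran = np.array(op.tran, dtype=float) / gemmi.Op.DEN
    if not np.allclose(np.abs(np.linalg.det(rot)), 1.0):
        raise CifFormatError(f"symmetry operator {triplet!r} is not unimodular")
    return rot, tran


def expand_sites(structure: CrystalStructure, tol: float = MERGE_TOL) -> list[AtomSite]:
    """Apply every symmetry operator to every site and merge duplicates.

    Two images are considered the same atom when they coincide within ``tol``
    in every fractional coordinate (minimum-image convention).
    """
    ops = [parse_symop(s) for s in (structure.symmetry_ops or ["x,y,z"])]
    out: list[AtomSite] = []
    positions: dict[str, list[np.ndarray]] = {}
    for site in structure.sites:
        x = np.array(site.frac_coords)
        for rot, tran in ops:
            pos = (rot @ x + tran) % 1.0
            seen = positions.setdefault(site.element, [])
            dup = False
            for prev in seen:
                d = pos - prev
                d -= np.round(d)
                if np.max(np.abs(d)) < tol:
                    dup = True
                    break
            if not dup:
                seen.append(pos)
                out.append(replace(site, frac_coords=tuple(pos)))
    return out


# ---------------------------------------------------------------------------
# CIF I/O (core-tag subset)

_CELL_TAGS = {
    "a": "_cell_length_a",
    "b": "_cell_length_b",
    "c": "_cell_length_c",
    "alpha": "_cell_angle_alpha",
    "beta": "_cell_angle_beta",
    "gamma": "_cell_angle_gamma",
}

_SYMOP_TAGS = ("_symmetry_equiv_pos_as_xyz", "_space_group_symop_operation_xyz")
_SG_TAGS = ("_symmetry_space_group_name_H-M", "_space_group_name_H-M_alt")


def _cif_number(text: str, tag: str) -> float:
    # strip a trailing s.u. in parentheses, e.g. "4.9896(2)"
    try:
        return float(text.split("(")[0])
    except (ValueError, AttributeError) as exc:
        raise CifFormatError(f"bad numeric value {text!r} for {tag}") from exc


def _clean_element(label: str) -> str:
    sym = "".join(ch for ch in label if ch.isalpha())[:2]
    if len(sym) > 1 and sym[1].isupper():
        sym = sym[0]
    return sym.capitalize()


def read_cif(path) -> CrystalStructure:
    """Read a CIF file (core-tag subset) into a :class:`CrystalStructure`.

    Operators come from the symmetry loop when present, otherwise the file is
    treated as P1.  Fractional coordinates are reduced into [0, 1).
    """
    doc = gemmi.cif.read_file(str(path))
    if len(doc) == 0:
        raise CifFormatError(f"{path}: no data block")
    block = doc[0]

    lat = []
    for tag in _CELL_TAGS.values():
        val = block.find_value(tag)
        if val is None:
            raise CifFormatError(f"{path}: missing required tag {tag}")
        lat.append(_cif_number(val, tag))

    symbol = "P1"
    for tag in _SG_TAGS:
        val = block.find_value(tag)
        if val is not None:
            symbol = gemmi.cif.as_string(val)
            break

    ops: list[str] = []
    for tag in _SYMOP_TAGS:
        col = block.find_loop(tag)
        if len(col) > 0:
            ops = [gemmi.cif.as_string(v) for v in col]
            break
    if not ops:
        ops = ["x,y,z"]
    for op in ops:
        parse_symop(op)  # raises CifFormatError on bad strings

    sym_col = None
    for cand in ("_atom_site_type_symbol", "_atom_site_label"):
        col = block.find_loop(cand)
        if len(col) > 0:
            sym_col = list(col)
            break
    if sym_col is None:
        raise CifFormatError(f"{path}: no atom-site loop")
    fx = list(block.find_loop("_atom_site_fract_x"))
    fy = list(block.find_loop("_atom_site_fract_y"))
    fz = list(block.find_loop("_atom_site_fract_z"))
    if not (len(fx) == len(fy) == len(fz) == len(sym_col)) or not fx:
        raise CifFormatError(f"{path}: incomplete fractional-coordinate loop")
    occ = list(block.find_loop("_atom_site_occupancy")) or ["1"] * len(fx)
    biso = list(block.find_loop("_atom_site_B_iso_or_equiv")) or ["0"] * len(fx)

    sites = [
        AtomSite(
            element=_clean_element(gemmi.cif.as_string(s)),
            frac_coords=(
                _cif_number(x, "_atom_site_fract_x"),
                _cif_number(y, "_atom_site_fract_y"),
                _cif_number(z, "_atom_site_fract_z"),
            ),
            occupancy=_cif_number(o, "_atom_site_occupancy"),
            b_iso=_cif_number(bv, "_atom_site_B_iso_or_equiv"),
        )
        for s, x, y, z, o, bv in zip(sym_col, fx, fy, fz, occ, biso)
    ]

    zval = block.find_value("_cell_formula_units_Z")
    formula_units = int(_cif_number(zval, "_cell_formula_units_Z")) if zval else 1

    return CrystalStructure(
        lattice=tuple(lat),
        space_group_symbol=symbol,
        symmetry_ops=ops,
        sites=sites,
        formula_units=formula_units,
    )


def write_cif(structure: CrystalStructure, path, name: str = "micphase") -> None:
    """Write the core-tag CIF subset that :func:`read_cif` understands."""
    a, b, c, al, be, ga = structure.lattice
    lines = [
        f"data_{name}",
        f"_cell_length_a {a:.6f}",
        f"_cell_length_b {b:.6f}",
        f"_cell_length_c {c:.6f}",
        f"_cell_angle_alpha {al:.6f}",
        f"_cell_angle_beta {be:.6f}",
        f"_cell_angle_gamma {ga:.6f}",
        f"_symmetry_space_group_name_H-M '{structure.space_group_symbol}'",
        f"_cell_formula_units_Z {structure.formula_units}",
        "loop_",
        "_symmetry_equiv_pos_as_xyz",
    ]
    lines += [f"  '{op}'" for op in structure.symmetry_ops]
    lines += [
        "loop_",
        "_atom_site_type_symbol",
        "_atom_site_fract_x",
        "_atom_site_fract_y",
        "_atom_site_fract_z",
        "_atom_site_occupancy",
        "_atom_site_B_iso_or_equiv",
    ]
    for s in structure.sites:
        x, y, z = s.frac_coords
        lines.append(
            f"  {s.element} {x:.6f} {y:.6f} {z:.6f} {s.occupancy:.4f} {s.b_iso:.4f}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# candidate catalog

# CaCO3 polymorph entries from the Materials Project database:
# (materials id, space group, formation energy eV/atom, band gap eV,
#  cell volume A^3, atoms per cell, density g/cc)
_CATALOG = (
    ("mp-3953", "R3c", -2.707, 5.002, 127.17, 10, 2.614),
    ("mp-556235", "P21/c", -2.705, 4.960, 253.066, 20, 2.627),
    ("mp-561412", "C2", -2.700, 4.958, 191.628, 15, 2.602),
    ("mp-560265", "P6522", -2.699, 4.944, 1174.591, 90, 2.547),
    ("mp-1194399", "C2/c", -2.699, 4.910, 389.315, 30, 2.561),
    ("mp-1197939", "P1", -2.698, 4.943, 1170.318, 90, 2.556),
    ("mp-553939", "Pnma", -2.694, 4.700, 258.226, 20, 2.574),
    ("mp-1079918", "P1", -2.691, 4.849, 124.855, 10, 2.662),
    ("mp-4626", "Pnma", -2.683, 4.171, 234.244, 20, 2.838),
    ("mp-1197230", "P1", -2.683, 4.940, 591.983, 50, 2.807),
    ("mp-3205", "Pmmn", -2.537, 4.257, 110.731, 10, 3.002),
    ("mp-548403", "C2221", -2.395, 5.719, 105.128, 10, 3.162),
    ("mp-641635", "Pnma", -1.338, 1.185, 306.458, 20, 2.169),
    ("mp-696740", "C2/c", -0.689, 1.435, 118.88, 10, 2.796),
)


def load_candidate_catalog() -> list[CandidatePhase]:
    """The packaged 14-entry CaCO3 polymorph catalog (no structures attached)."""
    return [CandidatePhase(*row) for row in _CATALOG]
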