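"""Synthetic inputs: reference structures, noisy spectra, random elastic tensors.

Everything the test suite and the examples need is generated here from
constants declared in source -- no network access, no binary data.

``make_reference_structures`` returns four CaCO3 models keyed by their
catalog materials id:

* ``mp-3953``   -- calcite: the real R-3c structure (hexagonal setting,
  Ca 6b, C 6a, O 18e with x = 0.257), cell scaled to the catalog volume.
* ``mp-560265`` -- a vaterite-like hexagonal model with genuine P6522
  operators and the catalog cell volume, but synthetic asymmetric-unit
  coordinates (90 atoms/cell): the polymorph's published coordinates are not
  reproduced here, only its symmetry, stoichiometry and density.
* ``mp-3205``   -- synthetic Pmmn decoy (10 atoms, catalog volume).
* ``mp-548403`` -- synthetic C2221-like decoy; C222(1) has no order-2 orbits,
  so this fixture uses a doubled conventional cell (20 atoms) at the catalog
  density.

Symmetry-operator lists are produced by closing a small generator set under
composition, which guarantees each fixture carries a consistent group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .elasticity import ElasticConstants, StabilityError
from .structures import AtomSite, CrystalStructure, write_cif
from .xrd import PowderPattern

__all__ = [
    "NoiseConfig",
    "generate_group",
    "make_reference_structures",
    "write_fixture_cifs",
    "add_measurement_noise",
    "random_elastic_constants",
    "FIXTURE_IDS",
]

FIXTURE_IDS = ("mp-3953", "mp-560265", "mp-3205", "mp-548403")


@dataclass(frozen=True)
class NoiseConfig:
    """Measurement-noise emulation: Gaussian noise plus a polynomial background."""

    sigma_frac: float = 0.02  # noise s.d. as a fraction of the pattern maximum
    background: tuple[float, ...] = ()  # numpy polyval coefficients, highest first
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_frac < 0:
            raise ValueError("sigma_frac must be non-negative")


def generate_group(generators: list[str], max_order: int = 192) -> list[str]:
    """Close a set of coordinate-triplet generators under composition.

    Translations are wrapped into [0, 1).  Returns the sorted list of unique
    operator triplets; raises if the closure exceeds ``max_order`` (a sign of
    an inconsistent generator set).
    """
    ops = {gemmi.Op("x,y,z").triplet(): gemmi.Op("x,y,z")}
    frontier = [gemmi.Op(g).wrap() for g in generators]
    for op in frontier:
        ops.setdefault(op.triplet(), op)
    changed = True
    while changed:
        changed = False
        current = list(ops.values())
        for a in current:
            for b in current:
                c = (a * b).wrap()
                if c.triplet() not in ops:
                    ops[c.triplet()] = c
                    changed = True
                    if len(ops) > max_order:
                        raise ValueError("generator set does not close into a small group")
    return sorted(ops)


# generator sets (closed at import time by the structure factory)
_R3C_GENERATORS = ["-y,x-y,z", "y,x,-z+1/2", "-x,-y,-z", "x+2/3,y+1/3,z+1/3"]
_P6522_GENERATORS = ["x-y,x,z+5/6", "y,x,-z"]
_PMMN_GENERATORS = ["-x,y,z", "x,-y,z", "x+1/2,y+1/2,-z"]
_C2221_LIKE_GENERATORS = ["-x,-y,z+1/2", "x,-y,-z", "x+1/2,y+1/2,z"]


def make_reference_structures() -> dict[str, CrystalStructure]:
    """The four fixture CaCO3 models keyed by catalog materials id."""
    structures: dict[str, CrystalStructure] = {}

    # calcite, hexagonal setting of R-3c; a chosen so the cell volume matches
    # 3x the catalog primitive volume (127.17 A^3) at c = 17.30 A
    structures["mp-3953"] = CrystalStructure(
        lattice=(5.04630, 5.04630, 17.30, 90.0, 90.0, 120.0),
        space_group_symbol="R3c",
        symmetry_ops=generate_group(_R3C_GENERATORS),
        sites=[
            AtomSite("Ca", (0.0, 0.0, 0.0)),
            AtomSite("C", (0.0, 0.0, 0.25)),
            AtomSite("O", (0.2568, 0.0, 0.25)),
        ],
        formula_units=6,
    )

    # vaterite-like model: true P6522 operators, catalog volume (1174.591 A^3),
    # synthetic asymmetric unit expanding to 18 Ca + 18 C + 54 O = 90 atoms
    structures["mp-560265"] = CrystalStructure(
        lattice=(7.29303, 7.29303, 25.50, 90.0, 90.0, 120.0),
        space_group_symbol="P6522",
        symmetry_ops=generate_group(_P6522_GENERATORS),
        sites=[
            AtomSite("Ca", (0.42, 0.42, 0.0)),      # on the 2-fold axis: orbit 6
            AtomSite("Ca", (0.15, 0.38, 0.05)),     # general: orbit 12
            AtomSite("C", (0.13, 0.13, 0.0)),       # orbit 6
            AtomSite("C", (0.45, 0.11, 0.21)),      # orbit 12
            AtomSite("O", (0.75, 0.75, 0.0)),       # orbit 6
            AtomSite("O", (0.52, 0.20, 0.13)),      # orbit 12
            AtomSite("O", (0.38, 0.02, 0.22)),      # orbit 12
            AtomSite("O", (0.81, 0.33, 0.07)),      # orbit 12
            AtomSite("O", (0.09, 0.64, 0.17)),      # orbit 12
        ],
        formula_units=18,
    )

    # Pmmn decoy: 10 atoms at the catalog volume (110.731 A^3)
    structures["mp-3205"] = CrystalStructure(
        lattice=(4.43, 4.75, 110.731 / (4.43 * 4.75), 90.0, 90.0, 90.0),
        space_group_symbol="Pmmn",
        symmetry_ops=generate_group(_PMMN_GENERATORS),
        sites=[
            AtomSite("Ca", (0.0, 0.0, 0.10)),       # orbit 2
            AtomSite("C", (0.0, 0.0, 0.60)),        # orbit 2
            AtomSite("O", (0.0, 0.0, 0.85)),        # orbit 2
            AtomSite("O", (0.24, 0.0, 0.45)),       # orbit 4
        ],
        formula_units=2,
    )

    # C2221-like decoy: doubled conventional cell, 20 atoms, catalog density
    structures["mp-548403"] = CrystalStructure(
        lattice=(4.90, 7.00, 2 * 105.128 / (4.90 * 7.00), 90.0, 90.0, 90.0),
        space_group_symbol="C2221",
        symmetry_ops=generate_group(_C2221_LIKE_GENERATORS),
        sites=[
            AtomSite("Ca", (0.20, 0.0, 0.0)),       # orbit 4
            AtomSite("C", (0.70, 0.0, 0.0)),        # orbit 4
            AtomSite("O", (0.45, 0.0, 0.0)),        # orbit 4
            AtomSite("O", (0.10, 0.15, 0.40)),      # general: orbit 8
        ],
        formula_units=4,
    )
    return structures


def write_fixture_cifs(outdir) -> list[Path]:
    """Write every fixture structure to ``<outdir>/<materials_id>.cif``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for mid, structure in make_reference_structures().items():
        path = outdir / f"{mid}.cif"
        write_cif(structure, path, name=mid.replace("-", "_"))
        paths.append(path)
    return paths


def add_measurement_noise(pattern: PowderPattern, config: NoiseConfig) -> PowderPattern:
    """Seeded Gaussian noise plus polynomial background on a normalized pattern.

    The grid is unchanged; negative intensities are clipped to zero.  The
    result is no longer flagged as normalized (its maximum moved).
    """
    rng = np.random.default_rng(config.seed)
    peak = float(np.max(pattern.intensity))
    y = pattern.intensity + rng.normal(0.0, config.sigma_frac * peak, pattern.intensity.shape)
    if config.background:
        y = y + np.polyval(list(config.background), pattern.two_theta)
    return PowderPattern(
        wavelength=pattern.wavelength,
        two_theta=pattern.two_theta.copy(),
        intensity=np.clip(y, 0.0, None),
        normalized=False,
    )


# uniform sampling ranges (GPa) for random Born-stable tensors
_C_RANGES = {
    "c11": (50.0, 400.0),
    "c33": (50.0, 400.0),
    "c12": (10.0, 150.0),
    "c13": (10.0, 150.0),
    "c44": (10.0, 150.0),
    "c14": (-30.0, 30.0),
}


def random_elastic_constants(
    symmetry: str = "hexagonal",
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> ElasticConstants:
    """Rejection-sample a Born-stable tensor from declared uniform ranges."""
    if rng is None:
        rng = np.random.default_rng(seed)
    while True:
        vals = {k: rng.uniform(*_C_RANGES[k]) for k in ("c11", "c12", "c13", "c33", "c44")}
        c14 = rng.uniform(*_C_RANGES["c14"]) if symmetry == "trigonal" else 0.0
        c = ElasticConstants(symmetry=symmetry, c14=c14, **vals)
        try:
            c.check_stability()
        except StabilityError:
            continue
        return c
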