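"""Powder X-ray diffractogram simulation.

Given a :class:`~micphase.structures.CrystalStructure`, this module
enumerates reflections inside a 2-theta window (Bragg's law on the
reciprocal metric), evaluates kinematic intensities

    I(hkl) = multiplicity * |F(hkl)|^2 * LP(2theta),

with F the structure factor over symmetry-expanded sites and LP the
unpolarized Lorentz-polarization correction, and renders a continuous
pattern by placing a pseudo-Voigt profile at every reflection.  Defaults
follow a standard laboratory measurement of biogenic carbonate powders:
Cu Ka1 radiation, a 20-60 degree scan at 0.02 degree steps.

Patterns are plain (2theta, intensity) arrays; the text format is
two-column whitespace-separated XY with '#' comments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .scattering import scattering_factor
from .structures import CrystalStructure, expand_sites, lattice_vectors

__all__ = [
    "CU_KA1",
    "CU_KA2",
    "ProfileConfig",
    "Reflection",
    "PowderPattern",
    "NormalizationError",
    "bragg_two_theta",
    "d_spacing",
    "lorentz_polarization",
    "structure_factor",
    "generate_reflections",
    "simulate_pattern",
    "normalize_pattern",
    "read_xy",
    "write_xy",
]

CU_KA1 = 1.5406  # angstrom
CU_KA2 = 1.5444

#: reflections merge when d agrees within this (A) ...
MERGE_D_TOL = 1e-5
#: ... and |F|^2 agrees within this relative tolerance
MERGE_F2_RTOL = 1e-6
#: reflections with |F|^2 below this fraction of the strongest are absences
ABSENCE_F2_FRAC = 1e-8


class NormalizationError(ValueError):
    """Raised when a pattern with no positive intensity is normalized."""


@dataclass(frozen=True)
class ProfileConfig:
    """Peak-shape and scan-window settings for pattern simulation."""

    fwhm: float = 0.15  # degrees 2theta
    eta: float = 0.5  # pseudo-Voigt Lorentzian fraction
    grid_step: float = 0.02  # degrees
    scan_min: float = 20.0
    scan_max: float = 60.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")
        if self.grid_step <= 0:
            raise ValueError("grid_step must be positive")
        if self.scan_min >= self.scan_max:
            raise ValueError("scan_min must be below scan_max")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.scan_max - self.scan_min) / self.grid_step)) + 1
        return self.scan_min + self.grid_step * np.arange(n)


@dataclass(frozen=True)
class Reflection:
    hkl: tuple[int, int, int]
    d_spacing: float
    two_theta: float
    multiplicity: int
    f2: float
    intensity: float


@dataclass
class PowderPattern:
    """A diffractogram: ascending 2-theta grid with non-negative intensities."""

    wavelength: float
    two_theta: np.ndarray
    intensity: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.two_theta = np.asarray(self.two_theta, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.two_theta.shape != self.intensity.shape:
            raise ValueError("two_theta and intensity must have the same length")
        if self.two_theta.size > 1 and not np.all(np.diff(self.two_theta) > 0):
            raise ValueError("two_theta grid must be strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


def bragg_two_theta(d: float, wavelength: float) -> float | None:
    """2-theta in degrees for spacing ``d``; None when lambda > 2d (no reflection)."""
    if d <= 0 or wavelength <= 0:
        raise ValueError("d and wavelength must be positive")
    ratio = wavelength / (2.0 * d)
    if ratio > 1.0:
        return None
    return 2.0 * math.degrees(math.asin(ratio))


def _reciprocal_metric(lattice) -> np.ndarray:
    vecs = lattice_vectors(lattice)
    return np.linalg.inv(vecs @ vecs.T)


def d_spacing(hkl, lattice) -> float:
    """Interplanar spacing for a general (triclinic) cell via 1/d^2 = h G* h."""
    h = np.asarray(hkl, dtype=float)
    if not np.any(h):
        raise ValueError("hkl must not be the zero vector")
    inv_d2 = float(h @ _reciprocal_metric(lattice) @ h)
    return 1.0 / math.sqrt(inv_d2)


def lorentz_polarization(two_theta) -> float | np.ndarray:
    """Unpolarized-beam Lorentz-polarization factor (1+cos^2 2t)/(sin^2 t cos t)."""
    tt = np.asarray(two_theta, dtype=float)
    if np.any(tt <= 0.0) or np.any(tt >= 180.0):
        raise ValueError("2theta must lie strictly inside (0, 180) degrees")
    t = np.radians(tt / 2.0)
    lp = (1.0 + np.cos(np.radians(tt)) ** 2) / (np.sin(t) ** 2 * np.cos(t))
    return lp if lp.shape else float(lp)


def _site_arrays(structure: CrystalStructure):
    sites = expand_sites(structure)
    elements = sorted({s.element for s in sites})
    coords = np.array([s.frac_coords for s in sites])
    occ = np.array([s.occupancy for s in sites])
    biso = np.array([s.b_iso for s in sites])
    el_index = np.array([elements.index(s.element) for s in sites])
    return elements, coords, occ, biso, el_index


def _f2_batch(structure: CrystalStructure, hkl: np.ndarray, s: np.ndarray) -> np.ndarray:
    """|F|^2 for an (n,3) array of hkl at matching s = sin(theta)/lambda."""
    elements, coords, occ, biso, el_index = _site_arrays(structure)
    f0 = np.empty((len(elements), len(s)))
    for i, el in enumerate(elements):
        f0[i] = scattering_factor(el, s)
    # per-site form factor with Debye-Waller damping: (n_sites, n_hkl)
    fj = f0[el_index] * np.exp(-biso[:, None] * s[None, :] ** 2)
    phase = np.exp(2j * np.pi * (coords @ hkl.T))
    F = np.sum(occ[:, None] * fj * phase, axis=0)
    return np.abs(F) ** 2


def structure_factor(
    structure: CrystalStructure, hkl, two_theta: float, wavelength: float = CU_KA1
) -> float:
    """|F(hkl)|^2 over symmetry-expanded sites at the given diffraction angle."""
    s = math.sin(math.radians(two_theta / 2.0)) / wavelength
    h = np.asarray(hkl, dtype=float).reshape(1, 3)
    return float(_f2_batch(structure, h, np.array([s]))[0])


def generate_reflections(
    structure: CrystalStructure,
    config: ProfileConfig = ProfileConfig(),
    wavelength: float = CU_KA1,
) -> list[Reflection]:
    """All reflections with 2-theta inside the scan window.

    The full hkl sphere is enumerated and symmetry-equivalent reflections
    (identical d and |F|^2 within tight tolerances) are merged into one entry
    whose multiplicity counts the group; systematic absences are dropped.
    """
    a, b, c = structure.lattice[:3]
    theta_max = math.radians(config.scan_max / 2.0)
    d_min = wavelength / (2.0 * math.sin(theta_max))
    hmax = math.ceil(max(a, b, c) / d_min)

    rng = np.arange(-hmax, hmax + 1)
    H, K, L = np.meshgrid(rng, rng, rng, indexing="ij")
    hkl = np.stack([H.ravel(), K.ravel(), L.ravel()], axis=1)
    hkl = hkl[np.any(hkl != 0, axis=1)]

    gstar = _reciprocal_metric(structure.lattice)
    inv_d2 = np.einsum("ij,jk,ik->i", hkl, gstar, hkl)
    d = 1.0 / np.sqrt(inv_d2)
    sin_t = wavelength / (2.0 * d)
    ok = sin_t <= 1.0
    two_theta = np.full(d.shape, np.nan)
    two_theta[ok] = 2.0 * np.degrees(np.arcsin(sin_t[ok]))
    in_window = ok & (two_theta >= config.scan_min) & (two_theta <= config.scan_max)
    if not np.any(in_window):
        warnings.warn("no reflections fall inside the scan window")
        return []

    hkl = hkl[in_window]
    d = d[in_window]
    two_theta = two_theta[in_window]
    s = 1.0 / (2.0 * d)
    f2 = _f2_batch(structure, hkl.astype(float), s)

    keep = f2 >= ABSENCE_F2_FRAC * np.max(f2)
    hkl, d, two_theta, f2 = hkl[keep], d[keep], two_theta[keep], f2[keep]

    order = np.lexsort((f2, -d))
    reflections: list[Reflection] = []
    groups: list[dict] = []
    for idx in order:
        placed = False
        for g in groups:
            if (
                abs(d[idx] - g["d"]) <= MERGE_D_TOL
                and abs(f2[idx] - g["f2"]) <= MERGE_F2_RTOL * max(f2[idx], g["f2"])
            ):
                g["mult"] += 1
                cand = tuple(int(v) for v in hkl[idx])
                if cand > g["hkl"]:  # prefer the positive-index representative
                    g["hkl"] = cand
                placed = True
                break
        if not placed:
            groups.append(
                {
                    "hkl": tuple(int(v) for v in hkl[idx]),
                    "d": float(d[idx]),
                    "tt": float(two_theta[idx]),
                    "f2": float(f2[idx]),
                    "mult": 1,
                }
            )
    for g in groups:
        intensity = g["mult"] * g["f2"] * lorentz_polarization(g["tt"])
        reflections.append(
            Reflection(
                hkl=g["hkl"],
                d_spacing=g["d"],
                two_theta=g["tt"],
                multiplicity=g["mult"],
                f2=g["f2"],
                intensity=intensity,
            )
        )
    reflections.sort(key=lambda r: r.two_theta)
    return reflections


def _pseudo_voigt(x: np.ndarray, fwhm: float, eta: float) -> np.ndarray:
    """Unit-area pseudo-Voigt: eta * Lorentzian + (1 - eta) * Gaussian."""
    gauss = (2.0 / fwhm) * math.sqrt(math.log(2.0) / math.pi) * np.exp(
        -4.0 * math.log(2.0) * (x / fwhm) ** 2
    )
    lorentz = (2.0 / (math.pi * fwhm)) / (1.0 + 4.0 * (x / fwhm) ** 2)
    return eta * lorentz + (1.0 - eta) * gauss


def simulate_pattern(
    structure: CrystalStructure,
    config: ProfileConfig = ProfileConfig(),
    wavelength: float = CU_KA1,
    kalpha2: bool = False,
) -> PowderPattern:
    """Continuous powder pattern on the uniform scan grid, normalized to 100.

    With ``kalpha2`` the Ka2 line is added at half weight; by default only the
    Ka1 wavelength is used.
    """
    grid = config.grid
    total = np.zeros_like(grid)
    lines = [(wavelength, 1.0)]
    if kalpha2:
        lines.append((CU_KA2 * wavelength / CU_KA1, 0.5))
    for lam, weight in lines:
        for refl in generate_reflections(structure, config, lam):
            total += weight * refl.intensity * _pseudo_voigt(
                grid - refl.two_theta, config.fwhm, config.eta
            )
    pattern = PowderPattern(wavelength=wavelength, two_theta=grid, intensity=total)
    if not np.any(total > 0):
        warnings.warn("empty pattern: no reflections in the scan window")
        return pattern
    return normalize_pattern(pattern)


def normalize_pattern(pattern: PowderPattern) -> PowderPattern:
    """Scale intensities so the maximum is exactly 100 (idempotent)."""
    peak = float(np.max(pattern.intensity))
    if peak <= 0:
        raise NormalizationError("cannot normalize a pattern with no positive intensity")
    if pattern.normalized and peak == 100.0:
        intensity = pattern.intensity.copy()
    else:
        # divide-then-scale keeps the maximum at exactly 100.0
        intensity = (pattern.intensity / peak) * 100.0
    return PowderPattern(
        wavelength=pattern.wavelength,
        two_theta=pattern.two_theta.copy(),
        intensity=intensity,
        normalized=True,
    )


def write_xy(pattern: PowderPattern, path) -> None:
    """Two-column XY text: '# wavelength=... normalized=...' header then data."""
    with open(path, "w") as fh:
        fh.write(f"# wavelength={pattern.wavelength:.4f} normalized={pattern.normalized}\n")
        fh.write("# two_theta_deg intensity\n")
        for tt, y in zip(pattern.two_theta, pattern.intensity):
            fh.write(f"{tt:.4f} {y:.6f}\n")


def read_xy(path, wavelength: float = CU_KA1) -> PowderPattern:
    """Read two-column XY text; '#' lines are comments.

    A 'wavelength=' entry in a comment header overrides the default.
    """
    tts, ys = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("wavelength="):
                        wavelength = float(tok.split("=", 1)[1])
                continue
            parts = line.split()
            tts.append(float(parts[0]))
            ys.append(float(parts[1]))
    return PowderPattern(wavelength=wavelength, two_theta=np.array(tts), intensity=np.array(ys))
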