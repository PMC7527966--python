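"""Voigt-Reuss-Hill polycrystalline elasticity for hexagonal/trigonal crystals.

Single-crystal stiffness constants C11, C12, C13, C33, C44 (GPa), with
C66 = (C11 - C12)/2, are converted to polycrystalline bulk (B) and shear (G)
moduli.  Voigt (uniform strain) is an upper bound, Reuss (uniform stress) a
lower bound, and Hill's average their arithmetic mean:

    B_V = [2(C11 + C12) + 4 C13 + C33] / 9
    G_V = [7 C11 - 5 C12 + 12 C44 + 2 C33 - 4 C13] / 30
    B_R = C2 / M,  C2 = (C11 + C12) C33 - 2 C13^2,  M = C11 + C12 + 2 C33 - 4 C13
    G_R = 5 C2 C44 C66 / [6 B_V C44 C66 + 2 C2 (C44 + C66)]

Young's modulus and Poisson's ratio follow from any (B, G) pair:

    E = 9 B G / (3 B + G),   nu = (3 B - 2 G) / (2 (3 B + G)).

Trigonal tensors carry C14 (and C15), but the averaging above ignores them,
treating the crystal with the hexagonal-form expressions; C14/C15 are stored
and reported only.  A Poisson's ratio below the empirical critical value 0.26
classifies the aggregate as brittle, at or above it as ductile.

``variant="as_printed"`` switches B_V and B_R to alternate published forms
([2(C11+C12) + C33 + C13]/9 and C2/(C11+C12+C33-C13)) for auditability; the
standard forms are the default and are what G_V above is algebraically
consistent with.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ElasticConstants",
    "VRHResult",
    "StabilityError",
    "DUCTILITY_CRITICAL_NU",
    "voigt_moduli",
    "reuss_moduli",
    "hill_average",
    "young_and_poisson",
    "classify_ductility",
    "vrh_report",
    "vrh_from_bounds",
]

DUCTILITY_CRITICAL_NU = 0.26


class StabilityError(ValueError):
    """Raised when elastic constants violate a Born stability criterion."""


@dataclass(frozen=True)
class ElasticConstants:
    """Independent stiffness constants of a hexagonal or trigonal crystal (GPa)."""

    c11: float
    c12: float
    c13: float
    c33: float
    c44: float
    c14: float = 0.0  # trigonal only; unused by the averaging
    c15: float = 0.0  # stored and reported only
    symmetry: str = "hexagonal"

    def __post_init__(self) -> None:
        if self.symmetry not in ("hexagonal", "trigonal"):
            raise ValueError(f"unknown symmetry {self.symmetry!r}")

    @property
    def c66(self) -> float:
        return (self.c11 - self.c12) / 2.0

    def check_stability(self) -> None:
        """Born mechanical-stability criteria; raises naming the violation."""
        if self.c44 <= 0:
            raise StabilityError(f"C44 > 0 violated (C44 = {self.c44})")
        if self.c11 <= abs(self.c12):
            raise StabilityError(
                f"C11 > |C12| violated (C11 = {self.c11}, C12 = {self.c12})"
            )
        if (self.c11 + self.c12) * self.c33 <= 2.0 * self.c13**2:
            raise StabilityError(
                "(C11 + C12) C33 > 2 C13^2 violated "
                f"(C11 = {self.c11}, C12 = {self.c12}, C33 = {self.c33}, C13 = {self.c13})"
            )


@dataclass
class VRHResult:
    """Voigt/Reuss/Hill moduli (GPa), derived E and nu, and ductility class."""

    b_v: float
    b_r: float
    b_h: float
    g_v: float
    g_r: float
    g_h: float
    e_v: float
    e_r: float
    e_h: float
    nu_v: float
    nu_r: float
    nu_h: float
    b_avg: float
    e_avg: float
    g_avg: float
    nu_avg: float
    ductility: str

    def rows(self) -> dict[str, tuple[float, float, float, float]]:
        """(B, E, G, nu) per averaging scheme, matching the report layout."""
        return {
            "Voigt": (self.b_v, self.e_v, self.g_v, self.nu_v),
            "Reuss": (self.b_r, self.e_r, self.g_r, self.nu_r),
            "Hill": (self.b_h, self.e_h, self.g_h, self.nu_h),
            "Average": (self.b_avg, self.e_avg, self.g_avg, self.nu_avg),
        }

    def rounded_rows(self, ndigits: int = 3) -> dict[str, tuple[float, ...]]:
        return {k: tuple(round(v, ndigits) for v in vals) for k, vals in self.rows().items()}


def voigt_moduli(c: ElasticConstants, variant: str = "standard") -> tuple[float, float]:
    """Uniform-strain (upper-bound) bulk and shear moduli."""
    c.check_stability()
    if variant == "as_printed":
        b_v = (2.0 * (c.c11 + c.c12) + c.c33 + c.c13) / 9.0
    else:
        b_v = (2.0 * (c.c11 + c.c12) + 4.0 * c.c13 + c.c33) / 9.0
    g_v = (7.0 * c.c11 - 5.0 * c.c12 + 12.0 * c.c44 + 2.0 * c.c33 - 4.0 * c.c13) / 30.0
    return b_v, g_v


def reuss_moduli(c: ElasticConstants, variant: str = "standard") -> tuple[float, float]:
    """Uniform-stress (lower-bound) bulk and shear moduli."""
    c.check_stability()
    c2 = (c.c11 + c.c12) * c.c33 - 2.0 * c.c13**2
    if variant == "as_printed":
        denom = c.c11 + c.c12 + c.c33 - c.c13
    else:
        denom = c.c11 + c.c12 + 2.0 * c.c33 - 4.0 * c.c13
    if denom == 0:
        raise StabilityError("degenerate tensor: zero denominator in B_R")
    b_r = c2 / denom
    b_v, _ = voigt_moduli(c)  # G_R is defined through the standard B_V
    g_denom = 6.0 * b_v * c.c44 * c.c66 + 2.0 * c2 * (c.c44 + c.c66)
    if g_denom == 0:
        raise StabilityError("degenerate tensor: zero denominator in G_R")
    g_r = 5.0 * c2 * c.c44 * c.c66 / g_denom
    return b_r, g_r


def hill_average(voigt: float, reuss: float) -> float:
    """Hill's estimate: the arithmetic mean of the Voigt and Reuss bounds."""
    if voigt <= 0 or reuss <= 0:
        raise ValueError("moduli must be positive")
    return 0.5 * (voigt + reuss)


def young_and_poisson(b: float, g: float) -> tuple[float, float]:
    """E = 9BG/(3B+G) and nu = (3B-2G)/(2(3B+G)) from bulk and shear moduli."""
    if b <= 0 or g <= 0:
        raise ValueError("moduli must be positive")
    denom = 3.0 * b + g
    return 9.0 * b * g / denom, (3.0 * b - 2.0 * g) / (2.0 * denom)


def classify_ductility(nu: float) -> str:
    """Brittle below nu = 0.26, ductile at or above it."""
    if not -1.0 < nu < 0.5:
        raise ValueError(f"Poisson's ratio {nu} outside (-1, 0.5)")
    return "brittle" if nu < DUCTILITY_CRITICAL_NU else "ductile"


def vrh_from_bounds(b_v: float, g_v: float, b_r: float, g_r: float) -> VRHResult:
    """Full report (Hill row, E/nu columns, averages) from Voigt/Reuss bounds."""
    b_h = hill_average(b_v, b_r)
    g_h = hill_average(g_v, g_r)
    e_v, nu_v = young_and_poisson(b_v, g_v)
    e_r, nu_r = young_and_poisson(b_r, g_r)
    e_h, nu_h = young_and_poisson(b_h, g_h)
    return VRHResult(
        b_v=b_v, b_r=b_r, b_h=b_h,
        g_v=g_v, g_r=g_r, g_h=g_h,
        e_v=e_v, e_r=e_r, e_h=e_h,
        nu_v=nu_v, nu_r=nu_r, nu_h=nu_h,
        b_avg=(b_v + b_r + b_h) / 3.0,
        e_avg=(e_v + e_r + e_h) / 3.0,
        g_avg=(g_v + g_r + g_h) / 3.0,
        nu_avg=(nu_v + nu_r + nu_h) / 3.0,
        ductility=classify_ductility(nu_h),
    )


def vrh_report(c: ElasticConstants, variant: str = "standard") -> VRHResult:
    """Voigt, Reuss and Hill moduli with E/nu per row and column averages."""
    b_v, g_v = voigt_moduli(c, variant)
    b_r, g_r = reuss_moduli(c, variant)
    return vrh_from_bounds(b_v, g_v, b_r, g_r)
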