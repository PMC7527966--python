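"""Atomic X-ray scattering factors (neutral atoms, Cromer-Mann 4-Gaussian fit).

f0(s) = sum_i a_i exp(-b_i s^2) + c with s = sin(theta)/lambda in 1/A.
Coefficients are the International Tables for Crystallography Vol. C values
for neutral atoms, valid to s ~ 2 1/A (far beyond a 20-60 deg Cu Ka scan).
"""

from __future__ import annotations

import numpy as np

__all__ = ["CROMER_MANN", "scattering_factor", "UnsupportedElementError"]


class UnsupportedElementError(KeyError):
    """Raised for an element without packaged scattering coefficients."""


# element -> (a1..a4, b1..b4, c)
CROMER_MANN: dict[str, tuple[tuple[float, ...], tuple[float, ...], float]] = {
    "H": ((0.493002, 0.322912, 0.140191, 0.040810),
          (10.5109, 26.1257, 3.14236, 57.7997), 0.003038),
    "C": ((2.31000, 1.02000, 1.58860, 0.865000),
          (20.8439, 10.2075, 0.568700, 51.6512), 0.215600),
    "N": ((12.2126, 3.13220, 2.01250, 1.16630),
          (0.005700, 9.89330, 28.9975, 0.582600), -11.5290),
    "O": ((3.04850, 2.28680, 1.54630, 0.867000),
          (13.2771, 5.70110, 0.323900, 32.9089), 0.250800),
    "Mg": ((5.42040, 2.17350, 1.22690, 2.30730),
           (2.82750, 79.2611, 0.380800, 7.19370), 0.858400),
    "Ca": ((8.62660, 7.38730, 1.58990, 1.02110),
           (10.4421, 0.659900, 85.7484, 178.437), 1.37510),
}


def scattering_factor(element: str, s):
    """f0 for ``element`` at s = sin(theta)/lambda (scalar or array, 1/A)."""
    try:
        a, b, c = CROMER_MANN[element]
    except KeyError:
        raise UnsupportedElementError(
            f"no packaged scattering coefficients for element {element!r}"
        ) from None
    s2 = np.asarray(s, dtype=float) ** 2
    f = c + sum(ai * np.exp(-bi * s2) for ai, bi in zip(a, b))
    return f if f.shape else float(f)
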