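"""Polycrystalline moduli of biogenic vaterite from its Voigt/Reuss bounds.

The Voigt (uniform strain) and Reuss (uniform stress) bounds of the
identified hexagonal CaCO3 phase are combined into Hill averages, Young's
modulus E = 9BG/(3B+G) and Poisson's ratio nu = (3B-2G)/(2(3B+G)), and the
aggregate is classified as ductile (nu >= 0.26) or brittle.
"""

from micphase import vrh_from_bounds

# single-crystal-derived bounds for the hexagonal (P6522) vaterite phase, GPa
res = vrh_from_bounds(b_v=70.051, g_v=26.265, b_r=64.113, g_r=25.371)

print(f"{'scheme':<8} {'B/GPa':>8} {'E/GPa':>8} {'G/GPa':>8} {'nu':>6}")
for scheme, (b, e, g, nu) in res.rounded_rows().items():
    print(f"{scheme:<8} {b:>8.3f} {e:>8.3f} {g:>8.3f} {nu:>6.3f}")
print(f"ductility class from the Hill Poisson ratio: {res.ductility}")
print("B measures incompressibility, G rigidity, E stiffness; nu ~0.33 -> ductile")
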