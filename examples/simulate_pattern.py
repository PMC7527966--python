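"""Simulate the powder XRD pattern of calcite and list its strongest peaks.

Builds the packaged calcite reference structure (R-3c, hexagonal setting),
simulates a Cu Ka1 diffractogram over 20-60 degrees 2-theta and prints the
five strongest reflections.  Peak positions follow Bragg's law from the
lattice; relative intensities come from |F|^2 x multiplicity x LP.
"""

from micphase import generate_reflections, simulate_pattern
from micphase.fixtures import make_reference_structures

calcite = make_reference_structures()["mp-3953"]
pattern = simulate_pattern(calcite)
reflections = sorted(generate_reflections(calcite), key=lambda r: r.intensity, reverse=True)

print("calcite (R3c) Cu Ka1 pattern:", pattern.two_theta.size, "points, max 100")
print("five strongest reflections (hkl, 2theta/deg, d/A, relative intensity):")
top = reflections[:5]
scale = 100.0 / top[0].intensity
for r in top:
    print(f"  {str(r.hkl):>12}  {r.two_theta:7.3f}  {r.d_spacing:6.4f}  {r.intensity * scale:6.1f}")
print("the (104) reflection dominating near 29 degrees is the classic calcite signature")
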