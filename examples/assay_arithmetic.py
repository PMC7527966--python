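"""Precipitate gravimetry and biocement strength gains.

The precipitate mass is the difference between the loaded and empty filter
paper; the strength gain is the percent increase of a bioaugmented cement
cube's 28-day compressive strength over the uninoculated control.
"""

from micphase import precipitate_weight, strength_gain

print("precipitate on filter: ", precipitate_weight(w_total=1.37, w_paper=1.12), "g")

control = 29.05  # MPa, uninoculated cement at 28 days
for source, mpa in [("calcium nitrate", 37.02), ("calcium acetate", 36.62),
                    ("calcium chloride", 31.86)]:
    print(f"{source:<17} {mpa:6.2f} MPa -> +{strength_gain(mpa, control):4.1f} % over control")
print("gains above ~25% indicate an effective calcium source for biocementation")
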