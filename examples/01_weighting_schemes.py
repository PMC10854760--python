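"""Apply the different intensity-weighting schemes to one spectrum.

Builds a small max-normalized spectrum with one strong and several weak
fragments, runs it through the classic power-law presets, entropy-
conditional weighting, and the frequency-aware scheme, and prints the
transformed intensities side by side.
"""

import numpy as np

from specweight import (
    SCHEMES,
    Spectrum,
    SpectrumLibrary,
    apply_scheme,
    build_frequency_table,
)

spectrum = Spectrum(
    precursor_mz=400.0,
    mz=[85.03, 127.04, 213.09, 259.09, 331.10],
    intensities=[0.02, 0.08, 0.15, 1.00, 0.05],
    identifier="demo",
)

# a toy reference library: the 259.09 bin appears everywhere, the rest
# only in some spectra, so the frequency factor differs per peak
reference = SpectrumLibrary([
    Spectrum(400.0, [127.04, 259.09], [1.0, 1.0], identifier="r1"),
    Spectrum(410.0, [213.09, 259.09], [1.0, 1.0], identifier="r2"),
    Spectrum(420.0, [259.09, 331.10], [1.0, 1.0], identifier="r3"),
    Spectrum(430.0, [259.09], [1.0], identifier="r4"),
])
table = build_frequency_table(reference, resolution=0.1)

print(f"{'m/z':>8}  {'raw':>6}", end="")
names = ["sokolow", "stein_scott", "intensity_only", "entropy", "proposed"]
for name in names:
    print(f"  {name:>14}", end="")
print()
weighted = {name: apply_scheme(spectrum, name, table) for name in names}
for i, mz in enumerate(spectrum.mz):
    print(f"{mz:8.2f}  {spectrum.intensities[i]:6.3f}", end="")
    for name in names:
        print(f"  {weighted[name].intensities[i]:14.4f}", end="")
    print()

print("\nThe raw spectrum is dominated by the 259.09 peak. Intensity-only")
print("weighting compresses that dominance; m/z-power schemes additionally")
print("favour high-mass fragments; the frequency-aware scheme boosts peaks")
print("whose m/z bins are common in the reference library (f(259.1) = 1)")
print("and damps rare ones, each factor raised to the power 0.25.")
print(f"\nRegistered presets: {', '.join(sorted(SCHEMES))}")
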