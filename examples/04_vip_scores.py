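"""Use VIP scores to see which ppm regions carry a property's signal.

Variable-importance-in-projection scores average to 1 in the mean
square; regions scoring well above 1 dominate the calibration and are
the natural candidates when narrowing the modeled spectral range.
"""

import numpy as np

from nmrcal import (GeneratorConfig, Pretreatment, fit_pls, synthesize,
                    vip_scores)

spectra, refs = synthesize(GeneratorConfig(seed=7))
y = refs.property_values("fat")

pre = Pretreatment(kind="snv")
Xt, fitted = pre.fit_transform(spectra)
model = fit_pls(Xt, y, 4, property_name="fat", pretreatment=fitted)

vip = vip_scores(model)
grid = Xt.grid
print(f"mean squared VIP = {np.mean(vip**2):.6f} (identity check)")

mask = vip > 1.5
runs, start = [], None
for i, flag in enumerate(mask):
    if flag and start is None:
        start = i
    if not flag and start is not None:
        runs.append((grid[start], grid[i - 1]))
        start = None
if start is not None:
    runs.append((grid[start], grid[-1]))
print("high-VIP regions for fat (VIP > 1.5):")
for hi, lo in runs:
    if hi - lo > 0.5:
        print(f"  {hi:6.1f} - {lo:6.1f} ppm")
print("the aliphatic lipid band (~28-38 ppm) carries fat's own signal;")
print("carbohydrate regions (60-80, ~105 ppm) appear too because, after")
print("row-wise SNV normalization, mass shares co-vary through closure.")
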