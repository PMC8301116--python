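"""Generate a synthetic bee-pollen NMR study and look at its structure.

Builds 35 synthetic 13C CPMAS-like spectra (3072 points, 220-0 ppm) with
a matching reference table, then prints where the strongest signals lie
and how the composition statistics compare to real pollen.
"""

import numpy as np

from nmrcal import GeneratorConfig, pearson_r, synthesize

spectra, refs = synthesize(GeneratorConfig(seed=7))

mean = spectra.X.mean(axis=0)
print(f"{spectra.n_samples} spectra on {spectra.n_points} points, "
      f"{spectra.grid[0]:.0f}-{spectra.grid[-1]:.0f} ppm")
peak = spectra.grid[np.argmax(mean)]
carb = (spectra.grid <= 80) & (spectra.grid >= 60)
carb_peak = spectra.grid[carb][np.argmax(mean[carb])]
print(f"tallest mean-spectrum line: {peak:.0f} ppm (lipid CH2); "
      f"carbohydrate stack peaks near {carb_peak:.0f} ppm "
      "- the fingerprint of whole pollen")

df = refs.frame
print(f"protein {df.protein.min():.1f}-{df.protein.max():.1f}%  "
      f"fat {df.fat.min():.1f}-{df.fat.max():.1f}%  "
      f"sugars {df.reducing_sugars.min():.1f}-{df.reducing_sugars.max():.1f}%")
r = pearson_r(df.tp, df.abts)
print(f"TP vs ABTS correlation at n=35: r = {r:.2f} "
      "(tends to ~0.84 at large n; small studies scatter)")
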