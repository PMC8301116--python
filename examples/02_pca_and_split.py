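"""Explore the spectral matrix with PCA and pick a calibration set.

PCA shows how much of the spectral variation is systematic (composition
and scatter) versus noise; the bootstrap Kennard-Stone split then picks
25 calibration samples that span the score space, leaving 10 validation
samples that sit inside the calibrated region.
"""

from nmrcal import (GeneratorConfig, fit_pca, pca_coverage_split, project,
                    synthesize)

spectra, refs = synthesize(GeneratorConfig(seed=7))

pca = fit_pca(spectra, 5)
print("explained variance by PC (%):",
      ", ".join(f"{v:.1f}" for v in pca.explained_variance_pct))
print(f"first five PCs together: {pca.explained_variance_pct.sum():.1f}% "
      "(moderate signal-to-noise: the rest is mostly spectral noise)")

split = pca_coverage_split(spectra, n_val=10, seed=0)
print(f"calibration: {len(split.calibration_ids)} samples, "
      f"validation: {len(split.validation_ids)} samples")

cal = project(pca, spectra.subset(split.calibration_ids))[:, :2]
val = project(pca, spectra.subset(split.validation_ids))[:, :2]
inside = ((val[:, 0] >= cal[:, 0].min()) & (val[:, 0] <= cal[:, 0].max()) &
          (val[:, 1] >= cal[:, 1].min()) & (val[:, 1] <= cal[:, 1].max()))
print(f"validation samples inside the calibration PC1/PC2 box: "
      f"{inside.sum()}/{len(inside)} (external prediction is interpolative)")
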