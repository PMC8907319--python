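"""Show what SNV pretreatment removes from diffuse-reflectance spectra.

Simulates spectra with per-sample multiplicative gain and additive
offset (particle-size scatter effects), applies the standard normal
variate, and verifies that the distortion is gone: spectra that differ
only by gain and offset become identical after SNV.
"""

import dataclasses

import numpy as np

from nircal import default_tea_config, simulate, snv

plain = dataclasses.replace(
    default_tea_config(seed=4, n_vars=654),
    scatter_gain_range=(1.0, 1.0),
    scatter_offset_range=(0.0, 0.0),
    baseline_degree=0,
    noise_sd=0.0,
)
scattered = dataclasses.replace(
    plain, scatter_gain_range=(0.8, 1.2), scatter_offset_range=(-0.1, 0.1)
)

a, _, _ = simulate(plain)
b, truth, _ = simulate(scattered)

raw_gap = np.abs(a.absorbance - b.absorbance).max()
snv_gap = np.abs(snv(a).absorbance - snv(b).absorbance).max()

print(f"max |difference| before SNV: {raw_gap:.4f} absorbance units")
print(f"max |difference| after  SNV: {snv_gap:.2e}")
print()
out = snv(b)
print(f"post-SNV row means (first 3): {out.absorbance.mean(axis=1)[:3]}")
print(f"post-SNV row sds   (first 3): {out.absorbance.std(axis=1, ddof=1)[:3]}")
print()
print("The scatter distortion (gain up to +-20%, offset up to +-0.1) is")
print("removed to machine precision, and every spectrum ends up with")
print("mean 0 and unit sample standard deviation.")
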