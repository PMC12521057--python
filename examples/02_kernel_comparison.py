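"""Reconstruction-kernel dependence of global noise.

Generates one phantom twice with the *same* pre-filter noise amplitude: a
sharp kernel (white noise) and a smooth kernel (2 mm FWHM Gaussian-
correlated noise).  Smoothing removes high-frequency noise power, so every
tissue metric reads lower on the smooth reconstruction — the reason a
noise threshold is only meaningful relative to the reconstruction used.
"""

from ctnoise import PhantomSpec, compute_scan, make_phantom

common = dict(shape=(6, 256, 256), pixel_spacing_mm=0.7,
              body_semi_axes_mm=(60.0, 80.0), sigma_hu=10.0, seed=4,
              rescale_to_sigma=False)  # compare at equal pre-filter amplitude

sharp, _ = make_phantom(PhantomSpec(kernel_fwhm_mm=0.0, **common))
smooth, _ = make_phantom(PhantomSpec(kernel_fwhm_mm=2.0, **common))

s_sharp, s_smooth = compute_scan(sharp), compute_scan(smooth)
print(f"{'metric':<24s} {'sharp':>8s} {'smooth':>8s}")
for metric in ("Duke_tissue_mode", "Wisconsin_tissue_mean", "Wisconsin_tissue_mode"):
    print(f"{metric:<24s} {s_sharp.scan_values[metric]:8.2f} {s_smooth.scan_values[metric]:8.2f}")
print("The smooth kernel reads several HU lower on every tissue metric.")
print("An exam reported from its smoothest reconstruction can therefore")
print("pass a noise threshold that its diagnostic (sharp) series exceeds.")
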