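"""Gaussian mode analysis of pooled bundle orientations.

Samples 600 bundle orientations from a two-mode axial mixture (centers
30° and 96°, weights 0.6/0.4), bins them at 10°, and fits wrapped
Gaussian modes with chi-square model selection, reporting the mode
centers, peak frequencies and the intermodal angle.
"""

import numpy as np

from fiborient import (
    AngularHistogram,
    fit_gaussian_modes,
    intermodal_angle,
    sample_mode_angles,
)

rng = np.random.default_rng(0)
angles, _ = sample_mode_angles([30.0, 96.0], [0.6, 0.4], 10.0, 600, rng)
hist = AngularHistogram.from_angles(angles, bin_width=10.0)
fit = fit_gaussian_modes(hist)

print(f"selected K = {fit.K} modes "
      f"(chi2 = {fit.chi2:.1f}, dof = {fit.dof}, p = {fit.p_value:.3f})")
for i, m in enumerate(fit.modes, start=1):
    print(f"  Mode {i}: center {m.center_deg:6.1f}°, sigma {m.sigma_deg:5.1f}°, "
          f"peak frequency {m.peak_frequency:.1f}% of N={fit.n_total}")
print(f"intermodal angle: {intermodal_angle(fit):.1f}°")
# Mode 1 (the taller peak) recovers the 0.6-weight component near 30°;
# the intermodal angle recovers the planted 66° separation — the
# quantity used to probe lattice-like collagen organization.
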