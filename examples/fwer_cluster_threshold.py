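"""Monte-Carlo minimum-cluster-size thresholds for FWER control.

For a voxel-wise p-value, simulates smoothed Gaussian noise on the analysis
mask and finds the smallest cluster extent whose family-wise probability of
appearing anywhere by chance stays below alpha.  Stronger smoothing inflates
null clusters, so the required extent grows with FWHM; stricter voxel-wise p
shrinks it.
"""

import numpy as np

from rfnclust import SignificanceConfig, cluster_size_threshold, fwer_curve, generate_box_mask
from rfnclust.stats import analytic_envelope

mask = generate_box_mask((12, 12, 8), voxel_size_mm=(3, 3, 3))
cfg = SignificanceConfig(alpha_fwer=0.01, n_iterations=2000, seed=11)

print(f"mask: {mask.n_voxels} voxels, alpha = {cfg.alpha_fwer}")
for fwhm in (0.0, 6.0):
    for p in (1e-4, 1e-3, 1e-2):
        s = cluster_size_threshold(mask, p, fwhm, cfg)
        print(f"  FWHM {fwhm:3.0f} mm, voxel p {p:7.0e}  ->  S_min = {s}")

# the full curve: minimum CC -> voxel p (analytic null envelope) -> S_min
grid = np.arange(0.05, 0.51, 0.05)
env = analytic_envelope(tau=0.3, n_timepoints=290, n_subjects=20, cc_grid=grid)
curve = fwer_curve(mask, env, fwhm_mm=6.0, cfg=cfg, cc_grid=grid)
print("minimum-CC grid:", np.round(curve.min_cc, 2).tolist())
print("required extent:", curve.s_min.tolist())
# clusters whose (size, min CC) lie above this curve are significant at
# FWER p <= 0.01; the size floor (default 12) is applied on top.
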