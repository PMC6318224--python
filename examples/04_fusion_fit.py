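"""Data fusion: sharper orientations from joint HR + LR inference.

Simulates a small two-way-crossing phantom where the HR dataset is noisy
(SNR 15) and the LR dataset is angularly rich and clean (SNR 40), then fits
(a) the HR data alone voxel-wise and (b) both datasets jointly.  The joint
fit keeps the HR grid but borrows angular information from the LR data
through the spatial model and the neighborhood Watson orientation prior.
Takes a minute or two.
"""

import numpy as np

from rubix import MCMCConfig, count_fibres, run_rubix, run_voxelwise, simulate_pair
from rubix.phantom import PhantomSpec

spec = PhantomSpec(
    hr_grid_shape=(4, 4, 2), per_axis_ratio=(2, 2, 2),
    field_kind="crossing90", snr_hr=15.0, snr_lr=40.0, rng_seed=3,
)
hr, lr, truth = simulate_pair(spec)
mask = np.ones(spec.hr_grid_shape, bool)
cfg = MCMCConfig(n_burnin=400, n_sample_iters=200, thin=4, rng_seed=2)

post_fused = run_rubix(hr, truth["hr_scheme"], lr, truth["lr_scheme"],
                       mask, (2, 2, 2), mcmc_cfg=cfg)
post_hr = run_voxelwise(hr, truth["hr_scheme"], mask, mcmc_cfg=cfg)

for name, post in [("HR only ", post_hr), ("fused   ", post_fused)]:
    _, roi = count_fibres(post.mean_fractions)
    mf = post.mean_fractions
    cones = post.cones_95()
    pooled = np.mean([
        cones[i, mf[i] > 0.05].mean() if (mf[i] > 0.05).any() else cones[i, 0]
        for i in range(post.n_voxels)
    ])
    print(f"{name}: 2-way crossings detected in {100 * roi['frac_ge2']:.0f}% "
          f"of voxels, mean 95% cone {pooled:.1f} deg")

print("\nFusion keeps the HR grid but tightens the orientation posteriors "
      "(smaller cone) — the LR data constrain the solution through the "
      "shared neighborhood prior.")
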