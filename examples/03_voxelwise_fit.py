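"""Voxel-wise deconvolution: recover a fibre orientation from noisy data.

Simulates one single-fibre voxel at SNR 30 under a 3-shell protocol, runs a
short MCMC chain and prints the posterior summaries next to the ground
truth.  Takes a few seconds.
"""

import numpy as np

from rubix import (
    BallParams,
    FibreCompartment,
    KernelParams,
    MCMCConfig,
    VoxelParams,
    add_rician_noise,
    make_scheme,
    predict_voxel_signal,
    run_voxelwise,
)

scheme = make_scheme([1000, 2000, 3000], 90, n_b0=5, seed=7)
v_true = np.array([0.0, 0.6, 0.8])
truth = VoxelParams(
    S0=1000.0, ball=BallParams(1e-3, 1e-4), kernel=KernelParams(1e-3, 0.13),
    fibres=(FibreCompartment(0.7, v_true),),
)
rng = np.random.default_rng(0)
data = add_rician_noise(predict_voxel_signal(truth, scheme), 1000 / 30, rng)

post = run_voxelwise(
    data.reshape(1, 1, 1, -1), scheme, np.ones((1, 1, 1), bool),
    mcmc_cfg=MCMCConfig(n_burnin=500, n_sample_iters=250, thin=5, rng_seed=1),
)

dyad = post.mean_dyads()[0, 0]
ang = np.degrees(np.arccos(min(abs(dyad @ v_true), 1.0)))
print(f"retained draws per parameter: {post.n_draws}")
print(f"posterior mean fractions:     {np.round(post.mean_fractions[0], 3)}")
print(f"true f: (0.7, 0, 0) — the ARD prior shrinks the unused compartments")
print(f"orientation error:            {ang:.2f} deg")
print(f"posterior mean d_m:           {post.mean('d_m')[0]:.2e}  (true 1.0e-03)")
print(f"95% cone of uncertainty:      {post.cones_95()[0, 0]:.2f} deg")
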