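"""Metropolis sampler: validation targets, reproducibility, support, modes."""

import numpy as np
import pytest

from rubix import (
    MCMCConfig,
    metropolis_update,
    posterior_mode,
    run_voxelwise,
    sample_target,
)
from rubix.phantom import PhantomSpec, add_rician_noise, make_scheme, simulate_pair

SHORT = MCMCConfig(n_burnin=400, n_sample_iters=200, thin=4, rng_seed=9)


class TestMetropolisUpdate:
    def test_vanishing_scale_accepts(self):
        """Proposal scale -> 0: the posterior change vanishes, acceptance -> 1."""
        rng = np.random.default_rng(0)
        logp = lambda s: -0.5 * s["x"] ** 2
        acc = []
        state = {"x": 0.3}
        for _ in range(200):
            state, a = metropolis_update(state, logp, {"x": 1e-9}, rng)
            acc.append(a["x"])
        assert np.mean(acc) > 0.999

    def test_flat_posterior_accepts(self):
        rng = np.random.default_rng(1)
        state = {"x": 0.0}
        acc = []
        for _ in range(500):
            state, a = metropolis_update(state, lambda s: 0.0, {"x": 2.0}, rng)
            acc.append(a["x"])
        assert np.mean(acc) == 1.0

    def test_out_of_support_rejected(self):
        rng = np.random.default_rng(2)
        logp = lambda s: 0.0 if s["x"] > 0 else -np.inf
        state = {"x": 1e-6}
        for _ in range(100):
            state, _ = metropolis_update(state, logp, {"x": 1.0}, rng)
            assert state["x"] > 0


class TestGaussianTargetValidation:
    def test_mean_and_variance_within_mc_error(self):
        """1-D Gaussian target under the default chain schedule: retained
        draws = 1250/25 = 50; mean/var within 3 MC standard errors."""
        mu, sig = 2.0, 0.7
        cfg = MCMCConfig(rng_seed=4)  # paper schedule: 5000/1250/25
        draws, rates = sample_target(
            lambda s: -0.5 * ((s["x"] - mu) / sig) ** 2,
            {"x": 0.0}, cfg)
        x = draws["x"]
        assert x.size == 50
        # thinned draws are close to independent; allow mild autocorrelation
        se_mean = sig / np.sqrt(x.size)
        assert abs(x.mean() - mu) < 3 * se_mean
        se_var = sig**2 * np.sqrt(2.0 / (x.size - 1))
        assert abs(x.var(ddof=1) - sig**2) < 3 * se_var
        assert 0.1 < rates["x"] < 0.95


@pytest.fixture(scope="module")
def single_fibre_fit(three_shell_scheme_module):
    """A short voxel-wise fit of one noisy single-fibre voxel."""
    import rubix

    scheme = three_shell_scheme_module
    vp = rubix.VoxelParams(
        S0=1000.0, ball=rubix.BallParams(1e-3, 1e-4),
        kernel=rubix.KernelParams(1e-3, 0.13),
        fibres=(rubix.FibreCompartment(0.7, [1.0, 0.0, 0.0]),),
    )
    clean = rubix.predict_voxel_signal(vp, scheme)
    rng = np.random.default_rng(0)
    Y = add_rician_noise(clean, 1000.0 / 30.0, rng)
    data = Y.reshape(1, 1, 1, -1)
    mask = np.ones((1, 1, 1), bool)
    return data, scheme, mask


@pytest.fixture(scope="module")
def three_shell_scheme_module():
    return make_scheme([1000, 2000, 3000], 90, n_b0=5, seed=11)


class TestRunVoxelwise:
    def test_chain_reproducible_and_in_support(self, single_fibre_fit):
        data, scheme, mask = single_fibre_fit
        a = run_voxelwise(data, scheme, mask, mcmc_cfg=SHORT)
        b = run_voxelwise(data, scheme, mask, mcmc_cfg=SHORT)
        for k in a.draws:
            np.testing.assert_array_equal(a.draws[k], b.draws[k])
        # support preservation on every retained draw
        assert np.all(a.draws["f"] >= 0)
        assert np.all(a.draws["f"].sum(axis=2) <= 1 + 1e-12)
        assert np.all(a.draws["d_m"] > 0)
        assert np.all((a.draws["lambda_R"] > 0) & (a.draws["lambda_R"] < 1))
        assert np.all(a.draws["tau"] > 0)
        norms = np.linalg.norm(a.draws["v"], axis=-1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-9)
        assert a.n_draws == SHORT.n_draws

    def test_noise_free_orientation_recovery(self, three_shell_scheme_module):
        """Noise-free single-fibre voxel: posterior orientation within 1 deg."""
        import rubix

        scheme = three_shell_scheme_module
        v_true = np.array([0.0, 0.6, 0.8])
        vp = rubix.VoxelParams(
            S0=1000.0, ball=rubix.BallParams(1e-3, 1e-4),
            kernel=rubix.KernelParams(1e-3, 0.13),
            fibres=(rubix.FibreCompartment(0.7, v_true),),
        )
        data = rubix.predict_voxel_signal(vp, scheme).reshape(1, 1, 1, -1)
        post = run_voxelwise(data, scheme, np.ones((1, 1, 1), bool),
                             mcmc_cfg=SHORT)
        md = post.mean_dyads()[0, 0]
        ang = np.degrees(np.arccos(min(abs(md @ v_true), 1.0)))
        assert ang < 1.0

    def test_all_zero_voxel_skipped(self, three_shell_scheme_module):
        scheme = three_shell_scheme_module
        data = np.zeros((2, 1, 1, len(scheme)))
        data[0, 0, 0] = 1000.0 * np.exp(-scheme.bvals * 1e-3)
        post = run_voxelwise(data, scheme, np.ones((2, 1, 1), bool),
                             mcmc_cfg=SHORT)
        assert post.n_voxels == 1
        assert tuple(post.voxel_indices[0]) == (0, 0, 0)

    def test_cone_shrinks_with_snr(self, three_shell_scheme_module):
        """Posterior concentration: the 95% cone decreases monotonically as
        SNR grows (10 -> 30 -> 100)."""
        import rubix

        scheme = three_shell_scheme_module
        vp = rubix.VoxelParams(
            S0=1000.0, ball=rubix.BallParams(1e-3, 1e-4),
            kernel=rubix.KernelParams(1e-3, 0.13),
            fibres=(rubix.FibreCompartment(0.7, [1.0, 0.0, 0.0]),),
        )
        clean = rubix.predict_voxel_signal(vp, scheme)
        cones = []
        for snr in [10.0, 30.0, 100.0]:
            rng = np.random.default_rng(17)
            data = np.stack(
                [add_rician_noise(clean, 1000.0 / snr, rng) for _ in range(4)]
            ).reshape(4, 1, 1, -1)
            post = run_voxelwise(data, scheme, np.ones((4, 1, 1), bool),
                                 mcmc_cfg=SHORT)
            cones.append(float(post.cones_95()[:, 0].mean()))
        assert cones[0] > cones[1] > cones[2]


class TestPosteriorMode:
    def test_constant_draws(self):
        assert posterior_mode(np.full(30, 3.14)) == pytest.approx(3.14)

    def test_gaussian_draws_mode_near_mean(self):
        rng = np.random.default_rng(5)
        draws = rng.normal(1.5, 0.2, 2000)
        assert posterior_mode(draws) == pytest.approx(1.5, abs=0.05)

    def test_antipodal_orientation_draws(self):
        v = np.array([0.0, 0.0, 1.0])
        draws = np.vstack([np.tile(v, (25, 1)), np.tile(-v, (25, 1))])
        mode = posterior_mode(draws)
        assert abs(mode @ v) == pytest.approx(1.0, abs=1e-9)
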