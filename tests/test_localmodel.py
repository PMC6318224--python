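"""Forward model: Gamma-ball and axially symmetric kernel attenuations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rubix import (
    BallParams,
    FibreCompartment,
    GradientScheme,
    KernelParams,
    VoxelParams,
    ball_attenuation,
    kernel_attenuation,
    predict_voxel_signal,
)
from _oracles import quadrature_anisotropic_attenuation


class TestBallAttenuation:
    @pytest.mark.parametrize(
        "b, d_m, d_std, expected",
        [
            (0.0, 1e-3, 0.5e-3, 1.0),  # b = 0 identity
            (1000.0, 1e-3, 0.5e-3, 0.4096),  # beta = 4000, alpha = 4, 0.8^4
            (2000.0, 1e-3, 1e-8, np.exp(-2.0)),  # mono-exponential limit
        ],
    )
    def test_values(self, b, d_m, d_std, expected):
        att = ball_attenuation(b, BallParams(d_m=d_m, d_std=d_std))
        assert att == pytest.approx(expected, abs=1e-6)

    def test_monoexponential_limit_uniform_over_b(self):
        """As d_std -> 0 the Gamma ball tends to exp(-b d_m) for b <= 3000."""
        b = np.linspace(0, 3000, 31)
        for d_std in [1e-5, 1e-6]:
            gap = np.max(
                np.abs(ball_attenuation(b, BallParams(1e-3, d_std)) - np.exp(-b * 1e-3))
            )
            assert gap < 5e-3 * (d_std / 1e-5) ** 2 + 1e-9
        # below the switch threshold: analytic limit, exact
        gap = np.max(
            np.abs(ball_attenuation(b, BallParams(1e-3, 1e-8)) - np.exp(-b * 1e-3))
        )
        assert gap < 1e-12

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ball_attenuation(-10.0, BallParams(1e-3, 1e-4))
        with pytest.raises(ValueError):
            BallParams(d_m=-1e-3, d_std=1e-4)
        with pytest.raises(ValueError):
            BallParams(d_m=np.nan, d_std=1e-4)


class TestKernelAttenuation:
    kernel = KernelParams(lambda_m=1e-3, lambda_R=0.13)

    def test_b0_identity(self):
        assert kernel_attenuation(0.0, [0, 0, 1], self.kernel, [1, 0, 0]) == 1.0

    def test_parallel_and_perpendicular(self):
        par = kernel_attenuation(1000, [1, 0, 0], self.kernel, [1, 0, 0])
        perp = kernel_attenuation(1000, [0, 1, 0], self.kernel, [1, 0, 0])
        assert par == pytest.approx(np.exp(-3.0 / 1.26), rel=1e-9)
        assert perp == pytest.approx(np.exp(-0.39 / 1.26), rel=1e-9)

    def test_antipodal_invariance(self):
        g = np.array([0.3, -0.5, 0.81])
        g /= np.linalg.norm(g)
        v = np.array([0.0, 0.6, 0.8])
        a = kernel_attenuation(2000, g, self.kernel, v)
        b = kernel_attenuation(2000, g, self.kernel, -v)
        assert a == pytest.approx(b, rel=1e-14)

    def test_lambdaR_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            KernelParams(lambda_m=1e-3, lambda_R=1.3)
        with pytest.raises(ValueError):
            KernelParams(lambda_m=1e-3, lambda_R=0.0)

    def test_quadrature_convolution_oracle(self):
        """Closed form vs dense spherical quadrature of the convolution
        integral for a delta fODF: < 1e-3 relative on random parameters."""
        rng = np.random.default_rng(42)
        for _ in range(20):
            b = rng.uniform(500, 3000)
            lam_m = rng.uniform(0.5e-3, 1.5e-3)
            lam_R = rng.uniform(0.05, 0.4)
            g = rng.standard_normal(3)
            g /= np.linalg.norm(g)
            v = rng.standard_normal(3)
            v /= np.linalg.norm(v)
            closed = kernel_attenuation(b, g, KernelParams(lam_m, lam_R), v)
            quad = quadrature_anisotropic_attenuation(b, g, lam_m, lam_R, v)
            assert abs(closed - quad) / quad < 1e-3


class TestPredictVoxelSignal:
    def test_single_fibre_parallel(self, wm_voxel):
        vp = VoxelParams(
            S0=1000.0, ball=wm_voxel.ball, kernel=wm_voxel.kernel,
            fibres=(FibreCompartment(1.0, [1.0, 0.0, 0.0]),),
        )
        scheme = GradientScheme([1000.0], [[1.0, 0.0, 0.0]])
        assert predict_voxel_signal(vp, scheme)[0] == pytest.approx(92.4, abs=0.1)

    def test_pure_ball_reduction(self, wm_voxel, three_shell_scheme):
        vp = VoxelParams(S0=500.0, ball=wm_voxel.ball, kernel=wm_voxel.kernel,
                         fibres=())
        sig = predict_voxel_signal(vp, three_shell_scheme)
        expected = 500.0 * ball_attenuation(three_shell_scheme.bvals, wm_voxel.ball)
        np.testing.assert_allclose(sig, expected, rtol=1e-14)

    def test_half_fibre_half_ball_composition(self):
        vp = VoxelParams(
            S0=1.0,
            ball=BallParams(1e-3, 0.5e-3),
            kernel=KernelParams(1e-3, 0.13),
            fibres=(FibreCompartment(0.5, [1.0, 0.0, 0.0]),),
        )
        scheme = GradientScheme([1000.0], [[0.0, 1.0, 0.0]])  # g perp v
        assert predict_voxel_signal(vp, scheme)[0] == pytest.approx(
            0.5 * 0.4096 + 0.5 * 0.7338, abs=1e-4
        )

    def test_oversubscribed_fractions_rejected(self, wm_voxel):
        with pytest.raises(ValueError):
            VoxelParams(
                S0=1.0, ball=wm_voxel.ball, kernel=wm_voxel.kernel,
                fibres=(FibreCompartment(0.7, [1, 0, 0]),
                        FibreCompartment(0.6, [0, 1, 0])),
            )

    def test_flip_and_permutation_invariance(self, three_shell_scheme):
        v1 = np.array([1.0, 0.0, 0.0])
        v2 = np.array([0.0, 0.6, 0.8])
        ball = BallParams(1e-3, 1e-4)
        kern = KernelParams(1e-3, 0.13)

        def mk(fibres):
            return predict_voxel_signal(
                VoxelParams(S0=100.0, ball=ball, kernel=kern, fibres=fibres),
                three_shell_scheme,
            )

        base = mk((FibreCompartment(0.4, v1), FibreCompartment(0.3, v2)))
        flipped = mk((FibreCompartment(0.4, -v1), FibreCompartment(0.3, v2)))
        permuted = mk((FibreCompartment(0.3, v2), FibreCompartment(0.4, v1)))
        np.testing.assert_allclose(base, flipped, rtol=1e-14)
        np.testing.assert_allclose(base, permuted, rtol=1e-14)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        f=st.floats(0.0, 1.0),
        d_std=st.floats(0.0, 8e-4),
        seed=st.integers(0, 10_000),
    )
    def test_signal_monotone_in_b_and_bounded(self, f, d_std, seed):
        """For a fixed direction S_k is non-increasing in b and in (0, S0]."""
        rng = np.random.default_rng(seed)
        v = rng.standard_normal(3)
        v /= np.linalg.norm(v)
        g = rng.standard_normal(3)
        g /= np.linalg.norm(g)
        b = np.array([0.0, 500.0, 1000.0, 2000.0, 3000.0])
        vp = VoxelParams(
            S0=100.0, ball=BallParams(1e-3, d_std),
            kernel=KernelParams(1e-3, 0.13),
            fibres=(FibreCompartment(f, v),),
        )
        scheme = GradientScheme(b, np.tile(g, (b.size, 1)))
        sig = predict_voxel_signal(vp, scheme)
        assert np.all(np.diff(sig) <= 1e-12)
        assert np.all(sig > 0) and np.all(sig <= 100.0 + 1e-9)
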