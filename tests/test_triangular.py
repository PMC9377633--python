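"""Upper-triangular generator: spectra, assembly, norms, rotation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from schurnet.geometry import effective_rank
from schurnet.triangular import (
    FeedforwardSpec,
    SpectrumSpec,
    assemble,
    build_network,
    default_n_real,
    rotate_to_recurrent,
    sample_feedforward,
    sample_spectrum,
    scale_feedforward,
    scale_spectrum_to_norm,
    split_norm,
)


def _multiset_close(a, b, tol=1e-8):
    a = np.sort_complex(np.asarray(a))
    b = np.sort_complex(np.asarray(b))
    return np.allclose(a, b, atol=tol)


class TestSampleSpectrum:
    def test_single_value_zero_real(self, rng):
        spec = SpectrumSpec(N=50, real_kind="single_value", value=0.0, d_im=10.0, n_real=2)
        lam = sample_spectrum(spec, rng)
        assert np.allclose(lam.real, 0.0)
        assert np.all(np.abs(lam.imag) <= 5.0)
        assert abs(lam.imag.sum()) < 1e-12

    def test_conjugate_pairing_and_count(self, rng):
        spec = SpectrumSpec(N=200)
        lam = sample_spectrum(spec, rng)
        assert lam.size == 200
        # 3% purely real at N = 200
        assert int(np.sum(lam.imag == 0)) == 6
        assert abs(lam.imag.sum()) < 1e-10

    def test_zero_trace_outlier_construction(self, rng):
        spec = SpectrumSpec(N=200, real_kind="outlier_zero_trace", outlier=-10.0)
        lam = sample_spectrum(spec, rng)
        # M = |outlier| / 0.5 = 20 eigenvalues pinned at the supremum
        assert int(np.sum(np.isclose(lam.real, 0.5))) == 20
        assert np.isclose(lam.real.min(), -10.0)
        assert abs(lam.real.sum()) < 1e-10

    def test_zero_trace_rounding_warns(self, rng):
        spec = SpectrumSpec(N=200, real_kind="outlier_zero_trace", outlier=-10.2)
        with pytest.warns(UserWarning, match="rounded"):
            lam = sample_spectrum(spec, rng)
        assert abs(lam.real.sum()) < 1e-10

    def test_uniform_with_balancer_is_zero_trace_and_stable(self, rng):
        spec = SpectrumSpec(N=200, real_kind="uniform_with_small_outlier")
        for _ in range(5):
            lam = sample_spectrum(spec, rng)
            assert abs(lam.real.sum()) < 1e-10
            assert lam.real.max() < 0.5 + 1e-12

    def test_clustered_imaginary(self, rng):
        spec = SpectrumSpec(
            N=40, imag_kind="clustered", cluster_center=100.0, cluster_radius=0.5,
            real_kind="single_value", value=0.0, n_real=0,
        )
        lam = sample_spectrum(spec, rng)
        assert np.all(np.abs(np.abs(lam.imag) - 100.0) <= 0.5)

    def test_uniform_interval_bounds(self, rng):
        spec = SpectrumSpec(N=50, real_kind="uniform_interval", d_re=10.0, n_real=2)
        lam = sample_spectrum(spec, rng)
        assert np.all(lam.real > -9.5) and np.all(lam.real < 0.5)

    def test_default_n_real(self):
        assert default_n_real(200) == 6
        # complement always even
        for n in (10, 50, 101, 200):
            assert (n - default_n_real(n)) % 2 == 0


class TestAssemble:
    def test_block_layout_and_eigenvalues(self, rng):
        lam = np.array([0.2 + 1j, 0.2 - 1j, -0.1 + 3j, -0.1 - 3j, 0.4 + 0j])
        T = np.triu(rng.uniform(-0.5, 0.5, (5, 5)), k=1)
        T[0, 1] = T[2, 3] = 0.0  # in-block cells
        net = assemble(lam, T)
        assert net.Lambda[0, 0] == 0.2 and net.Lambda[0, 1] == -1.0
        assert net.Lambda[1, 0] == 1.0 and net.Lambda[1, 1] == 0.2
        assert _multiset_close(np.linalg.eigvals(net.W), lam)

    def test_diagonal_when_real_and_no_feedforward(self):
        lam = np.array([0.1, -0.2, 0.3], dtype=complex)
        net = assemble(lam, np.zeros((3, 3)))
        assert np.allclose(net.W, np.diag([0.1, -0.2, 0.3]))
        # normal matrix
        assert np.allclose(net.W @ net.W.T, net.W.T @ net.W)

    def test_rejects_nonzero_in_block_cell(self, rng):
        lam = np.array([0.2 + 1j, 0.2 - 1j, 0.4 + 0j])
        T = np.zeros((3, 3))
        T[0, 1] = 0.3
        with pytest.raises(ValueError):
            assemble(lam, T)

    def test_rejects_lower_triangular_content(self):
        lam = np.array([0.1, 0.2, 0.3], dtype=complex)
        T = np.zeros((3, 3))
        T[2, 0] = 1.0
        with pytest.raises(ValueError):
            assemble(lam, T)

    def test_pythagorean_norm_identity(self, rng):
        net = build_network(
            SpectrumSpec(N=30, n_real=2, d_im=8.0),
            FeedforwardSpec(kind="uniform", target_norm=20.0),
            rng,
        )
        assert np.linalg.norm(net.W, "fro") ** 2 == pytest.approx(
            net.spectrum_norm**2 + net.feedforward_norm**2, rel=1e-12
        )
        assert net.spectrum_norm**2 == pytest.approx(
            np.sum(np.abs(net.eigenvalues) ** 2), rel=1e-12
        )

    def test_strictly_upper_outside_blocks(self, rng):
        net = build_network(
            SpectrumSpec(N=30, n_real=2),
            FeedforwardSpec(kind="uniform", target_norm=10.0),
            rng,
        )
        lower = np.tril(net.W, k=-1)
        # only the beta entries of the 2x2 blocks live below the diagonal
        sub = np.tril(lower, k=-2)
        assert np.all(sub == 0)


class TestFeedforward:
    def test_scaling_exact(self, rng):
        T = np.triu(rng.uniform(-0.5, 0.5, (20, 20)), k=1)
        for target in (75.0, 1.0):
            assert np.linalg.norm(scale_feedforward(T, target), "fro") == pytest.approx(
                target, rel=1e-10
            )
        assert np.all(scale_feedforward(T, 0.0) == 0)
        assert np.allclose(scale_feedforward(T, 150.0), 2 * scale_feedforward(T, 75.0))

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            scale_feedforward(np.zeros((4, 4)), 10.0)

    @pytest.mark.parametrize("kind", ["uniform", "sparse", "chain2"])
    def test_kinds_respect_layout(self, kind, rng):
        spec = SpectrumSpec(N=20, n_real=2, d_im=4.0)
        lam = sample_spectrum(spec, rng)
        T = sample_feedforward(FeedforwardSpec(kind=kind, target_norm=9.0), lam, rng)
        assert np.linalg.norm(T, "fro") == pytest.approx(9.0, rel=1e-10)
        assert np.all(np.tril(T) == 0)
        net = assemble(lam, T)  # must not clash with block cells
        assert _multiset_close(np.linalg.eigvals(net.W), lam, tol=1e-6)

    def test_chain2_only_superdiagonal(self, rng):
        spec = SpectrumSpec(N=20, n_real=2, d_im=4.0)
        lam = sample_spectrum(spec, rng)
        T = sample_feedforward(FeedforwardSpec(kind="chain2", target_norm=5.0), lam, rng)
        assert np.all(np.triu(T, k=2) == 0)


class TestSpectrumScaling:
    def test_imaginary_rescale_hits_target(self, rng):
        lam = sample_spectrum(SpectrumSpec(N=50, n_real=2, d_im=10.0), rng)
        scaled = scale_spectrum_to_norm(lam, 300.0)
        assert np.sqrt(np.sum(np.abs(scaled) ** 2)) == pytest.approx(300.0, rel=1e-12)
        assert np.allclose(scaled.real, lam.real)

    def test_infeasible_target_rejected(self, rng):
        lam = sample_spectrum(SpectrumSpec(N=50, n_real=2, d_im=10.0), rng)
        with pytest.raises(ValueError):
            scale_spectrum_to_norm(lam, 1e-6)

    def test_split_norm_endpoints_and_middle(self, rng):
        spec = SpectrumSpec(N=30, n_real=2, d_im=10.0)
        lam = sample_spectrum(spec, rng)
        T = sample_feedforward(FeedforwardSpec(kind="uniform", target_norm=1.0), lam, rng)
        normal = split_norm(100.0, 100.0, lam, T)
        assert np.all(normal.T == 0)
        assert np.allclose(normal.W @ normal.W.T, normal.W.T @ normal.W, atol=1e-8)
        nilpotent = split_norm(100.0, 0.0, lam, T)
        assert np.allclose(nilpotent.Lambda, 0)
        assert np.max(np.abs(np.linalg.eigvals(nilpotent.W))) < 1e-6
        half = split_norm(100.0, 50.0, lam, T)
        assert half.spectrum_norm == pytest.approx(100.0 / np.sqrt(2), rel=1e-10)
        assert half.feedforward_norm == pytest.approx(100.0 / np.sqrt(2), rel=1e-10)


class TestRotation:
    def test_spectrum_and_erank_preserved(self, rng):
        net = build_network(
            SpectrumSpec(N=20, n_real=2, d_im=6.0),
            FeedforwardSpec(kind="uniform", target_norm=12.0),
            rng,
        )
        W_rec = rotate_to_recurrent(net, rng)
        assert _multiset_close(
            np.linalg.eigvals(W_rec), np.linalg.eigvals(net.W), tol=1e-7
        )

        def erank_v(M):
            V = np.linalg.eig(M)[1]
            return effective_rank(V / np.linalg.norm(V, axis=0))

        assert erank_v(W_rec) == pytest.approx(erank_v(net.W), abs=1e-6)


@given(st.integers(0, 2**31 - 1))
def test_spectrum_norm_independent_of_feedforward(seed):
    rng = np.random.default_rng(seed)
    spec = SpectrumSpec(N=12, n_real=2, d_im=5.0)
    lam = sample_spectrum(spec, rng)
    t_small = sample_feedforward(FeedforwardSpec(kind="uniform", target_norm=1.0), lam, rng)
    t_big = sample_feedforward(FeedforwardSpec(kind="uniform", target_norm=40.0), lam, rng)
    a = assemble(lam, t_small)
    b = assemble(lam, t_big)
    assert a.spectrum_norm == pytest.approx(b.spectrum_norm, rel=1e-12)
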