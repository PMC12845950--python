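"""Eigen (H/A/alpha) and model-based (mv/ms) decompositions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cropsar.decomposition import (
    DecompFlags,
    eigen_decompose,
    entropy_anisotropy_alpha,
    model_based_decompose,
    sar_feature_vector,
    volume_quadratic_coefficient,
)
from cropsar.sar import C2Raster, StokesRaster, c2_to_stokes, stokes_to_c2


def c2_scalar(c11, c22, c12=0j):
    return C2Raster(
        c11=np.array([[c11]]), c22=np.array([[c22]]), c12=np.array([[c12]])
    )


def stokes_scalar(s1, s2, s3, s4):
    return StokesRaster(*(np.array([[v]], dtype=float) for v in (s1, s2, s3, s4)))


def brute_force_mv(s1, s2, s3, s4, step=1e-4):
    """Grid minimizer of |a mv^2 + b mv + c| over [0, s1] — independent
    oracle for the quadratic-root retrieval."""
    a = 0.75
    b = -2.0 * (s1 - 0.5 * s2)
    c = s1**2 - s2**2 - s3**2 - s4**2
    grid = np.arange(0.0, s1 + step, step)
    resid = np.abs(a * grid**2 + b * grid + c)
    return grid[int(np.argmin(resid))]


class TestEigen:
    def test_diagonal_case(self):
        e = eigen_decompose(c2_scalar(3.0, 1.0))
        assert e.l1[0, 0] == pytest.approx(3.0)
        assert e.l2[0, 0] == pytest.approx(1.0)
        assert e.p1[0, 0] == pytest.approx(0.75)
        assert e.alpha1[0, 0] == pytest.approx(0.0)
        assert e.alpha2[0, 0] == pytest.approx(90.0)

    def test_degenerate_spectrum(self):
        e = eigen_decompose(c2_scalar(1.0, 1.0))
        assert e.l1[0, 0] == pytest.approx(e.l2[0, 0])
        assert e.p1[0, 0] == pytest.approx(0.5)

    def test_rank_one(self):
        e = eigen_decompose(c2_scalar(1.0, 0.0))
        assert e.l1[0, 0] == pytest.approx(1.0)
        assert e.l2[0, 0] == pytest.approx(0.0)
        assert e.p1[0, 0] == pytest.approx(1.0)

    def test_matches_numpy_eigh(self, rng):
        # closed-form 2x2 eigenvalues against the general solver
        for _ in range(50):
            z = rng.normal(size=(2, 3)) + 1j * rng.normal(size=(2, 3))
            cov = z @ z.conj().T / 3
            e = eigen_decompose(
                c2_scalar(cov[0, 0].real, cov[1, 1].real, cov[0, 1])
            )
            w = np.linalg.eigvalsh(cov)
            assert e.l1[0, 0] == pytest.approx(w[1], rel=1e-10)
            assert e.l2[0, 0] == pytest.approx(w[0], rel=1e-10, abs=1e-12)

    def test_zero_span_flagged(self):
        e = eigen_decompose(c2_scalar(0.0, 0.0))
        assert e.degenerate[0, 0]
        assert e.p1[0, 0] == pytest.approx(0.5)


class TestHAAlpha:
    def test_maximum_entropy(self):
        haa = entropy_anisotropy_alpha(eigen_decompose(c2_scalar(1.0, 1.0)))
        assert haa.h[0, 0] == pytest.approx(1.0)
        assert haa.a[0, 0] == pytest.approx(0.0)

    def test_deterministic_case(self):
        haa = entropy_anisotropy_alpha(eigen_decompose(c2_scalar(1.0, 0.0)))
        assert haa.h[0, 0] == pytest.approx(0.0)
        assert haa.a[0, 0] == pytest.approx(1.0)

    def test_worked_example(self):
        # P = (0.75, 0.25), alpha_i = (0, 90) deg
        haa = entropy_anisotropy_alpha(eigen_decompose(c2_scalar(3.0, 1.0)))
        assert haa.h[0, 0] == pytest.approx(0.8113, abs=5e-5)
        assert haa.a[0, 0] == pytest.approx(0.5)
        assert haa.alpha[0, 0] == pytest.approx(22.5)

    def test_ranges_on_random_covariances(self, rng):
        z = rng.normal(size=(64, 64, 2, 4)) + 1j * rng.normal(size=(64, 64, 2, 4))
        cov = np.einsum("...ik,...jk->...ij", z, z.conj()) / 4
        c2 = C2Raster(
            c11=cov[..., 0, 0].real, c22=cov[..., 1, 1].real, c12=cov[..., 0, 1]
        )
        haa = entropy_anisotropy_alpha(eigen_decompose(c2))
        assert ((haa.h >= 0) & (haa.h <= 1)).all()
        assert ((haa.a >= 0) & (haa.a <= 1)).all()
        assert ((haa.alpha >= 0) & (haa.alpha <= 90)).all()


class TestModelBased:
    def test_volume_coefficient(self):
        assert volume_quadratic_coefficient() == 0.75

    @pytest.mark.parametrize(
        "s, expected",
        [
            ((2, 1, 0, 0), (2.0, 0.0)),  # pure volume, double root
            ((1, 1, 0, 0), (0.0, 1.0)),  # pure polarized; root 4/3 > s1 rejected
            ((2, 0.5, 1, 0), (1.0, 1.0)),  # volume + polarized mixture
        ],
    )
    def test_worked_cases(self, s, expected):
        md = model_based_decompose(stokes_scalar(*s))
        assert md.mv[0, 0] == pytest.approx(expected[0], abs=1e-12)
        assert md.ms[0, 0] == pytest.approx(expected[1], abs=1e-12)
        # agreement with the brute-force grid oracle
        assert md.mv[0, 0] == pytest.approx(brute_force_mv(*s), abs=2e-4)

    def test_zero_power(self):
        md = model_based_decompose(stokes_scalar(0, 0, 0, 0))
        assert md.mv[0, 0] == 0.0
        assert md.ms[0, 0] == 0.0
        assert md.flags[0, 0] & DecompFlags.ZERO_POWER

    def test_negative_discriminant_flagged(self):
        # s slightly super-polarized (|s_pol| > s1) -> outside model manifold
        md = model_based_decompose(stokes_scalar(1.0, 1.05, 0.2, 0.0))
        assert md.flags[0, 0] != 0
        assert 0.0 <= md.mv[0, 0] <= 1.0

    def test_oracle_equivalence_random_stokes(self, rng):
        """Quadratic-root mv matches the grid minimizer on random valid
        Stokes vectors (partially polarized, drawn via random covariances)."""
        n = 10_000
        z = rng.normal(size=(n, 2, 3)) + 1j * rng.normal(size=(n, 2, 3))
        cov = np.einsum("nik,njk->nij", z, z.conj()) / 3
        c2 = C2Raster(
            c11=cov[:, 0, 0].real.reshape(-1, 1),
            c22=cov[:, 1, 1].real.reshape(-1, 1),
            c12=cov[:, 0, 1].reshape(-1, 1),
        )
        s = c2_to_stokes(c2)
        md = model_based_decompose(s)
        step = 1e-4
        for i in range(0, n, 500):  # chunked grid evaluation
            sl = slice(i, i + 500)
            s1 = s.s1[sl, 0]
            b = -2.0 * (s1 - 0.5 * s.s2[sl, 0])
            c = s1**2 - s.s2[sl, 0] ** 2 - s.s3[sl, 0] ** 2 - s.s4[sl, 0] ** 2
            smax = s1.max()
            grid = np.arange(0.0, smax + step, step)
            resid = np.abs(
                0.75 * grid[None, :] ** 2
                + b[:, None] * grid[None, :]
                + c[:, None]
            )
            resid[grid[None, :] > s1[:, None]] = np.inf
            mv_bf = grid[np.argmin(resid, axis=1)]
            np.testing.assert_allclose(md.mv[sl, 0], mv_bf, atol=2e-4 * max(smax, 1))

    def test_scale_equivariance(self, rng):
        z = rng.normal(size=(32, 2, 4)) + 1j * rng.normal(size=(32, 2, 4))
        cov = np.einsum("nik,njk->nij", z, z.conj()) / 4
        c2 = C2Raster(
            c11=cov[:, 0, 0].real.reshape(-1, 1),
            c22=cov[:, 1, 1].real.reshape(-1, 1),
            c12=cov[:, 0, 1].reshape(-1, 1),
        )
        s = c2_to_stokes(c2)
        k = 7.3
        sk = StokesRaster(s1=k * s.s1, s2=k * s.s2, s3=k * s.s3, s4=k * s.s4)
        md, mdk = model_based_decompose(s), model_based_decompose(sk)
        np.testing.assert_allclose(mdk.mv, k * md.mv, rtol=1e-9)
        np.testing.assert_allclose(mdk.ms, k * md.ms, rtol=1e-9)
        # H/A/alpha are scale-invariant
        haa = entropy_anisotropy_alpha(eigen_decompose(c2))
        c2k = stokes_to_c2(sk)
        haak = entropy_anisotropy_alpha(eigen_decompose(c2k))
        np.testing.assert_allclose(haak.h, haa.h, atol=1e-10)
        np.testing.assert_allclose(haak.alpha, haa.alpha, atol=1e-8)


@given(
    c11=st.floats(0, 10), c22=st.floats(0, 10),
    re12=st.floats(-3, 3), im12=st.floats(-3, 3),
)
@settings(derandomize=True, max_examples=100)
def test_energy_conservation_property(c11, c22, re12, im12):
    """0 <= mv <= s1 and ms = s1 - mv for any PSD covariance pixel."""
    # project C12 into the PSD cone
    lim = np.sqrt(c11 * c22)
    c12 = complex(re12, im12)
    if abs(c12) > lim:
        c12 = c12 * (lim / abs(c12)) if abs(c12) > 0 else 0j
    s = c2_to_stokes(c2_scalar(c11, c22, c12))
    md = model_based_decompose(s)
    s1 = s.s1[0, 0]
    assert -1e-12 <= md.mv[0, 0] <= s1 + 1e-9 * max(s1, 1)
    assert md.ms[0, 0] == pytest.approx(s1 - md.mv[0, 0], abs=1e-12)


class TestFeatureVector:
    def test_seven_bands_in_order(self, rng):
        c2 = C2Raster(
            c11=rng.uniform(0.1, 1, (8, 8)), c22=rng.uniform(0.1, 1, (8, 8)),
            c12=np.zeros((8, 8), complex), date="20240228",
        )
        haa = entropy_anisotropy_alpha(eigen_decompose(c2))
        md = model_based_decompose(c2_to_stokes(c2))
        cube = sar_feature_vector(c2, haa, md)
        assert cube.n_bands == 7
        assert [m.feature for m in cube.meta] == [
            "VV_dB", "VH_dB", "H", "A", "alpha", "mv", "ms"
        ]
        assert all(m.date == "20240228" for m in cube.meta)

    def test_date_mismatch_rejected(self, rng):
        c2 = C2Raster(
            c11=rng.uniform(0.1, 1, (4, 4)), c22=rng.uniform(0.1, 1, (4, 4)),
            c12=np.zeros((4, 4), complex), date="20240228",
        )
        haa = entropy_anisotropy_alpha(eigen_decompose(c2))
        md = model_based_decompose(c2_to_stokes(c2))
        md.date = "20240311"
        with pytest.raises(ValueError, match="date"):
            sar_feature_vector(c2, haa, md)
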