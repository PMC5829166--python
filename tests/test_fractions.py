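"""Synthesis-fraction deconvolution, strand averaging and tract excess."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import hydenseq as hq
from hydenseq.fractions import (
    POLS,
    CorrectedDensity,
    FractionProfile,
    PolymeraseRates,
    canonical_fractions,
    estimate_symmetry_axis,
    reflect_and_average,
    rescale_to_canonical,
    solve_fractions,
    subtract_background,
    subtract_canonical_lagging,
)
from hydenseq.meta import MetaProfile


def _meta(same, opposite, bin_width=5, window=None):
    same = np.asarray(same, dtype=float)
    window = window or (0, bin_width * len(same))
    return MetaProfile(bin_width=bin_width, window=window, same=same,
                       opposite=np.asarray(opposite, dtype=float), n_origins=1)


def _densities_from_fractions(f_same, f_opp, rates, window=(-10_000, 10_000)):
    """Forward model: per-strain densities R @ f on a shared grid."""
    out = {}
    for pol in POLS:
        rho = rates.strain_vector(pol)
        same = rho @ f_same
        opp = rho @ f_opp
        n = f_same.shape[1]
        prof = MetaProfile(bin_width=(window[1] - window[0]) // n, window=window,
                           same=same, opposite=opp, n_origins=1)
        out[pol] = CorrectedDensity(variant_pol=pol, profile=prof, rescale_constant=1.0)
    return out


def _random_simplex(rng, n):
    x = rng.dirichlet(np.ones(3), size=n).T
    return x


class TestSubtractBackground:
    def test_identical_profiles_cancel(self):
        p = _meta([3, 4, 5], [1, 2, 3])
        d = subtract_background(p, p)
        assert d.same.sum() == 0 and d.opposite.sum() == 0

    def test_zero_background_passthrough(self):
        minus = _meta([3, 4, 5], [1, 2, 3])
        zero = _meta([0, 0, 0], [0, 0, 0])
        d = subtract_background(minus, zero)
        np.testing.assert_array_equal(d.same, minus.same)

    def test_negative_bins_clipped(self):
        minus = _meta([3, 0, 5], [0, 0, 0])
        plus = _meta([1, 2, 1], [0, 0, 0])
        d = subtract_background(minus, plus)
        np.testing.assert_array_equal(d.same, [2, 0, 4])


class TestSolveFractions:
    def test_noiseless_identity_random_draws(self):
        rng = np.random.default_rng(42)
        rates = PolymeraseRates()
        n = 300
        f_same = _random_simplex(rng, n)
        f_opp = _random_simplex(rng, n)
        corrected = _densities_from_fractions(f_same, f_opp, rates,
                                              window=(0, 5 * n))
        out = solve_fractions(corrected, rates)
        np.testing.assert_allclose(out["same"].stack(), f_same, atol=1e-8)
        np.testing.assert_allclose(out["opposite"].stack(), f_opp, atol=1e-8)
        np.testing.assert_allclose(out["same"].stack().sum(axis=0), 1.0, atol=1e-12)

    def test_pure_epsilon_recovered(self):
        rates = PolymeraseRates()
        f = np.zeros((3, 50))
        f[2] = 1.0
        corrected = _densities_from_fractions(f, f, rates, window=(0, 250))
        out = solve_fractions(corrected, rates)
        assert np.all(out["same"].f_epsilon >= 0.99)

    def test_singular_strain_design_diagnosed(self):
        rates = PolymeraseRates(
            wild_type={"alpha": 1.0, "delta": 1.0, "epsilon": 1.0},
            variant_fold={"alpha": 1.0 + 1e-9, "delta": 1.0 + 1e-9, "epsilon": 1.0 + 1e-9},
        )
        f = np.full((3, 4), 1 / 3)
        corrected = _densities_from_fractions(f, f, rates, window=(0, 20))
        with pytest.raises(ValueError, match="cond"):
            solve_fractions(corrected, rates)

    def test_monotone_in_planted_delta_share(self):
        """Raising the planted Pol delta share never lowers the recovered one."""
        rates = PolymeraseRates()
        recovered = []
        for fd in np.linspace(0.0, 1.0, 11):
            f = np.array([[0.05], [fd], [max(0.0, 0.95 - fd)]])
            f /= f.sum(axis=0)
            corrected = _densities_from_fractions(f, f, rates, window=(0, 5))
            out = solve_fractions(corrected, rates)
            recovered.append(out["same"].f_delta[0])
        assert np.all(np.diff(recovered) >= -1e-9)

    def test_rescale_then_solve_inverts_forward_model(self):
        """Planted per-strain scale constants are removed by flank anchoring."""
        rng = np.random.default_rng(5)
        rates = PolymeraseRates()
        window = (-10_000, 10_000)
        n = 4000
        centers = np.arange(window[0], window[1], 5) + 2.5
        canon = canonical_fractions(15 / 165)
        f_same = np.tile(canon["lagging"][:, None], (1, n)).astype(float)
        f_same[:, centers > 0] = canon["leading"][:, None]
        bump = (np.abs(centers - 50) < 150)
        f_same[:, bump] = np.array([0.1, 0.8, 0.1])[:, None]
        f_opp = f_same[:, ::-1].copy()
        scales = {"alpha": 3.0, "delta": 0.5, "epsilon": 7.0}
        corrected_in = {}
        for pol in POLS:
            rho = rates.strain_vector(pol)
            prof = MetaProfile(bin_width=5, window=window,
                               same=scales[pol] * (rho @ f_same),
                               opposite=scales[pol] * (rho @ f_opp), n_origins=1)
            corrected_in[pol] = rescale_to_canonical(prof, pol, rates, 15 / 165)
            assert corrected_in[pol].rescale_constant == pytest.approx(scales[pol], rel=1e-9)
        out = solve_fractions(corrected_in, rates)
        np.testing.assert_allclose(out["same"].stack(), f_same, atol=1e-8)


class TestReflectAndAverage:
    def _fp(self, stack, window=(-100, 100)):
        stack = np.clip(np.asarray(stack, dtype=float), 0, None)
        stack /= stack.sum(axis=0)
        n = stack.shape[1]
        return FractionProfile(
            bin_width=(window[1] - window[0]) // n, window=window,
            f_alpha=stack[0], f_delta=stack[1], f_epsilon=stack[2],
        )

    def test_mirror_pair_about_zero_is_fixed_point(self):
        n = 40
        x = np.linspace(-1, 1, n)
        a = 0.2 + 0.1 * x
        d = 0.5 - 0.2 * x
        same = np.vstack([a, d, 1 - a - d])
        opp = same[:, ::-1]
        avg = reflect_and_average(self._fp(same), self._fp(opp), axis_bp=0.0)
        np.testing.assert_allclose(avg.stack(), same, atol=1e-9)

    def test_single_strand_signal_averages_with_its_reflection(self):
        n = 40
        same = np.full((3, n), 1 / 3)
        same[0, 10] += 0.3
        same[2, 10] -= 0.3
        opp = np.full((3, n), 1 / 3)
        avg = reflect_and_average(self._fp(same), self._fp(opp), axis_bp=0.0)
        assert avg.f_alpha[10] == pytest.approx((same[0, 10] + 1 / 3) / 2)


class TestSymmetryAxis:
    def _gauss_pair(self, axis, centers, width=40.0, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        same = np.exp(-0.5 * ((centers - (axis + 80)) / width) ** 2)
        opp = np.exp(-0.5 * ((centers - (axis - 80)) / width) ** 2)
        same = same + noise * rng.standard_normal(len(centers))
        opp = opp + noise * rng.standard_normal(len(centers))
        return same, opp

    def test_exact_pair_about_45(self):
        centers = np.arange(-1000, 1000, 5) + 2.5
        same, opp = self._gauss_pair(45.0, centers)
        assert estimate_symmetry_axis(same, opp, centers=centers) == pytest.approx(45.0)

    def test_exact_pair_about_zero(self):
        centers = np.arange(-1000, 1000, 5) + 2.5
        same, opp = self._gauss_pair(0.0, centers)
        assert estimate_symmetry_axis(same, opp, centers=centers) == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_noised_pair_within_tolerance(self, seed):
        centers = np.arange(-1000, 1000, 5) + 2.5
        same, opp = self._gauss_pair(45.0, centers, noise=0.05, seed=seed)
        axis = estimate_symmetry_axis(same, opp, centers=centers)
        assert abs(axis - 45.0) <= 2.5


class TestSubtractCanonicalLagging:
    def _fp_from_delta(self, f_delta, window=(-10_000, 10_000)):
        f_delta = np.asarray(f_delta, dtype=float)
        n = len(f_delta)
        rest = (1.0 - f_delta) / 2.0
        return FractionProfile(
            bin_width=(window[1] - window[0]) // n, window=window,
            f_alpha=rest, f_delta=f_delta, f_epsilon=rest, strand="averaged",
        )

    def test_flat_profile_gives_zero_excess(self):
        fp = self._fp_from_delta(np.full(4000, 0.6))
        ex = subtract_canonical_lagging(fp)
        np.testing.assert_allclose(ex.excess, 0.0, atol=1e-12)
        assert ex.canonical_level == pytest.approx(0.6)

    def test_gaussian_bump_recovered(self):
        centers = np.arange(-10_000, 10_000, 5) + 2.5
        bump = 0.3 * np.exp(-0.5 * ((centers - 40) / 60) ** 2)
        fp = self._fp_from_delta(0.5 + bump)
        ex = subtract_canonical_lagging(fp)
        np.testing.assert_allclose(ex.excess, bump, atol=1e-3)
        assert abs(ex.peak_bp - 40) <= 5
        # FWHM of a Gaussian is 2.355 sigma
        assert ex.fwhm_bp == pytest.approx(2.355 * 60, abs=10)
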