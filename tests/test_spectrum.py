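"""Single-track spectra, convolution, and the compound track model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rifvar as rv
from rifvar.spectrum import SingleTrackSpectrum, TrackNumberModel


def spectrum(z, p):
    return SingleTrackSpectrum(np.asarray(z, float), np.asarray(p, float))


class TestSpectrumInvariants:
    def test_rejects_empty_unsorted_and_unnormalized(self):
        with pytest.raises(ValueError):
            spectrum([], [])
        with pytest.raises(ValueError):
            spectrum([0.3, 0.1], [0.5, 0.5])
        with pytest.raises(ValueError):
            spectrum([0.1, 0.3], [0.6, 0.6])
        with pytest.raises(ValueError):
            spectrum([-0.1, 0.3], [0.5, 0.5])
        with pytest.raises(ValueError):
            spectrum([0.1, 0.3], [-0.1, 1.1])

    @pytest.mark.parametrize(
        "z, p, mean, sd",
        [
            ([0.1], [1.0], 0.1, 0.0),  # point mass
            ([0.1, 0.3], [0.5, 0.5], 0.2, 0.1),  # symmetric two-point
            ([0.0, 1.0], [0.9, 0.1], 0.1, 0.3),  # sqrt(0.1*0.9) = 0.3
        ],
    )
    def test_single_track_moments(self, z, p, mean, sd):
        m, s = rv.single_track_moments(spectrum(z, p))
        assert m == pytest.approx(mean, abs=1e-12)
        assert s == pytest.approx(sd, abs=1e-12)


class TestConvolveTracks:
    def test_zero_tracks_is_point_mass_at_zero(self, two_point_spectrum):
        f0 = rv.convolve_tracks(two_point_spectrum, 0)
        assert f0.z_grid.tolist() == [0.0]
        assert f0.pmf.tolist() == [1.0]

    def test_one_track_preserves_distribution(self, two_point_spectrum):
        f1 = rv.convolve_tracks(two_point_spectrum, 1, dz=0.1)
        assert f1.mean == pytest.approx(two_point_spectrum.mean, rel=1e-12)
        assert f1.sd == pytest.approx(two_point_spectrum.sd, rel=1e-9)

    def test_point_mass_five_tracks(self):
        f5 = rv.convolve_tracks(spectrum([0.1], [1.0]), 5, dz=0.1)
        # all mass at 5 * z1
        assert f5.mean == pytest.approx(0.5, rel=1e-12)
        assert f5.sd == pytest.approx(0.0, abs=1e-9)

    def test_two_track_sum_enumeration(self, two_point_spectrum):
        # direct enumeration of 2-track sums: {0.2: 0.25, 0.4: 0.5, 0.6: 0.25}
        f2 = rv.convolve_tracks(two_point_spectrum, 2, dz=0.1)
        expected = {0.2: 0.25, 0.4: 0.5, 0.6: 0.25}
        for z, p in zip(f2.z_grid, f2.pmf):
            assert p == pytest.approx(expected.get(round(z, 10), 0.0), abs=1e-12)

    def test_moment_scaling(self, two_point_spectrum):
        f7 = rv.convolve_tracks(two_point_spectrum, 7, dz=0.01)
        assert f7.mean == pytest.approx(7 * 0.2, rel=1e-9)
        assert f7.sd**2 == pytest.approx(7 * 0.1**2, rel=1e-6)

    def test_support_overflow_raises_instead_of_truncating(self, two_point_spectrum):
        with pytest.raises(ValueError, match="z_max"):
            rv.convolve_tracks(two_point_spectrum, 10, z_max=1.0)
        with pytest.raises(ValueError):
            rv.convolve_tracks(two_point_spectrum, -1)


class TestCompoundDistribution:
    def test_no_tracks_gives_point_mass_at_zero(self, two_point_spectrum):
        f = rv.compound_distribution(two_point_spectrum, TrackNumberModel(0.0))
        assert f.z_grid.tolist() == [0.0] and f.pmf.tolist() == [1.0]

    def test_constant_track_energy_reduces_to_scaled_poisson(self):
        # compound of a point mass at z1 is Poisson on {0, z1, 2 z1, ...}
        z1, n = 0.1, 3.0
        f = rv.compound_distribution(spectrum([z1], [1.0]), TrackNumberModel(n), dz=z1)
        assert f.mean == pytest.approx(n * z1, rel=1e-8)
        assert f.sd**2 == pytest.approx(n * z1**2, rel=1e-7)

    def test_compound_moments_two_point(self, two_point_spectrum):
        # mean = n*z1bar = 0.4; var = n*(z1bar^2 + sd1^2) = 2*(0.04+0.01) = 0.10
        f = rv.compound_distribution(
            two_point_spectrum, TrackNumberModel(2.0), mass_tolerance=1e-9, dz=0.1
        )
        assert f.pmf.sum() == pytest.approx(1.0, abs=1e-9)
        assert f.mean == pytest.approx(0.4, rel=1e-7)
        assert f.sd**2 == pytest.approx(0.10, rel=1e-6)

    def test_mass_tolerance_validated(self, two_point_spectrum):
        with pytest.raises(ValueError):
            rv.compound_distribution(two_point_spectrum, TrackNumberModel(2.0), mass_tolerance=0.5)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        atoms=st.lists(
            st.tuples(st.integers(0, 60), st.floats(0.05, 1.0)),
            min_size=1,
            max_size=5,
            unique_by=lambda t: t[0],
        ),
        n=st.floats(0.1, 5.0),
    )
    def test_oracle_equivalence_with_closed_form_moments(self, atoms, n):
        """Compound moments equal n*z1bar and n*(z1bar^2 + sd1^2) on small
        on-grid spectra (so discretization is exact)."""
        dz = 0.005
        atoms = sorted(atoms)
        z = np.array([a * dz for a, _ in atoms])
        w = np.array([p for _, p in atoms])
        spec = SingleTrackSpectrum(z, w / w.sum())
        m1, s1 = rv.single_track_moments(spec)
        f = rv.compound_distribution(spec, TrackNumberModel(n), mass_tolerance=1e-9, dz=dz)
        expect_mean = n * m1
        expect_var = n * (m1**2 + s1**2)
        assert f.mean == pytest.approx(expect_mean, abs=1e-6 + 1e-6 * expect_mean)
        assert f.sd**2 == pytest.approx(expect_var, abs=1e-6 + 1e-6 * expect_var)


class TestNormalApproximation:
    def test_pure_poisson_fluctuation(self):
        spec = rv.normal_approximation(spectrum([0.01], [1.0]), TrackNumberModel(100.0))
        assert spec.mean_z == pytest.approx(1.0)
        assert spec.sd_z == pytest.approx(0.1)

    def test_doubling_n_scales_sd_by_sqrt2(self, two_point_spectrum):
        s1 = rv.normal_approximation(two_point_spectrum, TrackNumberModel(3.0))
        s2 = rv.normal_approximation(two_point_spectrum, TrackNumberModel(6.0))
        assert s2.sd_z / s1.sd_z == pytest.approx(np.sqrt(2), rel=1e-12)

    def test_matches_compound_moments(self, two_point_spectrum):
        spec = rv.normal_approximation(two_point_spectrum, TrackNumberModel(2.0))
        assert spec.mean_z == pytest.approx(0.4)
        assert spec.sd_z == pytest.approx(np.sqrt(0.10))

    def test_ks_distance_to_compound_shrinks_with_track_number(self):
        """The compound law converges to its normal approximation: the KS
        distance decreases in n and is below 0.01 by n = 100."""
        from scipy import stats

        # atoms off a coarse common lattice, so the fine grid fills in and the
        # discrete CDF can approach the continuous limit
        skewed = spectrum([0.10, 0.17, 0.23], [0.5, 0.3, 0.2])
        distances = []
        for n in (5, 20, 50, 100):
            f = rv.compound_distribution(skewed, TrackNumberModel(float(n)), dz=0.01)
            approx = rv.normal_approximation(skewed, TrackNumberModel(float(n)))
            cdf = np.cumsum(f.pmf)
            ref = stats.norm.cdf(f.z_grid, approx.mean_z, approx.sd_z)
            distances.append(float(np.max(np.abs(cdf - ref))))
        assert all(a > b for a, b in zip(distances, distances[1:]))
        assert distances[-1] < 0.01

    def test_track_number_model_validation(self):
        with pytest.raises(ValueError):
            TrackNumberModel(-1.0)
        assert TrackNumberModel(25.0).normal_regime
        assert not TrackNumberModel(5.0).normal_regime
        p = TrackNumberModel(3.0).probabilities(1e-9)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)
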