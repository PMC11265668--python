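import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from markspread import (
    Profile,
    complex_proximity_profile,
    fit_quadratic_trend,
    profile_kurtosis,
    profile_sd,
    profile_to_bedgraph,
    rna_length_scale,
    rna_shell_density,
)


def centered_profile(values_by_site: dict, half_width: int) -> Profile:
    sites = np.arange(-half_width, half_width + 1)
    p = np.array([values_by_site.get(int(i), 0.0) for i in sites])
    return Profile(sites, p)


class TestProfileSd:
    def test_point_mass_has_zero_width(self):
        assert profile_sd(centered_profile({0: 1.0}, 3)) == 0.0

    def test_symmetric_two_point_profile(self):
        prof = centered_profile({-1: 0.5, 1: 0.5}, 2)
        assert profile_sd(prof) == pytest.approx(1.0)

    def test_negative_radicand_fails_loudly(self):
        # off-centre, total mass > 1: the literal form is not a variance
        prof = Profile(np.arange(9, 12), np.ones(3))
        with pytest.raises(ValueError, match="radicand"):
            profile_sd(prof)
        assert profile_sd(prof, normalized=True) == pytest.approx(
            np.sqrt(2.0 / 3.0)
        )

    @given(
        raw=st.lists(st.floats(0.01, 1.0), min_size=3, max_size=21),
    )
    def test_normalized_equals_literal_on_unit_mass(self, raw):
        p = np.array(raw)
        p = p / p.sum()
        half = len(p) // 2
        sites = np.arange(len(p)) - half
        prof = Profile(sites, p)
        assert profile_sd(prof) == pytest.approx(
            profile_sd(prof, normalized=True), abs=1e-9
        )

    def test_symmetrized_profile_zeroes_cross_term(self):
        prof = centered_profile({-2: 0.2, 1: 0.9, 2: 0.9}, 3)
        folded = prof.symmetrized()
        assert np.allclose(folded.p, folded.p[::-1])
        # folded width is computable even when the raw one is not
        assert profile_sd(folded) >= 0

    def test_widening_by_symmetric_kernel_increases_width(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.random(15)
            p /= p.sum()
            prof = Profile(np.arange(-7, 8), p)
            spread = np.convolve(p, [0.25, 0.5, 0.25])
            wide = Profile(np.arange(-8, 9), spread / spread.sum())
            assert profile_sd(wide, normalized=True) >= profile_sd(
                prof, normalized=True
            )


class TestProfileKurtosis:
    def test_two_point_distribution(self):
        prof = centered_profile({-1: 0.5, 1: 0.5}, 2)
        assert profile_kurtosis(prof) == pytest.approx(1.0)

    def test_gaussian_limit_is_three(self):
        sites = np.arange(-300, 301)
        p = np.exp(-(sites.astype(float) ** 2) / (2 * 40.0**2))
        prof = Profile(sites, p / p.max())
        assert profile_kurtosis(prof) == pytest.approx(3.0, rel=1e-3)

    def test_uniform_limit_is_nine_fifths(self):
        n = 400
        prof = Profile(np.arange(-n, n + 1), np.full(2 * n + 1, 0.5))
        assert profile_kurtosis(prof) == pytest.approx(9 / 5, rel=0.01)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError, match="variance"):
            profile_kurtosis(centered_profile({0: 1.0}, 2))


class TestRnaShellDensity:
    def test_no_particles_all_zero(self):
        sd = rna_shell_density(np.empty((0, 2)), dr=1.0, r_max=5.0)
        assert np.all(sd.densities == 0)

    def test_single_particle_density_formula(self):
        dr = 2.0
        sd = rna_shell_density(np.array([[1.0, 0.0]]), dr=dr, r_max=10.0)
        assert sd.densities[0] == pytest.approx(1.0 / (math.pi * dr**2))
        assert np.all(sd.densities[1:] == 0)

    def test_uniform_points_give_flat_density(self, rng):
        n, r_max = 10_000, 8.0
        pts = rng.uniform(-r_max, r_max, size=(4 * n, 2))
        pts = pts[(pts**2).sum(axis=1) <= r_max**2][:n]
        sd = rna_shell_density(pts, dr=1.0, r_max=r_max)
        target = n / (math.pi * r_max**2)
        # Poisson counting error per shell, 5 sigma
        sigma = np.sqrt(np.maximum(sd.counts, 1)) / (
            math.pi * (sd.edges[1:] ** 2 - sd.edges[:-1] ** 2)
        )
        assert np.all(np.abs(sd.densities - target) < 5 * sigma)

    def test_counts_sum_to_particles_within_radius(self, rng):
        pts = rng.normal(scale=3.0, size=(500, 2))
        sd = rna_shell_density(pts, dr=0.5, r_max=4.0)
        inside = np.count_nonzero((pts**2).sum(axis=1) < 4.0**2)
        assert sd.counts.sum() == inside


class TestComplexProximityProfile:
    sites = np.column_stack([np.arange(-3, 4.0), np.zeros(7)])

    def test_no_complexes_all_zero(self):
        prof = complex_proximity_profile(
            [np.empty((0, 2))] * 4, self.sites, d_prox=1.0
        )
        assert np.all(prof == 0)

    def test_stationary_complex_counts_once_per_covered_site(self):
        c = np.array([[3.0, 0.0]])
        prof = complex_proximity_profile([c, c], self.sites, d_prox=1.0)
        # site +3 (distance 0) and +2 (distance 1, inclusive) are covered
        assert np.array_equal(prof, [0, 0, 0, 0, 0, 1, 1])

    def test_counts_are_additive_over_complexes(self):
        c = np.array([[0.0, 0.2], [0.0, -0.2]])
        prof = complex_proximity_profile([c], self.sites, d_prox=1.0)
        assert prof[3] == 2


class TestRnaLengthScale:
    def test_reference_value(self):
        assert rna_length_scale(2e-4, 1e-3) == pytest.approx(0.4472, abs=1e-4)

    def test_quadrupling_diffusivity_doubles_length(self):
        assert rna_length_scale(8e-4, 1e-3) == pytest.approx(
            2 * rna_length_scale(2e-4, 1e-3)
        )

    def test_zero_decay_is_infinite(self):
        assert rna_length_scale(2e-4, 0.0) == math.inf


class TestFitQuadraticTrend:
    def test_exact_parabola(self):
        x = np.array([-2.0, -1, 0, 1, 2])
        a, b, c = fit_quadratic_trend(x, x**2)
        assert (a, b, c) == pytest.approx((1.0, 0.0, 0.0), abs=1e-10)

    def test_exact_line(self):
        x = np.array([0.0, 1, 2, 3])
        a, b, c = fit_quadratic_trend(x, 2 * x + 3)
        assert (a, b, c) == pytest.approx((0.0, 2.0, 3.0), abs=1e-10)

    def test_noisy_recovery(self, rng):
        x = np.linspace(0, 1, 200)
        y = 54.15 * x**2 + 2.05 * x + 3.37 + rng.normal(scale=0.05, size=x.size)
        a, b, c = fit_quadratic_trend(x, y)
        assert a == pytest.approx(54.15, abs=0.5)
        assert b == pytest.approx(2.05, abs=0.5)
        assert c == pytest.approx(3.37, abs=0.2)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            fit_quadratic_trend([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBedgraphExport:
    def test_half_open_intervals_and_values(self, tmp_path):
        prof = centered_profile({-1: 0.25, 0: 1.0, 1: 0.5}, 1)
        path = tmp_path / "track.bedGraph"
        profile_to_bedgraph(prof, path, chrom="chrII", bin_size=200)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("track type=bedGraph")
        assert lines[1] == "chrII\t0\t200\t0.25"
        assert lines[2] == "chrII\t200\t400\t1"
        assert lines[3] == "chrII\t400\t600\t0.5"


class TestProfileContainer:
    def test_non_contiguous_sites_rejected(self):
        with pytest.raises(ValueError):
            Profile(np.array([0, 2, 3]), np.array([0.1, 0.2, 0.3]))

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            Profile(np.arange(3), np.array([0.0, 1.5, 0.2]))

    def test_average_requires_common_support(self):
        a = Profile(np.arange(-1, 2), np.full(3, 0.5))
        b = Profile(np.arange(0, 3), np.full(3, 0.5))
        with pytest.raises(ValueError):
            Profile.average([a, b])
        avg = Profile.average([a, a])
        assert np.allclose(avg.p, a.p)
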