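"""Degrader depth profile, LGCP sampling, and spatial metrics."""

import numpy as np
import pytest

from mcpafate import (
    DepthProfileParams,
    LGCPParams,
    colonization_ratio,
    compute_cv,
    depth_mean_profile,
    genes_to_biomass,
    mean_intensity,
    sample_field,
    uniform_field,
)
from mcpafate.fields import DegraderField, gaussian_field


@pytest.fixture(scope="module")
def profile():
    return DepthProfileParams()


class TestDepthProfile:
    def test_topsoil_value(self, profile):
        assert depth_mean_profile(0.1, profile) == pytest.approx(12.21)

    def test_continuity_at_interface(self, profile):
        assert depth_mean_profile(profile.d_TS, profile) == pytest.approx(
            profile.B_TS)
        assert depth_mean_profile(profile.d_TS + 1e-9, profile) == \
            pytest.approx(profile.B_TS, rel=1e-6)

    def test_exponential_decay_below_topsoil(self, profile):
        # 12.21 * exp(-3 * 0.6) evaluated directly
        assert depth_mean_profile(0.9, profile) == pytest.approx(
            2.018299425, rel=1e-8)

    def test_negative_depth_rejected(self, profile):
        with pytest.raises(ValueError):
            depth_mean_profile(-0.1, profile)


class TestGeneConversion:
    def test_reference_abundance_gives_B_TS(self):
        assert genes_to_biomass(1.11e8, 1.10e-7) == pytest.approx(12.21)

    def test_zero_and_roundtrip(self):
        assert genes_to_biomass(0.0, 1.1e-7) == 0.0
        b = genes_to_biomass(3.7e7, 1.1e-7)
        assert b / 1.1e-7 == pytest.approx(3.7e7)


class TestMeanIntensity:
    def test_topsoil_areal_intensity(self, profile):
        lam = mean_intensity(0.1, profile, LGCPParams(1.0, 9e-3), 1240.0)
        assert lam == pytest.approx(6.882e6, rel=1e-6)
        # expected genes per 5 mm x 5 mm cell
        assert lam * 2.5e-5 == pytest.approx(172.05, rel=1e-6)

    def test_linear_in_thin_section_thickness(self, profile):
        lg1 = LGCPParams(1.0, 9e-3, d_v_sts=0.05e-3)
        lg2 = LGCPParams(1.0, 9e-3, d_v_sts=0.10e-3)
        assert mean_intensity(0.1, profile, lg2, 1240.0) == pytest.approx(
            2 * mean_intensity(0.1, profile, lg1, 1240.0))


class TestGaussianField:
    def test_moments_of_synthesized_field(self):
        rng = np.random.default_rng(5)
        g = gaussian_field(128, 128, 1e-3, sigma2=1.5, beta=8e-3, rng=rng)
        assert g.mean() == pytest.approx(0.0, abs=0.3)
        assert g.var() == pytest.approx(1.5, rel=0.25)

    def test_correlation_decay(self):
        rng = np.random.default_rng(6)
        acc0 = acc10 = 0.0
        for _ in range(8):
            g = gaussian_field(96, 96, 1e-3, 1.0, 5e-3, rng)
            acc0 += g.var()
            acc10 += np.mean(g[:, :-10] * g[:, 10:])
        # exp(-10mm/5mm) = e^-2 ~ 0.135 of the variance
        assert acc10 / acc0 == pytest.approx(np.exp(-2.0), abs=0.08)


class TestSampling:
    def test_poisson_limit_at_zero_variance(self, profile, rho_lookup):
        """sigma^2 = 0 reduces to an inhomogeneous Poisson process."""
        f = sample_field(profile, LGCPParams(0.0, 9e-3), rho_lookup,
                         0.3, 0.3, rng=np.random.default_rng(11))
        counts = f.gene_count
        assert counts.mean() == pytest.approx(172.05, rel=0.03)
        # index of dispersion ~ 1 for Poisson counts
        assert counts.var() / counts.mean() == pytest.approx(1.0, abs=0.1)
        assert compute_cv(f) == pytest.approx(100 / np.sqrt(172.05), rel=0.1)
        assert colonization_ratio(f) == pytest.approx(100.0, abs=0.1)

    def test_seed_reproducibility(self, profile, rho_lookup):
        lg = LGCPParams(1.2, 9e-3)
        f1 = sample_field(profile, lg, rho_lookup, 0.1, 0.1, rng=42)
        f2 = sample_field(profile, lg, rho_lookup, 0.1, 0.1, rng=42)
        assert np.array_equal(f1.gene_count, f2.gene_count)

    def test_ensemble_mean_biomass_is_unbiased(self, profile, rho_lookup):
        """Mean-corrected LGCP: E[cell B] = depth profile (within 2 SEM)."""
        rng = np.random.default_rng(13)
        lg = LGCPParams(1.0, 6e-3)
        means = [sample_field(profile, lg, rho_lookup, 0.1, 0.1,
                              rng=rng).B.mean() for _ in range(60)]
        mean = np.mean(means)
        sem = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(mean - 12.21) < 2 * sem + 0.05

    def test_subsoil_more_heterogeneous_less_colonized(self, profile,
                                                       rho_lookup):
        """Emergent depth trend: CV rises and CR falls below the topsoil."""
        rng = np.random.default_rng(17)
        cv_ts, cv_ss, cr_ts, cr_ss = [], [], [], []
        for _ in range(10):
            f = sample_field(profile, LGCPParams(1.687, 9.6e-3), rho_lookup,
                             0.15, 0.9, rng=rng)
            cv_ts.append(compute_cv(f, 0.0, 0.3))
            cv_ss.append(compute_cv(f, 0.3, 0.9))
            cr_ts.append(colonization_ratio(f, 0.0, 0.3))
            cr_ss.append(colonization_ratio(f, 0.3, 0.9))
        assert np.mean(cv_ss) > np.mean(cv_ts)
        assert np.mean(cr_ss) < np.mean(cr_ts)


class TestMetrics:
    def _make(self, B):
        B = np.asarray(B, dtype=float)
        ny, nx = B.shape
        yc = (np.arange(ny) + 0.5) * 5e-3
        xc = (np.arange(nx) + 0.5) * 5e-3
        genes_per_g = B / 1.1e-7 * 1e-3 / 1e3  # arbitrary consistent scale
        return DegraderField(B, B.copy(), genes_per_g, yc, xc, 5e-3)

    def test_uniform_field_cv_zero(self):
        f = self._make(np.full((10, 10), 3.3))
        assert compute_cv(f, 0.0, 0.05) == 0.0

    def test_two_group_cv_closed_form(self):
        """Half the cells at B, half at 3B: CV = 50% exactly."""
        B = np.concatenate([np.full((5, 10), 1.0), np.full((5, 10), 3.0)])
        f = self._make(B)
        assert compute_cv(f, 0.0, 0.05) == pytest.approx(50.0)

    def test_hom_field_cv_zero_by_construction(self, profile, rho_lookup):
        f = uniform_field(profile, LGCPParams(0.0, 9e-3), rho_lookup,
                          0.1, 0.3)
        assert compute_cv(f) == pytest.approx(0.0, abs=1e-9)

    def test_zero_field_cr_and_cv_error(self):
        f = self._make(np.zeros((4, 4)))
        assert colonization_ratio(f, 0.0, 0.02) == 0.0
        with pytest.raises(ValueError):
            compute_cv(f, 0.0, 0.02)

    def test_single_gene_per_cell_exceeds_threshold(self, profile,
                                                    rho_lookup):
        """One gene in a 5 mm cell is ~645 genes/g, above the 100 genes/g
        colonization threshold, so CR counts exactly the occupied cells."""
        f = sample_field(profile, LGCPParams(2.0, 9e-3), rho_lookup,
                         0.1, 0.3, rng=3)
        occupied = 100.0 * np.mean(f.gene_count[f.region_mask(0, 0.3)] >= 1)
        assert colonization_ratio(f) == pytest.approx(occupied)
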