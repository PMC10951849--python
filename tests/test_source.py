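"""Band Fourier segments, eLORETA inverse, source power ratios and the
voxel-wise permutation test."""

import itertools

import numpy as np
import pytest

from thetareg.containers import DataError
from thetareg.source import (
    band_fourier,
    eloreta_inverse,
    power_ratio_contrast,
    source_band_power,
    voxel_permutation_test,
)

from conftest import build_epochs


def stationary_epochs(rng, n_ch=4, n_tr=40, sfreq=100.0):
    return build_epochs(rng.standard_normal((n_ch, 1301, n_tr)), sfreq=sfreq)


class TestBandFourier:
    def test_tone_concentrates_in_its_bin(self, rng):
        sfreq = 100.0
        t = -6.0 + np.arange(1301) / sfreq
        n_tr = 30
        data = np.empty((1, 1301, n_tr))
        for k in range(n_tr):
            data[0, :, k] = np.sin(2 * np.pi * 6.0 * t + rng.uniform(0, 2 * np.pi))
        ep = build_epochs(data, sfreq=sfreq)
        spec = band_fourier(ep, "regulation")
        power = (np.abs(spec.coefficients[:, 0, :]) ** 2).mean(axis=0)
        i6 = int(np.argmin(np.abs(spec.bins - 6.0)))
        others = np.delete(power, i6)
        assert power[i6] > 10 * others.max()

    def test_zero_signal_zero_coefficients(self):
        ep = build_epochs(np.zeros((2, 1301, 3)), sfreq=100.0)
        spec = band_fourier(ep, "baseline")
        assert np.abs(spec.coefficients).max() == 0.0

    def test_eleven_theta_bins(self, rng):
        spec = band_fourier(stationary_epochs(rng), "regulation")
        assert len(spec.bins) == 11
        assert spec.bins[0] == 3.5 and spec.bins[-1] == 8.5

    def test_stationary_process_segment_powers_match(self, rng):
        """Unit-energy tapers make baseline and regulation PSD estimates
        agree for a stationary process despite different segment lengths."""
        ep = stationary_epochs(rng, n_tr=120)
        p_reg = (np.abs(band_fourier(ep, "regulation").coefficients) ** 2).mean()
        p_base = (np.abs(band_fourier(ep, "baseline").coefficients) ** 2).mean()
        assert 0.8 < p_reg / p_base < 1.25

    def test_off_grid_bin_raises(self, rng):
        with pytest.raises(DataError):
            band_fourier(stationary_epochs(rng, n_tr=3), "regulation",
                         bins=np.array([3.6]))

    def test_unknown_segment_raises(self, rng):
        with pytest.raises(DataError):
            band_fourier(stationary_epochs(rng, n_tr=3), "rest")


class TestEloreta:
    def test_exact_point_source_localisation(self, leadfield, operator_exact):
        """Noiseless single-dipole data localises to the true voxel for
        every voxel and orientation (zero-localisation-error property)."""
        n_v = leadfield.gain.shape[0]
        for v in range(n_v):
            for o in range(3):
                j = operator_exact.apply(leadfield.gain[v, o])
                power = (j ** 2).sum(axis=1)
                assert int(np.argmax(power)) == v

    def test_linearity_and_scaling(self, leadfield, operator_exact, rng):
        x = rng.standard_normal(64)
        y = rng.standard_normal(64)
        jxy = operator_exact.apply(x + y)
        jx, jy = operator_exact.apply(x), operator_exact.apply(y)
        assert np.max(np.abs(jxy - jx - jy)) < 1e-10 * np.max(np.abs(jxy))
        assert np.allclose(operator_exact.apply(3.0 * x), 3.0 * jx, rtol=1e-12)

    def test_convergence_report(self, operator_exact):
        assert operator_exact.final_change < 1e-6
        assert operator_exact.n_iterations <= 100

    def test_negative_regularisation_rejected(self, leadfield):
        with pytest.raises(DataError):
            eloreta_inverse(leadfield, alpha_reg=-0.1)


class TestSourcePower:
    def test_zero_spectra_zero_power(self, operator_exact):
        from thetareg.source import BandSpectra, THETA_BINS

        spec = BandSpectra(np.zeros((3, 64, 11), complex), THETA_BINS, "regulation")
        assert source_band_power(operator_exact, spec).max() == 0.0

    def test_common_phase_rotation_invariance(self, operator_exact, rng):
        from thetareg.source import BandSpectra, THETA_BINS

        coef = rng.standard_normal((4, 64, 11)) + 1j * rng.standard_normal((4, 64, 11))
        p1 = source_band_power(operator_exact,
                               BandSpectra(coef, THETA_BINS, "regulation"))
        p2 = source_band_power(operator_exact,
                               BandSpectra(coef * np.exp(0.9j), THETA_BINS,
                                           "regulation"))
        assert np.allclose(p1, p2, rtol=1e-10)

    def test_planted_source_peaks_near_truth(self, leadfield, operator_exact, rng):
        from thetareg.source import BandSpectra, THETA_BINS

        v = 17
        moment = rng.standard_normal(3)
        topo = moment @ leadfield.gain[v]
        coef = (topo[None, :, None]
                * np.exp(2j * np.pi * rng.random((60, 1, 11))))
        coef = coef + 0.02 * np.abs(topo).max() * (
            rng.standard_normal(coef.shape) + 1j * rng.standard_normal(coef.shape))
        power = source_band_power(
            operator_exact, BandSpectra(coef, THETA_BINS, "regulation"))
        top = int(np.argmax(power))
        hm = leadfield.head_model
        dist = np.linalg.norm(hm.voxel_positions[top] - hm.voxel_positions[v])
        spacing = np.median(np.linalg.norm(
            hm.voxel_positions - hm.voxel_positions[v], axis=1)[1:10])
        assert top == v or dist <= spacing


class TestPowerRatio:
    def test_stationary_ratio_near_one_contrast_near_zero(self, rng):
        base = {"reappraise": np.full(5, 2.0), "maintain": np.full(5, 3.0)}
        reg = {"reappraise": np.full(5, 2.0) * 1.01,
               "maintain": np.full(5, 3.0) * 0.99}
        c = power_ratio_contrast(reg, base)
        assert np.abs(c).max() < 0.05

    def test_antisymmetric_under_condition_swap(self, rng):
        reg = {"reappraise": rng.uniform(1, 2, 6), "maintain": rng.uniform(1, 2, 6)}
        base = {"reappraise": rng.uniform(1, 2, 6), "maintain": rng.uniform(1, 2, 6)}
        c1 = power_ratio_contrast(reg, base, ("reappraise", "maintain"))
        c2 = power_ratio_contrast(reg, base, ("maintain", "reappraise"))
        assert np.allclose(c1, -c2, atol=1e-14)

    def test_zero_baseline_names_voxel(self):
        base = {"reappraise": np.array([1.0, 0.0, 2.0]),
                "maintain": np.ones(3)}
        reg = {"reappraise": np.ones(3), "maintain": np.ones(3)}
        with pytest.raises(DataError, match="voxel 1"):
            power_ratio_contrast(reg, base)


def brute_force_voxel_p(a, b):
    """Exhaustive two-sided permutation p of the group mean difference."""
    pooled = np.vstack([a, b])
    n = pooled.shape[0]
    n_a = a.shape[0]
    obs = a.mean(axis=0) - b.mean(axis=0)
    count = np.zeros(pooled.shape[1])
    total = 0
    for c in itertools.combinations(range(n), n_a):
        sel = np.zeros(n, bool)
        sel[list(c)] = True
        diff = pooled[sel].mean(axis=0) - pooled[~sel].mean(axis=0)
        count += np.abs(diff) >= np.abs(obs) - 1e-12
        total += 1
    return count / total


class TestVoxelPermutation:
    def test_monte_carlo_matches_enumeration(self, rng):
        a = rng.standard_normal((4, 5)) + [1.2, 0, 0, 0.5, 0]
        b = rng.standard_normal((4, 5))
        n_perm = 4000
        res = voxel_permutation_test(a, b, n_perm=n_perm, seed=11)
        exact = brute_force_voxel_p(a, b)
        se = np.sqrt(np.maximum(exact * (1 - exact), 1e-6) / n_perm)
        assert np.all(np.abs(res.p_values - exact) < 3 * se + 2 / n_perm)

    def test_null_rejection_rate_calibrated(self, rng):
        rejections = []
        for s in range(120):
            r = np.random.default_rng(s)
            res = voxel_permutation_test(r.standard_normal((6, 4)),
                                         r.standard_normal((6, 4)),
                                         n_perm=250, seed=s)
            rejections.append(res.p_values < 0.05)
        rate = np.mean(rejections)
        n = 120 * 4
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n)

    def test_one_sided_option(self, rng):
        a = rng.standard_normal((6, 3)) + 1.0
        b = rng.standard_normal((6, 3))
        two = voxel_permutation_test(a, b, n_perm=500, seed=1, tails="two")
        one = voxel_permutation_test(a, b, n_perm=500, seed=1, tails="greater")
        assert np.all(one.p_values <= two.p_values + 1e-12)

    def test_cluster_reporting_on_grid(self, rng):
        """Two well-separated significant groups of voxels are reported as
        two contiguous clusters with sensible centroids."""
        offsets = np.array([[k * 0.002, 0.0, 0.0] for k in range(5)])
        pts = np.concatenate([
            np.array([0.05, 0, 0]) + offsets,
            np.array([-0.05, 0, 0]) - offsets,
        ])
        effect = np.zeros(10)
        effect[:5] = 4.0
        effect[5:] = -4.0
        a = rng.standard_normal((8, 10)) * 0.3 + effect
        b = rng.standard_normal((8, 10)) * 0.3
        res = voxel_permutation_test(a, b, n_perm=500, seed=2,
                                     voxel_positions=pts)
        assert len(res.clusters) == 2
        cx = sorted(c["centroid_mm"][0] for c in res.clusters)
        assert cx[0] < -30 and cx[1] > 30

    def test_metadata_states_no_correction(self, rng):
        res = voxel_permutation_test(rng.standard_normal((3, 4)),
                                     rng.standard_normal((3, 4)),
                                     n_perm=120, seed=0)
        assert "correction" in res.metadata

    def test_too_few_permutations_rejected(self, rng):
        with pytest.raises(DataError):
            voxel_permutation_test(rng.standard_normal((3, 4)),
                                   rng.standard_normal((3, 4)), n_perm=50)
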