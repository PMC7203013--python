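"""Peak detection, Gaussian fitting and the burst-time clock."""

import numpy as np
import pytest

from ltrburst import (
    GaussianPeak,
    burst_time,
    detect_peaks,
    fit_gpdf,
    profile_and_date,
    simulate,
    SimConfig,
)
from ltrburst.dots import IdentityDistribution


def mixture_distribution(components, lo, hi, width):
    n = int(round((hi - lo) / width))
    edges = lo + width * np.arange(n + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    counts = np.zeros_like(mids)
    for amp, mu, sigma in components:
        counts += amp * np.exp(-0.5 * ((mids - mu) / sigma) ** 2)
    return IdentityDistribution(edges, counts)


class TestDetectPeaks:
    def test_unimodal_gives_one_window_containing_mode(self, gaussian_dist_factory):
        dist = gaussian_dist_factory(88.0, 0.5, 1000, 84.0, 92.0, 0.1)
        windows = detect_peaks(dist)
        assert len(windows) == 1
        lo, hi = windows[0]
        assert lo < 88.0 < hi

    def test_two_gaussians_split_near_exact_valley(self):
        """Window boundary sits at the brute-force valley of the true mixture."""
        comps = [(1000, 88.0, 0.3), (1000, 94.0, 0.3)]
        dist = mixture_distribution(comps, 86.0, 96.0, 0.1)
        # independent oracle: argmin of the exact mixture curve between modes
        grid = np.linspace(88.0, 94.0, 60001)
        curve = sum(a * np.exp(-0.5 * ((grid - m) / s) ** 2) for a, m, s in comps)
        oracle_valley = grid[int(np.argmin(curve))]
        w1, w2 = detect_peaks(dist)
        assert w1[1] == pytest.approx(w2[0])
        assert abs(w1[1] - oracle_valley) <= 0.5
        assert w1[0] < 88.0 < w1[1] < 94.0 < w2[1]

    def test_flat_distribution_has_no_peaks(self):
        dist = IdentityDistribution(
            np.arange(80.0, 90.1, 0.1), np.full(100, 5.0)
        )
        assert detect_peaks(dist) == []

    def test_all_zero_distribution_is_empty(self):
        dist = IdentityDistribution(np.arange(80.0, 90.1, 0.1), np.zeros(100))
        assert detect_peaks(dist) == []

    def test_too_few_nonempty_bins_rejected(self):
        counts = np.zeros(100)
        counts[10] = counts[50] = 1.0
        dist = IdentityDistribution(np.arange(80.0, 90.1, 0.1), counts)
        with pytest.raises(ValueError, match="non-empty bins"):
            detect_peaks(dist)


class TestFitGpdf:
    def test_exact_histogram_recovers_generator(self, gaussian_dist_factory):
        dist = gaussian_dist_factory(88.25, 0.2415, 1000, 86.5, 90.0, 0.1)
        peak = fit_gpdf(dist, (86.5, 90.0))
        assert peak.mu == pytest.approx(88.25, rel=1e-6)
        assert peak.sigma_pct == pytest.approx(0.2415, rel=1e-6)
        assert peak.amplitude == pytest.approx(1000, rel=1e-6)
        assert peak.adj_r2 >= 0.9999
        assert not peak.rejected

    def test_noise_floor_shifts_mu_slightly_and_lowers_adj_r2(self, gaussian_dist_factory):
        dist = gaussian_dist_factory(88.25, 0.2415, 1000, 86.5, 90.0, 0.1)
        rng = np.random.default_rng(12345)
        noisy = IdentityDistribution(
            dist.bin_edges, dist.counts + rng.uniform(0, 50, size=dist.counts.size)
        )
        peak = fit_gpdf(noisy, (86.5, 90.0))
        assert abs(peak.mu - 88.25) < 0.02
        assert peak.adj_r2 < 1.0

    def test_three_bin_window_is_underdetermined(self, gaussian_dist_factory):
        dist = gaussian_dist_factory(88.0, 0.3, 100, 86.0, 90.0, 0.1)
        with pytest.raises(ValueError, match=">= 4"):
            fit_gpdf(dist, (87.9, 88.2))

    def test_poor_fit_flagged_rejected_not_dropped(self):
        rng = np.random.default_rng(0)
        edges = np.arange(80.0, 90.05, 0.1)
        counts = rng.uniform(10, 20, size=edges.size - 1)
        counts[50] = 100.0  # a spike a Gaussian cannot describe well
        dist = IdentityDistribution(edges, counts)
        peak = fit_gpdf(dist, (80.0, 90.0))
        assert peak.rejected
        assert peak.adj_r2 < 0.95


class TestBurstTime:
    @pytest.mark.parametrize(
        "sigma_pct,age_ma",
        [(0.24147, 0.89), (0.16550, 0.61), (1.5465, 5.70), (0.54264, 2.00)],
    )
    def test_printed_burst_ages(self, sigma_pct, age_ma):
        """The clock maps each observed peak width to its published age."""
        peak = GaussianPeak(88.0, sigma_pct, 1000.0, 0.999, (85.0, 91.0))
        est = burst_time(peak, r=7e-9)
        assert est.t_ma == pytest.approx(age_ma, rel=0.01)

    def test_calibration_identity_exact(self):
        peak = GaussianPeak(88.0, 0.333, 1000.0, 0.999, (85.0, 91.0))
        est = burst_time(peak)
        assert est.K / (peak.sigma_pct / 100.0) == pytest.approx(2.58, rel=1e-14)
        assert est.t * est.r == pytest.approx(est.K, rel=1e-14)

    def test_age_monotone_in_sigma_and_rate(self):
        mk = lambda s: GaussianPeak(88.0, s, 1.0, 1.0, (80.0, 96.0))
        t = lambda s, r: burst_time(mk(s), r=r).t
        assert t(0.2, 7e-9) < t(0.3, 7e-9) < t(0.4, 7e-9)
        assert t(0.3, 3.5e-9) == pytest.approx(2 * t(0.3, 7e-9))

    def test_zero_width_limit_gives_zero_age(self):
        ages = [burst_time(GaussianPeak(88.0, s, 1.0, 1.0, (80, 96))).t
                for s in (1e-3, 1e-5, 1e-7)]
        assert ages == sorted(ages, reverse=True)
        assert ages[-1] < 1.0

    def test_non_positive_rate_rejected(self):
        peak = GaussianPeak(88.0, 0.3, 1.0, 1.0, (80.0, 96.0))
        with pytest.raises(ValueError, match="r must be positive"):
            burst_time(peak, r=0)

    def test_mean_divergence_mode(self):
        peak = GaussianPeak(99.3, 0.3, 1.0, 1.0, (98.0, 100.0))
        est = burst_time(peak, mode="mean")
        assert est.K == pytest.approx(0.007)
        assert est.too_recent  # mu above the reliable-dating threshold

    def test_near_perfect_peaks_flagged_too_recent(self):
        old = burst_time(GaussianPeak(88.0, 0.3, 1.0, 1.0, (80.0, 96.0)))
        young = burst_time(GaussianPeak(97.9, 0.3, 1.0, 1.0, (96.0, 100.0)))
        assert not old.too_recent
        assert young.too_recent


class TestProfileAndDate:
    def test_empty_hits_give_empty_estimates(self):
        assert profile_and_date([]) == []

    def test_two_burst_table_yields_two_ordered_estimates(self):
        ds = simulate(SimConfig(bursts=((0.61e6, 300), (2.0e6, 300)), seed=11))
        ests = profile_and_date(list(ds.hits))
        assert len(ests) == 2
        # youngest burst first: mean identity strictly decreasing
        assert ests[0].peak.mu > ests[1].peak.mu

    def test_five_component_mixture_recovers_five_estimates(self):
        """A five-burst landscape like the cotton Gypsy profile separates.

        Ages are spaced so that adjacent peaks sit further apart than the
        sum of their binomial widths (older peaks are wider), the regime
        where valley splitting is well defined."""
        ages = (0.61e6, 2.0e6, 4.0e6, 7.0e6, 11.0e6)
        ds = simulate(SimConfig(bursts=tuple((a, 400) for a in ages), seed=3))
        ests = profile_and_date(list(ds.hits))
        assert len(ests) == 5
        mus = [e.peak.mu for e in ests]
        assert mus == sorted(mus, reverse=True)
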