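"""Group summaries, double-SD selection, rank-sum test, Cohen's d."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fgrs.spectra import Band, BandPanel, SpectraSet, Spectrum
from fgrs.stats import (
    abs_diff_spectrum,
    band_stats_table,
    cohens_d,
    double_sd_mask,
    group_mean_sd,
    mann_whitney_u,
    significance_stars,
)


def exact_ranksum_p(x, y):
    """Two-sided rank-sum p by exhaustive enumeration of all labelings."""
    pooled = np.concatenate([x, y])
    nx = len(x)
    u_obs = sum(
        1.0 if xi > yj else (0.5 if xi == yj else 0.0)
        for xi in x for yj in y
    )
    center = nx * len(y) / 2.0
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        xs = pooled[list(idx)]
        ys = np.delete(pooled, list(idx))
        u = sum(
            1.0 if xi > yj else (0.5 if xi == yj else 0.0)
            for xi in xs for yj in ys
        )
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestGroupSummary:
    def test_identical_spectra_zero_sd(self, axis571):
        y = np.linspace(0, 1, 571)
        spectra = [
            Spectrum(axis571, y, sample_id=f"s{i}", label="high")
            for i in range(3)
        ]
        summary = group_mean_sd(SpectraSet.from_spectra(spectra), "high")
        np.testing.assert_allclose(summary.sd, 0.0, atol=1e-15)
        assert summary.n == 3

    def test_hand_computed_mean_sd(self):
        axis = np.array([100.0, 200.0])
        spectra = [
            Spectrum(axis, [0.1, 0.0], sample_id="a", label="g"),
            Spectrum(axis, [0.3, 0.0], sample_id="b", label="g"),
        ]
        summary = group_mean_sd(SpectraSet.from_spectra(spectra), "g")
        assert summary.mean.intensities[0] == pytest.approx(0.2)
        assert summary.sd[0] == pytest.approx(0.1414, abs=1e-4)

    def test_absent_label_errors(self, two_class_set):
        with pytest.raises(ValueError):
            group_mean_sd(two_class_set, "nope")


class TestDiffAndMask:
    def test_equal_groups_zero_diff_empty_mask(self, two_class_set):
        a = group_mean_sd(two_class_set, "high")
        diff = abs_diff_spectrum(a, a)
        np.testing.assert_array_equal(diff.intensities, 0.0)
        assert double_sd_mask(a, a).n_selected == 0

    def test_diff_is_symmetric(self, two_class_set):
        a = group_mean_sd(two_class_set, "high")
        b = group_mean_sd(two_class_set, "low")
        np.testing.assert_array_equal(
            abs_diff_spectrum(a, b).intensities,
            abs_diff_spectrum(b, a).intensities,
        )

    def test_single_outlier_channel_selected(self, axis571):
        # |diff| is 0.01 everywhere except one channel at 1.0; the scalar
        # threshold (2 x across-channel SD) must keep exactly that channel
        diff = np.full(571, 0.01)
        diff[300] = 1.0
        mean_a = Spectrum(axis571, diff, sample_id="a")
        mean_b = Spectrum(axis571, np.zeros(571), sample_id="b")
        from fgrs.stats import GroupSummary

        a = GroupSummary("A", mean_a, np.zeros(571), 5)
        b = GroupSummary("B", mean_b, np.zeros(571), 5)
        mask = double_sd_mask(a, b)
        expected_threshold = 2.0 * np.std(diff, ddof=1)
        assert mask.threshold_value == pytest.approx(expected_threshold)
        assert mask.n_selected == 1
        assert mask.mask[300]

    def test_mask_shrinks_with_multiplier(self, two_class_set):
        a = group_mean_sd(two_class_set, "high")
        b = group_mean_sd(two_class_set, "low")
        m2 = double_sd_mask(a, b, multiplier=2.0)
        m3 = double_sd_mask(a, b, multiplier=3.0)
        assert np.all(m3.mask <= m2.mask)


class TestMannWhitney:
    def test_fully_separated_exact_p(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_multisets_half_u(self):
        x = [1.0, 2.0, 3.0, 4.0]
        u, _ = mann_whitney_u(x, x)
        assert u == pytest.approx(len(x) ** 2 / 2)

    @given(st.integers(0, 2**31), st.integers(1, 10), st.integers(1, 10))
    def test_u_conservation(self, seed, nx, ny):
        g = np.random.default_rng(seed)
        x, y = g.random(nx), g.random(ny)
        ux, _ = mann_whitney_u(x, y)
        uy, _ = mann_whitney_u(y, x)
        assert ux + uy == pytest.approx(nx * ny)

    @pytest.mark.parametrize("nx,ny", [(2, 3), (4, 4), (5, 3), (6, 6)])
    def test_small_sample_p_matches_enumeration(self, nx, ny, rng):
        x = rng.random(nx)
        y = rng.random(ny) + 0.3
        _, p = mann_whitney_u(x, y)
        assert p == pytest.approx(exact_ranksum_p(x, y), abs=1e-12)

    @given(st.integers(0, 2**31))
    def test_normal_approximation_close_to_exact_at_n8(self, seed):
        g = np.random.default_rng(seed)
        x, y = g.random(8), g.random(8) + g.random() * 0.5
        _, p_auto = mann_whitney_u(x, y)  # exact path (n <= 8, no ties)
        import scipy.stats

        p_norm = scipy.stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic"
        ).pvalue
        assert abs(p_auto - p_norm) <= 0.02

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d([1, 2, 3], [3, 2, 1]) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        # pooled SD is exactly 1, mean difference -2
        assert cohens_d([1, 2, 3], [3, 4, 5]) == pytest.approx(-2.0)

    @given(st.integers(0, 2**31))
    def test_antisymmetry(self, seed):
        g = np.random.default_rng(seed)
        x, y = g.random(6), g.random(7)
        assert cohens_d(x, y) == pytest.approx(-cohens_d(y, x))

    @given(st.integers(0, 2**31), st.floats(0.1, 100.0))
    def test_scale_invariance(self, seed, a):
        g = np.random.default_rng(seed)
        x, y = g.random(5), g.random(5) + 0.5
        assert cohens_d(a * x, a * y) == pytest.approx(
            cohens_d(x, y), rel=1e-9
        )

    def test_zero_pooled_sd_errors(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d([1.0, 1.0], [2.0, 2.0])


class TestStarsAndTable:
    @pytest.mark.parametrize(
        "p,stars",
        [(5e-4, "***"), (1e-3, "***"), (5e-3, "**"), (0.03, "*"),
         (0.05, ""), (0.5, "")],
    )
    def test_star_thresholds(self, p, stars):
        assert significance_stars(p) == stars

    def test_single_band_two_plus_two_exact(self, axis571):
        band = Band("phe", 1003, 1003)
        idx = int(np.argmin(np.abs(axis571 - 1003)))
        spectra = []
        for i, (label, v) in enumerate(
            [("high", 1.0), ("high", 1.1), ("low", 0.1), ("low", 0.2)]
        ):
            y = np.zeros(571)
            y[idx] = v
            spectra.append(
                Spectrum(axis571, y, sample_id=f"s{i}", label=label)
            )
        sset = SpectraSet.from_spectra(spectra)
        rows = band_stats_table(sset, ("high", "low"), BandPanel((band,)))
        assert len(rows) == 1
        # complete separation of 2 vs 2: exact two-sided p = 2/6
        assert rows[0].p_value == pytest.approx(1 / 3)
        assert rows[0].d > 0

    def test_null_false_positive_rate(self, axis571, panel):
        # pure-noise data: fraction of band tests with p < 0.05 stays
        # near the nominal level
        g = np.random.default_rng(202409)
        n_sig = 0
        n_tot = 0
        for _ in range(25):
            spectra = [
                Spectrum(axis571, g.random(571), sample_id=f"s{i}",
                         label="high" if i < 10 else "low")
                for i in range(20)
            ]
            sset = SpectraSet.from_spectra(spectra)
            rows = band_stats_table(sset, ("high", "low"), panel)
            n_sig += sum(r.p_value < 0.05 for r in rows)
            n_tot += len(rows)
        rate = n_sig / n_tot
        # binomial 3-sigma band around 0.05 for n_tot trials
        se = np.sqrt(0.05 * 0.95 / n_tot)
        assert abs(rate - 0.05) < 3 * se + 1e-9
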