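import numpy as np
import pandas as pd
import pytest

from ecoplace.profiles import (StationProfile, clade_onset_depth,
                               finite_derivative, lli_maximum_depth,
                               negative_maximum_depth, simpson_diversity)
from ecoplace.synth import logistic_deep_fraction


class TestSimpson:
    def test_single_passing_clade_is_zero(self):
        assert simpson_diversity([5.0, 0.2], presence_cutoff=1.0) == 0.0

    @pytest.mark.parametrize("k", [2, 3, 5, 8])
    def test_equal_clades_closed_form(self, k):
        assert simpson_diversity([4.0] * k) == pytest.approx(1 - 1 / k,
                                                             abs=1e-12)

    def test_worked_example(self):
        # {6, 4}: 1 - (0.6^2 + 0.4^2) = 0.48
        assert simpson_diversity([6.0, 4.0]) == pytest.approx(0.48)

    def test_nothing_passes_is_missing(self):
        assert np.isnan(simpson_diversity([0.5, 0.2], presence_cutoff=1.0))

    def test_rescaling_invariance_without_cutoff(self):
        counts = [3.0, 7.0, 1.5]
        a = simpson_diversity(counts, presence_cutoff=0.0)
        b = simpson_diversity([c * 13 for c in counts], presence_cutoff=0.0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            k = int(rng.integers(1, 9))
            x = rng.uniform(1, 10, size=k)
            v = simpson_diversity(x, presence_cutoff=0.0)
            assert 0.0 <= v <= 1 - 1 / k + 1e-12


class TestFiniteDerivative:
    def test_worked_example(self):
        mids, d = finite_derivative([10.0, 4.0], [100.0, 200.0])
        assert mids.tolist() == [150.0]
        assert d[0] == pytest.approx(-0.06)

    def test_constant_series_all_zero(self):
        _, d = finite_derivative([3.0] * 5, [0, 10, 30, 70, 100])
        np.testing.assert_array_equal(d, 0.0)

    def test_linear_series_constant_derivative(self):
        z = np.array([0.0, 25.0, 75.0, 200.0])
        v = 2.5 * z + 1.0
        _, d = finite_derivative(v, z)
        np.testing.assert_allclose(d, 2.5)

    def test_duplicate_depths_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            finite_derivative([1.0, 2.0], [50.0, 50.0])

    def test_logistic_extremum_near_midpoint(self):
        """The derivative extremum of a sampled logistic falls within one
        interval of the true inflection depth."""
        z = np.linspace(0, 600, 20)
        v = logistic_deep_fraction(z, 310.0, 0.03)
        mids, d = finite_derivative(v, z)
        peak = mids[np.argmax(d)]
        assert abs(peak - 310.0) <= (z[1] - z[0])


class TestLandmarks:
    def test_negative_maximum(self):
        assert negative_maximum_depth([50, 150, 300],
                                      [-0.1, -0.5, -0.2]) == 150.0

    def test_negative_maximum_tie_shallowest(self):
        assert negative_maximum_depth([50, 150], [-0.5, -0.5]) == 50.0

    def test_all_nonnegative_flagged_missing(self):
        assert np.isnan(negative_maximum_depth([50, 150], [0.0, 0.3]))

    def test_lli_maximum(self):
        assert lli_maximum_depth([10, 50, 100, 200], [1, 5, 9, 2]) == 100.0
        assert np.isnan(lli_maximum_depth([10, 50], [0.0, 0.0]))

    def test_onset_step_profile(self):
        depths = [10, 100, 200, 300, 400, 500]
        values = [0, 0, 0, 5, 8, 9]
        assert clade_onset_depth(depths, values) == 300.0

    def test_onset_all_zero_missing(self):
        assert np.isnan(clade_onset_depth([10, 20, 30], [0, 0, 0]))

    def test_onset_requires_sustained_rise(self):
        depths = [10, 100, 200, 300, 400, 500]
        values = [0, 3, 0.5, 5, 8, 9]   # the blip at 100 m fails sustain,
        # and 0.5 at 200 m is below the 10%-of-maximum threshold
        assert clade_onset_depth(depths, values) == 300.0

    def test_onset_on_sampled_logistic(self):
        z = np.arange(25.0, 525.0, 25.0)
        v = logistic_deep_fraction(z, 200.0, 0.05)
        onset = clade_onset_depth(z, v)
        # 0.1 of max is reached ~44 m above z*; within 2 grid steps above
        assert 200.0 - 2 * 25.0 <= onset <= 200.0


class TestStationProfile:
    def _profile(self):
        depths = np.array([25.0, 75.0, 125.0, 175.0, 225.0])
        lli = np.array([1.0, 4.0, 9.0, 3.0, 1.0])
        ratio = np.array([0.9, 0.9, 0.6, 0.2, 0.1])
        deep = logistic_deep_fraction(depths, 125.0, 0.08)
        clades = pd.DataFrame({"Ia.1": 1 - deep, "IIb.x": deep}, index=depths)
        return StationProfile("S", depths, clades, prd_rpob=ratio, lli=lli)

    def test_landmarks_all_near_transition(self):
        lm = self._profile().landmarks("IIb.x")
        assert lm["z_lli"] == 125.0
        assert lm["z_negmax"] == 150.0    # midpoint of the steepest drop
        assert abs(lm["z_onset"] - 125.0) <= 100.0

    def test_depth_ordering_enforced(self):
        with pytest.raises(ValueError):
            StationProfile("S", np.array([1.0, 3.0, 2.0, 4.0]),
                           pd.DataFrame(index=[1.0, 3.0, 2.0, 4.0]))

    def test_too_few_depths_rejected(self):
        with pytest.raises(ValueError, match="4 depths"):
            StationProfile("S", np.array([1.0, 2.0, 3.0]),
                           pd.DataFrame(index=[1.0, 2.0, 3.0]))

    def test_simpson_series_per_depth(self):
        prof = self._profile()
        s = prof.simpson_series(presence_cutoff=0.0)
        assert len(s) == 5
        mid = prof.clade_abundance.loc[125.0]
        expected = 1 - ((mid / mid.sum()) ** 2).sum()
        assert s.loc[125.0] == pytest.approx(expected)
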