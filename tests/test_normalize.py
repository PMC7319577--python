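"""The 2-8% normalization rule, its DMS/CMCT variant, and replicate averaging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from probekit.errors import (
    NonPositiveFactorError,
    ReconciliationError,
    StateError,
    TooFewValuesError,
)
from probekit.normalize import (
    average_profiles,
    normalization_factor,
    normalize_profile,
    selection_counts,
)

from .conftest import brute_force_factor, make_profile


class TestSelectionCounts:
    @pytest.mark.parametrize(
        "n,expected",
        [(100, (10, 2)), (20, (2, 1)), (11, (2, 1)), (500, (50, 10)), (95, (10, 2))],
    )
    def test_ceil_rule(self, n, expected):
        assert selection_counts(n) == expected

    @pytest.mark.parametrize("n", [1, 5, 10])
    def test_too_few_values(self, n):
        with pytest.raises(TooFewValuesError, match="11"):
            selection_counts(n)


class TestFactor:
    def test_values_1_to_20(self):
        # select {20, 19}, exclude {20}, average {19}
        assert normalization_factor(np.arange(1, 21)) == 19.0

    def test_values_1_to_100(self):
        # select 91..100, exclude 99 and 100, mean of 91..98
        assert normalization_factor(np.arange(1, 101)) == 94.5

    def test_all_nonpositive(self):
        with pytest.raises(NonPositiveFactorError):
            normalization_factor(np.full(20, -1.0))

    def test_ties_resolved_stably(self):
        # twelve equal values: selected/excluded windows all hold the same value
        assert normalization_factor(np.full(12, 3.0)) == 3.0

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(11, 51))
            vals = rng.gamma(1.5, 2.0, size=n)
            assert normalization_factor(vals) == brute_force_factor(vals)


class TestNormalizeProfile:
    def test_divide_and_clamp(self):
        res = normalize_profile(make_profile(np.arange(1, 21)))
        assert res.factor == 19.0
        v = res.profile.values
        assert v[17] == pytest.approx(18 / 19)
        assert v[18] == 1.0 and v[19] == 1.0  # clamped
        assert res.profile.normalized

    def test_negative_values_clamp_to_zero(self):
        vals = list(np.arange(1, 21)) + [-2.0, -0.5]
        res = normalize_profile(make_profile(vals))
        assert res.profile.values[-2:].min() == 0.0
        assert res.profile.values[-2:].max() == 0.0

    def test_missing_positions_stay_missing(self):
        vals = list(np.arange(1, 21)) + [None]
        res = normalize_profile(make_profile(vals))
        assert not res.profile.measured[-1]
        assert np.isnan(res.profile.values[-1])

    def test_already_normalized_rejected(self):
        with pytest.raises(StateError):
            normalize_profile(make_profile([0.1] * 20, normalized=True))

    def test_dms_subset_rule(self):
        # (ACGU)x6: G/U carry huge signal, A/C carry 1..12 -> divisor from A/C
        # only, so G/U outputs clamp to 1
        vals, ac = [], iter(range(1, 13))
        for _ in range(6):
            vals += [next(ac), next(ac), 1e4, 1e4]  # A, C, G, U
        res = normalize_profile(
            make_profile(vals, sequence="ACGU" * 6, probe="DMS"),
            nucleotide_specific=True,
        )
        assert res.factor == 11.0  # 1..12: select {12, 11}, exclude {12}
        gu = res.profile.values[np.array([c in "GU" for c in "ACGU" * 6])]
        assert (gu == 1.0).all()
        assert "A/C" in res.subset

    def test_subset_too_small_names_subset(self):
        prof = make_profile(np.arange(1, 13), sequence="ACGUACGUACGU", probe="DMS")
        with pytest.raises(TooFewValuesError, match="A/C"):
            normalize_profile(prof, nucleotide_specific=True)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_range_and_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(2.0, 3.0, size=int(rng.integers(11, 120)))
        res = normalize_profile(make_profile(vals))
        out = res.profile.values
        assert np.isfinite(out).all()
        assert out.min() >= 0.0 and out.max() <= 1.0
        order = np.argsort(vals)
        assert (np.diff(out[order]) >= 0).all()

    def test_scale_invariance_powers_of_two_exact(self, rng):
        vals = rng.gamma(1.0, 2.0, size=60)
        base = normalize_profile(make_profile(vals)).profile.values
        for c in (0.5, 4.0, 2.0**20):
            scaled = normalize_profile(make_profile(c * vals)).profile.values
            np.testing.assert_array_equal(scaled, base)

    def test_scale_invariance_general(self, rng):
        vals = rng.gamma(1.0, 2.0, size=60)
        base = normalize_profile(make_profile(vals)).profile.values
        for c in (3.0, 7.3, 1e6):
            scaled = normalize_profile(make_profile(c * vals)).profile.values
            np.testing.assert_array_almost_equal_nulp(scaled, base, nulp=4)


class TestAveraging:
    def test_idempotent_on_identical(self):
        p = make_profile([0.2, 0.4, None], normalized=True)
        avg = average_profiles([p, p])
        np.testing.assert_allclose(avg.values[:2], [0.2, 0.4])
        assert not avg.measured[2]

    def test_available_replicate_mean(self):
        a = make_profile([0.2, None], normalized=True)
        b = make_profile([0.4, 0.6], normalized=True)
        avg = average_profiles([a, b])
        np.testing.assert_allclose(avg.values, [0.3, 0.6])
        assert avg.measured.all()

    def test_order_invariant(self, rng):
        profs = [
            make_profile(np.round(rng.random(16), 3), normalized=True)
            for _ in range(3)
        ]
        fwd = average_profiles(profs)
        rev = average_profiles(profs[::-1])
        np.testing.assert_allclose(fwd.values, rev.values, rtol=1e-12)

    def test_sequence_mismatch_rejected(self):
        a = make_profile([0.1] * 4, sequence="ACGU", normalized=True)
        b = make_profile([0.1] * 4, sequence="ACGA", normalized=True)
        with pytest.raises(ReconciliationError):
            average_profiles([a, b])

    def test_unnormalized_rejected(self):
        a = make_profile([0.1] * 4, normalized=True)
        b = make_profile([0.1] * 4, normalized=False)
        with pytest.raises(StateError):
            average_profiles([a, b])
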