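"""Cell-length-profile segmentation: literal rules, oracles, robustness."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from helpers_brute import brute_elongation_onset, brute_maturation_onset
from rootkinetics import (
    CellLengthProfile,
    InsufficientDataError,
    SegmentationError,
    detect_elongation_onset,
    detect_maturation_onset,
    mature_cell_length,
    segment_profile,
    simulate_cell_file,
    summarize_seedling,
)


def _profile(lengths, **kw):
    return CellLengthProfile(root_id="r", lengths=np.asarray(lengths, float), **kw)


class TestElongationOnset:
    def test_literal_doubling_rule(self):
        assert detect_elongation_onset(_profile([5, 5, 5, 11, 13, 20, 30, 40])) == 4

    def test_dividing_cell_skipped(self):
        # cell 3 doubles but its successor is shorter: skip; rule fires at 5
        assert detect_elongation_onset(_profile([5, 5, 12, 11, 24, 30, 40, 50])) == 5

    def test_constant_profile_fails(self):
        with pytest.raises(SegmentationError):
            detect_elongation_onset(_profile([7.0] * 12))

    def test_last_cell_never_onset(self):
        # doubling at the final cell has no successor to confirm
        with pytest.raises(SegmentationError):
            detect_elongation_onset(_profile([5, 5, 5, 5, 5, 5, 5, 11]))

    def test_steep_world_noiseless_onset(self, steep_spec):
        prof = simulate_cell_file(steep_spec, 0.0, seed=1)
        # first cell past Lm has the meristem length (continuity); the next
        # one doubles (r/P > 1), so onset is Lm/l0 + 2
        assert detect_elongation_onset(prof) == 22

    def test_onset_robust_to_length_noise(self, steep_spec):
        # CV 5%: onset moves by <= 1 cell in >= 95% of replicates
        hits = 0
        n = 300
        for seed in range(n):
            prof = simulate_cell_file(steep_spec, 0.05, seed=seed)
            try:
                onset = detect_elongation_onset(prof)
            except SegmentationError:
                continue
            hits += abs(onset - 22) <= 1
        assert hits / n >= 0.95


class TestMaturationOnset:
    def test_literal_rule_on_worked_sequence(self):
        lengths = [5, 5, 100, 140, 180, 182, 181, 185, 183]
        # onset at cell 3; 182 <= 1.05*180 so the 180-cell (index 5) is mature
        assert detect_maturation_onset(_profile(lengths), onset=3) == 5

    def test_monotone_growing_tail_fails(self):
        lengths = [5.0, 5.0, 11.0] + [11.0 * 1.1**i for i in range(1, 12)]
        with pytest.raises(SegmentationError):
            detect_maturation_onset(_profile(lengths), onset=3)

    def test_steep_world_onset_is_first_cell_beyond_growth_zone(self, steep_spec):
        prof = simulate_cell_file(steep_spec, 0.0, seed=1)
        onset = detect_elongation_onset(prof)
        maturation = detect_maturation_onset(prof, onset)
        first_beyond = (
            int(np.nonzero(prof.boundaries() >= steep_spec.growth_zone_length)[0][0])
            + 1
        )
        assert maturation == first_beyond

    def test_smooth_bump_stops_scan_early(self, default_spec):
        # gentle raised-cosine start: successive ratios stay within tol just
        # past the meristem, so a scan from the true onset stops immediately
        prof = simulate_cell_file(default_spec, 0.0, seed=1)
        onset = int(np.nonzero(prof.boundaries() >= 500.0)[0][0]) + 1
        assert detect_maturation_onset(prof, onset) == onset + 1


class TestMatureCellLength:
    def test_mean_of_five(self):
        prof = _profile([5, 5, 12, 30, 200, 210, 190, 205, 195])
        assert mature_cell_length(prof, 5) == pytest.approx(200.0)

    def test_identity_on_equal_cells(self):
        prof = _profile([5, 10, 25, 60] + [150.0] * 5)
        assert mature_cell_length(prof, 5) == pytest.approx(150.0)

    def test_ground_truth_onset_recovers_exact_mature_length(self, default_spec):
        prof = simulate_cell_file(default_spec, 0.0, seed=1)
        first_beyond = (
            int(np.nonzero(prof.boundaries() >= default_spec.growth_zone_length)[0][0])
            + 1
        )
        assert mature_cell_length(prof, first_beyond) == pytest.approx(
            150.0, abs=1e-9
        )

    def test_too_few_mature_cells(self):
        with pytest.raises(InsufficientDataError):
            mature_cell_length(_profile([5, 10, 20, 40, 80, 160]), 4)


class TestBruteForceOracle:
    def test_detectors_match_brute_force_on_random_profiles(self, rng):
        for _ in range(1000):
            n = int(rng.integers(8, 40))
            lengths = np.exp(rng.normal(2.0, 0.6, size=n)).round(2) + 0.1
            prof = _profile(lengths)
            expected = brute_elongation_onset(list(lengths))
            if expected is None:
                with pytest.raises(SegmentationError):
                    detect_elongation_onset(prof)
                continue
            onset = detect_elongation_onset(prof)
            assert onset == expected
            expected_m = brute_maturation_onset(list(lengths), onset)
            if expected_m is None:
                with pytest.raises(SegmentationError):
                    detect_maturation_onset(prof, onset)
            else:
                assert detect_maturation_onset(prof, onset) == expected_m

    @given(
        st.lists(
            st.floats(min_value=0.5, max_value=500.0, allow_nan=False),
            min_size=3,
            max_size=25,
        )
    )
    def test_elongation_onset_property(self, lengths):
        prof = _profile(lengths)
        expected = brute_elongation_onset(lengths)
        if expected is None:
            with pytest.raises(SegmentationError):
                detect_elongation_onset(prof)
        else:
            assert detect_elongation_onset(prof) == expected


class TestSeedlingAveraging:
    def _summary(self, count=30, mlen=480.0, mature=150.0):
        return segment_profile(
            _profile(
                [mlen / count] * count
                + [2.5 * mlen / count, 3 * mlen / count, 80.0]
                + [mature] * 5
            )
        )

    def test_mean_of_two_files(self):
        left = self._summary(count=30)
        right = self._summary(count=34)
        seedling = summarize_seedling(left, right)
        assert seedling.meristem_cell_count == pytest.approx(32.0)
        assert seedling.n_files_used == 2
        assert not seedling.partial

    def test_commutative_and_idempotent(self):
        a = self._summary(count=30)
        b = self._summary(count=34, mlen=520.0)
        ab, ba = summarize_seedling(a, b), summarize_seedling(b, a)
        assert ab.meristem_length == ba.meristem_length
        aa = summarize_seedling(a, a)
        assert aa.meristem_cell_count == a.meristem_cell_count
        assert aa.mature_cell_length == a.mature_cell_length

    def test_single_file_flagged_partial(self):
        a = self._summary()
        s = summarize_seedling(a, None)
        assert s.partial and s.n_files_used == 1
        assert s.meristem_cell_count == a.meristem_cell_count

    def test_minimum_cell_count_enforced(self):
        with pytest.raises(InsufficientDataError):
            segment_profile(_profile([5, 5, 11, 13, 150, 150, 150]))
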