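import numpy as np
import pytest

from uwbvitals.candidate_selection import CandidateSet
from uwbvitals.errors import ReconstructionError
from uwbvitals.vital_reconstruction import (
    WidthConfig,
    append_segment,
    correlation_width,
    init_reconstruction,
    reconstruct,
    select_append_segment,
    select_initial_segment,
    zero_crossings,
)

FS = 110.0

# the worked-example vectors of the reconstruction procedure
FIRST_CROSSINGS = [234, 231, 223, 231, 230, 235, 224, 220]
SECOND_CROSSINGS = [354, 359, 351, 344, 347, 360, 354, 351]
PRINTED_WIDTHS = [17.1, 13.3, 18.3, 9.3, 16.2, 23.8, 18.2, 22.8]


def make_candidates(rows):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    return CandidateSet(
        indices=np.arange(rows.shape[0]),
        best_fit_matrix=rows,
        profile=np.full(rows.shape[0], 0.5),
    )


def tone(freq, n, phase=0.0, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / FS + phase)


class TestZeroCrossings:
    def test_sampled_sinusoid_two_periods(self):
        n = 440  # two periods of 0.5 Hz at 110 Hz
        x = tone(0.5, n, phase=1e-6)
        c = zero_crossings(x)
        assert len(c) == 4 - 1 or len(c) == 4  # crossings within the sampled span
        half = FS / 0.5 / 2
        for i, idx in enumerate(c):
            assert abs(idx - (i + 1) * half) <= 1

    def test_strictly_positive_has_none(self):
        assert zero_crossings(np.ones(10) + 0.5).size == 0

    def test_alternating_signs_cross_everywhere(self):
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0])
        np.testing.assert_array_equal(zero_crossings(x), [1, 2, 3, 4])

    def test_zero_samples_inherit_previous_sign(self):
        x = np.array([1.0, 0.0, 2.0, -1.0])
        np.testing.assert_array_equal(zero_crossings(x), [3])

    def test_hysteresis_suppresses_noise_flicker(self, rng):
        x = tone(0.3, 2200, amp=1.0) + rng.normal(0, 0.05, 2200)
        strict = zero_crossings(x)
        robust = zero_crossings(x, hysteresis=0.2)
        true_count = 2 * 0.3 * 20  # 2 f T
        assert len(strict) > true_count
        assert abs(len(robust) - true_count) <= 1


class TestCorrelationWidth:
    def test_phase_break_narrows_width(self):
        n = 1110  # three periods of ~0.3 Hz
        clean = tone(0.3, n)
        broken = clean.copy()
        broken[n // 2:] *= -1.0
        assert correlation_width(clean) > correlation_width(broken)

    def test_white_noise_is_narrow(self, rng):
        assert correlation_width(rng.normal(size=2000)) <= 2.0

    def test_width_grows_with_period(self):
        # three full cycles of each tone: slower breathing -> wider correlation
        widths = [correlation_width(tone(f, round(3 * FS / f))) for f in (0.4, 0.3, 0.2)]
        assert widths[0] < widths[1] < widths[2]

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            correlation_width(np.zeros(16))

    def test_offset_does_not_inflate_width(self):
        x = tone(0.3, 1110)
        assert correlation_width(x + 5.0) == pytest.approx(correlation_width(x), abs=1.0)


class TestWorkedExample:
    def test_initialisation_on_printed_first_crossings(self):
        src, end = select_initial_segment(FIRST_CROSSINGS)
        assert end == 235
        assert src + 1 == 6  # candidate 6 in 1-based reporting

    def test_second_iteration_on_printed_widths(self):
        src, end = select_append_segment(PRINTED_WIDTHS, SECOND_CROSSINGS)
        assert src + 1 == 6
        assert end == 360

    def test_initial_tie_breaks_to_lowest_source(self):
        src, end = select_initial_segment([200, 235, 235, 100])
        assert (src, end) == (1, 235)

    def test_append_tie_breaks_to_lowest_source(self):
        src, end = select_append_segment([5.0, 9.0, 9.0], [300, 310, 320])
        assert (src, end) == (1, 310)


class TestReconstruction:
    def test_init_picks_furthest_first_crossing(self):
        rows = [
            tone(0.3, 900, phase=0.2),
            tone(0.3, 900, phase=0.1),  # smallest phase -> latest first crossing
            tone(0.3, 900, phase=0.35),
        ]
        cands = make_candidates(rows)
        cfg = WidthConfig(hysteresis_frac=0.0, min_segment=1)
        state = init_reconstruction(cands, cfg)
        firsts = [zero_crossings(r)[0] for r in rows]
        assert state.end_index == max(firsts)
        assert state.provenance[0].source == int(np.argmax(firsts))
        np.testing.assert_array_equal(
            state.constructed, rows[state.provenance[0].source][: state.end_index]
        )

    def test_constant_sign_candidates_unsegmentable(self):
        cands = make_candidates([np.ones(50), 2 * np.ones(50)])
        with pytest.raises(ReconstructionError, match="no segmentable"):
            init_reconstruction(cands)

    def test_phase_consistent_continuation_wins(self):
        """Appending the in-phase candidate must beat the inverted one."""
        n = 1100
        base = tone(0.3, n)
        cands = make_candidates([base, -base])
        cfg = WidthConfig(hysteresis_frac=0.0)
        state = init_reconstruction(cands, cfg)
        state = append_segment(state, cands, cfg)
        # every appended segment keeps coming from the same source
        assert {s.source for s in state.provenance} == {state.provenance[0].source}

    def test_provenance_tiles_without_gaps(self):
        rows = [tone(0.3, 1200, phase=p) for p in (0.0, 0.05, -0.05)]
        vital = reconstruct(make_candidates(rows))
        cursor = 0
        for seg in vital.provenance:
            assert seg.start == cursor
            assert seg.end > seg.start
            cursor = seg.end
        assert cursor == len(vital.samples)
        # segments are verbatim copies from their source rows
        for seg in vital.provenance:
            np.testing.assert_array_equal(
                vital.samples[seg.start:seg.end],
                rows[seg.source][seg.start:seg.end],
            )

    def test_identical_candidates_reproduce_the_tone(self):
        rows = [tone(0.25, 900)] * 3
        vital = reconstruct(make_candidates(rows))
        np.testing.assert_array_equal(vital.samples, rows[0][: len(vital.samples)])

    def test_deterministic(self, rng):
        rows = [tone(0.3, 800) + rng.normal(0, 0.1, 800) for _ in range(3)]
        v1 = reconstruct(make_candidates(rows))
        v2 = reconstruct(make_candidates(rows))
        np.testing.assert_array_equal(v1.samples, v2.samples)
        assert v1.provenance == v2.provenance

    def test_empty_candidates_rejected(self):
        empty = CandidateSet(
            indices=np.array([], dtype=int),
            best_fit_matrix=np.empty((0, 10)),
            profile=np.zeros(10),
        )
        with pytest.raises(ReconstructionError, match="no vital signal"):
            reconstruct(empty)

    def test_greedy_equals_exhaustive_small_instance(self, rng):
        """At every iteration the greedy choice matches brute-force scoring
        of all candidate widths."""
        from uwbvitals.vital_reconstruction import _candidate_crossings

        rows = [tone(2.0, 200, phase=p) + rng.normal(0, 0.05, 200) for p in (0, 0.3, -0.2)]
        cands = make_candidates(rows)
        cfg = WidthConfig(hysteresis_frac=0.0, min_segment=1, score_context=None)
        crossings = _candidate_crossings(cands, cfg)
        state = init_reconstruction(cands, cfg)
        while True:
            options = [
                (j, int(c[c > state.end_index][0]))
                for j, c in enumerate(crossings)
                if (c > state.end_index).any()
            ]
            if not options:
                break
            brute = []
            for j, nxt in options:
                tent = np.concatenate(
                    [state.constructed, cands.best_fit_matrix[j, state.end_index:nxt]]
                )
                brute.append(correlation_width(tent, cfg))
            expected_src, expected_end = options[int(np.argmax(brute))]
            state = append_segment(state, cands, cfg)
            assert state.provenance[-1].source == expected_src
            assert state.end_index == expected_end

    def test_reconstruction_beats_individual_corrupted_candidates(self, rng):
        """Candidates share a tone but are corrupted by noise bursts in
        disjoint spans; the assembled signal correlates with the clean tone
        better than every individual candidate."""
        n = 2200
        clean = tone(0.3, n)
        rows = []
        spans = [(0, 700), (700, 1400), (1400, 2200)]
        for j, (a, b) in enumerate(spans):
            row = clean + rng.normal(0, 0.02, n)
            row[a:b] += rng.normal(0, 1.5, b - a)
            rows.append(row)
        vital = reconstruct(make_candidates(rows))
        m = len(vital.samples)

        def corr(x):
            return abs(np.corrcoef(x[:m], clean[:m])[0, 1])

        assert corr(vital.samples) > max(corr(r) for r in rows)
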