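import numpy as np
import pytest

from uwbvitals.clutter_removal import (
    ClutterState,
    freeze_clutter,
    remove_clutter,
    subtract_background,
    subtract_frozen,
    update_clutter,
)
from uwbvitals.errors import DimensionError, StateError


def run_updates(c0, alpha, frames):
    state = ClutterState(c=c0, alpha=alpha, k=1)
    history = [state]
    for f in frames:
        state = update_clutter(state, f)
        history.append(state)
    return state, history


class TestUpdate:
    @pytest.mark.parametrize("alpha", [0.97, 0.8])
    def test_constant_input_matches_closed_form(self, rng, alpha):
        """k updates with a constant frame: c_k = a^k c0 + (1 - a^k) r0."""
        c0 = rng.normal(size=32)
        r0 = rng.normal(size=32)
        state, _ = run_updates(c0, alpha, [r0] * 25)
        expected = alpha**25 * c0 + (1 - alpha**25) * r0
        np.testing.assert_allclose(state.c, expected, atol=1e-12)

    def test_alpha_near_one_freezes_clutter(self, rng):
        c0 = rng.normal(size=8)
        state, _ = run_updates(c0, 1.0 - 1e-12, [rng.normal(size=8)] * 5)
        np.testing.assert_allclose(state.c, c0, atol=1e-10)

    def test_length_mismatch(self, rng):
        state = ClutterState(c=np.zeros(8), alpha=0.9, k=1)
        with pytest.raises(DimensionError):
            update_clutter(state, np.zeros(9))

    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            ClutterState(c=np.zeros(2), alpha=1.0, k=0)
        with pytest.raises(ValueError):
            ClutterState(c=np.zeros(2), alpha=0.0, k=0)


class TestSubtract:
    def test_static_scene_cancels(self, rng):
        frame = rng.normal(size=16)
        state = ClutterState.from_first_frame(frame, 0.97)
        np.testing.assert_array_equal(subtract_background(frame, state), np.zeros(16))

    def test_geometric_decay_of_residual(self, rng):
        """Constant input: |y_k| shrinks by exactly alpha per update."""
        alpha = 0.9
        c0 = rng.normal(size=16)
        r0 = rng.normal(size=16)
        norm0 = np.linalg.norm(r0 - c0)
        state = ClutterState(c=c0, alpha=alpha, k=1)
        for k in range(1, 12):
            y = subtract_background(r0, state)
            assert np.linalg.norm(y) == pytest.approx(alpha ** (k - 1) * norm0, abs=1e-9)
            state = update_clutter(state, r0)

    def test_single_frame_target_passes_through(self, rng):
        background = rng.normal(size=64)
        state, _ = run_updates(background, 0.97, [background] * 50)
        target = background.copy()
        target[30] += 5.0
        y = subtract_background(target, state)
        assert y[30] == pytest.approx(5.0, abs=1e-9)
        assert np.max(np.abs(np.delete(y, 30))) < 1e-9

    def test_linearity_in_the_frame(self, rng):
        state = ClutterState(c=rng.normal(size=12), alpha=0.8, k=1)
        f1, f2 = rng.normal(size=12), rng.normal(size=12)
        a, b = 0.3, 1.7
        lhs = subtract_background(a * f1 + b * f2, state)
        rhs = (
            a * subtract_background(f1, state)
            + b * subtract_background(f2, state)
            + (a + b - 1) * state.c
        )
        np.testing.assert_allclose(lhs, rhs, atol=1e-12)


class TestVectorizedBlock:
    def test_matches_frame_by_frame_fold(self, rng):
        """remove_clutter equals the update/subtract recursion with c0 = r0."""
        data = rng.normal(size=(40, 6))
        alpha = 0.85
        y_fast = remove_clutter(data, alpha)
        state = ClutterState.from_first_frame(data[0], alpha)
        expected = [np.zeros(6)]
        for frame in data[1:]:
            expected.append(subtract_background(frame, state))
            state = update_clutter(state, frame)
        np.testing.assert_allclose(y_fast, np.array(expected), atol=1e-12)


class TestFreeze:
    def test_zero_margin_equals_transition_clutter(self, rng):
        _, history = run_updates(rng.normal(size=8), 0.8, list(rng.normal(size=(20, 8))))
        frozen = freeze_clutter(history, k_transient=15, k_margin=0)
        np.testing.assert_array_equal(frozen.c_stopped, history[15].c)

    def test_static_scene_margin_irrelevant(self, rng):
        frame = rng.normal(size=8)
        _, history = run_updates(frame, 0.8, [frame] * 20)
        for margin in (0, 5, 10):
            frozen = freeze_clutter(history, k_transient=15, k_margin=margin)
            np.testing.assert_allclose(frozen.c_stopped, frame, atol=1e-12)

    def test_freeze_is_replay_to_earlier_frame(self, rng):
        """Object enters at frame 77; margin 10 freezes the clutter replayed
        to frame 67, i.e. untouched by the object."""
        background = rng.normal(size=16)
        frames = [background + rng.normal(0, 0.01, 16) for _ in range(100)]
        for k in range(77, 100):
            frames[k] = frames[k] + 5.0
        _, history = run_updates(frames[0], 0.8, frames[1:])
        frozen = freeze_clutter(history, k_transient=77, k_margin=10)
        _, replay = run_updates(frames[0], 0.8, frames[1:68])
        np.testing.assert_allclose(frozen.c_stopped, replay[67].c, atol=1e-12)
        assert frozen.k_transient == 77 and frozen.k_margin == 10

    def test_insufficient_history_raises(self, rng):
        _, history = run_updates(rng.normal(size=4), 0.8, list(rng.normal(size=(5, 4))))
        with pytest.raises(StateError):
            freeze_clutter(history[-2:], k_transient=5, k_margin=3)

    def test_subtract_frozen_never_mutates(self, rng):
        _, history = run_updates(rng.normal(size=8), 0.8, list(rng.normal(size=(20, 8))))
        state = history[-1]
        c_before = state.c.copy()
        frozen = freeze_clutter(history, k_transient=10, k_margin=5)
        frozen_c = frozen.c_stopped.copy()
        subtract_frozen(rng.normal(size=8), frozen)
        subtract_background(rng.normal(size=8), state)
        np.testing.assert_array_equal(state.c, c_before)
        np.testing.assert_array_equal(frozen.c_stopped, frozen_c)

    def test_frozen_retains_object_while_running_decays(self, rng):
        """A static object after the freeze stays visible in y-breve while
        the running-clutter residual decays toward noise."""
        background = np.zeros(16)
        _, history = run_updates(background, 0.8, [background] * 20)
        frozen = freeze_clutter(history, k_transient=20, k_margin=0)
        state = history[-1]
        scene = background.copy()
        scene[5] = 4.0
        for _ in range(40):
            state = update_clutter(state, scene)
        y = subtract_background(scene, state)
        y_breve = subtract_frozen(scene, frozen)
        assert abs(y_breve[5]) == pytest.approx(4.0, abs=1e-6)
        assert abs(y[5]) < 1e-3
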