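import pytest
from hypothesis import given, settings, strategies as st

from eogkit.blink_detector import BlinkEvent, ClickEvent
from eogkit.event_fusion import (
    DEFAULT_LAYOUT,
    FusionPolicy,
    ValidatedSaccade,
    classify_direction,
    decode_commands,
    fuse,
)
from eogkit.saccade_model import SaccadeCandidate


def cand(index, channel="h", angle=20.0):
    return SaccadeCandidate(index=index, channel=channel, variation=angle / 0.1, angle_deg=angle)


class TestClassifyDirection:
    @pytest.mark.parametrize(
        "h,v,expected",
        [
            (20.0, 0.0, "R"),
            (15.0, 15.0, "UR"),
            (0.0, 20.0, "U"),
            (-15.0, 15.0, "UL"),
            (-20.0, 0.0, "L"),
            (-15.0, -15.0, "DL"),
            (0.0, -20.0, "D"),
            (15.0, -15.0, "DR"),
        ],
    )
    def test_eight_sectors(self, h, v, expected):
        assert classify_direction(h, v) == expected

    def test_sub_threshold_has_no_class(self):
        assert classify_direction(0.5, 0.5, min_angle=2.0) is None

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_direction(float("nan"), 0.0)


class TestFuse:
    def test_validated_candidate_kept(self):
        out = fuse([cand(100)], [1], [])
        assert len(out) == 1
        assert out[0].direction == "R"
        assert out[0].h_deg == pytest.approx(20.0)

    def test_network_rejection_discards(self):
        assert fuse([cand(100)], [0], []) == []

    def test_blink_coincident_candidate_discarded(self):
        assert fuse([cand(100)], [1], [BlinkEvent(index=110, similarity=0.9)]) == []

    def test_distant_blink_does_not_discard(self):
        out = fuse([cand(100)], [1], [BlinkEvent(index=200, similarity=0.9)])
        assert len(out) == 1

    def test_no_candidates_empty_output(self):
        assert fuse([], [], [BlinkEvent(index=10, similarity=0.9)]) == []

    def test_h_and_v_candidates_merge_into_oblique(self):
        out = fuse([cand(100, "h", 15.0), cand(102, "v", 15.0)], [1, 1], [])
        assert len(out) == 1
        assert out[0].direction == "UR"
        assert out[0].index == 100

    def test_distant_candidates_stay_separate(self):
        out = fuse([cand(100, "h"), cand(160, "v")], [1, 1], [])
        assert [s.direction for s in out] == ["R", "U"]

    def test_sub_minimum_movement_dropped(self):
        out = fuse([cand(100, "h", 1.0)], [1], [], FusionPolicy(min_angle_deg=5.0))
        assert out == []

    def test_misaligned_classes_rejected(self):
        with pytest.raises(ValueError):
            fuse([cand(100)], [], [])

    @settings(derandomize=True, max_examples=40)
    @given(
        cand_idx=st.lists(st.integers(50, 5000), min_size=0, max_size=8, unique=True),
        blink_idx=st.lists(st.integers(0, 5000), min_size=0, max_size=5),
    )
    def test_coincident_candidates_always_suppressed(self, cand_idx, blink_idx):
        policy = FusionPolicy()
        candidates = [cand(i) for i in sorted(cand_idx)]
        blinks = [BlinkEvent(index=i, similarity=0.9) for i in sorted(blink_idx)]
        out = fuse(candidates, [1] * len(candidates), blinks, policy)
        for s in out:
            assert all(abs(s.index - b) > policy.coincidence for b in blink_idx)

    @settings(derandomize=True, max_examples=40)
    @given(
        cand_idx=st.lists(st.integers(50, 5000), min_size=0, max_size=8, unique=True),
        blink_idx=st.lists(st.integers(0, 5000), min_size=1, max_size=5),
        drop=st.integers(0, 4),
    )
    def test_removing_a_blink_never_removes_a_saccade(self, cand_idx, blink_idx, drop):
        candidates = [cand(i) for i in sorted(cand_idx)]
        blinks = [BlinkEvent(index=i, similarity=0.9) for i in sorted(blink_idx)]
        fewer = blinks[: drop % len(blinks)] + blinks[drop % len(blinks) + 1 :]
        kept_full = {s.index for s in fuse(candidates, [1] * len(candidates), blinks)}
        kept_fewer = {s.index for s in fuse(candidates, [1] * len(candidates), fewer)}
        assert kept_full <= kept_fewer


class TestDecodeCommands:
    def sacc(self, index, direction="R"):
        return ValidatedSaccade(index=index, h_deg=20.0, v_deg=0.0, direction=direction)

    def test_click_inside_window_emits_command(self):
        # saccade at 1.0 s, click at 2.0 s, 2 s window
        out = decode_commands([self.sacc(100)], [ClickEvent(index=200, count=2, span=50)])
        assert [c.command for c in out] == [DEFAULT_LAYOUT["R"]]

    def test_no_click_no_command(self):
        assert decode_commands([self.sacc(100)], []) == []

    def test_click_without_preceding_saccade_ignored(self):
        assert decode_commands([], [ClickEvent(index=200, count=2, span=50)]) == []

    def test_click_after_window_lapses(self):
        out = decode_commands([self.sacc(100)], [ClickEvent(index=400, count=2, span=50)])
        assert out == []

    def test_new_selection_supersedes_unconfirmed_one(self):
        saccades = [self.sacc(100, "R"), self.sacc(180, "U")]
        out = decode_commands(saccades, [ClickEvent(index=250, count=2, span=40)])
        assert [c.command for c in out] == [DEFAULT_LAYOUT["U"]]

    def test_click_never_reused(self):
        saccades = [self.sacc(100, "R")]
        clicks = [ClickEvent(index=150, count=2, span=40), ClickEvent(index=200, count=2, span=40)]
        out = decode_commands(saccades, clicks)
        assert len(out) == 1

    @settings(derandomize=True, max_examples=40)
    @given(
        sac_idx=st.lists(st.integers(0, 3000), min_size=0, max_size=6, unique=True),
        click_idx=st.lists(st.integers(0, 3000), min_size=0, max_size=6, unique=True),
    )
    def test_every_command_pairs_click_after_saccade(self, sac_idx, click_idx):
        saccades = [self.sacc(i) for i in sorted(sac_idx)]
        clicks = [ClickEvent(index=i, count=2, span=30) for i in sorted(click_idx)]
        out = decode_commands(saccades, clicks)
        for c in out:
            assert c.click.index > c.saccade.index
            assert c.click.index - c.saccade.index <= 200
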