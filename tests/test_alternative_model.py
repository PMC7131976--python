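import numpy as np
import pandas as pd
import pytest

from mazepoint.alternative_model import (DeleteLeg, ModelComparison,
                                         RotateSubroute, SetLegLength,
                                         aggregate_preference,
                                         alternative_route, apply_edits,
                                         compare_models)
from mazepoint.geometry import (MazeLayout, angular_error, realize_layout,
                                true_direction)
from tests.conftest import vonmises_deg


class TestEdits:
    def test_empty_edit_list_is_identity(self, route):
        assert apply_edits(route, []) == route

    def test_delete_leg_translates_downstream(self, route, layout):
        edited = realize_layout(apply_edits(route, [DeleteLeg(5, 6)]))
        shift = layout.coords[6] - layout.coords[5]
        assert edited.coords[6] == pytest.approx(edited.coords[5])
        for loc in (7, 8, 9):
            assert edited.coords[loc] == pytest.approx(
                layout.coords[loc] - shift)
        for loc in (1, 2, 3, 4, 5):
            assert edited.coords[loc] == pytest.approx(layout.coords[loc])

    def test_set_leg_length_matches_reference_leg(self, route):
        edited = apply_edits(route, [SetLegLength(6, 7, match=(8, 9))])
        assert edited.leg(6, 7).length == edited.leg(8, 9).length

    def test_rotate_subroute_changes_only_one_turn(self, route):
        edited = apply_edits(route, [RotateSubroute(7, -90.0)])
        assert edited.turns[7] == route.turns[7] - 90.0
        assert {k: v for k, v in edited.turns.items() if k != 7} \
            == {k: v for k, v in route.turns.items() if k != 7}

    def test_dangling_reference_names_edit(self, route):
        with pytest.raises(ValueError, match=r"\(4, 9\)"):
            apply_edits(route, [DeleteLeg(4, 9)])
        with pytest.raises(ValueError, match="not interior"):
            apply_edits(route, [RotateSubroute(1, 90.0)])

    def test_edits_never_touch_the_input(self, route):
        before = route.leg(5, 6).length
        apply_edits(route, [DeleteLeg(5, 6), SetLegLength(6, 7, length=1.0)])
        assert route.leg(5, 6).length == before


class TestCompositeDistortion:
    def test_leg_6_7_shrinks_to_leg_8_9(self, route):
        alt = alternative_route(route)
        assert alt.leg(6, 7).length == route.leg(8, 9).length
        assert alt.leg(5, 6).length == 0.0

    def test_untouched_legs_keep_their_lengths(self, route):
        alt = alternative_route(route)
        for pair in [(1, 2), (2, 3), (3, 4), (4, 5), (7, 8), (8, 9)]:
            assert alt.leg(*pair).length == route.leg(*pair).length

    def test_inverse_edits_restore_leg_lengths(self, route):
        alt = alternative_route(route)
        restored = apply_edits(alt, [
            SetLegLength(5, 6, length=route.leg(5, 6).length),
            SetLegLength(6, 7, length=route.leg(6, 7).length),
            RotateSubroute(7, 90.0),
        ])
        assert [l.length for l in restored.legs] \
            == [l.length for l in route.legs]
        assert restored.turns == route.turns

    def test_rotated_tail_is_rigid(self, route, layout, alt_layout):
        # distances and the internal angle within locations 7-9 survive the
        # rotation: the component moves as a rigid body
        for a, b in [(7, 8), (8, 9), (7, 9)]:
            d0 = np.linalg.norm(layout.coords[a] - layout.coords[b])
            d1 = np.linalg.norm(alt_layout.coords[a] - alt_layout.coords[b])
            assert d1 == pytest.approx(d0)
        turn0 = angular_error(true_direction(layout, 7, 8),
                              true_direction(layout, 8, 9))
        turn1 = angular_error(true_direction(alt_layout, 7, 8),
                              true_direction(alt_layout, 8, 9))
        assert turn1 == pytest.approx(turn0)

    def test_default_rotation_gives_valid_layout(self, route):
        # realizes without corridor collisions under the default sign
        lay = realize_layout(alternative_route(route, rotation_sign=-1))
        assert len(lay.coords) == 9


def _records(trials, judged_by_participant, session=1):
    rows = []
    for p, judged in judged_by_participant.items():
        for (o, t), j in zip(trials, judged):
            rows.append((p, session, o, t, j, False, 0.0))
    return pd.DataFrame(rows, columns=[
        "participant", "session", "origin", "target", "judged_deg",
        "visible", "error_deg"])


class TestCompareModels:
    def test_perfect_pointer_prefers_correct(self, layout, alt_layout):
        trials = [(3, 6), (3, 7), (2, 6)]
        judged = [true_direction(layout, *t) for t in trials]
        recs = _records(trials, {"p1": judged})
        (cmp,) = compare_models(recs, set(trials), layout, alt_layout)
        assert cmp.better_fit == "correct"
        assert cmp.mean_error_correct == pytest.approx(0.0)
        assert cmp.error_reduction == 0.0

    def test_identical_layouts_tie_toward_correct(self, layout, rng):
        trials = [(3, 6), (3, 7)]
        judged = list(rng.uniform(0, 360, 2))
        recs = _records(trials, {"p1": judged})
        (cmp,) = compare_models(recs, set(trials), layout, layout)
        assert cmp.better_fit == "correct"

    @pytest.mark.parametrize("kappa", [4.0, 8.0, 20.0])
    def test_generating_layout_wins(self, layout, alt_layout, rng, kappa):
        # directions sampled around the alternative layout's truths are
        # recognized as alternative-born, increasingly surely with kappa
        trials = [(2, 6), (3, 6), (3, 7), (4, 6), (5, 7), (7, 9)]
        wins = 0
        n_rep = 40
        for _ in range(n_rep):
            judged = [float(vonmises_deg(rng, true_direction(alt_layout, *t),
                                         kappa, 1)[0]) for t in trials]
            recs = _records(trials, {"p": judged})
            (cmp,) = compare_models(recs, set(trials), layout, alt_layout)
            wins += cmp.better_fit == "alternative"
        assert wins >= {4.0: 30, 8.0: 36, 20.0: 38}[kappa]

    def test_error_reduction_fraction(self, layout, alt_layout):
        trials = [(3, 6), (3, 7)]
        judged = [true_direction(alt_layout, *t) for t in trials]
        recs = _records(trials, {"p1": judged})
        (cmp,) = compare_models(recs, set(trials), layout, alt_layout)
        assert cmp.better_fit == "alternative"
        assert cmp.error_reduction == pytest.approx(1.0)
        assert cmp.mean_error_correct > 0

    def test_gauge_invariance(self, layout, alt_layout, rng):
        # rotating both layouts and the judged directions by the same angle
        # changes nothing in the comparison output
        phi = 73.0
        rad = np.radians(phi)
        rot = np.array([[np.cos(rad), np.sin(rad)],
                        [-np.sin(rad), np.cos(rad)]])  # clockwise by phi

        def rotate(lay):
            return MazeLayout(
                coords={i: rot.T @ c for i, c in lay.coords.items()},
                walls=lay.walls, landmarks=lay.landmarks, bounds=lay.bounds,
                corridor_width=lay.corridor_width,
                hedge_height=lay.hedge_height)

        trials = [(2, 6), (3, 7), (5, 7)]
        judged = list(rng.uniform(0, 360, 3))
        recs = _records(trials, {"p": judged})
        base = compare_models(recs, set(trials), layout, alt_layout)
        recs_rot = recs.assign(judged_deg=(recs["judged_deg"] - phi) % 360)
        moved = compare_models(recs_rot, set(trials), rotate(layout),
                               rotate(alt_layout))
        for a, b in zip(base, moved):
            assert a.better_fit == b.better_fit
            assert a.mean_error_correct == pytest.approx(b.mean_error_correct)
            assert a.error_reduction == pytest.approx(b.error_reduction)

    def test_participant_without_bimodal_records_skipped(self, layout,
                                                         alt_layout, caplog):
        trials = [(3, 6)]
        recs = pd.concat([
            _records(trials, {"p1": [100.0]}),
            _records([(1, 2)], {"p2": [50.0]}),  # p2 only on another trial
        ])
        with caplog.at_level("INFO"):
            out = compare_models(recs, set(trials), layout, alt_layout)
        assert [c.participant for c in out] == ["p1"]
        assert "p2" in caplog.text

    def test_empty_bimodal_set_rejected(self, layout, alt_layout):
        with pytest.raises(ValueError):
            compare_models(pd.DataFrame(), set(), layout, alt_layout)


def _comparison(p, session, better, reduction=0.3):
    return ModelComparison(participant=p, session=session, n_trials=5,
                           mean_error_correct=50.0,
                           mean_error_alternative=35.0 if better == "alternative" else 60.0,
                           better_fit=better,
                           error_reduction=reduction if better == "alternative" else 0.0)


class TestAggregatePreference:
    def _profiles(self, participants, groups, levels):
        return pd.DataFrame({"participant": participants, "group": groups,
                             "sod_level": levels})

    def test_all_correct_gives_zero_percent(self):
        comps = [_comparison(f"p{i}", 1, "correct") for i in range(4)]
        profiles = self._profiles([f"p{i}" for i in range(4)],
                                  ["G"] * 4, ["low", "low", "high", "high"])
        out = aggregate_preference(comps, profiles)
        filled = out[out["n"] > 0]
        assert (filled["pct_alternative"] == 0).all()

    def test_single_participant_cells_are_extreme(self):
        comps = [_comparison("a", 1, "alternative"),
                 _comparison("b", 1, "correct")]
        profiles = self._profiles(["a", "b"], ["G", "G"], ["low", "high"])
        out = aggregate_preference(comps, profiles).set_index(
            ["group", "sod_level", "session"])
        assert out.loc[("G", "low", 1), "pct_alternative"] == 100.0
        assert out.loc[("G", "high", 1), "pct_alternative"] == 0.0

    def test_empty_cells_reported_missing(self):
        comps = [_comparison("a", 1, "alternative")]
        profiles = self._profiles(["a"], ["G"], ["low"])
        comps2 = comps + [_comparison("b", 2, "correct")]
        profiles2 = pd.concat([profiles, self._profiles(["b"], ["E"], ["high"])])
        out = aggregate_preference(comps2, profiles2).set_index(
            ["group", "sod_level", "session"])
        # the grid contains cells with no participants: NaN, not 0
        empty = out.loc[("E", "low", 1)]
        assert empty["n"] == 0 and np.isnan(empty["pct_alternative"])

    def test_mean_reduction_only_over_alternative_winners(self):
        comps = [_comparison("a", 1, "alternative", 0.6),
                 _comparison("b", 1, "alternative", 0.2),
                 _comparison("c", 1, "correct")]
        profiles = self._profiles(["a", "b", "c"], ["G"] * 3, ["low"] * 3)
        out = aggregate_preference(comps, profiles)
        cell = out[(out["group"] == "G") & (out["sod_level"] == "low")
                   & (out["session"] == 1)].iloc[0]
        assert cell["pct_alternative"] == pytest.approx(100 * 2 / 3)
        assert cell["mean_error_reduction"] == pytest.approx(0.4)
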