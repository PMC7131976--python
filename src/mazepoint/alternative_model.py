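"""Distorted-maze ("alternative") representations and model comparison.

Systematic pointing errors are hypothesized to arise from a distorted
cognitive map of the maze. Distortions are expressed as composable edits of
the intrinsic route spec -- forgetting a leg, mis-remembering a leg length,
rotating a whole sub-route at one turn -- never as ad-hoc coordinate
surgery, so every edited representation is again a realizable route.

The packaged composite distortion deletes the leg between locations 5 and
6, shrinks leg 6-7 to the length of leg 8-9, and rotates the final
sub-route (locations 7-9) by 90 degrees at location 7. Judged directions
are then scored against both the correct and the edited layout per
participant and session, over the trials flagged bimodal, and the layout
with the smaller mean absolute error wins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .geometry import (DEFAULT_CORRIDOR_WIDTH, DEFAULT_HEDGE_HEIGHT, Leg,
                       MazeLayout, RouteSpec, angular_error, realize_layout,
                       true_direction)

__all__ = [
    "DeleteLeg",
    "SetLegLength",
    "RotateSubroute",
    "MazeEdit",
    "ModelComparison",
    "apply_edits",
    "fig_alternative_edits",
    "alternative_route",
    "alternative_layout",
    "compare_models",
    "aggregate_preference",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Route edits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeleteLeg:
    """Forget a route segment: its endpoints fuse; the turns remembered at
    the fused joint add up, and everything downstream translates rigidly."""

    from_id: int
    to_id: int


@dataclass(frozen=True)
class SetLegLength:
    """Mis-remember one leg's length, either as an explicit value or as
    "the same length as" another leg (alignment error)."""

    from_id: int
    to_id: int
    length: float | None = None
    match: tuple[int, int] | None = None


@dataclass(frozen=True)
class RotateSubroute:
    """Rotate the sub-route starting at a location by a signed angle
    (degrees, + = clockwise): the turn remembered at that location changes,
    carrying the downstream component rigidly with it."""

    at_location: int
    angle_deg: float


MazeEdit = DeleteLeg | SetLegLength | RotateSubroute


def _find_leg(spec: RouteSpec, from_id: int, to_id: int,
              edit: MazeEdit) -> int:
    for i, leg in enumerate(spec.legs):
        if (leg.from_id, leg.to_id) == (from_id, to_id):
            return i
    raise ValueError(f"edit {edit!r} references leg ({from_id}, {to_id}) "
                     "which does not exist")


def apply_edits(spec: RouteSpec, edits: list[MazeEdit]) -> RouteSpec:
    """Apply route edits in order and return the edited spec.

    A deleted leg is retained with zero length (its endpoints coincide in
    any realized layout), which keeps location ids stable across editing.
    Coordinates of the edited representation come from
    :func:`mazepoint.geometry.realize_layout` as usual.
    """
    out = spec
    for edit in edits:
        legs = list(out.legs)
        if isinstance(edit, DeleteLeg):
            i = _find_leg(out, edit.from_id, edit.to_id, edit)
            legs[i] = replace(legs[i], length=0.0)
            out = replace(out, legs=tuple(legs))
        elif isinstance(edit, SetLegLength):
            i = _find_leg(out, edit.from_id, edit.to_id, edit)
            if (edit.length is None) == (edit.match is None):
                raise ValueError(f"edit {edit!r}: give exactly one of "
                                 "length or match")
            if edit.match is not None:
                j = _find_leg(out, edit.match[0], edit.match[1], edit)
                new_len = out.legs[j].length
            else:
                new_len = float(edit.length)
            if new_len < 0:
                raise ValueError(f"edit {edit!r}: negative length")
            legs[i] = replace(legs[i], length=new_len)
            out = replace(out, legs=tuple(legs))
        elif isinstance(edit, RotateSubroute):
            if edit.at_location not in range(2, out.n_locations):
                raise ValueError(f"edit {edit!r}: location "
                                 f"{edit.at_location} is not interior")
            turns = dict(out.turns)
            turns[edit.at_location] = turns.get(edit.at_location, 0.0) \
                + edit.angle_deg
            out = replace(out, turns=turns)
        else:
            raise TypeError(f"unknown edit {edit!r}")
    out.validate(allow_zero_legs=True)
    return out


def fig_alternative_edits(rotation_sign: int = -1) -> list[MazeEdit]:
    """The packaged composite distortion for the nine-location maze.

    Forgetting leg 5-6, shortening leg 6-7 to the length of leg 8-9, and
    rotating the final three-location component 90 degrees at location 7.
    The rotation handedness is not pinned down by the source figure; the
    default -90 turns the component toward the maze body and leaves the
    edited route free of corridor collisions.
    """
    if abs(rotation_sign) != 1:
        raise ValueError("rotation_sign must be +1 or -1")
    return [
        DeleteLeg(5, 6),
        SetLegLength(6, 7, match=(8, 9)),
        RotateSubroute(7, rotation_sign * 90.0),
    ]


def alternative_route(spec: RouteSpec, rotation_sign: int = -1) -> RouteSpec:
    """Apply the packaged composite distortion to a nine-location route."""
    if spec.n_locations != 9:
        raise ValueError("the packaged distortion assumes nine locations")
    return apply_edits(spec, fig_alternative_edits(rotation_sign))


def alternative_layout(spec: RouteSpec, rotation_sign: int = -1,
                       corridor_width: float = DEFAULT_CORRIDOR_WIDTH,
                       hedge_height: float = DEFAULT_HEDGE_HEIGHT) -> MazeLayout:
    return realize_layout(alternative_route(spec, rotation_sign),
                          corridor_width, hedge_height)


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelComparison:
    """Correct versus alternative representation for one participant-session."""

    participant: str
    session: int
    n_trials: int
    mean_error_correct: float
    mean_error_alternative: float
    better_fit: str               # "correct" | "alternative"
    error_reduction: float        # 1 - alt/correct when alternative wins, else 0


def _trial_directions(layout: MazeLayout,
                      trials: set[tuple[int, int]]) -> dict[tuple[int, int], float]:
    return {t: true_direction(layout, t[0], t[1]) for t in sorted(trials)}


def compare_models(records: pd.DataFrame,
                   bimodal_trials: set[tuple[int, int]],
                   correct: MazeLayout,
                   alternative: MazeLayout) -> list[ModelComparison]:
    """Score each participant-session against both maze representations.

    Only records of trials in ``bimodal_trials`` enter. Each judged azimuth
    is scored by its absolute angular error against the trial's true
    direction in each layout; per participant and session the layout with
    the smaller mean error fits better (ties go to the correct layout).
    ``error_reduction`` is ``1 - alt/correct`` when the alternative wins.

    Every trial must be resolvable (non-coincident endpoints) in both
    layouts; participants without any bimodal-trial record are skipped with
    a log entry.
    """
    if not bimodal_trials:
        raise ValueError("no bimodal trials to compare on")
    dir_correct = _trial_directions(correct, bimodal_trials)
    dir_alt = _trial_directions(alternative, bimodal_trials)

    mask = [(o, t) in bimodal_trials
            for o, t in zip(records["origin"], records["target"])]
    sub = records.loc[mask].copy()
    skipped = set(records["participant"]) - set(sub["participant"])
    for p in sorted(skipped):
        log.info("participant %s has no records on bimodal trials; skipped", p)

    trials = list(zip(sub["origin"], sub["target"]))
    judged = sub["judged_deg"].to_numpy(dtype=float)
    err_c = np.array([angular_error(j, dir_correct[t])
                      for j, t in zip(judged, trials)])
    err_a = np.array([angular_error(j, dir_alt[t])
                      for j, t in zip(judged, trials)])
    sub = sub.assign(_err_c=err_c, _err_a=err_a)

    out = []
    for (p, s), grp in sub.groupby(["participant", "session"], sort=True):
        mc = float(grp["_err_c"].mean())
        ma = float(grp["_err_a"].mean())
        alt_wins = ma < mc
        out.append(ModelComparison(
            participant=str(p), session=int(s), n_trials=len(grp),
            mean_error_correct=mc, mean_error_alternative=ma,
            better_fit="alternative" if alt_wins else "correct",
            error_reduction=float(1.0 - ma / mc) if alt_wins and mc > 0 else 0.0,
        ))
    return out


def comparisons_to_frame(comparisons: list[ModelComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in comparisons])


def aggregate_preference(comparisons: list[ModelComparison],
                         profiles: pd.DataFrame) -> pd.DataFrame:
    """Alternative-model preference rates per group, SOD level and session.

    ``profiles`` must carry ``participant``, ``group`` and ``sod_level``
    columns. Returns one row per (group, sod_level, session) cell of the
    full grid -- cells with no participants report ``NaN``, not zero --
    plus per-session ``overall`` rows. ``pct_alternative`` is the
    percentage of participants whose data the alternative representation
    fits better; ``mean_error_reduction`` averages the error-reduction
    fraction over those participants only.
    """
    if not comparisons:
        raise ValueError("no model comparisons to aggregate")
    df = comparisons_to_frame(comparisons).merge(
        profiles[["participant", "group", "sod_level"]],
        on="participant", how="left", validate="many_to_one")
    if df["group"].isna().any():
        missing = sorted(df.loc[df["group"].isna(), "participant"].unique())
        raise ValueError(f"participants missing from profiles: {missing}")

    def _cell(grp: pd.DataFrame) -> pd.Series:
        alt = grp["better_fit"] == "alternative"
        return pd.Series({
            "n": len(grp),
            "pct_alternative": 100.0 * alt.mean(),
            "mean_error_reduction": grp.loc[alt, "error_reduction"].mean()
            if alt.any() else np.nan,
        })

    cells = (df.groupby(["group", "sod_level", "session"])
             .apply(_cell, include_groups=False))
    grid = pd.MultiIndex.from_product(
        [sorted(df["group"].unique()), sorted(df["sod_level"].unique()),
         sorted(df["session"].unique())],
        names=["group", "sod_level", "session"])
    cells = cells.reindex(grid).reset_index()

    overall = (df.groupby("session").apply(_cell, include_groups=False)
               .reset_index())
    overall.insert(0, "group", "overall")
    overall.insert(1, "sod_level", "all")
    out = pd.concat([cells, overall], ignore_index=True)
    out["n"] = out["n"].fillna(0).astype(int)
    return out
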