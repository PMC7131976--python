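"""Synthetic pointing cohorts with the structure the analysis assumes.

The generator emulates the study design end to end: three perspective
groups (ground G, ground-plus-elevated G+E, elevated E) across two
experiments, two test sessions, 72 ordered pointing trials per participant
per session, latent low/high sense-of-direction strata, and six TLX
workload items per session.

Judged directions on visible trials concentrate tightly on the true
direction (von Mises noise at high concentration). Non-visible trials on
*eligible* pairs -- by default every pair touching the distorted tail of
the maze, locations 6-9 -- draw their mean direction from the alternative
(distorted) layout with probability ``p_alt`` and from the correct layout
otherwise, then add von Mises noise whose concentration depends on SOD
stratum, group and session. All other non-visible trials always point at
the correct direction, noisily. Adoption of the alternative representation
is Bernoulli per trial by default; a switch makes it a latent
per-participant-per-session state instead (a unified distorted map rather
than piecemeal distortion).

Everything is deterministic given the master seed: each participant gets an
independent child stream of a ``SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .geometry import MazeLayout, angular_error, normalize_azimuth, true_direction
from .participants import TLX_SCALE, raw_tlx
from .visibility import classify_pointing_pairs

__all__ = ["GeneratorConfig", "reference_config", "simulate_cohort"]


def _nested(d):  # default-factory helper
    return field(default_factory=lambda: {k: (dict(v) if isinstance(v, dict) else v)
                                          for k, v in d.items()})


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort. Defaults are the reference
    conditions (see :func:`reference_config`)."""

    # cohort composition
    n_per_group: dict = _nested({"G": 24, "G+E": 24, "E": 24})
    experiment_of_group: dict = _nested({"G": 1, "G+E": 1, "E": 2})

    # SOD score strata: mean and sd of a truncated normal on the SBSOD range
    sod_strata: dict = _nested({"low": (3.2, 0.6), "high": (5.2, 0.6)})
    sod_bounds: tuple = (1.0, 7.0)

    # pointing noise concentrations
    kappa_visible: float = 200.0
    kappa_nonvisible: dict = _nested({
        "G": {"low": 3.0, "high": 8.0},      # ability gap present
        "G+E": {"low": 6.0, "high": 6.0},    # gap bridged
        "E": {"low": 6.0, "high": 6.0},
    })
    session2_kappa_gain: float = 1.4         # practice: less noise in session 2

    # alternative-representation adoption probability per trial,
    # p_alt[group][stratum][session]
    p_alt: dict = _nested({
        "G": {"low": {1: 0.85, 2: 0.65}, "high": {1: 0.25, 2: 0.15}},
        "G+E": {"low": {1: 0.55, 2: 0.40}, "high": {1: 0.45, 2: 0.30}},
        "E": {"low": {1: 0.60, 2: 0.45}, "high": {1: 0.50, 2: 0.35}},
    })
    per_participant_adoption: bool = False
    # pairs eligible for alternative-model directions: any trial whose origin
    # or target lies in this set (None -> all non-visible pairs)
    eligible_locations: tuple = (6, 7, 8, 9)

    # workload items
    tlx_session_mean: dict = _nested({1: 5.3, 2: 4.8})
    tlx_sd: float = 1.2

    # compliance outliers: huge visible-trial noise, to be caught by the
    # exclusion fence
    outlier_rate: float = 0.04
    outlier_kappa_visible: float = 1.0

    seed: int = 1234

    def validate(self) -> None:
        for g, n in self.n_per_group.items():
            if n < 1:
                raise ValueError(f"n_per_group[{g!r}] must be >= 1")
            if g not in self.experiment_of_group:
                raise ValueError(f"group {g!r} has no experiment assignment")
        for g in self.n_per_group:
            for s in ("low", "high"):
                if self.kappa_nonvisible[g][s] <= 0:
                    raise ValueError("concentrations must be positive")
                for sess in (1, 2):
                    p = self.p_alt[g][s][sess]
                    if not 0.0 <= p <= 1.0:
                        raise ValueError("p_alt values must lie in [0, 1]")
        if self.kappa_visible <= 0 or self.outlier_kappa_visible <= 0:
            raise ValueError("concentrations must be positive")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def reference_config() -> GeneratorConfig:
    """The packaged reference conditions.

    24 participants per group; visible trials nearly noise-free
    (kappa = 200, circular sd about 4 degrees); non-visible concentration
    split by SOD stratum in the ground-only group but not in the groups
    with elevated access; session 2 less noisy than session 1; alternative-
    representation adoption highest for low-SOD ground-only participants
    and lower everywhere in session 2. Pairs touching locations 6-9 are
    eligible for the distorted directions.
    """
    return GeneratorConfig()


# ---------------------------------------------------------------------------


def _draw_truncnorm(rng, mean, sd, lo, hi, size=None):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _vm_deg(rng, mean_deg: float, kappa: float, size=None):
    draws = rng.vonmises(np.radians(mean_deg), kappa, size=size)
    return normalize_azimuth(np.degrees(draws)) if size is None \
        else np.degrees(draws) % 360.0


def eligible_trials(config: GeneratorConfig, correct: MazeLayout,
                    alternative: MazeLayout,
                    pairs: pd.DataFrame) -> set[tuple[int, int]]:
    """Non-visible ordered pairs that can take alternative-model directions:
    they touch an eligible location, and both layouts give them a defined
    direction."""
    locs = set(config.eligible_locations) if config.eligible_locations else None
    out = set()
    for o, t, vis in pairs.itertuples(index=False):
        if vis or (locs is not None and o not in locs and t not in locs):
            continue
        try:
            true_direction(alternative, o, t)
            true_direction(correct, o, t)
        except ValueError:
            continue
        out.add((o, t))
    return out


def simulate_cohort(config: GeneratorConfig, correct: MazeLayout,
                    alternative: MazeLayout,
                    seed: int | None = None
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a full cohort: (participant profiles, pointing records).

    Returns two frames. ``profiles`` has one row per participant with
    group, experiment, SOD score and latent stratum, TLX items and Raw TLX
    per session, latent outlier flag, and per-session mean visible error.
    ``records`` has one row per participant x session x ordered pair with
    the judged azimuth, visibility flag, and the absolute pointing error
    against the correct layout.

    Deterministic for a given master seed: participants get independent
    child streams of a single ``SeedSequence``, so cohort size changes do
    not reshuffle earlier participants' data.
    """
    config.validate()
    if set(correct.location_ids) != set(alternative.location_ids):
        raise ValueError("layouts must share location ids")
    master = config.seed if seed is None else seed

    pairs = classify_pointing_pairs(correct, 1.4)
    trial_list = list(zip(pairs["origin"], pairs["target"], pairs["visible"]))
    dir_correct = {(o, t): true_direction(correct, o, t)
                   for o, t, _ in trial_list}
    elig = eligible_trials(config, correct, alternative, pairs)
    dir_alt = {tr: true_direction(alternative, *tr) for tr in elig}

    groups = sorted(config.n_per_group)
    n_total = sum(config.n_per_group.values())
    ss = np.random.SeedSequence(master)
    cohort_rng = np.random.default_rng(ss.spawn(1)[0])
    child_seeds = ss.spawn(n_total)

    lo_sod, hi_sod = config.sod_bounds
    profile_rows, record_rows = [], []
    pid = 0
    for group in groups:
        n = config.n_per_group[group]
        for i_in_group in range(n):
            rng = np.random.default_rng(child_seeds[pid])
            participant = f"P{pid + 1:03d}"
            stratum = "low" if i_in_group < (n + 1) // 2 else "high"
            mean, sd = config.sod_strata[stratum]
            sod = float(_draw_truncnorm(rng, mean, sd, lo_sod, hi_sod))
            outlier = bool(rng.random() < config.outlier_rate)
            kv = config.outlier_kappa_visible if outlier else config.kappa_visible

            profile = {
                "participant": participant, "group": group,
                "experiment": config.experiment_of_group[group],
                "sod_score": round(sod, 3), "sod_stratum": stratum,
                "outlier": outlier,
            }
            for session in (1, 2):
                knv = config.kappa_nonvisible[group][stratum]
                if session == 2:
                    knv *= config.session2_kappa_gain
                p_alt = config.p_alt[group][stratum][session]
                adopt_all = (rng.random() < p_alt
                             if config.per_participant_adoption else None)
                vis_errors = []
                for o, t, vis in trial_list:
                    truth = dir_correct[(o, t)]
                    if vis:
                        judged = float(_vm_deg(rng, truth, kv))
                    else:
                        if (o, t) in elig:
                            adopt = adopt_all if adopt_all is not None \
                                else bool(rng.random() < p_alt)
                        else:
                            adopt = False
                        mean_dir = dir_alt[(o, t)] if adopt else truth
                        judged = float(_vm_deg(rng, mean_dir, knv))
                    err = angular_error(judged, truth)
                    if vis:
                        vis_errors.append(err)
                    record_rows.append((participant, group,
                                        config.experiment_of_group[group],
                                        session, o, t, round(judged, 4),
                                        bool(vis), round(err, 4)))
                items = np.clip(
                    _draw_truncnorm(rng, config.tlx_session_mean[session],
                                    config.tlx_sd, *TLX_SCALE, size=6),
                    *TLX_SCALE)
                items = tuple(round(float(x), 2) for x in items)
                for j, x in enumerate(items, start=1):
                    profile[f"tlx{j}_s{session}"] = x
                profile[f"raw_tlx_s{session}"] = round(raw_tlx(items), 4)
                profile[f"mean_visible_error_s{session}"] = round(
                    float(np.mean(vis_errors)), 4)
            profile_rows.append(profile)
            pid += 1

    del cohort_rng  # reserved for cohort-level draws; none currently
    profiles = pd.DataFrame(profile_rows)
    records = pd.DataFrame(record_rows, columns=[
        "participant", "group", "experiment", "session", "origin", "target",
        "judged_deg", "visible", "error_deg"])
    return profiles, records
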