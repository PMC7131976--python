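"""End-to-end orchestration of the pointing-error analysis.

A single YAML config drives the whole chain: visibility classification,
cohort simulation (or a records CSV), the visible-error exclusion fence,
the SOD median split, per-target error summaries, per-trial mixture fits
with modality selection, construction of the alternative maze, the
per-participant model comparison, and the preference aggregation. Every
stage writes a CSV or JSON artifact and the run closes with a manifest
(config and layout hashes, seed, output list) that makes reruns checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .alternative_model import (aggregate_preference, alternative_layout,
                                compare_models, comparisons_to_frame)
from .circular_stats import MixtureConfig, per_target_error_summary, select_modality
from .geometry import (GROUND_EYE_HEIGHT, MazeLayout, layout_from_json,
                       reference_layout, reference_route, true_direction)
from .participants import exclude_by_visible_error, sod_median_split
from .synthetic_data import GeneratorConfig, reference_config, simulate_cohort
from .visibility import classify_pointing_pairs

__all__ = ["RunManifest", "run_pipeline", "load_layout"]

log = logging.getLogger(__name__)

STAGES = ("visibility", "records", "exclusion", "sod_split",
          "target_summary", "mixtures", "comparison")


@dataclass
class RunManifest:
    config_hash: str
    layout_hash: str
    seed: int
    version: str
    outputs: list[str] = field(default_factory=list)
    stages_completed: list[str] = field(default_factory=list)
    failed_stage: str | None = None
    started: float = 0.0
    finished: float = 0.0

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _sha256(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def load_layout(spec: str | None, base: Path) -> MazeLayout:
    """Resolve a layout reference: 'reference' (or None) for the packaged
    maze, otherwise a path to a maze JSON document."""
    if spec in (None, "reference"):
        return reference_layout()
    return layout_from_json((base / spec).read_text())


def _mixture_config(thresholds: dict) -> MixtureConfig:
    allowed = {"restarts", "tol", "max_iter", "kappa_cap", "w_min", "s_min",
               "bootstrap_B"}
    unknown = set(thresholds) - allowed
    if unknown:
        raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
    return MixtureConfig(**thresholds)


def run_pipeline(config: str | Path | dict,
                 out_dir: str | Path | None = None) -> RunManifest:
    """Run the full analysis described by a YAML config (path or dict).

    Config keys: ``layout`` ('reference' or a maze JSON path), ``out_dir``,
    either ``simulate`` ({seed, overrides...}) or ``records`` (CSV path),
    optional ``thresholds`` (mixture fitting), ``alternative``
    ({rotation_sign}), ``eye_height``, ``min_angles``.

    Missing inputs fail before any stage runs. A stage failure keeps the
    partial outputs and records the failure point in the manifest.
    """
    base = Path(".")
    if isinstance(config, (str, Path)):
        base = Path(config).parent
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, dict):
        raise TypeError("config must be a mapping or a path to one")
    if "simulate" not in config and "records" not in config:
        raise ValueError("config needs a 'simulate' block or a 'records' CSV")
    if "records" in config and not (base / config["records"]).exists():
        raise FileNotFoundError(f"records file {config['records']} not found")

    out = Path(out_dir if out_dir is not None
               else config.get("out_dir", "mazepoint_run"))
    out.mkdir(parents=True, exist_ok=True)
    layout = load_layout(config.get("layout"), base)
    eye = float(config.get("eye_height", GROUND_EYE_HEIGHT))
    sim_block = config.get("simulate") or {}
    seed = int(sim_block.get("seed", 0))

    manifest = RunManifest(
        config_hash=_sha256(json.dumps(config, sort_keys=True, default=str)),
        layout_hash=_sha256(json.dumps(layout.to_geojson(), sort_keys=True)),
        seed=seed, version=__version__, started=time.time())

    def _done(stage: str, path: Path) -> None:
        manifest.stages_completed.append(stage)
        manifest.outputs.append(path.name)
        log.info("stage %-14s -> %s", stage, path.name)

    try:
        t0 = time.time()
        # 1. visibility classification
        pairs = classify_pointing_pairs(layout, eye)
        pairs.to_csv(out / "pairs.csv", index=False)
        _done("visibility", out / "pairs.csv")

        # 2. records: simulate or load
        rotation_sign = int(config.get("alternative", {}).get("rotation_sign", -1))
        route = layout.route if layout.route is not None else reference_route()
        alt = alternative_layout(route, rotation_sign)
        if "records" in config:
            records = pd.read_csv(base / config["records"])
            profiles = pd.read_csv(base / config["participants"]) \
                if "participants" in config else None
        else:
            gen = reference_config()
            for key, val in sim_block.get("overrides", {}).items():
                if not hasattr(gen, key):
                    raise ValueError(f"unknown generator override {key!r}")
                setattr(gen, key, val)
            profiles, records = simulate_cohort(gen, layout, alt, seed=seed)
        if records.empty:
            raise ValueError("no records")
        records.to_csv(out / "pointings.csv", index=False)
        _done("records", out / "pointings.csv")

        # 3. visible-error exclusion fence, per experiment pool
        vis = records[records["visible"]]
        mean_vis = vis.groupby("participant")["error_deg"].mean()
        experiment = records.drop_duplicates("participant") \
            .set_index("participant")["experiment"]
        excluded: set[str] = set()
        for _, pool in mean_vis.groupby(experiment):
            excluded |= exclude_by_visible_error(pool.to_dict())
        records = records[~records["participant"].isin(excluded)]
        pd.DataFrame({"participant": sorted(excluded)}).to_csv(
            out / "excluded.csv", index=False)
        _done("exclusion", out / "excluded.csv")

        # 4. SOD median split over the retained participants
        if profiles is None:
            raise ValueError("a participants table is required with records")
        profiles = profiles[~profiles["participant"].isin(excluded)]
        profiles = sod_median_split(profiles)
        profiles.to_csv(out / "participants.csv", index=False)
        _done("sod_split", out / "participants.csv")

        # 5. per-target error summary (non-visible trials)
        summary = per_target_error_summary(records[~records["visible"]])
        summary.to_csv(out / "target_summary.csv", index=False)
        _done("target_summary", out / "target_summary.csv")

        # 6. per-trial mixture fits over pooled non-visible directions
        mix_cfg = _mixture_config(config.get("thresholds", {}))
        min_angles = int(config.get("min_angles", 10))
        nonvis = records[~records["visible"]]
        fits = []
        for (o, t), grp in nonvis.groupby(["origin", "target"], sort=True):
            if len(grp) < min_angles:
                continue
            fits.append(select_modality(grp["judged_deg"].to_numpy(),
                                        config=mix_cfg, seed=seed,
                                        trial=(int(o), int(t))))
        (out / "fits.json").write_text(json.dumps(
            [f.to_dict() for f in fits], indent=2))
        _done("mixtures", out / "fits.json")

        # 7. alternative-model comparison over bimodal trials + aggregation
        bimodal = {f.trial for f in fits if f.verdict == "bimodal"}
        resolvable = set()
        for tr in bimodal:
            try:
                true_direction(alt, *tr)
                resolvable.add(tr)
            except ValueError:
                log.info("trial %s unresolvable in alternative layout", tr)
        comparisons = compare_models(nonvis, resolvable, layout, alt)
        comparisons_to_frame(comparisons).to_csv(
            out / "comparison.csv", index=False)
        preference = aggregate_preference(comparisons, profiles)
        preference.to_csv(out / "preference.csv", index=False)
        _done("comparison", out / "comparison.csv")
        manifest.outputs.append("preference.csv")
        log.info("pipeline finished in %.1f s", time.time() - t0)
    except Exception:
        done = set(manifest.stages_completed)
        manifest.failed_stage = next(s for s in STAGES if s not in done)
        manifest.finished = time.time()
        (out / "manifest.json").write_text(
            json.dumps(manifest.to_dict(), indent=2))
        raise

    manifest.finished = time.time()
    (out / "manifest.json").write_text(json.dumps(manifest.to_dict(), indent=2))
    return manifest
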