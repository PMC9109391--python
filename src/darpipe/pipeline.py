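"""End-to-end orchestration: simulate -> featurize -> split -> tune ->
evaluate -> ablate, plus classification of new tracking data with a saved
model.

A run is driven by a :class:`RunConfig` (loadable from a YAML mapping) and a
single global seed.  Stage ``k`` derives its own seed as ``1000*seed + k``
(a documented counter scheme), so stages can be rerun independently and the
whole run is deterministic under ``(config, seed)``.  Stage outputs land in
the run directory together with a manifest recording the config hash; an
unchanged rerun resumes from cached stage outputs.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import logging
import pathlib
import time
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import features as feat
from . import metrics as met
from . import models as mod
from . import preprocess as prep
from . import simulate as sim
from . import tracking

logger = logging.getLogger(__name__)

STAGES = ("simulate", "featurize", "split", "tune", "evaluate", "ablate")


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: str = "run"
    # inputs: either simulate=True or paths to tracks/labels (+ optional raster)
    simulate: bool = True
    tracks_csv: str | None = None
    labels_csv: str | None = None
    raster_csv: str | None = None
    timezone: str = tracking.DEFAULT_TIMEZONE
    feature_sets: tuple[str, ...] = ("movement_timing", "habitat", "history")
    fractions: tuple[float, float, float] = prep.DEFAULT_FRACTIONS
    split_mode: str = "record"
    candidates: tuple[int, ...] = tuple(range(1, 11))
    n_evals: int = 20
    # synthetic population settings (used when simulate=True)
    n_animals: int = 60
    days_per_animal: int = 40
    water_fraction: float = 0.35
    schedule_mode: str = "iid"
    ablation_combos: tuple[str, ...] = ("ALL", "MT+habitat", "MT+history", "MT")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("feature_sets", "fractions", "candidates", "ablation_combos"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if not np.isclose(sum(self.fractions), 1.0):
            raise ValueError("split fractions must sum to 1")
        if "habitat" in self.feature_sets and not self.simulate \
                and self.raster_csv is None:
            raise ValueError("habitat feature set requested but no raster given")
        if not self.simulate and (self.tracks_csv is None or self.labels_csv is None):
            raise ValueError("either simulate=True or tracks_csv+labels_csv required")

    def digest(self, seed: int) -> str:
        payload = json.dumps({**dataclasses.asdict(self), "seed": seed},
                             sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stage_seed(seed: int, stage: str) -> int:
    return (1000 * seed + STAGES.index(stage)) % (2 ** 31)


def _log_stage(outdir: pathlib.Path, stage: str, **info) -> None:
    entry = {"stage": stage, "time": datetime.datetime.now(datetime.UTC).isoformat(),
             **info}
    with open(outdir / "run.log", "a") as fh:
        fh.write(json.dumps(entry, default=str) + "\n")
    logger.info("stage %s: %s", stage, info)


def run_pipeline(config: RunConfig, seed: int = 0,
                 until: str | None = None) -> pathlib.Path:
    """Execute the pipeline (optionally only up to stage ``until``); returns
    the run directory.

    Stage outputs: ``features.csv``, ``split.csv``, ``model/`` (transformer,
    best hyperparameters, tuning history, training features),
    ``metrics.json`` + ``confusion.csv``, ``ablation.csv``, ``manifest.json``.
    """
    if until is not None and until not in STAGES:
        raise ValueError(f"unknown stage {until!r}")
    config.validate()
    outdir = pathlib.Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    digest = config.digest(seed)
    manifest_path = outdir / "manifest.json"
    manifest = (json.loads(manifest_path.read_text())
                if manifest_path.exists() else {})
    if manifest.get("digest") != digest:
        manifest = {"digest": digest, "seed": seed, "stages": {}}

    def done(stage: str, *paths) -> bool:
        return (manifest["stages"].get(stage) == digest
                and all((outdir / p).exists() for p in paths))

    def mark(stage: str, **info) -> None:
        manifest["stages"][stage] = digest
        manifest_path.write_text(json.dumps(manifest, indent=2))
        _log_stage(outdir, stage, **info)

    # --- inputs -----------------------------------------------------------
    grid = None
    if config.simulate:
        if done("simulate", "tracks.csv", "truth.csv", "landscape.csv"):
            pass
        else:
            scfg = sim.SyntheticConfig(
                n_animals=config.n_animals,
                days_per_animal=config.days_per_animal,
                water_fraction=config.water_fraction,
                schedule_mode=config.schedule_mode,
                seed=stage_seed(seed, "simulate"),
                timezone=config.timezone)
            pop = sim.simulate_population(scfg)
            sim.write_population(pop, outdir / "tracks.csv",
                                 outdir / "truth.csv", outdir / "landscape.csv")
            mark("simulate", n_days=len(pop.labeled_days))
        tracks_csv = outdir / "tracks.csv"
        labels_csv = outdir / "truth.csv"
        raster_csv = outdir / "landscape.csv"
        if until == "simulate":
            return outdir
    else:
        tracks_csv, labels_csv = config.tracks_csv, config.labels_csv
        raster_csv = config.raster_csv
    if "habitat" in config.feature_sets:
        from .landscape import WaterIndexGrid
        grid = WaterIndexGrid.from_csv(raster_csv)

    # --- featurize --------------------------------------------------------
    if not done("featurize", "features.csv"):
        fixes = tracking.read_tracks(tracks_csv, timezone=config.timezone)
        fixes = tracking.project_fixes(fixes, sim.SIM_PROJECTION
                                       if config.simulate else None)
        day_tracks, excluded = tracking.build_day_tracks(fixes, 60,
                                                         config.timezone)
        labels = pd.read_csv(labels_csv, parse_dates=["date"])
        lut = {(r.animal_id, r.date.date()): r.label
               for r in labels.itertuples()}
        labelled = [tracking.LabeledDay(t, lut[(t.animal_id, t.date)])
                    for t in day_tracks if (t.animal_id, t.date) in lut]
        table = feat.featurize_days(labelled, grid, config.feature_sets)
        table.to_csv(outdir / "features.csv", index=False)
        mark("featurize", n_days=len(table), n_excluded=len(excluded))
    if until == "featurize":
        return outdir
    table = pd.read_csv(outdir / "features.csv", parse_dates=["date"])

    # --- split ------------------------------------------------------------
    if not done("split", "split.csv"):
        idx = prep.split(table, config.fractions,
                         seed=stage_seed(seed, "split"), mode=config.split_mode)
        idx.to_csv(outdir / "split.csv")
        mark("split", sizes=[len(idx.train), len(idx.validation), len(idx.test)])
    if until == "split":
        return outdir
    split_df = pd.read_csv(outdir / "split.csv")
    idx = prep.SplitIndices(
        split_df.loc[split_df.partition == "train", "index"].to_numpy(),
        split_df.loc[split_df.partition == "validation", "index"].to_numpy(),
        split_df.loc[split_df.partition == "test", "index"].to_numpy(),
        seed=stage_seed(seed, "split"), mode=config.split_mode)
    train, val, test = (table.iloc[idx.train], table.iloc[idx.validation],
                        table.iloc[idx.test])

    # --- tune -------------------------------------------------------------
    specs = [c for c in mod.make_candidates()
             if c.candidate_id in config.candidates]
    if not done("tune", "model/model.json"):
        t0 = time.time()
        tuned: list[mod.TunedModel] = []
        scores = []
        for spec in specs:
            m = mod.tune(spec, train, val, n_evals=config.n_evals,
                         seed=stage_seed(seed, "tune") + spec.candidate_id)
            pred, _ = mod.predict(m, val)
            wf1 = met.evaluate(val["label"], pred).weighted_f1
            tuned.append(m)
            scores.append(wf1)
            _log_stage(outdir, "tune", candidate=spec.candidate_id,
                       val_macro_f1=m.validation_macro_f1, val_weighted_f1=wf1)
        best = tuned[int(np.argmax(scores))]
        best.save(outdir / "model")
        train.to_csv(outdir / "model" / "train_features.csv", index=False)
        pd.DataFrame({"candidate_id": [m.candidate_id for m in tuned],
                      "val_macro_f1": [m.validation_macro_f1 for m in tuned],
                      "val_weighted_f1": scores}).to_csv(
            outdir / "candidate_scores.csv", index=False)
        mark("tune", best_candidate=best.candidate_id,
             elapsed_s=round(time.time() - t0, 1))
    if until == "tune":
        return outdir
    best = mod.load_tuned(
        outdir / "model",
        pd.read_csv(outdir / "model" / "train_features.csv", parse_dates=["date"]))

    # --- evaluate ---------------------------------------------------------
    if not done("evaluate", "metrics.json", "confusion.csv"):
        pred, _ = mod.predict(best, test)
        cm = met.confusion(test["label"], pred)
        report = met.aggregate_metrics(cm)
        report.to_json(outdir / "metrics.json")
        cm.to_csv(outdir / "confusion.csv")
        met.plot_confusion(cm, outdir / "confusion.png")
        mark("evaluate", test_weighted_f1=report.weighted_f1,
             test_macro_f1=report.macro_f1)
    if until == "evaluate":
        return outdir

    # --- ablate -----------------------------------------------------------
    if config.ablation_combos and not done("ablate", "ablation.csv"):
        combos = {name: met.ABLATION_COMBOS[name]
                  for name in config.ablation_combos
                  if all(s in config.feature_sets
                         for s in met.ABLATION_COMBOS[name])}
        best_spec = next(c for c in specs if c.candidate_id == best.candidate_id)
        reports = met.ablation_run(table, combos, best_spec, best.best_params,
                                   idx, seed=stage_seed(seed, "ablate"))
        met.ablation_table(reports).to_csv(outdir / "ablation.csv")
        mark("ablate", combos=list(combos),
             weighted_f1={k: r.weighted_f1 for k, r in reports.items()})
    return outdir


def classify_new(
    model_dir,
    tracks_csv,
    raster_csv=None,
    timezone: str = tracking.DEFAULT_TIMEZONE,
) -> pd.DataFrame:
    """Classify novel tracking data with a saved model.

    Returns one row per complete animal-day with either a predicted class or
    an ineligibility reason (e.g. days lacking the 15 prior tracking days a
    history-feature model requires).
    """
    model_dir = pathlib.Path(model_dir)
    train = pd.read_csv(model_dir / "train_features.csv", parse_dates=["date"])
    model = mod.load_tuned(model_dir, train)
    needed_sets = sorted({feat.FEATURE_SET_OF[c] for c in model.transformer.columns
                          if c in feat.FEATURE_SET_OF})
    grid = None
    if "habitat" in needed_sets:
        if raster_csv is None:
            raise ValueError("model requires habitat features but no raster given")
        from .landscape import WaterIndexGrid
        grid = WaterIndexGrid.from_csv(raster_csv)

    fixes = tracking.read_tracks(tracks_csv, timezone=timezone)
    if len(fixes) == 0:
        return pd.DataFrame(columns=["animal_id", "date", "eligible",
                                     "prediction", "reason"])
    fixes = tracking.project_fixes(fixes)
    day_tracks, _ = tracking.build_day_tracks(fixes, 60, timezone)
    table = feat.featurize_days(day_tracks, grid, tuple(needed_sets))
    rows = []
    eligible_rows = []
    max_lag = max(hi for _, _, hi in feat.HISTORY_WINDOWS)
    for i, row in table.iterrows():
        if "history" in needed_sets:
            hist_cols = [c for c in table.columns
                         if feat.FEATURE_SET_OF.get(c) == "history"]
            if row[hist_cols].isna().any():
                rows.append({"animal_id": row["animal_id"], "date": row["date"],
                             "eligible": False, "prediction": None,
                             "reason": "insufficient history "
                                       f"(needs {max_lag} prior days)"})
                continue
        eligible_rows.append(i)
        rows.append({"animal_id": row["animal_id"], "date": row["date"],
                     "eligible": True, "prediction": None, "reason": ""})
    out = pd.DataFrame(rows)
    if eligible_rows:
        preds, _ = mod.predict(model, table.loc[eligible_rows])
        out.loc[out["eligible"], "prediction"] = preds
    return out
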