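"""End-to-end orchestration: simulate -> preprocess -> segment -> classify.

The run streams one recording at a time, so the 120-recording default
study never has to be resident in memory; only the all-band epochs
(stored float32) and the per-epoch feature rows are kept.  Per-stage
epoch counts are asserted at run time so the design bookkeeping
(subjects x conditions x trials all-band epochs, x4 sub-band, x5 feature
rows) is a built-in check rather than just a test.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from microband.classify import (
    filter_outliers,
    impurity_importance,
    oob_importance,
    run_grid,
)
from microband.config import PipelineConfig
from microband.covariates import ancova_table, average_trials
from microband.edf import write_edf
from microband.microstate import (
    MicrostateModel,
    assign_canonical_labels,
    epoch_features,
    extract_peak_maps,
    modified_kmeans,
)
from microband.preprocess import (
    SUB_BANDS,
    bandpass_fir,
    downsample,
    epoch_continuous,
    split_bands,
)
from microband.synthetic import SyntheticStudy, synthesize_study

logger = logging.getLogger("microband")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the partial manifest."""

    def __init__(self, stage: str, manifest: dict, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.manifest = manifest


@dataclass
class RunResult:
    """Everything one end-to-end run produces."""

    manifest: dict
    features: pd.DataFrame
    results: pd.DataFrame
    importance: pd.DataFrame
    importance_impurity: pd.DataFrame
    ancova: pd.DataFrame
    model: MicrostateModel
    study: SyntheticStudy = field(repr=False, default=None)


def run_all(config: PipelineConfig, out_dir: str | Path | None = None
            ) -> RunResult:
    """Run the whole pipeline under one validated configuration.

    Stages: synthesize the study; FIR-bandpass (all-band), down-sample
    and epoch every recording; fit the pooled-group microstate model on
    GFP-peak maps of the all-band epochs; back-fit all five bands and
    compute the 17 parameters per epoch; filter outlier epochs; run the
    classification grid and OOB importance; run the ANCOVA age check.
    Writes every stage output under ``out_dir`` when given.
    """
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "timestamp": datetime.datetime.now().isoformat(),
        "counts": {},
    }
    counts = manifest["counts"]
    stage = "simulate"
    try:
        design = config.sim.study_design()
        specs = config.sim.dynamics_specs()
        study = synthesize_study(design, specs, config.seed)
        counts["recordings"] = study.n_recordings
        bands = config.band_specs()
        out = Path(out_dir) if out_dir is not None else None
        if out is not None:
            out.mkdir(parents=True, exist_ok=True)

        stage = "preprocess"
        all_epochs = []
        for rec in study.iter_recordings():
            if config.write_edf and out is not None:
                raw_dir = out / "raw"
                raw_dir.mkdir(exist_ok=True)
                write_edf(rec, raw_dir / f"{rec.subject}_{rec.condition}.edf")
            filtered = bandpass_fir(rec, bands["all"], config.transition_hz)
            dec = downsample(filtered, config.target_fs)
            for ep in epoch_continuous(dec, design.trials_per_condition,
                                       design.trial_s, design.gap_s):
                all_epochs.append(
                    ep.copy_with(data=ep.data.astype(np.float32)))
        expected_all = (design.n_subjects * len(design.conditions)
                        * design.trials_per_condition)
        counts["all_band_epochs"] = len(all_epochs)
        if len(all_epochs) != expected_all:
            raise RuntimeError(
                f"all-band epoch count {len(all_epochs)} != {expected_all}")
        logger.info("preprocess: %d all-band epochs", len(all_epochs))

        stage = "fit_microstates"
        maps = extract_peak_maps(all_epochs, config.peak_cap_per_subject,
                                 seed=config.seed + 1)
        counts["pooled_peak_maps"] = int(maps.shape[0])
        model = modified_kmeans(maps, k=config.k,
                                n_restarts=config.n_restarts,
                                seed=config.seed + 2)
        if config.k == 4:
            model = assign_canonical_labels(model, study.templates)
        model = replace(model, ch_names=study.layout.names)
        counts["training_gev"] = model.training_gev
        logger.info("microstates: training GEV %.3f", model.training_gev)

        stage = "features"
        rows = []
        n_sub = 0
        chunk = 90
        for i0 in range(0, len(all_epochs), chunk):
            batch = all_epochs[i0:i0 + chunk]
            rows.extend(epoch_features(ep, model) for ep in batch)
            sub = split_bands(batch, bands=bands,
                              transition_hz=config.transition_hz)
            n_sub += len(sub)
            rows.extend(epoch_features(ep, model) for ep in sub)
        features = pd.DataFrame(rows)
        features = features.merge(study.subjects[["subject", "age"]],
                                  on="subject", how="left")
        counts["sub_band_epochs"] = n_sub
        counts["feature_epochs"] = len(features)
        counts["features_per_epoch"] = int(
            features.columns.str.startswith(
                ("coverage_", "duration_", "occurrence_", "gev_")).sum())
        if n_sub != len(SUB_BANDS) * len(all_epochs):
            raise RuntimeError("sub-band epoch count mismatch")
        if len(features) != (1 + len(SUB_BANDS)) * len(all_epochs):
            raise RuntimeError("feature epoch count mismatch")

        stage = "filter_outliers"
        kept, flog = filter_outliers(features, config.max_duration_ms)
        counts["outlier_filter"] = flog

        stage = "classify"
        results = run_grid(kept, cv_mode=config.cv_mode,
                           n_trees=config.n_trees, seed=config.seed)
        band_i, cond_i = config.importance_cell
        cell = kept[(kept.band == band_i) & (kept.condition == cond_i)]
        cell = cell.reset_index(drop=True)
        importance = oob_importance(cell, n_trees=config.n_trees,
                                    seed=config.seed)
        importance_imp = impurity_importance(cell, n_trees=config.n_trees,
                                             seed=config.seed)

        stage = "ancova"
        band_a, cond_a = config.ancova_cell
        acell = kept[(kept.band == band_a) & (kept.condition == cond_a)]
        sub_table = average_trials(acell.reset_index(drop=True))
        ancova = ancova_table(sub_table)
    except Exception as exc:  # noqa: BLE001 - rewrap with stage context
        raise PipelineError(stage, manifest, exc) from exc

    result = RunResult(manifest=manifest, features=features,
                       results=results, importance=importance,
                       importance_impurity=importance_imp, ancova=ancova,
                       model=model, study=study)
    if out is not None:
        _write_outputs(result, config, out)
    return result


def _write_outputs(result: RunResult, config: PipelineConfig,
                   out: Path) -> None:
    h = result.manifest["config_hash"]
    for name, df in (("features", result.features),
                     ("results", result.results),
                     ("importance", result.importance),
                     ("importance_impurity", result.importance_impurity),
                     ("ancova", result.ancova)):
        tagged = df.copy()
        tagged["config_hash"] = h
        tagged.to_csv(out / f"{name}.csv", index=False)
    design = result.study.design_table
    design["config_hash"] = h
    design.to_csv(out / "design.csv", index=False)
    result.model.to_json(out / "model.json")
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1))
    config.to_yaml(out / "config.yaml")
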