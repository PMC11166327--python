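"""End-to-end orchestration: simulate -> select -> fit -> metrics -> stats.

Each stage reads and writes documented plain-text contracts (see
:mod:`dnadapt.io`) so stages can be re-run in isolation; ``run_pipeline``
chains them, records the configuration and seeds in a run log, and is
deterministic for a fixed configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .trial_design import CATEGORIES, temporal_conditions
from .dn_model import dn_forward_batch
from .model_fitting import (ConditionResponseSet, FitConfig, fit_electrode,
                            DEFAULT_BOUNDS, DEFAULT_STARTS)
from .summary_metrics import (compute_recovery_curve, fwhm, overall_adaptation,
                              time_to_peak)
from .resampling_stats import bonferroni_alpha, bootstrap_metric, sign_test
from .selection import classify_selectivity, responsiveness
from .synthetic import AREAS, generate_cohort
from . import io as dio

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Flat, unit-suffixed configuration for the synthetic pipeline."""

    fs_hz: float = 256.0
    epoch_start_s: float = -0.1
    epoch_end_s: float = 1.5
    baseline_start_s: float = -0.1
    baseline_end_s: float = 0.0
    band_lo_hz: float = 50.0
    band_hi_hz: float = 200.0
    band_width_hz: float = 10.0
    zscore_threshold: float = 0.2
    dprime_threshold: float = 0.5
    model: str = "csdn"
    n_folds: int = 12
    n_starts: int = 3
    n_boot: int = 1000
    n_electrodes_per_area: int = 2
    noise_sd: float = 0.05
    n_trials_per_condition: int = 8
    seed: int = 0
    out_dir: str = "dnadapt_out"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _log(fh, msg: str) -> None:
    fh.write(msg + "\n")
    fh.flush()


def stage_simulate(cfg: PipelineConfig, out: Path):
    cohort = generate_cohort(cfg.n_electrodes_per_area, seed=cfg.seed,
                             fs=cfg.fs_hz, noise_sd=cfg.noise_sd,
                             n_trials=cfg.n_trials_per_condition,
                             epoch_s=(cfg.epoch_start_s, cfg.epoch_end_s))
    resp_dir = out / "responses"
    resp_dir.mkdir(parents=True, exist_ok=True)
    gts = []
    for gt, data in cohort:
        dio.write_responses(data, resp_dir / f"{gt.electrode_id}.tsv")
        gts.append(gt.to_dict())
    (out / "ground_truth.json").write_text(json.dumps(gts, indent=2))
    return cohort


def _avg_duration_response(data: ConditionResponseSet, category=None):
    keys = [(k, lv, c) for (k, lv, c) in data.responses
            if k == "duration" and (category is None or c == category)]
    return np.mean([data.responses[k] for k in keys], axis=0)


def stage_select(cfg: PipelineConfig, cohort, out: Path) -> pd.DataFrame:
    rows = []
    for gt, data in cohort:
        onset_idx = round(data.onset_s * data.fs)
        avg = _avg_duration_response(data)
        resp = responsiveness(avg, data.fs, onset_idx,
                              z_threshold=cfg.zscore_threshold,
                              electrode_id=gt.electrode_id)
        per_cat = {c: _avg_duration_response(data, c) for c in CATEGORIES}
        sel = classify_selectivity(per_cat, data.fs, onset_idx)
        rows.append({
            "electrode_id": gt.electrode_id, "area": gt.area,
            "zscore": resp.zscore, "onset_s": resp.onset_latency_s,
            "included": resp.included, "dprime_max": max(sel.dprime.values()),
            "preferred": sel.preferred,
            "selective_05": sel.selective_at[0.5],
            "selective_075": sel.selective_at[0.75],
            "selective_1": sel.selective_at[1.0],
        })
    df = pd.DataFrame(rows)
    df.to_csv(out / "selection.tsv", sep="\t", index=False)
    return df


def stage_fit(cfg: PipelineConfig, cohort, out: Path) -> dict:
    fit_dir = out / "fits"
    fit_dir.mkdir(parents=True, exist_ok=True)
    fit_cfg = FitConfig(model=cfg.model, n_folds=cfg.n_folds,
                        n_starts=cfg.n_starts, seed=cfg.seed,
                        bounds=dict(DEFAULT_BOUNDS),
                        starts=dict(DEFAULT_STARTS))
    fits = {}
    for gt, data in cohort:
        fit = fit_electrode(data, fit_cfg)
        fit.save(fit_dir / f"{gt.electrode_id}.json")
        fits[gt.electrode_id] = fit
    return fits


def stage_metrics(cfg: PipelineConfig, cohort, fits, out: Path
                  ) -> pd.DataFrame:
    rows = []
    rec_dir = out / "recovery"
    rec_dir.mkdir(parents=True, exist_ok=True)
    for gt, data in cohort:
        onset_idx = round(data.onset_s * data.fs)
        avg533 = np.mean([data.responses[("duration", 5, c)]
                          for c in CATEGORIES], axis=0)
        ttp = time_to_peak(avg533, data.fs, onset_idx)
        width = fwhm(avg533[onset_idx:], data.fs)
        rep = {lv: np.mean([data.responses[("repetition", lv, c)]
                            for c in CATEGORIES], axis=0)
               for lv in range(6)}
        dur134 = np.mean([data.responses[("duration", 3, c)]
                          for c in CATEGORIES], axis=0)
        curve = compute_recovery_curve(rep, dur134, data.fs, onset_idx)
        (rec_dir / f"{gt.electrode_id}.json").write_text(
            json.dumps(curve.to_dict(), indent=2))
        base = {"electrode_id": gt.electrode_id, "area": gt.area}
        rows += [
            {**base, "metric": "time_to_peak", "condition": "dur533",
             "value": ttp, "units": "s"},
            {**base, "metric": "fwhm", "condition": "dur533",
             "value": width, "units": "s"},
            {**base, "metric": "overall_adaptation", "condition": "all_isi",
             "value": overall_adaptation(curve), "units": "ratio"},
            {**base, "metric": "long_term_recovery_c", "condition": "fit",
             "value": curve.c, "units": "ratio"},
            {**base, "metric": "r2_cv", "condition": "all",
             "value": fits[gt.electrode_id].r2_cv, "units": "R2"},
        ]
    df = pd.DataFrame(rows)
    df.to_csv(out / "metrics.tsv", sep="\t", index=False)
    return df


def stage_stats(cfg: PipelineConfig, cohort, out: Path) -> dict:
    """Bootstrap time-to-peak per area and sign-test area contrasts."""
    by_area = {a: [] for a in AREAS}
    fs = cohort[0][1].fs
    onset_idx = round(cohort[0][1].onset_s * fs)
    for gt, data in cohort:
        avg533 = np.mean([data.responses[("duration", 5, c)]
                          for c in CATEGORIES], axis=0)
        by_area[gt.area].append(avg533)

    metric = lambda tc: time_to_peak(tc, fs, onset_idx)
    boots = {a: bootstrap_metric(tcs, metric, n=cfg.n_boot, seed=cfg.seed)
             for a, tcs in by_area.items() if tcs}
    pairs = [(a, b) for i, a in enumerate(AREAS) for b in AREAS[i + 1:]
             if a in boots and b in boots]
    alpha = bonferroni_alpha(0.025, max(len(pairs), 1))
    tests = []
    for a, b in pairs:
        res = sign_test(boots[a].samples, boots[b].samples, alpha=alpha)
        tests.append({"metric": "time_to_peak", "group_a": a, "group_b": b,
                      **res.to_dict()})
    result = {"bootstrap": {a: d.to_dict() for a, d in boots.items()},
              "sign_tests": tests}
    (out / "stats.json").write_text(json.dumps(result, indent=2))
    return result


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages; returns a bundle of stage outputs and paths."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    t0 = time.time()
    with (out / "run.log").open("w") as log:
        _log(log, f"config sha256[:12]={cfg.digest()} seed={cfg.seed}")
        stage = "simulate"
        try:
            cohort = stage_simulate(cfg, out)
            _log(log, f"simulate: {len(cohort)} electrodes "
                      f"({time.time() - t0:.1f}s)")
            stage = "select"
            selection = stage_select(cfg, cohort, out)
            _log(log, f"select: {int(selection['included'].sum())}/"
                      f"{len(selection)} electrodes included")
            stage = "fit"
            fits = stage_fit(cfg, cohort, out)
            _log(log, f"fit: {len(fits)} electrodes "
                      f"({time.time() - t0:.1f}s)")
            stage = "metrics"
            metrics = stage_metrics(cfg, cohort, fits, out)
            stage = "stats"
            stats = stage_stats(cfg, cohort, out)
            _log(log, f"done in {time.time() - t0:.1f}s")
        except Exception as exc:
            _log(log, f"FAILED at stage {stage}: {exc}")
            raise RuntimeError(f"pipeline failed at stage {stage!r}") from exc
    return {"out_dir": out, "cohort": cohort, "selection": selection,
            "fits": fits, "metrics": metrics, "stats": stats}
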