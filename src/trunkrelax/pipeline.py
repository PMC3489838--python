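"""End-to-end pipeline: simulate -> preprocess -> loop/NZ/energies -> fit ->
sensitivity/trends, with validated configuration and deterministic outputs.

Every stage is a thin call into the library modules; the pipeline adds
cohort bookkeeping (per-subject FR angles, per-trial seeds), skip handling
for unusable trials (no plateau, hold too short, hold angle inside the
neutral zone — the in vivo analogue of discarded exposures), and CSV/JSON
serialization with fixed float formatting so a config + seed pair always
produces byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .fitting import MODEL_KINDS, FitOptions, FitResult, fit_relaxation
from .hysteresis import build_loop, energies, neutral_zone, nz_change
from .io import write_trial
from .models import (ModelParams, params_from_dict, params_to_dict)
from .preprocess import (UnusableTrialError, extract_relaxation_segment,
                         resample_align, segment_phases, summarize_relaxation)
from .sensitivity import (fit_angle_trend, get_param, param_ids,
                          sensitivity_table, set_param)
from .synthetic import (DEFAULT_FRACTIONS, FR_ANGLE_MEAN_DEG, FR_ANGLE_SD_DEG,
                        GroundTruthSpec, ProtocolSpec, TrialRecording,
                        default_truth, draw_fr_angles, generate_trial)

__all__ = [
    "PipelineConfig", "ProtocolConfig", "TruthConfig", "CohortConfig",
    "FittingConfig", "PipelineResult", "run_pipeline", "load_config",
    "RESULTS_SCHEMA",
]

RESULTS_SCHEMA = "trunkrelax results schema v1"
_FLOAT_FMT = "%.10g"

_model_cfg = ConfigDict(extra="forbid")


class ProtocolConfig(BaseModel):
    model_config = _model_cfg
    ramp_rate: float = 3.0  # deg/s
    hold_duration: float = 960.0  # s
    angle_rate_hz: float = 100.0
    force_rate_hz: float = 1000.0
    moment_arm: float = 0.40  # m


class TruthConfig(BaseModel):
    model_config = _model_cfg
    params: Optional[dict] = None  # models.params_to_dict form; default Prony
    nz_width: float = 10.0  # deg
    nz_slope_fraction: float = 0.02
    stiffness_angle_gain: float = 0.02  # 1/deg
    force_noise_sd: float = 0.5  # N
    angle_noise_sd: float = 0.1  # deg

    def to_spec(self) -> GroundTruthSpec:
        kwargs = self.model_dump()
        raw = kwargs.pop("params")
        if raw is not None:
            kwargs["params"] = params_from_dict(raw)
            return GroundTruthSpec(**kwargs)
        return default_truth(**kwargs)


class CohortConfig(BaseModel):
    model_config = _model_cfg
    n_subjects: int = 10
    fractions: List[float] = Field(default_factory=lambda: list(DEFAULT_FRACTIONS))
    fr_mean: float = FR_ANGLE_MEAN_DEG  # deg
    fr_sd: float = FR_ANGLE_SD_DEG  # deg


class FittingConfig(BaseModel):
    model_config = _model_cfg
    models: List[str] = Field(default_factory=lambda: list(MODEL_KINDS))
    n_starts: int = 8
    prony_n: int = 2
    fit_rate_hz: float = 1.0  # hold segment decimated to this rate for fits
    fix_k_eq: bool = False


class PipelineConfig(BaseModel):
    model_config = _model_cfg
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    truth: TruthConfig = Field(default_factory=TruthConfig)
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    fitting: FittingConfig = Field(default_factory=FittingConfig)
    seed: int = 0
    input_trials: Optional[str] = None  # directory of trial CSVs; else simulate
    write_trials: bool = False
    log_level: str = "INFO"


def load_config(path: Path) -> PipelineConfig:
    return PipelineConfig.model_validate_json(Path(path).read_text())


@dataclass
class PipelineResult:
    outcomes: pd.DataFrame  # one row per usable trial
    fits: pd.DataFrame  # one row per trial x model
    comparison: pd.DataFrame  # model x %FR mean fit quality
    sensitivity: pd.DataFrame  # Eq.-5-style table per model parameter
    trends: dict  # outcome -> family -> TrendFit summary
    skipped: List[dict]
    seed: int


# -- helpers -----------------------------------------------------------------


def _mean_params(kind: str, params_list: Sequence[ModelParams]) -> ModelParams:
    """Parameter-wise mean across trials, used as the nominal set."""
    template = params_list[0]
    out = template
    for pid in param_ids(template):
        mean = float(np.mean([get_param(p, pid) for p in params_list]))
        out = set_param(out, pid, mean)
    return out


def _param_ranges(params_list: Sequence[ModelParams]) -> Dict[str, Tuple[float, float]]:
    template = params_list[0]
    ranges = {}
    for pid in param_ids(template):
        vals = [get_param(p, pid) for p in params_list]
        lo, hi = float(min(vals)), float(max(vals))
        if hi > lo:
            ranges[pid] = (lo, hi)
    return ranges


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# {RESULTS_SCHEMA}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def _analyze_trial(trial: TrialRecording, fit_cfg: FittingConfig,
                   fit_seed: int) -> Tuple[dict, List[dict]]:
    """All per-trial measures; raises UnusableTrialError for bad trials."""
    aligned = resample_align(trial)
    seg = segment_phases(aligned)
    summary = summarize_relaxation(aligned, seg)
    loop = build_loop(aligned, seg)
    nz_pre = neutral_zone(loop.loading_angle, loop.loading_moment)
    nz_post = neutral_zone(loop.unloading_angle, loop.unloading_moment)
    fr = aligned.fr_angle
    nz = nz_change(nz_pre, nz_post, fr) if math.isfinite(fr) else None
    en = energies(loop)

    meta = trial.metadata
    row = {
        "subject": meta.get("subject", -1),
        "fraction_fr": meta.get("target_fraction_fr", math.nan),
        "fr_angle_deg": fr,
        "theta0_deg": meta.get("theta0_deg", math.nan),
        "initial_moment_Nm": summary.initial_moment,
        "final_moment_Nm": summary.final_moment,
        "moment_drop_Nm": summary.moment_drop,
        "moment_drop_pct": summary.moment_drop_pct,
        "t90_s": summary.t90,
        "nz_pre_deg": nz_pre,
        "nz_post_deg": nz_post,
        "nz_pre_norm_pct": nz.nz_pre_normalized if nz else math.nan,
        "nz_post_norm_pct": nz.nz_post_normalized if nz else math.nan,
        "nz_pct_change": nz.pct_change if nz else math.nan,
        "E1_Nm_deg": en.e1,
        "E2_Nm_deg": en.e2,
        "dE_Nm_deg": en.de,
        "RE": en.re,
    }

    segment = extract_relaxation_segment(aligned, seg,
                                         decimate_hz=fit_cfg.fit_rate_hz)
    options = FitOptions(n_starts=fit_cfg.n_starts, seed=fit_seed,
                         prony_n=fit_cfg.prony_n, fix_k_eq=fit_cfg.fix_k_eq)
    fit_rows = []
    for kind in fit_cfg.models:
        fr_res = fit_relaxation(segment, kind, options)
        fit_rows.append({
            "subject": row["subject"], "fraction_fr": row["fraction_fr"],
            "model": kind, "r2": fr_res.r2, "rmse_Nm": fr_res.rmse,
            "converged": fr_res.converged,
            "theta0_deg": segment.theta0,
            "params_json": json.dumps(params_to_dict(fr_res.params),
                                      sort_keys=True),
        })
    return row, fit_rows


# -- pipeline ----------------------------------------------------------------


def run_pipeline(config: PipelineConfig, out_dir: Optional[Path] = None,
                 seed: Optional[int] = None,
                 stage: str = "report") -> PipelineResult:
    """Run the pipeline up to ``stage`` (one of ``simulate``, ``analyze``,
    ``fit``, ``sensitivity``, ``report``) and write that stage's artifacts
    under ``out_dir`` (if given)."""
    stages = ("simulate", "analyze", "fit", "sensitivity", "report")
    if stage not in stages:
        raise ValueError(f"stage must be one of {stages}")
    level = stages.index(stage)
    if seed is None:
        seed = config.seed
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

    truth = config.truth.to_spec()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    trials: List[TrialRecording] = []
    skipped: List[dict] = []
    if config.input_trials is not None:
        from .io import list_trials, read_trial
        trial_dir = Path(config.input_trials)
        names = list_trials(trial_dir)
        fit_seeds = rng.integers(0, 2**31 - 1, size=max(len(names), 1))
        for i, name in enumerate(names):
            trial = read_trial(trial_dir, name)
            trial.metadata.setdefault("subject", i)
            trial.metadata.setdefault("fit_seed", int(fit_seeds[i]))
            trials.append(trial)
    else:
        fr_angles = draw_fr_angles(config.cohort.n_subjects, rng,
                                   config.cohort.fr_mean, config.cohort.fr_sd)
        n_cells = config.cohort.n_subjects * len(config.cohort.fractions)
        trial_seeds = rng.integers(0, 2**31 - 1, size=n_cells)
        fit_seeds = rng.integers(0, 2**31 - 1, size=n_cells)
        i = 0
        for subject, fr in enumerate(fr_angles):
            for frac in config.cohort.fractions:
                protocol = ProtocolSpec(target_fraction_fr=float(frac),
                                        fr_angle=float(fr),
                                        **config.protocol.model_dump())
                try:
                    trial = generate_trial(protocol, truth,
                                           seed=int(trial_seeds[i]))
                except ValueError as exc:
                    skipped.append({"subject": subject,
                                    "fraction_fr": float(frac),
                                    "stage": "simulate", "reason": str(exc)})
                    i += 1
                    continue
                trial.metadata["subject"] = subject
                trial.metadata["fit_seed"] = int(fit_seeds[i])
                trials.append(trial)
                i += 1

    if out_dir is not None and (config.write_trials or stage == "simulate"):
        for trial in trials:
            name = (f"s{trial.metadata['subject']:02d}_"
                    f"f{int(round(trial.metadata['target_fraction_fr'] * 100)):03d}")
            write_trial(trial, out_dir / "trials", name)

    outcome_rows: List[dict] = []
    fit_rows: List[dict] = []
    if level >= 1:
        analysis_cfg = config.fitting if level >= 2 else \
            config.fitting.model_copy(update={"models": []})
        for trial in trials:
            try:
                row, frs = _analyze_trial(trial, analysis_cfg,
                                          trial.metadata["fit_seed"])
            except (UnusableTrialError, ValueError) as exc:
                skipped.append({"subject": trial.metadata.get("subject", -1),
                                "fraction_fr": trial.metadata.get(
                                    "target_fraction_fr", math.nan),
                                "stage": "analyze", "reason": str(exc)})
                continue
            outcome_rows.append(row)
            fit_rows.extend(frs)

    outcomes = pd.DataFrame(outcome_rows)
    fits = pd.DataFrame(fit_rows)

    comparison = pd.DataFrame()
    if level >= 2 and not fits.empty:
        comparison = (fits.groupby(["model", "fraction_fr"], as_index=False)
                      .agg(n_trials=("r2", "size"), mean_r2=("r2", "mean"),
                           mean_rmse_Nm=("rmse_Nm", "mean"))
                      .sort_values(["model", "fraction_fr"])
                      .reset_index(drop=True))

    sens = pd.DataFrame()
    trends: dict = {}
    if level >= 3 and not fits.empty:
        horizon = config.protocol.hold_duration
        theta0 = float(outcomes["theta0_deg"].mean())
        sens_frames = []
        for kind in config.fitting.models:
            plist = [params_from_dict(json.loads(s))
                     for s in fits.loc[fits["model"] == kind, "params_json"]]
            if len(plist) < 2:
                continue
            nominal = _mean_params(kind, plist)
            ranges = _param_ranges(plist)
            if ranges:
                sens_frames.append(sensitivity_table(nominal, ranges,
                                                     theta0, horizon))
        if sens_frames:
            sens = pd.concat(sens_frames, ignore_index=True)

        means = (outcomes.groupby("fraction_fr")
                 [["initial_moment_Nm", "moment_drop_Nm", "nz_pct_change"]]
                 .mean())
        x = 100.0 * means.index.to_numpy()
        for col, label in (("initial_moment_Nm", "initial_moment"),
                           ("moment_drop_Nm", "moment_drop"),
                           ("nz_pct_change", "nz_pct_change")):
            y = means[col].to_numpy()
            if len(x) < 2 or not np.all(np.isfinite(y)):
                continue
            entry = {}
            for family in ("linear", "exponential_through_origin"):
                tf = fit_angle_trend(x, y, family, include_origin=True)
                entry[family] = {"coefficients": tf.coefficients, "r2": tf.r2,
                                 "degenerate": tf.degenerate}
            trends[label] = entry

    if out_dir is not None:
        if level >= 1:
            _write_csv(outcomes, out_dir / "results.csv")
        if level >= 2:
            _write_csv(fits, out_dir / "fits.csv")
            _write_csv(comparison, out_dir / "model_comparison.csv")
        if level >= 3:
            _write_csv(sens, out_dir / "sensitivity.csv")
            (out_dir / "trends.json").write_text(
                json.dumps(trends, indent=2, sort_keys=True))
        config_json = config.model_dump_json()
        log = {
            "package_version": __version__,
            "seed": int(seed),
            "stage": stage,
            "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
            "n_trials_generated": len(trials),
            "n_trials_analyzed": len(outcome_rows),
            "n_skipped": len(skipped),
            "skipped": skipped,
        }
        (out_dir / "run_log.json").write_text(json.dumps(log, indent=2,
                                                         sort_keys=True))

    return PipelineResult(outcomes=outcomes, fits=fits, comparison=comparison,
                          sensitivity=sens, trends=trends, skipped=skipped,
                          seed=int(seed))
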