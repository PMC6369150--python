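"""End-to-end orchestration: simulate → stage → extract → spectra → analyze.

:func:`run_all` executes the whole study on a :class:`~adsleep.config.RunConfig`:

1. **simulate** — render the synthetic longitudinal study and assemble one
   "night" recording per time point (epochs concatenated, clock start
   23:00) plus the ground-truth log;
2. **stage** — score every 30-s window of each night with the rule-based
   classifier, emitting the annotation stream;
3. **extract** — pull the scored epochs per state within the nighttime
   window (alpha-delta epochs count as SWS, matching the scoring scheme),
   and reject gross-artifact epochs;
4. **spectra** — Hjorth-Laplacian montage, multitaper PSD per state,
   power-law normalization with state-specific fit ranges;
5. **features** — spindle band power and dominant spindle frequency from
   stage-2 spectra; delta and alpha band power from SWS spectra;
6. **analyze** — long-format study table, condition × hemisphere ANOVAs,
   within-active ANOVA and Tukey post-hocs.

All randomness derives from the study's ``master_seed``; re-running with
the same configuration reproduces every numeric output byte-for-byte.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .config import RunConfig
from .recording import Epoch, Recording
from .spectral import (
    find_spindle_peak,
    fit_power_law,
    integrate_band,
    multitaper_psd,
    normalize_spectrum,
)
from .staging import stage_recording
from .stats import build_study_table, run_paper_analysis
from .synthetic import StudyData, generate_study

__all__ = ["run_all", "night_recording", "extract_state_epochs", "state_features", "compute_features"]

#: annotation tags counted as slow wave sleep when extracting SWS epochs
SWS_TAGS = ("sws", "alpha_delta")


def night_recording(study: StudyData, time_point: str) -> Recording:
    """Concatenate a time point's epochs into one annotated recording.

    Epochs are interleaved across states in epoch-index order; the
    ground-truth state of each 30-s slot is carried as an annotation.
    The clock starts at 23:00, inside the nighttime scoring window.
    """
    eps = study.select(time_point=time_point)
    eps = sorted(eps, key=lambda e: (e.epoch_index, study.config.states.index(e.state_slot)))
    if not eps:
        raise ValueError(f"no epochs for time point {time_point!r}")
    fs = eps[0].recording.fs_hz
    samples = np.concatenate([e.recording.samples for e in eps], axis=1)
    annotations = []
    onset = 0.0
    for e in eps:
        dur = e.recording.duration_s
        annotations.append(rio.Annotation(onset, dur, f"truth:{e.truth.state}"))
        onset += dur
    return Recording(
        samples=samples,
        fs_hz=fs,
        labels=list(eps[0].recording.labels),
        start_time=_dt.datetime(2021, 1, 1, 23, 0, 0),
        annotations=annotations,
    )


def extract_state_epochs(
    rec: Recording,
    state: str,
    n: int | None,
    amp_limit_uv: float = 500.0,
    flat_limit_uv: float = 0.5,
) -> list[Epoch]:
    """Scored-epoch extraction for one state, with SWS-subtype merging.

    ``state="sws"`` collects epochs tagged either ``sws`` or
    ``alpha_delta`` (the latter is scored under the SWS category).
    Artifact rejection runs before the count cut so that ``n`` clean
    epochs are returned when available.
    """
    tags = SWS_TAGS if state == "sws" else (state,)
    epochs: list[Epoch] = []
    for tag in tags:
        try:
            epochs += rio.extract_epochs(rec, tag, n=None)
        except ValueError:
            continue
    if not epochs:
        raise ValueError(f"no epochs scored {state!r}")
    epochs.sort(key=lambda e: e.onset_s)
    kept, _ = rio.reject_artifacts(epochs, amp_limit_uv, flat_limit_uv)
    return kept[:n] if n is not None else kept


def state_features(epochs: list[Epoch], state: str, cfg: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Normalized-spectrum features for one state at one time point.

    Returns a tidy frame (channel, variable, value) — spindle power and
    dominant spindle frequency for stage 2; delta and alpha band power
    for SWS — plus a tidy per-channel residual spectrum for inspection.
    Channels without a spindle peak contribute no spindle_freq row.
    """
    sp = cfg.spectral
    est = multitaper_psd(epochs, nw=sp.nw, k=sp.k)
    fit = fit_power_law(est, sp.fit_ranges[state])
    ns = normalize_spectrum(est, fit)
    rows = []
    if state == "stage2":
        power = integrate_band(ns, sp.bands["spindle"], method=sp.band_method)
        peaks = find_spindle_peak(
            ns,
            search_hz=sp.peak_search_hz,
            fit_halfwidth_hz=sp.peak_fit_halfwidth_hz,
            prominence_frac=sp.peak_prominence_frac,
            rel_background_floor=sp.peak_rel_background_floor,
        )
        for ch, val in zip(power.labels, power.values):
            rows.append(dict(channel=ch, variable="spindle_power", value=float(val)))
        for pk in peaks:
            if pk.present:
                rows.append(dict(channel=pk.channel, variable="spindle_freq", value=pk.freq_hz))
    elif state == "sws":
        for band_name, variable in (("delta", "delta_power"), ("alpha", "alpha_power")):
            power = integrate_band(ns, sp.bands[band_name], method=sp.band_method)
            for ch, val in zip(power.labels, power.values):
                rows.append(dict(channel=ch, variable=variable, value=float(val)))
    else:
        raise ValueError(f"no features defined for state {state!r}")
    residual = pd.DataFrame(
        {
            "channel": np.repeat(ns.labels, len(ns.freqs_hz)),
            "freq_hz": np.tile(ns.freqs_hz, len(ns.labels)),
            "value": ns.residual.ravel(),
        }
    )
    return pd.DataFrame(rows), {"residual": residual, "estimate": est, "normalized": ns}


def compute_features(study: StudyData, cfg: RunConfig, staged: dict[str, Recording]) -> pd.DataFrame:
    """Feature table over all time points from staged night recordings."""
    frames = []
    for tp in study.config.time_points:
        rec = staged[tp]
        for state in ("stage2", "sws"):
            epochs = extract_state_epochs(
                rec, state, cfg.study.n_epochs_per_state,
                cfg.artifact_amp_limit_uv, cfg.artifact_flat_limit_uv,
            )
            feats, _ = state_features(epochs, state, cfg)
            feats.insert(0, "time_point", tp)
            frames.append(feats)
    return pd.concat(frames, ignore_index=True)


def _staging_accuracy(truth_tags: list[str], scored_tags: list[str]) -> dict:
    classes = sorted(set(truth_tags))
    recall = {}
    for c in classes:
        idx = [i for i, t in enumerate(truth_tags) if t == c]
        hits = sum(1 for i in idx if scored_tags[i] == c)
        recall[c] = hits / len(idx) if idx else float("nan")
    overall = sum(1 for a, b in zip(truth_tags, scored_tags) if a == b) / len(truth_tags)
    return {"overall": overall, "recall": recall, "n_epochs": len(truth_tags)}


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_all(cfg: RunConfig, outdir: str | Path, resume: bool = False) -> dict:
    """Execute the full pipeline into ``outdir``; returns the report dict.

    With ``resume=True`` an existing run with an identical configuration
    hash is returned as-is instead of being recomputed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = _config_hash(cfg)
    manifest_path = outdir / "manifest.json"
    report_path = outdir / "report.json"
    if resume and manifest_path.exists() and report_path.exists():
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("config_hash") == chash:
            return json.loads(report_path.read_text())

    stages: list[str] = []

    # 1. simulate ---------------------------------------------------------
    study = generate_study(cfg.study)
    study.truth_table().to_csv(outdir / "ground_truth.csv", index=False)
    nights: dict[str, Recording] = {}
    for tp in cfg.study.time_points:
        night = night_recording(study, tp)
        nights[tp] = night
        rio.write_recording(night, outdir / f"{tp}.csv.gz")
        if cfg.write_edf:
            rio.write_recording(night, outdir / f"{tp}.edf")
    stages.append("simulate")

    # 2. stage ------------------------------------------------------------
    staging_acc: dict[str, dict] = {}
    for tp, night in nights.items():
        annotations = stage_recording(night, thresholds=cfg.staging)
        truth_tags = [a.tag.removeprefix("truth:") for a in night.annotations]
        scored_tags = [a.tag for a in annotations]
        staging_acc[tp] = _staging_accuracy(truth_tags, scored_tags)
        rio.write_annotations(annotations, outdir / f"{tp}_annotations.csv")
        night.annotations = list(annotations)  # downstream uses scored labels
    stages.append("stage")

    # 3-5. extract, spectra, features ------------------------------------
    for tp, night in nights.items():
        if cfg.montage == "laplacian":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                nights[tp] = rio.hjorth_laplacian(night)
    stages.append("extract")
    features = compute_features(study, cfg, nights)
    features.to_csv(outdir / "features.csv", index=False)
    stages += ["spectra", "features"]

    # 6. analyze ----------------------------------------------------------
    table = build_study_table(features, cfg.study.condition_map)
    table.to_csv(outdir / "study_table.csv", index=False)
    report = run_paper_analysis(
        table,
        alpha=cfg.stats.alpha,
        ss_type=cfg.stats.ss_type,
        min_channel_frac=cfg.stats.min_channel_frac,
    )
    report["staging"] = staging_acc
    report["master_seed"] = cfg.study.master_seed
    report_path.write_text(json.dumps(report, sort_keys=True, indent=1))
    stages.append("analyze")

    manifest = {
        "config_hash": chash,
        "master_seed": cfg.study.master_seed,
        "stages": stages,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
        "versions": _versions(),
    }
    manifest_path.write_text(json.dumps(manifest, sort_keys=True, indent=1))
    return report


def _versions() -> dict:
    import scipy
    import statsmodels

    from . import __version__

    return {
        "adsleep": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "statsmodels": statsmodels.__version__,
    }
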