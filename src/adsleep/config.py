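"""Run configuration: one place where every tunable default lives.

The YAML-serializable :class:`RunConfig` gathers the synthetic-study
layout, spectral-estimation parameters (taper settings, state-specific
power-law fit ranges, bands of interest), staging thresholds, montage and
artifact options, and statistics options.  Every default that the
original scoring/estimation convention leaves open is set here, so each
such choice is greppable and overridable in one file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .staging import StagingThresholds
from .synthetic import StudyConfig, default_study_config

__all__ = ["SpectralConfig", "StatsConfig", "RunConfig"]

#: Power-law fit ranges per state (Hz): peak-free regions flanking the
#: bands of interest — 5-6 & 17-18 Hz for stage 2, 4-6 & 23-24 Hz for SWS.
DEFAULT_FIT_RANGES = {
    "stage2": ((5.0, 6.0), (17.0, 18.0)),
    "sws": ((4.0, 6.0), (23.0, 24.0)),
}

#: Bands of interest (Hz): spindle 9-16, delta 0.5-4, alpha 8-14.
DEFAULT_BANDS = {
    "spindle": (9.0, 16.0),
    "delta": (0.5, 4.0),
    "alpha": (8.0, 14.0),
}


@dataclass
class SpectralConfig:
    nw: float = 3.0
    k: int = 5
    fit_ranges: dict = field(default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_FIT_RANGES.items()})
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    band_method: str = "sum"  # or "trapezoid"
    peak_search_hz: tuple[float, float] = (9.0, 16.0)
    peak_fit_halfwidth_hz: float = 1.0
    peak_prominence_frac: float = 0.05
    peak_rel_background_floor: float = 1.5


@dataclass
class StatsConfig:
    alpha: float = 0.05
    ss_type: int = 2
    min_channel_frac: float = 0.5


@dataclass
class RunConfig:
    """Complete, reproducible description of an end-to-end run."""

    study: StudyConfig = field(default_factory=default_study_config)
    spectral: SpectralConfig = field(default_factory=SpectralConfig)
    staging: StagingThresholds = field(default_factory=StagingThresholds)
    stats: StatsConfig = field(default_factory=StatsConfig)
    montage: str = "laplacian"  # or "identity"
    artifact_amp_limit_uv: float = 500.0
    artifact_flat_limit_uv: float = 0.5
    write_edf: bool = False

    def __post_init__(self) -> None:
        if self.montage not in ("laplacian", "identity"):
            raise ValueError("montage must be 'laplacian' or 'identity'")
        if not 0 < self.stats.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return _plain(dataclasses.asdict(self))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        study = d.pop("study", None)
        spectral = d.pop("spectral", None)
        staging = d.pop("staging", None)
        stats = d.pop("stats", None)
        kw = dict(d)
        if study is not None:
            s = dict(study)
            s["time_points"] = tuple(s.get("time_points", ()))
            s["states"] = tuple(s.get("states", ()))
            s["channels"] = tuple(s.get("channels", ()))
            kw["study"] = StudyConfig(**s)
        if spectral is not None:
            sp = dict(spectral)
            sp["fit_ranges"] = {
                k: tuple(tuple(r) for r in v) for k, v in sp.get("fit_ranges", {}).items()
            }
            sp["bands"] = {k: tuple(v) for k, v in sp.get("bands", {}).items()}
            sp["peak_search_hz"] = tuple(sp.get("peak_search_hz", (9.0, 16.0)))
            kw["spectral"] = SpectralConfig(**sp)
        if staging is not None:
            kw["staging"] = StagingThresholds(**staging)
        if stats is not None:
            kw["stats"] = StatsConfig(**stats)
        return cls(**kw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _plain(obj):
    """Recursively turn tuples into lists so YAML round-trips cleanly."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
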