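"""Pipeline configuration with YAML round-trip.

Defaults follow the analysis protocol: 100 Hz working rate, 0.1-40 Hz
band-pass, TF-peaks in 4-25 Hz, SO band 0.3-1.5 Hz, SO-power quartiles,
18 phase bins over [-pi, pi), 10 PCA components, ICA order 5 for power maps
and 4 falling back to 3 for phase maps, Benjamini-Yekutieli FDR at
alpha = 0.1, Bonferroni-corrected pairwise tests at p <= 0.05, 5-fold
cross-validation and 1000 label-shuffle permutations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config", "derive_seed"]

SCHEMA_VERSION = 1


@dataclass
class SimulateConfig:
    scale_n: float = 1.0             # shrinks the default 39/16/16/17/11 cohort
    duration_s: float = 600.0
    fs: float = 100.0
    channels: list = field(default_factory=lambda: ["C3", "C4"])
    background_slope: float = 1.0
    write_edf: bool = True


@dataclass
class PreprocessConfig:
    target_fs: float = 100.0
    band_low_hz: float = 0.1
    band_high_hz: float = 40.0
    reference: str = "common-average"
    reject: bool = True


@dataclass
class DetectorConfig:
    window_s: float = 1.0
    step_s: float = 0.05
    n_tapers: int = 3
    baseline_percentile: float = 2.0
    threshold_db: float = 0.0
    min_height_db: float = 14.0
    marker_t_radius_s: float = 0.5
    marker_f_radius_hz: float = 1.0
    prominence_min_db: float = 3.0
    volume_min: float = 0.0
    fmin_hz: float = 4.0
    fmax_hz: float = 25.0
    dur_min_s: float = 0.1
    dur_max_s: float = 5.0
    bw_min_hz: float = 0.5
    bw_max_hz: float = 15.0


@dataclass
class HistogramConfig:
    freq_step_hz: float = 1.0
    n_power_bins: int = 4
    n_phase_bins: int = 18
    power_window_s: float = 30.0
    power_step_s: float = 0.1


@dataclass
class DecomposeConfig:
    n_pca: int = 10
    n_ica_power: int = 5
    ica_phase_candidates: list = field(default_factory=lambda: [4, 3])
    ica_seed: int = 0
    pattern_threshold: float = 0.7


@dataclass
class StatsConfig:
    alpha_fdr: float = 0.1
    alpha_pairwise: float = 0.05
    posthoc_gate: bool = True
    control: str = "control"


@dataclass
class EvaluateConfig:
    n_folds: int = 5
    n_perm: int = 1000
    ridge_c: float = 1.0
    n_top_reliability: int = 5
    smoothed_p: bool = True


@dataclass
class PipelineConfig:
    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    histogram: HistogramConfig = field(default_factory=HistogramConfig)
    decompose: DecomposeConfig = field(default_factory=DecomposeConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sections = {"simulate": SimulateConfig, "preprocess": PreprocessConfig,
                    "detector": DetectorConfig, "histogram": HistogramConfig,
                    "decompose": DecomposeConfig, "stats": StatsConfig,
                    "evaluate": EvaluateConfig}
        kw = {}
        for f in fields(cls):
            if f.name not in d:
                continue
            val = d[f.name]
            sub = sections.get(f.name)
            if sub is not None and isinstance(val, dict):
                known = {g.name for g in fields(sub)}
                unknown = set(val) - known
                if unknown:
                    raise ValueError(f"unknown keys in config section "
                                     f"{f.name!r}: {sorted(unknown)}")
                val = sub(**val)
            kw[f.name] = val
        return cls(**kw)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    d = yaml.safe_load(Path(path).read_text()) or {}
    if d.get("schema_version", SCHEMA_VERSION) != SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema {d.get('schema_version')}")
    return PipelineConfig.from_dict(d)


def save_config(cfg: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
    return path


def derive_seed(master: int, *keys) -> int:
    """Stable per-stage seed below 2**31, from the master seed and key path."""
    h = hashlib.sha256(repr((int(master),) + tuple(map(str, keys))).encode())
    return int.from_bytes(h.digest()[:4], "little") % (2 ** 31)
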