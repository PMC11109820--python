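"""Run configuration: one YAML-serializable object reaching every knob."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .aperiodic import AperiodicSettings
from .predict import RandomForestParams
from .simulate import (
    BandPowerEffect,
    CohortConfig,
    ConnectivityEffect,
    EffectSpec,
    ExponentEffect,
    NoiseParams,
    study_effects,
)
from .spectral import ConditioningParams

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run bit-for-bit given the inputs."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    apply_conditioning: bool = False
    conditioning: ConditioningParams = field(default_factory=ConditioningParams)
    welch_window_s: float = 2.0
    welch_overlap: float = 0.5
    aperiodic: AperiodicSettings = field(default_factory=AperiodicSettings)
    edge_trim_s: float = 1.0
    glm_modes: tuple[str, ...] = ("group",)
    n_perm: int = 5000
    run_prediction: bool = True
    forest: RandomForestParams = field(default_factory=RandomForestParams)


def _effects_from_dict(d: dict | str) -> EffectSpec:
    if d == "study":
        return study_effects()
    if d in ("null", None, {}):
        return EffectSpec()
    return EffectSpec(
        band_power=tuple(BandPowerEffect(**e) for e in d.get("band_power", [])),
        exponent=tuple(ExponentEffect(**e) for e in d.get("exponent", [])),
        connectivity=tuple(ConnectivityEffect(**e) for e in d.get("connectivity", [])),
    )


def _tupled(d: dict, keys: tuple[str, ...]) -> dict:
    return {k: tuple(v) if k in keys and isinstance(v, list) else v for k, v in d.items()}


def config_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    cohort_d = dict(d.pop("cohort", {}))
    noise_d = _tupled(dict(cohort_d.pop("noise", {})), ("coupling",))
    effects = _effects_from_dict(cohort_d.pop("effects", {}))
    cohort_d = _tupled(cohort_d, ("duration_range_s",))
    cohort = CohortConfig(noise=NoiseParams(**noise_d), effects=effects, **cohort_d)
    cond = ConditioningParams(
        **_tupled(dict(d.pop("conditioning", {})), ("notch_freqs", "bandpass"))
    )
    ap = AperiodicSettings(
        **_tupled(dict(d.pop("aperiodic", {})), ("fit_range", "peak_width_limits"))
    )
    forest = RandomForestParams(**d.pop("forest", {}))
    if "glm_modes" in d:
        d["glm_modes"] = tuple(d["glm_modes"])
    return RunConfig(cohort=cohort, conditioning=cond, aperiodic=ap, forest=forest, **d)


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(data)


def save_config(path, config: RunConfig) -> None:
    d = asdict(config)
    # EffectSpec dataclasses nest one level deeper than yaml needs
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
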