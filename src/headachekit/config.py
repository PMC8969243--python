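"""Run configuration: one YAML file covering every tunable threshold."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from datetime import time, timedelta
from pathlib import Path
from typing import Any, Dict, Optional, Union

import yaml

from .criteria import ClassifierConfig, CriteriaVersion
from .timeline import (
    COMMUTE_SPEED_KMH,
    LOCATION_MISMATCH_THRESHOLD_M,
    MAX_STRESS_PER_DAY,
    MAX_STRESS_PER_HOUR,
    SleepConfig,
)
from .triggers import TriggerWindows

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass(frozen=True)
class RunConfig:
    """All module thresholds in one place (documented defaults)."""

    version: CriteriaVersion = CriteriaVersion.V3
    very_severe_counts_as_severe: bool = True
    commute_speed_kmh: float = COMMUTE_SPEED_KMH
    sedentary_gap_s: float = 60.0
    stress_per_hour: int = MAX_STRESS_PER_HOUR
    stress_per_day: int = MAX_STRESS_PER_DAY
    stress_notification_min: float = 15.0
    location_mismatch_m: float = LOCATION_MISMATCH_THRESHOLD_M
    sleep_threshold: float = 10.0
    sleep_min_rest_h: float = 3.0
    sleep_max_wake_h: float = 1.0
    sleep_anomaly_k: float = 2.0
    exercise_window_h: float = 3.0
    stress_window_long_h: float = 5.0
    stress_window_short_h: float = 1.0
    relief_window_h: float = 6.0
    relief_min_stress_min: float = 60.0
    sleep_deficit_min: float = 90.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        object.__setattr__(self, "version", CriteriaVersion(self.version))
        numeric = {
            name: getattr(self, name)
            for name in (
                "commute_speed_kmh",
                "sedentary_gap_s",
                "stress_per_hour",
                "stress_per_day",
                "stress_notification_min",
                "location_mismatch_m",
                "sleep_threshold",
                "sleep_min_rest_h",
                "sleep_max_wake_h",
                "sleep_anomaly_k",
                "exercise_window_h",
                "stress_window_long_h",
                "stress_window_short_h",
                "relief_window_h",
                "relief_min_stress_min",
                "sleep_deficit_min",
            )
        }
        for name, value in numeric.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")

    @property
    def classifier(self) -> ClassifierConfig:
        return ClassifierConfig(very_severe_counts_as_severe=self.very_severe_counts_as_severe)

    @property
    def sleep(self) -> SleepConfig:
        return SleepConfig(
            threshold=self.sleep_threshold,
            max_wake=timedelta(hours=self.sleep_max_wake_h),
            min_rest=timedelta(hours=self.sleep_min_rest_h),
            anomaly_k=self.sleep_anomaly_k,
        )

    @property
    def trigger_windows(self) -> TriggerWindows:
        return TriggerWindows(
            exercise=timedelta(hours=self.exercise_window_h),
            stress_long=timedelta(hours=self.stress_window_long_h),
            stress_short=timedelta(hours=self.stress_window_short_h),
            relief=timedelta(hours=self.relief_window_h),
            relief_min_stress=timedelta(minutes=self.relief_min_stress_min),
            sleep_deficit=timedelta(minutes=self.sleep_deficit_min),
        )


def load_config(path: Union[str, Path, None]) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path, "r", encoding="utf-8") as handle:
        data: Dict[str, Any] = yaml.safe_load(handle) or {}
    return RunConfig(**data)


def save_config(config: RunConfig, path: Union[str, Path]) -> None:
    data = asdict(config)
    data["version"] = int(config.version)
    with open(path, "w", encoding="utf-8") as handle:
        yaml.safe_dump(data, handle, sort_keys=True)
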