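"""Pipeline configuration: defaults, TOML round-trip, validation.

Every analysis parameter lives here with its unit embedded in the key name
(``*_hz``, ``*_ms``, ``*_uv``).  Defaults are the standard protocol values:
70-2000 Hz bandpass, +-30 uV rejection, -30..0 ms baseline, -30..230 ms
epoch, consonant 20-67 ms / vowel 67-220 ms regions, 20 Hz extraction
bandwidth, F1 range 400-700 Hz with a 20 Hz margin.
"""

from __future__ import annotations

import dataclasses
import hashlib
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Tuple

from .synthetic import (
    DEFAULT_BASE_GAINS_UV,
    DEFAULT_GROUP_SIZES,
    CohortConfig,
    StimulusSpec,
    default_effect_plan,
)

__all__ = ["PipelineConfig", "load_config", "default_config_toml"]


@dataclass(frozen=True)
class PipelineConfig:
    # stimulus / extraction plan
    f0_hz: float = 129.0
    harmonic_hz: Tuple[float, ...] = (261.0, 393.0, 531.0, 665.0, 787.0)
    f1_range_hz: Tuple[float, float] = (400.0, 700.0)
    total_duration_ms: float = 209.0
    consonant_window_ms: Tuple[float, float] = (20.0, 67.0)
    vowel_window_ms: Tuple[float, float] = (67.0, 220.0)
    sampling_rate_hz: float = 30000.0
    extraction_bandwidth_hz: float = 20.0
    f1_margin_hz: float = 20.0
    # preprocessing
    filter_low_hz: float = 70.0
    filter_high_hz: float = 2000.0
    rejection_threshold_uv: float = 30.0
    baseline_window_ms: Tuple[float, float] = (-30.0, 0.0)
    epoch_window_ms: Tuple[float, float] = (-30.0, 230.0)
    zero_phase: bool = False
    # cohort simulation
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    sweeps_per_polarity: int = 3000
    effect_delta: float = 0.9
    noise_sd_uv: float = 2.0
    artifact_rate: float = 0.02
    envelope_gain_uv: float = 0.1
    master_seed: int = 0
    # statistics
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise ``ValueError`` naming the offending key on bad values."""
        def positive(key):
            if getattr(self, key) <= 0:
                raise ValueError(f"config key {key!r} must be positive")

        for key in (
            "f0_hz",
            "total_duration_ms",
            "sampling_rate_hz",
            "extraction_bandwidth_hz",
            "filter_low_hz",
            "filter_high_hz",
            "rejection_threshold_uv",
            "noise_sd_uv",
        ):
            positive(key)
        if self.f1_margin_hz < 0:
            raise ValueError("config key 'f1_margin_hz' must be >= 0")
        if not self.filter_low_hz < self.filter_high_hz:
            raise ValueError(
                "config key 'filter_low_hz' must be below 'filter_high_hz'"
            )
        if self.filter_high_hz >= self.sampling_rate_hz / 2:
            raise ValueError(
                "config key 'filter_high_hz' must be below Nyquist"
            )
        for key in ("baseline_window_ms", "epoch_window_ms",
                    "consonant_window_ms", "vowel_window_ms", "f1_range_hz"):
            lo, hi = getattr(self, key)
            if hi <= lo:
                raise ValueError(f"config key {key!r} must be increasing")
        b0, b1 = self.baseline_window_ms
        e0, e1 = self.epoch_window_ms
        if b0 < e0 or b1 > e1:
            raise ValueError(
                "config key 'baseline_window_ms' must lie inside 'epoch_window_ms'"
            )
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("config key 'artifact_rate' must lie in [0, 1]")
        if self.sweeps_per_polarity <= 0:
            raise ValueError("config key 'sweeps_per_polarity' must be positive")
        for g, n in self.group_sizes.items():
            if n <= 0:
                raise ValueError(
                    f"config key 'group_sizes.{g}' must be positive"
                )
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("config key 'alpha' must lie in (0, 1)")
        # cross-validate the stimulus plan itself
        self.stimulus_spec()

    def stimulus_spec(self) -> StimulusSpec:
        return StimulusSpec(
            f0_hz=self.f0_hz,
            harmonic_hz=tuple(self.harmonic_hz),
            f1_range_hz=tuple(self.f1_range_hz),
            total_duration_ms=self.total_duration_ms,
            consonant_window_ms=tuple(self.consonant_window_ms),
            vowel_window_ms=tuple(self.vowel_window_ms),
            sampling_rate_hz=self.sampling_rate_hz,
            extraction_bandwidth_hz=self.extraction_bandwidth_hz,
            f1_margin_hz=self.f1_margin_hz,
        )

    def cohort_config(self) -> CohortConfig:
        # the default effect plan names the study groups; drop entries for
        # groups a custom cohort does not define (a renamed cohort is a
        # null cohort unless the standard group labels are used)
        plan = {
            key: delta
            for key, delta in default_effect_plan(self.effect_delta).items()
            if key[0] in self.group_sizes
        }
        return CohortConfig(
            group_sizes=dict(self.group_sizes),
            sweeps_per_polarity=self.sweeps_per_polarity,
            sampling_rate_hz=self.sampling_rate_hz,
            effect_plan=plan,
            master_seed=self.master_seed,
            base_gains_uv=dict(DEFAULT_BASE_GAINS_UV),
            envelope_gain_uv=self.envelope_gain_uv,
            noise_sd_uv=self.noise_sd_uv,
            artifact_rate=self.artifact_rate,
        )

    def to_toml(self) -> str:
        """Flat TOML rendering (lists for intervals, a table for groups)."""
        lines = []
        for f in dataclasses.fields(self):
            val = getattr(self, f.name)
            if f.name == "group_sizes":
                continue
            if isinstance(val, tuple):
                lines.append(f"{f.name} = [{', '.join(repr(float(v)) for v in val)}]")
            elif isinstance(val, bool):
                lines.append(f"{f.name} = {'true' if val else 'false'}")
            else:
                lines.append(f"{f.name} = {val!r}")
        lines.append("")
        lines.append("[group_sizes]")
        for g, n in self.group_sizes.items():
            lines.append(f"{g} = {int(n)}")
        return "\n".join(lines) + "\n"

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_toml().encode()).hexdigest()

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


_TUPLE_KEYS = {
    "harmonic_hz",
    "f1_range_hz",
    "consonant_window_ms",
    "vowel_window_ms",
    "baseline_window_ms",
    "epoch_window_ms",
}


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a TOML config file (defaults when ``path`` is None)."""
    values: Dict = {}
    if path is not None:
        raw = tomllib.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, val in raw.items():
            values[key] = tuple(val) if key in _TUPLE_KEYS else val
    values.update(overrides)
    return PipelineConfig(**values)


def default_config_toml() -> str:
    return PipelineConfig().to_toml()
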