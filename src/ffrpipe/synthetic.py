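"""Synthetic stimulus and cohort generation.

Everything downstream of acquisition is testable against this module: it
produces a surrogate consonant-vowel stimulus with a known harmonic plan,
single-subject sweep sets with controllable spectral gains, and whole
cohorts with group-dependent effects on formant-band harmonics.

The sweep model
---------------
Each simulated sweep is the sum of

* a *temporal fine structure* component — one sinusoid per spectral band
  (F0, H2..H6) at the band's nominal frequency, delayed by the neural delay,
  scaled by the subject's per-band gain — which inverts sign when the
  stimulus polarity inverts;
* an *envelope-following* component at F0 that does **not** invert with
  polarity (cochlear-microphonic-free periodicity response);
* white Gaussian sensor noise;
* with a small probability per sweep, a square artifact deflection well
  beyond the rejection threshold.

Harmonic bands are attenuated during the consonant portion, mirroring the
weaker voicing of the fricative segment.

Subject gains
-------------
Per-subject band gains are drawn around cohort base values::

    gain[b] = base[b] * max(0, 1 + cv * (z[b] + effect_plan[group, b]))
    z[b]    = rho * u + sqrt(1 - rho^2) * e[b]

with one shared factor ``u`` per subject (overall response strength) and an
independent residual ``e[b]`` per band.  The between-subject SD of each gain
is ``base[b] * cv``, so ``effect_plan`` offsets are *standardized*: an entry
of 0.9 shifts that group's band gain by 0.9 between-subject SDs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping, Optional, Sequence, Tuple

import numpy as np

from .preprocess import SweepSet

__all__ = [
    "BAND_NAMES",
    "HARMONIC_NAMES",
    "DEFAULT_NEURAL_DELAY_MS",
    "StimulusSpec",
    "SubjectParams",
    "CohortConfig",
    "SubjectRecord",
    "synthesize_stimulus",
    "simulate_subject_sweeps",
    "simulate_cohort",
    "draw_subject_params",
    "simulate_feature_table",
    "subject_seed",
]

BAND_NAMES: Tuple[str, ...] = ("F0", "H2", "H3", "H4", "H5", "H6")
HARMONIC_NAMES: Tuple[str, ...] = ("H2", "H3", "H4", "H5", "H6")

#: Neural transmission delay assumed when the response region windows were
#: laid out; also the default delay injected by the sweep simulator.
DEFAULT_NEURAL_DELAY_MS = 10.0


@dataclass(frozen=True)
class StimulusSpec:
    """Frequency/time plan of the stimulus, anchoring all extraction.

    Defaults describe a 209 ms consonant-vowel syllable with F0 at 129 Hz,
    harmonics H2-H6 at 261/393/531/665/787 Hz, and a first-formant range of
    400-700 Hz.  Region windows are on the *response* time base and already
    include the neural delay allowance.
    """

    f0_hz: float = 129.0
    harmonic_hz: Tuple[float, ...] = (261.0, 393.0, 531.0, 665.0, 787.0)
    f1_range_hz: Tuple[float, float] = (400.0, 700.0)
    total_duration_ms: float = 209.0
    consonant_window_ms: Tuple[float, float] = (20.0, 67.0)
    vowel_window_ms: Tuple[float, float] = (67.0, 220.0)
    sampling_rate_hz: float = 30000.0
    extraction_bandwidth_hz: float = 20.0
    f1_margin_hz: float = 20.0

    def __post_init__(self) -> None:
        if self.f0_hz <= 0:
            raise ValueError("f0_hz must be positive")
        harm = tuple(float(h) for h in self.harmonic_hz)
        if len(harm) != 5:
            raise ValueError("harmonic_hz must list the 5 frequencies H2-H6")
        if any(b <= a for a, b in zip(harm, harm[1:])) or harm[0] <= self.f0_hz:
            raise ValueError("harmonic_hz must be strictly increasing and > f0_hz")
        if self.f1_range_hz[1] <= self.f1_range_hz[0]:
            raise ValueError("f1_range_hz must be increasing")
        if self.total_duration_ms <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("duration and sampling rate must be positive")
        c0, c1 = self.consonant_window_ms
        v0, v1 = self.vowel_window_ms
        if not (0 <= c0 < c1 <= v0 < v1):
            raise ValueError(
                "region windows must be ordered, disjoint except at the boundary"
            )
        if v1 > self.total_duration_ms + 2 * DEFAULT_NEURAL_DELAY_MS + 1e-9:
            raise ValueError("vowel window extends past stimulus + delay allowance")
        if self.extraction_bandwidth_hz <= 0:
            raise ValueError("extraction_bandwidth_hz must be positive")
        if self.f1_margin_hz < 0:
            raise ValueError("f1_margin_hz must be non-negative")

    @property
    def band_frequencies_hz(self) -> Dict[str, float]:
        """Nominal frequency of every band, keyed F0, H2..H6."""
        out = {"F0": self.f0_hz}
        out.update(dict(zip(HARMONIC_NAMES, self.harmonic_hz)))
        return out

    @property
    def consonant_vowel_boundary_ms(self) -> float:
        """Consonant/vowel boundary on the *stimulus* time base."""
        return self.vowel_window_ms[0] - DEFAULT_NEURAL_DELAY_MS

    @property
    def n_samples(self) -> int:
        return int(round(self.total_duration_ms * self.sampling_rate_hz / 1000.0))


def _edge_ramp(n: int, n_ramp: int) -> np.ndarray:
    """Unit envelope with raised-cosine onset/offset ramps."""
    env = np.ones(n)
    n_ramp = min(n_ramp, n // 2)
    if n_ramp > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = ramp
        env[-n_ramp:] = ramp[::-1]
    return env


def synthesize_stimulus(
    spec: StimulusSpec,
    component_gains: Optional[Mapping[str, float]] = None,
    consonant_attenuation: float = 0.3,
    fricative_noise: float = 0.15,
    f1_boost: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Build the surrogate consonant-vowel syllable waveform.

    A harmonic complex at ``spec.f0_hz`` with partials at the configured
    H2-H6 frequencies.  During the consonant segment the harmonics are
    attenuated and broadband noise is mixed in (fricative-like); during the
    vowel, partials inside the F1 range are boosted.  The result is
    peak-normalized to 1.

    Parameters
    ----------
    component_gains
        Optional per-band linear gains keyed by ``F0``, ``H2``..``H6``
        (default: 1 everywhere).
    """
    nyq = spec.sampling_rate_hz / 2.0
    gains = {b: 1.0 for b in BAND_NAMES}
    if component_gains:
        unknown = set(component_gains) - set(BAND_NAMES)
        if unknown:
            raise ValueError(f"unknown bands in component_gains: {sorted(unknown)}")
        gains.update({b: float(g) for b, g in component_gains.items()})
    n = spec.n_samples
    t = np.arange(n) / spec.sampling_rate_hz
    boundary = spec.consonant_vowel_boundary_ms / 1000.0
    is_consonant = t < boundary
    f1_lo, f1_hi = spec.f1_range_hz

    wave = np.zeros(n)
    for band, freq in spec.band_frequencies_hz.items():
        if gains[band] == 0.0:
            continue
        if freq >= nyq:
            raise ValueError(
                f"partial {band} at {freq} Hz is at/above Nyquist ({nyq} Hz)"
            )
        amp = np.full(n, gains[band])
        if band != "F0":
            amp[is_consonant] *= consonant_attenuation
            if f1_lo <= freq <= f1_hi:
                amp[~is_consonant] *= f1_boost
        wave += amp * np.sin(2.0 * np.pi * freq * t)

    if fricative_noise > 0:
        rng = np.random.default_rng(seed)
        noise = np.zeros(n)
        noise[is_consonant] = fricative_noise * rng.standard_normal(
            int(is_consonant.sum())
        )
        wave += noise

    wave *= _edge_ramp(n, int(round(0.005 * spec.sampling_rate_hz)))
    peak = np.max(np.abs(wave))
    if peak > 0:
        wave /= peak
    return wave


@dataclass(frozen=True)
class SubjectParams:
    """Generative knobs for one simulated subject."""

    group_label: str
    component_gains: Mapping[str, float]
    envelope_gain: float = 0.1
    noise_sd_uv: float = 2.0
    artifact_rate: float = 0.0
    neural_delay_ms: float = DEFAULT_NEURAL_DELAY_MS
    seed: int = 0

    def __post_init__(self) -> None:
        for band, g in self.component_gains.items():
            if band not in BAND_NAMES:
                raise ValueError(f"unknown band {band!r} in component_gains")
            if not np.isfinite(g) or g < 0:
                raise ValueError(f"gain for {band} must be finite and >= 0")
        if not np.isfinite(self.envelope_gain) or self.envelope_gain < 0:
            raise ValueError("envelope_gain must be finite and >= 0")
        if self.noise_sd_uv <= 0:
            raise ValueError("noise_sd_uv must be positive")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ValueError("artifact_rate must lie in [0, 1]")


# Default cohort layout: 14 native nonmusicians, 18 non-native nonmusicians,
# 10 non-native musicians; F1-band gains elevated for the native and
# musician groups.
DEFAULT_GROUP_SIZES: Dict[str, int] = {
    "native": 14,
    "nonnative_nonmusician": 18,
    "nonnative_musician": 10,
}
DEFAULT_BASE_GAINS_UV: Dict[str, float] = {
    "F0": 0.12,
    "H2": 0.08,
    "H3": 0.07,
    "H4": 0.06,
    "H5": 0.05,
    "H6": 0.04,
}


def default_effect_plan(
    delta: float = 0.9,
    bands: Sequence[str] = ("H3", "H4", "H5"),
    groups: Sequence[str] = ("native", "nonnative_musician"),
) -> Dict[Tuple[str, str], float]:
    """Standardized gain offsets elevating F1-band harmonics in two groups."""
    return {(g, b): delta for g in groups for b in bands}


@dataclass(frozen=True)
class CohortConfig:
    """Cohort-scale simulation parameters.

    ``effect_plan`` maps ``(group, band)`` to a standardized gain offset
    (units of that band's between-subject SD).  ``gain_shared_corr`` is the
    correlation induced between bands by the shared subject factor.
    """

    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    sweeps_per_polarity: int = 3000
    sampling_rate_hz: float = 30000.0
    effect_plan: Mapping[Tuple[str, str], float] = field(
        default_factory=default_effect_plan
    )
    master_seed: int = 0
    base_gains_uv: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_GAINS_UV)
    )
    gain_cv: float = 0.25
    gain_shared_corr: float = 0.7
    envelope_gain_uv: float = 0.1
    noise_sd_uv: float = 2.0
    artifact_rate: float = 0.02
    neural_delay_ms: float = DEFAULT_NEURAL_DELAY_MS

    def __post_init__(self) -> None:
        if not self.group_sizes:
            raise ValueError("group_sizes must not be empty")
        for g, n in self.group_sizes.items():
            if n <= 0:
                raise ValueError(f"group {g!r} has non-positive size {n}")
        if self.sweeps_per_polarity <= 0:
            raise ValueError("sweeps_per_polarity must be positive")
        for (g, b) in self.effect_plan:
            if g not in self.group_sizes:
                raise ValueError(f"effect_plan references unknown group {g!r}")
            if b not in BAND_NAMES:
                raise ValueError(f"effect_plan references unknown band {b!r}")
        if set(self.base_gains_uv) != set(BAND_NAMES):
            raise ValueError("base_gains_uv must cover exactly F0, H2..H6")
        if not 0.0 <= self.gain_shared_corr <= 1.0:
            raise ValueError("gain_shared_corr must lie in [0, 1]")
        if self.gain_cv <= 0:
            raise ValueError("gain_cv must be positive")

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())


def subject_seed(master_seed: int, index: int) -> int:
    """Deterministic, stream-independent seed for subject ``index``."""
    return int(np.random.SeedSequence((master_seed, index)).generate_state(1)[0])


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    params: SubjectParams


def draw_subject_params(config: CohortConfig) -> list[SubjectRecord]:
    """Draw per-subject generative parameters for the whole cohort.

    Deterministic given ``config.master_seed``; subject ``i`` always receives
    the same parameters regardless of how many subjects precede it.
    """
    records = []
    index = 0
    rho = config.gain_shared_corr
    for group in config.group_sizes:
        for _ in range(config.group_sizes[group]):
            seed = subject_seed(config.master_seed, index)
            rng = np.random.default_rng(np.random.SeedSequence((seed, 0)))
            u = rng.standard_normal()
            gains = {}
            for band in BAND_NAMES:
                e = rng.standard_normal()
                z = rho * u + np.sqrt(1.0 - rho * rho) * e
                delta = config.effect_plan.get((group, band), 0.0)
                gains[band] = config.base_gains_uv[band] * max(
                    0.0, 1.0 + config.gain_cv * (z + delta)
                )
            records.append(
                SubjectRecord(
                    subject_id=f"S{index + 1:03d}",
                    group=group,
                    params=SubjectParams(
                        group_label=group,
                        component_gains=gains,
                        envelope_gain=config.envelope_gain_uv,
                        noise_sd_uv=config.noise_sd_uv,
                        artifact_rate=config.artifact_rate,
                        neural_delay_ms=config.neural_delay_ms,
                        seed=seed,
                    ),
                )
            )
            index += 1
    return records


def _band_waveforms(
    spec: StimulusSpec,
    sampling_rate_hz: float,
    neural_delay_ms: float,
    epoch_window_ms: Tuple[float, float],
    consonant_attenuation: float = 0.3,
) -> Tuple[np.ndarray, Dict[str, np.ndarray], np.ndarray]:
    """Unit-gain neural component waveforms on the epoch time base.

    Returns ``(times_ms, fine-structure components by band, envelope)``.
    Harmonic components are attenuated during the consonant portion, the
    F0 fine-structure and the envelope run the whole stimulus.
    """
    e0, e1 = epoch_window_ms
    n = int(round((e1 - e0) * sampling_rate_hz / 1000.0))
    t_ms = e0 + np.arange(n) * 1000.0 / sampling_rate_hz
    onset = neural_delay_ms
    offset = neural_delay_ms + spec.total_duration_ms
    if offset > e1 + 1e-9:
        raise ValueError(
            f"epoch window {epoch_window_ms} ms does not cover stimulus "
            f"({spec.total_duration_ms} ms) plus neural delay ({neural_delay_ms} ms)"
        )
    active = (t_ms >= onset) & (t_ms < offset)
    t_stim_s = (t_ms - onset) / 1000.0
    boundary_ms = onset + spec.consonant_vowel_boundary_ms
    components: Dict[str, np.ndarray] = {}
    for band, freq in spec.band_frequencies_hz.items():
        if freq >= sampling_rate_hz / 2.0:
            raise ValueError(f"band {band} at {freq} Hz at/above Nyquist")
        w = np.where(active, np.sin(2.0 * np.pi * freq * t_stim_s), 0.0)
        if band != "F0":
            w = np.where(t_ms < boundary_ms, consonant_attenuation * w, w)
        components[band] = w
    envelope = np.where(
        active, np.sin(2.0 * np.pi * spec.f0_hz * t_stim_s), 0.0
    )
    return t_ms, components, envelope


def simulate_subject_sweeps(
    stimulus: np.ndarray,
    params: SubjectParams,
    spec: StimulusSpec,
    n_sweeps: int = 6000,
    sampling_rate_hz: Optional[float] = None,
    epoch_window_ms: Tuple[float, float] = (-30.0, 230.0),
) -> SweepSet:
    """Simulate one subject's epoched sweeps.

    Polarity labels alternate A, B, A, B, ...; the fine-structure component
    flips sign with polarity, the envelope and noise do not.  Fully
    reproducible from ``params.seed``.

    ``stimulus`` is used only for consistency checking (the neural
    components are regenerated from ``spec`` so per-band gains stay exactly
    interpretable in uV); pass the waveform produced by
    :func:`synthesize_stimulus` for the same spec.
    """
    fs = float(sampling_rate_hz or spec.sampling_rate_hz)
    stimulus = np.asarray(stimulus)
    expected = int(round(spec.total_duration_ms * spec.sampling_rate_hz / 1000.0))
    if stimulus.ndim != 1 or abs(stimulus.size - expected) > 1:
        raise ValueError(
            f"stimulus has {stimulus.size} samples, spec implies {expected}"
        )
    _, components, envelope = _band_waveforms(
        spec, fs, params.neural_delay_ms, epoch_window_ms
    )
    fine = np.zeros_like(envelope)
    for band, w in components.items():
        fine += params.component_gains.get(band, 0.0) * w
    env = params.envelope_gain * envelope

    n_samples = fine.size
    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 1)))
    signs = np.where(np.arange(n_sweeps) % 2 == 0, 1.0, -1.0)
    polarity = np.where(signs > 0, "A", "B")
    sweeps = signs[:, None] * fine[None, :] + env[None, :]
    sweeps = sweeps + rng.normal(0.0, params.noise_sd_uv, size=(n_sweeps, n_samples))

    if params.artifact_rate > 0:
        hit = rng.random(n_sweeps) < params.artifact_rate
        width = max(1, int(round(0.002 * fs)))  # 2 ms square pulse
        for i in np.nonzero(hit)[0]:
            amp = rng.uniform(50.0, 100.0) * rng.choice([-1.0, 1.0])
            start = rng.integers(0, max(1, n_samples - width))
            sweeps[i, start : start + width] += amp

    return SweepSet(
        sweeps=sweeps,
        polarity=polarity,
        sampling_rate_hz=fs,
        epoch_window_ms=epoch_window_ms,
    )


def simulate_cohort(
    config: CohortConfig,
    spec: StimulusSpec,
    stimulus: Optional[np.ndarray] = None,
    epoch_window_ms: Tuple[float, float] = (-30.0, 230.0),
) -> Iterator[Tuple[str, str, SweepSet]]:
    """Yield ``(subject_id, group, SweepSet)`` for every subject.

    Byte-identical on rerun with the same ``config`` (subject seeds derive
    from ``master_seed``).
    """
    if stimulus is None:
        stimulus = synthesize_stimulus(spec)
    for rec in draw_subject_params(config):
        sweeps = simulate_subject_sweeps(
            stimulus,
            rec.params,
            spec,
            n_sweeps=2 * config.sweeps_per_polarity,
            sampling_rate_hz=config.sampling_rate_hz,
            epoch_window_ms=epoch_window_ms,
        )
        yield rec.subject_id, rec.group, sweeps


def simulate_feature_table(
    config: CohortConfig,
    spec: StimulusSpec,
    consonant_attenuation: float = 0.3,
):
    """Cohort feature table straight from the gain model (no waveforms).

    Produces the same columns as the spectral-feature extractor, with each
    band amplitude equal to the subject's generative gain (harmonics scaled
    by ``consonant_attenuation`` in the consonant region).  This is the
    feature-level shortcut used for statistical calibration at scale, and it
    shares the gain-drawing code path with the sweep simulator.
    """
    import pandas as pd

    from .spectral import classify_f1_harmonics

    in_f1, non_f1 = classify_f1_harmonics(
        dict(zip(HARMONIC_NAMES, spec.harmonic_hz)),
        spec.f1_range_hz,
        spec.f1_margin_hz,
    )
    rows = []
    for rec in draw_subject_params(config):
        g = rec.params.component_gains
        for region, att in (("consonant", consonant_attenuation), ("vowel", 1.0)):
            amps = {b: att * g[b] for b in HARMONIC_NAMES}
            amps["F0"] = g["F0"]
            h_vals = [amps[b] for b in HARMONIC_NAMES]
            row = {
                "subject_id": rec.subject_id,
                "group": rec.group,
                "region": region,
                "f0_amp": amps["F0"],
            }
            row.update({b.lower() + "_amp": amps[b] for b in HARMONIC_NAMES})
            row["mean_h"] = float(np.mean(h_vals))
            row["f1_mean"] = float(np.mean([amps[b] for b in in_f1])) if in_f1 else np.nan
            row["non_f1_mean"] = (
                float(np.mean([amps[b] for b in non_f1])) if non_f1 else np.nan
            )
            rows.append(row)
    return pd.DataFrame(rows)
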