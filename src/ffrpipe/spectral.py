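"""Region-wise spectra and stimulus-anchored spectral features.

The feature set per subject and time region (consonant / vowel):

* ``f0_amp`` — peak amplitude in a fixed-width window around the refined F0
  stimulus peak;
* ``h2_amp`` .. ``h6_amp`` — likewise for harmonics H2-H6;
* ``mean_h`` — arithmetic mean of the five harmonic amplitudes;
* ``f1_mean`` / ``non_f1_mean`` — means over the harmonics classified
  inside / outside the first-formant range (+- margin).

Spectra are single-sided amplitude spectra (uV): rectangular window,
zero-padding to <= 1 Hz bins, amplitude ``2|X|/N`` with ``N`` the unpadded
segment length, so a unit sinusoid filling the segment reads ~1 uV.  The
extraction window around a peak at ``c`` with bandwidth ``w`` is the closed
interval ``[c - w/2, c + w/2]`` (a 118 Hz peak with 20 Hz bandwidth is
searched in [108, 128] Hz).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .preprocess import AveragedResponse, window_to_slice
from .synthetic import HARMONIC_NAMES, BAND_NAMES, StimulusSpec

__all__ = [
    "Spectrum",
    "RegionFeatures",
    "SpectralFeatures",
    "extraction_window",
    "amplitude_spectrum",
    "select_local_peak",
    "stimulus_peak_frequencies",
    "region_spectrum",
    "extract_peak_amplitude",
    "classify_f1_harmonics",
    "compute_features",
    "features_to_frame",
]


@dataclass
class Spectrum:
    """Single-sided amplitude spectrum of one response region."""

    freqs_hz: np.ndarray
    amplitude: np.ndarray
    region_label: str = "whole"
    resolution_hz: float = 0.0

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.freqs_hz.shape != self.amplitude.shape:
            raise ValueError("freqs_hz and amplitude must have equal length")
        if self.freqs_hz.size and (
            self.freqs_hz[0] != 0.0 or np.any(np.diff(self.freqs_hz) <= 0)
        ):
            raise ValueError("freqs_hz must increase strictly from 0")


def extraction_window(center_hz: float, bandwidth_hz: float) -> Tuple[float, float]:
    """Closed frequency interval searched around a spectral peak.

    Total width ``bandwidth_hz`` centered on the peak: ``center +- bw/2``.
    """
    if bandwidth_hz <= 0:
        raise ValueError("bandwidth_hz must be positive")
    half = bandwidth_hz / 2.0
    return (center_hz - half, center_hz + half)


def _n_fft(n_seg: int, sampling_rate_hz: float, max_bin_hz: float) -> int:
    """Power-of-two FFT length giving bin width <= max_bin_hz."""
    n_min = max(n_seg, int(np.ceil(sampling_rate_hz / max_bin_hz)))
    return 1 << int(np.ceil(np.log2(n_min)))


def amplitude_spectrum(
    x: np.ndarray,
    sampling_rate_hz: float,
    max_bin_hz: float = 1.0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Zero-padded single-sided amplitude spectrum of a segment.

    Amplitude convention: ``2 |FFT| / N`` with ``N`` the unpadded length
    (rectangular window), calibrated so a full-segment unit sinusoid at a
    bin center returns 1.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("segment must be 1-D with at least 2 samples")
    n_fft = _n_fft(x.size, sampling_rate_hz, max_bin_hz)
    spec = np.fft.rfft(x, n=n_fft)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sampling_rate_hz)
    amp = 2.0 * np.abs(spec) / x.size
    return freqs, amp


def select_local_peak(
    freqs_hz: np.ndarray,
    amplitude: np.ndarray,
    nominal_hz: float,
    halfwidth_hz: float = 30.0,
) -> float:
    """Frequency of the local amplitude maximum near ``nominal_hz``.

    Considers interior bins of ``[nominal - halfwidth, nominal + halfwidth]``
    that are local maxima (``>=`` both neighbours, so plateau edges count)
    and returns the frequency of the largest; exact ties resolve to the
    lowest frequency.  Raises when the window holds no local maximum.
    """
    freqs_hz = np.asarray(freqs_hz, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    lo, hi = nominal_hz - halfwidth_hz, nominal_hz + halfwidth_hz
    idx = np.nonzero((freqs_hz >= lo) & (freqs_hz <= hi))[0]
    if idx.size < 3:
        raise ValueError(
            f"search window [{lo}, {hi}] Hz covers too few spectrum bins"
        )
    inner = idx[1:-1]
    is_max = (amplitude[inner] >= amplitude[inner - 1]) & (
        amplitude[inner] >= amplitude[inner + 1]
    )
    candidates = inner[is_max]
    if candidates.size == 0:
        raise ValueError(
            f"no local spectral maximum within +-{halfwidth_hz} Hz of "
            f"{nominal_hz} Hz"
        )
    best = candidates[np.argmax(amplitude[candidates])]
    return float(freqs_hz[best])


def stimulus_peak_frequencies(
    stimulus: np.ndarray,
    spec: StimulusSpec,
    search_halfwidth_hz: float = 30.0,
    max_bin_hz: float = 1.0,
) -> Dict[str, float]:
    """Refine the nominal band frequencies against the stimulus spectrum.

    For each band (F0, H2..H6) returns the frequency of the local maximum of
    the whole-stimulus amplitude spectrum within ``+- search_halfwidth_hz``
    of the nominal value (see :func:`select_local_peak`).
    """
    stimulus = np.asarray(stimulus, dtype=float)
    if stimulus.size < spec.sampling_rate_hz / spec.f0_hz:
        raise ValueError("stimulus shorter than one F0 period")
    freqs, amp = amplitude_spectrum(stimulus, spec.sampling_rate_hz, max_bin_hz)
    out: Dict[str, float] = {}
    for band, nominal in spec.band_frequencies_hz.items():
        try:
            out[band] = select_local_peak(freqs, amp, nominal, search_halfwidth_hz)
        except ValueError as err:
            raise ValueError(f"band {band}: {err}") from err
    return out


def region_spectrum(
    response: AveragedResponse,
    window_ms: Tuple[float, float],
    region_label: str = "whole",
    max_bin_hz: float = 1.0,
) -> Spectrum:
    """FFT amplitude spectrum of one time region of the averaged response.

    The segment is cut with closed-open sample indexing, rectangular
    windowed, and zero-padded so the bin width is <= ``max_bin_hz``.
    """
    sl = window_to_slice(
        window_ms,
        response.epoch_window_ms,
        response.sampling_rate_hz,
        response.n_samples,
    )
    seg = response.samples[sl]
    if seg.size < 2:
        raise ValueError(f"window {window_ms} ms yields fewer than 2 samples")
    freqs, amp = amplitude_spectrum(seg, response.sampling_rate_hz, max_bin_hz)
    return Spectrum(
        freqs_hz=freqs,
        amplitude=amp,
        region_label=region_label,
        resolution_hz=float(freqs[1] - freqs[0]),
    )


def extract_peak_amplitude(
    spectrum: Spectrum, center_hz: float, bandwidth_hz: float
) -> float:
    """Maximum amplitude over bins inside the closed extraction window.

    The DC bin is never part of the feature.
    """
    lo, hi = extraction_window(center_hz, bandwidth_hz)
    if lo < 0 or hi > spectrum.freqs_hz[-1]:
        raise ValueError(
            f"extraction window [{lo}, {hi}] Hz outside spectrum range "
            f"[0, {spectrum.freqs_hz[-1]}] Hz"
        )
    mask = (spectrum.freqs_hz >= lo) & (spectrum.freqs_hz <= hi)
    mask &= spectrum.freqs_hz > 0.0
    if not mask.any():
        raise ValueError(f"no spectrum bins inside [{lo}, {hi}] Hz")
    return float(spectrum.amplitude[mask].max())


def classify_f1_harmonics(
    peak_freqs: Mapping[str, float],
    f1_range_hz: Tuple[float, float],
    margin_hz: float = 20.0,
) -> Tuple[Tuple[str, ...], Tuple[str, ...]]:
    """Partition H2-H6 into in-F1 and non-F1 members.

    A harmonic is in-F1 iff its (refined) frequency lies in the closed
    interval ``[f1_low - margin, f1_high + margin]``.  Empty classes are
    allowed and simply reported.
    """
    missing = [h for h in HARMONIC_NAMES if h not in peak_freqs]
    if missing:
        raise ValueError(f"missing refined frequencies for {missing}")
    lo = f1_range_hz[0] - margin_hz
    hi = f1_range_hz[1] + margin_hz
    in_f1 = tuple(h for h in HARMONIC_NAMES if lo <= peak_freqs[h] <= hi)
    non_f1 = tuple(h for h in HARMONIC_NAMES if h not in in_f1)
    return in_f1, non_f1


@dataclass
class RegionFeatures:
    f0_amp: float
    h_amps: Dict[str, float]
    mean_h: float
    f1_mean: float
    non_f1_mean: float


@dataclass
class SpectralFeatures:
    """Per-subject spectral features for both time regions."""

    subject_id: str
    group: str
    consonant: RegionFeatures
    vowel: RegionFeatures
    f1_members: Tuple[str, ...]

    def to_rows(self) -> list[dict]:
        rows = []
        for region in ("consonant", "vowel"):
            rf: RegionFeatures = getattr(self, region)
            row = {
                "subject_id": self.subject_id,
                "group": self.group,
                "region": region,
                "f0_amp": rf.f0_amp,
            }
            row.update({h.lower() + "_amp": rf.h_amps[h] for h in HARMONIC_NAMES})
            row["mean_h"] = rf.mean_h
            row["f1_mean"] = rf.f1_mean
            row["non_f1_mean"] = rf.non_f1_mean
            rows.append(row)
        return rows


def _region_features(
    response: AveragedResponse,
    spec: StimulusSpec,
    peak_freqs: Mapping[str, float],
    window_ms: Tuple[float, float],
    region_label: str,
    in_f1: Sequence[str],
    non_f1: Sequence[str],
    max_bin_hz: float,
) -> RegionFeatures:
    spectrum = region_spectrum(response, window_ms, region_label, max_bin_hz)
    bw = spec.extraction_bandwidth_hz

    def grab(band: str) -> float:
        try:
            return extract_peak_amplitude(spectrum, peak_freqs[band], bw)
        except ValueError as err:
            raise ValueError(f"{region_label}/{band}: {err}") from err

    f0_amp = grab("F0")
    h_amps = {h: grab(h) for h in HARMONIC_NAMES}
    mean_h = float(np.mean([h_amps[h] for h in HARMONIC_NAMES]))
    f1_mean = float(np.mean([h_amps[h] for h in in_f1])) if in_f1 else float("nan")
    non_f1_mean = (
        float(np.mean([h_amps[h] for h in non_f1])) if non_f1 else float("nan")
    )
    return RegionFeatures(f0_amp, h_amps, mean_h, f1_mean, non_f1_mean)


def compute_features(
    response: AveragedResponse,
    spec: StimulusSpec,
    peak_freqs: Mapping[str, float],
    subject_id: str = "",
    group: str = "",
    max_bin_hz: float = 1.0,
) -> SpectralFeatures:
    """Extract the full per-subject feature set for both regions.

    ``peak_freqs`` are the refined stimulus peak frequencies from
    :func:`stimulus_peak_frequencies`; one whole-stimulus FFT anchors both
    regions.
    """
    missing = [b for b in BAND_NAMES if b not in peak_freqs]
    if missing:
        raise ValueError(f"peak_freqs missing bands {missing}")
    in_f1, non_f1 = classify_f1_harmonics(
        peak_freqs, spec.f1_range_hz, spec.f1_margin_hz
    )
    consonant = _region_features(
        response, spec, peak_freqs, spec.consonant_window_ms,
        "consonant", in_f1, non_f1, max_bin_hz,
    )
    vowel = _region_features(
        response, spec, peak_freqs, spec.vowel_window_ms,
        "vowel", in_f1, non_f1, max_bin_hz,
    )
    return SpectralFeatures(
        subject_id=subject_id,
        group=group,
        consonant=consonant,
        vowel=vowel,
        f1_members=in_f1,
    )


def features_to_frame(features: Sequence[SpectralFeatures]) -> pd.DataFrame:
    """Long (subject x region) feature table, one row per subject-region."""
    rows: list[dict] = []
    for f in features:
        rows.extend(f.to_rows())
    return pd.DataFrame(rows)
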