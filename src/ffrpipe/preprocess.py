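"""Single-subject sweep preprocessing.

Turns an epoched multi-sweep recording into one polarity-subtracted average
per subject.  The canonical stage order is

    bandpass filter -> artifact rejection -> baseline correction ->
    polarity-subtracted averaging

as wrapped by :func:`preprocess_sweeps`.  Every stage is also exposed on its
own so the steps can be tested, reordered, or skipped explicitly.

Conventions
-----------
* Amplitudes are in microvolts (uV) throughout.
* Epoch windows are closed millisecond intervals, mapped to sample indices
  with closed-open (``[start, stop)``) slicing.
* The bandpass is a second-order Butterworth per edge (12 dB/octave
  asymptotic roll-off) applied causally by default; a zero-phase variant is
  available but doubles the effective roll-off.
* Artifact rejection uses strict exceedance: a sweep is dropped iff some
  sample satisfies ``|x| > threshold``; a sample at exactly the threshold is
  retained.
* The subtracted average is ``(mean_A - mean_B) / 2`` so its scale matches a
  single-polarity average.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Tuple

import numpy as np
from scipy import signal

__all__ = [
    "SweepSet",
    "AveragedResponse",
    "design_bandpass",
    "bandpass_filter",
    "reject_artifacts",
    "baseline_correct",
    "average_and_subtract",
    "preprocess_sweeps",
    "window_to_slice",
]

POLARITY_LABELS = ("A", "B")


def window_to_slice(
    window_ms: Tuple[float, float],
    epoch_window_ms: Tuple[float, float],
    sampling_rate_hz: float,
    n_samples: int,
) -> slice:
    """Map a millisecond window inside the epoch to a closed-open sample slice."""
    w0, w1 = window_ms
    e0, e1 = epoch_window_ms
    if w0 < e0 - 1e-9 or w1 > e1 + 1e-9:
        raise ValueError(
            f"window {window_ms} ms not contained in epoch {epoch_window_ms} ms"
        )
    i0 = int(round((w0 - e0) * sampling_rate_hz / 1000.0))
    i1 = int(round((w1 - e0) * sampling_rate_hz / 1000.0))
    i0 = max(i0, 0)
    i1 = min(i1, n_samples)
    if i1 - i0 < 1:
        raise ValueError(f"window {window_ms} ms is empty at this sampling rate")
    return slice(i0, i1)


@dataclass
class SweepSet:
    """Epoched multi-sweep EEG for one subject.

    Parameters
    ----------
    sweeps
        Array of shape ``(n_sweeps, n_samples)``, amplitudes in uV.
    polarity
        Per-sweep stimulus polarity label, one of ``"A"``/``"B"``.
    sampling_rate_hz
        Sampling rate of the epoch time base.
    epoch_window_ms
        Closed epoch interval in ms relative to stimulus onset
        (typically ``(-30, 230)``).
    """

    sweeps: np.ndarray
    polarity: np.ndarray
    sampling_rate_hz: float
    epoch_window_ms: Tuple[float, float] = (-30.0, 230.0)

    def __post_init__(self) -> None:
        self.sweeps = np.asarray(self.sweeps, dtype=float)
        self.polarity = np.asarray(self.polarity)
        if self.sweeps.ndim != 2:
            raise ValueError("sweeps must be a 2-D (n_sweeps, n_samples) array")
        if self.polarity.shape != (self.sweeps.shape[0],):
            raise ValueError("polarity must have one label per sweep row")
        bad = set(np.unique(self.polarity)) - set(POLARITY_LABELS)
        if bad:
            raise ValueError(f"unknown polarity labels: {sorted(bad)}")
        e0, e1 = self.epoch_window_ms
        if e1 <= e0:
            raise ValueError("epoch_window_ms must be increasing")
        expected = (e1 - e0) * self.sampling_rate_hz / 1000.0
        if abs(expected - self.sweeps.shape[1]) > 1.0 + 1e-9:
            raise ValueError(
                f"epoch window implies {expected:.1f} samples but sweeps have "
                f"{self.sweeps.shape[1]} columns"
            )

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def n_samples(self) -> int:
        return self.sweeps.shape[1]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms on the epoch time base."""
        e0 = self.epoch_window_ms[0]
        return e0 + np.arange(self.n_samples) * 1000.0 / self.sampling_rate_hz

    def count(self, label: str) -> int:
        return int(np.sum(self.polarity == label))


@dataclass
class AveragedResponse:
    """A subject's polarity-subtracted average waveform."""

    samples: np.ndarray
    sampling_rate_hz: float
    epoch_window_ms: Tuple[float, float]
    n_sweeps_used: Tuple[int, int] = (0, 0)  # (count A, count B)
    n_rejected: int = 0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D vector")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def times_ms(self) -> np.ndarray:
        e0 = self.epoch_window_ms[0]
        return e0 + np.arange(self.n_samples) * 1000.0 / self.sampling_rate_hz


def design_bandpass(
    low_hz: float, high_hz: float, sampling_rate_hz: float
) -> np.ndarray:
    """Second-order sections for the standard FFR bandpass.

    One second-order Butterworth per band edge, i.e. a 12 dB/octave
    asymptotic roll-off on each side.
    """
    nyq = sampling_rate_hz / 2.0
    if not (0.0 < low_hz < high_hz):
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= nyq:
        raise ValueError(
            f"corner frequency {high_hz} Hz at/above Nyquist ({nyq} Hz)"
        )
    return signal.butter(
        2, [low_hz, high_hz], btype="bandpass", fs=sampling_rate_hz, output="sos"
    )


def bandpass_filter(
    sweeps: SweepSet,
    low_hz: float = 70.0,
    high_hz: float = 2000.0,
    zero_phase: bool = False,
) -> SweepSet:
    """Bandpass each sweep (default 70-2000 Hz, 12 dB/octave roll-off).

    ``zero_phase=True`` filters forward and backward (no phase distortion)
    but doubles the effective roll-off to 24 dB/octave; the causal default
    preserves the nominal slope.
    """
    sos = design_bandpass(low_hz, high_hz, sweeps.sampling_rate_hz)
    if zero_phase:
        filtered = signal.sosfiltfilt(sos, sweeps.sweeps, axis=1)
    else:
        filtered = signal.sosfilt(sos, sweeps.sweeps, axis=1)
    return replace(sweeps, sweeps=np.ascontiguousarray(filtered))


def reject_artifacts(
    sweeps: SweepSet, threshold_uv: float = 30.0
) -> Tuple[SweepSet, int]:
    """Drop sweeps with any sample strictly exceeding ``+-threshold_uv``.

    Returns the surviving sweeps (order preserved) and the rejected count.
    Raises if every sweep is rejected.
    """
    if threshold_uv <= 0:
        raise ValueError("threshold_uv must be positive")
    exceeds = np.any(np.abs(sweeps.sweeps) > threshold_uv, axis=1)
    n_rejected = int(exceeds.sum())
    if n_rejected == sweeps.n_sweeps:
        raise ValueError(
            f"all {sweeps.n_sweeps} sweeps exceed +-{threshold_uv} uV"
        )
    keep = ~exceeds
    out = replace(sweeps, sweeps=sweeps.sweeps[keep], polarity=sweeps.polarity[keep])
    return out, n_rejected


def baseline_correct(
    sweeps: SweepSet, baseline_window_ms: Tuple[float, float] = (-30.0, 0.0)
) -> SweepSet:
    """Subtract each sweep's mean over the baseline window from the sweep."""
    sl = window_to_slice(
        baseline_window_ms,
        sweeps.epoch_window_ms,
        sweeps.sampling_rate_hz,
        sweeps.n_samples,
    )
    means = sweeps.sweeps[:, sl].mean(axis=1, keepdims=True)
    return replace(sweeps, sweeps=sweeps.sweeps - means)


def average_and_subtract(sweeps: SweepSet, n_rejected: int = 0) -> AveragedResponse:
    """Per-polarity means combined as ``(mean_A - mean_B) / 2``.

    Unequal surviving counts are allowed; each polarity is averaged over its
    own survivors.  Raises if either polarity is absent.
    """
    n_a = sweeps.count("A")
    n_b = sweeps.count("B")
    if n_a == 0 or n_b == 0:
        raise ValueError(
            f"both polarities required for subtraction (A: {n_a}, B: {n_b})"
        )
    avg_a = sweeps.sweeps[sweeps.polarity == "A"].mean(axis=0)
    avg_b = sweeps.sweeps[sweeps.polarity == "B"].mean(axis=0)
    return AveragedResponse(
        samples=(avg_a - avg_b) / 2.0,
        sampling_rate_hz=sweeps.sampling_rate_hz,
        epoch_window_ms=sweeps.epoch_window_ms,
        n_sweeps_used=(n_a, n_b),
        n_rejected=n_rejected,
    )


def preprocess_sweeps(
    sweeps: SweepSet,
    low_hz: float = 70.0,
    high_hz: float = 2000.0,
    threshold_uv: float = 30.0,
    baseline_window_ms: Tuple[float, float] = (-30.0, 0.0),
    zero_phase: bool = False,
) -> AveragedResponse:
    """Full per-subject pipeline: filter, reject, baseline, subtract-average."""
    filtered = bandpass_filter(sweeps, low_hz, high_hz, zero_phase=zero_phase)
    survivors, n_rejected = reject_artifacts(filtered, threshold_uv)
    corrected = baseline_correct(survivors, baseline_window_ms)
    return average_and_subtract(corrected, n_rejected=n_rejected)
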