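"""Report figures: grouped band bars and region spectra overlays.

Structural mirrors of the study-style summary graphics: per-band grouped
bars (mean +- 1 standard error across subjects per group) and per-region
average spectra overlaid per group with bar insets for the derived
features.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Mapping, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .preprocess import AveragedResponse
from .spectral import region_spectrum
from .synthetic import StimulusSpec

__all__ = ["plot_global_bands", "plot_region_spectra", "group_mean_sem"]

_BAND_ORDER = ["f0_amp", "f1_mean", "non_f1_mean", "mean_h"]
_BAND_LABELS = {
    "f0_amp": "F0",
    "f1_mean": "F1 (H3-H5)",
    "non_f1_mean": "Non-F1 (H2, H6)",
    "mean_h": "Harmonics (H2-H6)",
}


def group_mean_sem(
    features: pd.DataFrame, value: str
) -> pd.DataFrame:
    """Per-group mean and standard error of one feature column."""
    g = features.groupby("group", observed=True)[value]
    out = g.agg(["mean", "sem", "count"]).reset_index()
    return out


def plot_global_bands(features: pd.DataFrame, path: str | Path) -> Path:
    """Grouped bars per spectral band, averaged across regions, +-1 SEM."""
    subj = (
        features.groupby(["subject_id", "group"], observed=True)[_BAND_ORDER]
        .mean()
        .reset_index()
    )
    groups = sorted(subj["group"].unique())
    fig, ax = plt.subplots(figsize=(7, 4))
    width = 0.8 / len(groups)
    x = np.arange(len(_BAND_ORDER))
    for i, grp in enumerate(groups):
        sub = subj.loc[subj["group"] == grp, _BAND_ORDER]
        ax.bar(
            x + (i - (len(groups) - 1) / 2) * width,
            sub.mean().to_numpy(),
            width=width,
            yerr=sub.sem().to_numpy(),
            capsize=3,
            label=grp,
        )
    ax.set_xticks(x)
    ax.set_xticklabels([_BAND_LABELS[b] for b in _BAND_ORDER])
    ax.set_ylabel("Amplitude (uV)")
    ax.set_title("Spectral representation by band (regions averaged)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_region_spectra(
    responses: Mapping[str, Sequence[AveragedResponse]],
    spec: StimulusSpec,
    features: pd.DataFrame,
    path: str | Path,
    fmax_hz: float = 1200.0,
) -> Path:
    """Two-panel figure: mean consonant and vowel spectra per group, with
    per-region feature bars underneath (+-1 SEM)."""
    groups = sorted(responses)
    fig, axes = plt.subplots(2, 2, figsize=(10, 7))
    for col, (region, window) in enumerate(
        (("consonant", spec.consonant_window_ms), ("vowel", spec.vowel_window_ms))
    ):
        ax = axes[0][col]
        for grp in groups:
            spectra = [
                region_spectrum(r, window, region) for r in responses[grp]
            ]
            freqs = spectra[0].freqs_hz
            mean_amp = np.mean([s.amplitude for s in spectra], axis=0)
            keep = freqs <= fmax_hz
            ax.plot(freqs[keep], mean_amp[keep], lw=0.8, label=grp)
        ax.set_title(f"{region} spectrum")
        ax.set_xlabel("Frequency (Hz)")
        ax.set_ylabel("Amplitude (uV)")
        if col == 0:
            ax.legend(fontsize=7)

        bars = (
            ["f0_amp", "mean_h"]
            if region == "consonant"
            else ["f0_amp", "f1_mean", "non_f1_mean"]
        )
        axb = axes[1][col]
        sub = features.loc[features["region"] == region]
        width = 0.8 / len(groups)
        x = np.arange(len(bars))
        for i, grp in enumerate(groups):
            vals = sub.loc[sub["group"] == grp, bars]
            axb.bar(
                x + (i - (len(groups) - 1) / 2) * width,
                vals.mean().to_numpy(),
                width=width,
                yerr=vals.sem().to_numpy(),
                capsize=3,
                label=grp,
            )
        axb.set_xticks(x)
        axb.set_xticklabels([_BAND_LABELS[b] for b in bars], fontsize=8)
        axb.set_ylabel("Amplitude (uV)")
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
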