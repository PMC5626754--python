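"""File formats: sweep sets, averaged responses, tables, WAV, manifest.

Sweep-set files are plain text: a ``#``-prefixed key/value header (subject
id, group, sampling rate, epoch window, ordered polarity labels) followed
by a comma-delimited matrix, one sweep per row.  Averaged-response files
use the same header style with one sample per line.  All numeric output is
written with fixed formats so identical inputs produce identical bytes.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
from scipy.io import wavfile

from .preprocess import AveragedResponse, SweepSet

__all__ = [
    "write_sweepset",
    "read_sweepset",
    "write_averaged_response",
    "read_averaged_response",
    "write_wav",
    "read_wav",
    "sha256_file",
    "write_manifest",
    "read_manifest",
]

_FLOAT_FMT = "%.6g"


def _write_header(fh, meta: Dict[str, str]) -> None:
    for key, val in meta.items():
        fh.write(f"# {key} = {val}\n")


def _read_header(lines) -> Dict[str, str]:
    meta = {}
    for line in lines:
        if not line.startswith("#"):
            break
        key, _, val = line[1:].partition("=")
        meta[key.strip()] = val.strip()
    return meta


def write_sweepset(
    path: str | Path, sweeps: SweepSet, subject_id: str, group: str
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="\n") as fh:
        _write_header(
            fh,
            {
                "format": "ffrpipe-sweepset-v1",
                "subject_id": subject_id,
                "group": group,
                "sampling_rate_hz": repr(float(sweeps.sampling_rate_hz)),
                "epoch_window_ms": f"{sweeps.epoch_window_ms[0]!r},{sweeps.epoch_window_ms[1]!r}",
                "n_sweeps": str(sweeps.n_sweeps),
                "n_samples": str(sweeps.n_samples),
                "polarity": "".join(sweeps.polarity.tolist()),
            },
        )
        np.savetxt(fh, sweeps.sweeps, fmt=_FLOAT_FMT, delimiter=",")
    return path


def read_sweepset(path: str | Path) -> Tuple[SweepSet, Dict[str, str]]:
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    meta = _read_header(lines)
    if meta.get("format") != "ffrpipe-sweepset-v1":
        raise ValueError(f"{path}: not an ffrpipe sweep-set file")
    n_header = len(meta)
    data = np.loadtxt(lines[n_header:], delimiter=",", ndmin=2)
    e0, e1 = (float(v) for v in meta["epoch_window_ms"].split(","))
    sweeps = SweepSet(
        sweeps=data,
        polarity=np.array(list(meta["polarity"])),
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        epoch_window_ms=(e0, e1),
    )
    return sweeps, meta


def write_averaged_response(
    path: str | Path, response: AveragedResponse, subject_id: str, group: str
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="\n") as fh:
        _write_header(
            fh,
            {
                "format": "ffrpipe-average-v1",
                "subject_id": subject_id,
                "group": group,
                "sampling_rate_hz": repr(float(response.sampling_rate_hz)),
                "epoch_window_ms": f"{response.epoch_window_ms[0]!r},{response.epoch_window_ms[1]!r}",
                "n_sweeps_used_a": str(response.n_sweeps_used[0]),
                "n_sweeps_used_b": str(response.n_sweeps_used[1]),
                "n_rejected": str(response.n_rejected),
            },
        )
        np.savetxt(fh, response.samples, fmt="%.9g")
    return path


def read_averaged_response(
    path: str | Path,
) -> Tuple[AveragedResponse, Dict[str, str]]:
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    meta = _read_header(lines)
    if meta.get("format") != "ffrpipe-average-v1":
        raise ValueError(f"{path}: not an ffrpipe averaged-response file")
    samples = np.loadtxt(lines[len(meta):])
    e0, e1 = (float(v) for v in meta["epoch_window_ms"].split(","))
    resp = AveragedResponse(
        samples=samples,
        sampling_rate_hz=float(meta["sampling_rate_hz"]),
        epoch_window_ms=(e0, e1),
        n_sweeps_used=(int(meta["n_sweeps_used_a"]), int(meta["n_sweeps_used_b"])),
        n_rejected=int(meta["n_rejected"]),
    )
    return resp, meta


def write_wav(path: str | Path, waveform: np.ndarray, sampling_rate_hz: float) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    wavfile.write(path, int(round(sampling_rate_hz)), waveform.astype(np.float32))
    return path


def read_wav(path: str | Path) -> Tuple[np.ndarray, float]:
    rate, data = wavfile.read(path)
    return np.asarray(data, dtype=float), float(rate)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: str | Path, manifest: dict) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
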