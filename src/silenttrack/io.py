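"""Delimited-text readers/writers with JSON sidecars, and WAV support.

Stimulus signals and recordings are stored as TSV (one column per channel,
header row with names) plus a JSON sidecar carrying the sampling rate and
role/condition labels, so a run can be re-executed from files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .stimfeat import StimulusSignal
from .synthgen import SubjectRecording

__all__ = ["write_stimulus", "read_stimulus", "write_recording",
           "read_recording", "read_wav", "write_wav_carrier"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stimulus(sig: StimulusSignal, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({sig.role: sig.samples}).to_csv(path, sep="\t", index=False)
    _sidecar(path).write_text(json.dumps(
        {"rate": sig.rate, "role": sig.role}, indent=1))


def read_stimulus(path: str | Path) -> StimulusSignal:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    df = pd.read_csv(path, sep="\t")
    return StimulusSignal(samples=df.iloc[:, 0].to_numpy(),
                          rate=meta["rate"], role=meta["role"])


def write_recording(rec: SubjectRecording, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=rec.channel_names)
    df.to_csv(path, sep="\t", index=False)
    _sidecar(path).write_text(json.dumps(
        {"rate": rec.rate, "channel_roles": rec.channel_roles,
         "condition": rec.condition, "subject_id": rec.subject_id,
         "group": rec.group}, indent=1))


def read_recording(path: str | Path) -> SubjectRecording:
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    df = pd.read_csv(path, sep="\t")
    return SubjectRecording(data=df.to_numpy().T, rate=meta["rate"],
                            channel_roles=meta["channel_roles"],
                            condition=meta["condition"],
                            subject_id=meta["subject_id"],
                            group=meta["group"])


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Mono waveform in float; stereo is averaged to mono."""
    rate, data = wavfile.read(path)
    # integer PCM is not rescaled: envelope extraction is homogeneous
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data.mean(axis=1)
    return data, float(rate)


def write_wav_carrier(envelope: StimulusSignal, path: str | Path,
                      carrier_rate: float = 44100.0,
                      seed: int = 0) -> None:
    """Export a synthetic noise carrier amplitude-modulated by the
    envelope, so the envelope-extraction path can be exercised from WAV."""
    from scipy.signal import resample

    rng = np.random.default_rng(seed)
    n_out = int(round(envelope.duration * carrier_rate))
    env_up = np.clip(resample(envelope.samples, n_out), 0.0, None)
    carrier = rng.standard_normal(n_out)
    wave = env_up * carrier
    peak = np.abs(wave).max()
    if peak > 0:
        wave = wave / peak * 0.9
    wavfile.write(Path(path), int(carrier_rate),
                  (wave * 32767).astype(np.int16))
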