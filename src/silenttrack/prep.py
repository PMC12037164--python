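"""Broadband FIR filtering and fixed-length epoching.

Channel data and stimulus features are band-passed 0.1-12 Hz with a
zero-phase Hamming-window FIR filter applied by overlap-add (kernel length
6.6 times the reciprocal of the shortest transition band), then segmented
into non-overlapping 6-s epochs.  Filtering is applied to the continuous
data before epoching; stimulus features are carried alongside the channels
as extra rows so epoch alignment is guaranteed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .stimfeat import StimulusSignal
from .synthgen import SubjectRecording

__all__ = ["Epochs", "design_fir", "fir_bandpass", "epoch_segments",
           "assign_conditions", "preprocess_subject"]


@dataclass
class Epochs:
    """Epoched multichannel data (epochs x channels x samples).

    Channels may include stimulus-feature rows; ``channel_roles`` uses
    ``"stim:envelope"`` / ``"stim:lip"`` for those.  ``condition`` is a
    per-epoch label array.
    """

    data: np.ndarray
    rate: float
    epoch_length: float
    channel_names: list[str]
    channel_roles: list[str]
    condition: np.ndarray
    subject_id: str = "s00"
    group: str = "hearing"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.condition = np.asarray(self.condition)
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x samples")
        n_samp = int(round(self.epoch_length * self.rate))
        if self.data.shape[2] != n_samp:
            raise ValueError(
                f"epochs must have exactly {n_samp} samples, "
                f"got {self.data.shape[2]}")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("one name per channel required")
        if self.condition.shape[0] != self.data.shape[0]:
            raise ValueError("one condition label per epoch required")
        bad = set(self.condition) - {"forward", "backward"}
        if bad:
            raise ValueError(f"unknown condition labels: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def channel_index(self, name: str) -> int:
        return self.channel_names.index(name)


def design_fir(rate: float, hp: float, lp: float,
               transition_hp: float | None = None,
               transition_lp: float | None = None) -> np.ndarray:
    """Symmetric (linear-phase) Hamming-window band-pass FIR kernel.

    Kernel length is ``6.6 / min(transition) * rate`` samples, forced odd.
    Default transitions follow common MEG-toolbox practice: ``min(hp, 2)``
    Hz at the high-pass edge and 25% of ``lp`` at the low-pass edge; the
    length rule is applied to the shortest of the two.
    """
    if not 0 < hp < lp < rate / 2:
        raise ValueError(f"need 0 < hp < lp < rate/2, got ({hp}, {lp})")
    t_hp = min(hp, 2.0) if transition_hp is None else transition_hp
    t_lp = 0.25 * lp if transition_lp is None else transition_lp
    if t_hp <= 0 or t_lp <= 0:
        raise ValueError("transition widths must be positive")
    shortest = min(t_hp, t_lp)
    numtaps = int(round(6.6 / shortest * rate))
    if numtaps % 2 == 0:
        numtaps += 1
    return sps.firwin(numtaps, [hp, lp], window="hamming",
                      pass_zero=False, fs=rate)


def fir_bandpass(x: np.ndarray, rate: float, hp: float = 0.1, lp: float = 12.0,
                 transition_hp: float | None = None,
                 transition_lp: float | None = None) -> np.ndarray:
    """Zero-phase overlap-add FIR band-pass along the last axis.

    The symmetric kernel introduces a pure group delay which is compensated
    by centred alignment; the signal is reflect-padded by one kernel length
    before overlap-add and trimmed after, so recording edges do not bleed
    into the interior epochs.
    """
    h = design_fir(rate, hp, lp, transition_hp, transition_lp)
    x = np.asarray(x, dtype=float)
    one_d = x.ndim == 1
    x2 = np.atleast_2d(x)
    n = x2.shape[-1]
    if n <= h.size:
        raise ValueError(
            f"signal length {n} too short for FIR kernel of {h.size} "
            f"samples; need at least {h.size + 1} samples")
    pad = h.size
    xp = np.pad(x2, [(0, 0), (pad, pad)], mode="reflect")
    y = sps.oaconvolve(xp, h[None, :], mode="same", axes=-1)
    y = y[:, pad:pad + n]
    return y[0] if one_d else y


def _stack(recording: SubjectRecording,
           stimuli: dict[str, StimulusSignal] | None
           ) -> tuple[np.ndarray, list[str], list[str]]:
    """Stack channel rows and aligned stimulus rows into one matrix."""
    rows = [recording.data]
    names = list(recording.channel_names)
    roles = list(recording.channel_roles)
    n = recording.n_samples
    if stimuli:
        for key, sig in stimuli.items():
            if not np.isclose(sig.rate, recording.rate):
                raise ValueError(
                    f"stimulus '{key}' rate {sig.rate} != recording "
                    f"rate {recording.rate}")
            s = sig.samples[:n]
            if s.size < n:
                raise ValueError(f"stimulus '{key}' shorter than recording")
            rows.append(s[None, :])
            names.append(key)
            roles.append(f"stim:{sig.role}")
    return np.vstack(rows), names, roles


def _cut_epochs(matrix: np.ndarray, rate: float, epoch_length: float,
                names: list[str], roles: list[str],
                recording: SubjectRecording) -> Epochs:
    n_samp = int(round(epoch_length * rate))
    n_ep = matrix.shape[1] // n_samp
    if n_ep < 1:
        raise ValueError(
            f"recording of {matrix.shape[1]} samples shorter than one "
            f"{epoch_length}-s epoch ({n_samp} samples)")
    cut = matrix[:, : n_ep * n_samp]
    epochs = cut.reshape(matrix.shape[0], n_ep, n_samp).transpose(1, 0, 2)
    return Epochs(data=epochs.copy(), rate=rate, epoch_length=epoch_length,
                  channel_names=names, channel_roles=roles,
                  condition=np.repeat(recording.condition, n_ep),
                  subject_id=recording.subject_id, group=recording.group)


def epoch_segments(recording: SubjectRecording,
                   stimuli: dict[str, StimulusSignal] | None = None,
                   epoch_length: float = 6.0) -> Epochs:
    """Cut a recording (plus aligned stimulus features) into fixed epochs.

    Non-overlapping consecutive epochs; the trailing remainder is dropped;
    sample values are preserved exactly.
    """
    matrix, names, roles = _stack(recording, stimuli)
    return _cut_epochs(matrix, recording.rate, epoch_length, names, roles,
                       recording)


def preprocess_subject(recording: SubjectRecording,
                       stimuli: dict[str, StimulusSignal] | None = None,
                       hp: float = 0.1, lp: float = 12.0,
                       transition_hp: float | None = None,
                       transition_lp: float | None = None,
                       epoch_length: float = 6.0) -> Epochs:
    """FIR band-pass the continuous channels and stimulus features
    together, then epoch.  This is the standard preprocessing path ahead
    of the multitaper stage."""
    matrix, names, roles = _stack(recording, stimuli)
    filtered = fir_bandpass(matrix, recording.rate, hp=hp, lp=lp,
                            transition_hp=transition_hp,
                            transition_lp=transition_lp)
    return _cut_epochs(filtered, recording.rate, epoch_length, names, roles,
                       recording)


def assign_conditions(blocks: list[Epochs]) -> Epochs:
    """Concatenate per-block epochs; every epoch inherits its block's
    condition tag."""
    if not blocks:
        raise ValueError("no blocks given")
    first = blocks[0]
    for b in blocks[1:]:
        if b.channel_names != first.channel_names:
            raise ValueError("blocks must share channel layout")
        if not np.isclose(b.rate, first.rate) or \
                not np.isclose(b.epoch_length, first.epoch_length):
            raise ValueError("blocks must share rate and epoch length")
    return Epochs(
        data=np.concatenate([b.data for b in blocks], axis=0),
        rate=first.rate, epoch_length=first.epoch_length,
        channel_names=first.channel_names, channel_roles=first.channel_roles,
        condition=np.concatenate([b.condition for b in blocks]),
        subject_id=first.subject_id, group=first.group)
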