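"""Multitaper spectral decomposition and cross-spectral density.

Six-second epochs are projected onto discrete prolate spheroidal (Slepian)
tapers with +/-0.5 Hz spectral smoothing (time-halfbandwidth NW = 3, hence
K = 5 tapers) and Fourier coefficients are evaluated at the analysis grid
0.166...5 Hz in steps of 1/6 Hz (the Rayleigh spacing of a 6-s epoch).
Epochs and tapers are pooled as equally weighted independent estimates of
the cross-spectral density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import windows

from .prep import Epochs

__all__ = ["TaperedSpectra", "CSD", "default_freq_grid", "dpss_tapers",
           "mtm_spectra", "accumulate_csd"]

DEFAULT_HALF_BANDWIDTH = 0.5  # Hz


@dataclass
class TaperedSpectra:
    """Complex multitaper Fourier coefficients.

    ``coeffs`` has shape (epochs, tapers, channels, freqs).  Channel names,
    roles and per-epoch condition labels are carried through from the
    epochs for downstream selection.
    """

    coeffs: np.ndarray
    freqs: np.ndarray
    half_bandwidth: float
    rate: float
    channel_names: list[str]
    channel_roles: list[str]
    condition: np.ndarray
    subject_id: str = "s00"
    group: str = "hearing"

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if self.freqs[0] <= 0 or self.freqs[-1] >= self.rate / 2:
            raise ValueError("freqs must lie in (0, rate/2)")

    @property
    def n_tapers(self) -> int:
        return self.coeffs.shape[1]

    def select(self, condition: str) -> "TaperedSpectra":
        """Spectra restricted to epochs of one condition."""
        mask = self.condition == condition
        if not mask.any():
            raise ValueError(f"no epochs with condition {condition!r}")
        return TaperedSpectra(
            coeffs=self.coeffs[mask], freqs=self.freqs,
            half_bandwidth=self.half_bandwidth, rate=self.rate,
            channel_names=self.channel_names,
            channel_roles=self.channel_roles,
            condition=self.condition[mask],
            subject_id=self.subject_id, group=self.group)


@dataclass
class CSD:
    """Cross-spectral density matrices, one Hermitian channels x channels
    matrix per frequency, pooled over ``n_est = epochs * tapers`` equally
    weighted estimates."""

    matrices: np.ndarray  # (freqs, channels, channels), complex
    freqs: np.ndarray
    n_est: int
    channel_names: list[str]

    def index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            return self.channel_names.index(channel)
        return int(channel)


def default_freq_grid(epoch_length: float = 6.0,
                      f_max: float = 5.0) -> np.ndarray:
    """Multiples of the Rayleigh frequency 1/epoch_length up to f_max
    (0.166, 0.333, ... 5.0 Hz for the defaults: 30 bins)."""
    step = 1.0 / epoch_length
    n = int(np.floor(f_max / step + 1e-9))
    return step * np.arange(1, n + 1)


def dpss_tapers(n_samples: int, time_halfbandwidth: float) -> np.ndarray:
    """Orthonormal Slepian tapers, K = floor(2*NW) - 1.

    Each retained taper has spectral concentration > 0.9 within the
    half-bandwidth, the standard multitaper retention rule.
    """
    if n_samples < 8:
        raise ValueError("n_samples must be >= 8")
    if time_halfbandwidth < 1:
        raise ValueError("time_halfbandwidth (NW) must be >= 1")
    k = int(np.floor(2 * time_halfbandwidth)) - 1
    if k < 1:
        raise ValueError(
            f"NW={time_halfbandwidth} yields no usable tapers")
    tapers, ratios = windows.dpss(n_samples, time_halfbandwidth, Kmax=k,
                                  return_ratios=True)
    if np.any(ratios <= 0.9):
        raise ValueError(
            f"taper concentration below 0.9: {ratios}")
    return tapers


def mtm_spectra(epochs: Epochs, freqs: np.ndarray | None = None,
                half_bandwidth: float = DEFAULT_HALF_BANDWIDTH
                ) -> TaperedSpectra:
    """Tapered Fourier coefficients at exactly the requested grid
    frequencies (zero-padded-DFT evaluation), per epoch, taper and channel.
    """
    T = epochs.epoch_length
    if freqs is None:
        freqs = default_freq_grid(T)
    freqs = np.asarray(freqs, dtype=float)
    rayleigh = 1.0 / T
    if np.any(freqs < rayleigh - 1e-9):
        raise ValueError(
            f"frequencies below the Rayleigh resolution {rayleigh:.4f} Hz "
            "cannot be estimated from these epochs")
    step = np.min(np.diff(freqs)) if freqs.size > 1 else rayleigh
    if step < rayleigh - 1e-9:
        raise ValueError(
            f"grid step {step:.4f} Hz below the Rayleigh resolution; "
            f"minimum step is {rayleigh:.4f} Hz")
    if np.any(freqs >= epochs.rate / 2):
        raise ValueError("frequencies must be below the Nyquist rate")
    n = epochs.data.shape[2]
    nw = T * half_bandwidth
    tapers = dpss_tapers(n, nw)
    t = np.arange(n) / epochs.rate
    basis = np.exp(-2j * np.pi * freqs[:, None] * t[None, :])  # (F, n)
    tapered = epochs.data[:, None, :, :] * tapers[None, :, None, :]
    coeffs = np.einsum("ekcn,fn->ekcf", tapered, basis, optimize=True)
    return TaperedSpectra(
        coeffs=coeffs, freqs=freqs, half_bandwidth=half_bandwidth,
        rate=epochs.rate, channel_names=list(epochs.channel_names),
        channel_roles=list(epochs.channel_roles),
        condition=epochs.condition.copy(),
        subject_id=epochs.subject_id, group=epochs.group)


def accumulate_csd(spectra: TaperedSpectra) -> CSD:
    """Pool epochs and tapers into per-frequency cross-spectral matrices:
    S(f) = mean over estimates of x(f) x(f)^H."""
    ep, k, _, _ = spectra.coeffs.shape
    n_est = ep * k
    if n_est < 2:
        raise ValueError(
            "at least 2 estimates (epochs x tapers) are required; "
            "coherence from a single estimate is degenerate (identically 1)")
    x = spectra.coeffs  # (e, k, c, f)
    mats = np.einsum("ekaf,ekbf->fab", x, np.conj(x), optimize=True) / n_est
    return CSD(matrices=mats, freqs=spectra.freqs, n_est=n_est,
               channel_names=list(spectra.channel_names))
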