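"""Stimulus feature extraction.

The acoustic speech envelope is computed with a cochlear filterbank:
nine frequency bands equidistant on the cochlear frequency-position map
between 100 and 10,000 Hz, each band-pass filtered with a fourth-order
Butterworth filter, rectified via the Hilbert analytic signal, averaged
across bands, and resampled to the analysis rate (150 Hz).  Lip-area
traces recorded at video rate (50 Hz) are brought to the same rate with
FFT-based band-limited resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "StimulusSignal",
    "BandSpec",
    "cochlear_band_edges",
    "extract_envelope",
    "fft_resample",
]

# Liberman (1982) cat frequency-position map, rescaled so that the apex-to-base
# position interval [0, 1] spans up to 20 kHz (the human audible range), as in
# the Chimera filterbank convention:  f(x) = A * (10**(a*x) - k).
_CAT_A = 2.1
_CAT_K = 0.8
_F_MAX = 20000.0
_MAP_SCALE = _F_MAX / (10.0 ** _CAT_A - _CAT_K)


@dataclass
class StimulusSignal:
    """A single stimulus feature time series.

    Parameters
    ----------
    samples : ndarray
        Feature values, arbitrary units.
    rate : float
        Sampling rate in Hz.
    role : str
        Either ``"envelope"`` (non-negative acoustic envelope) or ``"lip"``
        (lip-area trace).
    """

    samples: np.ndarray
    rate: float
    role: str = "envelope"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError(f"rate must be positive, got {self.rate}")
        if self.role not in ("envelope", "lip"):
            raise ValueError(f"role must be 'envelope' or 'lip', got {self.role!r}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.role == "envelope" and self.samples.size and self.samples.min() < 0:
            raise ValueError("envelope samples must be non-negative")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.rate


@dataclass
class BandSpec:
    """Filterbank band edges (n_bands + 1 ordered frequencies in Hz)."""

    edges: np.ndarray
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("band edges must be strictly increasing")

    @property
    def n_bands(self) -> int:
        return self.edges.size - 1

    @property
    def edges_hz(self) -> np.ndarray:
        """Edges rounded to integer Hz, for reporting."""
        return np.round(self.edges).astype(int)


def _cochlear_position(freq):
    """Position (fraction of basilar-membrane length) for frequency in Hz."""
    return np.log10(np.asarray(freq, dtype=float) / _MAP_SCALE + _CAT_K) / _CAT_A


def _cochlear_frequency(pos):
    """Inverse map: frequency in Hz at position ``pos`` in [0, 1]."""
    return _MAP_SCALE * (10.0 ** (_CAT_A * np.asarray(pos, dtype=float)) - _CAT_K)


def cochlear_band_edges(f_lo: float = 100.0, f_hi: float = 10000.0,
                        n_bands: int = 9) -> BandSpec:
    """Band edges equidistant on the cochlear frequency-position map.

    The frequency range endpoints are mapped to basilar-membrane positions,
    ``n_bands + 1`` equally spaced positions are taken, and mapped back to
    frequency.  With the default 100-10,000 Hz range and nine bands the
    rounded edges are 100, 220, 402, 679, 1103, 1748, 2731, 4231, 6516,
    10000 Hz.
    """
    if n_bands < 1:
        raise ValueError(f"n_bands must be >= 1, got {n_bands}")
    if not 0 < f_lo < f_hi:
        raise ValueError(f"need 0 < f_lo < f_hi, got ({f_lo}, {f_hi})")
    x = np.linspace(_cochlear_position(f_lo), _cochlear_position(f_hi), n_bands + 1)
    edges = _cochlear_frequency(x)
    # pin the endpoints exactly: float round-trip can drift in the last ulp
    edges[0], edges[-1] = f_lo, f_hi
    return BandSpec(edges=edges, f_lo=f_lo, f_hi=f_hi)


def extract_envelope(audio: np.ndarray, rate: float,
                     bands: BandSpec | None = None,
                     out_rate: float = 150.0) -> StimulusSignal:
    """Full-band acoustic envelope via the cochlear filterbank.

    Per band: zero-phase fourth-order Butterworth band-pass, magnitude of
    the Hilbert analytic signal; the per-band envelopes are averaged with
    equal weights and resampled to ``out_rate``.

    Parameters
    ----------
    audio : ndarray
        Mono waveform, or (n_samples, 2) stereo which is averaged to mono.
    rate : float
        Audio sampling rate in Hz; must exceed twice the top band edge.
    bands : BandSpec, optional
        Defaults to nine cochlear-map bands over 100-10,000 Hz.
    out_rate : float
        Output envelope rate in Hz (default 150).
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim == 2:
        audio = audio.mean(axis=1)
    if audio.ndim != 1:
        raise ValueError("audio must be 1-D (or 2-D stereo)")
    if bands is None:
        bands = cochlear_band_edges()
    if rate <= 2 * bands.edges[-1]:
        raise ValueError(
            f"audio rate {rate} Hz too low for top band edge "
            f"{bands.edges[-1]:.0f} Hz (need > {2 * bands.edges[-1]:.0f} Hz)")
    env = np.zeros_like(audio)
    for lo, hi in zip(bands.edges[:-1], bands.edges[1:]):
        sos = sps.butter(4, [lo, hi], btype="bandpass", output="sos", fs=rate)
        band = sps.sosfiltfilt(sos, audio)
        env += np.abs(sps.hilbert(band))
    env /= bands.n_bands
    out = _resample_array(env, rate, out_rate)
    # FFT resampling can ring a hair below zero at sharp transients
    np.clip(out, 0.0, None, out=out)
    return StimulusSignal(samples=out, rate=out_rate, role="envelope")


def _resample_array(x: np.ndarray, in_rate: float, out_rate: float) -> np.ndarray:
    n_out = int(round(x.size * out_rate / in_rate))
    if n_out == x.size and np.isclose(in_rate, out_rate):
        return x.copy()
    return sps.resample(x, n_out)


def fft_resample(x: StimulusSignal, out_rate: float) -> StimulusSignal:
    """Fourier-domain (zero-pad / truncate) resampling of a stimulus signal.

    Band-limited content below the lower Nyquist frequency is preserved
    exactly; the length scales by ``out_rate / x.rate`` (rounded).
    """
    if out_rate <= 0:
        raise ValueError(f"out_rate must be positive, got {out_rate}")
    out = _resample_array(x.samples, x.rate, out_rate)
    if x.role == "envelope":
        np.clip(out, 0.0, None, out=out)
    return StimulusSignal(samples=out, rate=out_rate, role=x.role)
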