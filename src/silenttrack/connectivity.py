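"""Coherence, partial coherence, condition contrasts and band averages.

Coherence is the magnitude-squared coherence
``C_ab(f) = |S_ab(f)|**2 / (S_aa(f) S_bb(f))`` in [0, 1]; for independent
signals its expectation is the chance level ``1 / n_est``.  Partial
coherence removes, per frequency, the linear contribution of a third
channel from all entries of the cross-spectral matrix (Schur complement)
before forming the same ratio — here used to partialize the ocular channel
out of channel-stimulus coherence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .spectral import CSD

__all__ = ["CoherenceSpectrum", "ContrastSpectrum", "coherence",
           "partial_coherence", "condition_contrast", "band_average",
           "roi_peak_select"]

_EPS = 1e-300


@dataclass
class CoherenceSpectrum:
    """Per-frequency (partial) coherence for one channel pair.

    Frequencies with a degenerate (zero-power) denominator are NaN, and are
    excluded from band averages rather than zero-filled.
    """

    values: np.ndarray
    freqs: np.ndarray
    pair: tuple
    n_est: int
    partialized: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("coherence values must lie in [0, 1]")


@dataclass
class ContrastSpectrum:
    """Forward-minus-backward coherence difference per frequency."""

    values: np.ndarray
    freqs: np.ndarray
    pair: tuple
    partialized: str | None = None


def coherence(csd: CSD, a: int | str, b: int | str) -> CoherenceSpectrum:
    """Magnitude-squared coherence between channels ``a`` and ``b``."""
    ia, ib = csd.index(a), csd.index(b)
    if ia == ib:
        raise ValueError("coherence of a channel with itself is trivially 1")
    saa = csd.matrices[:, ia, ia].real
    sbb = csd.matrices[:, ib, ib].real
    sab = csd.matrices[:, ia, ib]
    return CoherenceSpectrum(
        values=_msc(sab, saa, sbb), freqs=csd.freqs,
        pair=(_name(csd, ia), _name(csd, ib)), n_est=csd.n_est)


def partial_coherence(csd: CSD, a: int | str, b: int | str,
                      z: int | str) -> CoherenceSpectrum:
    """Coherence between ``a`` and ``b`` with channel ``z`` partialized out.

    All three entries S_aa, S_bb, S_ab are replaced by their Schur
    complements ``S_xy - S_xz S_zz^-1 S_zy`` before forming the ratio.  A
    zero-power ``z`` at some frequency is treated as a no-op regressor
    there (with a warning), so the partial equals the raw coherence.
    """
    ia, ib, iz = csd.index(a), csd.index(b), csd.index(z)
    if iz in (ia, ib):
        raise ValueError("partialized channel must differ from the pair")
    if ia == ib:
        raise ValueError("coherence of a channel with itself is trivially 1")
    m = csd.matrices
    szz = m[:, iz, iz].real
    degenerate = szz <= 0
    if degenerate.any():
        warnings.warn(
            f"zero-power partial channel at {int(degenerate.sum())} "
            "frequencies; treating as no-op regressor there", RuntimeWarning)
    inv_szz = np.where(degenerate, 0.0, 1.0 / np.where(degenerate, 1.0, szz))

    def schur(x, y):
        return m[:, x, y] - m[:, x, iz] * inv_szz * m[:, iz, y]

    saa = schur(ia, ia).real
    sbb = schur(ib, ib).real
    sab = schur(ia, ib)
    return CoherenceSpectrum(
        values=_msc(sab, saa, sbb), freqs=csd.freqs,
        pair=(_name(csd, ia), _name(csd, ib)), n_est=csd.n_est,
        partialized=_name(csd, iz))


def _msc(sab: np.ndarray, saa: np.ndarray, sbb: np.ndarray) -> np.ndarray:
    denom = saa * sbb
    bad = denom <= _EPS
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.abs(sab) ** 2 / np.where(bad, np.nan, denom)
    # numerical round-off can push an exact-copy pair a few ulp past 1
    return np.clip(c, 0.0, 1.0)


def _name(csd: CSD, i: int) -> str:
    return csd.channel_names[i] if csd.channel_names else str(i)


def condition_contrast(coh_f: CoherenceSpectrum,
                       coh_b: CoherenceSpectrum) -> ContrastSpectrum:
    """Forward minus backward coherence, elementwise on a shared grid."""
    if coh_f.pair != coh_b.pair or coh_f.partialized != coh_b.partialized:
        raise ValueError("contrast requires the same channel pair")
    if coh_f.freqs.shape != coh_b.freqs.shape or \
            not np.allclose(coh_f.freqs, coh_b.freqs):
        raise ValueError("frequency grids do not match")
    return ContrastSpectrum(values=coh_f.values - coh_b.values,
                            freqs=coh_f.freqs, pair=coh_f.pair,
                            partialized=coh_f.partialized)


def band_average(spec: CoherenceSpectrum | ContrastSpectrum,
                 band: tuple, include_upper: bool = False) -> float:
    """Unweighted mean over grid frequencies with f_lo <= f < f_hi
    (``include_upper`` switches to a closed upper edge).  NaN-flagged
    frequencies are excluded."""
    lo, hi = band
    mask = (spec.freqs >= lo - 1e-9)
    mask &= (spec.freqs <= hi + 1e-9) if include_upper \
        else (spec.freqs < hi - 1e-9)
    if not mask.any():
        raise ValueError(f"band {band} does not intersect the grid")
    vals = spec.values[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"all frequencies in band {band} are undefined")
    return float(vals.mean())


def roi_peak_select(contrast_by_channel: dict[str, ContrastSpectrum],
                    roi: list[str], criterion_band: tuple) -> str:
    """Channel within the ROI maximizing the band-averaged
    forward-minus-backward contrast; ties break deterministically by ROI
    order."""
    if not roi:
        raise ValueError("roi must be non-empty")
    best, best_val = None, -np.inf
    for ch in roi:
        val = band_average(contrast_by_channel[ch], criterion_band)
        if val > best_val:
            best, best_val = ch, val
    return best
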