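"""Shared test utilities."""

import numpy as np

from silenttrack.prep import Epochs, epoch_segments
from silenttrack.spectral import accumulate_csd, mtm_spectra


def modulation_peak(samples, rate, lo=2.0, hi=5.0):
    """Argmax frequency of the modulation spectrum in [lo, hi] Hz."""
    x = np.asarray(samples, dtype=float)
    x = x - x.mean()
    f = np.fft.rfftfreq(x.size, 1.0 / rate)
    p = np.abs(np.fft.rfft(x)) ** 2
    m = (f >= lo) & (f <= hi)
    return float(f[m][np.argmax(p[m])])


def white_noise_epochs(rng, n_epochs=10, n_channels=2, rate=150.0,
                       epoch_length=6.0, names=None, roles=None):
    """Independent white-noise epochs for chance-level checks."""
    n = int(epoch_length * rate)
    data = rng.standard_normal((n_epochs, n_channels, n))
    names = names or [f"ch{i}" for i in range(n_channels)]
    roles = roles or ["neural"] * (n_channels - 1) + ["ocular"]
    return Epochs(data=data, rate=rate, epoch_length=epoch_length,
                  channel_names=names, channel_roles=roles,
                  condition=np.array(["forward"] * n_epochs))


def csd_of_recording(rec, stimuli=None, epoch_length=6.0):
    """Recording -> epochs -> multitaper CSD (no broadband FIR)."""
    ep = epoch_segments(rec, stimuli, epoch_length=epoch_length)
    return accumulate_csd(mtm_spectra(ep))
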