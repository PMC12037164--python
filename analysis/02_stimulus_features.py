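"""Exercise the acoustic-envelope path: cochlear band edges and envelope
extraction from a synthetic WAV carrier.

Prints the nine cochlear-map band edges, writes a synthetic
envelope-modulated noise carrier to WAV, re-extracts the envelope through
the full filterbank path, and reports the modulation-spectrum peak (which
should sit at the ~3.3 Hz syllable rate) plus the correlation between the
original and re-extracted envelopes.
"""

import sys
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "features"

from silenttrack import io as stio
from silenttrack.stimfeat import cochlear_band_edges, extract_envelope
from silenttrack.synthgen import make_speech_envelope


def modulation_peak(samples: np.ndarray, rate: float,
                    lo: float = 2.0, hi: float = 5.0) -> float:
    x = samples - samples.mean()
    f = np.fft.rfftfreq(x.size, 1.0 / rate)
    p = np.abs(np.fft.rfft(x)) ** 2
    m = (f >= lo) & (f <= hi)
    return float(f[m][np.argmax(p[m])])


def main(seed: int = 7) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    bands = cochlear_band_edges(100, 10000, 9)
    print("cochlear band edges (Hz):", bands.edges_hz.tolist())

    env = make_speech_envelope(duration=30.0, rate=150.0, seed=seed)
    wav = OUT / "carrier.wav"
    stio.write_wav_carrier(env, wav, seed=seed)
    audio, rate = stio.read_wav(wav)
    env2 = extract_envelope(audio, rate, bands=bands, out_rate=150.0)
    stio.write_stimulus(env2, OUT / "envelope_extracted.tsv")

    n = min(env.samples.size, env2.samples.size)
    r = np.corrcoef(env.samples[:n], env2.samples[:n])[0, 1]
    pk = modulation_peak(env2.samples, 150.0)
    print(f"re-extracted envelope: modulation peak {pk:.2f} Hz "
          f"(syllable rate 3.3 Hz), correlation with original r = {r:.3f}")


if __name__ == "__main__":
    main(*(int(a) for a in sys.argv[1:]))
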