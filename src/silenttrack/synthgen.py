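"""Synthetic stimuli, subject recordings, and multi-group cohorts.

The generator produces data with the statistical structure the analysis
assumes, so every downstream stage is testable without MEG recordings:

* a non-negative speech envelope with a ~3.3 Hz syllable-rate modulation
  peak and ~0.25 Hz sentence-level gating;
* a lip-area trace at video rate (50 Hz) correlated with the envelope;
* per subject and condition, multichannel recordings in which "neural"
  channels and one "ocular" channel couple to a band-limited component of
  the envelope on top of 1/f background noise, with a stereotyped blink
  train superposed on the ocular channel;
* a backward condition driven by the time-reversed stimulus, so coherence
  with the forward-order envelope is at chance.

The stimulus model has two latent components: a lip-visible component
(which the lip trace follows) and an acoustic-only component; the
composite speech envelope mixes both.  Channels couple exclusively to the
acoustic-only component — silent-speech tracking is specific to the
unheard acoustic features, not to the visible lip movements — so
channel-lip coherence is exactly at chance by construction.

The ``coupling_strength`` parameter is calibrated so that, within the
coupling band, the expected channel-driver coherence approximately equals
the strength value (in-band SNR = s / (1 - s)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.stats import rankdata as stats_rankdata

from .stimfeat import StimulusSignal, fft_resample

__all__ = [
    "SubjectRecording",
    "CohortSpec",
    "SubjectData",
    "make_speech_envelope",
    "make_lip_signal",
    "make_subject_recording",
    "make_cohort",
    "make_common_source_pair",
]

GROUPS = ("hearing", "dhh", "congenital")
CONDITIONS = ("forward", "backward")


@dataclass
class SubjectRecording:
    """Channels x samples for one subject and condition.

    Exactly one channel carries the ``"ocular"`` role (the blink-dominated
    vertical eye component); the rest are ``"neural"`` virtual channels.
    """

    data: np.ndarray
    rate: float
    channel_roles: list[str]
    condition: str
    subject_id: str = "s00"
    group: str = "hearing"

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.channel_roles):
            raise ValueError("one role per channel required")
        if sum(r == "ocular" for r in self.channel_roles) != 1:
            raise ValueError("exactly one ocular channel required")
        if any(r not in ("neural", "ocular") for r in self.channel_roles):
            raise ValueError("channel roles must be 'neural' or 'ocular'")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def ocular_index(self) -> int:
        return self.channel_roles.index("ocular")

    @property
    def channel_names(self) -> list[str]:
        k = 0
        names = []
        for r in self.channel_roles:
            if r == "ocular":
                names.append("ocular")
            else:
                names.append(f"neural{k:02d}")
                k += 1
        return names


def _default_strengths() -> dict:
    # Forward-only coupling; DHH > hearing > congenital (= none), matching
    # the qualitative group ordering the statistics must detect.  Magnitudes
    # are free parameters chosen for desk-scale power; the realized
    # channel-envelope coherence is several-fold smaller than the strength
    # because of lip orthogonalization and smoothing dilution (see the
    # methods note), so the defaults sit high within [0, 1).
    return {
        "hearing": {"forward": 0.6, "backward": 0.0},
        "dhh": {"forward": 0.75, "backward": 0.0},
        "congenital": {"forward": 0.0, "backward": 0.0},
    }


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    ``coupling_strength[group][condition]`` is the target in-band coherence
    between channels and the band-limited stimulus driver, in [0, 1).
    ``coupling_band`` defaults to 0.33-0.83 Hz, the frequency range of the
    reported ocular tracking effect.  Group sizes default to the study's
    (49 hearing, 18 acquired DHH, 7 congenitally deaf).
    """

    n_per_group: dict = field(
        default_factory=lambda: {"hearing": 49, "dhh": 18, "congenital": 7})
    coupling_band: tuple = (0.33, 0.83)
    coupling_strength: dict = field(default_factory=_default_strengths)
    ocular_gain: float = 0.8          # ocular strength relative to neural
    blink_rate: float = 0.2           # Hz, Poisson event rate
    blink_envelope_coupling: float = 0.3  # trough timing, forward only
    noise_exponent: float = 1.0       # 1/f**exponent background
    duration: float = 120.0           # s per condition
    rate: float = 150.0               # Hz, analysis rate
    n_neural: int = 4
    lip_corr: float = 0.6             # corr(lip, composite envelope)
    syllable_rate: float = 3.3        # Hz
    sentence_rate: float = 0.25       # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.coupling_band
        if not 0 < lo < hi:
            raise ValueError(f"need 0 < f_lo < f_hi, got {self.coupling_band}")
        for g, by_cond in self.coupling_strength.items():
            for c, s in by_cond.items():
                if not 0 <= s <= 1:
                    raise ValueError(
                        f"coupling_strength[{g}][{c}]={s} outside [0, 1]")

    def strength(self, group: str, condition: str) -> float:
        return self.coupling_strength.get(group, {}).get(condition, 0.0)


@dataclass
class SubjectData:
    """One subject's forward/backward recordings plus aligned stimuli.

    ``stimuli[condition]`` holds the envelope and lip signals *as presented*
    in that condition (time-reversed for backward), both at the recording
    rate; the lip trace is generated at 50 Hz and FFT-upsampled.
    """

    subject_id: str
    group: str
    recordings: dict
    stimuli: dict


# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------

def make_speech_envelope(duration: float, rate: float = 150.0,
                         syllable_rate: float = 3.3,
                         sentence_rate: float = 0.25,
                         seed: int | np.random.Generator = 0) -> StimulusSignal:
    """Quasi-periodic syllable pulse train with sentence-level gating.

    Syllable events sit on a jittered lattice around multiples of
    ``1 / syllable_rate``; pulses are convolved with a 100-ms Hann kernel
    and multiplied by a smoothed on/off sentence envelope (duty cycle 0.8)
    at ``sentence_rate``, plus a small positive noise floor.  The
    modulation spectrum peaks near the syllable rate with additional
    sub-1-Hz energy from the sentence gating.
    """
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    if syllable_rate <= 0 or sentence_rate <= 0:
        raise ValueError("syllable_rate and sentence_rate must be positive")
    if duration <= 2.0 / sentence_rate:
        raise ValueError(
            f"duration must exceed two sentence periods "
            f"({2.0 / sentence_rate:.1f} s)")
    if rate < 8 * syllable_rate:
        raise ValueError("rate too low to resolve the syllable rate")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))

    # syllable event train: jittered lattice, i.e. event i at i*T + jitter
    # with jitter SD 0.2*T.  Unlike renewal (cumulative-ISI) timing, whose
    # spectral peak sits a few percent above the nominal rate, the lattice
    # keeps the modulation peak exactly at syllable_rate while the jitter
    # broadens it like natural speech.
    period = 1.0 / syllable_rate
    n_events = int(duration * syllable_rate) + 1
    times = period * np.arange(n_events) \
        + rng.normal(0.0, 0.2 * period, size=n_events)
    times = np.sort(times[(times >= 0) & (times < duration)])
    train = np.zeros(n)
    idx = np.minimum((times * rate).astype(int), n - 1)
    np.add.at(train, idx, 1.0)

    kernel = sps.windows.hann(max(int(round(0.1 * rate)), 3))
    syllables = np.convolve(train, kernel, mode="same")

    # sentence gating: smoothed on/off wave with duty cycle 0.8 and
    # gamma-jittered sentence durations (CV ~ 0.3) around 1/sentence_rate,
    # so the sub-1-Hz gating power is broadband rather than a line train
    s_period = 1.0 / sentence_rate
    gate = np.zeros(n)
    pos = -rng.uniform(0.0, s_period)  # random phase of the first sentence
    shape = 1.0 / 0.3 ** 2
    while pos < duration:
        length = rng.gamma(shape, s_period / shape)
        on = slice(max(int(pos * rate), 0),
                   max(int((pos + 0.8 * length) * rate), 0))
        gate[on] = 1.0
        pos += length
    smooth = sps.windows.hann(max(int(round(0.3 * rate)), 3))
    gate = np.convolve(gate, smooth / smooth.sum(), mode="same")

    floor = 0.02 * np.abs(rng.standard_normal(n)) + 0.01
    env = syllables * gate + floor
    return StimulusSignal(samples=np.clip(env, 0.0, None), rate=rate,
                          role="envelope")


def make_lip_signal(envelope: StimulusSignal, target_corr: float = 0.6,
                    lag: float = 0.0, rate: float = 50.0,
                    seed: int | np.random.Generator = 0) -> StimulusSignal:
    """Lip-area trace correlated with the (lagged, resampled) envelope.

    The lip trace is a mixture of the standardized envelope and an
    independent envelope realization (so the two share a common spectral
    shape), mixed to the requested Pearson correlation:
    ``lip = rho * env + sqrt(1 - rho**2) * env_indep``.  A positive ``lag``
    delays the lip trace relative to the envelope.
    """
    if envelope.role != "envelope":
        raise ValueError("input signal must have role 'envelope'")
    if abs(target_corr) > 1:
        raise ValueError(f"|target_corr| must be <= 1, got {target_corr}")
    rng = np.random.default_rng(seed)
    z = fft_resample(envelope, rate).samples
    z = _standardize(z)
    shift = int(round(lag * rate))
    if shift:
        z = np.roll(z, shift)
    rho = float(target_corr)
    if abs(rho) < 1.0:
        dur = z.size / rate
        indep = make_speech_envelope(dur, rate=rate, seed=rng)
        noise = _standardize(indep.samples[: z.size])
        y = rho * z + math.sqrt(1.0 - rho ** 2) * noise
    else:
        y = rho * z
    return StimulusSignal(samples=y, rate=rate, role="lip")


# ---------------------------------------------------------------------------
# noise, blinks, coupling
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return x - x.mean()
    return (x - x.mean()) / sd


def one_over_f_noise(n: int, exponent: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f**exponent power spectrum, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n)
    return _standardize(x)


def blink_kernel(rate: float) -> np.ndarray:
    """Stereotyped 300-ms biphasic blink pulse (large positive lobe plus a
    small undershoot), as seen on the vertical eye component."""
    n_up = max(int(round(0.20 * rate)), 3)
    n_down = max(int(round(0.10 * rate)), 2)
    up = sps.windows.hann(n_up)
    down = -0.25 * sps.windows.hann(n_down)
    return np.concatenate([up, down])


def make_blink_train(duration: float, rate: float, blink_rate: float,
                     rng: np.random.Generator,
                     amplitude: float = 8.0,
                     envelope: np.ndarray | None = None,
                     envelope_coupling: float = 0.0,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Poisson blink train convolved with the blink kernel.

    Returns (signal, event_times).  Events closer than 400 ms are thinned
    so pulses do not fuse.  With ``envelope_coupling`` in (0, 1] and an
    ``envelope`` given, events are timed preferentially to envelope
    troughs (thinned inhomogeneous Poisson process whose acceptance
    probability falls linearly with the envelope rank), keeping the
    overall rate at ``blink_rate``.
    """
    n = int(round(duration * rate))
    out = np.zeros(n)
    if blink_rate <= 0:
        return out, np.array([])
    c = float(np.clip(envelope_coupling, 0.0, 1.0))
    eff_rate = blink_rate if (c == 0 or envelope is None) \
        else blink_rate / (1.0 - c / 2.0)
    isi = rng.exponential(1.0 / eff_rate,
                          size=int(duration * eff_rate * 2) + 10)
    times = np.cumsum(isi)
    times = times[times < duration - 0.35]
    if c > 0 and envelope is not None and times.size:
        # gate on the slow (sub-1-Hz, sentence-level) envelope so the bias
        # survives the ~0.1 s offset between blink onset and pulse peak
        sos = sps.butter(4, 1.0, btype="lowpass", output="sos", fs=rate)
        slow = sps.sosfiltfilt(sos, envelope)
        # acceptance falls from 1 at the envelope minimum to 1-c at the max
        u = stats_rankdata(slow) / slow.size
        idx = np.minimum((times * rate).astype(int), envelope.size - 1)
        accept = rng.random(times.size) < 1.0 - c * u[idx]
        times = times[accept]
    if times.size:
        keep = [times[0]]
        for t in times[1:]:
            if t - keep[-1] >= 0.4:
                keep.append(t)
        times = np.asarray(keep)
    kern = blink_kernel(rate)
    train = np.zeros(n)
    idx = (times * rate).astype(int)
    train[idx] = amplitude
    out = np.convolve(train, kern, mode="full")[:n]
    return out, times


def _bandpass(x: np.ndarray, band: tuple, rate: float) -> np.ndarray:
    sos = sps.butter(4, list(band), btype="bandpass", output="sos", fs=rate)
    return sps.sosfiltfilt(sos, x)


def _coupling_driver(source: np.ndarray, band: tuple,
                     rate: float) -> np.ndarray:
    """Unit-variance band-limited coupling driver."""
    return _standardize(_bandpass(source, band, rate))


def _gain_for_strength(strength: float, noise: np.ndarray, band: tuple,
                       rate: float) -> float:
    """Driver gain so that in-band SNR = s/(1-s), i.e. expected in-band
    coherence with the (unit-variance) driver is ~ s."""
    if strength <= 0:
        return 0.0
    strength = min(strength, 0.95)
    noise_band_sd = _bandpass(noise, band, rate).std()
    return math.sqrt(strength / (1.0 - strength)) * noise_band_sd


# ---------------------------------------------------------------------------
# recordings and cohorts
# ---------------------------------------------------------------------------

def make_subject_recording(envelope: StimulusSignal, spec: CohortSpec,
                           n_neural: int | None = None,
                           condition: str = "forward",
                           seed: int | np.random.Generator = 0,
                           acoustic: StimulusSignal | None = None,
                           subject_id: str = "s00",
                           group: str = "hearing") -> SubjectRecording:
    """Simulate one subject's multichannel recording for one condition.

    Each neural channel is ``gain * driver + 1/f noise``; the ocular channel
    additionally carries a Poisson blink train.  The driver is the coupling
    band-filtered acoustic-only envelope component (``acoustic``, falling
    back to the composite envelope when none is supplied), time-reversed in
    the backward condition, with gain set by
    ``spec.coupling_strength[group][condition]``.
    """
    if n_neural is None:
        n_neural = spec.n_neural
    if n_neural < 1:
        raise ValueError("n_neural must be >= 1")
    rate = envelope.rate
    lo, hi = spec.coupling_band
    if not 0 < lo < hi < rate / 2:
        raise ValueError(
            f"coupling_band {spec.coupling_band} outside (0, {rate / 2})")
    rng = np.random.default_rng(seed)
    env = envelope.samples
    source = env if acoustic is None else acoustic.samples[: env.size]
    if condition == "backward":
        env = env[::-1]
        source = source[::-1]
    elif condition != "forward":
        raise ValueError(f"condition must be one of {CONDITIONS}")
    driver = _coupling_driver(source, spec.coupling_band, rate)

    s = spec.strength(group, condition)
    n = env.size
    duration = n / rate
    data = np.empty((n_neural + 1, n))
    roles = ["neural"] * n_neural + ["ocular"]
    for ch in range(n_neural):
        noise = one_over_f_noise(n, spec.noise_exponent, rng)
        g = _gain_for_strength(s, noise, spec.coupling_band, rate)
        data[ch] = g * driver + noise
    noise = one_over_f_noise(n, spec.noise_exponent, rng)
    g_oc = _gain_for_strength(spec.ocular_gain * s, noise,
                              spec.coupling_band, rate)
    bc = spec.blink_envelope_coupling if condition == "forward" else 0.0
    blinks, _ = make_blink_train(duration, rate, spec.blink_rate, rng,
                                 envelope=env, envelope_coupling=bc)
    data[n_neural] = g_oc * driver + noise + blinks
    return SubjectRecording(data=data, rate=rate, channel_roles=roles,
                            condition=condition, subject_id=subject_id,
                            group=group)


def make_cohort(spec: CohortSpec) -> list[SubjectData]:
    """Simulate a full cohort: per subject, a forward and a backward
    recording plus the stimuli as presented in each condition.

    Reproducible under ``spec.seed``; noise is independent across subjects.
    """
    for g, n in spec.n_per_group.items():
        if n < 2:
            raise ValueError(
                f"n_per_group[{g}]={n}: at least 2 subjects per group are "
                "required for the statistical stages")
    root = np.random.SeedSequence(spec.seed)
    subjects: list[SubjectData] = []
    sid = 0
    for group in spec.n_per_group:
        for _ in range(spec.n_per_group[group]):
            ss = root.spawn(1)[0]
            rng = np.random.default_rng(ss)
            subject_id = f"s{sid:03d}"
            # two latent envelope components: lip-visible and acoustic-only
            kw = dict(rate=spec.rate, syllable_rate=spec.syllable_rate,
                      sentence_rate=spec.sentence_rate)
            e_shared = make_speech_envelope(spec.duration, seed=rng, **kw)
            e_acoustic = make_speech_envelope(spec.duration, seed=rng, **kw)
            rho = spec.lip_corr
            env = StimulusSignal(
                rho * e_shared.samples
                + math.sqrt(1.0 - rho ** 2) * e_acoustic.samples,
                spec.rate, "envelope")
            lip = make_lip_signal(e_shared, target_corr=1.0, seed=rng)
            lip150 = fft_resample(lip, spec.rate)
            recordings, stimuli = {}, {}
            for condition in CONDITIONS:
                rec = make_subject_recording(
                    env, spec, condition=condition, seed=rng,
                    acoustic=e_acoustic,
                    subject_id=subject_id, group=group)
                recordings[condition] = rec
                if condition == "forward":
                    stimuli[condition] = {"envelope": env, "lip": lip150}
                else:
                    stimuli[condition] = {
                        "envelope": StimulusSignal(
                            env.samples[::-1].copy(), spec.rate, "envelope"),
                        "lip": StimulusSignal(
                            lip150.samples[::-1].copy(), spec.rate, "lip"),
                    }
            subjects.append(SubjectData(subject_id=subject_id, group=group,
                                        recordings=recordings,
                                        stimuli=stimuli))
            sid += 1
    return subjects


def make_common_source_pair(duration: float = 240.0, rate: float = 150.0,
                            band: tuple = (0.5, 2.0),
                            seed: int | np.random.Generator = 0,
                            source_snr: float = 4.0,
                            ocular_noise: float = 0.05,
                            shared: bool = True) -> SubjectRecording:
    """Validation fixture for partial coherence.

    With ``shared=True``, two neural channels and the ocular channel are all
    driven by one latent band-limited source plus independent 1/f noise:
    pairwise raw coherence within the band is high, and partializing the
    ocular channel (a near-clean copy of the source, noise SD
    ``ocular_noise``) removes it.  The default band is wider than the
    +/-0.5 Hz multitaper smoothing so in-band coherence is not diluted by
    out-of-band noise within the smoothing window.  With ``shared=False`` the three channels
    are driven by independent band-limited sources, so partialization must
    leave channel-channel coherence unchanged up to estimation error.
    """
    lo, hi = band
    if not 0 < lo < hi < rate / 2:
        raise ValueError(f"band {band} outside (0, {rate / 2})")
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))

    def band_source():
        return _standardize(_bandpass(rng.standard_normal(n), band, rate))

    amp = math.sqrt(source_snr)

    common = band_source()
    data = np.empty((3, n))
    for ch in range(2):
        src = common if shared else band_source()
        noise = one_over_f_noise(n, 1.0, rng)
        nb = _bandpass(noise, band, rate).std()
        data[ch] = amp * nb * src + noise
    src = common if shared else band_source()
    noise = one_over_f_noise(n, 1.0, rng)
    nb = _bandpass(noise, band, rate).std()
    data[2] = amp * nb * src / max(ocular_noise, 1e-12) + noise
    return SubjectRecording(data=data, rate=rate,
                            channel_roles=["neural", "neural", "ocular"],
                            condition="forward", subject_id="fixture",
                            group="hearing")
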