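"""Synthetic two-lead ECG generation with known ground truth.

Emulates the study inputs: pairs of simultaneously recorded ECG leads that
share beat timing but differ in morphology (a limb lead I and a precordial
lead V2), sampled at 257 Hz, up to 30 minutes long, with optional irregular
rhythm, plus the three canonical ECG noise classes (baseline wander,
electrode motion, muscle artifact) injected at calibrated SNR.

Every generator is a pure function of its seed and parameters, and ground
truth (R-peak times, sample-pair lags) is returned alongside the waveforms
so alignment error can be measured exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import signal as sps

from .core import SamplePair, Signal

__all__ = [
    "RhythmSpec",
    "WaveParams",
    "LeadMorphology",
    "LEAD_I",
    "LEAD_V2",
    "NoiseSpec",
    "generate_rhythm",
    "render_lead",
    "generate_record_pair",
    "select_samples",
    "generate_noise",
    "add_noise",
]

NoiseKind = Literal["BW", "EM", "MA"]

_AR_COEF = 0.8          # beat-to-beat AR(1) coefficient of RR variation
_ECTOPIC_SHORT = 0.6    # premature beat arrives at RR * 0.6
_REFRACTORY = 0.25      # minimum RR the generator will emit, seconds


@dataclass(frozen=True)
class RhythmSpec:
    """Beat-timing model.

    ``rr_jitter_sd`` is the stationary SD (seconds) of an AR(1)
    beat-to-beat RR fluctuation with coefficient 0.8.  ``ectopy_rate`` is
    the per-beat probability of a premature beat (RR shortened to 60%,
    followed by a compensatory pause).  ``af_mode`` replaces the whole
    model with i.i.d. RR uniform on [0.4, 1.2] s, mimicking atrial
    fibrillation's irregularly irregular rhythm.
    """

    mean_hr: float = 70.0
    rr_jitter_sd: float = 0.04
    ectopy_rate: float = 0.0
    af_mode: bool = False

    def __post_init__(self) -> None:
        if not (30 <= self.mean_hr <= 200):
            raise ValueError(f"mean_hr must be in [30, 200] bpm, got {self.mean_hr}")
        if not (0 <= self.ectopy_rate <= 1):
            raise ValueError("ectopy_rate must be a probability")
        if self.rr_jitter_sd < 0:
            raise ValueError("rr_jitter_sd must be >= 0")


@dataclass(frozen=True)
class WaveParams:
    """One ECG wave as a Gaussian bump: center offset from R (s), width (s),
    amplitude (mV)."""

    center: float
    width: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("wave width must be positive")


@dataclass(frozen=True)
class LeadMorphology:
    """P-QRS-T morphology of one lead as a sum of five Gaussian bumps."""

    label: str
    waves: dict[str, WaveParams]

    def __post_init__(self) -> None:
        r_amp = abs(self.waves["R"].amplitude)
        others = [abs(w.amplitude) for k, w in self.waves.items() if k != "R"]
        if others and r_amp <= max(others):
            raise ValueError("R amplitude must dominate the other waves")


# Amplitude profiles loosely following textbook limb-lead-I and V2 shapes:
# lead I with modest S and T, V2 with a deeper S and taller T.  Wave centers
# and widths are shared across leads: both leads project the same electrical
# event, so only the projected amplitudes differ.
LEAD_I = LeadMorphology(
    label="I",
    waves={
        "P": WaveParams(-0.20, 0.035, 0.10),
        "Q": WaveParams(-0.040, 0.012, -0.10),
        "R": WaveParams(0.0, 0.016, 1.00),
        "S": WaveParams(0.040, 0.015, -0.15),
        "T": WaveParams(0.30, 0.070, 0.30),
    },
)

LEAD_V2 = LeadMorphology(
    label="V2",
    waves={
        "P": WaveParams(-0.20, 0.035, 0.05),
        "Q": WaveParams(-0.040, 0.012, -0.15),
        "R": WaveParams(0.0, 0.016, 0.90),
        "S": WaveParams(0.040, 0.015, -0.60),
        "T": WaveParams(0.30, 0.070, 0.55),
    },
)


@dataclass(frozen=True)
class NoiseSpec:
    """One noise condition: kind, target SNR in dB, RNG seed."""

    kind: NoiseKind
    snr_db: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.snr_db):
            raise ValueError("snr_db must be finite")


def generate_rhythm(duration: float, rhythm: RhythmSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw R-peak times (seconds) covering [0, duration)."""
    mean_rr = 60.0 / rhythm.mean_hr
    times = []
    t = float(rng.uniform(0.1, 0.1 + mean_rr))
    x = 0.0  # AR(1) state
    innov_sd = rhythm.rr_jitter_sd * np.sqrt(1.0 - _AR_COEF**2)
    pending_pause = False
    while t < duration:
        times.append(t)
        if rhythm.af_mode:
            rr = float(rng.uniform(0.4, 1.2))
        else:
            x = _AR_COEF * x + float(rng.normal(0.0, innov_sd))
            rr = mean_rr + x
            if pending_pause:
                # compensatory pause: premature + pause sum to 2 RR
                rr += (1.0 - _ECTOPIC_SHORT) * mean_rr
                pending_pause = False
            elif rhythm.ectopy_rate > 0 and rng.random() < rhythm.ectopy_rate:
                rr *= _ECTOPIC_SHORT
                pending_pause = True
        t += max(rr, _REFRACTORY)
    return np.asarray(times)


def render_lead(
    r_times: np.ndarray, duration: float, fs: float, morphology: LeadMorphology
) -> Signal:
    """Render beats at ``r_times`` as this lead's Gaussian-bump sum."""
    n = int(round(duration * fs))
    out = np.zeros(n)
    t_axis = np.arange(n) / fs
    for wave in morphology.waves.values():
        for r in r_times:
            c = r + wave.center
            lo = max(0, int((c - 4 * wave.width) * fs))
            hi = min(n, int((c + 4 * wave.width) * fs) + 1)
            if hi <= lo:
                continue
            tt = t_axis[lo:hi] - c
            out[lo:hi] += wave.amplitude * np.exp(-0.5 * (tt / wave.width) ** 2)
    return Signal(out, fs=fs, t0=0.0, label=morphology.label)


def generate_record_pair(
    duration: float,
    rhythm: RhythmSpec | None = None,
    fs: float = 257.0,
    seed: int = 0,
) -> tuple[Signal, Signal, np.ndarray]:
    """Generate a simultaneous (lead I, lead V2) record with shared beats.

    Returns the two leads plus the ground-truth R-peak times in seconds.
    Both leads place every wave at identical times; only the per-wave
    amplitudes differ, mirroring how real leads project one cardiac event.
    """
    if duration < 10:
        raise ValueError("duration must be >= 10 s")
    rhythm = rhythm or RhythmSpec()
    rng = np.random.default_rng(seed)
    r_times = generate_rhythm(duration, rhythm, rng)
    lead_i = render_lead(r_times, duration, fs, LEAD_I)
    lead_v2 = render_lead(r_times, duration, fs, LEAD_V2)
    return lead_i, lead_v2, r_times


def select_samples(
    lead_i: Signal,
    lead_v2: Signal,
    m: float,
    n_samples: int,
    margin: float = 30.0,
    seed: int = 0,
    record_id: str = "synthetic",
) -> list[SamplePair]:
    """Randomly cut matched sample pairs from a simultaneous two-lead record.

    Each pair is an ``m``-second lead-I reference plus a lead-V2 search
    window that starts ``margin`` seconds earlier and ends ``margin``
    seconds later, so the reference sits at lag ``margin`` inside the
    search -- the ground truth.  Start positions are uniform (overlaps
    between pairs allowed).
    """
    duration = min(lead_i.duration, lead_v2.duration)
    needed = m + 2 * margin
    if duration < needed:
        raise ValueError(
            f"record of {duration:.1f} s too short: needs >= {needed:.1f} s "
            f"for m={m} s with margin={margin} s"
        )
    rng = np.random.default_rng(seed)
    starts = rng.uniform(margin, duration - m - margin, size=n_samples)
    pairs = []
    for i, s in enumerate(starts):
        ref = lead_i.slice_seconds(s, s + m)
        search = lead_v2.slice_seconds(s - margin, s + m + margin)
        pairs.append(
            SamplePair(
                reference=ref,
                search=search,
                margin=margin,
                true_lag=margin,
                meta={"record_id": record_id, "sample_id": i, "seed": seed,
                      "start_s": float(s)},
            )
        )
    return pairs


def _unit_rms(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    rms = np.sqrt(np.mean(x**2))
    if rms == 0:
        raise ValueError("generated noise is degenerate (zero RMS)")
    return x / rms


def _bw_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Baseline wander: three random low-frequency sinusoids + slow walk."""
    t = np.arange(n) / fs
    out = np.zeros(n)
    freqs = rng.uniform(0.05, 0.5, size=3)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    amps = rng.uniform(0.5, 1.0, size=3)
    for f, p, a in zip(freqs, phases, amps):
        out += a * np.sin(2 * np.pi * f * t + p)
    walk = np.cumsum(rng.normal(size=n))
    sos = sps.butter(2, 0.4, btype="lowpass", fs=fs, output="sos")
    walk = sps.sosfiltfilt(sos, walk)
    std = walk.std()
    if std > 0:
        out += 0.5 * (walk - walk.mean()) / std
    return out


def _ma_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Muscle artifact: band-limited white noise with EMG-like bursts."""
    high = min(50.0, 0.45 * fs)
    sos = sps.butter(4, [20.0, high], btype="bandpass", fs=fs, output="sos")
    base = sps.sosfiltfilt(sos, rng.normal(size=n))
    # amplitude modulation: smooth envelope of 0.5-2 s bursts
    envelope = np.full(n, 0.3)
    t = 0.0
    dur_total = n / fs
    while t < dur_total:
        burst_len = rng.uniform(0.5, 2.0)
        gap = rng.uniform(0.5, 3.0)
        i0 = int(t * fs)
        i1 = min(n, int((t + burst_len) * fs))
        envelope[i0:i1] = rng.uniform(1.0, 3.0)
        t += burst_len + gap
    smooth = sps.windows.hann(max(3, int(0.2 * fs)))
    envelope = np.convolve(envelope, smooth / smooth.sum(), mode="same")
    return base * envelope


def _em_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Electrode motion: decaying step transients + band-limited bursts.

    The burst component is shaped to a 1/f amplitude spectrum within
    1-60 Hz, mirroring the steep low-frequency roll-off of recorded
    electrode-motion noise, which concentrates its power where ECG
    alignment operates.
    """
    out = np.zeros(n)
    dur_total = n / fs
    n_events = rng.poisson(0.2 * dur_total)
    starts = rng.uniform(0, dur_total, size=n_events)
    for s in starts:
        i0 = int(s * fs)
        tau = rng.uniform(0.1, 0.5)  # decay constant, s
        amp = rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 2.0)
        length = min(n - i0, int(5 * tau * fs))
        if length <= 0:
            continue
        out[i0:i0 + length] += amp * np.exp(-np.arange(length) / (tau * fs))
    high = min(60.0, 0.45 * fs)
    spec = np.fft.rfft(rng.normal(size=n))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    in_band = (freqs >= 1.0) & (freqs <= high)
    shape[in_band] = 1.0 / freqs[in_band]
    bursts = np.fft.irfft(spec * shape, n=n)
    bursts /= max(bursts.std(), 1e-12)
    envelope = np.zeros(n)
    for s in starts:
        i0 = int(s * fs)
        i1 = min(n, i0 + int(rng.uniform(0.2, 1.0) * fs))
        envelope[i0:i1] = 1.0
    out += bursts * (0.3 + envelope)
    return out


_NOISE_FNS = {"BW": _bw_noise, "MA": _ma_noise, "EM": _em_noise}


def generate_noise(kind: str, duration: float, fs: float, seed: int = 0) -> Signal:
    """Synthesize one of the three canonical ECG noise classes at unit RMS.

    BW concentrates power below 1 Hz, MA above 20 Hz with burst-like
    amplitude modulation, EM mixes step transients with 1-60 Hz bursts --
    spectral envelopes chosen to mimic the noise-stress-test recordings.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    try:
        fn = _NOISE_FNS[kind]
    except KeyError:
        raise ValueError(f"unknown noise kind {kind!r}; expected BW, EM or MA") from None
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    return Signal(_unit_rms(fn(n, fs, rng)), fs=fs, t0=0.0, label=f"noise:{kind}")


def add_noise(sig: Signal, noise: Signal, snr_db: float) -> Signal:
    """Add scaled noise so the output has exactly the requested SNR.

    Powers are mean squared deviations from the mean over the full
    segment; the scale alpha solves
    ``10 log10(P_signal / P_{alpha * noise}) = snr_db``.
    """
    if len(sig) != len(noise) or sig.fs != noise.fs:
        raise ValueError("signal and noise must share length and fs")
    p_sig = float(np.var(sig.samples))
    p_noise = float(np.var(noise.samples))
    if p_sig == 0 or p_noise == 0:
        raise ValueError("zero-power signal or noise")
    alpha = np.sqrt(p_sig / (p_noise * 10.0 ** (snr_db / 10.0)))
    return Signal(sig.samples + alpha * noise.samples, fs=sig.fs, t0=sig.t0,
                  label=sig.label)


def add_noise_kind(sig: Signal, kind: str, snr_db: float, seed: int = 0) -> Signal:
    """Convenience: synthesize matching-length noise of ``kind`` and add it."""
    noise = generate_noise(kind, len(sig) / sig.fs, sig.fs, seed=seed)
    # rounding of duration -> sample count can differ by one; trim to match
    if len(noise) != len(sig):
        noise = Signal(noise.samples[: len(sig)], fs=sig.fs, label=noise.label)
    return add_noise(sig, noise, snr_db)
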