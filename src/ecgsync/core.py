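"""Domain types and the ECG preprocessing chain.

The preprocessing pipeline prepares a raw single-lead ECG for amplitude
cross-correlation against a lead recorded by a different device:

1. resample to a common working rate (default 250 Hz),
2. zero-phase band-pass (2-10 Hz Butterworth, order 2, applied
   forward-backward) to suppress baseline wander and high-frequency noise
   without introducing any phase delay that would bias a lag estimate,
3. min-max normalization to put morphologically different leads on an
   equal amplitude footing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Any

import numpy as np
from scipy import signal as sps

__all__ = [
    "Signal",
    "PreprocessConfig",
    "SamplePair",
    "DegenerateSignalError",
    "SignalTooShortError",
    "resample",
    "bandpass_zero_phase",
    "minmax_normalize",
    "preprocess",
]


class DegenerateSignalError(ValueError):
    """Raised when a signal has no dynamic range (constant amplitude)."""


class SignalTooShortError(ValueError):
    """Raised when a signal is too short for the requested filter."""


@dataclass(frozen=True)
class Signal:
    """A uniformly sampled amplitude series.

    Sample ``n`` occurs at time ``t0 + n / fs`` seconds (0-based).

    Parameters
    ----------
    samples : ndarray
        Amplitudes in mV or normalized units; finite, length >= 1.
    fs : float
        Sampling rate in Hz, > 0.
    t0 : float
        Start time in seconds on the record's clock.
    label : str
        Free-text channel name, e.g. ``"I"`` or ``"V2"``.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=np.float64)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("samples must be finite")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        object.__setattr__(self, "samples", arr)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds (n samples / fs)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Time of each sample in seconds on the record's clock."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def slice_seconds(self, start: float, stop: float) -> "Signal":
        """Cut the half-open window [start, stop) in record-clock seconds."""
        i0 = int(round((start - self.t0) * self.fs))
        i1 = int(round((stop - self.t0) * self.fs))
        if i0 < 0 or i1 > len(self) or i0 >= i1:
            raise ValueError(
                f"window [{start}, {stop}) s outside record "
                f"[{self.t0}, {self.t0 + self.duration}) s"
            )
        return replace(self, samples=self.samples[i0:i1], t0=self.t0 + i0 / self.fs)


@dataclass(frozen=True)
class PreprocessConfig:
    """Settings for the three-step preprocessing chain."""

    target_fs: float = 250.0
    band_low: float = 2.0
    band_high: float = 10.0
    filter_order: int = 2
    normalize: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.band_low < self.band_high < self.target_fs / 2):
            raise ValueError(
                f"require 0 < band_low < band_high < target_fs/2, got "
                f"({self.band_low}, {self.band_high}) at fs {self.target_fs}"
            )
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")


@dataclass(frozen=True)
class SamplePair:
    """A short reference sample and the longer search sample containing it.

    The search signal spans ``2 * margin`` seconds more than the reference;
    ``true_lag`` is the ground-truth position (seconds) of the reference's
    start within the search signal, equal to ``margin`` for pairs built by
    symmetric padding.
    """

    reference: Signal
    search: Signal
    margin: float = 30.0
    true_lag: float = 30.0
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        extra = self.search.duration - self.reference.duration
        if abs(extra - 2 * self.margin) > 1.0 / min(self.reference.fs, self.search.fs) + 1e-9:
            raise ValueError(
                f"search must be 2*margin = {2 * self.margin} s longer than "
                f"reference (got {extra:.6f} s)"
            )
        if not (0 <= self.true_lag <= 2 * self.margin + 1e-9):
            raise ValueError("true_lag must lie in [0, 2*margin]")


def resample(sig: Signal, target_fs: float) -> Signal:
    """Resample to ``target_fs`` via polyphase rational resampling.

    The rate change is expressed as an exact integer ratio (e.g. 257 to
    250 Hz is up 250 / down 257) and applied with a Kaiser-windowed
    anti-aliasing low-pass, which is linear-phase.
    """
    if not target_fs > 0:
        raise ValueError(f"target_fs must be positive, got {target_fs}")
    if target_fs == sig.fs:
        return sig
    ratio = Fraction(target_fs / sig.fs).limit_denominator(10_000)
    up, down = ratio.numerator, ratio.denominator
    out = sps.resample_poly(sig.samples, up, down)
    return replace(sig, samples=out, fs=sig.fs * up / down)


def _effective_startup(fs: float, f_low: float) -> int:
    # One period of the lowest passband frequency bounds the filter's
    # effective impulse-response length for low-order Butterworth bands.
    return int(np.ceil(fs / f_low))


def bandpass_zero_phase(sig: Signal, cfg: PreprocessConfig | None = None) -> Signal:
    """Band-pass with a Butterworth filter applied forward then backward.

    Forward-backward application cancels the phase response, so an in-band
    component leaves the filter with zero net delay -- essential when the
    output feeds a lag estimator.  The effective magnitude response is the
    squared single-pass response.  Edges are handled by odd-reflection
    padding of three times the effective impulse-response length.
    """
    cfg = cfg or PreprocessConfig()
    if cfg.band_high >= sig.fs / 2:
        raise ValueError(
            f"band edge {cfg.band_high} Hz >= Nyquist {sig.fs / 2} Hz"
        )
    sos = sps.butter(
        cfg.filter_order, [cfg.band_low, cfg.band_high], btype="bandpass",
        fs=sig.fs, output="sos",
    )
    padlen = 3 * _effective_startup(sig.fs, cfg.band_low)
    if len(sig) <= padlen:
        raise SignalTooShortError(
            f"signal of {len(sig)} samples too short for zero-phase filtering "
            f"(needs > {padlen} samples at fs {sig.fs})"
        )
    out = sps.sosfiltfilt(sos, sig.samples, padtype="odd", padlen=padlen)
    return replace(sig, samples=out)


def minmax_normalize(sig: Signal) -> Signal:
    """Map amplitudes linearly onto [0, 1].

    Invariant under positive affine transforms of the input, which is what
    puts leads with different gains and offsets on an equal footing.
    """
    lo = float(np.min(sig.samples))
    hi = float(np.max(sig.samples))
    if hi == lo:
        raise DegenerateSignalError("signal has zero dynamic range")
    return replace(sig, samples=(sig.samples - lo) / (hi - lo))


def preprocess(sig: Signal, cfg: PreprocessConfig | None = None) -> Signal:
    """Run the full chain: resample, zero-phase band-pass, min-max normalize."""
    cfg = cfg or PreprocessConfig()
    out = resample(sig, cfg.target_fs)
    out = bandpass_zero_phase(out, cfg)
    if cfg.normalize:
        out = minmax_normalize(out)
    return out
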