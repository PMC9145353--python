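"""Record readers/writers: WFDB format-16 and two-column CSV.

Conventions used package-wide: timestamps are seconds as 64-bit reals,
sample indices are 0-based, windows are half-open [start, end).

WFDB support covers the subset the artifact touches: a ``.hea`` header plus
an interleaved little-endian 16-bit ``.dat`` file (signal format 16), with
per-channel gain/baseline so amplitudes round-trip to within one ADC
quantum.  CSV files carry the dialect ``t_seconds,amplitude`` (UTF-8, "."
decimal), one file per channel.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import Signal

__all__ = ["RecordHandle", "read_record", "write_record",
           "write_beat_sidecar", "read_beat_sidecar"]

_ADC_MAX = 32000  # leave headroom below the int16 limit


@dataclass(frozen=True)
class RecordHandle:
    path: Path
    format: str  # "wfdb" | "csv"
    channels: tuple[str, ...]
    fs: float
    duration: float


def _parse_hea(hea_path: Path) -> tuple[str, int, float, int, list[dict]]:
    lines = [
        ln.strip() for ln in hea_path.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]
    try:
        head = lines[0].split()
        name, n_sig, fs, n_samp = head[0], int(head[1]), float(head[2]), int(head[3])
    except (IndexError, ValueError) as exc:
        raise ValueError(f"malformed WFDB header at line 1 of {hea_path}: {exc}") from exc
    sig_specs = []
    for lineno, ln in enumerate(lines[1: 1 + n_sig], start=2):
        parts = ln.split()
        try:
            fname, fmt = parts[0], parts[1]
            if fmt != "16":
                raise ValueError(f"unsupported signal format {fmt} (only 16)")
            gain_spec = parts[2]
            units = "mV"
            if "/" in gain_spec:
                gain_spec, units = gain_spec.split("/", 1)
            baseline = 0
            if "(" in gain_spec:
                gain_str, base_str = gain_spec.rstrip(")").split("(")
                gain, baseline = float(gain_str), int(base_str)
            else:
                gain = float(gain_spec)
            label = parts[8] if len(parts) > 8 else f"ch{lineno - 2}"
        except (IndexError, ValueError) as exc:
            raise ValueError(
                f"malformed WFDB header at line {lineno} of {hea_path}: {exc}"
            ) from exc
        sig_specs.append(
            {"file": fname, "gain": gain, "baseline": baseline,
             "units": units, "label": label}
        )
    return name, n_sig, fs, n_samp, sig_specs


def _read_wfdb(path: Path, channels: list[str] | None) -> list[Signal]:
    hea = path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(f"no WFDB header {hea}")
    _, n_sig, fs, n_samp, specs = _parse_hea(hea)
    dat = hea.parent / specs[0]["file"]
    raw = np.fromfile(dat, dtype="<i2")
    if raw.size < n_samp * n_sig:
        raise ValueError(
            f"{dat} holds {raw.size} samples, header declares {n_samp * n_sig}"
        )
    mat = raw[: n_samp * n_sig].reshape(n_samp, n_sig)
    available = [s["label"] for s in specs]
    wanted = channels if channels is not None else available
    signals = []
    for ch in wanted:
        if ch not in available:
            raise KeyError(
                f"channel {ch!r} not in record; available: {available}"
            )
        k = available.index(ch)
        spec = specs[k]
        phys = (mat[:, k].astype(np.float64) - spec["baseline"]) / spec["gain"]
        signals.append(Signal(phys, fs=fs, t0=0.0, label=ch))
    return signals


def _read_csv(path: Path, channels: list[str] | None) -> list[Signal]:
    paths: list[Path]
    if path.is_dir():
        paths = sorted(path.glob("*.csv"))
        if channels is not None:
            by_label = {p.stem.split("_")[-1]: p for p in paths}
            missing = [c for c in channels if c not in by_label]
            if missing:
                raise KeyError(
                    f"channels {missing} not found; available: {sorted(by_label)}"
                )
            paths = [by_label[c] for c in channels]
    else:
        paths = [path]
    signals = []
    for p in paths:
        df = pd.read_csv(p)
        if list(df.columns[:2]) != ["t_seconds", "amplitude"]:
            raise ValueError(
                f"{p}: expected header 't_seconds,amplitude', got {list(df.columns)}"
            )
        t = df["t_seconds"].to_numpy()
        if t.size < 2:
            raise ValueError(f"{p}: need >= 2 rows to infer the sampling rate")
        fs = 1.0 / float(np.median(np.diff(t)))
        label = p.stem.split("_")[-1]
        signals.append(Signal(df["amplitude"].to_numpy(), fs=round(fs, 6),
                              t0=float(t[0]), label=label))
    return signals


def read_record(
    path: str | os.PathLike, format: str = "wfdb",
    channels: list[str] | None = None,
) -> list[Signal]:
    """Read one signal per requested channel, amplitudes in physical units."""
    path = Path(path)
    if format == "wfdb":
        return _read_wfdb(path, channels)
    if format == "csv":
        return _read_csv(path, channels)
    raise ValueError(f"unknown format {format!r}; expected 'wfdb' or 'csv'")


def write_record(
    signals: list[Signal], path: str | os.PathLike, format: str = "wfdb"
) -> RecordHandle:
    """Write channels sharing fs/length as one WFDB record or per-channel CSVs."""
    if not signals:
        raise ValueError("empty channel list")
    n = len(signals[0])
    fs = signals[0].fs
    for s in signals[1:]:
        if len(s) != n or s.fs != fs:
            raise ValueError("all channels must share sampling rate and length")
    path = Path(path)
    if format == "wfdb":
        path.parent.mkdir(parents=True, exist_ok=True)
        dat_name = path.name + ".dat"
        adc = np.empty((n, len(signals)), dtype="<i2")
        spec_lines = []
        for k, s in enumerate(signals):
            lo, hi = float(np.min(s.samples)), float(np.max(s.samples))
            span = max(hi - lo, 1e-12)
            gain = 2 * _ADC_MAX / span
            baseline = int(round(-(lo + hi) / 2 * gain))
            q = np.round(s.samples * gain + baseline).astype("<i2")
            adc[:, k] = q
            checksum = int(np.sum(q.astype(np.int64)) % 65536)
            spec_lines.append(
                f"{dat_name} 16 {gain:.6f}({baseline})/mV 16 0 {int(q[0])} "
                f"{checksum} 0 {s.label or f'ch{k}'}"
            )
        header = [f"{path.name} {len(signals)} {fs:g} {n}"] + spec_lines
        path.with_suffix(".hea").write_text("\n".join(header) + "\n")
        adc.tofile(path.parent / dat_name)
        written = path
    elif format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        for k, s in enumerate(signals):
            label = s.label or f"ch{k}"
            pd.DataFrame({"t_seconds": s.times, "amplitude": s.samples}).to_csv(
                path / f"{path.name}_{label}.csv", index=False
            )
        written = path
    else:
        raise ValueError(f"unknown format {format!r}")
    return RecordHandle(
        path=written, format=format,
        channels=tuple(s.label for s in signals), fs=fs, duration=n / fs,
    )


def write_beat_sidecar(
    path: str | os.PathLike, record: str, r_times: np.ndarray
) -> None:
    """Ground-truth R times as a CSV sidecar (record, beat_index, t_seconds)."""
    pd.DataFrame(
        {"record": record, "beat_index": np.arange(len(r_times)),
         "t_seconds": r_times}
    ).to_csv(path, index=False)


def read_beat_sidecar(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)
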