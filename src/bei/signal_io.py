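"""Core signal containers and file I/O for single-channel EEG.

The engagement-index pipeline works on one frontal EEG channel (nominally
Fpz referenced to the earlobe, 512 Hz) and a 1500 ms matching template.
Recordings come in as EDF or as two-column CSV (time_s, amplitude_uV);
templates as a single-column CSV spanning exactly 1500 ms.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from math import gcd
from pathlib import Path

import numpy as np

__all__ = [
    "EEGRecording",
    "Template",
    "read_recording",
    "write_recording",
    "load_template",
    "make_template",
    "default_template",
    "default_template_path",
    "TEMPLATE_MS",
]

#: Fixed template duration in milliseconds.
TEMPLATE_MS = 1500.0

#: Relative tolerance on CSV time-step uniformity (fraction of median step).
CSV_TIMEBASE_TOL = 0.01


class SignalIOError(ValueError):
    """Raised for unreadable, malformed or degenerate signal inputs."""


@dataclass
class EEGRecording:
    """Uniformly sampled single-channel EEG signal.

    Parameters
    ----------
    samples : ndarray
        Amplitude series in microvolts; must be finite.
    fs : float
        Sampling rate in Hz, > 0.
    channel_label : str
        Electrode label, e.g. ``"Fpz"``.
    t0 : float
        Recording start offset in seconds (annotation only).
    """

    samples: np.ndarray
    fs: float
    channel_label: str = "Fpz"
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise SignalIOError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise SignalIOError("samples contain non-finite values")
        if not (self.fs > 0):
            raise SignalIOError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def slice_seconds(self, start_s: float, stop_s: float) -> "EEGRecording":
        """Return the sub-recording covering [start_s, stop_s) from recording start."""
        i0 = int(round(start_s * self.fs))
        i1 = int(round(stop_s * self.fs))
        if not (0 <= i0 < i1 <= self.n_samples):
            raise SignalIOError(
                f"slice [{start_s}, {stop_s}) s outside recording of {self.duration_s} s"
            )
        return EEGRecording(
            self.samples[i0:i1], self.fs, self.channel_label, self.t0 + start_s
        )


@dataclass
class Template:
    """1500 ms normalized matching waveform.

    ``values`` lie in [-1, +1] with min exactly -1 and max exactly +1
    (min-max normalization); length equals ``round(1.5 * fs)`` samples.
    """

    values: np.ndarray
    fs: float
    duration_ms: float = field(default=TEMPLATE_MS)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = int(round(self.duration_ms / 1000.0 * self.fs))
        if self.values.size != expected:
            raise SignalIOError(
                f"template length {self.values.size} != round({self.duration_ms} ms "
                f"* {self.fs} Hz) = {expected}"
            )
        vmin, vmax = float(self.values.min()), float(self.values.max())
        if not (np.isclose(vmin, -1.0) and np.isclose(vmax, 1.0)):
            raise SignalIOError(
                f"template must be min-max normalized to [-1, +1], got [{vmin}, {vmax}]"
            )

    @property
    def n_samples(self) -> int:
        return self.values.size

    def opposite(self) -> np.ndarray:
        """Polarity-inverted template used for the opposite-distance channel."""
        return -self.values


# ---------------------------------------------------------------------------
# recordings


def _read_csv_columns(path: Path) -> np.ndarray:
    """Parse a numeric CSV, skipping a single optional header line."""
    rows: list[list[float]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        for lineno, row in enumerate(reader):
            row = [c.strip() for c in row if c.strip() != ""]
            if not row:
                continue
            try:
                rows.append([float(c) for c in row])
            except ValueError:
                if lineno == 0:
                    continue  # header
                raise SignalIOError(f"{path}: non-numeric row at line {lineno + 1}")
    if not rows:
        raise SignalIOError(f"{path}: no numeric data")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise SignalIOError(f"{path}: ragged rows")
    return np.asarray(rows, dtype=float)


def _read_recording_csv(path: Path) -> EEGRecording:
    data = _read_csv_columns(path)
    if data.shape[1] != 2:
        raise SignalIOError(
            f"{path}: expected two columns (time_s, amplitude_uV), got {data.shape[1]}"
        )
    t, x = data[:, 0], data[:, 1]
    if t.size < 2:
        raise SignalIOError(f"{path}: need at least two samples to infer a rate")
    dt = np.diff(t)
    med = float(np.median(dt))
    if med <= 0:
        raise SignalIOError(f"{path}: non-increasing timebase")
    if float(np.max(np.abs(dt - med))) > CSV_TIMEBASE_TOL * med:
        raise SignalIOError(
            f"{path}: non-uniform timebase (max deviation exceeds "
            f"{CSV_TIMEBASE_TOL:.0%} of the median step {med:g} s)"
        )
    return EEGRecording(x, fs=1.0 / med, t0=float(t[0]))


def _read_recording_edf(path: Path, channel: str | int | None) -> EEGRecording:
    import mne  # heavy import, only needed for EDF

    try:
        raw = mne.io.read_raw_edf(os.fspath(path), preload=True, verbose="error")
    except Exception as exc:  # mne raises a zoo of types for bad files
        raise SignalIOError(f"{path}: unreadable EDF ({exc})") from exc
    names = list(raw.ch_names)
    if channel is None:
        idx = 0
    elif isinstance(channel, int):
        if not (0 <= channel < len(names)):
            raise SignalIOError(f"{path}: channel index {channel} out of range")
        idx = channel
    else:
        if channel not in names:
            raise SignalIOError(
                f"{path}: channel {channel!r} absent (have {names})"
            )
        idx = names.index(channel)
    data_uv = raw.get_data(picks=[idx])[0] * 1e6  # mne returns volts
    return EEGRecording(data_uv, fs=float(raw.info["sfreq"]), channel_label=names[idx])


def read_recording(path: str | os.PathLike, channel: str | int | None = None) -> EEGRecording:
    """Read a single-channel EEG recording from EDF or two-column CSV.

    EDF: sampling rate and channel label come from the header; ``channel``
    selects by name or index (default: first channel). CSV: columns are
    (time_s, amplitude_uV); the rate is the reciprocal of the median time
    step, and a timebase whose steps deviate from the median by more than
    1% is rejected as non-uniform.
    """
    path = Path(path)
    if not path.exists():
        raise SignalIOError(f"no such file: {path}")
    if path.suffix.lower() == ".edf":
        return _read_recording_edf(path, channel)
    if channel not in (None, 0):
        raise SignalIOError("CSV recordings are single-channel; no channel selection")
    return _read_recording_csv(path)


def write_recording(rec: EEGRecording, path: str | os.PathLike) -> None:
    """Write a recording as two-column CSV (time_s, amplitude_uV)."""
    t = rec.t0 + np.arange(rec.n_samples) / rec.fs
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "amplitude_uV"])
        for ti, xi in zip(t, rec.samples):
            w.writerow([f"{ti:.10g}", f"{xi:.10g}"])


# ---------------------------------------------------------------------------
# templates


def _resample_poly(values: np.ndarray, n_target: int) -> np.ndarray:
    """Polyphase (linear-phase) resampling of a waveform to n_target samples."""
    from scipy.signal import resample_poly

    n = values.size
    if n == n_target:
        return values.copy()
    g = gcd(n_target, n)
    return resample_poly(values, n_target // g, n // g)[:n_target]


def make_template(values: np.ndarray, fs: float, target_fs: float) -> Template:
    """Build a Template from a raw 1500 ms waveform sampled at ``fs``.

    Applies the same delta-band (1-4 Hz) zero-phase filter used on the EEG
    segments, resamples to ``target_fs`` by polyphase resampling, and
    min-max normalizes to [-1, +1].
    """
    from .bei_engine import _bandpass_filter_short  # shared filter, avoids drift

    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise SignalIOError("template waveform must be a 1-D array of length >= 2")
    if not np.all(np.isfinite(values)):
        raise SignalIOError("template waveform contains non-finite values")
    if float(values.max()) == float(values.min()):
        raise SignalIOError("constant template waveform: min-max normalization undefined")
    n_target = int(round(TEMPLATE_MS / 1000.0 * target_fs))
    resampled = _resample_poly(values, n_target)
    filtered = _bandpass_filter_short(resampled, target_fs)
    rng = float(filtered.max() - filtered.min())
    if rng == 0:
        raise SignalIOError("constant template waveform: min-max normalization undefined")
    normalized = -1.0 + 2.0 * (filtered - filtered.min()) / rng
    return Template(normalized, fs=target_fs)


def load_template(path: str | os.PathLike, target_fs: float) -> Template:
    """Load a 1500 ms template from CSV and prepare it for matching.

    One-column CSV: the column is taken to span exactly 1500 ms. Two-column
    CSV (time_s, value): the spanned duration must equal 1500 ms within one
    sample. The waveform is delta-filtered, resampled to ``target_fs`` and
    min-max normalized.
    """
    path = Path(path)
    if not path.exists():
        raise SignalIOError(f"no such file: {path}")
    data = _read_csv_columns(path)
    if data.shape[1] == 1:
        values = data[:, 0]
    elif data.shape[1] == 2:
        t, values = data[:, 0], data[:, 1]
        dt = float(np.median(np.diff(t)))
        duration_ms = (t[-1] - t[0] + dt) * 1000.0
        if abs(duration_ms - TEMPLATE_MS) > dt * 1000.0:
            raise SignalIOError(
                f"{path}: template spans {duration_ms:.1f} ms, expected {TEMPLATE_MS:.0f}"
            )
    else:
        raise SignalIOError(f"{path}: expected 1 or 2 columns, got {data.shape[1]}")
    # original rate implied by the fixed 1500 ms duration
    fs_orig = data.shape[0] / (TEMPLATE_MS / 1000.0)
    return make_template(values, fs=fs_orig, target_fs=target_fs)


def default_template(target_fs: float = 512.0) -> Template:
    """Synthetic default template: a 1500 ms mid-delta oscillation burst.

    The original study's averaged-ERP template is proprietary and not
    published in tabular form, so this package ships a synthetic surrogate:
    five cycles of a 10/3 Hz sinusoid (mid delta band), passed through the
    same delta filter and normalization as any loaded template. A burst
    with sustained in-band amplitude is essential — a waveform that idles
    near zero for most of its 1500 ms sits within mean absolute distance
    0.5 of almost any normalized window, and the match threshold stops
    discriminating. All engine behavior is template-agnostic, so any
    1500 ms waveform can be swapped in.
    """
    fs_gen = 512.0
    n = int(round(TEMPLATE_MS / 1000.0 * fs_gen))
    t = np.arange(n) / fs_gen
    wave = _default_raw_waveform(t)
    return make_template(wave, fs=fs_gen, target_fs=target_fs)


def _default_raw_waveform(t: np.ndarray) -> np.ndarray:
    """Raw (pre-filter) default burst; also what the packaged CSV stores."""
    return np.sin(2 * np.pi * (5.0 / 1.5) * t)


def default_template_path() -> Path:
    """Path of the packaged synthetic template CSV (512 Hz, single column)."""
    return Path(__file__).parent / "data" / "synthetic_erp_template_512hz.csv"
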