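"""Brain Engagement Index engine.

Computes a real-time attention marker from single-channel frontal EEG by
template matching. Every 10 seconds the preceding 60 s of signal are cut
into six 10-second segments; each segment is delta-band (1-4 Hz) filtered,
min-max normalized to [-1, +1] and scanned by a sliding 1500 ms window.
Windows whose mean absolute distance to the normalized template falls below
0.5 count as matches, others as no-matches (each deduplicated so counted
events of a class never overlap). The segment BEI is matches/no-matches
clamped to [0, 1]; the emitted BEI is the median of the six segment values.

A noise-rejection cascade runs alongside: a 1500 ms window whose delta-band
amplitude has a standard-deviation/mean ratio above 1 is rejected as noisy;
a segment with more than one non-overlapping rejected window is discarded;
a minute with fewer than three clean segments produces no BEI (an explicit
gap, never interpolated).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import butter, sosfiltfilt

from .signal_io import EEGRecording, Template, SignalIOError, TEMPLATE_MS

__all__ = [
    "EngineConfig",
    "SegmentResult",
    "BEITrace",
    "StreamingBEI",
    "bandpass_delta",
    "normalize_unit_range",
    "window_distance",
    "noise_ratio",
    "classify_window",
    "scan_segment",
    "minute_bei",
    "stream_bei",
]

logger = logging.getLogger("bei.engine")


class DegenerateSegmentError(ValueError):
    """A constant (zero-range) stretch of signal cannot be normalized."""


@dataclass
class EngineConfig:
    """Engine parameters. Defaults are the study constants.

    delta_band : passband edges in Hz.
    segment_s / window_s / cadence_s : 10 s segments, 60 s analysis window,
        one emission every 10 s (so consecutive emissions share 50 s).
    template_ms : matching window length, 1500 ms.
    match_threshold : mean-absolute-distance boundary between match and
        no-match on normalized data.
    noise_ratio_threshold : SD/mean ratio of delta-band amplitude above
        which a 1500 ms window is rejected as noisy.
    max_rejected_windows_per_segment : more than this many non-overlapping
        rejected windows discards the whole segment.
    min_valid_segments_per_minute : fewer clean segments than this yields a
        missing BEI for the minute.
    opposite_mode : "ignore" (distance to the polarity-inverted template is
        computed and logged but classification uses the template distance
        alone) or "opposite_counts_as_nomatch" (a no-match additionally
        requires proximity to the inverted template; windows near neither
        waveform are left uncounted).
    filter_order : Butterworth order (applied forward-backward, zero phase).
    pad_s : filtering context taken from adjacent signal on each side of a
        segment, reflect-padded where no adjacent signal exists.
    """

    delta_band: tuple[float, float] = (1.0, 4.0)
    segment_s: float = 10.0
    window_s: float = 60.0
    template_ms: float = TEMPLATE_MS
    match_threshold: float = 0.5
    noise_ratio_threshold: float = 1.0
    max_rejected_windows_per_segment: int = 1
    min_valid_segments_per_minute: int = 3
    cadence_s: float = 10.0
    opposite_mode: str = "ignore"
    filter_order: int = 4
    pad_s: float = 2.0

    def __post_init__(self) -> None:
        lo, hi = self.delta_band
        if not (0 < lo < hi):
            raise ValueError(f"invalid delta band {self.delta_band}")
        for name in ("segment_s", "window_s", "template_ms", "match_threshold",
                     "noise_ratio_threshold", "cadence_s", "pad_s"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be strictly positive")
        ratio = self.window_s / self.segment_s
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"window_s ({self.window_s}) must be an integer multiple of "
                f"segment_s ({self.segment_s})"
            )
        if abs(self.cadence_s - self.segment_s) > 1e-9:
            raise ValueError("cadence_s must equal segment_s (one segment per emission)")
        if self.opposite_mode not in ("ignore", "opposite_counts_as_nomatch"):
            raise ValueError(f"unknown opposite_mode {self.opposite_mode!r}")

    @property
    def segments_per_window(self) -> int:
        return int(round(self.window_s / self.segment_s))

    def template_len(self, fs: float) -> int:
        return int(round(self.template_ms / 1000.0 * fs))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["delta_band"] = list(self.delta_band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EngineConfig":
        d = dict(d)
        if "delta_band" in d:
            d["delta_band"] = tuple(d["delta_band"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "EngineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass
class SegmentResult:
    """Outcome of scanning one 10-second segment."""

    start_s: float
    matches: int
    nomatches: int
    rejected_windows: int
    valid: bool
    bei: float | None
    reason: str | None = None  # set when invalid

    def __post_init__(self) -> None:
        if self.valid and not (self.bei is not None and 0.0 <= self.bei <= 1.0):
            raise ValueError(f"valid segment must carry a BEI in [0,1], got {self.bei}")


@dataclass
class BEITrace:
    """Time series of BEI emissions at the engine cadence.

    ``values`` holds NaN at missing (rejected-minute) timestamps; gaps are
    explicit and never interpolated.
    """

    times_s: np.ndarray
    values: np.ndarray
    n_valid_segments: np.ndarray
    segment_log: list[SegmentResult] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.n_valid_segments = np.asarray(self.n_valid_segments, dtype=int)
        if not (self.times_s.shape == self.values.shape == self.n_valid_segments.shape):
            raise ValueError("times, values and n_valid_segments must align")
        if self.times_s.size > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("emission timestamps must be strictly increasing")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("BEI values must lie in [0, 1]")

    @property
    def clean_values(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.times_s,
                "bei": self.values,
                "n_valid_segments": self.n_valid_segments,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path) -> "BEITrace":
        import pandas as pd

        df = pd.read_csv(path)
        need = {"time_s", "bei"}
        if not need.issubset(df.columns):
            raise SignalIOError(f"{path}: trace CSV needs columns {sorted(need)}")
        nvalid = df["n_valid_segments"] if "n_valid_segments" in df else np.zeros(len(df))
        return cls(
            df["time_s"].to_numpy(float),
            df["bei"].to_numpy(float),
            np.nan_to_num(np.asarray(nvalid, dtype=float)).astype(int),
        )


# ---------------------------------------------------------------------------
# filtering


def _delta_sos(fs: float, cfg: EngineConfig | None = None):
    # second-order sections: the ba form of a 1-4 Hz band at 512 Hz is
    # numerically ill-conditioned and amplifies round-off by ~1e6
    lo, hi = cfg.delta_band if cfg else (1.0, 4.0)
    order = cfg.filter_order if cfg else 4
    return butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def _bandpass_filter_short(x: np.ndarray, fs: float, cfg: EngineConfig | None = None) -> np.ndarray:
    """Zero-phase delta bandpass for short arrays (template-length and up).

    The waveform is zero-padded by 2 s on each side before filtering — a
    template is a transient surrounded by silence, so zero context is the
    physical continuation. The edge taper this produces is the true
    delta-band content of a finite burst.
    """
    sos = _delta_sos(fs, cfg)
    pad = int(round(2.0 * fs))
    return sosfiltfilt(sos, np.pad(x, pad))[pad : pad + x.size]


def bandpass_delta(rec: EEGRecording, cfg: EngineConfig | None = None) -> EEGRecording:
    """Zero-phase 4th-order Butterworth delta (1-4 Hz) bandpass.

    Applied forward-backward so the filtered signal keeps template
    alignment (no group delay). Requires a recording of at least three
    periods of the lowest passband frequency (~3 s at 1 Hz) so the filter
    transient cannot dominate.
    """
    cfg = cfg or EngineConfig()
    lo = cfg.delta_band[0]
    if rec.fs <= 2 * cfg.delta_band[1]:
        raise ValueError(
            f"sampling rate {rec.fs} Hz too low for a {cfg.delta_band[1]} Hz passband edge"
        )
    min_len = 3.0 / lo
    if rec.duration_s < min_len:
        raise ValueError(
            f"recording of {rec.duration_s:.2f} s shorter than filter warm-up ({min_len:.0f} s)"
        )
    sos = _delta_sos(rec.fs, cfg)
    return EEGRecording(sosfiltfilt(sos, rec.samples), rec.fs, rec.channel_label, rec.t0)


def _filter_segment_with_context(
    seg: np.ndarray,
    fs: float,
    cfg: EngineConfig,
    pre: np.ndarray | None = None,
    post: np.ndarray | None = None,
) -> np.ndarray:
    """Filter one segment using up to ``pad_s`` of true adjacent signal.

    Any context deficit is made up by reflect-padding at the outer edge, so
    batch and streaming runs see bit-identical inputs to the filter.
    """
    pad = int(round(cfg.pad_s * fs))
    pre = np.empty(0) if pre is None else np.asarray(pre, dtype=float)[-pad:]
    post = np.empty(0) if post is None else np.asarray(post, dtype=float)[:pad]
    x = np.concatenate([pre, seg, post])
    left_deficit = pad - pre.size
    right_deficit = pad - post.size
    if left_deficit > 0 or right_deficit > 0:
        x = np.pad(x, (max(left_deficit, 0), max(right_deficit, 0)), mode="reflect")
    y = sosfiltfilt(_delta_sos(fs, cfg), x)
    return y[pad : pad + seg.size]


# ---------------------------------------------------------------------------
# window primitives


def normalize_unit_range(segment: np.ndarray) -> np.ndarray:
    """Affine map of [min, max] onto [-1, +1], preserving sample order.

    The most negative deflection becomes -1 and the most positive +1.
    Raises :class:`DegenerateSegmentError` on a constant segment (zero
    range); callers treat such a segment as rejected.
    """
    x = np.asarray(segment, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples to normalize")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise DegenerateSegmentError("constant segment: zero range")
    return -1.0 + 2.0 * (x - lo) / (hi - lo)


def window_distance(window: np.ndarray, template: Template) -> tuple[float, float]:
    """Mean absolute distance of a window to the template and its opposite.

    Returns ``(d_template, d_opposite)`` where the opposite is the
    polarity-inverted template (under [-1, +1] normalization the inverted
    waveform is the meaningful "opposite"; see docs/methods.md).
    """
    w = np.asarray(window, dtype=float)
    if w.size != template.n_samples:
        raise ValueError(
            f"window length {w.size} != template length {template.n_samples}"
        )
    d_t = float(np.mean(np.abs(w - template.values)))
    d_o = float(np.mean(np.abs(w - template.opposite())))
    return d_t, d_o


def _amplitude_envelope(x: np.ndarray) -> np.ndarray:
    """Delta-activity amplitude: magnitude of the analytic (Hilbert) signal."""
    from scipy.signal import hilbert

    return np.abs(hilbert(np.asarray(x, dtype=float)))


def noise_ratio(window: np.ndarray, envelope: np.ndarray | None = None) -> float:
    """SD/mean ratio of delta-band *activity* for one 1500 ms window.

    "Activity" is the amplitude envelope of the filtered window (magnitude
    of the analytic signal): for clean delta-band EEG the envelope varies
    gently (ratio ~0.4-0.6, never near 1), while a large transient — eye
    blink, electrode pop — makes the envelope spike against its
    surroundings and pushes the ratio above 1. The signed filtered signal
    itself is unusable here (its SD/mean ratio is ~1.1-1.25 even for
    perfectly clean signal). A window with zero mean amplitude is flagged
    noisy by convention. ``envelope`` lets a caller pass a precomputed
    envelope (e.g. of a whole segment's analytic signal) instead of
    recomputing it from the short window.
    """
    env = _amplitude_envelope(window) if envelope is None else np.asarray(envelope, float)
    m = float(env.mean())
    if m == 0.0:
        return np.inf
    return float(env.std() / m)


def classify_window(window: np.ndarray, template: Template, cfg: EngineConfig) -> str | None:
    """Classify one normalized window as ``"match"``, ``"nomatch"`` or None.

    Match iff the mean absolute distance to the template is strictly below
    ``cfg.match_threshold``. Under the default ``opposite_mode="ignore"``
    everything else is a no-match; under ``"opposite_counts_as_nomatch"`` a
    no-match additionally requires distance to the inverted template below
    the threshold, and windows near neither return None (uncounted).
    """
    d_t, d_o = window_distance(window, template)
    if d_t < cfg.match_threshold:
        return "match"
    if cfg.opposite_mode == "opposite_counts_as_nomatch" and not (d_o < cfg.match_threshold):
        return None
    return "nomatch"


# ---------------------------------------------------------------------------
# segment scan


def scan_segment(
    segment: EEGRecording,
    template: Template,
    cfg: EngineConfig | None = None,
    pre: np.ndarray | None = None,
    post: np.ndarray | None = None,
) -> SegmentResult:
    """Scan one 10-second segment and return counts, validity and BEI.

    Pipeline: delta filter (with adjacent-signal context), min-max
    normalize, then slide a template-length window with one-sample stride.
    Per window, in scan order:

    1. noise gate — a noisy window (amplitude SD/mean ratio above
       threshold, computed on the filtered microvolt data) is excluded from
       classification; it increments the rejected count only when it does
       not overlap the previously rejected window.
    2. classification — match iff mean absolute distance to the template
       < 0.5 (on normalized data), else no-match.
    3. deduplication — an event is counted only if its window does not
       overlap the most recently counted event of the same class (greedy
       left-to-right bookkeeping).

    Segment BEI = matches / no-matches, clamped to at most 1; a segment
    with zero matches has BEI 0, one with matches but zero no-matches has
    BEI 1. More than ``max_rejected_windows_per_segment`` non-overlapping
    rejected windows, a constant segment, or a segment with no counted
    events at all invalidates the segment (BEI missing).

    ``pre``/``post`` carry raw adjacent samples used only as filter context.
    """
    cfg = cfg or EngineConfig()
    n_expected = int(round(cfg.segment_s * segment.fs))
    if segment.n_samples != n_expected:
        raise ValueError(
            f"segment has {segment.n_samples} samples, expected {n_expected} "
            f"({cfg.segment_s} s at {segment.fs} Hz)"
        )
    if template.n_samples != cfg.template_len(segment.fs):
        raise ValueError("template not sampled at the segment rate")
    start_s = segment.t0

    raw_range = float(segment.samples.max() - segment.samples.min())
    filt = _filter_segment_with_context(segment.samples, segment.fs, cfg, pre, post)
    filt_range = float(filt.max() - filt.min())
    # a constant (or constant-after-filtering) segment leaves only filter
    # round-off; normalizing that noise floor would classify garbage
    if filt_range <= 1e-8 * max(1.0, raw_range):
        logger.debug("segment %.0fs: DEGENERATE constant signal", start_s)
        return SegmentResult(start_s, 0, 0, 0, False, None, reason="degenerate")
    norm = normalize_unit_range(filt)

    L = template.n_samples
    wins_norm = sliding_window_view(norm, L)

    # envelope of the whole segment's analytic signal: one FFT instead of
    # one per window, and free of per-window Hilbert edge artifacts
    envelope = _amplitude_envelope(filt)
    wins_env = sliding_window_view(envelope, L)
    env_mean = wins_env.mean(axis=1)
    env_sd = wins_env.std(axis=1)
    with np.errstate(invalid="ignore"):
        noisy = (env_mean == 0.0) | (env_sd > cfg.noise_ratio_threshold * env_mean)

    d_t = np.mean(np.abs(wins_norm - template.values), axis=1)
    d_o = np.mean(np.abs(wins_norm + template.values), axis=1)
    is_match = d_t < cfg.match_threshold
    if cfg.opposite_mode == "opposite_counts_as_nomatch":
        countable_nomatch = ~is_match & (d_o < cfg.match_threshold)
    else:
        countable_nomatch = ~is_match

    matches = nomatches = rejected = 0
    last_end = {"match": -1, "nomatch": -1}
    last_rejected_end = -1
    noisy_l = noisy.tolist()
    match_l = is_match.tolist()
    nomatch_l = countable_nomatch.tolist()
    for i in range(len(noisy_l)):
        if noisy_l[i]:
            if i >= last_rejected_end:
                rejected += 1
                last_rejected_end = i + L
            continue
        if match_l[i]:
            cls = "match"
        elif nomatch_l[i]:
            cls = "nomatch"
        else:
            continue
        if i >= last_end[cls]:
            if cls == "match":
                matches += 1
            else:
                nomatches += 1
            last_end[cls] = i + L

    if rejected > cfg.max_rejected_windows_per_segment:
        logger.debug(
            "segment %.0fs: REJECTED_SEGMENT %d non-overlapping noisy windows",
            start_s, rejected,
        )
        return SegmentResult(start_s, matches, nomatches, rejected, False, None,
                             reason="too_many_rejected_windows")
    if matches == 0 and nomatches == 0:
        logger.debug("segment %.0fs: NO_EVENTS all windows rejected", start_s)
        return SegmentResult(start_s, matches, nomatches, rejected, False, None,
                             reason="no_events")
    if matches == 0:
        bei = 0.0
    elif nomatches == 0:
        bei = 1.0
    else:
        bei = min(1.0, matches / nomatches)
    return SegmentResult(start_s, matches, nomatches, rejected, True, bei)


def minute_bei(segments: Sequence[SegmentResult], cfg: EngineConfig | None = None) -> float | None:
    """Median of the valid segment BEIs over one analysis minute.

    Requires exactly ``window_s / segment_s`` (six) segment results; returns
    None (missing) when fewer than ``min_valid_segments_per_minute`` (three)
    are valid.
    """
    cfg = cfg or EngineConfig()
    if len(segments) != cfg.segments_per_window:
        raise ValueError(
            f"expected {cfg.segments_per_window} segment results, got {len(segments)}"
        )
    valid = [s.bei for s in segments if s.valid]
    if len(valid) < cfg.min_valid_segments_per_minute:
        logger.debug("minute ending %.0fs: REJECTED_MINUTE only %d valid segments",
                     segments[-1].start_s + cfg.segment_s, len(valid))
        return None
    return float(np.median(valid))


# ---------------------------------------------------------------------------
# streaming


class StreamingBEI:
    """Incremental BEI computation over a chunked sample stream.

    Samples are pushed in arbitrary chunk sizes; segment results are
    finalized once the segment plus its ``pad_s`` of trailing filter
    context is buffered (or at :meth:`finalize`), so a chunked run emits a
    trace identical to a one-shot batch run. Segments are aligned to a
    fixed 10 s grid anchored at the recording start; each emission is
    stamped with the end of its 60 s analysis window.
    """

    def __init__(self, fs: float, template: Template, cfg: EngineConfig | None = None):
        self.cfg = cfg or EngineConfig()
        self.fs = fs
        self.template = template
        self._seg_len = int(round(self.cfg.segment_s * fs))
        self._pad = int(round(self.cfg.pad_s * fs))
        self._buffer = np.empty(0)
        self._buffer_start = 0  # absolute index of buffer[0]
        self._n_seen = 0
        self._next_seg = 0
        self.segment_log: list[SegmentResult] = []
        self._emissions: list[tuple[float, float, int]] = []
        self._finalized = False

    def push(self, chunk: np.ndarray) -> list[tuple[float, float, int]]:
        """Feed samples; returns emissions (time_s, bei_or_nan, n_valid) now ready."""
        if self._finalized:
            raise RuntimeError("stream already finalized")
        chunk = np.asarray(chunk, dtype=float).ravel()
        if chunk.size:
            if not np.all(np.isfinite(chunk)):
                raise SignalIOError("stream chunk contains non-finite values")
            self._buffer = np.concatenate([self._buffer, chunk])
            self._n_seen += chunk.size
        return self._process(final=False)

    def finalize(self) -> list[tuple[float, float, int]]:
        """Flush segments whose trailing context will never arrive."""
        out = self._process(final=True)
        self._finalized = True
        return out

    def _process(self, final: bool) -> list[tuple[float, float, int]]:
        cfg, L = self.cfg, self._seg_len
        out: list[tuple[float, float, int]] = []
        while True:
            seg_start = self._next_seg * L
            seg_end = seg_start + L
            if seg_end > self._n_seen:
                break
            if not final and seg_end + self._pad > self._n_seen:
                break  # wait for trailing filter context
            rel = seg_start - self._buffer_start
            seg = self._buffer[rel : rel + L]
            pre = self._buffer[max(rel - self._pad, 0) : rel]
            post = self._buffer[rel + L : rel + L + self._pad]
            rec = EEGRecording(seg, self.fs, t0=seg_start / self.fs)
            res = scan_segment(rec, self.template, cfg,
                               pre=pre if pre.size else None,
                               post=post if post.size else None)
            self.segment_log.append(res)
            self._next_seg += 1
            # drop buffer no longer needed (keep pad before next segment)
            keep_from = self._next_seg * L - self._pad
            if keep_from > self._buffer_start:
                self._buffer = self._buffer[keep_from - self._buffer_start :]
                self._buffer_start = keep_from
            k = len(self.segment_log)
            if k >= cfg.segments_per_window:
                window = self.segment_log[k - cfg.segments_per_window : k]
                val = minute_bei(window, cfg)
                t = k * cfg.segment_s
                n_valid = sum(s.valid for s in window)
                out.append((t, np.nan if val is None else val, n_valid))
        self._emissions.extend(out)
        return out

    def trace(self) -> BEITrace:
        if not self._emissions:
            return BEITrace(np.empty(0), np.empty(0), np.empty(0, dtype=int),
                            segment_log=list(self.segment_log))
        t, v, nv = zip(*self._emissions)
        return BEITrace(np.array(t), np.array(v), np.array(nv, dtype=int),
                        segment_log=list(self.segment_log))


def stream_bei(
    rec: EEGRecording,
    template: Template,
    cfg: EngineConfig | None = None,
    chunks: Iterable[np.ndarray] | None = None,
) -> BEITrace:
    """Compute the full BEI trace of a recording.

    Emits one value every ``cadence_s`` starting at t = ``window_s``
    (stamped with the end of the analysis window), each the median over the
    six most recent 10-second segments; segment results are computed once
    and shared across the overlapping minutes. A recording shorter than one
    analysis window yields an empty trace with a warning. Passing
    ``chunks`` feeds the engine incrementally instead of one-shot; both
    paths produce identical traces.
    """
    cfg = cfg or EngineConfig()
    engine = StreamingBEI(rec.fs, template, cfg)
    if rec.duration_s < cfg.window_s:
        logger.warning(
            "recording of %.1f s shorter than the %.0f s analysis window: empty trace",
            rec.duration_s, cfg.window_s,
        )
        return engine.trace()
    if chunks is None:
        engine.push(rec.samples)
    else:
        for chunk in chunks:
            engine.push(chunk)
    engine.finalize()
    return engine.trace()
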