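"""Synthetic EEG and rated-session data with known ground truth.

The study's recordings and videos are not public, so every other module is
exercised on surrogates generated here: band-limited 1/f background noise
standing in for frontal resting EEG, template instances embedded at a
controlled Poisson rate (the "engagement" signal the matcher should find),
blink-like biphasic transients (the dominant Fpz artifact), and paired
two-rater Likert scores whose dependence on a latent per-session
engagement level is set by a single link parameter. All generators are
bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .signal_io import EEGRecording, Template

__all__ = [
    "SynthSpec",
    "gen_background",
    "embed_templates",
    "inject_artifacts",
    "gen_recording",
    "gen_session_dataset",
]


@dataclass
class SynthSpec:
    """Parameters of one synthetic EEG recording.

    duration_s, fs : length and rate (512 Hz matches the study hardware).
    one_over_f_exponent : spectral slope of the background (power ~ 1/f^a;
        a = 1 is the classic EEG-like pink spectrum).
    band_limits : background band edges in Hz (0.5-40 Hz covers the
        clinically relevant EEG range of a dry frontal electrode).
    rms_uv : background RMS amplitude; ~10 uV is typical of frontal EEG.
    embed_rate : expected template occurrences per 10 s segment.
    embed_amplitude : peak scale of embedded templates, as a multiple of
        the background RMS (3x gives the high-SNR events an averaged-ERP
        component represents).
    artifact_rate : blink-like transients per minute (2/min emulates the
        occasional large blink that survives a subject's quiet fixation).
    artifact_amplitude : transient peak in uV (~150 uV, typical blink at Fpz).
    seed : RNG seed; identical (spec, seed) reproduce the samples exactly.
    """

    duration_s: float = 120.0
    fs: float = 512.0
    one_over_f_exponent: float = 1.0
    band_limits: tuple[float, float] = (0.5, 40.0)
    rms_uv: float = 10.0
    embed_rate: float = 2.0
    embed_amplitude: float = 3.0
    artifact_rate: float = 2.0
    artifact_amplitude: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duration_s", "fs"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be positive")
        for name in ("rms_uv", "embed_rate", "embed_amplitude",
                     "artifact_rate", "artifact_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band_limits"] = list(self.band_limits)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthSpec":
        d = dict(d)
        if "band_limits" in d:
            d["band_limits"] = tuple(d["band_limits"])
        return cls(**d)


def gen_background(spec: SynthSpec) -> EEGRecording:
    """Band-limited 1/f background noise at the requested RMS.

    White Gaussian noise is shaped in the frequency domain to an amplitude
    spectrum ~ f^(-a/2) inside ``band_limits`` and zero outside, then
    rescaled to ``rms_uv``. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs))
    white = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, 1.0 / spec.fs)
    lo, hi = spec.band_limits
    shape = np.zeros_like(freqs)
    inband = (freqs >= lo) & (freqs <= hi)
    shape[inband] = freqs[inband] ** (-spec.one_over_f_exponent / 2.0)
    x = np.fft.irfft(np.fft.rfft(white) * shape, n)
    rms = float(np.sqrt(np.mean(x**2)))
    if rms > 0 and spec.rms_uv > 0:
        x *= spec.rms_uv / rms
    else:
        x = np.zeros(n)
    return EEGRecording(x, spec.fs, channel_label="Fpz(synthetic)")


def embed_templates(
    rec: EEGRecording,
    template: Template,
    rate: float,
    amplitude: float,
    seed: int,
) -> tuple[EEGRecording, np.ndarray]:
    """Add scaled template instances at Poisson, non-overlapping times.

    ``rate`` is the expected number of occurrences per 10 s; ``amplitude``
    scales the (unit-normalized) template relative to the recording's RMS.
    Onsets are drawn uniformly over all non-overlapping configurations
    (sorted uniforms on the free space, then instance lengths stacked in);
    a Poisson draw too large for non-overlap to be satisfiable raises.
    Returns the new recording and the sorted ground-truth onset times in
    seconds.
    """
    rng = np.random.default_rng(seed)
    dur = rec.duration_s
    tpl_s = template.n_samples / rec.fs
    n_events = int(rng.poisson(rate * dur / 10.0))
    if n_events == 0:
        return EEGRecording(rec.samples.copy(), rec.fs, rec.channel_label, rec.t0), np.empty(0)
    free = dur - n_events * tpl_s
    if free < 0:
        raise ValueError(
            f"rate {rate}/10s asks for {n_events} non-overlapping {tpl_s:.1f} s "
            f"instances in {dur:.0f} s: infeasible"
        )
    gaps = np.sort(rng.uniform(0, free, size=n_events))
    onsets = (gaps + tpl_s * np.arange(n_events)).tolist()
    base_rms = float(np.sqrt(np.mean(rec.samples**2)))
    scale = amplitude * (base_rms if base_rms > 0 else 1.0)
    x = rec.samples.copy()
    L = template.n_samples
    for t in onsets:
        i = int(round(t * rec.fs))
        x[i : i + L] += scale * template.values[: x.size - i]
    return EEGRecording(x, rec.fs, rec.channel_label, rec.t0), np.asarray(onsets)


def _blink_pulse(fs: float) -> np.ndarray:
    """Unit-peak biphasic half-second transient (blink surrogate)."""
    n = int(round(0.5 * fs))
    t = np.arange(n) / fs
    pulse = np.sin(2 * np.pi * 2.0 * t) * np.hanning(n)
    return pulse / np.abs(pulse).max()


def inject_artifacts(
    rec: EEGRecording,
    rate: float,
    amplitude: float,
    seed: int,
) -> EEGRecording:
    """Add blink-like high-amplitude transients at Poisson times.

    ``rate`` is transients per minute; ``amplitude`` their peak in uV.
    Transients are low-frequency biphasic half-second pulses and may
    overlap each other (real blinks do). Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    n_events = int(rng.poisson(rate * rec.duration_s / 60.0))
    x = rec.samples.copy()
    if n_events == 0 or amplitude == 0:
        return EEGRecording(x, rec.fs, rec.channel_label, rec.t0)
    pulse = amplitude * _blink_pulse(rec.fs)
    dur_s = pulse.size / rec.fs
    for t in rng.uniform(0, max(rec.duration_s - dur_s, 0), size=n_events):
        i = int(round(t * rec.fs))
        seg = pulse[: x.size - i]
        x[i : i + seg.size] += seg
    return EEGRecording(x, rec.fs, rec.channel_label, rec.t0)


def gen_recording(spec: SynthSpec, template: Template) -> tuple[EEGRecording, np.ndarray]:
    """Full synthetic recording: background + embedded templates + artifacts.

    Sub-seeds for the three stages are derived from ``spec.seed`` so the
    recording is reproducible as a whole. Returns the recording and the
    ground-truth template onset times.
    """
    rec = gen_background(spec)
    rec, truth = embed_templates(
        rec, template, spec.embed_rate, spec.embed_amplitude, seed=spec.seed + 1_000_003
    )
    rec = inject_artifacts(
        rec, spec.artifact_rate, spec.artifact_amplitude, seed=spec.seed + 2_000_003
    )
    return rec, truth


def gen_session_dataset(
    n_patients: int,
    engagement_link: float = 5.0,
    rater_noise_sd: float = 0.7,
    seed: int = 0,
):
    """Paired two-session, two-rater Likert datasets with known link.

    Per patient, two latent session engagement levels are drawn uniform on
    [0.2, 0.8]; the expected Likert change of a session is
    ``engagement_link * (latent - 0.5)`` (so link 0 is the exact null and
    the default 5 maps the full latent spread onto +-1.5 points).
    Independent N(0, rater_noise_sd) noise is added per rater, then scores
    are rounded and clipped to the integer [-3, +3] scale. Conditions are
    assigned at random per patient and session order alternates so half
    the cohort starts with feedback, as in a two-period crossover.

    Returns ``(scores_df, pairing_df, truth_df)`` matching the statistics
    interfaces: scores (patient_id, condition, rater1, rater2), pairing
    (patient_id, higher_bei_condition, first_condition), truth (latent
    levels and expected changes).
    """
    import pandas as pd

    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    if rater_noise_sd < 0:
        raise ValueError("rater_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    scores, pairing, truth = [], [], []
    for k in range(n_patients):
        pid = f"P{k + 1:03d}"
        latent = {c: rng.uniform(0.2, 0.8) for c in ("feedback", "no_feedback")}
        first = "feedback" if k % 2 == 0 else "no_feedback"
        higher = max(latent, key=latent.get)
        for cond in ("feedback", "no_feedback"):
            mu = engagement_link * (latent[cond] - 0.5)
            r1, r2 = (
                int(np.clip(np.round(mu + rng.normal(0, rater_noise_sd)), -3, 3))
                for _ in range(2)
            )
            scores.append(
                {"patient_id": pid, "condition": cond, "rater1": r1, "rater2": r2}
            )
            truth.append(
                {"patient_id": pid, "condition": cond,
                 "latent_bei": latent[cond], "expected_change": mu}
            )
        pairing.append(
            {"patient_id": pid, "higher_bei_condition": higher, "first_condition": first}
        )
    return pd.DataFrame(scores), pd.DataFrame(pairing), pd.DataFrame(truth)
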