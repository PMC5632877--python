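"""Session-level engagement metrics and the real-time feedback advisory.

Two deliverables sit here. First, the session BEI: each patient does two
treatment sessions (one with live feedback, one without); all BEI samples
from both sessions are pooled, and each session is graded by the fraction
of its samples lying strictly above the pooled mean + 1 SD — the session
with the larger fraction is the "higher BEI" session. Second, the
escalation ladder a therapist follows when live engagement drops: a
relative decrease of more than 10% below the patient's running average,
sustained for at least 30 s, first prompts encouragement, then a change of
exercise difficulty (intensify if too easy, ease off if too hard), then
rest or passive exercise; recovery resets the ladder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .bei_engine import BEITrace

__all__ = [
    "SessionPair",
    "SessionBEIResult",
    "FeedbackEvent",
    "AdvisorConfig",
    "FeedbackAdvisor",
    "session_bei",
    "feedback_advisor",
    "summarize_blocks",
]

logger = logging.getLogger("bei.session")

ACTIONS = ("encourage", "intensify", "reduce_intensity", "rest_or_passive")


@dataclass
class SessionPair:
    """The two monitored sessions of one patient."""

    trace_fb: BEITrace
    trace_nofb: BEITrace
    patient_id: str = ""
    first_session: str = "feedback"  # which condition came first

    def __post_init__(self) -> None:
        for name, tr in (("feedback", self.trace_fb), ("no_feedback", self.trace_nofb)):
            if tr.clean_values.size == 0:
                raise ValueError(f"{name} trace has no non-missing BEI values")


@dataclass
class SessionBEIResult:
    """Pooled threshold and per-session above-threshold fractions."""

    pooled_mean: float
    pooled_sd: float
    threshold: float
    fraction_above_fb: float
    fraction_above_nofb: float
    higher_session: str  # "feedback" | "no_feedback" | "tie"

    def to_dict(self) -> dict:
        return {
            "pooled_mean": self.pooled_mean,
            "pooled_sd": self.pooled_sd,
            "threshold": self.threshold,
            "fraction_above_fb": self.fraction_above_fb,
            "fraction_above_nofb": self.fraction_above_nofb,
            "higher_session": self.higher_session,
        }


@dataclass
class FeedbackEvent:
    """One advisory emitted by the escalation ladder."""

    time_s: float
    action: str
    triggering_drop: float  # relative decrease vs baseline at emission

    def __post_init__(self) -> None:
        if self.action not in ACTIONS:
            raise ValueError(f"unknown action {self.action!r}")


def session_bei(pair: SessionPair, sd_ddof: int = 1) -> SessionBEIResult:
    """Grade a patient's two sessions by the pooled mean + 1 SD threshold.

    Pools all non-missing BEI values from both sessions, computes the
    pooled mean and sample standard deviation (``sd_ddof=1``; set 0 for the
    population flavor), and per session the fraction of values strictly
    above mean + SD. The session with the strictly larger fraction is
    labelled higher; equal fractions are reported as a tie.
    """
    a = pair.trace_fb.clean_values
    b = pair.trace_nofb.clean_values
    pooled = np.concatenate([a, b])
    if pooled.size < 2:
        raise ValueError("need at least 2 pooled BEI values")
    mean = float(pooled.mean())
    sd = float(pooled.std(ddof=sd_ddof))
    thr = mean + sd
    frac_fb = float(np.mean(a > thr))
    frac_nofb = float(np.mean(b > thr))
    if frac_fb > frac_nofb:
        higher = "feedback"
    elif frac_nofb > frac_fb:
        higher = "no_feedback"
    else:
        higher = "tie"
    return SessionBEIResult(mean, sd, thr, frac_fb, frac_nofb, higher)


@dataclass
class AdvisorConfig:
    """Trigger and escalation parameters of the feedback ladder.

    ``drop_fraction``: relative decrease below the running baseline that
    opens a drop episode (study value: more than 10%). ``min_drop_s``: how
    long the drop must persist before the first advisory (study value:
    30 s). ``escalation_s``: additional persistence between ladder stages
    (unspecified in the study; defaults to the same 30 s). ``cadence_s``:
    arrival spacing of BEI values.
    """

    drop_fraction: float = 0.10
    min_drop_s: float = 30.0
    escalation_s: float = 30.0
    cadence_s: float = 10.0


class FeedbackAdvisor:
    """Causal escalation-ladder state machine over a live BEI stream.

    The baseline is the running mean of all non-missing values seen so far
    in the session (engagement is judged relative to the individual
    patient, not an absolute scale). A drop episode opens when the current
    value falls strictly below (1 - drop_fraction) x baseline and closes on
    recovery; each non-missing in-drop value extends the episode by one
    cadence interval, and missing values neither extend nor reset it. The
    ladder fires encourage at ``min_drop_s``, a difficulty change one
    ``escalation_s`` later (direction set by the performance hint), and
    rest/passive another ``escalation_s`` after that — each stage at most
    once per episode, in order.
    """

    def __init__(self, cfg: AdvisorConfig | None = None, performance: str = "too_easy"):
        if performance not in ("too_easy", "too_hard"):
            raise ValueError("performance hint must be 'too_easy' or 'too_hard'")
        self.cfg = cfg or AdvisorConfig()
        self.performance = performance
        self._sum = 0.0
        self._n = 0
        self._drop_elapsed = 0.0
        self._stage = 0
        self.events: list[FeedbackEvent] = []

    @property
    def baseline(self) -> float | None:
        return self._sum / self._n if self._n else None

    def _stage_action(self) -> str:
        if self._stage == 0:
            return "encourage"
        if self._stage == 1:
            return "intensify" if self.performance == "too_easy" else "reduce_intensity"
        return "rest_or_passive"

    def update(self, time_s: float, value: float | None) -> list[FeedbackEvent]:
        """Consume one emission; returns any events fired at this step."""
        if value is None or not np.isfinite(value):
            return []  # gaps neither extend nor reset a drop
        self._sum += value
        self._n += 1
        baseline = self._sum / self._n
        cfg = self.cfg
        if baseline > 0 and value < (1.0 - cfg.drop_fraction) * baseline:
            self._drop_elapsed += cfg.cadence_s
        else:
            self._drop_elapsed = 0.0
            self._stage = 0
            return []
        fired: list[FeedbackEvent] = []
        while self._stage < 3 and self._drop_elapsed >= (
            cfg.min_drop_s + self._stage * cfg.escalation_s
        ):
            event = FeedbackEvent(
                time_s=time_s,
                action=self._stage_action(),
                triggering_drop=1.0 - value / baseline,
            )
            logger.debug("advisor t=%.0fs: %s (drop %.0f%%)",
                         time_s, event.action, 100 * event.triggering_drop)
            self.events.append(event)
            fired.append(event)
            self._stage += 1
        return fired


def feedback_advisor(
    live_values: BEITrace | Iterable[tuple[float, float | None]],
    cfg: AdvisorConfig | None = None,
    performance: str = "too_easy",
) -> list[FeedbackEvent]:
    """Run the escalation ladder over a full session and return its events.

    ``live_values`` is a BEITrace or an iterable of (time_s, value) pairs
    where value None/NaN marks a missing emission.
    """
    advisor = FeedbackAdvisor(cfg, performance)
    if isinstance(live_values, BEITrace):
        pairs = zip(live_values.times_s, live_values.values)
    else:
        pairs = iter(live_values)
    for t, v in pairs:
        advisor.update(float(t), None if v is None else float(v))
    return advisor.events


@dataclass
class BlockSummary:
    """Start/end/mean BEI over one labelled exercise block."""

    label: str
    start_s: float
    stop_s: float
    first: float | None
    last: float | None
    mean: float | None
    n: int


def summarize_blocks(
    trace: BEITrace,
    blocks: Sequence[tuple[str, float, float]],
) -> tuple[list[BlockSummary], dict[str, float | None]]:
    """Per-block start/end/mean BEI plus per-label averages across blocks.

    ``blocks`` is a sequence of (label, start_s, stop_s) intervals; a block
    picks up the emissions with start_s <= time < stop_s. Per block the
    summary carries the first and last non-missing value and the mean of
    the non-missing values (an exercise run at one difficulty level is
    typically split into two such blocks, averaged per label). A block with
    no non-missing values is reported empty with a warning.
    """
    if len(trace.times_s) == 0:
        raise ValueError("empty trace")
    span = (float(trace.times_s[0]), float(trace.times_s[-1]))
    summaries: list[BlockSummary] = []
    for label, start, stop in blocks:
        if not (start < stop):
            raise ValueError(f"block {label!r}: empty interval [{start}, {stop})")
        if stop <= span[0] or start > span[1]:
            raise ValueError(f"block {label!r} [{start}, {stop}) outside trace span {span}")
        sel = (trace.times_s >= start) & (trace.times_s < stop)
        vals = trace.values[sel]
        clean = vals[np.isfinite(vals)]
        if clean.size == 0:
            logger.warning("block %r [%s, %s): no non-missing BEI values", label, start, stop)
            summaries.append(BlockSummary(label, start, stop, None, None, None, 0))
        else:
            summaries.append(
                BlockSummary(label, start, stop, float(clean[0]), float(clean[-1]),
                             float(clean.mean()), int(clean.size))
            )
    level_means: dict[str, float | None] = {}
    for label in dict.fromkeys(s.label for s in summaries):  # preserve order
        means = [s.mean for s in summaries if s.label == label and s.mean is not None]
        level_means[label] = float(np.mean(means)) if means else None
    return summaries, level_means
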