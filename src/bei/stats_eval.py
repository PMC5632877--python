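"""Paired-session outcome statistics.

Each patient's two sessions are scored for temporary functional change by
two blinded raters on a 7-point Likert scale [-3, +3]; the per-session
score is the rater average, and a patient whose raters ever disagree by
more than one point is excluded. The primary comparison asks whether the
higher-engagement session of each patient scores better than the
lower-engagement one: a one-sided Wilcoxon signed-rank test on the paired
mean scores, plus a 2x2 chi-square for order effects and a probit-based
effect size for the above-threshold proportions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "RatedSession",
    "WilcoxonResult",
    "ChiSquareResult",
    "rater_filter",
    "wilcoxon_paired",
    "chi_square_2x2",
    "categorical_effect_size",
    "cumulative_threshold_curve",
    "LIKERT_MIN",
    "LIKERT_MAX",
]

LIKERT_MIN, LIKERT_MAX = -3, 3

#: maximum tolerated absolute rater disagreement (points)
MAX_RATER_DIFF = 1

#: smallest n for which the normal approximation replaces exact enumeration
NORMAL_APPROX_MIN_N = 10


@dataclass
class RatedSession:
    """One session scored by two blinded raters."""

    patient_id: str
    condition: str  # "feedback" | "no_feedback"
    rater1_score: int
    rater2_score: int

    def __post_init__(self) -> None:
        for s in (self.rater1_score, self.rater2_score):
            if s is None or not float(s).is_integer():
                raise ValueError(f"rater scores must be integers, got {s!r}")
            if not (LIKERT_MIN <= s <= LIKERT_MAX):
                raise ValueError(f"rater score {s} outside [{LIKERT_MIN}, {LIKERT_MAX}]")
        if self.condition not in ("feedback", "no_feedback"):
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def mean_score(self) -> float:
        return (self.rater1_score + self.rater2_score) / 2.0

    @property
    def rater_diff(self) -> int:
        return abs(self.rater1_score - self.rater2_score)


def rater_filter(
    sessions: Sequence[RatedSession],
) -> tuple[list[RatedSession], list[dict]]:
    """Drop patients whose raters disagree by more than one point.

    A patient is excluded if for *any* of their sessions
    |rater1 - rater2| > 1. Returns the retained sessions (original order)
    and an exclusion log of ``{"patient_id", "max_rater_diff"}`` records.
    """
    by_patient: dict[str, list[RatedSession]] = {}
    for s in sessions:
        by_patient.setdefault(s.patient_id, []).append(s)
    excluded = {
        pid: max(s.rater_diff for s in ss)
        for pid, ss in by_patient.items()
        if any(s.rater_diff > MAX_RATER_DIFF for s in ss)
    }
    retained = [s for s in sessions if s.patient_id not in excluded]
    log = [
        {"patient_id": pid, "max_rater_diff": diff} for pid, diff in excluded.items()
    ]
    return retained, log


@dataclass
class WilcoxonResult:
    z: float
    p: float
    n: int  # pairs after zero-difference removal
    w_plus: float
    w_minus: float
    method: str  # "exact" | "normal"
    defined: bool = True


def _signed_ranks(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop zeros; return (nonzero diffs, midranks of their magnitudes)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))  # midranks for ties
    return d, ranks


def _exact_tail_p(ranks: np.ndarray, w_obs: float) -> float:
    """P(W+ >= w_obs) under H0 by enumeration of all 2^n sign assignments."""
    n = ranks.size
    if n > 24:
        raise ValueError(f"exact enumeration over 2^{n} sign patterns is infeasible")
    totals = np.zeros(1)
    for r in ranks:  # distribution of W+ built rank by rank
        totals = np.concatenate([totals, totals + r])
    # float sums: compare with a tolerance so midrank halves don't misbin
    return float(np.mean(totals >= w_obs - 1e-9))


def wilcoxon_paired(
    higher_scores: Sequence[float],
    lower_scores: Sequence[float],
    alternative: str = "greater",
    method: str = "auto",
) -> WilcoxonResult:
    """Wilcoxon signed-rank test of higher- vs lower-engagement sessions.

    Differences higher - lower are formed pairwise; zero differences are
    dropped (classic convention) and tied magnitudes receive midranks. With
    fewer than 10 nonzero pairs (or ``method="exact"``) the p-value comes
    from exact enumeration of all 2^n sign assignments; otherwise from the
    normal approximation with tie-corrected variance. The default
    alternative is one-sided: higher-engagement sessions score higher
    ("two-sided" is available). Z follows the SPSS sign convention — it is
    computed from the rank sum counting *against* the alternative, so a
    positive effect yields a negative Z.

    All differences zero leaves the statistic undefined; the result is
    returned flagged rather than raised.
    """
    if alternative not in ("greater", "two-sided"):
        raise ValueError("alternative must be 'greater' or 'two-sided'")
    if method not in ("auto", "exact", "normal"):
        raise ValueError("method must be 'auto', 'exact' or 'normal'")
    hi = np.asarray(higher_scores, dtype=float)
    lo = np.asarray(lower_scores, dtype=float)
    if hi.shape != lo.shape:
        raise ValueError("paired score vectors must have equal length")
    d, ranks = _signed_ranks(hi - lo)
    n = d.size
    if n == 0:
        return WilcoxonResult(np.nan, np.nan, 0, np.nan, np.nan, "undefined", defined=False)
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())

    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    # SPSS sign: rank sum against the alternative (W-) below its mean -> Z < 0
    z = (w_minus - mu) / np.sqrt(var) if var > 0 else np.nan

    use_exact = method == "exact" or (method == "auto" and n < NORMAL_APPROX_MIN_N)
    if use_exact:
        p_greater = _exact_tail_p(ranks, w_plus)
        p_less = _exact_tail_p(ranks, w_minus)
        used = "exact"
    else:
        p_greater = float(sps.norm.cdf(z))  # z < 0 under the alternative
        p_less = float(sps.norm.sf(z))
        used = "normal"
    if alternative == "greater":
        p = p_greater
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return WilcoxonResult(float(z), p, n, w_plus, w_minus, used)


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    defined: bool = True


def chi_square_2x2(table, correction: bool = False) -> ChiSquareResult:
    """Pearson chi-square on a 2x2 contingency table (df = 1).

    No continuity correction by default; pass ``correction=True`` for the
    Yates-corrected variant. A zero row or column margin leaves the test
    undefined and is reported as such rather than raised.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)) or np.any(t < 0):
            raise ValueError("table entries must be non-negative integers")
        t = t.astype(int)
    if t.sum() == 0 or np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return ChiSquareResult(np.nan, 1, np.nan, defined=False)
    res = sps.chi2_contingency(t, correction=correction)
    return ChiSquareResult(float(res.statistic), int(res.dof), float(res.pvalue))


def categorical_effect_size(
    p1: float,
    p2: float,
    method: str = "probit",
    n: int | None = None,
) -> float:
    """Standardized effect size between two proportions.

    ``"probit"`` (default): d = Phi^-1(p1) - Phi^-1(p2), the difference of
    normal quantiles — the standardized-difference reading of a categorical
    effect. ``"cohens_h"``: h = 2 asin(sqrt(p1)) - 2 asin(sqrt(p2)).
    Positive when p1 > p2. Proportions of exactly 0 or 1 are undefined
    under the probit; when the underlying count ``n`` is supplied they get
    the 1/(2n) continuity adjustment, otherwise an error is raised.
    """
    if method not in ("probit", "cohens_h"):
        raise ValueError("method must be 'probit' or 'cohens_h'")
    props = []
    for p in (p1, p2):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"proportion {p} outside [0, 1]")
        if p in (0.0, 1.0) and method == "probit":
            if n is None:
                raise ValueError(
                    "proportion of exactly 0 or 1: supply n for the 1/(2n) adjustment"
                )
            p = 1.0 / (2 * n) if p == 0.0 else 1.0 - 1.0 / (2 * n)
        props.append(p)
    q1, q2 = props
    if method == "probit":
        return float(sps.norm.ppf(q1) - sps.norm.ppf(q2))
    return float(2 * np.arcsin(np.sqrt(q1)) - 2 * np.arcsin(np.sqrt(q2)))


def cumulative_threshold_curve(
    scores: Sequence[float],
    thresholds: Sequence[float] = tuple(range(LIKERT_MIN, LIKERT_MAX + 1)),
) -> dict[float, float]:
    """Fraction of session scores at or above each Likert threshold.

    Returns {t: fraction of scores >= t} for t in -3..+3 by default; the
    curve is monotone non-increasing and equals 1 at the scale minimum.
    """
    s = np.asarray(scores, dtype=float)
    if s.size == 0:
        raise ValueError("empty score list")
    return {float(t): float(np.mean(s >= t)) for t in thresholds}
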