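"""Single-case and group statistics for the pre/post intervention design.

The evaluation compares change scores (session 2 minus session 1) of
intervention recipients against an untreated control group:

* Crawford-Howell single-case t-test: the case's change score against the
  control changes, ``t = (x - mean(c)) / (sd(c) * sqrt((n+1)/n))`` with
  ``df = n - 1``, one-tailed in the expected improvement direction.  The
  sqrt((n+1)/n) inflation accounts for the small control sample.
* Pooled-variance independent two-sample t-test on change scores for
  domains with enough recipients (df = n1 + n2 - 2).
* Baseline equivalence (two-tailed independent t on session-1 values) and
  a paired two-tailed t on the control group's own pre/post changes, both
  of which should be nonsignificant in a clean design.

Improvement direction per domain mirrors the flag directions: a decrease
is an improvement for a high AvgCon, AvgNoCon, MaxExc and ExcPct; an
increase for NumCon and for a low AvgCon.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .policy import InterventionRecommendation, NormativeReference, compute_thresholds
from .profiles import DOMAINS, SessionProfile

__all__ = [
    "ChangeScore",
    "TestResult",
    "ParticipantData",
    "StudyReport",
    "DegenerateDataError",
    "InsufficientDataError",
    "crawford_howell",
    "independent_t",
    "paired_t",
    "improvement_direction",
    "evaluate_study",
]


class DegenerateDataError(ValueError):
    """Raised when a test statistic is undefined (zero variance)."""


class InsufficientDataError(ValueError):
    """Raised when too few observations are available for a test."""


@dataclass(frozen=True)
class ChangeScore:
    participant: str
    domain: str
    session1: float
    session2: float

    @property
    def delta(self) -> float:
        return self.session2 - self.session1


@dataclass(frozen=True)
class TestResult:
    statistic_t: float
    df: int
    p_value: float
    tails: str  # "one" | "two"
    improvement_direction: str = "none"  # "decrease" | "increase" | "none"

    def __post_init__(self):
        if self.df < 1:
            raise ValueError("df must be >= 1")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def crawford_howell(case_value: float, controls, improvement_direction: str = "decrease") -> TestResult:
    """Single-case t-test of one value against a small control sample.

    One-tailed: small p means the case lies far from the controls in the
    improvement direction.
    """
    controls = np.asarray(controls, dtype=float)
    n = controls.size
    if n < 2:
        raise InsufficientDataError("Crawford-Howell needs at least 2 controls")
    sd = controls.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("control sample has zero variance")
    if improvement_direction not in ("decrease", "increase"):
        raise ValueError("improvement_direction must be 'decrease' or 'increase'")
    t = (case_value - controls.mean()) / (sd * math.sqrt((n + 1) / n))
    df = n - 1
    p = sps.t.cdf(t, df) if improvement_direction == "decrease" else sps.t.sf(t, df)
    return TestResult(statistic_t=float(t), df=df, p_value=float(p), tails="one",
                      improvement_direction=improvement_direction)


def independent_t(group1, group2, tails: str = "two", improvement_direction: str = "none") -> TestResult:
    """Pooled-variance two-sample t-test (df = n1 + n2 - 2).

    One-tailed p is taken in ``improvement_direction`` for group1 relative
    to group2 (decrease: small p when group1 mean is lower).
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise InsufficientDataError("each group needs at least 2 observations")
    df = g1.size + g2.size - 2
    sp2 = ((g1.size - 1) * g1.var(ddof=1) + (g2.size - 1) * g2.var(ddof=1)) / df
    if sp2 == 0:
        raise DegenerateDataError("pooled variance is zero")
    t = (g1.mean() - g2.mean()) / math.sqrt(sp2 * (1 / g1.size + 1 / g2.size))
    if tails == "two":
        p = 2 * sps.t.sf(abs(t), df)
    elif tails == "one":
        if improvement_direction == "decrease":
            p = sps.t.cdf(t, df)
        elif improvement_direction == "increase":
            p = sps.t.sf(t, df)
        else:
            raise ValueError("one-tailed test needs an improvement direction")
    else:
        raise ValueError("tails must be 'one' or 'two'")
    return TestResult(statistic_t=float(t), df=df, p_value=float(min(p, 1.0)), tails=tails,
                      improvement_direction=improvement_direction)


def paired_t(pre_values, post_values) -> TestResult:
    """Two-tailed one-sample t on paired differences (post - pre)."""
    pre = np.asarray(pre_values, dtype=float)
    post = np.asarray(post_values, dtype=float)
    if pre.size != post.size:
        raise ValueError("pre and post must have equal length")
    if pre.size < 2:
        raise InsufficientDataError("paired test needs at least 2 pairs")
    diffs = post - pre
    if diffs.std(ddof=1) == 0:
        if np.all(diffs == 0):
            raise DegenerateDataError("no change: all paired differences are zero")
        raise DegenerateDataError("paired differences have zero variance (constant shift)")
    t, p = sps.ttest_rel(post, pre)
    return TestResult(statistic_t=float(t), df=pre.size - 1, p_value=float(p), tails="two")


def improvement_direction(domain: str, flag_direction: str = "high") -> str:
    """Expected direction of change under successful intervention."""
    if domain == "AvgCon":
        return "decrease" if flag_direction == "high" else "increase"
    if domain == "NumCon":
        return "increase"
    return "decrease"  # AvgNoCon, MaxExc, ExcPct are flagged high only


@dataclass(frozen=True)
class ParticipantData:
    """Two session profiles for one participant, plus recommendations if any."""

    participant: str
    session1: SessionProfile
    session2: SessionProfile
    recommendations: tuple[InterventionRecommendation, ...] = ()


@dataclass
class CaseResult:
    participant: str
    domain: str
    direction: str
    delta: float
    test: TestResult
    significant: bool
    moved_inside: bool


@dataclass
class StudyReport:
    """Full statistical evaluation of a two-session test/control study."""

    baseline_tests: dict[str, TestResult]
    case_results: list[CaseResult]
    group_tests: dict[str, TestResult]
    control_prepost_tests: dict[str, TestResult | None]
    n_interventions: int
    n_significant: int
    n_moved_inside: int
    alpha: float

    def to_dict(self) -> dict:
        def tr(t: TestResult | None):
            if t is None:
                return None
            return {
                "t": t.statistic_t,
                "df": t.df,
                "p": t.p_value,
                "tails": t.tails,
                "improvement_direction": t.improvement_direction,
            }

        return {
            "alpha": self.alpha,
            "baseline_tests": {d: tr(t) for d, t in self.baseline_tests.items()},
            "case_results": [
                {
                    "participant": c.participant,
                    "domain": c.domain,
                    "direction": c.direction,
                    "delta": c.delta,
                    "test": tr(c.test),
                    "significant": c.significant,
                    "moved_inside": c.moved_inside,
                }
                for c in self.case_results
            ],
            "group_tests": {d: tr(t) for d, t in self.group_tests.items()},
            "control_prepost_tests": {d: tr(t) for d, t in self.control_prepost_tests.items()},
            "summary": {
                "interventions_given": self.n_interventions,
                "significant_improvements": self.n_significant,
                "moved_inside_no_intervention_region": self.n_moved_inside,
            },
        }

    def to_markdown(self) -> str:
        lines = ["# Study report", ""]
        lines.append(f"Interventions given: {self.n_interventions}")
        lines.append(f"Significant improvements (alpha={self.alpha}): {self.n_significant}")
        lines.append(f"Moved inside the no-intervention region: {self.n_moved_inside}")
        lines.append("")
        lines.append("## Baseline equivalence (session 1, test vs control, two-tailed)")
        for d, t in self.baseline_tests.items():
            lines.append(f"- {d}: t({t.df}) = {t.statistic_t:.3g}, p = {t.p_value:.3g}")
        lines.append("")
        lines.append("## Intervention cases (Crawford-Howell, one-tailed)")
        for c in self.case_results:
            mark = "significant" if c.significant else "ns"
            lines.append(
                f"- {c.participant} {c.domain} ({c.direction}): delta = {c.delta:.3g}, "
                f"t({c.test.df}) = {c.test.statistic_t:.3g}, p = {c.test.p_value:.3g} [{mark}]"
            )
        lines.append("")
        lines.append("## Group change-score tests (one-tailed, pooled variance)")
        for d, t in self.group_tests.items():
            lines.append(f"- {d}: t({t.df}) = {t.statistic_t:.3g}, p = {t.p_value:.3g}")
        lines.append("")
        lines.append("## Control pre/post checks (paired, two-tailed)")
        for d, t in self.control_prepost_tests.items():
            if t is None:
                lines.append(f"- {d}: no change / degenerate")
            else:
                lines.append(f"- {d}: t({t.df}) = {t.statistic_t:.3g}, p = {t.p_value:.3g}")
        return "\n".join(lines) + "\n"


def _domain_values(group: list[ParticipantData], domain: str, session: int) -> np.ndarray:
    vals = []
    for p in group:
        prof = p.session1 if session == 1 else p.session2
        v = prof.domain_value(domain)
        if math.isnan(v):
            warnings.warn(f"{p.participant}: {domain} undefined in session {session}; dropped", stacklevel=2)
            continue
        vals.append(v)
    return np.asarray(vals, dtype=float)


def _deltas(group: list[ParticipantData], domain: str) -> np.ndarray:
    out = []
    for p in group:
        v1 = p.session1.domain_value(domain)
        v2 = p.session2.domain_value(domain)
        if math.isnan(v1) or math.isnan(v2):
            warnings.warn(f"{p.participant}: {domain} undefined; delta dropped", stacklevel=2)
            continue
        out.append(v2 - v1)
    return np.asarray(out, dtype=float)


def evaluate_study(
    test_group: list[ParticipantData],
    control_group: list[ParticipantData],
    ref: NormativeReference | None = None,
    alpha: float = 0.05,
    min_group_n: int = 6,
) -> StudyReport:
    """Run the full statistical evaluation of a pre/post A/B study.

    Produces baseline-equivalence tests, one Crawford-Howell test per
    intervention case, group change-score tests for (domain, direction)
    subgroups with at least ``min_group_n`` recipients, control pre/post
    checks, and the summary counts.
    """
    if not test_group or not control_group:
        raise InsufficientDataError("both groups must be nonempty")
    ref = ref or NormativeReference.default()
    thresholds = compute_thresholds(ref)

    baseline: dict[str, TestResult] = {}
    for domain in DOMAINS:
        t_vals = _domain_values(test_group, domain, 1)
        c_vals = _domain_values(control_group, domain, 1)
        try:
            baseline[domain] = independent_t(t_vals, c_vals, tails="two")
        except (DegenerateDataError, InsufficientDataError) as exc:
            warnings.warn(f"baseline test skipped for {domain}: {exc}", stacklevel=2)

    control_deltas = {domain: _deltas(control_group, domain) for domain in DOMAINS}

    case_results: list[CaseResult] = []
    recipients: dict[tuple[str, str], list[float]] = {}
    for p in test_group:
        for rec in p.recommendations:
            v1 = p.session1.domain_value(rec.domain)
            v2 = p.session2.domain_value(rec.domain)
            if math.isnan(v1) or math.isnan(v2):
                warnings.warn(f"{p.participant}: {rec.domain} undefined; case skipped", stacklevel=2)
                continue
            delta = v2 - v1
            direction = improvement_direction(rec.domain, rec.direction)
            test = crawford_howell(delta, control_deltas[rec.domain], direction)
            bounds = thresholds[rec.domain]
            if rec.direction == "high":
                inside = v2 < bounds["upper"]
            else:
                inside = v2 > bounds["lower"]
            case_results.append(
                CaseResult(
                    participant=p.participant,
                    domain=rec.domain,
                    direction=rec.direction,
                    delta=float(delta),
                    test=test,
                    significant=bool(test.p_value < alpha),
                    moved_inside=bool(inside),
                )
            )
            recipients.setdefault((rec.domain, rec.direction), []).append(delta)

    group_tests: dict[str, TestResult] = {}
    for (domain, direction), deltas in sorted(recipients.items()):
        if len(deltas) < min_group_n:
            continue
        direction_of_improvement = improvement_direction(domain, direction)
        try:
            group_tests[f"{domain}:{direction}"] = independent_t(
                deltas, control_deltas[domain], tails="one",
                improvement_direction=direction_of_improvement,
            )
        except (DegenerateDataError, InsufficientDataError) as exc:
            warnings.warn(f"group test skipped for {domain}: {exc}", stacklevel=2)

    control_prepost: dict[str, TestResult | None] = {}
    for domain in DOMAINS:
        pre = _domain_values(control_group, domain, 1)
        post = _domain_values(control_group, domain, 2)
        try:
            control_prepost[domain] = paired_t(pre, post) if pre.size == post.size else None
        except DegenerateDataError:
            control_prepost[domain] = None  # reported as "no change"

    n_sig = sum(c.significant for c in case_results)
    n_inside = sum(c.significant and c.moved_inside for c in case_results)
    return StudyReport(
        baseline_tests=baseline,
        case_results=case_results,
        group_tests=group_tests,
        control_prepost_tests=control_prepost,
        n_interventions=len(case_results),
        n_significant=n_sig,
        n_moved_inside=n_inside,
        alpha=alpha,
    )
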