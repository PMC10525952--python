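"""ROC analysis of FD as a disease marker, Youden cutoffs, and FD staging.

Low fractal dimension marks disease, so every decision rule has the form
"positive iff score <= threshold".  AUC uses the rank-sum identity with ties
counted one half; confidence intervals use the Hanley–McNeil standard error
on the logit scale; sensitivity/specificity intervals are exact binomial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps

from .errors import InvalidArgumentError

STAGE_SEVERITY_ORDER = ("Healthy", "Stage I/II", "Stage III", "Stage IV")


@dataclass(frozen=True)
class StagingRule:
    """Published FD cutoffs for staging periodontitis severity."""

    healthy_above: float = 1.188
    stage3_at_or_below: float = 1.158
    stage4_at_or_below: float = 1.102

    def __post_init__(self) -> None:
        if not self.stage4_at_or_below < self.stage3_at_or_below < self.healthy_above:
            raise InvalidArgumentError("staging thresholds must be strictly ordered")


@dataclass(frozen=True)
class SituationSpec:
    """One ROC 'situation': which stages are positive and which negative."""

    name: str
    positive: frozenset[str]
    negative: frozenset[str]

    def __post_init__(self) -> None:
        if not self.positive or not self.negative:
            raise InvalidArgumentError("positive and negative sets must be non-empty")
        if self.positive & self.negative:
            raise InvalidArgumentError("positive and negative sets must be disjoint")


DEFAULT_SITUATIONS: tuple[SituationSpec, ...] = (
    SituationSpec("#1", frozenset({"I", "II", "III", "IV"}), frozenset({"Control"})),
    SituationSpec("#2", frozenset({"III", "IV"}), frozenset({"Control", "I", "II"})),
    SituationSpec("#3", frozenset({"III", "IV"}), frozenset({"I", "II"})),
    SituationSpec("#4", frozenset({"IV"}), frozenset({"I", "II", "III"})),
    SituationSpec("#5", frozenset({"I", "II"}), frozenset({"Control"})),
)


@dataclass(frozen=True)
class RocResult:
    auc: float
    auc_ci: tuple[float, float]
    p_vs_half: float
    criterion: float
    sensitivity: float  # percent
    sensitivity_ci: tuple[float, float]  # percent
    specificity: float  # percent
    specificity_ci: tuple[float, float]  # percent
    n_positive: int
    n_negative: int
    curve: tuple[tuple[float, float], ...]  # (fpr, tpr) points
    situation: str | None = None


def _check_classes(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise InvalidArgumentError("both classes must be present")
    return n_pos, n_neg


def empirical_roc(scores: Sequence[float], labels: Sequence[int],
                  direction: str = "le") -> tuple[tuple[float, float], ...]:
    """ROC points (fpr, tpr) over all distinct thresholds plus endpoints.

    ``direction='le'`` means a subject is called positive when its score is
    at or below the threshold; ``'ge'`` flips the rule.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if direction not in ("le", "ge"):
        raise InvalidArgumentError("direction must be 'le' or 'ge'")
    n_pos, n_neg = _check_classes(labels)
    s = scores if direction == "le" else -scores
    points = [(0.0, 0.0)]
    for t in np.unique(s):
        called = s <= t
        tpr = float((called & (labels == 1)).sum()) / n_pos
        fpr = float((called & (labels == 0)).sum()) / n_neg
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return tuple(points)


def mann_whitney_auc(scores: Sequence[float], labels: Sequence[int],
                     direction: str = "le") -> float:
    """AUC via the rank-sum identity, ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos, n_neg = _check_classes(labels)
    s = scores if direction == "le" else -scores
    ranks = sps.rankdata(s)
    # positives are expected LOW under direction 'le', so negatives rank high
    r_neg = float(ranks[labels == 0].sum())
    return (r_neg - n_neg * (n_neg + 1) / 2.0) / (n_pos * n_neg)


def _hanley_mcneil_se(a: float, n_pos: int, n_neg: int) -> float:
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (a * (1.0 - a) + (n_pos - 1) * (q1 - a * a)
           + (n_neg - 1) * (q2 - a * a)) / (n_pos * n_neg)
    return math.sqrt(max(var, 0.0))


def auc_with_ci(scores: Sequence[float], labels: Sequence[int],
                direction: str = "le",
                confidence: float = 0.95) -> tuple[float, tuple[float, float], float]:
    """AUC, its Hanley–McNeil CI (logit-transformed) and p versus 0.5."""
    labels_arr = np.asarray(labels, dtype=int)
    n_pos, n_neg = _check_classes(labels_arr)
    a = mann_whitney_auc(scores, labels, direction)
    se = _hanley_mcneil_se(a, n_pos, n_neg)
    z = sps.norm.ppf(0.5 + confidence / 2.0)
    if se == 0.0 or a <= 0.0 or a >= 1.0:
        lo = max(0.0, a - z * se)
        hi = min(1.0, a + z * se)
    else:
        logit = math.log(a / (1.0 - a))
        se_logit = se / (a * (1.0 - a))
        lo = 1.0 / (1.0 + math.exp(-(logit - z * se_logit)))
        hi = 1.0 / (1.0 + math.exp(-(logit + z * se_logit)))
    p = 1.0 if se == 0.0 else float(2.0 * sps.norm.sf(abs(a - 0.5) / se))
    return a, (lo, hi), min(p, 1.0)


def clopper_pearson(successes: int, n: int,
                    confidence: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial CI, returned as percentages."""
    if n < 1 or not 0 <= successes <= n:
        raise InvalidArgumentError("need 0 <= successes <= n, n >= 1")
    alpha = 1.0 - confidence
    lo = 0.0 if successes == 0 else float(
        sps.beta.ppf(alpha / 2.0, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(
        sps.beta.ppf(1.0 - alpha / 2.0, successes + 1, n - successes))
    return 100.0 * lo, 100.0 * hi


def youden_criterion(scores: Sequence[float], labels: Sequence[int],
                     direction: str = "le") -> tuple[float, float, float]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Candidate thresholds are the attained score values.  Ties in J are broken
    toward higher sensitivity.  Returns (criterion, sensitivity%, specificity%).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos, n_neg = _check_classes(labels)
    s = scores if direction == "le" else -scores
    best = None
    for t in np.unique(s):
        called = s <= t
        sens = float((called & (labels == 1)).sum()) / n_pos
        spec = float((~called & (labels == 0)).sum()) / n_neg
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12 or (
                abs(j - best[0]) <= 1e-12 and sens > best[1]):
            best = (j, sens, spec, t)
    _, sens, spec, t = best
    criterion = t if direction == "le" else -t
    return float(criterion), 100.0 * sens, 100.0 * spec


def run_situation(records: Iterable, situation: SituationSpec,
                  direction: str = "le") -> RocResult:
    """ROC analysis of FD for one situation over a cohort.

    ``records`` is an iterable of objects (or mapping rows) with ``stage``
    and ``fd`` attributes/keys.
    """
    scores, labels = [], []
    seen = set()
    for r in records:
        stage = r["stage"] if isinstance(r, dict) else r.stage
        fd = r["fd"] if isinstance(r, dict) else r.fd
        seen.add(stage)
        if stage in situation.positive:
            labels.append(1)
            scores.append(float(fd))
        elif stage in situation.negative:
            labels.append(0)
            scores.append(float(fd))
    missing = (situation.positive | situation.negative) - seen
    if missing:
        raise InvalidArgumentError(
            f"cohort is missing stages required by situation "
            f"{situation.name}: {sorted(missing)}")

    scores_arr = np.asarray(scores)
    labels_arr = np.asarray(labels)
    a, ci, p = auc_with_ci(scores_arr, labels_arr, direction)
    crit, sens_pct, spec_pct = youden_criterion(scores_arr, labels_arr, direction)
    n_pos = int(labels_arr.sum())
    n_neg = int(labels_arr.size - n_pos)
    sens_ci = clopper_pearson(round(sens_pct / 100.0 * n_pos), n_pos)
    spec_ci = clopper_pearson(round(spec_pct / 100.0 * n_neg), n_neg)
    curve = empirical_roc(scores_arr, labels_arr, direction)
    return RocResult(auc=a, auc_ci=ci, p_vs_half=p, criterion=crit,
                     sensitivity=sens_pct, sensitivity_ci=sens_ci,
                     specificity=spec_pct, specificity_ci=spec_ci,
                     n_positive=n_pos, n_negative=n_neg, curve=curve,
                     situation=situation.name)


def classify_stage(fd: float, rule: StagingRule | None = None) -> str:
    """Map an FD value to a severity band; boundaries closed on the disease side."""
    if fd <= 0:
        raise InvalidArgumentError("fd must be positive")
    if rule is None:
        rule = StagingRule()
    if fd > rule.healthy_above:
        return "Healthy"
    if fd > rule.stage3_at_or_below:
        return "Stage I/II"
    if fd > rule.stage4_at_or_below:
        return "Stage III"
    return "Stage IV"
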