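"""Adnexal-mass triage scoring and diagnostic-performance evaluation.

The clinical problem: a woman presents with a pelvic (adnexal) mass and the
question is whether it is benign or malignant, because malignant masses belong
in a tertiary oncology centre while benign ones can be managed locally.  Six
widely used triage tests answer that question from pre-operative data:

* RMI 1-4 (Risk of Malignancy Index): the multiplicative score
  ``M x U x CA125`` (``x S`` for version 4) combining a menopausal factor M,
  an ultrasound-morphology factor U, serum CA125 (U/ml) and, for version 4,
  a tumour-size factor S.  Versions differ only in the factor tables and in
  the decision cutoff (200 for versions 1-3, 450 for version 4).
* HE4 (Human Epididymis protein 4, pmol/l) used alone at a 70 pmol/l cutoff.
* ROMA (Risk of Ovarian Malignancy Algorithm): a menopause-specific linear
  predictive index on ln(HE4) and ln(CA125) pushed through the logistic
  function, read as a risk percentage with cutoffs 11.4 % (premenopausal)
  and 29.9 % (postmenopausal).

The module provides, in pipeline order:

1. domain types and the six scoring rules (pure functions of one record);
2. binary-outcome construction (borderline tumours grouped with benign),
   confusion counts, sensitivity/specificity/PPV/NPV with Wilson intervals,
   empirical ROC curves, the Mann-Whitney AUC with DeLong variance,
   DeLong paired AUC comparison, Mann-Whitney and chi-square tests, and
   subgroup evaluation (epithelial-only, pre/postmenopausal);
3. the summary counts of the 155-patient reference cohort the defaults are
   calibrated to, usable as fixed inputs for metric recomputation;
4. a seeded synthetic-cohort generator (log-normal biomarkers, Bernoulli
   ultrasound findings, categorical histology subtypes) so the whole
   analysis runs without patient data;
5. CSV cohort I/O, report writers and the run configuration the CLI uses.

All scoring is deterministic and side-effect free; all simulation randomness
flows through an explicit seed.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "MenopausalStatus",
    "Risk",
    "Histology",
    "UltrasoundFindings",
    "PatientRecord",
    "ScorePanel",
    "TEST_NAMES",
    "DEFAULT_CUTOFFS",
    "Cutoffs",
    "morphology_score",
    "rmi_m_factor",
    "rmi_u_factor",
    "rmi_size_factor",
    "compute_rmi",
    "roma_predictive_index",
    "roma_value",
    "classify_rmi",
    "classify_roma",
    "classify_he4",
    "score_panel",
    "test_score",
    "ConfusionCounts",
    "MetricEstimate",
    "DiagnosticPerformance",
    "RocCurve",
    "AucEstimate",
    "binary_outcome",
    "tabulate_confusion",
    "performance_metrics",
    "round_half_up",
    "empirical_roc",
    "auc",
    "delong_ci",
    "delong_paired_test",
    "mann_whitney_test",
    "chi_square_test",
    "group_summary",
    "SUBGROUP_FILTERS",
    "evaluate_subgroup",
    "evaluate_cohort",
    "reference_class_counts",
    "reference_menopause_by_histology",
    "reference_confusion_counts",
    "composition_summary",
    "ClassProfile",
    "CohortConfig",
    "default_config",
    "generate_cohort",
    "calibration_report",
    "RunConfig",
    "read_cohort",
    "write_cohort",
    "panel_table",
    "write_reports",
    "EPITHELIAL_SUBTYPES",
    "SUBTYPE_COUNTS",
]

logger = logging.getLogger("ovatriage")


# --------------------------------------------------------------------------
# Configuration constants
# --------------------------------------------------------------------------

TEST_NAMES = ("rmi1", "rmi2", "rmi3", "rmi4", "roma", "he4")

#: Published decision cutoffs.  All are inclusive: score >= cutoff is
#: high risk (the ROMA rule is stated with ">=" and the others are applied
#: the same way for uniformity).
DEFAULT_CUTOFFS: Mapping[str, float] = {
    "rmi123": 200.0,
    "rmi4": 450.0,
    "he4": 70.0,      # pmol/l
    "roma_pre": 11.4,  # percent
    "roma_post": 29.9,  # percent
}

#: Upper reporting limit of the HE4 immunoassay (pmol/l); values at or above
#: it are stored right-censored.
DEFAULT_HE4_CENSOR_BOUND = 1500.0


@dataclass(frozen=True)
class Cutoffs:
    """Decision cutoffs for the six tests (all inclusive: >= is high risk)."""

    rmi123: float = DEFAULT_CUTOFFS["rmi123"]
    rmi4: float = DEFAULT_CUTOFFS["rmi4"]
    he4: float = DEFAULT_CUTOFFS["he4"]
    roma_pre: float = DEFAULT_CUTOFFS["roma_pre"]
    roma_post: float = DEFAULT_CUTOFFS["roma_post"]

    def __post_init__(self) -> None:
        for name in ("rmi123", "rmi4", "he4", "roma_pre", "roma_post"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cutoff {name!r} must be positive")


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

class MenopausalStatus(enum.Enum):
    PRE = "pre"
    POST = "post"


class Histology(enum.Enum):
    BENIGN = "benign"
    BORDERLINE = "borderline"
    MALIGNANT = "malignant"


class Risk(enum.Enum):
    LOW = "low"
    HIGH = "high"


@dataclass(frozen=True)
class UltrasoundFindings:
    """The five ultrasound morphology features, one point each."""

    multilocular: bool = False
    solid_areas: bool = False
    bilateral: bool = False
    ascites: bool = False
    intraabdominal_metastases: bool = False

    def __post_init__(self) -> None:
        for name in (
            "multilocular",
            "solid_areas",
            "bilateral",
            "ascites",
            "intraabdominal_metastases",
        ):
            if not isinstance(getattr(self, name), (bool, np.bool_)):
                raise TypeError(f"ultrasound finding {name!r} must be boolean")


@dataclass(frozen=True)
class PatientRecord:
    """One subject: demographics, biomarkers, ultrasound findings, histology.

    ``he4_censored`` marks a right-censored HE4 (the stored value is the
    assay's reporting bound, e.g. 1500 for a ">1500" result).  ``epithelial``
    may be True only for malignant histology; ``max_diameter_cm`` is optional
    but required whenever RMI 4 is requested.
    """

    id: str
    age: float
    menopausal: MenopausalStatus
    ca125: float
    he4: float
    ultrasound: UltrasoundFindings
    histology: Histology
    he4_censored: bool = False
    max_diameter_cm: float | None = None
    subtype: str | None = None
    epithelial: bool | None = None

    def __post_init__(self) -> None:
        if not (self.age > 0 and math.isfinite(self.age)):
            raise ValueError(f"record {self.id!r}: age must be positive and finite")
        if not (self.ca125 >= 0 and math.isfinite(self.ca125)):
            raise ValueError(f"record {self.id!r}: ca125 must be nonnegative and finite")
        if not (self.he4 >= 0 and math.isfinite(self.he4)):
            raise ValueError(f"record {self.id!r}: he4 must be nonnegative and finite")
        if self.max_diameter_cm is not None and not self.max_diameter_cm > 0:
            raise ValueError(f"record {self.id!r}: max_diameter_cm must be positive")
        if self.epithelial and self.histology is not Histology.MALIGNANT:
            raise ValueError(
                f"record {self.id!r}: epithelial flag requires malignant histology"
            )


@dataclass(frozen=True)
class ScorePanel:
    """The six computed test values and their binary classifications."""

    rmi1: float
    rmi2: float
    rmi3: float
    rmi4: float | None
    roma_pi: float
    roma_value: float
    he4: float
    he4_censored: bool
    classifications: Mapping[str, Risk]


# --------------------------------------------------------------------------
# Triage scoring
# --------------------------------------------------------------------------

def morphology_score(findings: UltrasoundFindings) -> int:
    """Ultrasound morphology score: one point per positive finding, 0-5."""
    return int(
        bool(findings.multilocular)
        + bool(findings.solid_areas)
        + bool(findings.bilateral)
        + bool(findings.ascites)
        + bool(findings.intraabdominal_metastases)
    )


_M_POSTMENOPAUSAL = {1: 3, 2: 4, 3: 3, 4: 4}


def rmi_m_factor(version: int, status: MenopausalStatus) -> int:
    """Menopausal factor M: 1 premenopausal; 3 (RMI 1/3) or 4 (RMI 2/4) post."""
    if version not in (1, 2, 3, 4):
        raise ValueError(f"unknown RMI version {version!r}")
    if status is MenopausalStatus.PRE:
        return 1
    return _M_POSTMENOPAUSAL[version]


def rmi_u_factor(version: int, morphology: int) -> int:
    """Ultrasound factor U.

    Version 1 maps morphology 0 -> 0, 1 -> 1, >1 -> 3; versions 2-4 map
    {0, 1} -> 1 and >1 -> 4 (versions 2, 4) or 3 (version 3).
    """
    if version not in (1, 2, 3, 4):
        raise ValueError(f"unknown RMI version {version!r}")
    if not (isinstance(morphology, (int, np.integer)) and 0 <= morphology <= 5):
        raise ValueError(f"morphology score must be an integer in [0, 5], got {morphology!r}")
    if version == 1:
        return 0 if morphology == 0 else (1 if morphology == 1 else 3)
    high = 4 if version in (2, 4) else 3
    return 1 if morphology <= 1 else high


def rmi_size_factor(diameter_cm: float) -> int:
    """Tumour-size factor S: 1 below 7 cm, 2 at or above 7 cm."""
    if not diameter_cm > 0:
        raise ValueError(f"diameter must be positive, got {diameter_cm!r}")
    return 2 if diameter_cm >= 7.0 else 1


def compute_rmi(version: int, record: PatientRecord) -> float:
    """Risk of Malignancy Index ``M * U * CA125`` (``* S`` for version 4)."""
    m = rmi_m_factor(version, record.menopausal)
    u = rmi_u_factor(version, morphology_score(record.ultrasound))
    value = m * u * record.ca125
    if version == 4:
        if record.max_diameter_cm is None:
            raise ValueError(
                f"record {record.id!r}: RMI 4 requires max_diameter_cm"
            )
        value *= rmi_size_factor(record.max_diameter_cm)
    return float(value)


def roma_predictive_index(
    status: MenopausalStatus, he4: float, ca125: float
) -> float:
    """ROMA predictive index PI on the natural-log biomarker scale.

    Premenopausal:  PI = -12.0 + 2.38 ln(HE4) + 0.0626 ln(CA125)
    Postmenopausal: PI = -8.09 + 1.04 ln(HE4) + 0.732 ln(CA125)
    """
    if not he4 > 0:
        raise ValueError(f"ROMA requires HE4 > 0 (got {he4!r}): ln undefined")
    if not ca125 > 0:
        raise ValueError(f"ROMA requires CA125 > 0 (got {ca125!r}): ln undefined")
    if status is MenopausalStatus.PRE:
        return -12.0 + 2.38 * math.log(he4) + 0.0626 * math.log(ca125)
    return -8.09 + 1.04 * math.log(he4) + 0.732 * math.log(ca125)


def roma_value(pi: float) -> float:
    """ROMA risk percentage ``100 exp(PI) / (1 + exp(PI))``.

    Computed through the logistic sigmoid, so it saturates cleanly at 0/100
    for large |PI| instead of overflowing.
    """
    if not math.isfinite(pi):
        raise ValueError(f"ROMA predictive index must be finite, got {pi!r}")
    return float(100.0 * expit(pi))


def classify_rmi(version: int, score: float, cutoffs: Cutoffs = Cutoffs()) -> Risk:
    """High risk iff the RMI meets its cutoff (200 for RMI 1-3, 450 for RMI 4)."""
    if version not in (1, 2, 3, 4):
        raise ValueError(f"unknown RMI version {version!r}")
    cutoff = cutoffs.rmi4 if version == 4 else cutoffs.rmi123
    return Risk.HIGH if score >= cutoff else Risk.LOW


def classify_roma(
    status: MenopausalStatus, value: float, cutoffs: Cutoffs = Cutoffs()
) -> Risk:
    """High risk iff the ROMA percentage meets the menopause-specific cutoff."""
    cutoff = cutoffs.roma_pre if status is MenopausalStatus.PRE else cutoffs.roma_post
    return Risk.HIGH if value >= cutoff else Risk.LOW


def classify_he4(
    he4: float, censored: bool = False, cutoffs: Cutoffs = Cutoffs()
) -> Risk:
    """High risk iff HE4 meets the 70 pmol/l cutoff.

    A right-censored value is a lower bound; a bound at or above the cutoff is
    necessarily high risk, while a bound below it carries no information and
    is rejected as inconsistent input.
    """
    if censored and he4 < cutoffs.he4:
        raise ValueError(
            f"censored HE4 bound {he4} below cutoff {cutoffs.he4} is uninformative"
        )
    return Risk.HIGH if he4 >= cutoffs.he4 else Risk.LOW


def score_panel(
    record: PatientRecord,
    cutoffs: Cutoffs = Cutoffs(),
    *,
    allow_partial: bool = False,
) -> ScorePanel:
    """Apply all six tests to one record.

    With ``allow_partial=True`` a record without a tumour diameter gets
    RMI 4 (and its classification) marked absent instead of raising; the
    remaining five tests are always scored.  Censored HE4 enters ROMA at its
    bound, a conservative lower bound on the predictive index.
    """
    try:
        pi = roma_predictive_index(record.menopausal, record.he4, record.ca125)
    except ValueError as exc:
        raise ValueError(f"ROMA failed for record {record.id!r}: {exc}") from exc
    value = roma_value(pi)

    scores: dict[str, float | None] = {
        "rmi1": compute_rmi(1, record),
        "rmi2": compute_rmi(2, record),
        "rmi3": compute_rmi(3, record),
    }
    if record.max_diameter_cm is None and allow_partial:
        scores["rmi4"] = None
    else:
        scores["rmi4"] = compute_rmi(4, record)

    classifications: dict[str, Risk | None] = {
        "rmi1": classify_rmi(1, scores["rmi1"], cutoffs),
        "rmi2": classify_rmi(2, scores["rmi2"], cutoffs),
        "rmi3": classify_rmi(3, scores["rmi3"], cutoffs),
        "rmi4": None
        if scores["rmi4"] is None
        else classify_rmi(4, scores["rmi4"], cutoffs),
        "roma": classify_roma(record.menopausal, value, cutoffs),
        "he4": classify_he4(record.he4, record.he4_censored, cutoffs),
    }
    return ScorePanel(
        rmi1=scores["rmi1"],
        rmi2=scores["rmi2"],
        rmi3=scores["rmi3"],
        rmi4=scores["rmi4"],
        roma_pi=pi,
        roma_value=value,
        he4=record.he4,
        he4_censored=record.he4_censored,
        classifications=classifications,
    )


def test_score(record: PatientRecord, test: str) -> float | None:
    """The continuous score a named test assigns to one record.

    Returns None for RMI 4 when the diameter is missing.  All six tests are
    oriented larger-is-more-malignant.
    """
    if test in ("rmi1", "rmi2", "rmi3"):
        return compute_rmi(int(test[-1]), record)
    if test == "rmi4":
        return None if record.max_diameter_cm is None else compute_rmi(4, record)
    if test == "roma":
        return roma_value(
            roma_predictive_index(record.menopausal, record.he4, record.ca125)
        )
    if test == "he4":
        return record.he4
    raise ValueError(f"unknown test {test!r}; expected one of {TEST_NAMES}")


# --------------------------------------------------------------------------
# Outcomes, confusion counts and proportion metrics
# --------------------------------------------------------------------------

def binary_outcome(record: PatientRecord) -> bool:
    """True (positive) for malignant histology; borderline groups with benign."""
    if record.histology is None:  # pragma: no cover - dataclass forbids None
        raise ValueError(f"record {record.id!r}: histology missing")
    return record.histology is Histology.MALIGNANT


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"confusion count {name} must be nonnegative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.fn + other.fn,
            self.tn + other.tn,
        )


def tabulate_confusion(
    outcomes: Sequence[bool], classifications: Sequence[Risk]
) -> ConfusionCounts:
    """Cross-tabulate true outcomes against high/low-risk classifications."""
    if len(outcomes) != len(classifications):
        raise ValueError(
            f"length mismatch: {len(outcomes)} outcomes vs "
            f"{len(classifications)} classifications"
        )
    tp = fp = fn = tn = 0
    for pos, cls in zip(outcomes, classifications):
        if cls is Risk.HIGH:
            if pos:
                tp += 1
            else:
                fp += 1
        else:
            if pos:
                fn += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class MetricEstimate:
    """A percentage with its Wilson 95 % (or other level) confidence interval."""

    value: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.value <= self.ci_high <= 100):
            raise ValueError("metric estimate and CI must be ordered within [0, 100]")


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Sensitivity, specificity, PPV and NPV as percentages with CIs.

    PPV/NPV are None ('undefined') when their denominator is zero, which
    happens when a test calls every subject low risk or every subject high
    risk.
    """

    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate | None
    npv: MetricEstimate | None


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Display rounding with ties away from zero (56.25 -> 56.3), the
    convention clinical tables use, unlike Python's round-half-even."""
    factor = 10.0 ** ndigits
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)


def _proportion_estimate(count: int, nobs: int, level: float) -> MetricEstimate:
    lo, hi = proportion_confint(count, nobs, alpha=1 - level, method="wilson")
    value = 100.0 * count / nobs
    # guard against float round-off pushing a boundary CI past the estimate
    return MetricEstimate(
        value=value,
        ci_low=max(0.0, min(100.0 * lo, value)),
        ci_high=min(100.0, max(100.0 * hi, value)),
    )


def performance_metrics(
    counts: ConfusionCounts, level: float = 0.95
) -> DiagnosticPerformance:
    """Point estimates are the exact count ratios x 100; CIs are Wilson score
    intervals (chosen for their small-count behaviour)."""
    if counts.positives == 0:
        raise ValueError("sensitivity undefined: no positive outcomes")
    if counts.negatives == 0:
        raise ValueError("specificity undefined: no negative outcomes")
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level!r}")
    predicted_pos = counts.tp + counts.fp
    predicted_neg = counts.fn + counts.tn
    return DiagnosticPerformance(
        sensitivity=_proportion_estimate(counts.tp, counts.positives, level),
        specificity=_proportion_estimate(counts.tn, counts.negatives, level),
        ppv=None
        if predicted_pos == 0
        else _proportion_estimate(counts.tp, predicted_pos, level),
        npv=None
        if predicted_neg == 0
        else _proportion_estimate(counts.tn, predicted_neg, level),
    )


# --------------------------------------------------------------------------
# ROC, AUC and the DeLong method
# --------------------------------------------------------------------------

def _validate_scores_outcomes(
    scores: Sequence[float], outcomes: Sequence[bool]
) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and outcomes must be 1-D and paired")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    if y.all() or not y.any():
        raise ValueError("need at least one positive and one negative outcome")
    return s, y


@dataclass(frozen=True)
class RocCurve:
    """An empirical ROC curve: one point per distinct score threshold.

    ``thresholds[i]`` is the smallest score still called high risk at point
    i; the leading (0, 0) anchor carries threshold +inf.  Tied scores
    collapse to a single point, so ties appear as diagonal segments.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        if not (
            self.fpr[0] == 0
            and self.tpr[0] == 0
            and self.fpr[-1] == 1
            and self.tpr[-1] == 1
        ):
            raise ValueError("ROC curve must run from (0, 0) to (1, 1)")
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("ROC coordinates must be nondecreasing")


def empirical_roc(
    scores: Sequence[float], outcomes: Sequence[bool]
) -> RocCurve:
    """Sweep the decision threshold from +inf down through every distinct score."""
    s, y = _validate_scores_outcomes(scores, outcomes)
    order = np.argsort(-s, kind="stable")
    s_sorted, y_sorted = s[order], y[order]
    # last index of each run of tied scores = the cumulative counts after
    # calling everything down to that score high risk
    distinct = np.nonzero(np.r_[np.diff(s_sorted) != 0, True])[0]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(~y_sorted)[distinct]
    pos, neg = y.sum(), (~y).sum()
    return RocCurve(
        thresholds=np.r_[np.inf, s_sorted[distinct]],
        fpr=np.r_[0.0, fp / neg],
        tpr=np.r_[0.0, tp / pos],
    )


def auc(scores: Sequence[float], outcomes: Sequence[bool]) -> float:
    """Area under the empirical ROC curve.

    Computed as the Mann-Whitney concordance probability via midranks: the
    mean over all positive-negative pairs of 1 (positive scores higher),
    0.5 (tie) or 0.  Identical, including tie handling, to the trapezoidal
    area under :func:`empirical_roc`.
    """
    s, y = _validate_scores_outcomes(scores, outcomes)
    ranks = stats.rankdata(s)  # midranks
    m = int(y.sum())
    n = y.size - m
    rank_sum = ranks[y].sum()
    return float((rank_sum - m * (m + 1) / 2) / (m * n))


@dataclass(frozen=True)
class AucEstimate:
    auc: float
    se: float
    ci95: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (0 <= lo <= self.auc <= hi <= 1):
            raise ValueError("AUC CI must be ordered and contain the estimate")


def _delong_placements(
    s: np.ndarray, y: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and the per-subject placement values V10 (positives), V01 (negatives)."""
    x_pos = s[y][:, None]
    x_neg = s[~y][None, :]
    heaviside = (x_pos > x_neg).astype(float) + 0.5 * (x_pos == x_neg)
    v10 = heaviside.mean(axis=1)
    v01 = heaviside.mean(axis=0)
    return float(v10.mean()), v10, v01


def delong_ci(
    scores: Sequence[float], outcomes: Sequence[bool], level: float = 0.95
) -> AucEstimate:
    """Nonparametric (DeLong) AUC variance and normal-approximation CI.

    The variance is ``S10/m + S01/n`` where S10, S01 are the sample variances
    of the placement values over the m positives and n negatives.  A
    perfectly separating score has zero variance and a degenerate CI.  The
    CI is truncated to [0, 1].
    """
    s, y = _validate_scores_outcomes(scores, outcomes)
    m = int(y.sum())
    n = y.size - m
    if m < 2 or n < 2:
        raise ValueError("DeLong variance requires >= 2 positives and >= 2 negatives")
    if not 0 < level < 1:
        raise ValueError(f"confidence level must be in (0, 1), got {level!r}")
    a, v10, v01 = _delong_placements(s, y)
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.5 + level / 2)
    return AucEstimate(
        auc=a, se=se, ci95=(max(0.0, a - z * se), min(1.0, a + z * se))
    )


def delong_paired_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    outcomes: Sequence[bool],
) -> tuple[float, float, float]:
    """DeLong paired z-test for the difference of two AUCs on the same subjects.

    Returns ``(auc_a - auc_b, z, two-sided p)``.  The variance of the
    difference is estimated from the per-subject differences of placement
    values, which absorbs the covariance between the two scores.  When the
    two scores are rank-identical the difference and its variance are both
    zero and p = 1.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape:
        raise ValueError("paired score lists must have equal length")
    sa, y = _validate_scores_outcomes(sa, outcomes)
    sb, _ = _validate_scores_outcomes(sb, outcomes)
    m = int(y.sum())
    n = y.size - m
    if m < 2 or n < 2:
        raise ValueError("DeLong test requires >= 2 positives and >= 2 negatives")
    auc_a, v10_a, v01_a = _delong_placements(sa, y)
    auc_b, v10_b, v01_b = _delong_placements(sb, y)
    diff = auc_a - auc_b
    var = (v10_a - v10_b).var(ddof=1) / m + (v01_a - v01_b).var(ddof=1) / n
    if var <= 1e-16:
        # degenerate: identical placements (e.g. a monotone transform)
        return diff, 0.0, 1.0 if abs(diff) <= 1e-12 else 0.0
    z = diff / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return diff, float(z), float(p)


# --------------------------------------------------------------------------
# Rank and association tests
# --------------------------------------------------------------------------

def mann_whitney_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when both groups have n <= 8 and there are no ties;
    otherwise the normal approximation with mid-rank tie correction.
    Returns (U of group_a, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([a, b])
    tie_free = np.unique(combined).size == combined.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def chi_square_test(contingency: Sequence[Sequence[int]]) -> tuple[float, int, float]:
    """Pearson chi-square test of independence, no continuity correction.

    Returns (statistic, degrees of freedom, p).  Rejects tables with a zero
    row or column margin (expected counts undefined).
    """
    table = np.asarray(contingency)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        raise ValueError("contingency table must hold nonnegative integers")
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        raise ValueError("contingency table has a zero row or column margin")
    res = stats.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


# --------------------------------------------------------------------------
# Cohort summaries and subgroup evaluation
# --------------------------------------------------------------------------

def group_summary(
    cohort: Sequence[PatientRecord], test: str
) -> dict[str, dict[str, float] | None]:
    """Median and (min, max) of one test's score per histology class.

    An empty stratum (or one with no scorable records) is reported as None,
    never as zero.
    """
    out: dict[str, dict[str, float] | None] = {}
    for hist in Histology:
        values = [
            v
            for r in cohort
            if r.histology is hist and (v := test_score(r, test)) is not None
        ]
        if not values:
            out[hist.value] = None
        else:
            out[hist.value] = {
                "n": len(values),
                "median": float(np.median(values)),
                "min": float(min(values)),
                "max": float(max(values)),
            }
    return out


SUBGROUP_FILTERS = ("all", "epithelial_only", "premenopausal", "postmenopausal")


def _apply_subgroup(
    cohort: Sequence[PatientRecord], subgroup: str
) -> list[PatientRecord]:
    if subgroup == "all":
        return list(cohort)
    if subgroup == "epithelial_only":
        # positives restricted to epithelial malignancies; negatives all kept
        return [
            r
            for r in cohort
            if r.histology is not Histology.MALIGNANT or bool(r.epithelial)
        ]
    if subgroup == "premenopausal":
        return [r for r in cohort if r.menopausal is MenopausalStatus.PRE]
    if subgroup == "postmenopausal":
        return [r for r in cohort if r.menopausal is MenopausalStatus.POST]
    raise ValueError(f"unknown subgroup {subgroup!r}; expected one of {SUBGROUP_FILTERS}")


def evaluate_subgroup(
    cohort: Sequence[PatientRecord],
    test: str,
    subgroup: str = "all",
    cutoffs: Cutoffs = Cutoffs(),
    level: float = 0.95,
) -> tuple[DiagnosticPerformance, AucEstimate, ConfusionCounts]:
    """Confusion metrics and DeLong AUC for one test on one cohort subgroup.

    RMI 4 is evaluated on the records with a recorded diameter only (the
    other tests keep the full subgroup, so denominators can differ for
    incomplete cohorts).
    """
    subset = _apply_subgroup(cohort, subgroup)
    scored = [
        (r, v) for r in subset if (v := test_score(r, test)) is not None
    ]
    if len(scored) < len(subset):
        logger.warning(
            "%s: %d record(s) without a score dropped from %s evaluation",
            test, len(subset) - len(scored), subgroup,
        )
    if not scored:
        raise ValueError(f"subgroup {subgroup!r} has no scorable records for {test}")
    outcomes = [binary_outcome(r) for r, _ in scored]
    scores = [v for _, v in scored]
    n_pos = sum(outcomes)
    if n_pos == 0 or n_pos == len(outcomes):
        raise ValueError(
            f"subgroup {subgroup!r} leaves no "
            f"{'positive' if n_pos == 0 else 'negative'} outcomes for {test}"
        )
    if n_pos < 5:
        logger.warning(
            "%s/%s: only %d positive outcome(s); estimates are unstable",
            test, subgroup, n_pos,
        )
    classifications = [
        score_panel(r, cutoffs, allow_partial=True).classifications[test]
        for r, _ in scored
    ]
    counts = tabulate_confusion(outcomes, classifications)
    return (
        performance_metrics(counts, level),
        delong_ci(scores, outcomes, level),
        counts,
    )


def evaluate_cohort(
    cohort: Sequence[PatientRecord],
    cutoffs: Cutoffs = Cutoffs(),
    level: float = 0.95,
    subgroups: Sequence[str] = SUBGROUP_FILTERS,
    bonferroni: bool = False,
) -> dict:
    """Full evaluation of all six tests on a cohort.

    Returns a nested dict with, per subgroup and test, the diagnostic
    performance, AUC estimate and confusion counts; per test, the class
    medians and pairwise Mann-Whitney p-values; and the pairwise DeLong AUC
    comparisons on the whole cohort (optionally Bonferroni-adjusted across
    the 15 test pairs; unadjusted by default).
    """
    results: dict = {"subgroups": {}, "medians": {}, "median_tests": {},
                     "auc_comparisons": {}, "roc": {}}
    for subgroup in subgroups:
        per_test: dict[str, dict] = {}
        for test in TEST_NAMES:
            try:
                perf, auc_est, counts = evaluate_subgroup(
                    cohort, test, subgroup, cutoffs, level
                )
            except ValueError as exc:
                logger.warning("skipping %s/%s: %s", test, subgroup, exc)
                per_test[test] = {"error": str(exc)}
                continue
            per_test[test] = {
                "performance": perf,
                "auc": auc_est,
                "counts": counts,
            }
        results["subgroups"][subgroup] = per_test

    pairs = [
        (Histology.BENIGN, Histology.MALIGNANT),
        (Histology.BENIGN, Histology.BORDERLINE),
        (Histology.BORDERLINE, Histology.MALIGNANT),
    ]
    for test in TEST_NAMES:
        results["medians"][test] = group_summary(cohort, test)
        comparisons = {}
        for h_a, h_b in pairs:
            a = [v for r in cohort if r.histology is h_a
                 and (v := test_score(r, test)) is not None]
            b = [v for r in cohort if r.histology is h_b
                 and (v := test_score(r, test)) is not None]
            key = f"{h_a.value}_vs_{h_b.value}"
            if not a or not b:
                comparisons[key] = None
                continue
            u, p = mann_whitney_test(a, b)
            comparisons[key] = {"U": u, "p": p}
        results["median_tests"][test] = comparisons

        scored = [(test_score(r, test), binary_outcome(r)) for r in cohort]
        scored = [(v, o) for v, o in scored if v is not None]
        if scored and 0 < sum(o for _, o in scored) < len(scored):
            results["roc"][test] = empirical_roc(
                [v for v, _ in scored], [o for _, o in scored]
            )

    test_pairs = [
        (a, b) for i, a in enumerate(TEST_NAMES) for b in TEST_NAMES[i + 1:]
    ]
    n_comparisons = len(test_pairs)
    complete = [r for r in cohort if r.max_diameter_cm is not None]
    outcomes = [binary_outcome(r) for r in complete]
    if 0 < sum(outcomes) < len(outcomes):
        score_vectors = {
            t: [test_score(r, t) for r in complete] for t in TEST_NAMES
        }
        for a, b in test_pairs:
            diff, z, p = delong_paired_test(
                score_vectors[a], score_vectors[b], outcomes
            )
            if bonferroni:
                p = min(1.0, p * n_comparisons)
            results["auc_comparisons"][f"{a}_vs_{b}"] = {
                "auc_diff": diff, "z": z, "p": p,
            }
    return results


# --------------------------------------------------------------------------
# Reference-cohort summary counts
# --------------------------------------------------------------------------
# Published summary counts of the 155-patient adnexal-mass cohort the default
# synthetic configuration emulates.  These are fixed input data: the class
# mix, the menopause-by-histology cross-table, and each test's confusion
# counts (after grouping borderline with benign), from which the printed
# percentages can be recomputed with performance_metrics.

_REFERENCE_CLASS_COUNTS = {"benign": 120, "borderline": 8, "malignant": 27}

# rows: premenopausal, postmenopausal; columns: benign, borderline, malignant
_REFERENCE_MENOPAUSE_BY_HISTOLOGY = np.array([[99, 6, 8], [21, 2, 19]])

_REFERENCE_CONFUSION = {
    "rmi1": ConfusionCounts(tp=17, fn=10, tn=120, fp=8),
    "rmi2": ConfusionCounts(tp=18, fn=9, tn=114, fp=14),
    "rmi3": ConfusionCounts(tp=17, fn=10, tn=116, fp=12),
    "rmi4": ConfusionCounts(tp=18, fn=9, tn=118, fp=10),
    "roma": ConfusionCounts(tp=16, fn=11, tn=119, fp=9),
    "he4": ConfusionCounts(tp=10, fn=17, tn=124, fp=4),
}


def reference_class_counts() -> dict[str, int]:
    """Histology class counts of the reference cohort (n = 155)."""
    return dict(_REFERENCE_CLASS_COUNTS)


def reference_menopause_by_histology() -> np.ndarray:
    """2x3 menopause-by-histology cross-table of the reference cohort."""
    return _REFERENCE_MENOPAUSE_BY_HISTOLOGY.copy()


def reference_confusion_counts() -> dict[str, ConfusionCounts]:
    """Per-test confusion counts of the reference cohort (borderline grouped
    with benign, published cutoffs)."""
    return dict(_REFERENCE_CONFUSION)


def composition_summary(class_counts: Mapping[str, int],
                        menopause_by_histology: np.ndarray) -> dict[str, float]:
    """Percentage composition of a cohort from its summary counts.

    Returns class prevalences, the overall pre/postmenopausal split, and the
    per-class pre/postmenopausal percentages, all on the 0-100 scale.
    """
    n = sum(class_counts.values())
    table = np.asarray(menopause_by_histology, dtype=float)
    if table.shape != (2, 3):
        raise ValueError("menopause_by_histology must be 2x3 (pre/post x classes)")
    if table.sum() != n:
        raise ValueError("cross-table total does not match class counts")
    out = {f"{k}_pct": 100.0 * v / n for k, v in class_counts.items()}
    out["premenopausal_pct"] = 100.0 * table[0].sum() / n
    out["postmenopausal_pct"] = 100.0 * table[1].sum() / n
    for j, klass in enumerate(("benign", "borderline", "malignant")):
        col = table[:, j].sum()
        out[f"{klass}_premenopausal_pct"] = 100.0 * table[0, j] / col
        out[f"{klass}_postmenopausal_pct"] = 100.0 * table[1, j] / col
    return out


# --------------------------------------------------------------------------
# Synthetic cohort generation
# --------------------------------------------------------------------------

#: Histology subtype vocabulary with reference-cohort frequencies, per class.
SUBTYPE_COUNTS: Mapping[str, Mapping[str, int]] = {
    "benign": {
        "mature teratoma": 38,
        "benign ovarian cyst": 32,
        "endometrioma": 25,
        "endometrioid tumor": 6,
        "serous cystadenoma": 7,
        "mucinous cystadenoma": 6,
        "tubo-ovarian abscess": 5,
        "leiomyoma": 1,
    },
    "borderline": {
        "borderline serous cystadenoma": 5,
        "borderline mucinous cystadenoma": 3,
    },
    "malignant": {
        "serous cystadenocarcinoma": 10,
        "mucinous cystadenocarcinoma": 2,
        "endometrioid adenocarcinoma": 1,
        "sarcomatous tumor": 3,
        "immature teratoma": 2,
        "granulosa cell tumor": 5,
        "dysgerminoma": 1,
        "ovarian yolk sac tumor": 1,
        "fallopian tube adenocarcinoma": 1,
        "peritoneal carcinoma": 1,
    },
}

#: Malignant subtypes counted as epithelial ovarian cancer.  Fallopian-tube
#: and peritoneal carcinomas are included so the epithelial count composition
#: of the reference cohort (15 of 27) is reachable.
EPITHELIAL_SUBTYPES = frozenset(
    {
        "serous cystadenocarcinoma",
        "mucinous cystadenocarcinoma",
        "endometrioid adenocarcinoma",
        "fallopian tube adenocarcinoma",
        "peritoneal carcinoma",
    }
)


@dataclass(frozen=True)
class ClassProfile:
    """Class-conditional sampling distributions for one histology class.

    Biomarkers and diameter are log-normal (positive, right-skewed — the
    reference ranges span orders of magnitude); log-means are the natural
    logs of the target medians.  Ultrasound findings are independent
    Bernoullis in the order (multilocular, solid areas, bilateral, ascites,
    intra-abdominal metastases).
    """

    prevalence: float
    postmenopausal_prob: float
    ca125_logmean: float
    ca125_logsd: float
    he4_logmean: float
    he4_logsd: float
    ultrasound_probs: tuple[float, float, float, float, float]
    diameter_logmean: float
    diameter_logsd: float
    age_mean: float
    age_sd: float
    subtype_weights: Mapping[str, float]

    def __post_init__(self) -> None:
        probs = (self.prevalence, self.postmenopausal_prob, *self.ultrasound_probs)
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if self.ca125_logsd <= 0 or self.he4_logsd <= 0 or self.diameter_logsd <= 0:
            raise ValueError("log-scale standard deviations must be positive")
        total = sum(self.subtype_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subtype weights must sum to 1, got {total}")


@dataclass(frozen=True)
class CohortConfig:
    """Full parameterization of the synthetic cohort generator."""

    n: int
    seed: int
    profiles: Mapping[str, ClassProfile]
    he4_censor_bound: float = DEFAULT_HE4_CENSOR_BOUND
    marker_rank_correlation: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"cohort size must be >= 1, got {self.n}")
        expected = {h.value for h in Histology}
        if set(self.profiles) != expected:
            raise ValueError(f"profiles must cover exactly {sorted(expected)}")
        total = sum(p.prevalence for p in self.profiles.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"class prevalences must sum to 1, got {total}")
        if not -1 < self.marker_rank_correlation < 1:
            raise ValueError("marker rank correlation must lie in (-1, 1)")
        if self.he4_censor_bound <= 0:
            raise ValueError("HE4 censor bound must be positive")


def _normalized(counts: Mapping[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


def default_config(n: int = 155, seed: int = 0) -> CohortConfig:
    """The default study conditions: a 155-patient cohort with the reference
    class mix (77.4 / 5.2 / 17.4 %), menopausal split and biomarker scale.

    HE4 log-medians equal the logs of the reference per-class medians
    (42.17 / 47.03 / 57.59 pmol/l).  CA125, ultrasound, diameter and age
    parameters are calibrated so composite-score medians land in the
    reference order of magnitude (benign tens, malignant hundreds), with the
    borderline class deliberately mimicking benign biomarkers — no test is
    expected to separate benign from borderline.
    """
    benign = ClassProfile(
        prevalence=0.774,
        postmenopausal_prob=0.175,
        ca125_logmean=math.log(18.0), ca125_logsd=1.0,
        he4_logmean=math.log(42.17), he4_logsd=0.30,
        ultrasound_probs=(0.25, 0.12, 0.08, 0.05, 0.01),
        diameter_logmean=math.log(6.0), diameter_logsd=0.45,
        age_mean=38.0, age_sd=12.0,
        subtype_weights=_normalized(SUBTYPE_COUNTS["benign"]),
    )
    borderline = ClassProfile(
        prevalence=0.052,
        postmenopausal_prob=0.25,
        ca125_logmean=math.log(30.0), ca125_logsd=1.0,
        he4_logmean=math.log(47.03), he4_logsd=0.35,
        ultrasound_probs=(0.35, 0.25, 0.12, 0.08, 0.01),
        diameter_logmean=math.log(7.0), diameter_logsd=0.40,
        age_mean=38.0, age_sd=11.0,
        subtype_weights=_normalized(SUBTYPE_COUNTS["borderline"]),
    )
    malignant = ClassProfile(
        prevalence=0.174,
        postmenopausal_prob=0.704,
        ca125_logmean=math.log(150.0), ca125_logsd=1.5,
        he4_logmean=math.log(57.59), he4_logsd=1.0,
        ultrasound_probs=(0.50, 0.70, 0.35, 0.50, 0.30),
        diameter_logmean=math.log(9.0), diameter_logsd=0.50,
        age_mean=51.0, age_sd=13.0,
        subtype_weights=_normalized(SUBTYPE_COUNTS["malignant"]),
    )
    return CohortConfig(
        n=n,
        seed=seed,
        profiles={
            "benign": benign,
            "borderline": borderline,
            "malignant": malignant,
        },
    )


_VARIABLE_STREAMS = ("menopause", "age", "markers", "ultrasound", "diameter", "subtype")


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Draw a synthetic cohort: a pure function of the config (incl. seed).

    The root SeedSequence spawns one child stream for class assignment plus
    one per (class, variable), so adding a variable or resizing one class
    never perturbs draws elsewhere.  CA125 and HE4 share a Gaussian copula
    with the configured rank correlation (default independent).
    """
    classes = [h.value for h in Histology]
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(1 + len(classes) * len(_VARIABLE_STREAMS))
    class_rng = np.random.default_rng(children[0])
    prevalences = [config.profiles[c].prevalence for c in classes]
    assignment = class_rng.choice(len(classes), size=config.n, p=prevalences)

    records: list[PatientRecord | None] = [None] * config.n
    rho = config.marker_rank_correlation
    # Gaussian copula correlation reproducing a Spearman rank correlation rho
    rho_gauss = 2.0 * math.sin(math.pi * rho / 6.0) if rho else 0.0

    for ci, klass in enumerate(classes):
        profile = config.profiles[klass]
        idx = np.nonzero(assignment == ci)[0]
        k = idx.size
        streams = {
            name: np.random.default_rng(
                children[1 + ci * len(_VARIABLE_STREAMS) + vi]
            )
            for vi, name in enumerate(_VARIABLE_STREAMS)
        }
        postmeno = streams["menopause"].random(k) < profile.postmenopausal_prob
        age = np.clip(
            streams["age"].normal(profile.age_mean, profile.age_sd, k), 14.0, 90.0
        )
        z = streams["markers"].standard_normal((k, 2))
        z_he4 = z[:, 0]
        z_ca125 = rho_gauss * z[:, 0] + math.sqrt(1 - rho_gauss**2) * z[:, 1]
        he4 = np.exp(profile.he4_logmean + profile.he4_logsd * z_he4)
        ca125 = np.exp(profile.ca125_logmean + profile.ca125_logsd * z_ca125)
        censored = he4 >= config.he4_censor_bound
        he4 = np.where(censored, config.he4_censor_bound, he4)
        flags = streams["ultrasound"].random((k, 5)) < np.asarray(
            profile.ultrasound_probs
        )
        diameter = np.exp(
            streams["diameter"].normal(
                profile.diameter_logmean, profile.diameter_logsd, k
            )
        )
        names = list(profile.subtype_weights)
        weights = np.array([profile.subtype_weights[s] for s in names])
        subtype_idx = streams["subtype"].choice(len(names), size=k, p=weights)

        hist = Histology(klass)
        for j, i in enumerate(idx):
            subtype = names[subtype_idx[j]]
            records[i] = PatientRecord(
                id=f"S{i + 1:05d}",
                age=float(round(age[j], 1)),
                menopausal=MenopausalStatus.POST if postmeno[j] else MenopausalStatus.PRE,
                ca125=float(round(ca125[j], 2)),
                he4=float(round(he4[j], 2)),
                he4_censored=bool(censored[j]),
                ultrasound=UltrasoundFindings(*map(bool, flags[j])),
                max_diameter_cm=float(round(diameter[j], 1)),
                histology=hist,
                subtype=subtype,
                epithelial=(subtype in EPITHELIAL_SUBTYPES)
                if hist is Histology.MALIGNANT
                else None,
            )
    return records  # type: ignore[return-value]


def calibration_report(
    cohort: Sequence[PatientRecord], config: CohortConfig
) -> pd.DataFrame:
    """Empirical vs configured per-class summaries with absolute deviations.

    One row per (class, quantity): prevalence, postmenopausal fraction and
    the CA125/HE4 medians.  A class absent from the cohort is reported with
    empirical values NaN, not dropped and not zero.
    """
    rows = []
    n = len(cohort)
    if n == 0:
        raise ValueError("cohort must be nonempty")
    for klass, profile in config.profiles.items():
        members = [r for r in cohort if r.histology.value == klass]
        k = len(members)
        targets = {
            "prevalence": profile.prevalence,
            "postmenopausal_fraction": profile.postmenopausal_prob,
            "ca125_median": math.exp(profile.ca125_logmean),
            "he4_median": math.exp(profile.he4_logmean),
        }
        if k == 0:
            empirical = {q: math.nan for q in targets}
            empirical["prevalence"] = 0.0
        else:
            empirical = {
                "prevalence": k / n,
                "postmenopausal_fraction": sum(
                    r.menopausal is MenopausalStatus.POST for r in members
                ) / k,
                "ca125_median": float(np.median([r.ca125 for r in members])),
                "he4_median": float(np.median([r.he4 for r in members])),
            }
        for quantity, target in targets.items():
            emp = empirical[quantity]
            rows.append(
                {
                    "class": klass,
                    "quantity": quantity,
                    "configured": target,
                    "empirical": emp,
                    "abs_deviation": abs(emp - target),
                    "n": k,
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Cohort CSV I/O
# --------------------------------------------------------------------------

#: CSV schema: these columns are required; subtype and epithelial are optional.
COHORT_COLUMNS = (
    "id", "age", "menopausal", "ca125", "he4",
    "multilocular", "solid_areas", "bilateral", "ascites", "metastases",
    "diameter_cm", "histology",
)
OPTIONAL_COLUMNS = ("subtype", "epithelial")

_MENOPAUSAL_VALUES = {"pre": MenopausalStatus.PRE, "post": MenopausalStatus.POST}


def _parse_flag(cell: str, column: str) -> bool:
    if cell in ("0", "1"):
        return cell == "1"
    raise ValueError(f"column {column!r}: expected 0/1, got {cell!r}")


def _parse_row(row: Mapping[str, str], has_optional: dict[str, bool]) -> PatientRecord:
    menop = _MENOPAUSAL_VALUES.get(row["menopausal"].strip().lower())
    if menop is None:
        raise ValueError(
            f"menopausal must be 'pre' or 'post', got {row['menopausal']!r}"
        )
    try:
        hist = Histology(row["histology"].strip().lower())
    except ValueError:
        raise ValueError(
            f"histology must be benign/borderline/malignant, got {row['histology']!r}"
        ) from None
    he4_cell = row["he4"].strip()
    if he4_cell.startswith(">"):
        he4, censored = float(he4_cell[1:]), True
    else:
        he4, censored = float(he4_cell), False
    diameter_cell = row["diameter_cm"].strip()
    diameter = float(diameter_cell) if diameter_cell else None
    subtype = row.get("subtype", "").strip() or None if has_optional["subtype"] else None
    epithelial = None
    if has_optional["epithelial"]:
        cell = row.get("epithelial", "").strip()
        if cell:
            epithelial = _parse_flag(cell, "epithelial")
    return PatientRecord(
        id=row["id"].strip(),
        age=float(row["age"]),
        menopausal=menop,
        ca125=float(row["ca125"]),
        he4=he4,
        he4_censored=censored,
        ultrasound=UltrasoundFindings(
            multilocular=_parse_flag(row["multilocular"].strip(), "multilocular"),
            solid_areas=_parse_flag(row["solid_areas"].strip(), "solid_areas"),
            bilateral=_parse_flag(row["bilateral"].strip(), "bilateral"),
            ascites=_parse_flag(row["ascites"].strip(), "ascites"),
            intraabdominal_metastases=_parse_flag(
                row["metastases"].strip(), "metastases"
            ),
        ),
        max_diameter_cm=diameter,
        histology=hist,
        subtype=subtype,
        epithelial=epithelial,
    )


def read_cohort(path: str | Path, strict: bool = False) -> list[PatientRecord]:
    """Read a cohort CSV into validated records.

    A ">1500"-style HE4 cell sets the censored flag with the bound as value.
    Rows that fail validation are skipped with a logged reason (``strict``
    turns any bad row into a fatal error); a missing required column is
    always fatal.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if frame.empty:
        raise ValueError(f"{path}: cohort file contains no rows")
    has_optional = {c: c in frame.columns for c in OPTIONAL_COLUMNS}
    records: list[PatientRecord] = []
    errors: list[str] = []
    for i, row in enumerate(frame.to_dict(orient="records")):
        try:
            records.append(_parse_row(row, has_optional))
        except (ValueError, KeyError) as exc:
            errors.append(f"row {i + 2}: {exc}")  # +2: header + 1-based
    if errors:
        message = "; ".join(errors)
        if strict:
            raise ValueError(f"{path}: {len(errors)} invalid row(s): {message}")
        for err in errors:
            logger.warning("%s: skipped %s", path, err)
    if not records:
        raise ValueError(f"{path}: no valid rows")
    return records


def _record_row(r: PatientRecord) -> dict[str, object]:
    u = r.ultrasound
    return {
        "id": r.id,
        "age": r.age,
        "menopausal": r.menopausal.value,
        "ca125": r.ca125,
        "he4": f">{r.he4:g}" if r.he4_censored else r.he4,
        "multilocular": int(u.multilocular),
        "solid_areas": int(u.solid_areas),
        "bilateral": int(u.bilateral),
        "ascites": int(u.ascites),
        "metastases": int(u.intraabdominal_metastases),
        "diameter_cm": "" if r.max_diameter_cm is None else r.max_diameter_cm,
        "histology": r.histology.value,
        "subtype": r.subtype or "",
        "epithelial": "" if r.epithelial is None else int(r.epithelial),
    }


def write_cohort(cohort: Sequence[PatientRecord], path: str | Path) -> None:
    """Write a cohort to the CSV schema read by :func:`read_cohort`."""
    frame = pd.DataFrame([_record_row(r) for r in cohort],
                         columns=list(COHORT_COLUMNS) + list(OPTIONAL_COLUMNS))
    frame.to_csv(path, index=False)


def panel_table(
    cohort: Sequence[PatientRecord], cutoffs: Cutoffs = Cutoffs()
) -> pd.DataFrame:
    """Per-patient score panel: six scores plus six low/high classifications."""
    rows = []
    for r in cohort:
        panel = score_panel(r, cutoffs, allow_partial=True)
        row: dict[str, object] = {
            "id": r.id,
            "rmi1": round(panel.rmi1, 2),
            "rmi2": round(panel.rmi2, 2),
            "rmi3": round(panel.rmi3, 2),
            "rmi4": "NA" if panel.rmi4 is None else round(panel.rmi4, 2),
            "roma_pi": round(panel.roma_pi, 4),
            "roma_value": round(panel.roma_value, 1),
            "he4": f">{panel.he4:g}" if panel.he4_censored else panel.he4,
        }
        for t in TEST_NAMES:
            cls = panel.classifications[t]
            row[f"{t}_risk"] = "NA" if cls is None else cls.value
        rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Report writing and run configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """Everything an evaluation run needs besides the cohort itself."""

    cutoffs: Cutoffs = Cutoffs()
    ci_level: float = 0.95
    subgroups: tuple[str, ...] = SUBGROUP_FILTERS
    out_dir: Path = Path("ovatriage_reports")
    seed: int = 0
    strict: bool = False
    bonferroni: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.ci_level < 1:
            raise ValueError("CI level must be in (0, 1)")
        unknown = set(self.subgroups) - set(SUBGROUP_FILTERS)
        if unknown:
            raise ValueError(f"unknown subgroup(s) {sorted(unknown)}")


def _fmt_metric(est: MetricEstimate | None) -> tuple[object, object, object]:
    if est is None:
        return "NA", "NA", "NA"
    return round(est.value, 1), round(est.ci_low, 1), round(est.ci_high, 1)


def _performance_frame(per_test: Mapping[str, dict]) -> pd.DataFrame:
    rows = []
    for test in TEST_NAMES:
        entry = per_test.get(test, {})
        if "error" in entry or not entry:
            rows.append({"test": test, "n": "NA", "sensitivity_pct": "NA",
                         "specificity_pct": "NA", "ppv_pct": "NA", "npv_pct": "NA",
                         "auc": "NA", "auc_ci_low": "NA", "auc_ci_high": "NA"})
            continue
        perf: DiagnosticPerformance = entry["performance"]
        auc_est: AucEstimate = entry["auc"]
        counts: ConfusionCounts = entry["counts"]
        row: dict[str, object] = {
            "test": test,
            "n": counts.positives + counts.negatives,
        }
        for name, est in (
            ("sensitivity", perf.sensitivity),
            ("specificity", perf.specificity),
            ("ppv", perf.ppv),
            ("npv", perf.npv),
        ):
            value, lo, hi = _fmt_metric(est)
            row[f"{name}_pct"] = value
            row[f"{name}_ci_low"] = lo
            row[f"{name}_ci_high"] = hi
        row["auc"] = round(auc_est.auc, 3)
        row["auc_ci_low"] = round(auc_est.ci95[0], 3)
        row["auc_ci_high"] = round(auc_est.ci95[1], 3)
        rows.append(row)
    return pd.DataFrame(rows)


def write_reports(results: dict, config: RunConfig) -> list[Path]:
    """Write evaluation results to CSV files in ``config.out_dir``.

    Emits one performance table per subgroup, the per-class median/range
    table, the pairwise Mann-Whitney median-comparison table, the pairwise
    DeLong AUC comparisons and one ROC coordinate file per test.
    Percentages are written at 1 decimal, AUCs at 3, matching conventional
    display precision.  Deterministic inputs yield byte-identical files.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for subgroup, per_test in results["subgroups"].items():
        path = out / f"performance_{subgroup}.csv"
        _performance_frame(per_test).to_csv(path, index=False)
        written.append(path)

    median_rows = []
    for test in TEST_NAMES:
        for klass, summary in results["medians"][test].items():
            if summary is None:
                median_rows.append({"test": test, "class": klass, "n": 0,
                                    "median": "NA", "min": "NA", "max": "NA"})
            else:
                median_rows.append({
                    "test": test, "class": klass, "n": int(summary["n"]),
                    "median": round(summary["median"], 2),
                    "min": round(summary["min"], 2),
                    "max": round(summary["max"], 2),
                })
    path = out / "medians_by_class.csv"
    pd.DataFrame(median_rows).to_csv(path, index=False)
    written.append(path)

    comparison_rows = []
    for test in TEST_NAMES:
        for pair, res in results["median_tests"][test].items():
            comparison_rows.append({
                "test": test, "comparison": pair,
                "U": "NA" if res is None else round(res["U"], 1),
                "p": "NA" if res is None else format(res["p"], ".4g"),
            })
    path = out / "median_comparisons.csv"
    pd.DataFrame(comparison_rows).to_csv(path, index=False)
    written.append(path)

    auc_rows = [
        {"pair": pair, "auc_diff": round(res["auc_diff"], 4),
         "z": round(res["z"], 3), "p": format(res["p"], ".4g")}
        for pair, res in results["auc_comparisons"].items()
    ]
    path = out / "auc_comparisons.csv"
    pd.DataFrame(auc_rows, columns=["pair", "auc_diff", "z", "p"]).to_csv(
        path, index=False
    )
    written.append(path)

    for test, curve in results["roc"].items():
        path = out / f"roc_{test}.csv"
        pd.DataFrame({
            "threshold": curve.thresholds,
            "fpr": curve.fpr,
            "tpr": curve.tpr,
        }).to_csv(path, index=False)
        written.append(path)

    logger.info("wrote %d report file(s) to %s", len(written), out)
    return written
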