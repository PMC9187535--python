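"""Screening-test evaluation of triage output.

Implements the pooled-confusion convention of a screening test: an
inconclusive rating can never clear a patient, so inconclusive cases count
as test-positive — true positive when disease is present, false positive
when it is absent.  Two pooling modes are provided:

``"as_published"``
    Every diseased inconclusive case is a true positive.
``"strict"``
    A diseased inconclusive case is a true positive only if its per-case
    detection flag (the voxel-level anomaly map overlapping the lesion) is
    set; otherwise it is a false negative.

On top of the pooled 2x2 table: sensitivity/specificity/PPV/NPV,
test-yield summaries, ROC/AUC with the Youden-optimal cutoff, and a
two-sided Fisher exact test for comparing definite-rating proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve

from .calibration import ScoredCase

__all__ = [
    "ConfusionSummary",
    "ScreeningMetrics",
    "YieldSummary",
    "RocResult",
    "pooled_confusion",
    "screening_metrics",
    "yield_summary",
    "roc_auc",
    "fisher_exact_2x2",
]

LABELS = ("pathological", "inconclusive", "normal")


@dataclass
class ConfusionSummary:
    """3-label x 2-truth counts plus the pooled screening 2x2 counts.

    Pooling identity: ``tp = path&disease + (pooled) inconclusive&disease``,
    ``fp = path&no-disease + inconclusive&no-disease``,
    ``tn = normal&no-disease``, ``fn = normal&disease`` (plus, in strict
    mode, undetected diseased inconclusive cases).
    """

    table: dict[tuple[str, bool], int]
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def pooled_confusion(
    cases: list[tuple[str, bool]] | list[tuple[str, bool, bool]],
    mode: str = "as_published",
) -> ConfusionSummary:
    """Pool triage labels against binary truth into screening counts.

    ``cases`` holds ``(label, disease_present)`` tuples, optionally with a
    third ``detected`` flag used by ``mode="strict"`` for diseased
    inconclusive cases (defaults to True when omitted).
    """
    if mode not in ("as_published", "strict"):
        raise ValueError(f"unknown pooling mode {mode!r}")
    table: dict[tuple[str, bool], int] = {(l, t): 0 for l in LABELS for t in (True, False)}
    tp = fp = tn = fn = 0
    for case in cases:
        label, disease = case[0], bool(case[1])
        detected = bool(case[2]) if len(case) > 2 else True
        if label not in LABELS:
            raise ValueError(f"unknown triage label {label!r}")
        table[(label, disease)] += 1
        if label == "pathological":
            tp += disease
            fp += not disease
        elif label == "normal":
            fn += disease
            tn += not disease
        else:  # inconclusive counts as test-positive (screening convention)
            if not disease:
                fp += 1
            elif mode == "as_published" or detected:
                tp += 1
            else:
                fn += 1
    return ConfusionSummary(table=table, tp=tp, fp=fp, tn=tn, fn=fn)


@dataclass
class ScreeningMetrics:
    """Sensitivity, specificity, PPV, NPV as proportions in [0, 1].

    A metric whose denominator is zero is ``None`` (explicitly undefined),
    never silently 0.
    """

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None

    def as_percent(self) -> dict[str, float | None]:
        return {
            k: (None if v is None else 100.0 * v)
            for k, v in self.__dict__.items()
        }


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def screening_metrics(c: ConfusionSummary) -> ScreeningMetrics:
    """Standard screening metrics from pooled counts."""
    return ScreeningMetrics(
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        ppv=_ratio(c.tp, c.tp + c.fp),
        npv=_ratio(c.tn, c.tn + c.fn),
    )


@dataclass
class YieldSummary:
    """Share of definite (non-inconclusive) ratings, overall and per class."""

    n_total: int
    n_definite: int
    n_inconclusive: int
    test_yield: float
    per_class_definite_rate: dict[str, float | None] = field(default_factory=dict)


def yield_summary(cases: list[tuple[str, str]]) -> YieldSummary:
    """``cases``: (triage label, ground-truth class) pairs.

    The ground-truth class is free-form (e.g. normal / chronic / subacute /
    hvs / lacunar); the definite rate is reported for each class present.
    """
    n_total = len(cases)
    if n_total == 0:
        raise ValueError("no cases")
    definite = [label != "inconclusive" for label, _ in cases]
    for label, _ in cases:
        if label not in LABELS:
            raise ValueError(f"unknown triage label {label!r}")
    n_definite = int(sum(definite))
    classes = sorted({cls for _, cls in cases})
    per_class = {}
    for cls in classes:
        sub = [d for d, (_, c) in zip(definite, cases) if c == cls]
        per_class[cls] = sum(sub) / len(sub)
    return YieldSummary(
        n_total=n_total,
        n_definite=n_definite,
        n_inconclusive=n_total - n_definite,
        test_yield=n_definite / n_total,
        per_class_definite_rate=per_class,
    )


@dataclass
class RocResult:
    """ROC summary: trapezoidal AUC (= Mann-Whitney with midrank ties),
    Youden index J = max(sens + spec - 1) with its maximizing cutoff, and a
    seeded percentile-bootstrap 95% CI for the AUC."""

    auc: float
    youden_j: float
    youden_cutoff: float
    auc_ci: tuple[float, float]
    n_normal: int
    n_pathological: int


def _auc_from_scores(y: np.ndarray, s: np.ndarray) -> float:
    fpr, tpr, _ = roc_curve(y, s, drop_intermediate=False)
    return float(np.trapezoid(tpr, fpr))


def roc_auc(cases: list[ScoredCase], n_boot: int = 2000, seed: int = 0) -> RocResult:
    """ROC analysis of anomaly scores against binary truth.

    The Youden-optimal cutoff is chosen among the observed scores, applied
    as ``score > cutoff -> pathological``; ties in J break toward the
    higher cutoff.  The bootstrap resamples cases with a fixed seed;
    degenerate (single-class) replicates are skipped.
    """
    y = np.array([c.truth == "pathological" for c in cases], dtype=int)
    s = np.array([c.score for c in cases], dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("ROC analysis requires both truth classes")
    auc = _auc_from_scores(y, s)

    cutoffs = np.unique(s)[::-1]  # descending: ties in J resolve high
    best_j, best_cut = -np.inf, cutoffs[0]
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    for cut in cutoffs:
        pred = s > cut
        sens = (pred & (y == 1)).sum() / n_pos
        spec = (~pred & (y == 0)).sum() / n_neg
        j = sens + spec - 1.0
        if j > best_j:
            best_j, best_cut = j, cut
    rng = np.random.default_rng(seed)
    boots = []
    n = len(y)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.sum() in (0, n):
            continue
        boots.append(_auc_from_scores(yb, s[idx]))
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan))
    return RocResult(
        auc=auc,
        youden_j=float(best_j),
        youden_cutoff=float(best_cut),
        auc_ci=(float(lo), float(hi)),
        n_normal=n_neg,
        n_pathological=n_pos,
    )


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]]
    (hypergeometric enumeration: tables as or less probable than observed)."""
    for x in (a, b, c, d):
        if x < 0 or int(x) != x:
            raise ValueError("counts must be non-negative integers")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)
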