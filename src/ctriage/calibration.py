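"""Two-threshold triage calibration under a zero false-omission constraint.

A triage system labels each scan ``normal`` (score below a lower cutoff),
``pathological`` (above an upper cutoff), or ``inconclusive`` (in between).
Calibration picks the cutoffs on a labelled validation set so that no
truly pathological case is ever labelled normal (false omission rate 0)
while as few normal cases as possible receive a definite pathological
label:

* ``t_low``  = the minimum score among pathological validation cases, so
  every score strictly below it belongs to normal cases only;
* ``t_high`` = the maximum score among normal validation cases, so every
  score strictly above it belongs to pathological cases only (validation
  FPR of the definite-pathological label is 0, the minimum achievable).

If the classes separate (``t_low > t_high``) both cutoffs collapse to
their midpoint and the inconclusive band vanishes.  Scores exactly equal
to either cutoff are rated inconclusive — ties never receive a definite
label.

:class:`TriageCalibrator` wraps the rule as a scikit-learn estimator:
``fit(scores, truth_labels)`` learns ``t_low_``/``t_high_``;
``predict(scores)`` returns triage labels.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "TriageThresholds",
    "ScoredCase",
    "TriageCalibrator",
    "calibrate_thresholds",
    "classify",
    "TRIAGE_LABELS",
]

TRIAGE_LABELS = ("normal", "inconclusive", "pathological")
TRUTH_LABELS = ("normal", "pathological")


@dataclass(frozen=True)
class ScoredCase:
    """One validation/test case: anomaly score plus ground-truth label."""

    subject_id: str
    score: float
    truth: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0, 1], got {self.score}")
        if self.truth not in TRUTH_LABELS:
            raise ValueError(f"truth must be one of {TRUTH_LABELS}, got {self.truth!r}")


@dataclass(frozen=True)
class TriageThresholds:
    """Lower/upper anomaly-score cutoffs bounding the inconclusive band."""

    t_low: float
    t_high: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.t_low <= self.t_high <= 1.0:
            raise ValueError(
                f"need 0 <= t_low <= t_high <= 1, got ({self.t_low}, {self.t_high})"
            )

    def save(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump({"t_low": self.t_low, "t_high": self.t_high}, fh, indent=2)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "TriageThresholds":
        with open(path) as fh:
            d = json.load(fh)
        return cls(t_low=d["t_low"], t_high=d["t_high"])


def calibrate_thresholds(
    validation: Sequence[ScoredCase], margin: float = 0.0
) -> TriageThresholds:
    """Calibrate the triage cutoffs on a labelled validation set.

    Requires at least one case of each truth class.  ``margin`` optionally
    widens the inconclusive band symmetrically (``t_low`` down, ``t_high``
    up, clipped to [0, 1]) for deployment conservatism; default 0.
    """
    if margin < 0:
        raise ValueError("margin must be >= 0")
    path_scores = [c.score for c in validation if c.truth == "pathological"]
    norm_scores = [c.score for c in validation if c.truth == "normal"]
    if not path_scores or not norm_scores:
        raise ValueError(
            "calibration requires at least one normal and one pathological case"
        )
    t_low = min(path_scores)
    t_high = max(norm_scores)
    if t_low > t_high:  # classes separate: no inconclusive band needed
        t_low = t_high = 0.5 * (t_low + t_high)
    t_low = max(0.0, t_low - margin)
    t_high = min(1.0, t_high + margin)
    return TriageThresholds(t_low=t_low, t_high=t_high)


def classify(score: float, thresholds: TriageThresholds) -> str:
    """Triage label for one anomaly score.

    Strictly below ``t_low`` -> ``"normal"``; strictly above ``t_high`` ->
    ``"pathological"``; otherwise (including exact ties with either cutoff)
    ``"inconclusive"``.
    """
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score must be in [0, 1], got {score}")
    if score < thresholds.t_low:
        return "normal"
    if score > thresholds.t_high:
        return "pathological"
    return "inconclusive"


class TriageCalibrator(BaseEstimator):
    """Scikit-learn-style wrapper around the two-threshold triage rule.

    Parameters
    ----------
    margin : float, default=0.0
        Optional symmetric widening of the inconclusive band.

    Attributes
    ----------
    t_low_, t_high_ : float
        Calibrated cutoffs.
    thresholds_ : TriageThresholds
        The same cutoffs as a value object.
    """

    def __init__(self, margin: float = 0.0) -> None:
        self.margin = margin

    def fit(self, X: Iterable[float], y: Iterable[str]) -> "TriageCalibrator":
        """``X``: anomaly scores; ``y``: truth labels (normal/pathological)."""
        scores = np.asarray(list(X), dtype=float).ravel()
        truths = list(y)
        cases = [
            ScoredCase(subject_id=str(i), score=float(s), truth=t)
            for i, (s, t) in enumerate(zip(scores, truths, strict=True))
        ]
        thr = calibrate_thresholds(cases, margin=self.margin)
        self.thresholds_ = thr
        self.t_low_ = thr.t_low
        self.t_high_ = thr.t_high
        return self

    def predict(self, X: Iterable[float]) -> np.ndarray:
        """Triage labels for an array of anomaly scores."""
        check_is_fitted(self, "thresholds_")
        scores = np.asarray(list(X), dtype=float).ravel()
        return np.array([classify(float(s), self.thresholds_) for s in scores], dtype=object)
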