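"""Normal / cirrhotic classification of run-connectivity features.

Two routes mirror common clinical-texture practice:

* interval rules — per ``(radius, k)`` a normal upper bound and a
  cirrhotic lower bound with a nonempty indeterminate gap between them
  (counts falling in the gap are flagged as fibrosis-suspect);
* learned boundaries — a linear-margin classifier (SVM) or a k-nearest-
  neighbor vote on the 2-D projection ``(count[R=3,k=4], count[R=3,k=5])``.

The margin classifier standardizes the two features and rescales the box
constraint per class by group size (the historical default of the classic
MATLAB ``svmtrain``), so the 44-vs-6 class imbalance of the reference data
does not collapse the fit onto the majority class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from os import PathLike

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from hepatex.connectivity import ConnectivityFeatures

LABEL_NORMAL = "normal"
LABEL_CIRRHOTIC = "cirrhotic"
LABEL_INDETERMINATE = "indeterminate"

#: 2-D feature projection used by the margin / neighbor classifiers.
DEFAULT_FEATURE_PAIR = ((3, 4), (3, 5))


@dataclass(frozen=True)
class IntervalRule:
    """Count intervals for one ``(radius, k)``: normal <= normal_max,
    cirrhotic >= cirrhotic_min, indeterminate in between."""

    normal_max: int
    cirrhotic_min: int

    def __post_init__(self) -> None:
        if self.normal_max >= self.cirrhotic_min:
            raise ValueError(
                f"overlapping intervals: normal_max {self.normal_max} >= "
                f"cirrhotic_min {self.cirrhotic_min}"
            )

    def classify(self, count: int) -> str:
        if count <= self.normal_max:
            return LABEL_NORMAL
        if count >= self.cirrhotic_min:
            return LABEL_CIRRHOTIC
        return LABEL_INDETERMINATE


@dataclass(frozen=True)
class IntervalRuleSet:
    """Per-(radius, k) interval rules; the packaged default holds the
    reference bounds derived from the 50-template study data."""

    rules: dict[tuple[int, int], IntervalRule]

    @classmethod
    def from_mapping(cls, mapping: dict[str, dict[str, int]]) -> "IntervalRuleSet":
        rules = {}
        for key, bounds in mapping.items():
            r_part, k_part = key.split("_")
            radius = int(r_part.lstrip("Rr"))
            k = int(k_part.lstrip("k"))
            rules[(radius, k)] = IntervalRule(
                normal_max=int(bounds["normal_max"]),
                cirrhotic_min=int(bounds["cirrhotic_min"]),
            )
        return cls(rules=rules)

    @classmethod
    def from_json(cls, path: str | PathLike) -> "IntervalRuleSet":
        with open(path) as fh:
            return cls.from_mapping(json.load(fh))

    @classmethod
    def default(cls) -> "IntervalRuleSet":
        ref = resources.files("hepatex.data").joinpath("interval_rules.json")
        return cls.from_mapping(json.loads(ref.read_text()))

    def __getitem__(self, key: tuple[int, int]) -> IntervalRule:
        try:
            return self.rules[key]
        except KeyError:
            raise KeyError(
                f"no interval rule for radius={key[0]}, k={key[1]}"
            ) from None


@dataclass(frozen=True)
class ClassificationResult:
    label: str
    per_rule_votes: dict[tuple[int, int], str]
    evaluated_operator: str


def classify_by_rules(
    features: ConnectivityFeatures,
    rules: IntervalRuleSet,
    radius: int | None = None,
    run_length: int | None = None,
) -> ClassificationResult:
    """Label a template by interval rules.

    With an explicit ``(radius, run_length)`` a single rule decides the
    label.  Otherwise every rule with a matching count votes and the
    majority of non-indeterminate votes wins; ties (or all-indeterminate)
    yield ``indeterminate``.
    """
    if (radius is None) != (run_length is None):
        raise ValueError("give both radius and run_length, or neither")
    if radius is not None:
        pairs = [(radius, run_length)]
    else:
        pairs = [key for key in sorted(rules.rules) if key in features.counts]
        if not pairs:
            raise ValueError("no rule matches any available count")
    votes: dict[tuple[int, int], str] = {}
    for r, k in pairs:
        if (r, k) not in features.counts:
            raise KeyError(f"features lack a count for radius={r}, k={k}")
        votes[(r, k)] = rules[(r, k)].classify(features.counts[(r, k)])
    n_normal = sum(1 for v in votes.values() if v == LABEL_NORMAL)
    n_cirr = sum(1 for v in votes.values() if v == LABEL_CIRRHOTIC)
    if n_cirr > n_normal:
        label = LABEL_CIRRHOTIC
    elif n_normal > n_cirr:
        label = LABEL_NORMAL
    else:
        label = LABEL_INDETERMINATE
    return ClassificationResult(
        label=label, per_rule_votes=votes, evaluated_operator=features.operator
    )


class MarginClassifier:
    """Linear-margin decision function on 2-D feature points."""

    def __init__(self, scaler: StandardScaler | None, svc: SVC, classes: np.ndarray):
        self._scaler = scaler
        self._svc = svc
        self.classes_ = classes

    def predict(self, points: np.ndarray) -> np.ndarray:
        x = np.asarray(points, dtype=np.float64)
        if x.ndim == 1:
            x = x[np.newaxis, :]
        if self._scaler is not None:
            x = self._scaler.transform(x)
        return self._svc.predict(x)

    @property
    def coef_(self) -> np.ndarray:
        return self._svc.coef_

    @property
    def intercept_(self) -> np.ndarray:
        return self._svc.intercept_


def fit_margin_classifier(
    points: np.ndarray,
    labels: np.ndarray,
    *,
    C: float = 1.0,
    standardize: bool = True,
    class_weight: str | dict | None = "balanced",
) -> MarginClassifier:
    """Fit a linear-kernel SVM on 2-D feature points.

    Defaults emulate the classic ``svmtrain`` behavior: features are
    shifted/scaled to zero mean and unit variance and the box constraint is
    rescaled per class by group size.

    Raises
    ------
    ValueError
        If fewer than two classes are present.
    """
    x = np.asarray(points, dtype=np.float64)
    y = np.asarray(labels)
    if x.ndim != 2:
        raise ValueError(f"points must be 2-D (n_samples, n_features), got {x.shape}")
    if np.unique(y).size < 2:
        raise ValueError("training data must contain at least two classes")
    scaler = None
    if standardize:
        scaler = StandardScaler().fit(x)
        x = scaler.transform(x)
    svc = SVC(kernel="linear", C=C, class_weight=class_weight).fit(x, y)
    return MarginClassifier(scaler, svc, svc.classes_)


class NeighborClassifier:
    """Majority vote over the k nearest training points (Euclidean).

    Even-k ties are resolved by the class of the single nearest neighbor;
    equidistant neighbors are ranked by training-set order, so prediction
    is deterministic.
    """

    def __init__(self, points: np.ndarray, labels: np.ndarray, k_neighbors: int):
        self._x = np.asarray(points, dtype=np.float64)
        self._y = np.asarray(labels)
        self.k_neighbors = k_neighbors

    def predict(self, points: np.ndarray) -> np.ndarray:
        q = np.asarray(points, dtype=np.float64)
        if q.ndim == 1:
            q = q[np.newaxis, :]
        out = []
        for row in q:
            d = np.linalg.norm(self._x - row, axis=1)
            order = np.argsort(d, kind="stable")[: self.k_neighbors]
            votes = self._y[order]
            classes, tallies = np.unique(votes, return_counts=True)
            top = tallies.max()
            winners = classes[tallies == top]
            if winners.size == 1:
                out.append(winners[0])
            else:
                out.append(self._y[order[0]])  # documented tie-break
        return np.asarray(out)


def fit_neighbor_classifier(
    points: np.ndarray, labels: np.ndarray, k_neighbors: int = 3
) -> NeighborClassifier:
    """Build a k-nearest-neighbor decision function on 2-D features."""
    x = np.asarray(points, dtype=np.float64)
    y = np.asarray(labels)
    if k_neighbors < 1:
        raise ValueError(f"k_neighbors must be >= 1, got {k_neighbors}")
    if k_neighbors > len(y):
        raise ValueError(
            f"k_neighbors={k_neighbors} exceeds the {len(y)} training points"
        )
    return NeighborClassifier(x, y, k_neighbors)


@dataclass(frozen=True)
class EvaluationReport:
    """Per-class accuracies with cirrhosis as the positive class."""

    per_class_accuracy: dict[str, float]
    sensitivity: float
    specificity: float
    confusion: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict[str, object]:
        return {
            "per_class_accuracy": dict(self.per_class_accuracy),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "confusion": dict(self.confusion),
        }


def evaluate(
    classifier,
    points: np.ndarray,
    labels: np.ndarray,
    *,
    positive: str = LABEL_CIRRHOTIC,
    negative: str = LABEL_NORMAL,
) -> EvaluationReport:
    """Per-class accuracy, sensitivity and specificity of a decision function."""
    y = np.asarray(labels)
    if y.size == 0:
        raise ValueError("cannot evaluate on an empty set")
    pred = np.asarray(classifier.predict(np.asarray(points, dtype=np.float64)))
    per_class: dict[str, float] = {}
    for cls in np.unique(y):
        mask = y == cls
        per_class[str(cls)] = float((pred[mask] == cls).mean())
    tp = int(((y == positive) & (pred == positive)).sum())
    fn = int(((y == positive) & (pred != positive)).sum())
    tn = int(((y == negative) & (pred == negative)).sum())
    fp = int(((y == negative) & (pred != negative)).sum())
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return EvaluationReport(
        per_class_accuracy=per_class,
        sensitivity=sens,
        specificity=spec,
        confusion={"tp": tp, "fn": fn, "tn": tn, "fp": fp},
    )
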