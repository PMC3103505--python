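"""Representation spaces and leave-one-out linear discriminant classification.

Each subject is embedded as one point whose coordinates are the values of a
network measure obtained from the N tracking-algorithm variants (N = 3 gives
a 3-D space per measure; M measures combined give an M*N-dimensional space).
Groups are discriminated by leave-one-out cross-validated LDA with pooled
within-class covariance (diagonal ridge loading for stability, equal class
priors), which returns a posterior probability of being a control subject
for every held-out subject, and the mean boundary hyperplane across folds.
A forward sequential wrapper selects the combination of measures: measures
are ranked by single-measure LOO accuracy and appended greedily while the
combined accuracy strictly improves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ClassificationResult",
    "RepresentationSpace",
    "accuracy_from_posteriors",
    "build_space",
    "lda_loocv",
    "sequential_forward_select",
]

#: canonical measure ordering, used to break ties in the forward selection
MEASURE_ORDER = ("C", "L", "Q", "E_glob", "E_loc", "sigma")


@dataclass
class RepresentationSpace:
    """Subjects embedded as points, one coordinate per (measure, algorithm)."""

    measures: list[str]
    algorithms: list[str]
    points: np.ndarray  # (n_subjects, M * N)
    subjects: list[str]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        m, n = len(self.measures), len(self.algorithms)
        if self.points.shape != (len(self.subjects), m * n):
            raise ValueError(
                f"points shape {self.points.shape} != "
                f"({len(self.subjects)}, {m}*{n})"
            )

    @property
    def n_dims(self) -> int:
        return self.points.shape[1]

    def combined_with(self, other: "RepresentationSpace") -> "RepresentationSpace":
        if self.subjects != other.subjects:
            raise ValueError("representation spaces index different subjects")
        if self.algorithms != other.algorithms:
            raise ValueError("representation spaces use different algorithm axes")
        return RepresentationSpace(
            measures=self.measures + other.measures,
            algorithms=self.algorithms,
            points=np.hstack([self.points, other.points]),
            subjects=self.subjects,
        )


@dataclass
class ClassificationResult:
    """Per-subject control posteriors, mean boundary hyperplane, % correct."""

    subjects: list[str]
    posteriors: np.ndarray  # P(control | x) per subject
    predicted: list[str]
    true_labels: list[str]
    percent_correct: float
    hyperplane: np.ndarray  # mean unit-normal coefficients, then intercept
    selected_measures: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.posteriors = np.asarray(self.posteriors, dtype=float)
        if np.any((self.posteriors < 0) | (self.posteriors > 1)):
            raise ValueError("posteriors must lie in [0, 1]")


def build_space(
    metric_values: dict[str, pd.DataFrame],
    measures: list[str] | None = None,
) -> RepresentationSpace:
    """Assemble a representation space from per-measure subject x algorithm
    tables.

    ``metric_values`` maps measure name -> DataFrame indexed by subject with
    one column per algorithm variant. The coordinate layout is deterministic:
    measures in declared order, algorithms in declared (column) order within
    each measure. Missing values are rejected, naming the offending cell.
    """
    if not metric_values:
        raise ValueError("need at least one measure table")
    measures = list(measures) if measures is not None else list(metric_values)
    first = metric_values[measures[0]]
    subjects = [str(s) for s in first.index]
    algorithms = [str(a) for a in first.columns]
    blocks = []
    for m in measures:
        tab = metric_values[m]
        if [str(s) for s in tab.index] != subjects:
            raise ValueError(f"measure {m!r} indexes different subjects")
        if tab.isna().any().any():
            subj = tab.index[tab.isna().any(axis=1)][0]
            algo = tab.columns[tab.isna().any(axis=0)][0]
            raise ValueError(
                f"missing value for subject {subj!r}, measure {m!r}, "
                f"algorithm {algo!r}"
            )
        blocks.append(tab.to_numpy(dtype=float))
    return RepresentationSpace(
        measures=measures,
        algorithms=algorithms,
        points=np.hstack(blocks),
        subjects=subjects,
    )


def _lda_fit(
    X: np.ndarray, y: np.ndarray, ridge: float
) -> tuple[np.ndarray, float, np.ndarray, np.ndarray]:
    """Fit a two-class LDA with pooled ridge-loaded covariance, equal priors.

    Returns (w, b, mu_pos, mu_neg) with the decision function w @ x + b equal
    to the log posterior odds of the positive (control) class.
    """
    d = X.shape[1]
    mu_pos = X[y == 1].mean(axis=0)
    mu_neg = X[y == 0].mean(axis=0)
    resid = np.vstack([X[y == 1] - mu_pos, X[y == 0] - mu_neg])
    dof = max(len(X) - 2, 1)
    cov = resid.T @ resid / dof
    tr = np.trace(cov)
    cov = cov + (ridge * tr / d if tr > 0 else ridge) * np.eye(d)
    try:
        w = np.linalg.solve(cov, mu_pos - mu_neg)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular even after ridge loading; "
            "increase the ridge parameter"
        ) from err
    b = -0.5 * (mu_pos + mu_neg) @ w  # equal priors: no log-odds offset
    return w, float(b), mu_pos, mu_neg


def lda_loocv(
    space: RepresentationSpace,
    labels,
    ridge: float = 1e-6,
    positive_label: str = "control",
) -> ClassificationResult:
    """Leave-one-out LDA returning per-subject control posteriors.

    For each rotation, all subjects but one train an LDA (pooled within-class
    covariance with diagonal ridge loading ``ridge * trace / d``, equal class
    priors) and the held-out subject receives the posterior probability of
    belonging to the control class; the prediction is the class with
    posterior > 0.5. The mean boundary hyperplane is the average of per-fold
    coefficient vectors after normalizing each to a unit normal.
    """
    labels = [str(l) for l in labels]
    X = space.points
    if len(labels) != len(X):
        raise ValueError("one label per subject required")
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError("exactly two classes required")
    y = np.array([1 if l == positive_label else 0 for l in labels])
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("each class needs at least 2 members")
    negative_label = next(c for c in classes if c != positive_label)
    n = len(X)
    posteriors = np.empty(n)
    planes = np.zeros((n, X.shape[1] + 1))
    for i in range(n):
        mask = np.arange(n) != i
        w, b, _, _ = _lda_fit(X[mask], y[mask], ridge)
        z = w @ X[i] + b
        posteriors[i] = 1.0 / (1.0 + np.exp(-np.clip(z, -700, 700)))
        norm = np.linalg.norm(w)
        if norm > 0:
            planes[i] = np.concatenate([w, [b]]) / norm
    predicted = [positive_label if p > 0.5 else negative_label for p in posteriors]
    pct = accuracy_from_posteriors(posteriors, labels, positive_label=positive_label)
    return ClassificationResult(
        subjects=list(space.subjects),
        posteriors=posteriors,
        predicted=predicted,
        true_labels=labels,
        percent_correct=pct,
        hyperplane=planes.mean(axis=0),
    )


def accuracy_from_posteriors(
    posteriors,
    true_labels,
    threshold: float = 0.5,
    positive_label: str = "control",
) -> float:
    """Percent of subjects whose thresholded posterior matches the true label.

    A subject is called ``positive_label`` when its posterior exceeds
    ``threshold``; a posterior exactly at the threshold is counted incorrect
    (and logged). Reported to 2 decimals.
    """
    posteriors = np.asarray(posteriors, dtype=float)
    if np.any((posteriors < 0) | (posteriors > 1)):
        raise ValueError("posteriors must lie in [0, 1]")
    labels = [str(l) for l in true_labels]
    if len(labels) != len(posteriors):
        raise ValueError("one label per posterior required")
    n_ties = int(np.sum(posteriors == threshold))
    if n_ties:
        logger.warning(
            "%d posterior(s) exactly at threshold %.3g counted incorrect",
            n_ties, threshold,
        )
    correct = 0
    for p, l in zip(posteriors, labels):
        if p == threshold:
            continue
        call_positive = p > threshold
        if call_positive == (l == positive_label):
            correct += 1
    return round(100.0 * correct / len(labels), 2)


def sequential_forward_select(
    spaces: dict[str, RepresentationSpace],
    labels,
    ridge: float = 1e-6,
    positive_label: str = "control",
) -> ClassificationResult:
    """Forward sequential feature selection over measures, wrapper-style.

    Measures are ranked by their single-measure LOO accuracy (ties broken by
    the canonical order C, L, Q, E_glob, E_loc, sigma, then input order);
    starting from the best single predictor, the next-ranked measure's
    coordinates are appended while the combined LOO accuracy strictly
    improves. Deterministic for fixed inputs.
    """
    if not spaces:
        raise ValueError("need at least one measure space")
    names = list(spaces)

    def _rank_key(item):
        name, acc = item
        canon = MEASURE_ORDER.index(name) if name in MEASURE_ORDER else len(MEASURE_ORDER)
        return (-acc, canon, names.index(name))

    singles = {
        name: lda_loocv(spaces[name], labels, ridge, positive_label).percent_correct
        for name in names
    }
    ranking = [name for name, _ in sorted(singles.items(), key=_rank_key)]
    selected = [ranking[0]]
    current = spaces[ranking[0]]
    best = lda_loocv(current, labels, ridge, positive_label)
    for name in ranking[1:]:
        if best.percent_correct >= 100.0:
            break
        candidate_space = current.combined_with(spaces[name])
        candidate = lda_loocv(candidate_space, labels, ridge, positive_label)
        if candidate.percent_correct > best.percent_correct:
            selected.append(name)
            current, best = candidate_space, candidate
        else:
            break
    best.selected_measures = selected
    return best
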