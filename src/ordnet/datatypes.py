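"""Core data containers shared across the pipeline.

Every container validates its structural contract on construction, so
downstream stages can assume well-formed inputs: ordinal scores are
integers in ``[0, MAX_SCORE]``, networks are exactly symmetric with a
zero diagonal, correlation matrices are positive semidefinite within
tolerance.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TIME_LABELS = ("baseline", "followup")
N_CATEGORIES = 7
MAX_SCORE = N_CATEGORIES - 1


class ValidationError(ValueError):
    """A container or input file violates its structural contract."""


class ConfigError(ValueError):
    """A configuration is internally inconsistent or infeasible."""


class ConvergenceError(RuntimeError):
    """An iterative solver failed to converge within its budget."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class ItemPanel:
    """Subjects x items matrix of ordinal responses at one wave.

    Parameters
    ----------
    subject_ids : array-like of shape (n,)
        Unique subject identifiers, order defines row order.
    time_label : {"baseline", "followup"}
        Wave this panel belongs to.
    scores : ndarray of shape (n, p)
        Integer item scores in ``[0, MAX_SCORE]``; no missing values
        (listwise deletion happens at load time).
    item_labels : list of str
        Column names, order defines column order.
    """

    subject_ids: np.ndarray
    time_label: str
    scores: np.ndarray
    item_labels: list[str]

    def __post_init__(self):
        self.subject_ids = np.asarray(self.subject_ids)
        self.item_labels = list(self.item_labels)
        scores = np.asarray(self.scores)
        if scores.ndim != 2:
            raise ValidationError("scores must be a 2-D matrix")
        if self.time_label not in TIME_LABELS:
            raise ValidationError(
                f"time_label must be one of {TIME_LABELS}, got {self.time_label!r}"
            )
        n, p = scores.shape
        if len(self.subject_ids) != n:
            raise ValidationError(
                f"{len(self.subject_ids)} subject ids for {n} score rows"
            )
        if len(self.item_labels) != p:
            raise ValidationError(
                f"{len(self.item_labels)} item labels for {p} score columns"
            )
        if len(set(self.item_labels)) != p:
            raise ValidationError("item labels must be unique")
        if len(np.unique(self.subject_ids)) != n:
            raise ValidationError("duplicate subject_id in panel")
        if not np.issubdtype(scores.dtype, np.integer):
            if not np.all(np.isfinite(scores)) or np.any(scores != np.round(scores)):
                raise ValidationError("scores must be integers with no missing values")
            scores = scores.astype(np.int64)
        if scores.size and (scores.min() < 0 or scores.max() > MAX_SCORE):
            raise ValidationError(
                f"scores must lie in [0, {MAX_SCORE}]"
            )
        self.scores = scores.astype(np.int64)

    @property
    def n_subjects(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.scores, columns=self.item_labels)
        frame.insert(0, "time", self.time_label)
        frame.insert(0, "subject_id", self.subject_ids)
        return frame

    def take_rows(self, index: np.ndarray, relabel: bool = False) -> "ItemPanel":
        """Row subset/resample. ``relabel=True`` assigns fresh ids so
        bootstrap resamples (with duplicates) stay valid panels."""
        index = np.asarray(index)
        ids = (
            np.array([f"r{i}" for i in range(len(index))], dtype=object)
            if relabel
            else self.subject_ids[index]
        )
        return ItemPanel(ids, self.time_label, self.scores[index], self.item_labels)


@dataclass
class PairedPanel:
    """Baseline and follow-up panels aligned subject-by-subject."""

    baseline: ItemPanel
    followup: ItemPanel

    def __post_init__(self):
        if self.baseline.item_labels != self.followup.item_labels:
            raise ValidationError("waves must share item labels in identical order")
        if self.baseline.n_subjects != self.followup.n_subjects or not np.array_equal(
            self.baseline.subject_ids, self.followup.subject_ids
        ):
            raise ValidationError("waves must share subject ids in identical order")
        if self.baseline.time_label != "baseline" or self.followup.time_label != "followup":
            raise ValidationError("wave time labels must be baseline/followup")

    @property
    def n_subjects(self) -> int:
        return self.baseline.n_subjects

    @property
    def item_labels(self) -> list[str]:
        return self.baseline.item_labels


@dataclass
class TransformedMatrix:
    """Continuous matrix produced by the rank-based Gaussianization."""

    values: np.ndarray
    item_labels: list[str]
    time_label: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.item_labels):
            raise ValidationError("values shape does not match item labels")


def _check_square(values: np.ndarray, labels: list[str], what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValidationError(f"{what} must be square")
    if values.shape[0] != len(labels):
        raise ValidationError(f"{what} size does not match item labels")
    return values


@dataclass
class CorrelationMatrix:
    """p x p Pearson correlation matrix with labels.

    Symmetric within 1e-12 (then symmetrized exactly), diagonal forced
    to 1, eigenvalues >= -1e-8.
    """

    values: np.ndarray
    item_labels: list[str]

    def __post_init__(self):
        self.item_labels = list(self.item_labels)
        values = _check_square(self.values, self.item_labels, "correlation matrix")
        if np.max(np.abs(values - values.T), initial=0.0) > 1e-12:
            raise ValidationError("correlation matrix not symmetric within 1e-12")
        values = (values + values.T) / 2.0
        if values.size and np.max(np.abs(np.diag(values) - 1.0)) > 1e-12:
            raise ValidationError("correlation matrix diagonal must be 1")
        np.fill_diagonal(values, 1.0)
        if values.size and np.linalg.eigvalsh(values).min() < -1e-8:
            raise ValidationError("correlation matrix not PSD within 1e-8")
        self.values = values

    @property
    def n_items(self) -> int:
        return len(self.item_labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.item_labels, columns=self.item_labels)


@dataclass
class Network:
    """Symmetric weighted network of partial correlations.

    ``weights[i, j]`` is the edge weight between items i and j; the
    diagonal is zero and weights lie in [-1, 1].
    """

    weights: np.ndarray
    item_labels: list[str]

    def __post_init__(self):
        self.item_labels = list(self.item_labels)
        weights = _check_square(self.weights, self.item_labels, "network")
        if not np.array_equal(weights, weights.T):
            raise ValidationError("network weights must be exactly symmetric")
        if weights.size and np.any(np.diag(weights) != 0.0):
            raise ValidationError("network diagonal must be exactly zero")
        if weights.size and np.max(np.abs(weights)) > 1.0 + 1e-9:
            raise ValidationError("network weights must lie in [-1, 1]")
        self.weights = np.clip(weights, -1.0, 1.0)

    @property
    def n_items(self) -> int:
        return len(self.item_labels)

    @property
    def edge_count(self) -> int:
        iu = np.triu_indices(self.n_items, k=1)
        return int(np.count_nonzero(self.weights[iu]))

    def edge_list(self) -> pd.DataFrame:
        """Long table of the nonzero upper-triangle edges."""
        rows = []
        p = self.n_items
        for i in range(p):
            for j in range(i + 1, p):
                w = self.weights[i, j]
                if w != 0.0:
                    rows.append((self.item_labels[i], self.item_labels[j], w))
        return pd.DataFrame(rows, columns=["item_a", "item_b", "weight"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.item_labels, columns=self.item_labels)


def symmetric_network(weights: np.ndarray, item_labels: list[str]) -> Network:
    """Build a :class:`Network` after exact symmetrization and diagonal reset."""
    weights = np.asarray(weights, dtype=float)
    weights = (weights + weights.T) / 2.0
    np.fill_diagonal(weights, 0.0)
    return Network(weights, item_labels)
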