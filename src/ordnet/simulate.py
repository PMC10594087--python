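"""Synthetic paired ordinal panels with a planted partial-correlation network.

The generating mechanism is the latent-Gaussian threshold model: latent
vectors are drawn from a multivariate normal whose precision matrix
encodes a block-structured partial-correlation network, then each item
is discretized through ordered cut-points into scores ``0..6``.  The
follow-up wave shares the baseline topology with all edge weights
scaled by a single factor, lower latent means, and per-subject
cross-wave dependence, so every downstream stage (estimation,
comparison, community detection) has exact ground truth to recover.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ConfigError,
    ItemPanel,
    MAX_SCORE,
    Network,
    PairedPanel,
    symmetric_network,
)

#: Default cut-points give a right-skewed score distribution (most mass
#: on scores 0-3), the typical shape for mild-to-moderate severity data.
DEFAULT_THRESHOLDS = np.array([-0.25, 0.55, 1.25, 1.95, 2.65, 3.35])

DEFAULT_ITEMS = [
    "item1", "item2", "item3", "item5", "item6", "item7",
    "item8", "item9", "item10", "item11", "item12", "item13",
]

DEFAULT_BLOCKS = {
    "anhedonia": ["item1", "item2", "item3"],
    "asociality": ["item5", "item6"],
    "avolition": ["item7", "item8"],
    "blunted_affect": ["item9", "item10", "item11"],
    "alogia": ["item12", "item13"],
}


@dataclass
class GeneratorConfig:
    """Full parameterization of the paired-panel generator.

    ``thresholds`` is an ``(p, 6)`` array of strictly increasing
    cut-points per item (7 categories); ``mean_shift_followup`` is a
    scalar or per-item latent mean change applied at follow-up.
    """

    n_subjects: int
    item_labels: list[str]
    blocks: dict[str, list[str]]
    within_weight: float
    between_weight: float
    strength_scale_followup: float = 1.0
    subject_dependence: float = 0.0
    thresholds: np.ndarray | None = None
    mean_shift_followup: float | np.ndarray = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.item_labels = list(self.item_labels)
        p = len(self.item_labels)
        if self.n_subjects <= 0:
            raise ConfigError("n_subjects must be positive")
        if len(set(self.item_labels)) != p:
            raise ConfigError("item labels must be unique")
        flat = [it for items in self.blocks.values() for it in items]
        if sorted(flat) != sorted(self.item_labels):
            raise ConfigError("blocks must partition item_labels (disjoint, exhaustive)")
        if not (0.0 <= self.within_weight < 1.0):
            raise ConfigError("within_weight must lie in [0, 1)")
        if not (0.0 <= self.between_weight <= max(self.within_weight, 0.0)):
            raise ConfigError("between_weight must lie in [0, within_weight]")
        if not (0.0 < self.strength_scale_followup <= 1.0):
            raise ConfigError("strength_scale_followup must lie in (0, 1]")
        if not (0.0 <= self.subject_dependence < 1.0):
            raise ConfigError("subject_dependence must lie in [0, 1)")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigError("missing_rate must lie in [0, 1)")
        if self.thresholds is None:
            self.thresholds = np.tile(DEFAULT_THRESHOLDS, (p, 1))
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        if self.thresholds.ndim == 1:
            self.thresholds = np.tile(self.thresholds, (p, 1))
        if self.thresholds.shape != (p, MAX_SCORE):
            raise ConfigError(
                f"thresholds must have shape ({p}, {MAX_SCORE}), "
                f"got {self.thresholds.shape}"
            )
        if np.any(np.diff(self.thresholds, axis=1) <= 0):
            raise ConfigError("thresholds must be strictly increasing per item")
        self.mean_shift_followup = np.broadcast_to(
            np.asarray(self.mean_shift_followup, dtype=float), (p,)
        ).copy()

    @property
    def n_items(self) -> int:
        return len(self.item_labels)

    def block_assignment(self) -> np.ndarray:
        """Per-item block index (1-based, block order as given)."""
        lookup = {}
        for b, (name, items) in enumerate(self.blocks.items(), start=1):
            for it in items:
                lookup[it] = b
        return np.array([lookup[it] for it in self.item_labels])

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "item_labels": self.item_labels,
            "blocks": {k: list(v) for k, v in self.blocks.items()},
            "within_weight": self.within_weight,
            "between_weight": self.between_weight,
            "strength_scale_followup": self.strength_scale_followup,
            "subject_dependence": self.subject_dependence,
            "thresholds": self.thresholds.tolist(),
            "mean_shift_followup": self.mean_shift_followup.tolist(),
            "missing_rate": self.missing_rate,
            "seed": self.seed,
        }


def default_config(n_subjects: int = 612, seed: int = 0, **overrides) -> GeneratorConfig:
    """A 12-item, 5-block configuration mirroring the default study design."""
    params = dict(
        n_subjects=n_subjects,
        item_labels=DEFAULT_ITEMS,
        blocks=DEFAULT_BLOCKS,
        within_weight=0.3,
        between_weight=0.02,
        strength_scale_followup=0.9,
        subject_dependence=0.5,
        mean_shift_followup=-0.25,
        seed=seed,
    )
    params.update(overrides)
    return GeneratorConfig(**params)


@dataclass
class TruthBundle:
    """Ground truth implied by a :class:`GeneratorConfig`."""

    true_network_baseline: Network
    true_network_followup: Network
    true_partition: np.ndarray
    latent_corr_baseline: np.ndarray
    latent_corr_followup: np.ndarray

    def to_dict(self) -> dict:
        return {
            "item_labels": self.true_network_baseline.item_labels,
            "true_network_baseline": self.true_network_baseline.weights.tolist(),
            "true_network_followup": self.true_network_followup.weights.tolist(),
            "true_partition": self.true_partition.tolist(),
            "latent_corr_baseline": self.latent_corr_baseline.tolist(),
            "latent_corr_followup": self.latent_corr_followup.tolist(),
        }

    def write(self, stem: Path) -> list[Path]:
        stem = Path(stem)
        json_path = stem.with_suffix(".json")
        json_path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        tsv_path = stem.with_suffix(".tsv")
        self.true_network_baseline.edge_list().to_csv(tsv_path, sep="\t", index=False)
        return [json_path, tsv_path]


def _planted_precision(config: GeneratorConfig, scale: float) -> np.ndarray:
    p = config.n_items
    assign = config.block_assignment()
    same = assign[:, None] == assign[None, :]
    theta = np.where(same, -config.within_weight, -config.between_weight) * scale
    np.fill_diagonal(theta, 1.0)
    return theta


def _corr_from_precision(theta: np.ndarray) -> np.ndarray:
    sigma = np.linalg.inv(theta)
    sigma = (sigma + sigma.T) / 2.0
    d = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(d, d)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return corr


def make_true_network(config: GeneratorConfig) -> TruthBundle:
    """Planted partial-correlation networks and implied latent correlations.

    The precision matrix has unit diagonal and off-diagonal
    ``-within_weight`` inside blocks / ``-between_weight`` across
    blocks, so the planted partial correlation between items i and j is
    exactly the configured weight.  Configurations whose implied
    precision is not positive definite are rejected.
    """
    theta_b = _planted_precision(config, 1.0)
    min_eig = np.linalg.eigvalsh(theta_b).min()
    if min_eig <= 1e-10:
        raise ConfigError(
            "implied precision matrix is not positive definite "
            f"(min eigenvalue {min_eig:.4g}) for within_weight="
            f"{config.within_weight}, between_weight={config.between_weight}, "
            f"blocks={[len(v) for v in config.blocks.values()]}"
        )
    s = config.strength_scale_followup
    theta_f = _planted_precision(config, s)

    weights_b = -theta_b.copy()
    np.fill_diagonal(weights_b, 0.0)
    weights_f = s * weights_b

    return TruthBundle(
        true_network_baseline=symmetric_network(weights_b, config.item_labels),
        true_network_followup=symmetric_network(weights_f, config.item_labels),
        true_partition=config.block_assignment(),
        latent_corr_baseline=_corr_from_precision(theta_b),
        latent_corr_followup=_corr_from_precision(theta_f),
    )


def _discretize(latent: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Map latent columns to scores 0..6 by counting exceeded cut-points."""
    n, p = latent.shape
    scores = np.empty((n, p), dtype=np.int64)
    for j in range(p):
        scores[:, j] = np.searchsorted(thresholds[j], latent[:, j], side="right")
    return scores


def _cholesky_or_raise(corr: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise ConfigError("latent correlation matrix is not positive definite") from exc


def sample_ordinal_panel(
    latent_corr: np.ndarray,
    n: int,
    thresholds: np.ndarray,
    mean_shift: float | np.ndarray = 0.0,
    seed: int | np.random.Generator | None = None,
    *,
    item_labels: list[str] | None = None,
    time_label: str = "baseline",
    subject_ids: np.ndarray | None = None,
) -> ItemPanel:
    """Draw an ordinal panel from the latent-Gaussian threshold model."""
    latent_corr = np.asarray(latent_corr, dtype=float)
    p = latent_corr.shape[0]
    thresholds = np.asarray(thresholds, dtype=float)
    if thresholds.ndim == 1:
        thresholds = np.tile(thresholds, (p, 1))
    chol = _cholesky_or_raise(latent_corr)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    latent = rng.standard_normal((n, p)) @ chol.T + np.asarray(mean_shift, dtype=float)
    scores = _discretize(latent, thresholds)
    if item_labels is None:
        item_labels = [f"item{j + 1}" for j in range(p)]
    if subject_ids is None:
        subject_ids = np.array([f"S{i + 1:05d}" for i in range(n)], dtype=object)
    return ItemPanel(subject_ids, time_label, scores, item_labels)


def make_paired_panel(config: GeneratorConfig) -> tuple[PairedPanel, TruthBundle]:
    """Jointly draw the two waves with per-subject cross-wave dependence.

    With ``x, y`` iid standard normal and ``rho = subject_dependence``,
    the baseline latent is ``L_b x`` and the follow-up latent is
    ``L_f (rho x + sqrt(1 - rho^2) y)`` plus the follow-up mean shift,
    so each wave has its configured latent correlation and the
    cross-wave covariance is ``rho * L_b L_f'`` (positive semidefinite
    by construction; zero dependence gives independent waves).
    """
    truth = make_true_network(config)
    n, p = config.n_subjects, config.n_items
    rho = config.subject_dependence
    chol_b = _cholesky_or_raise(truth.latent_corr_baseline)
    chol_f = _cholesky_or_raise(truth.latent_corr_followup)

    rng = np.random.default_rng(config.seed)
    x = rng.standard_normal((n, p))
    y = rng.standard_normal((n, p))
    latent_b = x @ chol_b.T
    latent_f = (rho * x + np.sqrt(1.0 - rho**2) * y) @ chol_f.T
    latent_f = latent_f + config.mean_shift_followup

    subject_ids = np.array([f"S{i + 1:05d}" for i in range(n)], dtype=object)
    baseline = ItemPanel(
        subject_ids, "baseline", _discretize(latent_b, config.thresholds), config.item_labels
    )
    followup = ItemPanel(
        subject_ids, "followup", _discretize(latent_f, config.thresholds), config.item_labels
    )
    return PairedPanel(baseline, followup), truth


def apply_missingness(
    panel: ItemPanel, rate: float, seed: int | np.random.Generator | None = None
) -> pd.DataFrame:
    """Return the panel as a frame with cells blanked at the given rate.

    Missingness lives only in the serialized frame; :class:`ItemPanel`
    itself stays complete.
    """
    frame = panel.to_frame()
    if rate <= 0:
        return frame
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = rng.random((panel.n_subjects, panel.n_items)) < rate
    values = frame[panel.item_labels].to_numpy(dtype=float)
    values[mask] = np.nan
    frame[panel.item_labels] = values
    return frame


def write_panel(panel: ItemPanel, path: Path, missing_frame: pd.DataFrame | None = None) -> Path:
    path = Path(path)
    frame = missing_frame if missing_frame is not None else panel.to_frame()
    frame.to_csv(path, index=False)
    return path
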