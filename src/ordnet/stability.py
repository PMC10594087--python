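"""Bootstrap accuracy of edge weights and case-dropping centrality stability."""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ItemPanel, Network
from .estimation import EstimatorSettings, network_from_scores
from . import metrics

logger = logging.getLogger(__name__)

DEFAULT_PROPORTIONS = tuple(np.round(np.arange(0.1, 0.91, 0.1), 10))
CENTRALITY_INDICES = ("strength", "closeness", "betweenness", "expected_influence")


def _resample_seeds(seed, count: int) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(count)]


@dataclass
class EdgeStabilityResult:
    """Per-edge bootstrap summary of the estimated network."""

    item_labels: list[str]
    original: np.ndarray
    boot_mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    B: int
    B_failed: int
    level: tuple[float, float]
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        p = len(self.item_labels)
        for i in range(p):
            for j in range(i + 1, p):
                rows.append(
                    (
                        self.item_labels[i],
                        self.item_labels[j],
                        self.original[i, j],
                        self.boot_mean[i, j],
                        self.lower[i, j],
                        self.upper[i, j],
                    )
                )
        return pd.DataFrame(
            rows, columns=["item_a", "item_b", "weight", "boot_mean", "lower", "upper"]
        )


def edge_bootstrap(
    panel: ItemPanel,
    settings: EstimatorSettings | None = None,
    B: int = 1000,
    seed: int | None = None,
    quantiles: tuple[float, float] = (0.025, 0.975),
) -> EdgeStabilityResult:
    """Nonparametric bootstrap of the full estimation pipeline.

    Each of the B resamples redraws n subjects with replacement and
    re-runs transform -> correlation -> penalty-path selection.  Failed
    resamples are skipped and counted; more than 5% failures aborts.
    """
    if B < 100:
        logger.warning("edge_bootstrap: B=%d < 100 gives unreliable quantiles", B)
    settings = settings or EstimatorSettings()
    n = panel.n_subjects
    original = network_from_scores(panel.scores, panel.item_labels, settings)
    draws = []
    failed = 0
    for rng in _resample_seeds(seed, B):
        idx = rng.integers(0, n, size=n)
        try:
            net = network_from_scores(panel.scores[idx], panel.item_labels, settings)
        except Exception as exc:  # noqa: BLE001 - estimator failures are data-driven
            failed += 1
            logger.debug("edge_bootstrap: resample failed: %s", exc)
            continue
        draws.append(net.weights)
    if failed > 0.05 * B:
        raise RuntimeError(
            f"edge_bootstrap: {failed}/{B} resamples failed (> 5% tolerated)"
        )
    stack = np.stack(draws)
    boot_mean = stack.mean(axis=0)
    # percentile interval, widened (rarely needed) to contain the
    # bootstrap mean: point-mass-at-zero edge distributions can
    # otherwise put the mean outside the raw quantiles
    lower = np.minimum(np.quantile(stack, quantiles[0], axis=0), boot_mean)
    upper = np.maximum(np.quantile(stack, quantiles[1], axis=0), boot_mean)
    return EdgeStabilityResult(
        item_labels=panel.item_labels,
        original=original.weights,
        boot_mean=boot_mean,
        lower=lower,
        upper=upper,
        B=B,
        B_failed=failed,
        level=quantiles,
        seed=seed,
    )


@dataclass
class CaseDropResult:
    """Centrality correlations under case-dropping subsampling.

    ``correlations[index]`` is a (len(proportions), B) array; skipped
    proportions hold NaN.
    """

    proportions: np.ndarray
    correlations: dict[str, np.ndarray]
    skipped: list[float]
    B: int
    seed: int | None
    original: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        rows = []
        for q_idx, q in enumerate(self.proportions):
            for index, corr in self.correlations.items():
                vals = corr[q_idx]
                rows.append(
                    (
                        q,
                        index,
                        float(np.nanmean(vals)) if np.isfinite(vals).any() else np.nan,
                        float(np.nanquantile(vals, 0.025)) if np.isfinite(vals).any() else np.nan,
                        float(np.nanquantile(vals, 0.975)) if np.isfinite(vals).any() else np.nan,
                    )
                )
        return pd.DataFrame(
            rows, columns=["drop_proportion", "index", "mean_r", "r_lo", "r_hi"]
        )


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        # constant vectors: identical means perfectly stable
        return 1.0 if np.array_equal(a, b) else 0.0
    return float(np.corrcoef(a, b)[0, 1])


def case_drop_bootstrap(
    panel: ItemPanel,
    settings: EstimatorSettings | None = None,
    proportions=DEFAULT_PROPORTIONS,
    B: int = 250,
    seed: int | None = None,
    indices=CENTRALITY_INDICES,
) -> CaseDropResult:
    """Drop a proportion of cases without replacement, recompute centralities,
    and correlate them with the full-sample values."""
    settings = settings or EstimatorSettings()
    n = panel.n_subjects
    p = panel.n_items
    original_net = network_from_scores(panel.scores, panel.item_labels, settings)
    original = metrics.centrality_table(original_net)

    proportions = np.asarray(sorted(proportions), dtype=float)
    correlations = {index: np.full((len(proportions), B), np.nan) for index in indices}
    skipped = []
    rngs = _resample_seeds(seed, len(proportions) * B)
    for q_idx, q in enumerate(proportions):
        keep = int(round((1.0 - q) * n))
        if keep < p + 5:
            skipped.append(float(q))
            logger.warning(
                "case_drop_bootstrap: proportion %.2f skipped (retained %d < p+5=%d)",
                q, keep, p + 5,
            )
            continue
        for b in range(B):
            rng = rngs[q_idx * B + b]
            idx = np.sort(rng.choice(n, size=keep, replace=False))
            try:
                net = network_from_scores(panel.scores[idx], panel.item_labels, settings)
            except Exception as exc:  # noqa: BLE001
                logger.debug("case_drop_bootstrap: subsample failed: %s", exc)
                continue
            table = metrics.centrality_table(net)
            for index in indices:
                correlations[index][q_idx, b] = _safe_corr(
                    original[index].to_numpy(), table[index].to_numpy()
                )
    return CaseDropResult(
        proportions=proportions,
        correlations=correlations,
        skipped=skipped,
        B=B,
        seed=seed,
        original=original,
    )


def cs_coefficient(
    result: CaseDropResult, r_threshold: float = 0.7, prob: float = 0.95
) -> dict[str, float]:
    """Largest drop proportion keeping corr >= r_threshold in >= prob of draws."""
    out = {}
    for index, corr in result.correlations.items():
        cs = 0.0
        for q_idx, q in enumerate(result.proportions):
            vals = corr[q_idx]
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                continue
            if np.mean(vals >= r_threshold) >= prob:
                cs = max(cs, float(q))
        out[index] = cs
    return out
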