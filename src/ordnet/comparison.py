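"""Permutation network-comparison test for paired (dependent) samples.

The structure statistic ``M`` is the largest absolute edge-weight
difference between the two estimated networks; the global-strength
statistic ``S`` is the absolute difference of overall connectivity.
The dependent-samples null swaps each subject's two waves independently
with probability 1/2 and re-estimates both networks per replicate;
p-values use the add-one estimator ``(1 + #{perm >= obs}) / (B + 1)``.
Edge-level differences are tested against the same permutation
replicates and Holm-adjusted.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ItemPanel, Network, PairedPanel, ValidationError
from .estimation import EstimatorSettings, network_from_scores
from .metrics import global_strength

logger = logging.getLogger(__name__)


def nct_statistics(net1: Network, net2: Network) -> tuple[float, float, np.ndarray]:
    """(M, S, per-edge |difference| matrix) for two networks on the same labels."""
    if net1.item_labels != net2.item_labels:
        raise ValidationError("networks must share item labels in identical order")
    edge_diffs = np.abs(net1.weights - net2.weights)
    p = net1.n_items
    iu = np.triu_indices(p, k=1)
    m_stat = float(edge_diffs[iu].max()) if len(iu[0]) else 0.0
    s_stat = abs(global_strength(net1) - global_strength(net2))
    return m_stat, s_stat, edge_diffs


def swap_waves(pair: PairedPanel, mask: np.ndarray) -> PairedPanel:
    """Swap baseline/follow-up rows for the subjects flagged in ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (pair.n_subjects,):
        raise ValidationError("mask length must equal the number of subjects")
    b, f = pair.baseline.scores, pair.followup.scores
    new_b = np.where(mask[:, None], f, b)
    new_f = np.where(mask[:, None], b, f)
    ids = pair.baseline.subject_ids
    labels = pair.item_labels
    return PairedPanel(
        ItemPanel(ids, "baseline", new_b, labels),
        ItemPanel(ids, "followup", new_f, labels),
    )


def permute_paired(
    pair: PairedPanel, seed: int | np.random.Generator | None = None
) -> PairedPanel:
    """One draw of the dependent-samples permutation (per-subject wave swap)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = rng.random(pair.n_subjects) < 0.5
    return swap_waves(pair, mask)


def holm_adjust(pvalues) -> np.ndarray:
    """Bonferroni-Holm step-down adjustment, returned in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("pvalues must be 1-D")
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValidationError("pvalues must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        value = min(p[idx] * (m - rank), 1.0)
        running_max = max(running_max, value)
        adjusted[idx] = running_max
    return adjusted


@dataclass
class NCTResult:
    """Observed statistics, permutation p-values and per-edge tests."""

    item_labels: list[str]
    M: float
    S: float
    g1: float
    g2: float
    p_M: float
    p_S: float
    edge_diffs: np.ndarray
    edge_p_raw: np.ndarray
    edge_p_holm: np.ndarray
    edges_reported: bool
    perm_M: np.ndarray
    perm_S: np.ndarray
    B: int
    B_failed: int
    alpha: float
    seed: int | None

    def edge_table(self) -> pd.DataFrame:
        rows = []
        p = len(self.item_labels)
        k = 0
        for i in range(p):
            for j in range(i + 1, p):
                rows.append(
                    (
                        self.item_labels[i],
                        self.item_labels[j],
                        self.edge_diffs[i, j],
                        self.edge_p_raw[k],
                        self.edge_p_holm[k],
                    )
                )
                k += 1
        return pd.DataFrame(
            rows, columns=["item_a", "item_b", "abs_diff", "p_raw", "p_holm"]
        )

    def to_dict(self) -> dict:
        return {
            "M": self.M,
            "S": self.S,
            "global_strength_1": self.g1,
            "global_strength_2": self.g2,
            "p_M": self.p_M,
            "p_S": self.p_S,
            "B": self.B,
            "B_failed": self.B_failed,
            "alpha": self.alpha,
            "seed": self.seed,
            "edges_reported": self.edges_reported,
            "edges": self.edge_table().to_dict(orient="records"),
        }

    def write(self, stem: Path) -> list[Path]:
        stem = Path(stem)
        json_path = stem.with_suffix(".json")
        json_path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        csv_path = Path(str(stem) + "_edges.csv")
        self.edge_table().to_csv(csv_path, index=False)
        return [json_path, csv_path]


def _pair_stats(
    pair: PairedPanel, settings: EstimatorSettings
) -> tuple[float, float, np.ndarray, float, float]:
    net1 = network_from_scores(pair.baseline.scores, pair.item_labels, settings)
    net2 = network_from_scores(pair.followup.scores, pair.item_labels, settings)
    m_stat, s_stat, diffs = nct_statistics(net1, net2)
    return m_stat, s_stat, diffs, global_strength(net1), global_strength(net2)


def nct_dependent(
    pair: PairedPanel,
    settings: EstimatorSettings | None = None,
    B: int = 1000,
    seed: int | None = None,
    edge_tests: str = "auto",
    alpha: float = 0.05,
) -> NCTResult:
    """Dependent-samples permutation test of network and global-strength invariance.

    ``edge_tests``: "auto" reports post hoc edge tests only when either
    global test is significant at ``alpha``; "all" always reports;
    "none" never reports (p-values are computed regardless).
    """
    if edge_tests not in ("auto", "all", "none"):
        raise ValidationError(f"unknown edge_tests policy {edge_tests!r}")
    if B < 100:
        logger.warning("nct_dependent: B=%d < 100 gives coarse p-values", B)
    settings = settings or EstimatorSettings()
    m_obs, s_obs, diffs_obs, g1, g2 = _pair_stats(pair, settings)
    p = len(pair.item_labels)
    iu = np.triu_indices(p, k=1)
    obs_edges = diffs_obs[iu]

    rng = np.random.default_rng(seed)
    perm_m, perm_s = [], []
    edge_ge = np.zeros(len(obs_edges))
    failed = 0
    for _ in range(B):
        mask = rng.random(pair.n_subjects) < 0.5
        try:
            m_b, s_b, diffs_b, _, _ = _pair_stats(swap_waves(pair, mask), settings)
        except Exception as exc:  # noqa: BLE001 - estimator failures are data-driven
            failed += 1
            logger.debug("nct_dependent: replicate failed: %s", exc)
            continue
        perm_m.append(m_b)
        perm_s.append(s_b)
        edge_ge += diffs_b[iu] >= obs_edges
    if failed > 0.05 * B:
        raise RuntimeError(f"nct_dependent: {failed}/{B} replicates failed (> 5%)")
    perm_m = np.asarray(perm_m)
    perm_s = np.asarray(perm_s)
    b_ok = len(perm_m)
    p_m = (1.0 + np.sum(perm_m >= m_obs)) / (b_ok + 1.0)
    p_s = (1.0 + np.sum(perm_s >= s_obs)) / (b_ok + 1.0)
    edge_p_raw = (1.0 + edge_ge) / (b_ok + 1.0)
    edge_p_holm = holm_adjust(edge_p_raw)
    if edge_tests == "all":
        reported = True
    elif edge_tests == "none":
        reported = False
    else:
        reported = bool(p_s < alpha or p_m < alpha)
    return NCTResult(
        item_labels=pair.item_labels,
        M=m_obs,
        S=s_obs,
        g1=g1,
        g2=g2,
        p_M=float(p_m),
        p_S=float(p_s),
        edge_diffs=diffs_obs,
        edge_p_raw=edge_p_raw,
        edge_p_holm=edge_p_holm,
        edges_reported=reported,
        perm_M=perm_m,
        perm_S=perm_s,
        B=B,
        B_failed=failed,
        alpha=alpha,
        seed=seed,
    )


def nct_independent(
    panel1: ItemPanel,
    panel2: ItemPanel,
    settings: EstimatorSettings | None = None,
    B: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> NCTResult:
    """Minimal unpaired variant: pool rows and reshuffle group membership."""
    if panel1.item_labels != panel2.item_labels:
        raise ValidationError("panels must share item labels")
    settings = settings or EstimatorSettings()
    labels = panel1.item_labels
    pooled = np.vstack([panel1.scores, panel2.scores])
    n1 = panel1.n_subjects
    n_total = pooled.shape[0]

    def stats(scores1, scores2):
        net1 = network_from_scores(scores1, labels, settings)
        net2 = network_from_scores(scores2, labels, settings)
        m, s, d = nct_statistics(net1, net2)
        return m, s, d, global_strength(net1), global_strength(net2)

    m_obs, s_obs, diffs_obs, g1, g2 = stats(panel1.scores, panel2.scores)
    p = len(labels)
    iu = np.triu_indices(p, k=1)
    obs_edges = diffs_obs[iu]
    rng = np.random.default_rng(seed)
    perm_m, perm_s = [], []
    edge_ge = np.zeros(len(obs_edges))
    failed = 0
    for _ in range(B):
        perm = rng.permutation(n_total)
        try:
            m_b, s_b, diffs_b, _, _ = stats(pooled[perm[:n1]], pooled[perm[n1:]])
        except Exception:  # noqa: BLE001
            failed += 1
            continue
        perm_m.append(m_b)
        perm_s.append(s_b)
        edge_ge += diffs_b[iu] >= obs_edges
    if failed > 0.05 * B:
        raise RuntimeError(f"nct_independent: {failed}/{B} replicates failed (> 5%)")
    b_ok = len(perm_m)
    p_m = (1.0 + np.sum(np.asarray(perm_m) >= m_obs)) / (b_ok + 1.0)
    p_s = (1.0 + np.sum(np.asarray(perm_s) >= s_obs)) / (b_ok + 1.0)
    edge_p_raw = (1.0 + edge_ge) / (b_ok + 1.0)
    return NCTResult(
        item_labels=labels,
        M=m_obs,
        S=s_obs,
        g1=g1,
        g2=g2,
        p_M=float(p_m),
        p_S=float(p_s),
        edge_diffs=diffs_obs,
        edge_p_raw=edge_p_raw,
        edge_p_holm=holm_adjust(edge_p_raw),
        edges_reported=bool(p_s < alpha or p_m < alpha),
        perm_M=np.asarray(perm_m),
        perm_S=np.asarray(perm_s),
        B=B,
        B_failed=failed,
        alpha=alpha,
        seed=seed,
    )
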