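"""Panel ingestion, item exclusion, and rank-based Gaussianization.

The transform applied before correlation estimation is the truncated
empirical-CDF variant of the nonparanormal marginal transform: mid-rank
ECDF values are Winsorized to ``[delta_n, 1 - delta_n]`` with
``delta_n = 1 / (4 n^{1/4} sqrt(pi log n))`` and pushed through the
standard normal quantile function, then scaled to unit sample standard
deviation.  Ties (heavy in 7-point data) receive identical transformed
values via average ranks.
"""
from __future__ import annotations

import logging
import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import ndtr, ndtri, owens_t
from scipy.stats import rankdata

from .datatypes import (
    CorrelationMatrix,
    ItemPanel,
    MAX_SCORE,
    PairedPanel,
    TransformedMatrix,
    ValidationError,
)

logger = logging.getLogger(__name__)

MISSING_MARKERS = ["", "NA"]


def _read_table(path: Path, delimiter: str | None) -> pd.DataFrame:
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(
        path,
        sep=delimiter,
        na_values=MISSING_MARKERS,
        keep_default_na=False,
        dtype={"subject_id": str},
    )


def load_panel(
    path: Path,
    time_label: str | None = None,
    delimiter: str | None = None,
) -> ItemPanel:
    """Read a wide CSV/TSV panel, validate scores, listwise-delete missing rows.

    The file must have a ``subject_id`` column; a ``time`` column is
    optional (required when ``time_label`` is not given, in which case
    it must be constant).  Any cell outside ``[0, 6]`` or non-integer
    raises :class:`ValidationError` citing the row and column.
    """
    frame = _read_table(path, delimiter)
    if "subject_id" not in frame.columns:
        raise ValidationError(f"{path}: missing required column 'subject_id'")
    if time_label is None:
        if "time" not in frame.columns:
            raise ValidationError(f"{path}: no time column and no time_label given")
        labels = frame["time"].dropna().unique()
        if len(labels) != 1:
            raise ValidationError(f"{path}: 'time' column is not constant: {labels}")
        time_label = str(labels[0])
    item_cols = [c for c in frame.columns if c not in ("subject_id", "time")]
    if not item_cols:
        raise ValidationError(f"{path}: no item columns found")

    values = frame[item_cols].to_numpy(dtype=float)
    finite = np.isfinite(values)
    bad = finite & ((values < 0) | (values > MAX_SCORE) | (values != np.round(values)))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValidationError(
            f"{path}: invalid score {values[r, c]!r} at row {r + 2} "
            f"(file line), column '{item_cols[c]}' — scores must be "
            f"integers in [0, {MAX_SCORE}]"
        )
    complete = finite.all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info(
            "load_panel(%s): dropped %d of %d rows with missing items (listwise deletion)",
            path, n_dropped, len(frame),
        )
    subject_ids = frame.loc[complete, "subject_id"].to_numpy()
    if len(np.unique(subject_ids)) != len(subject_ids):
        dup = pd.Series(subject_ids).value_counts().idxmax()
        raise ValidationError(f"{path}: duplicate subject_id {dup!r}")
    return ItemPanel(subject_ids, time_label, values[complete].astype(np.int64), item_cols)


def pair_panels(baseline: ItemPanel, followup: ItemPanel) -> PairedPanel:
    """Align two waves on their common subjects (complete cases only)."""
    if baseline.item_labels != followup.item_labels:
        raise ValidationError("waves have different item labels")
    common = np.intersect1d(baseline.subject_ids, followup.subject_ids)
    n_drop = (baseline.n_subjects - len(common)) + (followup.n_subjects - len(common))
    if n_drop:
        logger.info("pair_panels: dropped %d wave rows without a matching subject", n_drop)
    order_b = {s: i for i, s in enumerate(baseline.subject_ids)}
    keep_b = np.array(sorted((order_b[s] for s in common)))
    ids = baseline.subject_ids[keep_b]
    order_f = {s: i for i, s in enumerate(followup.subject_ids)}
    keep_f = np.array([order_f[s] for s in ids])
    return PairedPanel(baseline.take_rows(keep_b), followup.take_rows(keep_f))


def load_paired(
    baseline_path: Path, followup_path: Path, delimiter: str | None = None
) -> PairedPanel:
    return pair_panels(
        load_panel(baseline_path, "baseline", delimiter),
        load_panel(followup_path, "followup", delimiter),
    )


def exclude_items(panel: ItemPanel, drop: list[str]) -> ItemPanel:
    """Remove the named item columns, preserving the order of the rest."""
    unknown = [d for d in drop if d not in panel.item_labels]
    if unknown:
        raise ValidationError(f"unknown item(s) to drop: {unknown}")
    keep = [i for i, lab in enumerate(panel.item_labels) if lab not in set(drop)]
    return ItemPanel(
        panel.subject_ids,
        panel.time_label,
        panel.scores[:, keep],
        [panel.item_labels[i] for i in keep],
    )


def npn_delta(n: int) -> float:
    """Winsorization level for the truncated-ECDF transform."""
    return 1.0 / (4.0 * n**0.25 * math.sqrt(math.pi * math.log(n)))


def nonparanormal_transform(panel: ItemPanel | np.ndarray, item_labels=None) -> TransformedMatrix:
    """Marginal Gaussianization of each item column (see module docstring)."""
    if isinstance(panel, ItemPanel):
        scores = panel.scores
        item_labels = panel.item_labels
        time_label = panel.time_label
    else:
        scores = np.asarray(panel)
        if item_labels is None:
            item_labels = [f"item{j + 1}" for j in range(scores.shape[1])]
        time_label = None
    n, p = scores.shape
    if n < 10:
        raise ValidationError(f"nonparanormal transform needs n >= 10, got n={n}")
    delta = npn_delta(n)
    out = np.empty((n, p), dtype=float)
    for j in range(p):
        col = scores[:, j]
        if col.min() == col.max():
            raise ValidationError(
                f"item '{item_labels[j]}' is constant; it carries no network information"
            )
        if np.issubdtype(col.dtype, np.integer) and 0 <= col.min() and col.max() <= MAX_SCORE:
            # bincount-based average ranks: fast path for ordinal columns
            counts = np.bincount(col, minlength=MAX_SCORE + 1)
            avg_rank = np.cumsum(counts) - (counts - 1) / 2.0
            u = avg_rank[col] / n
        else:
            u = rankdata(col, method="average") / n
        u = np.clip(u, delta, 1.0 - delta)
        x = ndtri(u)
        out[:, j] = x / x.std(ddof=1)
    return TransformedMatrix(out, list(item_labels), time_label)


def correlation(t: TransformedMatrix | np.ndarray, item_labels=None) -> CorrelationMatrix:
    """Pearson correlation of the transformed columns, clipped to PSD."""
    if isinstance(t, TransformedMatrix):
        values = t.values
        item_labels = t.item_labels
    else:
        values = np.asarray(t, dtype=float)
        if item_labels is None:
            item_labels = [f"item{j + 1}" for j in range(values.shape[1])]
    n, p = values.shape
    if n < 3:
        raise ValidationError(f"need at least 3 complete rows to correlate, got {n}")
    if n <= p:
        warnings.warn(f"correlation with n={n} <= p={p} rows is ill-conditioned")
    corr = np.corrcoef(values, rowvar=False)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    eigvals, eigvecs = np.linalg.eigh(corr)
    if eigvals.min() < -1e-8:
        logger.info("correlation: clipping negative eigenvalue %.3g to PSD", eigvals.min())
    if eigvals.min() < 0:
        corr = (eigvecs * np.clip(eigvals, 0.0, None)) @ eigvecs.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
        corr = (corr + corr.T) / 2.0
        np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(corr, list(item_labels))


# ---------------------------------------------------------------------------
# Optional polychoric route (config option; npn-then-Pearson is the default)
# ---------------------------------------------------------------------------

def bivariate_normal_cdf(h: float, k: float, rho: float) -> float:
    """P(X <= h, Y <= k) for standard bivariate normal via Owen's T."""
    if rho >= 1.0 - 1e-12:
        return float(ndtr(min(h, k)))
    if rho <= -1.0 + 1e-12:
        return float(max(ndtr(h) + ndtr(k) - 1.0, 0.0))
    if not np.isfinite(h) and h > 0:
        return float(ndtr(k))
    if not np.isfinite(k) and k > 0:
        return float(ndtr(h))
    if not np.isfinite(h) or not np.isfinite(k):
        return 0.0
    denom = math.sqrt(1.0 - rho * rho)
    eps = 1e-14
    hh = h if abs(h) > eps else eps
    kk = k if abs(k) > eps else eps
    a_h = (kk - rho * hh) / (hh * denom)
    a_k = (hh - rho * kk) / (kk * denom)
    beta = 0.0
    if h * k < 0 or (h * k == 0 and (h + k) < 0):
        beta = 0.5
    val = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(hh, a_h) - owens_t(kk, a_k) - beta
    return float(min(max(val, 0.0), 1.0))


def _marginal_thresholds(col: np.ndarray) -> np.ndarray:
    n = len(col)
    counts = np.bincount(col, minlength=MAX_SCORE + 1)
    cum = np.cumsum(counts)[:-1] / n
    cum = np.clip(cum, 1e-6, 1.0 - 1e-6)
    return ndtri(cum)


def _polychoric_rho(col_a: np.ndarray, col_b: np.ndarray) -> float:
    ta = np.concatenate(([-np.inf], _marginal_thresholds(col_a), [np.inf]))
    tb = np.concatenate(([-np.inf], _marginal_thresholds(col_b), [np.inf]))
    counts = np.zeros((MAX_SCORE + 1, MAX_SCORE + 1))
    np.add.at(counts, (col_a, col_b), 1.0)
    occ = np.argwhere(counts > 0)

    def negloglik(rho: float) -> float:
        cdf = np.array(
            [[bivariate_normal_cdf(a, b, rho) for b in tb] for a in ta]
        )
        ll = 0.0
        for i, j in occ:
            p_cell = cdf[i + 1, j + 1] - cdf[i, j + 1] - cdf[i + 1, j] + cdf[i, j]
            ll += counts[i, j] * math.log(max(p_cell, 1e-12))
        return -ll

    res = minimize_scalar(negloglik, bounds=(-0.995, 0.995), method="bounded",
                          options={"xatol": 1e-4})
    return float(res.x)


def polychoric_correlation(panel: ItemPanel) -> CorrelationMatrix:
    """Pairwise two-step polychoric correlations of the raw ordinal scores."""
    p = panel.n_items
    corr = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            corr[i, j] = corr[j, i] = _polychoric_rho(panel.scores[:, i], panel.scores[:, j])
    eigvals, eigvecs = np.linalg.eigh(corr)
    if eigvals.min() < 0:
        logger.info("polychoric_correlation: clipping min eigenvalue %.3g", eigvals.min())
        corr = (eigvecs * np.clip(eigvals, 1e-10, None)) @ eigvecs.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
        corr = (corr + corr.T) / 2.0
        np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(corr, panel.item_labels)
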