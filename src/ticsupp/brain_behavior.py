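"""Brain-behaviour coupling: mask summaries of dERSP vs. suppression scores.

For each spatial IC cluster, the suppression-minus-free contrast (dERSP) of
every member IC is averaged over the cluster's significance mask; when a
subject contributes several ICs the summaries are averaged across them, so
the subject remains the unit of analysis.  Per (cluster, group) cell a
Pearson correlation with the behavioural suppression ratio is computed, a
percentile bootstrap over subjects gives its confidence interval, and
Benjamini-Hochberg FDR correction is applied jointly across all cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .behavioral import AdjustedModelResult, covariate_correlation, fdr_bh, fit_adjustment_model

__all__ = [
    "EmptyMaskError",
    "mask_mean_delta",
    "bootstrap_pearson_ci",
    "correlate_with_ratio",
    "adjusted_power_regression",
]


class EmptyMaskError(ValueError):
    """The significance mask contains no pixels; no summary can be formed."""


def mask_mean_delta(deltas, subject_ids, mask) -> pd.Series:
    """Per-subject mean dERSP over mask pixels, averaged across member ICs.

    Parameters
    ----------
    deltas
        sequence of per-IC dERSP maps (``DeltaERSP`` or 2-D arrays), one per
        member IC of the cluster.
    subject_ids
        subject of each member IC, aligned with ``deltas``.
    mask
        boolean time-frequency mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise EmptyMaskError("significance mask is empty")
    values = []
    for d in deltas:
        arr = np.asarray(getattr(d, "values", d), dtype=float)
        if arr.shape != mask.shape:
            raise ValueError(f"dERSP shape {arr.shape} != mask shape {mask.shape}")
        values.append(arr[mask].mean())
    per_ic = pd.DataFrame({"subject_id": np.asarray(subject_ids), "value": values})
    out = per_ic.groupby("subject_id", sort=True)["value"].mean()
    if out.isna().any():
        raise ValueError("mask summary produced NaN values")
    return out


def bootstrap_pearson_ci(
    x, y, n_boot: int = 2000, seed: int = 0, ci: float = 0.95
) -> tuple[float, float]:
    """Percentile bootstrap CI of Pearson r, resampling subjects with replacement."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    xs, ys = x[idx], y[idx]
    xc = xs - xs.mean(axis=1, keepdims=True)
    yc = ys - ys.mean(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc * yc).sum(axis=1) / np.sqrt(
            (xc**2).sum(axis=1) * (yc**2).sum(axis=1)
        )
    r = r[np.isfinite(r)]  # drop degenerate constant resamples
    lo = (1.0 - ci) / 2.0
    return float(np.percentile(r, 100 * lo)), float(np.percentile(r, 100 * (1 - lo)))


def correlate_with_ratio(
    summaries: pd.DataFrame,
    scores: pd.DataFrame,
    n_boot: int = 2000,
    seed: int = 0,
    min_n: int = 5,
) -> pd.DataFrame:
    """Brain-behaviour correlations per (cluster, group) cell with bootstrap CIs.

    Parameters
    ----------
    summaries
        columns ``cluster``, ``group``, ``subject_id``, ``summary`` (one row
        per subject per cluster).
    scores
        columns ``subject_id``, ``ratio`` (the behavioural suppression score).
    n_boot, seed
        bootstrap resamples of subjects and the RNG seed (deterministic).
    min_n
        minimum subjects per cell; smaller cells raise.

    FDR correction is applied jointly across all returned cells, matching a
    family of all IC clusters x groups.
    """
    merged = summaries.merge(scores[["subject_id", "ratio"]], on="subject_id")
    rows = []
    rng = np.random.default_rng(seed)
    for (cluster, group), cell in merged.groupby(["cluster", "group"], sort=True):
        if len(cell) < min_n:
            raise ValueError(
                f"cell ({cluster}, {group}) has {len(cell)} subjects; need >= {min_n}"
            )
        x = cell["summary"].to_numpy(dtype=float)
        y = cell["ratio"].to_numpy(dtype=float)
        r, p = covariate_correlation(x, y)
        cell_seed = int(rng.integers(0, 2**31 - 1))
        ci_lo, ci_hi = bootstrap_pearson_ci(x, y, n_boot=n_boot, seed=cell_seed)
        rows.append(
            {
                "cluster": cluster,
                "group": group,
                "n": len(cell),
                "r": r,
                "p_raw": p,
                "ci_lo": ci_lo,
                "ci_hi": ci_hi,
                "ci_contains_estimate": bool(ci_lo <= r <= ci_hi),
            }
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = fdr_bh(out["p_raw"].to_numpy())
    return out


def adjusted_power_regression(data: pd.DataFrame) -> AdjustedModelResult:
    """Covariate-adjusted regression of the mask summary on the suppression score.

    ``data`` needs columns ``summary``, ``score``, ``age``, ``drug``; the
    model is the fixed-effects fit ``summary ~ age + drug + score`` with
    uncorrected per-term p-values and adjusted R^2.
    """
    return fit_adjustment_model(data, formula="summary ~ age + drug + score")
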