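"""Behavioral analysis of tic/blink counts.

Event counts per block are normalised to events/min; suppression conditions
are compared within each group by paired t-tests with Benjamini-Hochberg
FDR correction; behavioural suppression is summarised by the ratio
``NoSupp / ((Supp_Vrb + Supp_Rwd) / 2)`` (higher = better suppression); and
fixed-effect linear models adjust group/condition contrasts for age and
psychotropic-drug use, optionally comparing against a random-intercept
mixed model with a likelihood-ratio test.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .synthetic_data import CONDITIONS, CohortTable, EventSeries

__all__ = [
    "normalize_counts",
    "condition_rates",
    "pairwise_paired_tests",
    "suppression_ratio",
    "suppression_scores",
    "covariate_correlation",
    "fdr_bh",
    "AdjustedModelResult",
    "LRTestResult",
    "fit_adjustment_model",
]

_RATE_COLS = {c: f"rate_{c}" for c in CONDITIONS}


def normalize_counts(events: EventSeries) -> float:
    """Events per minute within one block."""
    if events.block_duration_s <= 0:
        raise ValueError("block duration must be positive")
    return events.n_events / (events.block_duration_s / 60.0)


def condition_rates(cohort: CohortTable, include_excluded: bool = True) -> pd.DataFrame:
    """Per-subject normalised rates per condition plus the Supp_Ave collapse."""
    table = cohort.subjects if include_excluded else cohort.included()
    rows = []
    for _, subj in table.iterrows():
        rates = {
            _RATE_COLS[c]: normalize_counts(cohort.event_series(subj.subject_id, c))
            for c in CONDITIONS
        }
        rates["rate_Supp_Ave"] = (rates["rate_Supp_Vrb"] + rates["rate_Supp_Rwd"]) / 2.0
        rows.append({"subject_id": subj.subject_id, "group": subj.group, **rates})
    return pd.DataFrame(rows)


def _paired_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Paired t and two-sided p, with a degeneracy flag for zero-variance diffs."""
    diff = x - y
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return 0.0, 1.0, True
        return float(np.sign(diff.mean()) * np.inf), 0.0, True
    t, p = stats.ttest_rel(x, y)
    return float(t), float(p), False


def pairwise_paired_tests(rates: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests across all condition pairs, within each group.

    FDR correction (Benjamini-Hochberg) is applied within each group's
    family of three pairwise tests.  Degenerate zero-variance difference
    vectors are flagged rather than raising, so simulated edge cases do not
    abort a cohort run.
    """
    results = []
    for group, sub in rates.groupby("group", sort=False):
        if len(sub) < 3:
            raise ValueError(f"need at least 3 subjects per group; {group} has {len(sub)}")
        for a, b in combinations(CONDITIONS, 2):
            xa = sub[_RATE_COLS[a]].to_numpy(dtype=float)
            xb = sub[_RATE_COLS[b]].to_numpy(dtype=float)
            if np.any(~np.isfinite(xa)) or np.any(~np.isfinite(xb)):
                raise ValueError(f"missing condition rates in group {group}")
            t, p, degenerate = _paired_t(xa, xb)
            results.append(
                {
                    "group": group,
                    "condition_a": a,
                    "condition_b": b,
                    "n": len(sub),
                    "t": t,
                    "df": len(sub) - 1,
                    "p_raw": p,
                    "degenerate": degenerate,
                }
            )
    out = pd.DataFrame(results)
    out["p_fdr"] = np.nan
    for group in out.group.unique():
        sel = out.group == group
        out.loc[sel, "p_fdr"] = fdr_bh(out.loc[sel, "p_raw"].to_numpy())
    return out


def suppression_ratio(rate_nosupp, rate_vrb, rate_rwd):
    """Behavioural suppression ratio ``NoSupp / ((Supp_Vrb + Supp_Rwd)/2)``.

    Accepts scalars or aligned arrays; raises when any denominator is zero.
    """
    no = np.asarray(rate_nosupp, dtype=float)
    denom = (np.asarray(rate_vrb, dtype=float) + np.asarray(rate_rwd, dtype=float)) / 2.0
    if np.any(denom == 0):
        raise ValueError("suppression ratio undefined: zero mean suppression rate")
    out = no / denom
    return float(out) if out.ndim == 0 else out


def suppression_scores(rates: pd.DataFrame) -> pd.DataFrame:
    """Per-subject suppression ratios from a :func:`condition_rates` table."""
    ratio = suppression_ratio(
        rates["rate_NoSupp"], rates["rate_Supp_Vrb"], rates["rate_Supp_Rwd"]
    )
    return pd.DataFrame(
        {"subject_id": rates.subject_id, "group": rates.group, "ratio": ratio}
    )


def covariate_correlation(x, y) -> tuple[float, float]:
    """Pearson correlation and two-sided p between two per-subject scalars."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need at least 3 paired finite observations")
    if np.allclose(x[ok].std(), 0) or np.allclose(y[ok].std(), 0):
        raise ValueError("correlation undefined for a constant input vector")
    r, p = stats.pearsonr(x[ok], y[ok])
    return float(r), float(p)


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class LRTestResult:
    """Random-intercept likelihood-ratio test against the fixed-only model."""

    sigma: float  # random-intercept SD
    delta_chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class AdjustedModelResult:
    terms: pd.DataFrame  # coef, se, p per design term
    adjusted_r2: float
    lr_test: LRTestResult | None = None


def fit_adjustment_model(
    data: pd.DataFrame,
    formula: str = "rate ~ age + drug + C(condition, Treatment('NoSupp'))"
    " * C(group, Treatment('TDC'))",
    random_intercept: str | None = None,
) -> AdjustedModelResult:
    """Fixed-effects linear adjustment model with uncorrected per-term p.

    The default formula is the covariate-adjusted condition-by-group model
    for event rates (treatment coding with TDC and NoSupp as references).
    With ``random_intercept`` set to a grouping column (e.g. ``subject_id``),
    a random-intercept mixed model is fit by maximum likelihood and compared
    with the fixed-only model by a 1-df likelihood-ratio test.
    """
    ols = smf.ols(formula, data=data)
    if ols.exog.shape[0] <= ols.exog.shape[1]:
        raise ValueError("fewer observations than model parameters")
    if np.linalg.matrix_rank(ols.exog) < ols.exog.shape[1]:
        raise ValueError("rank-deficient design matrix")
    fit = ols.fit()
    terms = pd.DataFrame(
        {"coef": fit.params, "se": fit.bse, "p": fit.pvalues}
    )
    lr = None
    if random_intercept is not None:
        mixed = MixedLM.from_formula(
            formula, groups=data[random_intercept], data=data
        ).fit(reml=False)
        ml_fit = ols.fit()  # OLS log-likelihood is the ML fixed-only likelihood
        delta = max(0.0, 2.0 * (mixed.llf - ml_fit.llf))
        lr = LRTestResult(
            sigma=float(np.sqrt(mixed.cov_re.iloc[0, 0])),
            delta_chi2=float(delta),
            df=1,
            p=float(stats.chi2.sf(delta, 1)),
        )
    return AdjustedModelResult(
        terms=terms, adjusted_r2=float(fit.rsquared_adj), lr_test=lr
    )
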