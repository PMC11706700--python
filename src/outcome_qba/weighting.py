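"""Propensity scores, ATE weighting, trimming, balance, weighted outcome models.

The propensity score is the probability of receiving the exposure given
baseline covariates, estimated by main-effects logistic regression.
Inverse probability of treatment weights target the average treatment
effect: ``1/PS`` for the exposed and ``1/(1-PS)`` for the comparator
(unstabilised by default).  Scores are trimmed to the region of common
support before any outcome modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .contingency import Z95, EffectEstimate
from .errors import ContractViolationError, DegenerateTableError, FittingError, TrimmingError

__all__ = [
    "PropensityResult",
    "BalanceRow",
    "fit_propensity",
    "trim_common_support",
    "smd_table",
    "weighted_logistic_or",
]


@dataclass
class PropensityResult:
    """Fitted scores, ATE weights and post-trimming inclusion flags."""

    scores: np.ndarray
    weights: np.ndarray
    kept: np.ndarray
    exposed: np.ndarray
    coefficients: dict[str, float]

    def __post_init__(self):
        n = len(self.scores)
        if not (len(self.weights) == len(self.kept) == len(self.exposed) == n):
            raise ContractViolationError("propensity arrays must share one length")


@dataclass(frozen=True)
class BalanceRow:
    """Standardised mean difference for one covariate, before/after weighting."""

    covariate: str
    smd_before: float
    smd_after: float


def _weights_from_scores(scores: np.ndarray, exposed: np.ndarray, stabilized: bool) -> np.ndarray:
    w = np.where(exposed, 1.0 / scores, 1.0 / (1.0 - scores))
    if stabilized:
        p = exposed.mean()
        w = np.where(exposed, p, 1.0 - p) * w
    return w


def fit_propensity(
    cohort: pd.DataFrame,
    covariates: list[str],
    stabilized: bool = False,
) -> PropensityResult:
    """Fit a main-effects logistic propensity model and derive ATE weights.

    Raises :class:`FittingError` on non-convergence or separation
    (fitted probabilities indistinguishable from 0/1).
    """
    if "arm" not in cohort.columns:
        raise ContractViolationError("cohort lacks an 'arm' column")
    missing = [c for c in covariates if c not in cohort.columns]
    if missing:
        raise ContractViolationError(f"covariates absent from cohort: {missing}")
    exposed = (cohort["arm"] == "exposed").to_numpy()
    if exposed.sum() < 2 or (~exposed).sum() < 2:
        raise ContractViolationError("need at least 2 patients per arm")

    X = sm.add_constant(cohort[covariates].astype(float), has_constant="add")
    try:
        fit = sm.GLM(exposed.astype(float), X, family=sm.families.Binomial()).fit()
    except Exception as exc:  # perfect separation raises from the IRLS loop
        raise FittingError(f"propensity model failed: {exc}") from exc
    scores = np.asarray(fit.fittedvalues, dtype=float)
    if not np.all(np.isfinite(fit.params)) or scores.min() < 1e-10 or scores.max() > 1 - 1e-10:
        raise FittingError(
            "propensity model separated: fitted probabilities reach 0/1 "
            f"(range {scores.min():.3g}-{scores.max():.3g})"
        )
    weights = _weights_from_scores(scores, exposed, stabilized)
    return PropensityResult(
        scores=scores,
        weights=weights,
        kept=np.ones(len(scores), dtype=bool),
        exposed=exposed,
        coefficients=dict(zip(X.columns, np.asarray(fit.params, dtype=float))),
    )


def trim_common_support(result: PropensityResult) -> PropensityResult:
    """Keep patients whose score lies in the overlap of the arm-wise ranges."""
    s, e = result.scores, result.exposed
    lo = max(s[e].min(), s[~e].min())
    hi = min(s[e].max(), s[~e].max())
    if lo > hi:
        raise TrimmingError(f"empty common support: arm ranges do not overlap ({lo:.3f} > {hi:.3f})")
    kept = (s >= lo) & (s <= hi)
    if not (kept & e).any() or not (kept & ~e).any():
        raise TrimmingError("an arm is empty after common-support trimming")
    return PropensityResult(
        scores=s,
        weights=result.weights,
        kept=kept,
        exposed=e,
        coefficients=result.coefficients,
    )


def _smd(x1, x0, w1=None, w0=None) -> float:
    if w1 is None:
        m1, m0 = x1.mean(), x0.mean()
        v1 = x1.var(ddof=1)
        v0 = x0.var(ddof=1)
    else:
        m1 = np.average(x1, weights=w1)
        m0 = np.average(x0, weights=w0)
        v1 = np.average((x1 - m1) ** 2, weights=w1)
        v0 = np.average((x0 - m0) ** 2, weights=w0)
    pooled = (v1 + v0) / 2.0
    if pooled <= 0:
        return float("nan")
    return float((m1 - m0) / np.sqrt(pooled))


def smd_table(
    cohort: pd.DataFrame,
    result: PropensityResult,
    covariates: list[str] | None = None,
) -> list[BalanceRow]:
    """Standardised mean differences before and after weighting.

    ``SMD = (mean_exposed - mean_comparator) / sqrt((var_exposed + var_comparator)/2)``,
    with weighted moments for the post-weighting column.  Restricted to
    patients kept after trimming.  A zero pooled variance yields NaN rather
    than an exception so full batteries can be tabulated.
    """
    if covariates is None:
        covariates = [c for c in result.coefficients if c != "const"]
    rows = []
    k, e, w = result.kept, result.exposed, result.weights
    for cov in covariates:
        x = cohort[cov].to_numpy(dtype=float)
        x1, x0 = x[k & e], x[k & ~e]
        w1, w0 = w[k & e], w[k & ~e]
        rows.append(
            BalanceRow(
                covariate=cov,
                smd_before=_smd(x1, x0),
                smd_after=_smd(x1, x0, w1, w0),
            )
        )
    return rows


def weighted_logistic_or(
    cohort: pd.DataFrame,
    result: PropensityResult,
    outcome: str,
    method: str = "iptw",
) -> EffectEstimate:
    """IPT-weighted logistic regression of an outcome flag on exposure.

    The 95% CI uses a robust (HC0 sandwich) variance, the standard choice
    for weighted estimating equations.
    """
    if outcome not in cohort.columns:
        raise ContractViolationError(f"outcome column {outcome!r} absent from cohort")
    k = result.kept
    y = cohort[outcome].to_numpy(dtype=float)[k]
    e = result.exposed[k].astype(float)
    w = result.weights[k]
    for arm_mask, name in ((e == 1, "exposed"), ((e == 0), "comparator")):
        if y[arm_mask].sum() == 0:
            raise DegenerateTableError(f"no {outcome} events in the {name} arm after trimming")
    X = sm.add_constant(pd.DataFrame({"exposed": e}), has_constant="add")
    try:
        fit = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=w).fit(cov_type="HC0")
    except Exception as exc:
        raise FittingError(f"weighted outcome model failed: {exc}") from exc
    beta = float(fit.params["exposed"])
    se = float(fit.bse["exposed"])
    return EffectEstimate(
        or_value=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z95 * se)),
        ci_high=float(np.exp(beta + Z95 * se)),
        log_se=se,
        method=method,
    )
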