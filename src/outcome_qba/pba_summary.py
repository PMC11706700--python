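"""Summary-level probabilistic bias analysis on 2x2 tables.

Each Monte Carlo iteration draws (Se, Sp) from their priors, matrix-corrects
the any-event subpopulation table, derives PPV/NPV, re-adjusts the observed
table, optionally adds misclassification random error (binomial draws with
the PPV / 1-NPV probabilities) and conventional random error (a standard
normal multiple of the conventional log-OR standard error), re-inserts
non-events and records the odds ratio.  Iterations whose correction yields
non-positive cells are discarded and counted — they signal bias parameters
incompatible with the observed data.  The retained draws are summarised by
their median and a 95% simulation interval (2.5th/97.5th percentiles),
which reflects systematic error, bias-parameter uncertainty,
misclassification randomness and conventional random error together.

Randomness under one seed is consumed in a fixed documented order:
sensitivity draws, specificity draws, binomial reclassification draws,
then standard-normal draws — so results are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bias_params import BetaSpec, BiasParams
from .contingency import TwoByTwo
from .errors import AnalysisFailureError, ContractViolationError
from .rng import child_rng

__all__ = ["PBAOptions", "PBAResult", "pba_summary"]


@dataclass(frozen=True)
class PBAOptions:
    """Monte Carlo settings shared by summary- and record-level PBA."""

    n_iterations: int = 100_000
    seed: int = 0
    include_misclass_random_error: bool = True
    include_conventional_error: bool = True
    si_quantiles: tuple[float, float] = (0.025, 0.975)
    keep_draws: bool = False

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ContractViolationError("n_iterations must be >= 1")
        lo, hi = self.si_quantiles
        if not (0.0 <= lo < hi <= 1.0):
            raise ContractViolationError("si_quantiles must be an increasing pair in [0, 1]")


@dataclass(frozen=True)
class PBAResult:
    """Median OR, simulation interval and discard accounting."""

    median_or: float
    si_low: float
    si_high: float
    n_iterations: int
    n_discarded: int
    draws: np.ndarray | None = field(default=None, compare=False)

    @property
    def discard_fraction(self) -> float:
        return self.n_discarded / self.n_iterations

    def to_dict(self) -> dict:
        return {
            "median_or": self.median_or,
            "si_low": self.si_low,
            "si_high": self.si_high,
            "n_iterations": self.n_iterations,
            "n_discarded": self.n_discarded,
            "discard_fraction": self.discard_fraction,
        }


def _summarise(log_or: np.ndarray, n_iterations: int, n_discarded: int, options: PBAOptions) -> PBAResult:
    if log_or.size == 0:
        raise AnalysisFailureError(
            "all iterations discarded: bias-parameter priors are incompatible with the data",
            discard_fraction=1.0,
        )
    ors = np.exp(log_or)
    lo, hi = np.quantile(ors, options.si_quantiles)
    return PBAResult(
        median_or=float(np.median(ors)),
        si_low=float(lo),
        si_high=float(hi),
        n_iterations=n_iterations,
        n_discarded=n_discarded,
        draws=ors if options.keep_draws else None,
    )


def pba_summary(
    subpop: TwoByTwo,
    totals: tuple[float, float],
    se_spec: BetaSpec,
    sp_spec: BetaSpec,
    options: PBAOptions,
) -> PBAResult:
    """Run summary-level PBA on an any-event subpopulation table.

    ``totals`` are the full-cohort arm sizes used to re-insert non-events
    before each iteration's OR.  Non-differential parameters: one (Se, Sp)
    draw applies to both arms per iteration.
    """
    if subpop.scope != "any_event_subpop":
        raise ContractViolationError("pba_summary expects an any_event_subpop table")
    n_e_total, n_c_total = totals
    n_it = options.n_iterations
    rng = child_rng(options.seed, "pba-summary")

    se = se_spec.sample_with(n_it, rng)
    sp = sp_spec.sample_with(n_it, rng)
    denom = se + sp - 1.0
    bad = denom <= 0.0

    a_obs, b_obs, c_obs, d_obs = subpop.cells
    n_e, n_c = subpop.n_exposed, subpop.n_comparator

    with np.errstate(divide="ignore", invalid="ignore"):
        a_corr = (a_obs - (1.0 - sp) * n_e) / denom
        c_corr = (c_obs - (1.0 - sp) * n_c) / denom
    b_corr = n_e - a_corr
    d_corr = n_c - c_corr
    invalid = bad | (a_corr <= 0) | (b_corr <= 0) | (c_corr <= 0) | (d_corr <= 0)

    pi_e = a_corr / n_e
    pi_c = c_corr / n_c
    with np.errstate(divide="ignore", invalid="ignore"):
        ppv_e = se * pi_e / (se * pi_e + (1 - sp) * (1 - pi_e))
        npv_e = sp * (1 - pi_e) / ((1 - se) * pi_e + sp * (1 - pi_e))
        ppv_c = se * pi_c / (se * pi_c + (1 - sp) * (1 - pi_c))
        npv_c = sp * (1 - pi_c) / ((1 - se) * pi_c + sp * (1 - pi_c))

    # expected reclassification of the observed table
    a_adj = ppv_e * a_obs + (1 - npv_e) * b_obs
    c_adj = ppv_c * c_obs + (1 - npv_c) * d_obs

    if options.include_misclass_random_error:
        # binomial realisation of the reclassification, sizes = observed cells
        safe = ~invalid
        p_tp_e = np.where(safe, np.clip(ppv_e, 0, 1), 0.5)
        p_fn_e = np.where(safe, np.clip(1 - npv_e, 0, 1), 0.5)
        p_tp_c = np.where(safe, np.clip(ppv_c, 0, 1), 0.5)
        p_fn_c = np.where(safe, np.clip(1 - npv_c, 0, 1), 0.5)
        a_adj = rng.binomial(int(round(a_obs)), p_tp_e) + rng.binomial(int(round(b_obs)), p_fn_e)
        c_adj = rng.binomial(int(round(c_obs)), p_tp_c) + rng.binomial(int(round(d_obs)), p_fn_c)
        a_adj = a_adj.astype(float)
        c_adj = c_adj.astype(float)
        invalid = invalid | (a_adj <= 0) | (c_adj <= 0) | (a_adj >= n_e) | (c_adj >= n_c)

    b_full = n_e_total - a_adj
    d_full = n_c_total - c_adj
    with np.errstate(divide="ignore", invalid="ignore"):
        log_or = np.log(a_adj / b_full) - np.log(c_adj / d_full)
        log_se = np.sqrt(1 / a_adj + 1 / b_full + 1 / c_adj + 1 / d_full)

    if options.include_conventional_error:
        z = rng.standard_normal(n_it)
        with np.errstate(invalid="ignore"):
            log_or = log_or - z * log_se

    invalid = invalid | ~np.isfinite(log_or)
    retained = log_or[~invalid]
    return _summarise(retained, n_it, int(invalid.sum()), options)
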