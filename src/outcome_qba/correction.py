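"""Misclassification algebra: matrix correction, predictive values, SBA.

Given observed case counts ``x`` among ``N`` patients in an arm and assumed
sensitivity ``Se`` and specificity ``Sp``, the corrected (true) case count is

    A = (x - (1 - Sp) * N) / (Se + Sp - 1)

per arm, with margins preserved.  Corrected prevalences give positive and
negative predictive values

    PPV = Se*pi / (Se*pi + (1-Sp)*(1-pi))
    NPV = Sp*(1-pi) / ((1-Se)*pi + Sp*(1-pi))

which in turn re-adjust the observed table (the expectation of the
record-level Bernoulli reclassification).  Corrections that push any cell
to zero or below signal bias parameters incompatible with the data and are
flagged, not patched.

Simple bias analysis (SBA) runs this chain once at fixed parameters and
reports a point estimate only: a standard error computed from the adjusted
table would ignore the uncertainty in the bias parameters themselves and
would therefore understate the true uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .bias_params import BiasParams
from .contingency import EffectEstimate, TwoByTwo, build_subpop_table, crude_or, reinsert_nonevents
from .errors import (
    ContractViolationError,
    DegenerateTableError,
    NegativeCellError,
    NonIdentifiableCorrectionError,
)

__all__ = [
    "PredictiveValues",
    "CorrectionOutcome",
    "correct_counts",
    "predictive_values",
    "expected_adjusted_table",
    "simple_bias_analysis",
]


@dataclass(frozen=True)
class PredictiveValues:
    """Arm-wise PPV/NPV and the corrected prevalences they derive from."""

    ppv_exposed: float
    npv_exposed: float
    ppv_comparator: float
    npv_comparator: float
    prev_exposed: float
    prev_comparator: float


@dataclass(frozen=True)
class CorrectionOutcome:
    """A corrected subpopulation table plus its validity flag.

    ``valid`` is False when any corrected cell is non-positive, meaning the
    bias parameters are incompatible with the observed counts;
    ``failure_cells`` names the offending cells.
    """

    corrected: TwoByTwo
    valid: bool
    failure_cells: tuple[str, ...] = ()


def _corrected_cases(x: float, n: float, se: float, sp: float) -> float:
    return (x - (1.0 - sp) * n) / (se + sp - 1.0)


def correct_counts(subpop: TwoByTwo, params: BiasParams) -> CorrectionOutcome:
    """Matrix-correct an any-event subpopulation table with arm-wise Se/Sp.

    Margins are preserved exactly.  Raises
    :class:`NonIdentifiableCorrectionError` when ``Se + Sp <= 1`` in either
    arm; incompatibility of valid parameters with the data is reported via
    the ``valid`` flag, not an exception, so Monte Carlo callers can count
    and discard.
    """
    if subpop.scope != "any_event_subpop":
        raise ContractViolationError("correct_counts expects an any_event_subpop table")
    for exposed in (True, False):
        se, sp = params.for_arm(exposed)
        if se + sp <= 1.0:
            raise NonIdentifiableCorrectionError(
                f"Se + Sp = {se + sp:.3f} <= 1 in the "
                f"{'exposed' if exposed else 'comparator'} arm"
            )

    a_corr = _corrected_cases(subpop.a, subpop.n_exposed, params.se_exposed, params.sp_exposed)
    c_corr = _corrected_cases(
        subpop.c, subpop.n_comparator, params.se_comparator, params.sp_comparator
    )
    b_corr = subpop.n_exposed - a_corr
    d_corr = subpop.n_comparator - c_corr

    failures = tuple(
        name
        for name, v in zip(("a", "b", "c", "d"), (a_corr, b_corr, c_corr, d_corr))
        if v <= 0.0
    )
    corrected = TwoByTwo(a=a_corr, b=b_corr, c=c_corr, d=d_corr, scope="any_event_subpop")
    return CorrectionOutcome(corrected=corrected, valid=not failures, failure_cells=failures)


def predictive_values(
    subpop: TwoByTwo, corrected: TwoByTwo, params: BiasParams
) -> PredictiveValues:
    """PPV/NPV per arm from corrected prevalences and the bias parameters."""
    out = {}
    for arm, n, cases in (
        ("exposed", subpop.n_exposed, corrected.a),
        ("comparator", subpop.n_comparator, corrected.c),
    ):
        if n <= 0:
            raise DegenerateTableError(f"empty {arm} arm")
        se, sp = params.for_arm(arm == "exposed")
        pi = cases / n
        denom_p = se * pi + (1.0 - sp) * (1.0 - pi)
        denom_n = (1.0 - se) * pi + sp * (1.0 - pi)
        if denom_p <= 0.0 or denom_n <= 0.0:
            raise DegenerateTableError(
                f"degenerate prevalence {pi:.4f} in {arm} arm (zero PV denominator)"
            )
        out[arm] = (se * pi / denom_p, sp * (1.0 - pi) / denom_n, pi)
    return PredictiveValues(
        ppv_exposed=out["exposed"][0],
        npv_exposed=out["exposed"][1],
        ppv_comparator=out["comparator"][0],
        npv_comparator=out["comparator"][1],
        prev_exposed=out["exposed"][2],
        prev_comparator=out["comparator"][2],
    )


def expected_adjusted_table(subpop: TwoByTwo, pv: PredictiveValues) -> TwoByTwo:
    """Re-adjust the observed table with PPV/NPV (expected reclassification).

    Per arm: adjusted cases = PPV * observed cases + (1 - NPV) * observed
    non-cases.  Algebraically identical to the matrix-corrected cells when
    the PVs come from the same (Se, Sp) — the record-level Bernoulli trials
    have exactly this expectation.
    """
    a_adj = pv.ppv_exposed * subpop.a + (1.0 - pv.npv_exposed) * subpop.b
    c_adj = pv.ppv_comparator * subpop.c + (1.0 - pv.npv_comparator) * subpop.d
    return TwoByTwo(
        a=a_adj,
        b=subpop.n_exposed - a_adj,
        c=c_adj,
        d=subpop.n_comparator - c_adj,
        scope="any_event_subpop",
    )


def simple_bias_analysis(
    source,
    params: BiasParams,
    outcome: str | None = None,
    totals: tuple[float, float] | None = None,
) -> EffectEstimate:
    """One-shot bias correction at fixed (Se, Sp): a point estimate, no CI.

    ``source`` is either a cohort table (``outcome`` required; totals taken
    from the cohort) or an any-event subpopulation :class:`TwoByTwo`
    (``totals`` required).  The chain is: subpopulation table -> matrix
    correction -> re-insert non-events -> crude OR.  The returned estimate
    deliberately carries no interval (``ci_low == ci_high == or_value``,
    ``log_se = 0``).
    """
    if isinstance(source, TwoByTwo):
        if totals is None:
            raise ContractViolationError("totals required when correcting a bare table")
        subpop = source
        n_e, n_c = totals
    elif isinstance(source, pd.DataFrame):
        if outcome is None:
            raise ContractViolationError("outcome required when correcting a cohort")
        subpop = build_subpop_table(source, outcome)
        n_e = int((source["arm"] == "exposed").sum())
        n_c = int((source["arm"] == "comparator").sum())
    else:
        raise ContractViolationError(f"unsupported source type {type(source).__name__}")

    result = correct_counts(subpop, params)
    if not result.valid:
        arms = sorted({"exposed" if cell in ("a", "b") else "comparator" for cell in result.failure_cells})
        raise NegativeCellError(
            f"correction produced non-positive cells {result.failure_cells} "
            f"({' and '.join(arms)} arm)",
            cells=list(result.failure_cells),
        )
    full = reinsert_nonevents(result.corrected, n_e, n_c)
    est = crude_or(full, method="sba")
    return EffectEstimate(
        or_value=est.or_value,
        ci_low=est.or_value,
        ci_high=est.or_value,
        log_se=0.0,
        method="sba",
    )
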