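"""Deterministic sweeps over fixed bias-parameter values.

Grids answer "how wrong would the bias parameters have to be" questions:
each cell fixes (Se, Sp) — optionally with arm-specific sensitivities at a
shared specificity — and reports the corrected odds ratio.  Random-error
layers are off by default so each cell is a deterministic map of the
observed table; a flag runs full PBA machinery per cell instead.  Cells
whose correction is invalid (negative counts) carry a sentinel status so
heatmaps can still be rendered.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .bias_params import BetaSpec, BiasParams
from .contingency import TwoByTwo, crude_or, reinsert_nonevents
from .correction import correct_counts
from .errors import ContractViolationError
from .pba_summary import PBAOptions, pba_summary

__all__ = ["GridResult", "grid_nondifferential", "grid_differential"]


@dataclass(frozen=True)
class GridResult:
    """Long-format grid of corrected estimates.

    ``table`` has columns ``se_exposed, se_comparator, sp, or, si_low,
    si_high, status`` with status in {"ok", "invalid"}; interval columns are
    NaN for deterministic (point) cells.
    """

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _point_cell(subpop, totals, se_e, se_c, sp, options):
    params = BiasParams(se_exposed=se_e, se_comparator=se_c, sp_exposed=sp, sp_comparator=sp)
    try:
        corr = correct_counts(subpop, params)
    except ContractViolationError:
        raise
    if not corr.valid:
        return {"or": float("nan"), "si_low": float("nan"), "si_high": float("nan"), "status": "invalid"}
    if options is not None and (
        options.include_misclass_random_error or options.include_conventional_error
    ):
        if se_e != se_c:
            raise ContractViolationError(
                "per-cell PBA supports non-differential cells only"
            )
        res = pba_summary(
            subpop, totals, BetaSpec.point_mass(se_e), BetaSpec.point_mass(sp), options
        )
        return {"or": res.median_or, "si_low": res.si_low, "si_high": res.si_high, "status": "ok"}
    full = reinsert_nonevents(corr.corrected, *totals)
    est = crude_or(full, method="grid")
    return {"or": est.or_value, "si_low": float("nan"), "si_high": float("nan"), "status": "ok"}


def grid_nondifferential(
    subpop: TwoByTwo,
    totals: tuple[float, float],
    se_values: list[float],
    sp_values: list[float],
    options: PBAOptions | None = None,
) -> GridResult:
    """Corrected OR over the Cartesian grid of non-differential (Se, Sp)."""
    if not se_values or not sp_values:
        raise ContractViolationError("grid value lists must be non-empty")
    rows = []
    for se in sorted(set(se_values)):
        for sp in sorted(set(sp_values)):
            cell = _point_cell(subpop, totals, se, se, sp, options)
            rows.append({"se_exposed": se, "se_comparator": se, "sp": sp, **cell})
    return GridResult(table=pd.DataFrame(rows))


def grid_differential(
    subpop: TwoByTwo,
    totals: tuple[float, float],
    se_exposed_values: list[float],
    se_comparator_values: list[float],
    sp_fixed: float,
    options: PBAOptions | None = None,
) -> GridResult:
    """Arm-specific sensitivity sweep at one shared specificity.

    Probes differential misclassification: how asymmetric would outcome
    ascertainment between the arms need to be to move, or reverse, the
    corrected estimate.
    """
    if not (0.0 < sp_fixed <= 1.0):
        raise ContractViolationError("sp_fixed must lie in (0, 1]")
    if not se_exposed_values or not se_comparator_values:
        raise ContractViolationError("sensitivity value lists must be non-empty")
    rows = []
    for se_e in sorted(set(se_exposed_values)):
        for se_c in sorted(set(se_comparator_values)):
            cell = _point_cell(subpop, totals, se_e, se_c, sp_fixed, None)
            rows.append({"se_exposed": se_e, "se_comparator": se_c, "sp": sp_fixed, **cell})
    return GridResult(table=pd.DataFrame(rows))
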