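"""2x2 exposure-outcome tables and crude odds ratios.

The bias correction operates on tables restricted to patients with an
any-cause event (hospitalised or died of any cause); patients without such
an event are re-inserted as non-cases before effect estimation, because
event occurrence itself is taken as correctly recorded and only the cause
can be misclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ContractViolationError, DegenerateTableError

__all__ = [
    "TwoByTwo",
    "EffectEstimate",
    "build_subpop_table",
    "reinsert_nonevents",
    "crude_or",
]

Z95 = 1.96  # Wald multiplier for 95% intervals


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure x outcome counts; cells may be fractional after correction.

    ``scope`` records whether the margins are the full cohort
    (``"full_cohort"``) or the any-cause-event subpopulation
    (``"any_event_subpop"``).
    """

    a: float  # exposed cases
    b: float  # exposed non-cases
    c: float  # comparator cases
    d: float  # comparator non-cases
    scope: str = "full_cohort"

    def __post_init__(self):
        if self.scope not in ("full_cohort", "any_event_subpop"):
            raise ContractViolationError(f"unknown scope {self.scope!r}")

    @property
    def n_exposed(self) -> float:
        return self.a + self.b

    @property
    def n_comparator(self) -> float:
        return self.c + self.d

    @property
    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    def to_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "c": self.c, "d": self.d, "scope": self.scope}

    @classmethod
    def from_dict(cls, d: dict) -> "TwoByTwo":
        return cls(a=d["a"], b=d["b"], c=d["c"], d=d["d"], scope=d.get("scope", "full_cohort"))


@dataclass(frozen=True)
class EffectEstimate:
    """An odds ratio with a 95% interval and the log-scale standard error."""

    or_value: float
    ci_low: float
    ci_high: float
    log_se: float
    method: str = "crude"

    def to_dict(self) -> dict:
        return {
            "or": self.or_value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "log_se": self.log_se,
            "method": self.method,
        }


def build_subpop_table(cohort: pd.DataFrame, outcome: str) -> TwoByTwo:
    """Restrict to any-cause events and count observed cause-specific cases.

    Case counting is patient-level: a patient with several hospital episodes
    is one case if any episode is observed cause-specific, and one non-case
    otherwise.

    Raises
    ------
    DegenerateTableError
        If either arm has no any-cause events.
    """
    if outcome not in ("hosp", "death"):
        raise ContractViolationError(f"outcome must be 'hosp' or 'death', got {outcome!r}")
    any_col, obs_col = f"any_{outcome}", f"obs_covid_{outcome}"
    for col in ("arm", any_col, obs_col):
        if col not in cohort.columns:
            raise ContractViolationError(f"cohort lacks column {col!r}")

    sub = cohort[cohort[any_col].astype(bool)]
    exposed = sub["arm"] == "exposed"
    n_e = int(exposed.sum())
    n_c = int((~exposed).sum())
    if n_e == 0 or n_c == 0:
        raise DegenerateTableError(
            f"no any-cause {outcome} events in the "
            f"{'exposed' if n_e == 0 else 'comparator'} arm"
        )
    a = int(sub.loc[exposed, obs_col].astype(bool).sum())
    c = int(sub.loc[~exposed, obs_col].astype(bool).sum())
    return TwoByTwo(a=a, b=n_e - a, c=c, d=n_c - c, scope="any_event_subpop")


def reinsert_nonevents(
    subpop: TwoByTwo, n_exposed_total: float, n_comparator_total: float
) -> TwoByTwo:
    """Expand a subpopulation table to the full cohort.

    Case cells are preserved exactly (fractional cells allowed); non-cases
    become ``total - cases``.
    """
    if subpop.scope != "any_event_subpop":
        raise ContractViolationError("reinsert_nonevents expects an any_event_subpop table")
    if subpop.n_exposed > n_exposed_total or subpop.n_comparator > n_comparator_total:
        raise ContractViolationError("subpopulation margins exceed cohort totals")
    if subpop.a > n_exposed_total or subpop.c > n_comparator_total:
        raise ContractViolationError("cases exceed arm totals")
    return TwoByTwo(
        a=subpop.a,
        b=n_exposed_total - subpop.a,
        c=subpop.c,
        d=n_comparator_total - subpop.c,
        scope="full_cohort",
    )


def crude_or(table: TwoByTwo, method: str = "crude") -> EffectEstimate:
    """Crude odds ratio with a Wald 95% confidence interval.

    ``OR = (a/b)/(c/d)``; ``SE(log OR) = sqrt(1/a + 1/b + 1/c + 1/d)``.
    Fractional cells (post-correction tables) are accepted; zero or negative
    cells are not (no continuity correction — invalid corrections are
    discarded upstream instead).
    """
    a, b, c, d = table.cells
    if min(a, b, c, d) <= 0:
        raise DegenerateTableError(f"non-positive cell in {table.cells}; OR undefined")
    or_value = (a / b) / (c / d)
    log_se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    half = Z95 * log_se
    return EffectEstimate(
        or_value=float(or_value),
        ci_low=float(or_value * np.exp(-half)),
        ci_high=float(or_value * np.exp(half)),
        log_se=log_se,
        method=method,
    )
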