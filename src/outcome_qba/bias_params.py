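"""Bias-parameter distributions: rescaled beta priors for Se and Sp.

Sensitivity and specificity priors are beta distributions, optionally
rescaled affinely onto a sub-interval ``[lower, upper]`` of the unit
interval.  The rescaling accommodates bounded specificities of the form
``Sp = lower + (upper - lower) * X`` with ``X ~ Beta(alpha, beta)``, used
when the data themselves bound the false-positive fraction (a cause-specific
outcome cannot have more false positives than there are non-cases).

Elicitation goes from a (2.5th percentile, median, 97.5th percentile)
triple to shape parameters by least squares on the quantile function.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import ContractViolationError, ElicitationError
from .rng import child_rng

__all__ = ["BetaSpec", "BiasParams", "beta_from_quantiles"]

#: maximum absolute deviation tolerated between requested and achieved quantiles
QUANTILE_TOL = 0.005


@dataclass(frozen=True)
class BetaSpec:
    """A beta distribution affinely rescaled onto ``[lower, upper]``.

    Parameters
    ----------
    alpha, beta
        Shape parameters, both > 0.
    lower, upper
        Support bounds, ``0 <= lower <= upper <= 1``.  Defaults give the
        standard beta on the unit interval.  ``lower == upper`` denotes a
        point mass (all quantiles and samples equal that value), used for
        fixed-parameter analyses such as SBA-equivalent PBA runs and
        sensitivity grids.
    """

    alpha: float
    beta: float
    lower: float = 0.0
    upper: float = 1.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ContractViolationError("beta shapes must be positive")
        if not (0.0 <= self.lower <= self.upper <= 1.0):
            raise ContractViolationError(
                f"support bounds must satisfy 0 <= lower <= upper <= 1, "
                f"got [{self.lower}, {self.upper}]"
            )

    @property
    def is_point_mass(self) -> bool:
        return self.lower == self.upper

    @property
    def _dist(self):
        return stats.beta(self.alpha, self.beta)

    def quantile(self, p):
        """Inverse CDF on the rescaled support."""
        p = np.asarray(p, dtype=float)
        if np.any(p < 0) or np.any(p > 1):
            raise ContractViolationError("quantile levels must lie in [0, 1]")
        if self.is_point_mass:
            return np.full_like(p, self.lower) if p.ndim else float(self.lower)
        return self.lower + (self.upper - self.lower) * self._dist.ppf(p)

    @property
    def median(self) -> float:
        return float(self.quantile(0.5))

    def sample(self, n: int, seed: int) -> np.ndarray:
        """``n`` independent draws on ``[lower, upper]``; deterministic under seed."""
        if n < 1:
            raise ContractViolationError("n must be >= 1")
        return self.sample_with(n, child_rng(seed, "beta-spec-sample"))

    def sample_with(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` values using a caller-managed generator (stream splicing)."""
        if self.is_point_mass:
            return np.full(n, self.lower)
        return self.lower + (self.upper - self.lower) * rng.beta(self.alpha, self.beta, size=n)

    @classmethod
    def point_mass(cls, value: float) -> "BetaSpec":
        """A degenerate spec concentrated exactly at ``value``."""
        if not (0.0 < value <= 1.0):
            raise ContractViolationError("point mass must lie in (0, 1]")
        return cls(alpha=1.0, beta=1.0, lower=value, upper=value)

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "beta": self.beta, "lower": self.lower, "upper": self.upper}

    @classmethod
    def from_dict(cls, d: dict) -> "BetaSpec":
        """Build from ``{alpha, beta[, lower, upper]}`` or ``{median, q025, q975[, lower, upper]}``."""
        if "alpha" in d:
            return cls(
                alpha=float(d["alpha"]),
                beta=float(d["beta"]),
                lower=float(d.get("lower", 0.0)),
                upper=float(d.get("upper", 1.0)),
            )
        if "median" in d:
            return beta_from_quantiles(
                median=float(d["median"]),
                q025=float(d["q025"]),
                q975=float(d["q975"]),
                lower=float(d.get("lower", 0.0)),
                upper=float(d.get("upper", 1.0)),
            )
        raise ContractViolationError(
            "spec dict needs either {alpha, beta} or {median, q025, q975}"
        )


@dataclass(frozen=True)
class BiasParams:
    """A (sensitivity, specificity) pair, optionally differential by arm."""

    se_exposed: float
    se_comparator: float
    sp_exposed: float
    sp_comparator: float

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if not (0.0 <= v <= 1.0):
                raise ContractViolationError(f"{name}={v} outside [0, 1]")

    @classmethod
    def nondifferential(cls, se: float, sp: float) -> "BiasParams":
        return cls(se_exposed=se, se_comparator=se, sp_exposed=sp, sp_comparator=sp)

    @property
    def is_nondifferential(self) -> bool:
        return (
            self.se_exposed == self.se_comparator
            and self.sp_exposed == self.sp_comparator
        )

    def for_arm(self, exposed: bool) -> tuple[float, float]:
        if exposed:
            return self.se_exposed, self.sp_exposed
        return self.se_comparator, self.sp_comparator


def beta_from_quantiles(
    median: float,
    q025: float,
    q975: float,
    lower: float = 0.0,
    upper: float = 1.0,
) -> BetaSpec:
    """Find beta shapes whose rescaled quantiles match a (q025, median, q975) triple.

    Minimises the summed squared error of the three quantiles over
    ``(log alpha, log beta)`` and requires the fit to land within
    ``QUANTILE_TOL`` (0.005, half a printed decimal) of every target.

    Raises
    ------
    ElicitationError
        If no beta distribution reproduces the triple within tolerance; the
        exception carries the best-achieved quantiles and shapes.
    """
    if not (lower <= q025 < median < q975 <= upper):
        raise ContractViolationError(
            "need lower <= q025 < median < q975 <= upper, got "
            f"({lower}, {q025}, {median}, {q975}, {upper})"
        )
    span = upper - lower
    targets = (np.array([q025, median, q975]) - lower) / span
    levels = np.array([0.025, 0.5, 0.975])

    def residuals(log_shapes):
        a, b = np.exp(log_shapes)
        return stats.beta.ppf(levels, a, b) - targets

    # moment-matched start: mean ~ median, sd ~ quarter of the 95% span
    m = float(np.clip(targets[1], 1e-3, 1 - 1e-3))
    s = max((targets[2] - targets[0]) / 3.92, 1e-3)
    nu = max(m * (1 - m) / s**2 - 1, 0.2)
    x0 = np.log([max(m * nu, 1e-2), max((1 - m) * nu, 1e-2)])

    sol = optimize.least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
    a, b = np.exp(sol.x)
    spec = BetaSpec(alpha=float(a), beta=float(b), lower=lower, upper=upper)
    achieved = spec.quantile(levels)
    err = np.max(np.abs(achieved - np.array([q025, median, q975])))
    if err > QUANTILE_TOL:
        raise ElicitationError(
            f"no beta on [{lower}, {upper}] matches quantiles "
            f"({q025}, {median}, {q975}); best achieved "
            f"({achieved[0]:.4f}, {achieved[1]:.4f}, {achieved[2]:.4f})",
            achieved=tuple(float(x) for x in achieved),
            shapes=(float(a), float(b)),
        )
    return spec
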