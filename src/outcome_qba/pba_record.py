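"""Record-level probabilistic bias analysis.

Per iteration: draw (Se, Sp); matrix-correct the observed any-event
subpopulation table to obtain corrected prevalences and arm-wise PPV/NPV;
reclassify each patient in the subpopulation by a Bernoulli trial —
observed-positive patients stay positive with probability PPV, observed-
negative patients flip positive with probability 1-NPV; patients without
the any-cause event always remain non-cases; then refit unweighted and
IPT-weighted logistic outcome models on the full cohort and record both
odds ratios.

For hospitalisation outcomes the trial runs per hospital episode (each
observed-positive episode keeps with PPV, each observed-negative episode
flips with 1-NPV) and the patient is a simulated case if any episode
simulates positive.  With episode dates out of scope, "first positive
episode" and "any positive episode" pick out the same patients, so the
per-episode trials are realised through the exact patient-level probability

    P(case) = 1 - (1 - PPV)^(k+) * NPV^(k-)

with k+/k- the patient's observed-positive/negative episode counts.

Propensity scores are fitted once on the cohort and reused across
iterations: outcome reclassification cannot alter treatment assignment.
Because the per-iteration outcome models contain exposure as the only
covariate, their maximum-likelihood odds ratios coincide with the
(weighted) 2x2 crude ORs, which is how iterations are computed; the
equivalence is exercised against statsmodels in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bias_params import BetaSpec, BiasParams
from .contingency import build_subpop_table
from .correction import correct_counts, predictive_values
from .errors import AnalysisFailureError, ContractViolationError
from .pba_summary import PBAOptions, PBAResult, _summarise
from .rng import child_rng
from .weighting import PropensityResult

__all__ = ["RecordPBAResult", "pba_record"]


@dataclass(frozen=True)
class RecordPBAResult:
    """Paired unweighted and IPT-weighted summaries from one iteration stream."""

    unweighted: PBAResult
    weighted: PBAResult
    n_iterations: int

    def to_dict(self) -> dict:
        return {
            "unweighted": self.unweighted.to_dict(),
            "weighted": self.weighted.to_dict(),
            "n_iterations": self.n_iterations,
        }


def _episode_counts(sub: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Observed-positive and observed-negative episode counts per patient."""
    flags = sub["episode_obs_flags"].to_numpy()
    k_pos = np.array([f.count("1") for f in flags], dtype=np.int64)
    k_tot = np.array([len(f) for f in flags], dtype=np.int64)
    return k_pos, k_tot - k_pos


def pba_record(
    cohort: pd.DataFrame,
    ps: PropensityResult,
    se_spec: BetaSpec,
    sp_spec: BetaSpec,
    outcome: str,
    options: PBAOptions,
) -> RecordPBAResult:
    """Run record-level PBA for ``outcome`` in {"hosp", "death"}.

    ``ps`` must be fitted on ``cohort`` (same row order).  Iterations whose
    matrix correction is invalid, or whose simulated outcomes vanish in an
    arm, are discarded and counted.  Deterministic under ``options.seed``.
    """
    if outcome not in ("hosp", "death"):
        raise ContractViolationError(f"outcome must be 'hosp' or 'death', got {outcome!r}")
    if ps is None or len(ps.scores) != len(cohort):
        raise ContractViolationError("propensity result missing or misaligned with cohort")

    subpop = build_subpop_table(cohort, outcome)
    any_col, obs_col = f"any_{outcome}", f"obs_covid_{outcome}"
    in_sub = cohort[any_col].astype(bool).to_numpy()
    sub = cohort[in_sub]
    sub_exposed = (sub["arm"] == "exposed").to_numpy()
    sub_obs = sub[obs_col].astype(bool).to_numpy()
    kept = ps.kept
    sub_kept = kept[in_sub]
    weights = ps.weights

    exposed_all = ps.exposed
    # constant margins: non-event patients are always non-cases
    n_e_total = int(exposed_all.sum())
    n_c_total = int((~exposed_all).sum())
    n_e_kept = int((kept & exposed_all).sum())
    n_c_kept = int((kept & ~exposed_all).sum())
    w_e_total = float(weights[kept & exposed_all].sum())
    w_c_total = float(weights[kept & ~exposed_all].sum())
    sub_w = weights[in_sub]

    use_episodes = outcome == "hosp" and "episode_obs_flags" in cohort.columns
    if use_episodes:
        k_pos, k_neg = _episode_counts(sub)

    rng = child_rng(options.seed, "pba-record")
    n_it = options.n_iterations
    se_draws = se_spec.sample_with(n_it, rng)
    sp_draws = sp_spec.sample_with(n_it, rng)

    log_or_u = np.full(n_it, np.nan)
    log_or_w = np.full(n_it, np.nan)
    discarded = 0

    for it in range(n_it):
        params = BiasParams.nondifferential(float(se_draws[it]), float(sp_draws[it]))
        try:
            corr = correct_counts(subpop, params)
        except Exception:
            discarded += 1
            continue
        if not corr.valid:
            discarded += 1
            continue
        pv = predictive_values(subpop, corr.corrected, params)
        ppv = np.where(sub_exposed, pv.ppv_exposed, pv.ppv_comparator)
        npv = np.where(sub_exposed, pv.npv_exposed, pv.npv_comparator)

        if use_episodes:
            p_case = 1.0 - (1.0 - ppv) ** k_pos * npv**k_neg
        else:
            p_case = np.where(sub_obs, ppv, 1.0 - npv)
        sim = rng.random(len(sub)) < p_case

        a = int((sim & sub_exposed).sum())
        c = int((sim & ~sub_exposed).sum())
        if a == 0 or c == 0 or a >= n_e_total or c >= n_c_total:
            discarded += 1
            continue
        b = n_e_total - a
        d = n_c_total - c
        log_or_u[it] = np.log(a / b) - np.log(c / d)
        conv_se_u = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)

        sim_k = sim & sub_kept
        a_w = float(sub_w[sim_k & sub_exposed].sum())
        c_w = float(sub_w[sim_k & ~sub_exposed].sum())
        b_w = w_e_total - a_w
        d_w = w_c_total - c_w
        if min(a_w, b_w, c_w, d_w) <= 0:
            log_or_u[it] = np.nan
            discarded += 1
            continue
        log_or_w[it] = np.log(a_w / b_w) - np.log(c_w / d_w)
        # conventional SE on the effective (unweighted) kept counts
        a_k = int((sim_k & sub_exposed).sum())
        c_k = int((sim_k & ~sub_exposed).sum())
        if a_k == 0 or c_k == 0:
            log_or_u[it] = np.nan
            log_or_w[it] = np.nan
            discarded += 1
            continue
        conv_se_w = np.sqrt(1 / a_k + 1 / (n_e_kept - a_k) + 1 / c_k + 1 / (n_c_kept - c_k))

        if options.include_conventional_error:
            z = rng.standard_normal(2)
            log_or_u[it] -= z[0] * conv_se_u
            log_or_w[it] -= z[1] * conv_se_w

    ok = np.isfinite(log_or_u) & np.isfinite(log_or_w)
    if not ok.any():
        raise AnalysisFailureError(
            "all record-level iterations discarded", discard_fraction=1.0
        )
    unweighted = _summarise(log_or_u[ok], n_it, discarded, options)
    weighted = _summarise(log_or_w[ok], n_it, discarded, options)
    return RecordPBAResult(unweighted=unweighted, weighted=weighted, n_iterations=n_it)
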