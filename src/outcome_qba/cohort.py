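"""Synthetic active-comparator cohorts with a ground-truth outcome layer.

Emulates the structure the bias analysis assumes: two treatment arms with
confounded assignment, any-cause hospitalisation/death layers, a truly
cause-specific outcome layer nested inside the any-cause events, and an
observation layer produced from the truth by a known sensitivity/specificity
operator (optionally differential by arm, and per hospital episode).

The generator's role is to make every downstream stage testable: because the
true outcomes and the generating parameters are known, corrected estimates
can be checked against the truth they should recover.

Columns of a cohort table
-------------------------
``patient_id``            integer id
``arm``                   ``"exposed"`` or ``"comparator"``
``age``                   years (generated Normal(70, 10))
``gender``, ``smoking``, ``prior_exacerbation``, ``past_asthma``
                          binary covariates (0/1)
``any_hosp``, ``any_death``
                          any-cause event flags (0/1)
``true_covid_hosp``, ``true_covid_death``
                          ground-truth cause-specific flags (synthetic only)
``obs_covid_hosp``, ``obs_covid_death``
                          observed cause-specific flags
``n_episodes``            hospital episodes (0 unless ``any_hosp``)
``episode_true_flags``, ``episode_obs_flags``
                          per-episode 0/1 strings, e.g. ``"010"``
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .bias_params import BiasParams
from .errors import ContractViolationError, UnderpoweredConfigError
from .rng import child_rng

__all__ = [
    "CohortConfig",
    "generate_cohort",
    "apply_misclassification",
    "read_cohort",
    "write_cohort",
    "COVARIATES",
]

#: covariate battery; age is standardised as (age - 70) / 10 in linear predictors
COVARIATES = ("age", "gender", "smoking", "prior_exacerbation", "past_asthma")

#: marginal prevalences of the binary covariates
_BINARY_PREV = {
    "gender": 0.46,
    "smoking": 0.42,
    "prior_exacerbation": 0.37,
    "past_asthma": 0.23,
}

_AGE_MEAN, _AGE_SD = 70.0, 10.0


def _standardise(df: pd.DataFrame) -> pd.DataFrame:
    """Covariates on the scale the log-odds effects apply to.

    Age is z-scored and binaries are centred at their generating
    prevalences, so the ``baseline_*`` probabilities of a config are
    (approximately) the comparator-arm marginal rates rather than the rates
    of a zero-covariate patient.
    """
    x = df[list(COVARIATES)].astype(float).copy()
    x["age"] = (x["age"] - _AGE_MEAN) / _AGE_SD
    for name, prev in _BINARY_PREV.items():
        x[name] = x[name] - prev
    return x


@dataclass
class CohortConfig:
    """Generating parameters for a synthetic two-arm cohort.

    Defaults reproduce the scale of the motivating study: 56 059 exposed vs
    22 319 comparator patients, any-cause death risk ~2.6% at baseline,
    cause-specific deaths ~12.5% of any-cause deaths, any-cause
    hospitalisation ~12% with ~5% of hospitalised patients having the
    cause-specific outcome, and confounding through a small covariate
    battery (history of asthma and prior exacerbations drive treatment
    choice and also predict events).
    """

    n_exposed: int = 56_059
    n_comparator: int = 22_319
    covariate_effects_treatment: dict[str, float] = field(
        default_factory=lambda: {
            "age": 0.05,
            "past_asthma": 1.0,
            "prior_exacerbation": 0.55,
            "smoking": -0.15,
        }
    )
    covariate_effects_event: dict[str, float] = field(
        default_factory=lambda: {
            "age": 0.55,
            "smoking": 0.25,
            "prior_exacerbation": 0.45,
        }
    )
    baseline_any_hosp_prob: float = 0.115
    baseline_any_death_prob: float = 0.025
    true_or_hosp: float = 1.35
    true_or_death: float = 1.22
    frac_cause_specific_hosp: float = 0.05
    frac_cause_specific_death: float = 0.125
    #: odds ratio of the exposed arm on the any-cause event layers
    any_event_or_exposed: float = 1.15
    #: mean hospital episodes per hospitalised patient (>= 1)
    episode_rate: float = 1.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_exposed <= 0 or self.n_comparator <= 0:
            raise ContractViolationError("arm sizes must be positive")
        for name in (
            "baseline_any_hosp_prob",
            "baseline_any_death_prob",
            "frac_cause_specific_hosp",
            "frac_cause_specific_death",
        ):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ContractViolationError(f"{name}={v} must lie in (0, 1)")
        for name in ("true_or_hosp", "true_or_death", "any_event_or_exposed"):
            if getattr(self, name) <= 0:
                raise ContractViolationError(f"{name} must be > 0")
        if self.episode_rate < 1.0:
            raise ContractViolationError("episode_rate must be >= 1")
        unknown = (
            set(self.covariate_effects_treatment) | set(self.covariate_effects_event)
        ) - set(COVARIATES)
        if unknown:
            raise ContractViolationError(f"unknown covariates: {sorted(unknown)}")
        self._check_power()

    def _check_power(self) -> None:
        # crude expectation ignoring covariate spread; rejects hopeless configs
        for outcome, base, frac, or_true in (
            ("hosp", self.baseline_any_hosp_prob, self.frac_cause_specific_hosp, self.true_or_hosp),
            ("death", self.baseline_any_death_prob, self.frac_cause_specific_death, self.true_or_death),
        ):
            odds = frac / (1 - frac) * or_true
            frac_exp = odds / (1 + odds)
            exp_comp = self.n_comparator * base * frac
            exp_expo = self.n_exposed * base * self.any_event_or_exposed * frac_exp
            if min(exp_comp, exp_expo) < 1.0:
                raise UnderpoweredConfigError(
                    f"expected true {outcome} cases per arm "
                    f"({exp_expo:.2f} exposed, {exp_comp:.2f} comparator) below 1"
                )

    def to_dict(self) -> dict:
        return asdict(self)


def _solve_intercept(lin: np.ndarray, target_total: float) -> float:
    """Intercept c such that sum(expit(c + lin)) = target_total (monotone bisection)."""
    lo, hi = -20.0, 20.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if _expit(mid + lin).sum() < target_total:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate a patient-level cohort table under ``config``.

    Treatment is assigned by a logistic model on the covariates (with the
    intercept solved so the expected exposed count equals ``n_exposed``);
    any-cause events follow logistic models on covariates plus arm; true
    cause-specific outcomes are drawn only among patients with the
    corresponding any-cause event, with exposure log-odds
    ``ln(true_or_*)``; the observed layer starts equal to the truth
    (apply :func:`apply_misclassification` to degrade it).
    Deterministic under ``config.seed``.
    """
    config.validate()
    n = config.n_exposed + config.n_comparator
    rng = child_rng(config.seed, "generate-cohort")

    df = pd.DataFrame({"patient_id": np.arange(n, dtype=np.int64)})
    df["age"] = rng.normal(_AGE_MEAN, _AGE_SD, size=n)
    for name, prev in _BINARY_PREV.items():
        df[name] = (rng.random(n) < prev).astype(np.int8)

    x = _standardise(df)

    lin_t = np.zeros(n)
    for name, beta in config.covariate_effects_treatment.items():
        lin_t += beta * x[name].to_numpy()
    c_t = _solve_intercept(lin_t, config.n_exposed)
    exposed = rng.random(n) < _expit(c_t + lin_t)
    df["arm"] = np.where(exposed, "exposed", "comparator")

    lin_e = np.zeros(n)
    for name, beta in config.covariate_effects_event.items():
        lin_e += beta * x[name].to_numpy()
    arm_term = np.log(config.any_event_or_exposed) * exposed

    for flag, base in (
        ("any_hosp", config.baseline_any_hosp_prob),
        ("any_death", config.baseline_any_death_prob),
    ):
        p = _expit(np.log(base / (1 - base)) + lin_e + arm_term)
        df[flag] = (rng.random(n) < p).astype(np.int8)

    for flag, any_flag, frac, or_true in (
        ("true_covid_hosp", "any_hosp", config.frac_cause_specific_hosp, config.true_or_hosp),
        ("true_covid_death", "any_death", config.frac_cause_specific_death, config.true_or_death),
    ):
        has_event = df[any_flag].to_numpy().astype(bool)
        p = _expit(np.log(frac / (1 - frac)) + np.log(or_true) * exposed)
        df[flag] = (has_event & (rng.random(n) < p)).astype(np.int8)

    # hospital episodes: 1 + Poisson(rate - 1) per hospitalised patient; a true
    # case carries its true cause on exactly one uniformly chosen episode
    hosp = df["any_hosp"].to_numpy().astype(bool)
    n_ep = np.zeros(n, dtype=np.int64)
    n_ep[hosp] = 1 + rng.poisson(config.episode_rate - 1.0, size=int(hosp.sum()))
    df["n_episodes"] = n_ep
    true_idx = np.full(n, -1, dtype=np.int64)
    is_case = df["true_covid_hosp"].to_numpy().astype(bool)
    true_idx[is_case] = np.floor(rng.random(int(is_case.sum())) * n_ep[is_case]).astype(np.int64)

    flags = []
    for k, t in zip(n_ep, true_idx):
        if k == 0:
            flags.append("")
        else:
            s = ["0"] * int(k)
            if t >= 0:
                s[int(t)] = "1"
            flags.append("".join(s))
    df["episode_true_flags"] = flags

    # observation layer starts perfect; degrade with apply_misclassification
    df["obs_covid_hosp"] = df["true_covid_hosp"]
    df["obs_covid_death"] = df["true_covid_death"]
    df["episode_obs_flags"] = df["episode_true_flags"]
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    """Serialise a cohort table as UTF-8 CSV with a header row."""
    cohort.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort CSV, keeping episode-flag columns as strings."""
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    for col in ("episode_true_flags", "episode_obs_flags"):
        if col in df.columns:
            df[col] = df[col].astype(str).replace("nan", "")
    return df


def _require_columns(cohort: pd.DataFrame, cols: tuple[str, ...]) -> None:
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise ContractViolationError(f"cohort lacks required columns: {missing}")


def apply_misclassification(
    cohort: pd.DataFrame,
    params: BiasParams,
    outcome: str,
    seed: int,
) -> pd.DataFrame:
    """Degrade the true outcome layer into an observed layer with known Se/Sp.

    Only patients with the corresponding any-cause event can be observed
    positive: a true positive is kept with probability ``Se`` and a true
    negative becomes a false positive with probability ``1 - Sp``.  For
    ``outcome="hosp"`` the operator acts per hospital episode (the truly
    causal episode flips false-negative with ``1 - Se``; every other episode
    flips false-positive with ``1 - Sp``) and the patient-level observed
    flag is the OR over episodes.  Arm labels, covariates, any-cause flags
    and the true layer are never altered.
    """
    if outcome not in ("hosp", "death"):
        raise ContractViolationError(f"outcome must be 'hosp' or 'death', got {outcome!r}")
    _require_columns(cohort, ("arm", f"any_{outcome}", f"true_covid_{outcome}"))

    out = cohort.copy()
    rng = child_rng(seed, f"misclassify-{outcome}")
    exposed = (out["arm"] == "exposed").to_numpy()
    se = np.where(exposed, params.se_exposed, params.se_comparator)
    sp = np.where(exposed, params.sp_exposed, params.sp_comparator)

    if outcome == "death":
        has_event = out["any_death"].to_numpy().astype(bool)
        true = out["true_covid_death"].to_numpy().astype(bool)
        u = rng.random(len(out))
        obs = has_event & np.where(true, u < se, u < 1.0 - sp)
        out["obs_covid_death"] = obs.astype(np.int8)
        return out

    _require_columns(cohort, ("n_episodes", "episode_true_flags"))
    n_ep = out["n_episodes"].to_numpy()
    true_flags = out["episode_true_flags"].to_numpy()
    obs_flags = []
    obs_patient = np.zeros(len(out), dtype=np.int8)
    for i, (k, tf) in enumerate(zip(n_ep, true_flags)):
        if k == 0:
            obs_flags.append("")
            continue
        u = rng.random(int(k))
        bits = []
        for j, ch in enumerate(tf):
            if ch == "1":
                bits.append("1" if u[j] < se[i] else "0")
            else:
                bits.append("1" if u[j] < 1.0 - sp[i] else "0")
        s = "".join(bits)
        obs_flags.append(s)
        obs_patient[i] = 1 if "1" in s else 0
    out["episode_obs_flags"] = obs_flags
    out["obs_covid_hosp"] = obs_patient
    return out
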