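"""Pipeline orchestration: config -> cohort -> analyses -> result bundle.

A :class:`RunConfig` (built directly or loaded from YAML/JSON) names the
cohort source, the outcomes, the bias-parameter specs and the analyses to
run.  :func:`run_pipeline` executes the requested stages in order —
conventional crude and IPTW estimates, simple bias analysis, summary-level
PBA, record-level PBA, sensitivity grids — and returns one JSON-ready
bundle with every seed, iteration count and discard fraction recorded.
The root seed fans out to per-stage child streams (see :mod:`.rng`), so a
rerun with the same config reproduces the bundle byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .bias_params import BetaSpec, BiasParams
from .cohort import COVARIATES, CohortConfig, apply_misclassification, generate_cohort, read_cohort
from .contingency import build_subpop_table, crude_or, reinsert_nonevents
from .correction import simple_bias_analysis
from .errors import ContractViolationError, QBAError
from .grids import grid_nondifferential
from .pba_record import pba_record
from .pba_summary import PBAOptions, pba_summary
from .rng import child_seed
from .weighting import fit_propensity, smd_table, trim_common_support, weighted_logistic_or

__all__ = ["RunConfig", "run_pipeline", "forest_table", "load_config"]

logger = logging.getLogger("outcome_qba")

SCHEMA_VERSION = 1

#: fixed bias-parameter point values for SBA, per outcome
DEFAULT_SBA_PARAMS = {
    "hosp": {"se": 0.905, "sp": 0.960},
    "death": {"se": 0.722, "sp": 0.966},
}

#: default Se/Sp priors per outcome (rescaled beta distributions)
DEFAULT_BIAS_SPECS = {
    "hosp": {
        "se": {"alpha": 47.7, "beta": 5.5},
        "sp": {"alpha": 1.0, "beta": 1.0, "lower": 0.97, "upper": 1.0},
    },
    "death": {
        "se": {"alpha": 39.6, "beta": 15.4},
        "sp": {"alpha": 91.2, "beta": 3.9},
    },
}

_STAGES = ("conventional", "sba", "pba_summary", "pba_record", "grids")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    cohort_path: str | None = None
    synthetic: dict | None = None
    #: true (Se, Sp) used to degrade synthetic truth into the observed layer,
    #: keyed by outcome; omitted outcomes keep a perfectly observed layer
    misclassification: dict = field(default_factory=dict)
    outcomes: tuple[str, ...] = ("hosp", "death")
    analyses: tuple[str, ...] = ("conventional", "sba", "pba_summary")
    covariates: tuple[str, ...] = tuple(COVARIATES)
    #: optional boolean column; truthy rows are dropped before analysis
    exclude_column: str | None = None
    bias_specs: dict = field(default_factory=dict)
    sba_params: dict = field(default_factory=dict)
    n_iterations_summary: int = 100_000
    n_iterations_record: int = 10_000
    grid_se_values: tuple[float, ...] = (0.7, 0.8, 0.9, 1.0)
    grid_sp_values: tuple[float, ...] = (0.96, 0.97, 0.98, 0.99, 1.0)
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        if (self.cohort_path is None) == (self.synthetic is None):
            raise ContractViolationError("exactly one of cohort_path/synthetic must be set")
        if self.cohort_path is not None and not Path(self.cohort_path).exists():
            raise ContractViolationError(f"cohort file not found: {self.cohort_path}")
        unknown = set(self.analyses) - set(_STAGES)
        if unknown:
            raise ContractViolationError(f"unknown analyses: {sorted(unknown)}")
        for oc in self.outcomes:
            if oc not in ("hosp", "death"):
                raise ContractViolationError(f"unknown outcome {oc!r}")
        needs_pba = {"pba_summary", "pba_record", "grids"} & set(self.analyses)
        if needs_pba:
            for oc in self.outcomes:
                self.spec_for(oc, "se")  # raises if malformed
                self.spec_for(oc, "sp")
        if "pba_record" in self.analyses and not self.covariates:
            raise ContractViolationError(
                "record-level PBA needs propensity inputs: provide covariates"
            )

    def spec_for(self, outcome: str, which: str) -> BetaSpec:
        d = self.bias_specs.get(outcome, {}).get(which) or DEFAULT_BIAS_SPECS[outcome][which]
        return BetaSpec.from_dict(d)

    def sba_for(self, outcome: str) -> BiasParams:
        d = self.sba_params.get(outcome) or DEFAULT_SBA_PARAMS[outcome]
        return BiasParams.nondifferential(d["se"], d["sp"])

    def to_dict(self) -> dict:
        return {
            "cohort_path": self.cohort_path,
            "synthetic": self.synthetic,
            "misclassification": self.misclassification,
            "outcomes": list(self.outcomes),
            "analyses": list(self.analyses),
            "covariates": list(self.covariates),
            "exclude_column": self.exclude_column,
            "bias_specs": self.bias_specs,
            "sba_params": self.sba_params,
            "n_iterations_summary": self.n_iterations_summary,
            "n_iterations_record": self.n_iterations_record,
            "grid_se_values": list(self.grid_se_values),
            "grid_sp_values": list(self.grid_sp_values),
            "seed": self.seed,
        }


def load_config(path) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    kw = dict(raw)
    for key in ("outcomes", "analyses", "covariates", "grid_se_values", "grid_sp_values"):
        if key in kw and kw[key] is not None:
            kw[key] = tuple(kw[key])
    return RunConfig(**kw)


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stage_seed(config: RunConfig, label: str) -> int:
    # keep derived seeds in int32 range for portability of serialised configs
    return int(child_seed(config.seed, label).generate_state(1)[0] % (2**31))


def _load_cohort(config: RunConfig) -> pd.DataFrame:
    if config.cohort_path is not None:
        return read_cohort(config.cohort_path)
    cc = CohortConfig(**{**(config.synthetic or {}), "seed": _stage_seed(config, "cohort")})
    cohort = generate_cohort(cc)
    for oc, d in config.misclassification.items():
        params = BiasParams.nondifferential(d["se"], d["sp"]) if "se" in d else BiasParams(**d)
        cohort = apply_misclassification(
            cohort, params, oc, seed=_stage_seed(config, f"misclassify-{oc}")
        )
    return cohort


def run_pipeline(config: RunConfig) -> dict:
    """Execute every requested analysis; return one JSON-ready bundle.

    Stage errors propagate as :class:`QBAError` annotated with the stage
    name; results computed before the failure are preserved on the
    exception's ``partial`` attribute.
    """
    config.validate()
    cohort = _load_cohort(config)
    if config.exclude_column:
        if config.exclude_column not in cohort.columns:
            raise ContractViolationError(
                f"exclude_column {config.exclude_column!r} absent from cohort"
            )
        cohort = cohort[~cohort[config.exclude_column].astype(bool)].reset_index(drop=True)

    n_e = int((cohort["arm"] == "exposed").sum())
    n_c = int((cohort["arm"] == "comparator").sum())
    bundle: dict = {
        "schema_version": SCHEMA_VERSION,
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_exposed": n_e,
        "n_comparator": n_c,
        "outcomes": {oc: {} for oc in config.outcomes},
    }

    ps = None
    needs_ps = {"conventional", "pba_record"} & set(config.analyses)
    if needs_ps and config.covariates:
        ps = trim_common_support(fit_propensity(cohort, list(config.covariates)))
        bundle["balance"] = [
            {"covariate": r.covariate, "smd_before": r.smd_before, "smd_after": r.smd_after}
            for r in smd_table(cohort, ps, list(config.covariates))
        ]

    for oc in config.outcomes:
        res = bundle["outcomes"][oc]
        try:
            subpop = build_subpop_table(cohort, oc)
            res["subpop_table"] = subpop.to_dict()
            full = reinsert_nonevents(subpop, n_e, n_c)

            if "conventional" in config.analyses:
                res["conventional_crude"] = crude_or(full).to_dict()
                if ps is not None:
                    res["conventional_iptw"] = weighted_logistic_or(
                        cohort, ps, f"obs_covid_{oc}"
                    ).to_dict()
            if "sba" in config.analyses:
                res["sba"] = simple_bias_analysis(
                    subpop, config.sba_for(oc), totals=(n_e, n_c)
                ).to_dict()
            if "pba_summary" in config.analyses:
                opts = PBAOptions(
                    n_iterations=config.n_iterations_summary,
                    seed=_stage_seed(config, f"pba-summary-{oc}"),
                )
                res["pba_summary"] = pba_summary(
                    subpop, (n_e, n_c), config.spec_for(oc, "se"), config.spec_for(oc, "sp"), opts
                ).to_dict()
            if "pba_record" in config.analyses:
                if ps is None:
                    raise ContractViolationError(
                        "record-level PBA needs a fitted propensity model: "
                        "provide covariates"
                    )
                opts = PBAOptions(
                    n_iterations=config.n_iterations_record,
                    seed=_stage_seed(config, f"pba-record-{oc}"),
                )
                res["pba_record"] = pba_record(
                    cohort, ps, config.spec_for(oc, "se"), config.spec_for(oc, "sp"), oc, opts
                ).to_dict()
            if "grids" in config.analyses:
                grid = grid_nondifferential(
                    subpop, (n_e, n_c), list(config.grid_se_values), list(config.grid_sp_values)
                )
                res["grid_nondifferential"] = grid.table.to_dict(orient="records")
        except QBAError as exc:
            exc.stage = oc
            exc.partial = bundle
            logger.error("stage %s failed: %s", oc, exc)
            raise

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "results.json").write_text(json.dumps(bundle, indent=2, sort_keys=True))
        forest_table(bundle).to_csv(out / "forest.csv", index=False)
        if "balance" in bundle:
            pd.DataFrame(bundle["balance"]).to_csv(out / "balance.csv", index=False)
    return bundle


def forest_table(bundle: dict) -> pd.DataFrame:
    """Long-format estimate table for forest plotting.

    One row per (outcome, analysis): OR, lower, upper and the interval type
    — ``CI`` for conventional estimates, ``SI`` for PBA, ``none`` for SBA,
    which yields a point estimate only.  Values are read from the bundle,
    never recomputed.
    """
    rows = []
    for oc, res in bundle.get("outcomes", {}).items():
        if "conventional_crude" in res:
            e = res["conventional_crude"]
            rows.append((oc, "conventional_crude", e["or"], e["ci_low"], e["ci_high"], "CI"))
        if "conventional_iptw" in res:
            e = res["conventional_iptw"]
            rows.append((oc, "conventional_iptw", e["or"], e["ci_low"], e["ci_high"], "CI"))
        if "sba" in res:
            rows.append((oc, "sba", res["sba"]["or"], None, None, "none"))
        if "pba_summary" in res:
            e = res["pba_summary"]
            rows.append((oc, "pba_summary", e["median_or"], e["si_low"], e["si_high"], "SI"))
        if "pba_record" in res:
            for lab in ("unweighted", "weighted"):
                e = res["pba_record"][lab]
                rows.append(
                    (oc, f"pba_record_{lab}", e["median_or"], e["si_low"], e["si_high"], "SI")
                )
    if not rows:
        raise ContractViolationError("bundle contains no estimates")
    return pd.DataFrame(
        rows, columns=["outcome", "analysis", "or", "lower", "upper", "interval"]
    )
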