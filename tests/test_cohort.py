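"""Synthetic cohort generation and the misclassification operator."""

import numpy as np
import pandas as pd
import pytest

import outcome_qba as q
from outcome_qba.cohort import COVARIATES, read_cohort, write_cohort
from outcome_qba.errors import ContractViolationError, UnderpoweredConfigError


class TestGenerate:
    def test_row_count_and_schema(self):
        cfg = q.CohortConfig(n_exposed=3000, n_comparator=2000, seed=1)
        co = q.generate_cohort(cfg)
        assert len(co) == 5000
        for col in (
            "patient_id", "arm", "any_hosp", "any_death",
            "true_covid_hosp", "true_covid_death",
            "obs_covid_hosp", "obs_covid_death",
            "n_episodes", "episode_true_flags", "episode_obs_flags",
        ):
            assert col in co.columns
        assert set(co["arm"].unique()) <= {"exposed", "comparator"}

    def test_deterministic_under_seed_byte_for_byte(self, tmp_path):
        cfg = q.CohortConfig(n_exposed=2000, n_comparator=1000, seed=5)
        a, b = q.generate_cohort(cfg), q.generate_cohort(cfg)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_cohort(a, pa)
        write_cohort(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_csv_round_trip(self, tmp_path):
        co = q.generate_cohort(q.CohortConfig(n_exposed=500, n_comparator=400, seed=9))
        path = tmp_path / "c.csv"
        write_cohort(co, path)
        back = read_cohort(path)
        assert list(back.columns) == list(co.columns)
        assert (back["episode_obs_flags"] == co["episode_obs_flags"]).all()

    def test_no_confounding_balances_covariates(self):
        cfg = q.CohortConfig(
            n_exposed=20_000, n_comparator=20_000,
            covariate_effects_treatment={}, seed=3,
        )
        co = q.generate_cohort(cfg)
        e = co["arm"] == "exposed"
        for cov in COVARIATES:
            x = co[cov].astype(float)
            pooled_sd = x.std()
            diff = abs(x[e].mean() - x[~e].mean()) / pooled_sd
            assert diff < 0.03, f"{cov} imbalanced without confounding: {diff:.3f}"

    def test_null_exposure_effect_gives_null_true_or(self):
        cfg = q.CohortConfig(
            n_exposed=50_000, n_comparator=50_000,
            covariate_effects_treatment={},  # no confounding either
            true_or_death=1.0, any_event_or_exposed=1.0, seed=4,
        )
        co = q.generate_cohort(cfg)
        e = co["arm"] == "exposed"
        ne, nc = int(e.sum()), int((~e).sum())
        a = int(co.loc[e, "true_covid_death"].sum())
        c = int(co.loc[~e, "true_covid_death"].sum())
        est = q.crude_or(q.TwoByTwo(a, ne - a, c, nc - c))
        assert est.ci_low < 1.0 < est.ci_high

    def test_study_scale_expected_case_counts(self):
        """At the motivating study's scale, true case counts land near 529/133."""
        co = q.generate_cohort(q.CohortConfig(seed=0))
        e = co["arm"] == "exposed"
        a = int(co.loc[e, "true_covid_hosp"].sum())
        c = int(co.loc[~e, "true_covid_hosp"].sum())
        assert a == pytest.approx(529, rel=0.15)
        assert c == pytest.approx(133, rel=0.20)

    def test_episode_structure(self):
        co = q.generate_cohort(q.CohortConfig(n_exposed=3000, n_comparator=2000, seed=8))
        hosp = co["any_hosp"].astype(bool)
        assert (co.loc[hosp, "n_episodes"] >= 1).all()
        assert (co.loc[~hosp, "n_episodes"] == 0).all()
        lens = co["episode_true_flags"].str.len()
        assert (lens == co["n_episodes"]).all()
        # a true case carries its cause on exactly one episode
        cases = co["true_covid_hosp"].astype(bool)
        assert (co.loc[cases, "episode_true_flags"].str.count("1") == 1).all()
        assert (co.loc[hosp & ~cases, "episode_true_flags"].str.count("1") == 0).all()

    def test_cause_specific_implies_any_cause(self):
        co = q.generate_cohort(q.CohortConfig(n_exposed=3000, n_comparator=2000, seed=2))
        assert not ((co["true_covid_hosp"] == 1) & (co["any_hosp"] == 0)).any()
        assert not ((co["true_covid_death"] == 1) & (co["any_death"] == 0)).any()

    def test_underpowered_config_rejected(self):
        with pytest.raises(UnderpoweredConfigError):
            q.generate_cohort(
                q.CohortConfig(n_exposed=100, n_comparator=100, seed=0)
            )

    def test_invalid_probability_rejected(self):
        with pytest.raises(ContractViolationError):
            q.CohortConfig(baseline_any_hosp_prob=1.5).validate()


class TestMisclassification:
    def _cohort(self, seed=21):
        return q.generate_cohort(
            q.CohortConfig(n_exposed=30_000, n_comparator=30_000, seed=seed)
        )

    def test_perfect_parameters_are_identity(self):
        co = self._cohort()
        out = q.apply_misclassification(
            co, q.BiasParams.nondifferential(1.0, 1.0), "death", seed=1
        )
        assert (out["obs_covid_death"] == co["true_covid_death"]).all()
        out = q.apply_misclassification(
            co, q.BiasParams.nondifferential(1.0, 1.0), "hosp", seed=1
        )
        assert (out["obs_covid_hosp"] == co["true_covid_hosp"]).all()
        assert (out["episode_obs_flags"] == co["episode_true_flags"]).all()

    def test_death_operator_hits_target_se_sp(self):
        """Among the deceased, empirical P(obs+|true+) ~ Se and P(obs-|true-) ~ Sp."""
        cfg = q.CohortConfig(
            n_exposed=100_000, n_comparator=100_000,
            baseline_any_death_prob=0.9,  # nearly everyone dies: large subpopulation
            frac_cause_specific_death=0.3, seed=6,
        )
        co = q.generate_cohort(cfg)
        out = q.apply_misclassification(
            co, q.BiasParams.nondifferential(0.722, 0.966), "death", seed=2
        )
        dead = out["any_death"].astype(bool)
        true = out["true_covid_death"].astype(bool)
        obs = out["obs_covid_death"].astype(bool)
        se_hat = obs[dead & true].mean()
        sp_hat = (~obs)[dead & ~true].mean()
        assert se_hat == pytest.approx(0.722, abs=0.01)
        assert sp_hat == pytest.approx(0.966, abs=0.005)

    def test_differential_sensitivity_by_arm(self):
        cfg = q.CohortConfig(
            n_exposed=80_000, n_comparator=80_000,
            baseline_any_death_prob=0.5, frac_cause_specific_death=0.3, seed=7,
        )
        co = q.generate_cohort(cfg)
        params = q.BiasParams(
            se_exposed=0.9, se_comparator=0.6, sp_exposed=0.97, sp_comparator=0.97
        )
        out = q.apply_misclassification(co, params, "death", seed=3)
        dead_true = out["any_death"].astype(bool) & out["true_covid_death"].astype(bool)
        for arm, target in (("exposed", 0.9), ("comparator", 0.6)):
            m = dead_true & (out["arm"] == arm)
            assert out.loc[m, "obs_covid_death"].mean() == pytest.approx(target, abs=0.015)

    def test_hosp_operator_acts_per_episode(self):
        co = self._cohort(seed=30)
        out = q.apply_misclassification(
            co, q.BiasParams.nondifferential(0.8, 0.95), "hosp", seed=4
        )
        # patient flag is the OR over episode flags
        derived = out["episode_obs_flags"].str.contains("1").fillna(False)
        assert (out["obs_covid_hosp"].astype(bool) == derived).all()
        # flags only among hospitalised patients
        assert not (out.loc[out["any_hosp"] == 0, "obs_covid_hosp"].astype(bool)).any()

    def test_conservation_of_non_outcome_columns(self):
        co = self._cohort(seed=31)
        out = q.apply_misclassification(
            co, q.BiasParams.nondifferential(0.7, 0.96), "hosp", seed=5
        )
        for col in ("arm", "any_hosp", "any_death", "true_covid_hosp", "true_covid_death"):
            assert (out[col] == co[col]).all()

    def test_attenuation_toward_null(self):
        """Non-differential misclassification biases the crude OR toward 1."""
        cfg = q.CohortConfig(
            n_exposed=150_000, n_comparator=150_000,
            covariate_effects_treatment={},
            true_or_death=2.5, baseline_any_death_prob=0.15,
            frac_cause_specific_death=0.2, seed=9,
        )
        co = q.generate_cohort(cfg)
        out = q.apply_misclassification(
            co, q.BiasParams.nondifferential(0.75, 0.97), "death", seed=6
        )
        e = out["arm"] == "exposed"
        ne, nc = int(e.sum()), int((~e).sum())

        def crude(col):
            a = int(out.loc[e, col].sum())
            c = int(out.loc[~e, col].sum())
            return q.crude_or(q.TwoByTwo(a, ne - a, c, nc - c)).or_value

        assert crude("obs_covid_death") < crude("true_covid_death")

    def test_missing_true_flags_rejected(self):
        co = self._cohort(seed=32).drop(columns=["true_covid_death"])
        with pytest.raises(ContractViolationError):
            q.apply_misclassification(
                co, q.BiasParams.nondifferential(0.9, 0.97), "death", seed=1
            )
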