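"""Patient creation: sampling distributions, modifiers, determinism, fixture."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gamma
from scipy.stats import chisquare

from bloodsim import ModelConfig, create_patient, estimated_blood_volume
from bloodsim._rng import stream
from bloodsim.population import (
    FixtureParams,
    PopulationTable,
    TABLE_COLUMNS,
    generate_fixture_population,
    sample_age_within_band,
    sample_baseline_hb,
    sample_blood_loss,
    sample_procedure_cell,
    sample_weight,
)


def _tiny_table(freqs, procedures=None):
    n = len(freqs)
    procedures = procedures or ["hip"] * n
    return PopulationTable(
        pd.DataFrame(
            {
                "row_id": [f"r{i}" for i in range(n)],
                "procedure": procedures,
                "sex": ["female"] * n,
                "age_lo": [65] * n,
                "age_hi": [74] * n,
                "frequency": freqs,
                "revision_probability": [0.1] * n,
                "asa_ge3_probability": [0.4] * n,
                "base_los": [13.0] * n,
                "weight_mean": [75.0] * n,
                "weight_sd": [12.0] * n,
            },
            columns=TABLE_COLUMNS,
        )
    )


class TestCellSampling:
    def test_degenerate_mass_always_selected(self):
        table = _tiny_table([1.0])
        rng = stream(0, 0)
        for _ in range(20):
            row, band, sex = sample_procedure_cell(table, rng)
            assert row["row_id"] == "r0" and band == (65, 74) and sex == "female"

    def test_empirical_frequencies_match_half_half(self):
        table = _tiny_table([0.5, 0.5])
        rng = stream(1, 0)
        hits = sum(sample_procedure_cell(table, rng)[0]["row_id"] == "r0" for _ in range(100_000))
        assert hits / 100_000 == pytest.approx(0.5, abs=0.01)

    def test_seeded_draws_reproduce(self):
        table = _tiny_table([0.7, 0.3])
        seq1 = [sample_procedure_cell(table, stream(9, i))[0]["row_id"] for i in range(50)]
        seq2 = [sample_procedure_cell(table, stream(9, i))[0]["row_id"] for i in range(50)]
        assert seq1 == seq2

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            PopulationTable(pd.DataFrame(columns=TABLE_COLUMNS))

    def test_fixture_sampling_matches_frequencies_chisquare(self, fixture_table):
        """Goodness of fit of sampled cells against table masses at n=1e5."""
        rng = stream(5, 0)
        n = 100_000
        idx = [fixture_table.sample_index(rng) for _ in range(n)]
        counts = np.bincount(idx, minlength=len(fixture_table.df))
        expected = fixture_table.df["frequency"].to_numpy() * n
        keep = expected >= 5
        stat, p = chisquare(counts[keep], expected[keep] * counts[keep].sum() / expected[keep].sum())
        assert p > 0.001


class TestAgeAndWeight:
    def test_single_point_band(self):
        assert sample_age_within_band((70, 70), stream(0, 0)) == 70

    def test_uniform_within_band(self):
        rng = stream(2, 0)
        ages = np.array([sample_age_within_band((65, 74), rng) for _ in range(100_000)])
        freqs = np.bincount(ages, minlength=75)[65:75] / 100_000
        assert np.all(np.abs(freqs - 0.1) < 0.01)

    def test_inverted_band_rejected(self):
        with pytest.raises(ValueError, match="inverted"):
            sample_age_within_band((74, 65), stream(0, 0))

    def test_degenerate_weight(self):
        row = pd.Series({"weight_mean": 80.0, "weight_sd": 0.0})
        assert sample_weight(row, stream(0, 0)) == 80.0

    def test_weight_mean_recovered(self):
        row = pd.Series({"weight_mean": 75.0, "weight_sd": 12.0})
        rng = stream(3, 0)
        draws = np.array([sample_weight(row, rng) for _ in range(100_000)])
        assert draws.mean() == pytest.approx(75.0, abs=0.2)

    def test_weight_floor(self):
        row = pd.Series({"weight_mean": 36.0, "weight_sd": 30.0})
        rng = stream(4, 0)
        draws = [sample_weight(row, rng) for _ in range(2_000)]
        assert min(draws) >= 35.0


class TestBloodVolume:
    @pytest.mark.parametrize("weight, per_kg, expected", [(70, 65, 4550), (100, 65, 6500), (80, 70, 5600)])
    def test_examples(self, weight, per_kg, expected):
        assert estimated_blood_volume(weight, per_kg) == expected

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            estimated_blood_volume(0, 65)

    @given(w=st.floats(1, 300), c=st.floats(0.5, 3))
    @settings(max_examples=50, deadline=None)
    def test_linear_homogeneous_in_weight(self, w, c):
        assert estimated_blood_volume(c * w, 65) == pytest.approx(c * estimated_blood_volume(w, 65))


class TestBaselineHb:
    def test_weibull_mean_matches_closed_form(self):
        k, lam = 9.5, 14.3
        draws = sample_baseline_hb("female", (k, lam, 0.0), stream(6, 0), size=100_000)
        theory = lam * gamma(1 + 1 / k)
        assert draws.mean() == pytest.approx(theory, rel=0.01)

    def test_high_shape_concentrates_at_scale(self):
        draws = sample_baseline_hb("male", (200.0, 13.0, 0.0), stream(7, 0), size=20_000)
        assert draws.mean() == pytest.approx(13.0, abs=0.2)

    def test_seed_determinism(self):
        a = sample_baseline_hb("female", (9.5, 14.3, 0.0), stream(8, 0))
        b = sample_baseline_hb("female", (9.5, 14.3, 0.0), stream(8, 0))
        assert a == b

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            sample_baseline_hb("female", (-1.0, 14.3, 0.0), stream(0, 0))


class TestBloodLoss:
    def _clin(self, **over):
        cfg = ModelConfig()
        return cfg.clinical.model_copy(update={"blood_loss_sd": 0.0, **over})

    @pytest.mark.parametrize(
        "procedure, asa, old, rev, expected",
        [
            ("hip", False, False, False, 3.3),
            ("knee", False, False, True, 3.5 * 1.25),
            ("hip", True, True, True, 3.3 * 1.05 * 1.05 * 1.25),
            ("knee", False, False, False, 3.5),
        ],
    )
    def test_deterministic_modifier_composition(self, procedure, asa, old, rev, expected):
        loss = sample_blood_loss(procedure, asa, old, rev, self._clin(), stream(0, 0))
        assert loss == pytest.approx(expected)

    @pytest.mark.parametrize("flag", ["asa", "old", "rev"])
    def test_removing_any_flag_never_increases_loss(self, flag):
        clin = self._clin()
        full = dict(asa_ge3=True, old_age=True, revision=True)
        reduced = dict(full)
        key = {"asa": "asa_ge3", "old": "old_age", "rev": "revision"}[flag]
        reduced[key] = False
        assert sample_blood_loss("hip", clinical=clin, rng=stream(0, 0), **reduced) <= sample_blood_loss(
            "hip", clinical=clin, rng=stream(0, 0), **full
        )

    def test_zero_correlation_removes_flag_dependence(self):
        clin = self._clin(asa_loss_factor=1.0, age_loss_factor=1.0, revision_loss_factor=1.0)
        base = sample_blood_loss("hip", False, False, False, clin, stream(0, 0))
        loaded = sample_blood_loss("hip", True, True, True, clin, stream(0, 0))
        assert base == loaded

    def test_truncation_at_zero(self):
        cfg = ModelConfig()
        clin = cfg.clinical.model_copy(update={"blood_loss_mean_hip": 0.1, "blood_loss_sd": 2.0})
        rng = stream(11, 0)
        draws = [sample_blood_loss("hip", False, False, False, clin, rng) for _ in range(5_000)]
        assert min(draws) >= 0.0


class TestCreatePatient:
    def test_reproducible_given_seed_and_id(self, fixture_table, base_config):
        a = create_patient(17, fixture_table, base_config)
        b = create_patient(17, fixture_table, base_config)
        assert a == b

    def test_distinct_ids_differ(self, fixture_table, base_config):
        assert create_patient(0, fixture_table, base_config) != create_patient(1, fixture_table, base_config)

    def test_degenerate_config_fully_predictable(self):
        table = _tiny_table([1.0])
        table.df.loc[0, ["weight_sd", "revision_probability", "asa_ge3_probability"]] = [0.0, 0.0, 1.0]
        table = PopulationTable(table.df)
        cfg = ModelConfig(
            hb_weibull_female=(200.0, 12.0, 0.0),
            rheumatoid_risk_hip=0.0,
            cardiac_history_probability=1.0,
        )
        cfg.clinical.blood_loss_sd = 0.0
        p = create_patient(0, table, cfg)
        assert p.weight == 75.0
        assert p.ebv == pytest.approx(75.0 * 65)
        assert (p.asa_ge3, p.rheumatoid, p.cardiac_history, p.revision) == (True, False, True, False)
        assert p.baseline_hb == pytest.approx(12.0, abs=0.3)
        assert p.blood_loss_hb == pytest.approx(3.3 * 1.05)  # ASA only (age 65-74)

    def test_ebv_consistent_with_weight(self, fixture_table, base_config):
        p = create_patient(3, fixture_table, base_config)
        assert p.ebv == pytest.approx(p.weight * 65)
        assert p.age_band[0] <= p.age <= p.age_band[1]

    def test_hip_share_matches_fixture(self, fixture_table, base_config):
        rng = stream(12, 0)
        n = 50_000
        idx = [fixture_table.sample_index(rng) for _ in range(n)]
        hips = (fixture_table.df["procedure"].to_numpy() == "hip")[idx].mean()
        assert 0.56 <= hips <= 0.59

    def test_comorbidity_prevalences(self, fixture_table):
        cfg = ModelConfig(cardiac_history_probability=0.15)
        profiles = [create_patient(i, fixture_table, cfg) for i in range(20_000)]
        cardiac = np.mean([p.cardiac_history for p in profiles])
        revision = np.mean([p.revision for p in profiles])
        assert cardiac == pytest.approx(0.15, abs=0.01)
        assert revision == pytest.approx(0.104, abs=0.01)


class TestFixtureTable:
    def test_schema_and_invariants(self, fixture_table):
        assert list(fixture_table.df.columns) == TABLE_COLUMNS
        assert fixture_table.df["frequency"].sum() == pytest.approx(1.0)
        fixture_table.validate()

    def test_two_row_request_normalised(self):
        params = FixtureParams(
            age_bands=[(65, 74, 1.0)],
            strata={"hip": [("only", 1.0, 13.0, 0.4)], "knee": [("only", 1.0, 13.0, 0.4)]},
            female_share=1.0,
        )
        table = generate_fixture_population(params)
        assert len(table.df) == 2
        assert table.df["frequency"].sum() == pytest.approx(1.0)

    def test_deterministic(self):
        a = generate_fixture_population()
        b = generate_fixture_population()
        assert a == b

    def test_csv_round_trip(self, fixture_table, tmp_path):
        p = tmp_path / "pop.csv"
        fixture_table.to_csv(p)
        assert PopulationTable.from_csv(p).df["frequency"].sum() == pytest.approx(1.0)
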