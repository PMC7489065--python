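"""Parameterization: validation, packaged defaults, serialization."""

import math

import numpy as np
import pytest

from vmango.parameters import (
    DistributionSpec,
    ParameterError,
    ProbabilityTable,
    ValidationError,
    default_parameterization,
    load_parameterization,
    save_parameterization,
    truncated_poisson_mean,
    truncated_poisson_rate_for_mean,
    PROCESS_IDS,
)


class TestDistributionSpec:
    def test_multinomial_must_sum_to_one(self):
        with pytest.raises(ValidationError, match="sum"):
            DistributionSpec(
                "ordinal-multinomial", {"categories": [1, 2, 3], "probs": [0.3, 0.3, 0.3]}
            )

    @pytest.mark.parametrize(
        "family,params",
        [
            ("gaussian", {"mean": 1.0, "sd": 0.0}),
            ("gamma", {"shape": -1.0, "scale": 0.5}),
            ("bernoulli", {"p": 1.2}),
            ("mixture-of-gaussians", {"weights": [0.6, 0.3], "means": [1, 2], "sds": [1, 1]}),
        ],
    )
    def test_invalid_parameters_rejected(self, family, params):
        with pytest.raises(ValidationError):
            DistributionSpec(family, params)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValidationError):
            DistributionSpec("cauchy", {"loc": 0})


class TestTruncatedPoisson:
    @pytest.mark.parametrize("mean", [1.3, 1.6, 2.1, 2.4, 3.4, 4.2])
    def test_rate_solver_round_trips(self, mean):
        rate = truncated_poisson_rate_for_mean(mean)
        assert truncated_poisson_mean(rate) == pytest.approx(mean, abs=1e-9)

    def test_conditional_mean_one_is_degenerate(self, rng):
        spec = DistributionSpec("poisson-truncated", {"rate": truncated_poisson_rate_for_mean(1.0)})
        draws = [spec.sample(rng) for _ in range(200)]
        assert set(draws) == {1}

    def test_samples_are_positive_counts(self, rng):
        spec = DistributionSpec("poisson-truncated", {"rate": 2.0})
        draws = np.array([spec.sample(rng) for _ in range(2000)])
        assert (draws >= 1).all()


class TestDefaults:
    def test_defaults_self_validate(self, params):
        params.validate()  # raises on any invariant violation

    @pytest.mark.parametrize(
        "process,levels,expected_p",
        [
            ("vegetative_burst_within", {"mother_burst_date": 9}, 0.80),
            ("vegetative_burst_within", {"mother_burst_date": 12}, 0.80),
            ("vegetative_burst_within", {"mother_burst_date": 2}, 0.02),
            ("has_apical_daughter", {}, 0.98),
            ("has_lateral_daughters", {"mother_position": "apical"}, 0.66),
            ("has_lateral_daughters", {"mother_position": "lateral"}, 0.28),
            ("has_apical_daughter_between", {"ancestor_fate": "quiescent"}, 0.82),
            ("has_apical_daughter_between", {"ancestor_fate": "flowering"}, 0.0),
            ("has_apical_daughter_between", {"ancestor_fate": "fruiting"}, 0.0),
            ("has_lateral_daughters_between", {"ancestor_fate": "quiescent"}, 0.46),
            ("is_mixed_inflorescence", {}, 0.06),
            ("mixed_burst", {}, 0.53),
            ("mixed_has_apical", {}, 0.47),
            ("fruiting", {"bloom_window": "early"}, 0.40),
            ("fruiting", {"bloom_window": "mid"}, 0.20),
            ("fruiting", {"bloom_window": "late"}, 0.0),
        ],
    )
    def test_printed_probabilities_transcribed(self, params, process, levels, expected_p):
        spec = params.table(process).lookup(**levels)
        assert spec.family == "bernoulli"
        assert spec.params["p"] == pytest.approx(expected_p)

    @pytest.mark.parametrize(
        "process,levels,mean,sd",
        [
            ("gu_axis_length", {"position": "apical", "mother_position": "apical"}, 18.1, 4.1),
            ("gu_axis_length", {"position": "apical", "mother_position": "lateral"}, 13.8, 4.0),
            ("gu_axis_length", {"position": "lateral", "mother_position": "apical"}, 12.6, 3.4),
            ("leaf_length", {"position": "apical"}, 17.1, 2.7),
            ("leaf_length", {"position": "lateral"}, 14.9, 2.7),
            ("inflorescence_axis_length", {}, 23.1, 6.7),
        ],
    )
    def test_geometry_gaussians(self, params, process, levels, mean, sd):
        spec = params.table(process).lookup(**levels)
        assert (spec.params["mean"], spec.params["sd"]) == (mean, sd)

    def test_first_internode_gamma(self, params):
        spec = params.table("first_internode_apical").lookup()
        assert spec.family == "gamma"
        assert (spec.params["shape"], spec.params["scale"]) == (2.0, 0.76)

    def test_dry_mass_mixture(self, params):
        spec = params.table("fruit_initial_dry_mass").lookup()
        assert spec.params["weights"] == [0.97, 0.03]
        assert spec.params["means"] == [13.9, 29.2]
        assert spec.params["sds"] == [4.1, 0.66]

    @pytest.mark.parametrize(
        "fate,mean", [("quiescent", 2.4), ("flowering", 3.4), ("fruiting", 4.2)]
    )
    def test_between_cycle_lateral_counts(self, params, fate, mean):
        spec = params.table("n_lateral_daughters_between").lookup(ancestor_fate=fate)
        assert truncated_poisson_mean(spec.params["rate"]) == pytest.approx(mean)

    def test_gu_stage_g_thermal_params(self, params):
        stage = {s.name: s for s in params.thermal.gu_stages}["G"]
        assert stage.base_T == 9.8
        assert stage.tts_threshold == 316.4

    def test_leaf_growth_slope_rule(self, params):
        # B = L / (0.06 L - 0.08) evaluated at the mean apical leaf length
        assert params.thermal.leaf_growth.slope(17.1) == pytest.approx(
            17.1 / (0.06 * 17.1 - 0.08)
        )
        assert params.thermal.leaf_growth.slope(17.1) == pytest.approx(18.08, abs=0.01)

    def test_all_probabilities_in_unit_interval(self, params):
        for table in params.tables.values():
            for spec in table.rows.values():
                if spec.family == "bernoulli":
                    assert 0.0 <= spec.params["p"] <= 1.0
                if spec.family == "ordinal-multinomial":
                    assert abs(sum(spec.params["probs"]) - 1.0) < 1e-9


class TestLookup:
    def test_missing_combination_is_an_error(self, params):
        with pytest.raises(ParameterError, match="no row"):
            params.table("fruiting").lookup(bloom_window="midnight")

    def test_wildcard_matches_any_level(self):
        table = ProbabilityTable(
            "flowering",
            ("mother_position", "ancestor_fate"),
            {
                ("apical", "*"): DistributionSpec("bernoulli", {"p": 0.5}),
                ("lateral", "*"): DistributionSpec("bernoulli", {"p": 0.2}),
            },
        )
        assert table.lookup(mother_position="apical", ancestor_fate="fruiting").params["p"] == 0.5

    def test_every_automaton_process_resolves(self, params):
        """Completeness by enumeration over the automata's query space."""
        contexts = {
            "vegetative_burst_within": [{"mother_burst_date": m} for m in range(1, 13)],
            "has_apical_daughter": [{}],
            "has_lateral_daughters": [{"mother_position": p} for p in ("apical", "lateral")],
            "n_lateral_daughters": [
                {"mother_position": p, "cycle": c}
                for p in ("apical", "lateral")
                for c in (1, 2)
            ],
            "burst_month": [{"mother_burst_date": m} for m in (8, 9, 10, 11, 12, 1, 2, 3, 4)],
            "vegetative_burst_between": [
                {"ancestor_fate": f} for f in ("quiescent", "flowering", "fruiting")
            ],
            "has_apical_daughter_between": [
                {"ancestor_fate": f} for f in ("quiescent", "flowering", "fruiting")
            ],
            "has_lateral_daughters_between": [
                {"ancestor_fate": f} for f in ("quiescent", "flowering", "fruiting")
            ],
            "n_lateral_daughters_between": [
                {"ancestor_fate": f} for f in ("quiescent", "flowering", "fruiting")
            ],
            "burst_month_between": [
                {"ancestor_fate": f} for f in ("quiescent", "flowering", "fruiting")
            ],
            "is_mixed_inflorescence": [{}],
            "flowering": [
                {"mother_position": p, "ancestor_fate": f}
                for p in ("apical", "lateral")
                for f in ("quiescent", "flowering", "fruiting")
            ],
            "n_inflorescences": [{"mother_burst_date": m} for m in range(1, 13)],
            "bloom_week": [{}],
            "fruiting": [{"bloom_window": w} for w in ("early", "mid", "late")],
            "n_fruits": [{"n_inflorescences_class": c} for c in ("1", "2+")],
            "mixed_burst": [{}],
            "mixed_n_daughters": [{}],
            "mixed_has_apical": [{}],
            "mixed_burst_month": [{}],
            "gu_axis_length": [
                {"position": p, "mother_position": q}
                for p in ("apical", "lateral")
                for q in ("apical", "lateral")
            ],
            "leaf_length": [{"position": p} for p in ("apical", "lateral")],
            "first_internode_apical": [{}],
            "inflorescence_axis_length": [{}],
            "fruit_initial_dry_mass": [{}],
        }
        assert set(contexts) == set(PROCESS_IDS)
        for pid, queries in contexts.items():
            for q in queries:
                params.table(pid).lookup(**q).validate()


class TestSerialization:
    def test_round_trip_is_lossless(self, params, tmp_path):
        save_parameterization(params, str(tmp_path))
        loaded = load_parameterization(str(tmp_path))
        assert set(loaded.tables) == set(params.tables)
        for pid, table in params.tables.items():
            other = loaded.tables[pid]
            assert other.factors == table.factors
            assert set(other.rows) == set(table.rows)
            for key, spec in table.rows.items():
                ospec = other.rows[key]
                assert ospec.family == spec.family
                for name, value in spec.params.items():
                    assert ospec.params[name] == pytest.approx(value)
        assert loaded.config.to_dict() == params.config.to_dict()
        assert loaded.thermal.to_dict() == params.thermal.to_dict()
        assert loaded.allometry.to_dict() == params.allometry.to_dict()

    def test_invalid_table_rejected_on_load(self, params, tmp_path):
        save_parameterization(params, str(tmp_path))
        bad = tmp_path / "tables" / "bloom_week.csv"
        text = bad.read_text().replace("0.01", "0.5", 1)
        bad.write_text(text)
        with pytest.raises(ValidationError, match="bloom_week"):
            load_parameterization(str(tmp_path))

    def test_unknown_process_rejected(self, params, tmp_path):
        save_parameterization(params, str(tmp_path))
        src = tmp_path / "tables" / "fruiting.csv"
        (tmp_path / "tables" / "fruit_teleportation.csv").write_text(src.read_text())
        with pytest.raises(ValidationError, match="fruit_teleportation"):
            load_parameterization(str(tmp_path))

    def test_missing_config_is_parse_error(self, tmp_path):
        with pytest.raises(ParameterError, match="config.json"):
            load_parameterization(str(tmp_path))
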