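import numpy as np
import pytest

import gba
from gba.validation import (DEFAULT_KM, MAX_REACTIONS, check_data_integrity,
                            check_dimensions, check_mass_conservation,
                            check_model, check_nonnegativity,
                            repair_km_defaults)


class TestDataIntegrity:
    def test_clean_model_passes(self, example):
        assert check_data_integrity(*example).status == "pass"

    def test_missing_cell_in_k_named(self, example):
        model, conditions = example
        model = model.copy()
        model.K[1, 2] = np.nan
        res = check_data_integrity(model, conditions)
        assert res.status == "fail"
        assert any("'K'" in m and "'A'" in m and "'e2'" in m
                   for m in res.messages)

    def test_text_cell_in_conditions_fails(self, example):
        model, conditions = example
        a = np.array(conditions.a, dtype=object)
        a[0, 1] = "not-a-number"
        bad = gba.ConditionSet(conditions.condition_labels, conditions.rho, a,
                               external_labels=["x_s"])
        res = check_data_integrity(model, bad)
        assert res.status == "fail"
        assert any("x_s" in m for m in res.messages)

    def test_nan_kcat_fails(self, example):
        model, conditions = example
        model = model.copy()
        model.kcat_b[0] = np.nan
        assert check_data_integrity(model, conditions).status == "fail"


class TestDimensions:
    def test_template_passes(self):
        from gba.model_core import make_template
        assert check_dimensions(*make_template(4, 3)).status == "pass"

    def test_k_with_fewer_columns_fails(self, example):
        model, conditions = example
        model = model.copy()
        model.K = model.K[:, :-1]
        res = check_dimensions(model, conditions)
        assert res.status == "fail"
        assert any("K" in m for m in res.messages)

    def test_conditions_with_unknown_external_row_fails(self, example):
        model, conditions = example
        bad = gba.ConditionSet(conditions.condition_labels, conditions.rho,
                               conditions.a, external_labels=["x_unknown"])
        res = check_dimensions(model, bad)
        assert res.status == "fail"

    def test_extra_conditions_row_count_fails(self, example):
        model, conditions = example
        a2 = np.vstack([conditions.a, conditions.a])
        bad = gba.ConditionSet(conditions.condition_labels, conditions.rho, a2,
                               external_labels=["x_s", "x_s2"])
        assert check_dimensions(model, bad).status == "fail"


class TestNonnegativity:
    def test_valid_conditions_pass(self, example):
        assert check_nonnegativity(*example).status == "pass"

    def test_zero_density_fails(self, example):
        model, conditions = example
        bad = gba.ConditionSet(conditions.condition_labels,
                               np.array([300.0, 0.0, 300.0]), conditions.a,
                               external_labels=["x_s"])
        res = check_nonnegativity(model, bad)
        assert res.status == "fail"
        assert any("rho" in m for m in res.messages)

    def test_negative_external_names_condition_and_reactant(self, example):
        model, conditions = example
        a = np.array(conditions.a)
        a[0, 2] = -1.0
        bad = gba.ConditionSet(conditions.condition_labels, conditions.rho, a,
                               external_labels=["x_s"])
        res = check_nonnegativity(model, bad)
        assert res.status == "fail"
        assert any("high" in m and "x_s" in m for m in res.messages)


class TestMassConservation:
    def test_example_passes(self, example_model):
        assert check_mass_conservation(example_model).status == "pass"

    def test_scaled_column_fails_by_name(self, example_model):
        model = example_model.copy()
        model.M[:, 1] *= 2.0
        res = check_mass_conservation(model)
        assert res.status == "fail"
        assert any("e1" in m for m in res.messages)
        assert len(res.messages) == 1

    def test_all_zero_column_fails(self, example_model):
        model = example_model.copy()
        model.M[:, 3] = 0.0
        assert check_mass_conservation(model).status == "fail"


class TestKmRepair:
    def test_zero_substrate_km_repaired_to_default(self, minimal):
        model, _ = minimal
        model = model.copy()
        model.K[0, 0] = 0.0  # transporter substrate Km
        fixed, cells = repair_km_defaults(model)
        assert cells == [("x_s", "t")]
        assert fixed.K[0, 0] == DEFAULT_KM == 0.1

    def test_no_zero_km_is_identity(self, example_model):
        fixed, cells = repair_km_defaults(example_model)
        assert cells == []
        assert fixed is example_model

    def test_irreversible_product_not_repaired(self, minimal):
        model, _ = minimal
        model = model.copy()
        model.K[1, 0] = 0.0  # product C of irreversible transporter
        fixed, cells = repair_km_defaults(model)
        assert cells == []
        assert fixed.K[1, 0] == 0.0

    def test_reversible_product_repaired(self, minimal):
        model, _ = minimal
        model = model.copy()
        model.kcat_b[0] = 5.0
        model.K[1, 0] = 0.0  # product of the now-reversible transporter
        fixed, cells = repair_km_defaults(model)
        assert ("C", "t") in cells
        assert fixed.K[1, 0] == DEFAULT_KM

    def test_only_targeted_cells_change(self, example_model):
        model = example_model.copy()
        model.K[0, 0] = 0.0
        model.K[1, 1] = 0.0
        fixed, cells = repair_km_defaults(model)
        changed = np.sum(fixed.K != model.K)
        assert changed == len(cells) == 2


class TestCheckModel:
    def test_example_valid_no_repairs(self, example):
        report = check_model(*example)
        assert report.is_valid
        assert report.repaired_model is None
        names = [c.name for c in report.checks]
        assert names[:6] == ["data_integrity", "dimensions", "nonnegativity",
                             "mass_conservation", "km_defaults", "size_limit"]

    def test_21_reactions_fail_size_check(self):
        model, conditions = gba.generate_model(gba.ModelSpec(n_rxn=21, seed=0))
        report = check_model(model, conditions)
        assert not report.is_valid
        size = next(c for c in report.checks if c.name == "size_limit")
        assert size.status == "fail"

    def test_20_reactions_pass(self):
        model, conditions = gba.generate_model(gba.ModelSpec(n_rxn=20, seed=0))
        assert check_model(model, conditions).is_valid

    def test_size_limit_can_be_lifted(self):
        model, conditions = gba.generate_model(gba.ModelSpec(n_rxn=21, seed=0))
        report = check_model(model, conditions, max_reactions=None)
        assert report.is_valid

    def test_dimension_failure_still_reports_other_checks(self, example):
        model, conditions = example
        model = model.copy()
        model.K = model.K[:, :-1]
        report = check_model(model, conditions)
        assert not report.is_valid
        names = [c.name for c in report.checks]
        assert "data_integrity" in names
        assert "size_limit" in names

    def test_repair_reported_and_model_returned(self, minimal):
        model, conditions = minimal
        model = model.copy()
        model.K[0, 0] = 0.0
        report = check_model(model, conditions)
        assert report.is_valid
        assert report.repaired_model is not None
        assert report.repaired_model.K[0, 0] == DEFAULT_KM
        km = next(c for c in report.checks if c.name == "km_defaults")
        assert km.status == "repaired"
        assert len(km.messages) == 1

    def test_fix_km_false_turns_repair_into_failure(self, minimal):
        model, conditions = minimal
        model = model.copy()
        model.K[0, 0] = 0.0
        report = check_model(model, conditions, fix_km=False)
        assert not report.is_valid
        assert report.repaired_model is None

    def test_idempotent_on_repaired_model(self, minimal):
        model, conditions = minimal
        model = model.copy()
        model.K[0, 0] = 0.0
        report = check_model(model, conditions)
        report2 = check_model(report.repaired_model, conditions)
        assert report2.is_valid
        assert report2.repaired_model is None

    def test_max_reactions_default_is_20(self):
        assert MAX_REACTIONS == 20

    @pytest.mark.parametrize("seed", range(100))
    def test_generator_output_always_valid(self, seed):
        rng = np.random.default_rng(seed)
        spec = gba.ModelSpec(
            n_rxn=int(rng.integers(2, 21)),
            n_ext=1,
            reversible_fraction=float(rng.uniform(0, 0.5)),
            regulation_density=float(rng.uniform(0, 0.2)),
            seed=seed)
        model, conditions = gba.generate_model(spec)
        report = check_model(model, conditions)
        assert report.is_valid
        assert report.repaired_model is None
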