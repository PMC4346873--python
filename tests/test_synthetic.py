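"""Generator determinism, pass-rate control and fixture integrity."""

import math

import numpy as np
import pytest

from herbnet.adme import run_cascade
from herbnet.synthetic import (
    FIXTURE_NAMES,
    FixtureIntegrityError,
    GeneratorConfig,
    _verify,
    generate_compound_table,
    generate_interaction_table,
    load_fixture,
)
from herbnet.target_filter import gate_predictions


class TestCompoundGenerator:
    def test_same_seed_same_table(self):
        a = generate_compound_table(GeneratorConfig(seed=5, n_compounds=100))
        b = generate_compound_table(GeneratorConfig(seed=5, n_compounds=100))
        assert a == b

    def test_different_seed_different_table(self):
        a = generate_compound_table(GeneratorConfig(seed=5, n_compounds=100))
        b = generate_compound_table(GeneratorConfig(seed=6, n_compounds=100))
        assert a != b

    def test_all_pass_when_rates_are_one(self):
        config = GeneratorConfig(seed=1, n_compounds=50, p_dl=1, p_ob=1, p_caco2=1)
        records = generate_compound_table(config)
        result = run_cascade(records)
        assert all(count == 50 for count in result.stage_counts.values())

    def test_none_pass_when_rates_are_zero(self):
        config = GeneratorConfig(seed=1, n_compounds=50, p_dl=0, p_ob=0, p_caco2=0)
        result = run_cascade(generate_compound_table(config))
        assert result.stage_counts["dl"] == 0

    def test_funnel_fractions_within_three_binomial_se(self):
        # pass rates mirroring the published 389 -> 134 -> 61 -> 26 funnel,
        # drawn at n = 2000
        n = 2000
        config = GeneratorConfig(
            seed=123, n_compounds=n, p_dl=0.344, p_ob=0.455, p_caco2=0.426
        )
        records = generate_compound_table(config)
        for p, attr, thr in (
            (0.344, "dl", 0.18),
            (0.455, "ob", 30.0),
            (0.426, "caco2", -0.4),
        ):
            passed = sum(1 for r in records if getattr(r, attr) >= thr)
            se = math.sqrt(p * (1 - p) / n)
            assert abs(passed / n - p) <= 3 * se

    def test_exact_mode_hits_requested_counts(self):
        config = GeneratorConfig(
            seed=9, n_compounds=134, p_ob=61 / 134, exact=True, p_dl=1, p_caco2=1
        )
        records = generate_compound_table(config)
        assert sum(1 for r in records if r.ob >= 30.0) == 61

    def test_pass_rate_recovery_at_n_5000(self):
        n = 5000
        config = GeneratorConfig(seed=77, n_compounds=n)
        records = generate_compound_table(config)
        for p, attr, thr in (
            (config.p_dl, "dl", 0.18),
            (config.p_ob, "ob", 30.0),
            (config.p_caco2, "caco2", -0.4),
        ):
            passed = sum(1 for r in records if getattr(r, attr) >= thr)
            se = math.sqrt(p * (1 - p) / n)
            assert abs(passed / n - p) <= 3 * se

    def test_properties_respect_domains(self):
        records = generate_compound_table(GeneratorConfig(seed=2, n_compounds=500))
        assert all(0 <= r.ob <= 100 for r in records)
        assert all(0 <= r.dl <= 1 for r in records)

    def test_infeasible_pass_rate_rejected(self):
        with pytest.raises(ValueError, match="p_dl"):
            GeneratorConfig(seed=1, p_dl=1.5)


class TestInteractionGenerator:
    def make_tables(self, config):
        compounds = generate_compound_table(config)
        targets = load_fixture("table2").records
        return compounds, targets

    def test_density_zero_gives_empty_table(self):
        config = GeneratorConfig(seed=3, n_compounds=10, edge_density=0.0)
        compounds, targets = self.make_tables(config)
        assert generate_interaction_table(config, compounds, targets) == []

    def test_density_one_gives_complete_bipartite_set(self):
        config = GeneratorConfig(seed=3, n_compounds=10, edge_density=1.0)
        compounds, targets = self.make_tables(config)
        records = generate_interaction_table(config, compounds, targets)
        assert len(records) == 10 * 43

    def test_scores_above_gates_retain_everything(self):
        config = GeneratorConfig(
            seed=4,
            n_compounds=20,
            edge_density=0.5,
            svm_range=(0.85, 1.0),
            rf_range=(0.75, 1.0),
            dock_range=(45.0, 80.0),
        )
        compounds, targets = self.make_tables(config)
        records = generate_interaction_table(config, compounds, targets)
        retained, quarantined = gate_predictions(records)
        assert retained == records and not quarantined

    def test_density_recovery(self):
        density = 0.2
        config = GeneratorConfig(seed=8, n_compounds=500, edge_density=density)
        compounds, targets = self.make_tables(config)
        records = generate_interaction_table(config, compounds, targets)
        n_pairs = 500 * 43
        se = math.sqrt(density * (1 - density) / n_pairs)
        assert abs(len(records) / n_pairs - density) <= 3 * se


class TestFixtures:
    def test_all_fixtures_load_and_pass_checksum(self):
        for name in FIXTURE_NAMES:
            load_fixture(name)

    def test_kaempferol_row(self):
        by_id = {r.compound_id: r for r in load_fixture("table1").records}
        k = by_id["M_14"]
        assert (k.name, k.ob, k.caco2, k.dl) == ("kaempferol", 65.70, 0.27, 0.24)

    def test_metabolite_map_content(self):
        mapping = load_fixture("metabolite_map")
        assert mapping == {"M_28": "M_29", "M_04": "M_05"}

    def test_table2_bold_flags_on_six_rows(self):
        records = load_fixture("table2").records
        assert sum(r.shared_with_drugs for r in records) == 6

    def test_unknown_fixture_lists_available_names(self):
        with pytest.raises(KeyError, match="table1"):
            load_fixture("table99")

    def test_tampered_fixture_detected(self, tmp_path):
        path = tmp_path / "table1.tsv"
        path.write_bytes(b"compound_id\tname\tob\tcaco2\tdl\n")
        with pytest.raises(FixtureIntegrityError):
            _verify("table1", path)
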