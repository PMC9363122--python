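import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from osteosim.core import DrugEffects
from osteosim.pharmacology import (
    DRUGS,
    DoseEvent,
    Regimen,
    apply_dose,
    drug_effects,
    load_regimen,
    make_block_regimen,
    parse_duration,
    pk_derivatives,
    save_regimen,
    zero_drug_state,
)


class TestRegimenConstruction:
    def test_denosumab_semiannual_block(self):
        reg = make_block_regimen([("denosumab", 60, 0.5, 1.0)], start_age=67)
        assert [ev.time for ev in reg.events] == [67.0, 67.5]
        assert all(ev.dose == 60 for ev in reg.events)

    def test_weekly_alendronate_year_has_52_doses(self):
        reg = make_block_regimen([("alendronate", 70, 1 / 52, 1.0)], start_age=60)
        assert len(reg) == 52
        assert reg.total_dose() == {"alendronate": 70 * 52}

    def test_empty_block_list(self):
        reg = make_block_regimen([], start_age=60)
        assert len(reg) == 0 and reg.start is None

    def test_blocks_concatenate_sequentially(self):
        reg = make_block_regimen(
            [("alendronate", 70, 1 / 52, 1.0), ("denosumab", 60, 0.5, 1.0)],
            start_age=67,
        )
        dmab = [ev.time for ev in reg.events if ev.drug_id == "denosumab"]
        assert dmab == [68.0, 68.5]
        assert reg.label == "AD"

    def test_parallel_blocks_via_explicit_start(self):
        reg = make_block_regimen(
            [
                {"drug": "teriparatide", "dose_mg": 0.02, "every": "1 w",
                 "for": "6 mo", "start": 66.0},
                {"drug": "denosumab", "dose_mg": 60, "every": "6 mo",
                 "for": "1 yr", "start": 66.0},
            ]
        )
        assert reg.start == 66.0
        assert set(reg.drug_ids()) == {"teriparatide", "denosumab"}

    def test_events_sorted_and_validated(self):
        with pytest.raises(ValueError):
            DoseEvent("denosumab", 67.0, 0.0)
        with pytest.raises(ValueError):
            DoseEvent("aspirin", 67.0, 100.0)
        reg = Regimen(
            events=[DoseEvent("denosumab", 68.0, 60), DoseEvent("denosumab", 67.0, 60)]
        )
        assert [ev.time for ev in reg.events] == [67.0, 68.0]

    @pytest.mark.parametrize(
        "text,years",
        [("1 w", 1 / 52), ("6 mo", 0.5), ("2 yr", 2.0), ("1 d", 1 / 365),
         ("6mo", 0.5), (0.25, 0.25)],
    )
    def test_duration_parsing(self, text, years):
        assert parse_duration(text) == pytest.approx(years)

    def test_duration_parse_failure(self):
        with pytest.raises(ValueError):
            parse_duration("three fortnights")

    def test_regimen_file_round_trip(self, tmp_path):
        blocks = [
            {"drug": "alendronate", "dose_mg": 70, "every": "1 w", "for": "1 yr",
             "start": 67.0},
            {"drug": "romosozumab", "dose_mg": 140, "every": "1 mo", "for": "1 yr",
             "start": 68.0},
        ]
        path = tmp_path / "regimen.yaml"
        save_regimen(blocks, path)
        reg = load_regimen(path)
        direct = make_block_regimen(blocks)
        assert reg.events == direct.events


class TestPharmacokinetics:
    def test_zero_state_stays_zero(self, ref_params):
        state = zero_drug_state(["denosumab", "alendronate"])
        derivs = pk_derivatives(state, ref_params)
        for d in derivs.values():
            assert np.allclose(d, 0.0)

    def test_unknown_drug_rejected(self, ref_params):
        with pytest.raises(ValueError):
            pk_derivatives({"aspirin": np.zeros(3)}, ref_params)

    def test_dose_enters_depot_scaled_by_bioavailability(self, ref_params):
        state = zero_drug_state(["alendronate"])
        apply_dose(state, DoseEvent("alendronate", 60.0, 70.0), ref_params)
        F = ref_params.value("pk_alendronate_F")
        assert state["alendronate"][0] == pytest.approx(70.0 * F)

    def test_bisphosphonate_exchanges_with_bone_compartment(self, ref_params):
        state = {"alendronate": np.array([0.0, 1.0, 2.0])}
        d = pk_derivatives(state, ref_params)["alendronate"]
        p = ref_params.compile()
        assert d[2] == pytest.approx(
            p.pk_alendronate_k_bone * 1.0 - p.pk_alendronate_k_release * 2.0
        )

    def test_antibodies_have_no_bone_compartment_flux(self, ref_params):
        state = {"denosumab": np.array([0.0, 5.0, 0.0])}
        d = pk_derivatives(state, ref_params)["denosumab"]
        assert d[2] == 0.0


class TestDrugEffects:
    def test_neutral_at_zero_drug(self, ref_params):
        eff = drug_effects(zero_drug_state(list(DRUGS)), ref_params)
        for f in dataclasses.fields(DrugEffects):
            assert getattr(eff, f.name) == pytest.approx(1.0)

    def test_half_maximal_effect_at_ec50(self, ref_params):
        p = ref_params.compile()
        state = {"denosumab": np.array([0.0, p.pd_denosumab_ec50, 0.0])}
        eff = drug_effects(state, ref_params)
        assert eff.oc_differentiation == pytest.approx(
            1.0 - 0.5 * p.pd_denosumab_emax
        )

    def test_saturating_concentration_pins_at_emax(self, ref_params):
        p = ref_params.compile()
        state = {"teriparatide": np.array([0.0, 1e6, 0.0])}
        eff = drug_effects(state, ref_params)
        assert eff.ob_recruitment == pytest.approx(
            1.0 + p.pd_teriparatide_emax, rel=1e-6
        )

    @given(
        central=st.floats(0.0, 1e4),
        bone=st.floats(0.0, 1e4),
    )
    def test_multipliers_stay_within_declared_bounds(self, ref_params, central, bone):
        p = ref_params.compile()
        state = {
            "denosumab": np.array([0.0, central, 0.0]),
            "romosozumab": np.array([0.0, central, 0.0]),
            "alendronate": np.array([0.0, central, bone]),
            "teriparatide": np.array([0.0, central, 0.0]),
        }
        eff = drug_effects(state, ref_params)
        assert 1.0 - p.pd_denosumab_emax <= eff.oc_differentiation <= 1.0
        assert 1.0 - p.pd_romosozumab_emax <= eff.free_sclerostin <= 1.0
        assert 1.0 <= eff.oc_apoptosis <= 1.0 + p.pd_alendronate_emax_apo
        assert 1.0 - p.pd_alendronate_emax_res <= eff.resorption <= 1.0
        assert 1.0 <= eff.ob_recruitment <= 1.0 + p.pd_teriparatide_emax
        assert (
            1.0
            <= eff.mc_target
            <= 1.0 + p.pd_denosumab_mc_shift + p.pd_alendronate_mc_shift
        )
        eff.validate()

    def test_sclerostin_antibodies_compose_multiplicatively(self, ref_params):
        romo = drug_effects(
            {"romosozumab": np.array([0.0, 50.0, 0.0])}, ref_params
        ).free_sclerostin
        blo = drug_effects(
            {"blosozumab": np.array([0.0, 80.0, 0.0])}, ref_params
        ).free_sclerostin
        both = drug_effects(
            {
                "romosozumab": np.array([0.0, 50.0, 0.0]),
                "blosozumab": np.array([0.0, 80.0, 0.0]),
            },
            ref_params,
        ).free_sclerostin
        assert both == pytest.approx(romo * blo)
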