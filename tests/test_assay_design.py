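"""Planner arithmetic: recipes, feasible range, consumables, worklists."""

import math
from dataclasses import replace
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pegsolve.assay_design import (
    Consumables,
    DesignConfig,
    InfeasibleTargetError,
    TransferConfig,
    emit_worklist,
    max_achievable_peg,
    parse_worklist,
    plan_assay,
    plan_supernatant_transfer,
    summarize_consumables,
    well_name,
    write_layout,
)


class TestPlanAssay:
    def test_protein_volume_from_mass_conservation(self, design):
        plan = plan_assay(design)
        samples = [w for w in plan if w.role == "sample"]
        assert all(w.v_protein == Fraction(10, 3) for w in samples)

    def test_zero_peg_target_has_no_peg_and_buffer_fill(self, design):
        plan = plan_assay(design)
        zero = [w for w in plan if w.peg_target == 0 and w.role == "sample"]
        assert zero and all(w.v_peg == 0 for w in zero)
        assert all(w.v_buffer == Fraction(10) - Fraction(10, 3) for w in zero)

    def test_33_3_percent_target_uses_full_budget_from_top_stock(self):
        cfg = DesignConfig(peg_targets=[0.0, 10.0, 20.0, Fraction(100, 3)])
        plan = plan_assay(cfg)
        top = [w for w in plan if w.role == "sample"][-1]
        assert top.peg_stock_used == 50.0
        assert top.v_peg == Fraction(20, 3)  # target*V/stock
        assert top.v_buffer == 0

    def test_volumes_sum_exactly_and_realized_peg_exact(self, design):
        for w in plan_assay(design):
            assert w.v_peg + w.v_buffer + w.v_protein == Fraction(10)
            if w.peg_target > 0:
                realized = w.v_peg * Fraction(w.peg_stock_used) / Fraction(10)
                assert float(realized) == pytest.approx(w.peg_target, rel=1e-9)

    def test_blanks_replace_protein_with_buffer(self, design):
        for w in plan_assay(design):
            if w.role == "blank":
                assert w.v_protein == 0
                assert w.v_peg + w.v_buffer == Fraction(10)

    def test_stock_selection_prefers_lowest_feasible_stock(self, design):
        plan = plan_assay(design)
        stock_of = {w.peg_target: w.peg_stock_used for w in plan if w.peg_target > 0}
        # 3% from 15% stock needs 2 µL (fits); 30% needs 10 µL from 30% stock
        # (exceeds the 6.67 µL budget) so the 50% stock is required
        assert stock_of[3.0] == 15.0
        assert stock_of[9.0] == 15.0
        assert stock_of[12.0] == 30.0
        assert stock_of[30.0] == 50.0

    def test_infeasible_target_names_the_target(self, design):
        cfg = replace(design, peg_targets=[0.0, 40.0])
        with pytest.raises(InfeasibleTargetError, match="40"):
            plan_assay(cfg)

    def test_target_below_min_transfer_is_infeasible(self, design):
        # 0.5% from the 50% stock needs 0.1 µL < 0.33 µL; weaker stocks need
        # more volume but 15% stock gives 0.33 µL exactly -> feasible;
        # 0.1% is infeasible with every stock
        cfg = replace(design, peg_targets=[0.1])
        with pytest.raises(InfeasibleTargetError):
            plan_assay(cfg)
        plan = plan_assay(replace(design, peg_targets=[0.495]))
        assert plan[0].peg_stock_used == 15.0

    def test_well_count_and_row_major_layout(self, design):
        plan = plan_assay(design)
        assert len(plan) == 36  # 12 × (2 replicates + 1 blank)
        assert [w.well_id for w in plan[:4]] == ["A1", "A2", "A3", "A4"]
        assert plan[24].well_id == "B1"  # 24-column plate wraps


class TestMaxAchievablePeg:
    def test_default_stock_gives_one_third_of_50pct(self, design):
        assert max_achievable_peg(design) == pytest.approx(100.0 / 3.0, abs=1e-12)

    def test_concentrated_protein_stock_extends_range_to_45(self, design):
        cfg = replace(design, protein_stock_conc=10.0)
        assert max_achievable_peg(cfg) == pytest.approx(45.0, abs=1e-12)

    def test_no_protein_releases_entire_budget(self, design):
        cfg = replace(design, final_protein_conc=0.0)
        assert max_achievable_peg(cfg) == pytest.approx(50.0, abs=1e-12)

    @given(
        stock=st.floats(min_value=3.0, max_value=50.0),
        top_peg=st.floats(min_value=20.0, max_value=80.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_protein_stock_and_top_peg(self, stock, top_peg):
        base = DesignConfig(peg_targets=[0.0], protein_stock_conc=stock,
                            peg_stock_concs=[15.0, top_peg])
        stronger = DesignConfig(peg_targets=[0.0], protein_stock_conc=stock * 1.5,
                                peg_stock_concs=[15.0, top_peg])
        taller = DesignConfig(peg_targets=[0.0], protein_stock_conc=stock,
                              peg_stock_concs=[15.0, top_peg * 1.1])
        m = max_achievable_peg(base)
        assert max_achievable_peg(stronger) >= m - 1e-12
        assert max_achievable_peg(taller) >= m - 1e-12


class TestConsumables:
    def test_standard_run_uses_80_ul_and_240_ug(self, design):
        cons = summarize_consumables(plan_assay(design), design)
        assert cons.total_protein_volume == pytest.approx(80.0, abs=1e-12)
        assert cons.total_protein_mass == pytest.approx(240.0, abs=1e-12)
        assert cons.n_wells == 36

    def test_mass_equals_volume_times_stock_exactly(self, design):
        cons = summarize_consumables(plan_assay(design), design)
        assert cons.total_protein_mass == cons.total_protein_volume * 3.0

    def test_empty_plan_is_all_zero(self, design):
        cons = summarize_consumables([], design)
        assert cons == Consumables(0.0, 0.0, {}, 0.0, 0)

    def test_single_replicate_halves_protein(self, design):
        cfg = replace(design, replicates_per_conc=1)
        cons = summarize_consumables(plan_assay(cfg), cfg)
        assert cons.total_protein_volume == pytest.approx(40.0)


class TestSupernatantTransfer:
    def test_each_source_yields_6_ul_over_two_destinations(self, design):
        plan = plan_assay(design)
        transfers = plan_supernatant_transfer(plan, design)
        assert len(transfers) == 36
        t = transfers[0]
        assert len(t.dest_wells) == 2
        assert t.n_transfers * t.v_per_transfer == pytest.approx(6.0)

    def test_four_measurement_wells_per_concentration(self, design):
        plan = plan_assay(design)
        transfers = plan_supernatant_transfer(plan, design)
        by_source = {w.well_id: w for w in plan}
        per_conc: dict[float, int] = {}
        for t in transfers:
            src = by_source[t.source_well]
            if src.role == "sample":
                per_conc[src.peg_target] = per_conc.get(src.peg_target, 0) + len(
                    t.dest_wells
                )
        assert set(per_conc.values()) == {4}

    def test_zero_transfers_yields_empty_plan(self, design):
        plan = plan_assay(design)
        assert plan_supernatant_transfer(plan, design, TransferConfig(n_transfers=0)) == []

    def test_removal_beyond_evaporation_headroom_rejected(self, design):
        plan = plan_assay(design)
        with pytest.raises(ValueError, match="headroom"):
            plan_supernatant_transfer(
                plan, design, TransferConfig(v_per_transfer=3.0, n_transfers=3)
            )

    def test_destination_capacity_enforced(self, design):
        plan = plan_assay(design)
        with pytest.raises(ValueError, match="destination"):
            plan_supernatant_transfer(
                plan, design, TransferConfig(dest_rows=2, dest_cols=3)
            )

    def test_destinations_are_unique_and_row_major(self, design):
        transfers = plan_supernatant_transfer(plan_assay(design), design)
        dests = [d for t in transfers for d in t.dest_wells]
        assert len(dests) == len(set(dests)) == 72
        assert dests[:3] == ["A1", "A2", "A3"]


class TestWorklist:
    def test_round_trip_preserves_volumes_to_3_decimals(self, design, tmp_path):
        plan = plan_assay(design)
        path = emit_worklist(plan, tmp_path / "wl.csv")
        df = parse_worklist(path)
        by_dest = df.groupby("dest_well")["volume_ul"].sum()
        for w in plan:
            assert by_dest[w.well_id] == pytest.approx(10.0, abs=2e-3)
        protein_rows = df[df["reagent"] == "protein"]
        assert all(
            v == pytest.approx(float(Fraction(10, 3)), abs=5e-4)
            for v in protein_rows["volume_ul"]
        )

    def test_zero_volume_rows_omitted_and_protein_last(self, design, tmp_path):
        plan = plan_assay(design)
        df = parse_worklist(emit_worklist(plan, tmp_path / "wl.csv"))
        assert (df["volume_ul"] > 0).all()
        phases = df["reagent"].tolist()
        assert phases.index("protein") > max(
            i for i, p in enumerate(phases) if p == "peg"
        )
        # 0% wells have no PEG row: 24 sample + 12 blank wells, 3 with no PEG
        assert (df["reagent"] == "peg").sum() == 33

    def test_layout_counts(self, design, tmp_path):
        plan = plan_assay(design)
        path = write_layout(plan, tmp_path / "layout.csv", "mAb-1")
        import pandas as pd

        layout = pd.read_csv(path)
        assert (layout["role"] == "sample").sum() == 24
        assert (layout["role"] == "blank").sum() == 12


def test_well_name_row_major():
    assert [well_name(i) for i in (0, 23, 24)] == ["A1", "A24", "B1"]
    assert well_name(5, n_cols=3) == "B3"


@given(
    final_conc=st.floats(min_value=0.2, max_value=2.0),
    stock_conc=st.floats(min_value=2.5, max_value=20.0),
    n_targets=st.integers(min_value=1, max_value=8),
)
@settings(max_examples=40, deadline=None, derandomize=True)
def test_volume_conservation_property(final_conc, stock_conc, n_targets):
    """Any feasible plan conserves volume exactly and hits targets exactly."""
    targets = [2.0 * i for i in range(n_targets)]
    cfg = DesignConfig(
        final_protein_conc=final_conc,
        protein_stock_conc=stock_conc,
        peg_targets=targets,
    )
    try:
        plan = plan_assay(cfg)
    except InfeasibleTargetError:
        return
    total = Fraction(10)
    for w in plan:
        assert w.v_peg + w.v_buffer + w.v_protein == total
        for v in (w.v_peg, w.v_protein):
            assert v == 0 or float(v) >= cfg.min_transfer_volume - 1e-12
        if w.peg_target > 0:
            realized = float(w.v_peg * Fraction(w.peg_stock_used) / total)
            assert math.isclose(realized, w.peg_target, rel_tol=1e-9)
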