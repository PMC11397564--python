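"""Ladder lookup, fvnl points, the protein cap, and score arithmetic."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npmpfj import (NutrientProfile, fvnl_points, lookup_points, score_food,
                    score_records)
from npmpfj.bands import AT_LEAST
from npmpfj.errors import ConfigurationError


def oracle_lookup(value, table):
    """Independent linear scan over the threshold list (no early exit, no
    index arithmetic shared with the implementation)."""
    best = 0
    for k in range(1, len(table.thresholds) + 1):
        rung = table.thresholds[k - 1]
        if table.boundary_mode == AT_LEAST:
            if table.top_equality and k == len(table.thresholds):
                ok = abs(value - rung) <= 1e-9
            else:
                ok = value >= rung
        else:
            ok = value > rung
        if ok:
            best = k
    return best


class TestLookupPoints:
    @pytest.mark.parametrize("value,component,expected", [
        (84, "energy", 1),     # just clears the 1-point rung
        (83, "energy", 0),     # at the rung: strictly-greater, no point
        (913, "energy", 10),   # at the top rung: 11th point needs > 913
        (914, "energy", 11),
        (0, "energy", 0),
        (0, "satfat", 0),
        (40, "fvnl_nonconcentrated", 1),  # at-least semantics
        (25, "fvnl_concentrated", 1),
    ])
    def test_boundary_examples(self, band_tables, value, component, expected):
        assert lookup_points(value, band_tables[component]) == expected

    def test_negative_value_rejected(self, band_tables):
        with pytest.raises(ValueError):
            lookup_points(-1, band_tables["energy"])

    def test_every_cut_boundary_both_sides(self, band_tables):
        """At every rung of every ladder, the point flips exactly at the
        documented side of the cut (one float ulp away)."""
        for comp, table in band_tables.items():
            top = table.max_points
            for k, cut in enumerate(table.thresholds, start=1):
                above = np.nextafter(cut, np.inf)
                below = np.nextafter(cut, -np.inf)
                if table.boundary_mode == AT_LEAST:
                    if table.top_equality and k == top:
                        # "=100": only exact equality scores the top point
                        assert lookup_points(cut, table) == top
                        assert lookup_points(cut - 1e-6, table) == top - 1
                    else:
                        assert lookup_points(cut, table) >= k
                        assert lookup_points(below, table) == k - 1
                else:
                    assert lookup_points(cut, table) == k - 1
                    if above <= (table.thresholds[k] if k < top else np.inf):
                        assert lookup_points(above, table) == k

    def test_matches_linear_scan_oracle_on_random_values(self, band_tables):
        rng = np.random.default_rng(20240907)
        for comp, table in band_tables.items():
            hi = table.thresholds[-1] * 1.2
            values = rng.uniform(0, min(hi, 100) if comp.startswith("fvnl") else hi,
                                 size=10_000)
            for v in values:
                assert lookup_points(v, table) == oracle_lookup(v, table)


class TestFvnlPoints:
    @pytest.mark.parametrize("pct,conc,expected", [
        (100, False, 8),   # top rung: exact equality
        (99, False, 7),
        (39.9, False, 0),  # below the non-concentrated start
        (40, False, 1),
        (25, True, 1),
        (24.9, True, 0),
    ])
    def test_examples(self, pct, conc, expected):
        assert fvnl_points(pct, conc) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fvnl_points(100.1, False)
        with pytest.raises(ValueError):
            fvnl_points(-1, True)


def _profile(energy=0.0, satfat=0.0, sugars=0.0, sodium=0.0, fvnl=0.0,
             conc=False, protein=0.0, fiber=0.0):
    return NutrientProfile(energy, satfat, sugars, sodium, fvnl, conc,
                           protein, fiber)


class TestScoreFood:
    def test_all_zero_profile(self):
        pv = score_food(_profile())
        assert pv.baseline == 0 and pv.final == 0

    def test_worked_examples_score_to_hand_computed_vectors(self, worked_examples):
        for wx in worked_examples:
            assert score_food(wx.record.profile) == wx.expected, wx.record.food_id

    def test_cap_engaged_baseline_13_v4(self):
        # sodium 1340 -> 13 sodium points = baseline 13; fvnl 75 -> V 4
        pv = score_food(_profile(sodium=1340, fvnl=75, protein=10))
        assert pv.baseline == 13 and pv.v_pts == 4 and pv.p_pts == 0

    def test_cap_lifted_at_v5(self):
        pv = score_food(_profile(sodium=1340, fvnl=80, protein=10))
        assert pv.baseline == 13 and pv.v_pts == 5 and pv.p_pts == 3
        assert pv.final == 13 - 5 - 3

    def test_cap_not_engaged_below_baseline_13(self):
        pv = score_food(_profile(sodium=1237, fvnl=0, protein=10))  # baseline 12
        assert pv.baseline == 12 and pv.p_pts == 3

    def test_missing_table_is_configuration_error(self, band_tables):
        tables = {c: t for c, t in band_tables.items() if c != "protein"}
        with pytest.raises(ConfigurationError, match="protein"):
            score_food(_profile(), tables)

    def test_cap_soundness_on_synthetic_foods(self, synthetic_points):
        for pv in synthetic_points:
            if pv.p_pts > 0 and pv.baseline >= 13:
                assert pv.v_pts >= 5

    def test_identities_hold_on_synthetic_foods(self, synthetic_points):
        for pv in synthetic_points:
            assert pv.baseline == (pv.energy_pts + pv.satfat_pts
                                   + pv.sugars_pts + pv.sodium_pts)
            assert pv.final == pv.baseline - pv.v_pts - pv.p_pts - pv.f_pts


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    energy=st.floats(0, 900), satfat=st.floats(0, 95), sugars=st.floats(0, 100),
    sodium=st.floats(0, 3500), fvnl=st.floats(0, 100), conc=st.booleans(),
    protein=st.floats(0, 60), fiber=st.floats(0, 25),
    bump=st.sampled_from(["energy", "sodium", "fvnl", "fiber"]),
    delta=st.floats(0.1, 50),
)
def test_monotonicity(energy, satfat, sugars, sodium, fvnl, conc, protein,
                      fiber, bump, delta):
    """More of a negative component never lowers the final score; more
    fvnl or fiber never raises it (fvnl may additionally lift the protein
    cap, lowering the score further)."""
    base = _profile(energy, satfat, sugars, sodium, fvnl, conc, protein, fiber)
    pv0 = score_food(base)
    kwargs = dict(energy=energy, satfat=satfat, sugars=sugars, sodium=sodium,
                  fvnl=fvnl, conc=conc, protein=protein, fiber=fiber)
    if bump == "fvnl":
        kwargs["fvnl"] = min(100.0, fvnl + delta)
    elif bump == "fiber":
        kwargs["fiber"] = fiber + delta
    else:
        kwargs[bump] = kwargs[bump] + delta
    pv1 = score_food(_profile(**kwargs))
    if bump in ("energy", "sodium"):
        assert pv1.baseline >= pv0.baseline
        assert pv1.final >= pv0.final
    else:
        assert pv1.final <= pv0.final
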