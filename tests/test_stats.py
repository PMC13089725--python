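"""Odds-ratio contract, frequency arithmetic and table construction."""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_episode
from smmsurv.classify import classify, profiles_frame
from smmsurv.records import PRIVATE
from smmsurv.stats import (TwoByTwo, criterion_or_table, cross_schema_ratio,
                           deaths_by_count, frequency_table,
                           known_outcome_filter, round2)


class TestTwoByTwo:
    def test_national_margin_reconstructions(self):
        # abruptio placentae against the public known-outcome margins
        t = TwoByTwo.from_margins(160, 59899, 7456, 18621293)
        assert round2(t.odds_ratio()) == 6.80
        # shock: the largest published odds ratio
        t = TwoByTwo.from_margins(269, 1006, 7456, 18621293)
        assert round2(t.odds_ratio()) == 692.78

    def test_zero_death_cell_gives_zero(self):
        assert TwoByTwo(a=0, b=12, c=7456, d=18621281).odds_ratio() == 0.0

    def test_zero_reference_cells_are_undefined(self):
        assert math.isnan(TwoByTwo(a=5, b=0, c=3, d=7).odds_ratio())
        assert math.isnan(TwoByTwo(a=5, b=3, c=0, d=7).odds_ratio())

    def test_symmetric_table_is_unity(self):
        assert TwoByTwo(a=4, b=4, c=9, d=9).odds_ratio() == 1.0

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwo(a=-1, b=1, c=1, d=1)

    @given(st.tuples(*[st.integers(1, 500)] * 4))
    @settings(max_examples=100, deadline=None)
    def test_complement_is_reciprocal(self, cells):
        t = TwoByTwo(*cells)
        assert t.complement().odds_ratio() == pytest.approx(
            1.0 / t.odds_ratio())

    def test_margins_are_conserved(self):
        t = TwoByTwo.from_margins(160, 59899, 7456, 18621293)
        assert t.deaths_total == 7456 and t.alive_total == 18621293


def test_round2_is_half_up():
    assert round2(2.225) == 2.23
    assert round2(0.005) == 0.01
    assert math.isnan(round2(float("nan")))


def _hand_profiles():
    """20-episode hand cohort with mixed criteria and outcomes."""
    spec = [
        # (icds, outcome)
        (("O141",), "DISCHARGE_ALIVE"),
        (("O141",), "DEATH"),
        (("O141", "Z513"), "DEATH"),
        (("Z513",), "DISCHARGE_ALIVE"),
        (("Z513",), "DISCHARGE_ALIVE"),
        (("O450",), "DISCHARGE_ALIVE"),
        (("O450", "O141"), "DEATH"),
        ((), "DISCHARGE_ALIVE"),
        ((), "DISCHARGE_ALIVE"),
        ((), "DEATH"),
        ((), "DISCHARGE_ALIVE"),
        ((), "DISCHARGE_ALIVE"),
        ((), "DISCHARGE_ALIVE"),
        ((), "DISCHARGE_ALIVE"),
        ((), "TRANSFER"),
        (("O141",), "STAY"),
        (("J81",), "DISCHARGE_ALIVE"),
        (("J81", "O141"), "DEATH"),
        ((), "DISCHARGE_ALIVE"),
        ((), "DISCHARGE_ALIVE"),
    ]
    from smmsurv.records import DischargeOutcome
    eps = []
    for i, (icds, outcome) in enumerate(spec):
        eps.append(make_episode(
            form_id=f"A{i}", person=f"P{i}", icds=("O800", *icds),
            outcome=DischargeOutcome(outcome)))
    return profiles_frame([classify(e) for e in eps])


class TestTables:
    def test_known_outcome_filter(self):
        frame = _hand_profiles()
        known = known_outcome_filter(frame)
        assert len(known) == 18                       # 1 TRANSFER + 1 STAY out
        assert known_outcome_filter(known).equals(known)   # idempotent

    def test_frequency_arithmetic(self, cb):
        # printed-scale checks on the exact published numbers
        assert round2(100.0 * 1600796 / 18807757) == 8.51
        assert round2(100.0 * 652396 / 1600796) == 40.75
        frame = _hand_profiles()
        freq = frequency_table(frame, n_obstetric=20, codebook=cb).set_index("name")
        assert freq.loc["severe_preeclampsia", "n_cases"] == 6
        assert freq.loc["severe_preeclampsia", "pct_hospitalizations"] == 30.0
        assert freq.loc["SMM", "n_cases"] == 10
        assert freq.loc["shock", "n_cases"] == 0
        assert freq.loc["shock", "pct_smm_cases"] == 0.0
        # group totals are episode-level unions, not column sums
        assert freq.loc["HAEMORRHAGIC", "n_cases"] == 2

    def test_or_table_matches_exhaustive_enumeration(self, cb):
        frame = _hand_profiles()
        table = criterion_or_table(frame, cb).set_index("name")
        known = known_outcome_filter(frame)
        death = known["outcome"] == "DEATH"
        for name in cb.criterion_names:      # brute-force the four cells
            member = known[name]
            a = int((member & death).sum())
            b = int((member & ~death).sum())
            c = int((~member & death).sum())
            d = int((~member & ~death).sum())
            row = table.loc[name]
            assert (row.a, row.b, row.c, row.d) == (a, b, c, d)
            expected = (a * d) / (b * c) if b and c else float("nan")
            if a == 0 and b and c:
                expected = 0.0
            assert row.odds_ratio == pytest.approx(expected, nan_ok=True)

    def test_criterion_met_by_all_is_undefined(self, cb):
        from smmsurv.records import DischargeOutcome
        eps = [make_episode(form_id=f"A{i}", person=f"P{i}",
                            icds=("O141",),
                            outcome=DischargeOutcome.DEATH if i == 0
                            else DischargeOutcome.DISCHARGE_ALIVE)
               for i in range(4)]
        table = criterion_or_table(
            profiles_frame([classify(e) for e in eps]), cb).set_index("name")
        assert math.isnan(table.loc["severe_preeclampsia", "odds_ratio"])

    def test_deaths_by_count_partitions_cohort(self):
        frame = _hand_profiles()
        dbc = deaths_by_count(frame)
        known = known_outcome_filter(frame)
        assert dbc["total"].sum() == len(known)
        assert dbc["deaths"].sum() == int((known["outcome"] == "DEATH").sum())
        assert round2(100.0 * 1186 / 190805) == 0.62   # printed-scale check
        zero = dbc.set_index("n_criteria").loc[0]
        assert zero["total"] == zero["deaths"] + zero["alive"]

    def test_cross_schema_ratio(self, cb):
        pub = pd.DataFrame({"name": ["x", "y"], "kind": ["criterion"] * 2,
                            "n_cases": [1, 1],
                            "pct_hospitalizations": [0.0557, 0.5],
                            "pct_smm_cases": [1.0, 2.0]})
        priv = pd.DataFrame({"name": ["x", "y"], "kind": ["criterion"] * 2,
                             "n_cases": [1, 0],
                             "pct_hospitalizations": [0.9447, 0.0],
                             "pct_smm_cases": [1.0, 0.0]})
        ratio = cross_schema_ratio(pub, priv).set_index("name")
        assert round2(ratio.loc["x", "ratio_pct_hospitalizations"]) == 0.06
        assert ratio.loc["x", "ratio_pct_smm_cases"] == 1.0
        assert math.isnan(ratio.loc["y", "ratio_pct_hospitalizations"])
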