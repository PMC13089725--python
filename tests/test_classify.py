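"""Criterion evaluation, derived rules and the per-episode SMM profile."""
from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_episode
from smmsurv.classify import (classify, conditional_curettage_rule,
                              evaluate_criterion, icu_rule,
                              profiles_frame, prolonged_stay_rule)
from smmsurv.records import PRIVATE


class TestEvaluateCriterion:
    @pytest.mark.parametrize("kwargs, criterion", [
        (dict(icds=("O141",)), "severe_preeclampsia"),
        (dict(procs=("0303100028",)), "eclampsia"),
        (dict(schema=PRIVATE, form_id="E1", procs=("40302016",)),
         "respiratory_failure"),
        (dict(icds=("I109",)), "severe_hypertension"),   # I10 prefix capture
        (dict(icds=("A413",)), "sepsis"),
        (dict(icds=("O459",)), "abruptio_placentae"),
    ])
    def test_triggering_codes(self, cb, kwargs, criterion):
        assert evaluate_criterion(make_episode(**kwargs), cb[criterion], cb)

    def test_episode_without_listed_codes_meets_no_criterion(self, cb):
        ep = make_episode(icds=("O800", "Z302"), procs=("0310010039",))
        assert all(not evaluate_criterion(ep, crit, cb)
                   for crit in cb.operationalized())

    def test_non_operationalized_criterion_is_an_error(self, cb):
        ep = make_episode(icds=("O141",))
        with pytest.raises(ValueError, match="not operationalized"):
            evaluate_criterion(ep, cb["hellp_syndrome"], cb)

    def test_procedure_terminology_respects_schema(self, cb):
        # a TUSS-only trigger must not fire through the public schema
        pub = make_episode(procs=())
        priv = make_episode(schema=PRIVATE, form_id="E1", procs=("20204027",))
        assert evaluate_criterion(priv, cb["shock"], cb)
        assert not evaluate_criterion(pub, cb["shock"], cb)


class TestDerivedRules:
    def test_prolonged_stay_strict_threshold(self, cb):
        nine = make_episode(procs=("0310010039",), adm="2020-03-01",
                            dis="2020-03-10")
        seven = make_episode(procs=("0310010039",), adm="2020-03-01",
                             dis="2020-03-08")
        assert prolonged_stay_rule(nine, cb)
        assert not prolonged_stay_rule(seven, cb)        # exactly 7: excluded

    def test_prolonged_stay_requires_delivery(self, cb):
        ep = make_episode(icds=("O800",), adm="2020-03-01", dis="2020-03-15")
        assert not prolonged_stay_rule(ep, cb)

    def test_prolonged_stay_newborn_care_exclusion(self, cb):
        ep = make_episode(procs=("0310010039", "0802010024"),
                          adm="2020-03-01", dis="2020-03-10")
        assert not prolonged_stay_rule(ep, cb)

    def test_icu_counter_and_codes(self, cb):
        assert icu_rule(make_episode(icu=1), cb)
        assert not icu_rule(make_episode(icu=0), cb)
        assert icu_rule(make_episode(procs=("0802010105",)), cb)
        assert icu_rule(
            make_episode(schema=PRIVATE, form_id="E1", procs=("60001038",)),
            cb)

    def test_curettage_conditional_on_childbirth_context(self, cb):
        with_delivery = make_episode(procs=("0411020013", "0310010039"))
        alone = make_episode(procs=("0411020013",))       # abortion episode
        with_puerperal = make_episode(procs=("0411020013",), icds=("O85",))
        assert conditional_curettage_rule(with_delivery, cb)
        assert not conditional_curettage_rule(alone, cb)
        assert conditional_curettage_rule(with_puerperal, cb)
        # the conditional feeds the surgical-intervention criterion
        assert evaluate_criterion(with_delivery, cb["surgical_intervention"], cb)
        assert not evaluate_criterion(alone, cb["surgical_intervention"], cb)


class TestClassify:
    def test_profile_from_two_codes(self, cb):
        prof = classify(make_episode(icds=("O150", "Z513")), cb)
        assert prof.hits == {"eclampsia", "blood_transfusion"}
        assert prof.groups == {"HYPERTENSIVE", "MANAGEMENT"}
        assert prof.n_criteria == 2 and prof.is_smm

    def test_empty_episode(self, cb):
        prof = classify(make_episode(icds=("O800",)), cb)
        assert prof.n_criteria == 0 and not prof.is_smm

    def test_ten_disjoint_triggers(self, cb):
        codes = ("O450", "O001", "O720", "O710", "O141", "O150", "I109",
                 "I674", "O85", "J81")
        prof = classify(make_episode(icds=codes), cb)
        assert prof.n_criteria == 10
        assert prof.hits == {
            "abruptio_placentae", "ectopic_pregnancy",
            "postpartum_haemorrhage", "ruptured_uterus",
            "severe_preeclampsia", "eclampsia", "severe_hypertension",
            "hypertensive_encephalopathy", "endometritis",
            "pulmonary_oedema"}

    def test_classify_agrees_with_per_criterion_evaluation(self, cb):
        pool = ["O450", "O001", "O720", "I10", "O141", "Z513", "A419",
                "R568", "E055", "O740", "J18", "O800"]
        procs = ["0310010039", "0303100028", "0702050091", "0411020013"]

        @given(icds=st.sets(st.sampled_from(pool), max_size=6),
               prs=st.sets(st.sampled_from(procs), max_size=3),
               icu=st.integers(0, 2))
        @settings(max_examples=100, deadline=None)
        def check(icds, prs, icu):
            ep = make_episode(icds=tuple(icds), procs=tuple(prs), icu=icu)
            expected = {c.name for c in cb.operationalized()
                        if evaluate_criterion(ep, c, cb)}
            assert classify(ep, cb).hits == expected

        check()

    def test_criterion_independence(self, cb):
        """Removing the only code that fires criterion X changes the profile
        in X alone."""
        with_code = classify(make_episode(icds=("O141", "Z513")), cb)
        without = classify(make_episode(icds=("Z513",)), cb)
        assert with_code.hits - without.hits == {"severe_preeclampsia"}
        assert without.hits == {"blood_transfusion"}

    def test_union_bound_and_group_union_semantics(self, cb):
        # two haemorrhagic criteria on one episode + one elsewhere
        eps = [
            make_episode(form_id="A1", icds=("O450", "O720")),
            make_episode(form_id="A2", icds=("O141",)),
            make_episode(form_id="A3", icds=("O800",)),
        ]
        frame = profiles_frame([classify(e, cb) for e in eps], cb)
        n_smm = int(frame["is_smm"].sum())
        sum_criteria = int(frame[cb.criterion_names].to_numpy().sum())
        assert n_smm == 2 and sum_criteria == 3      # union bound is strict
        haem = [n for n in cb.criterion_names
                if cb.group_of[n] == "HAEMORRHAGIC"]
        assert int(frame[haem].any(axis=1).sum()) == 1   # episode-level union

    def test_profiles_frame_shape(self, cb):
        frame = profiles_frame([], cb)
        assert list(frame.columns[2:-3]) == cb.criterion_names
        assert frame.empty
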