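"""Episode assembly: chaining rule, transitivity, partition, outcome."""
from __future__ import annotations

from datetime import date, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import ALIVE, DEATH, STAY, TRANSFER, make_record
from smmsurv.episodes import EpisodeError, assemble_episodes, episode_outcome
from smmsurv.records import PRIVATE, PUBLIC


def test_same_day_handoff_chains():
    a = make_record(form_id="A1", adm="2020-03-01", dis="2020-03-05",
                    outcome=STAY)
    b = make_record(form_id="A2", adm="2020-03-05", dis="2020-03-09")
    (ep,) = assemble_episodes([a, b])
    assert len(ep.member_forms) == 2
    assert ep.admission_date == date(2020, 3, 1)
    assert ep.discharge_date == date(2020, 3, 9)


def test_gap_beyond_threshold_splits():
    a = make_record(form_id="A1", adm="2020-03-01", dis="2020-03-05",
                    outcome=ALIVE)
    b = make_record(form_id="A2", adm="2020-03-09", dis="2020-03-12")
    assert len(assemble_episodes([a, b])) == 2           # gap 4 > default 1
    assert len(assemble_episodes([a, b], max_gap_days=4)) == 1


def test_three_form_transitive_chain():
    a = make_record(form_id="A1", adm="2020-03-01", dis="2020-03-03",
                    outcome=STAY)
    b = make_record(form_id="A2", adm="2020-03-03", dis="2020-03-06",
                    outcome=STAY)
    c = make_record(form_id="A3", adm="2020-03-06", dis="2020-03-10")
    (ep,) = assemble_episodes([c, a, b])                 # input order irrelevant
    assert [m.form_id for m in ep.member_forms] == ["A1", "A2", "A3"]


def test_different_person_or_hospital_never_chains():
    a = make_record(form_id="A1", dis="2020-03-04")
    b = make_record(form_id="A2", person="P2", adm="2020-03-04")
    c = make_record(form_id="A3", hospital="H2", adm="2020-03-04")
    assert len(assemble_episodes([a, b, c])) == 3


def test_private_records_pass_through_one_to_one():
    records = [make_record(schema=PRIVATE, form_id=f"E{i}",
                           adm="2020-03-01", dis="2020-03-01")
               for i in range(4)]
    episodes = assemble_episodes(records)
    assert [ep.member_forms for ep in episodes] == [(r,) for r in records]


def test_missing_keys_yield_flagged_singletons():
    rec = make_record(person=None)
    (ep,) = assemble_episodes([rec])
    assert ep.flagged and ep.member_forms == (rec,)


def test_singleton_reproduces_record_fields():
    rec = make_record(icds=("O800", "O141"), procs=("0310010039",), icu=3,
                      outcome=DEATH)
    (ep,) = assemble_episodes([rec])
    assert ep.admission_date == rec.admission_date
    assert ep.discharge_date == rec.discharge_date
    assert ep.icu_days == rec.icu_days
    assert ep.diagnoses == rec.diagnoses
    assert ep.procedures == rec.procedures
    assert ep.outcome is DEATH


def test_episode_fields_aggregate_over_members():
    a = make_record(form_id="A1", adm="2020-03-01", dis="2020-03-05",
                    icds=("O800",), icu=2, outcome=TRANSFER)
    b = make_record(form_id="A2", adm="2020-03-05", dis="2020-03-09",
                    icds=("O800", "O150"), procs=("0303100028",), icu=3,
                    outcome=DEATH)
    (ep,) = assemble_episodes([a, b])
    assert ep.icu_days == 5
    assert ep.diagnosis_codes == {"O800", "O150"}       # union, deduplicated
    assert ep.procedure_codes == {"0303100028"}
    assert ep.outcome is DEATH                          # final member's


def test_death_on_non_final_form_is_invalid():
    a = make_record(form_id="A1", adm="2020-03-01", dis="2020-03-05",
                    outcome=DEATH)
    b = make_record(form_id="A2", adm="2020-03-05", dis="2020-03-09")
    (ep,) = assemble_episodes([a, b])
    with pytest.raises(EpisodeError, match="non-final"):
        episode_outcome(ep)


# ---------------------------------------------------------------------------
# brute-force oracle: transitive closure of the pairwise chaining rule
# ---------------------------------------------------------------------------

def _oracle_partition(records, max_gap):
    """Union-find over all record pairs under the pairwise rule."""
    parent = list(range(len(records)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, a in enumerate(records):
        for j, b in enumerate(records):
            if i >= j:
                continue
            early, late = (a, b) if a.admission_date <= b.admission_date \
                else (b, a)
            if (a.person_key == b.person_key
                    and a.hospital_key == b.hospital_key
                    and (late.admission_date - early.discharge_date).days
                    <= max_gap):
                parent[find(i)] = find(j)
    groups = {}
    for i in range(len(records)):
        groups.setdefault(find(i), set()).add(records[i].form_id)
    return sorted(map(frozenset, groups.values()), key=sorted)


@st.composite
def record_sets(draw):
    n = draw(st.integers(1, 10))
    records = []
    for i in range(n):
        start = draw(st.integers(0, 12))
        length = draw(st.integers(0, 5))
        records.append(make_record(
            form_id=f"A{i}",
            person=f"P{draw(st.integers(1, 3))}",
            hospital=f"H{draw(st.integers(1, 2))}",
            adm=(date(2020, 3, 1) + timedelta(days=start)).isoformat(),
            dis=(date(2020, 3, 1) + timedelta(days=start + length)).isoformat(),
            outcome=STAY))
    return records, draw(st.integers(0, 3))


@given(record_sets())
@settings(max_examples=150, deadline=None)
def test_assembly_matches_brute_force_closure(case):
    records, max_gap = case
    episodes = assemble_episodes(records, max_gap_days=max_gap)
    got = sorted((frozenset(m.form_id for m in ep.member_forms)
                  for ep in episodes), key=sorted)
    assert got == _oracle_partition(records, max_gap)
    # partition invariant: every record in exactly one episode
    assert sum(len(ep.member_forms) for ep in episodes) == len(records)


@given(record_sets())
@settings(max_examples=80, deadline=None)
def test_widening_gap_never_increases_episode_count(case):
    records, max_gap = case
    n_tight = len(assemble_episodes(records, max_gap_days=max_gap))
    n_loose = len(assemble_episodes(records, max_gap_days=max_gap + 2))
    assert n_loose <= n_tight
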