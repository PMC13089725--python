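"""Per-episode evaluation of the operationalized SMM (PLTC) criteria.

A criterion fires when any episode diagnosis matches its ICD set, any
procedure act matches the schema's procedure set, or its derived rule holds.
Three criteria carry derived rules that cannot be expressed as plain code
sets:

* prolonged stay — a delivery episode staying strictly more than 7 days
  (public schema: excluding episodes billed for newborn care);
* ICU admission — the public schema's ICU-days counter, in addition to the
  ICU procedure codes of either terminology;
* surgical intervention — the public curettage code counts only when the
  episode is a delivery or carries a puerperal-complication diagnosis
  (post-abortion curettage alone is not a severity marker).
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .codebook import Codebook, CriterionDefinition, default_codebook
from .episodes import EpisodeOfCare
from .records import PUBLIC, DischargeOutcome

__all__ = [
    "SMMProfile",
    "evaluate_criterion",
    "prolonged_stay_rule",
    "icu_rule",
    "conditional_curettage_rule",
    "classify",
    "classify_episodes",
    "profiles_frame",
]


@dataclass(frozen=True)
class SMMProfile:
    """Classification result for one obstetric episode."""

    episode_id: str
    schema: str
    hits: frozenset[str]
    groups: frozenset[str]
    outcome: DischargeOutcome

    @property
    def n_criteria(self) -> int:
        return len(self.hits)

    @property
    def is_smm(self) -> bool:
        return self.n_criteria >= 1


def _has_delivery(episode: EpisodeOfCare, cb: Codebook) -> bool:
    subset = cb.delivery_sigtap if episode.schema == PUBLIC else cb.delivery_tuss
    return not episode.procedure_codes.isdisjoint(subset)


def prolonged_stay_rule(episode: EpisodeOfCare,
                        codebook: Codebook | None = None) -> bool:
    """Delivery episode with a stay strictly longer than the threshold.

    Public-schema episodes billed for newborn care are excluded: their long
    stay reflects the infant, not maternal morbidity.
    """
    cb = codebook or default_codebook()
    if not _has_delivery(episode, cb):
        return False
    if episode.stay_days <= cb.prolonged_stay_days:
        return False
    if episode.schema == PUBLIC and \
            cb.newborn_care_sigtap in episode.procedure_codes:
        return False
    return True


def icu_rule(episode: EpisodeOfCare, codebook: Codebook | None = None) -> bool:
    """ICU admission: days-in-ICU counter (public) or ICU procedure codes."""
    cb = codebook or default_codebook()
    crit = cb["icu_admission"]
    if episode.schema == PUBLIC:
        if episode.icu_days > 0:
            return True
        return not episode.procedure_codes.isdisjoint(crit.sigtap_set)
    return not episode.procedure_codes.isdisjoint(crit.tuss_set)


def conditional_curettage_rule(episode: EpisodeOfCare,
                               codebook: Codebook | None = None) -> bool:
    """Curettage counts toward surgical intervention only in a childbirth or
    puerperal-complication context (the code itself does not distinguish
    post-abortion from puerperal curettage)."""
    cb = codebook or default_codebook()
    if cb.curettage_sigtap not in episode.procedure_codes:
        return False
    if _has_delivery(episode, cb):
        return True
    return any(cb.puerperal_icd.matches(code)
               for code in episode.diagnosis_codes)


_DERIVED_DISPATCH = {
    "PROLONGED_STAY": prolonged_stay_rule,
    "ICU_DAYS_COUNTER": icu_rule,
    "CONDITIONAL_CURETTAGE": conditional_curettage_rule,
}


def evaluate_criterion(episode: EpisodeOfCare, criterion: CriterionDefinition,
                       codebook: Codebook | None = None) -> bool:
    """True iff the criterion fires on the episode (code sets or derived rule).

    Raises ``ValueError`` for a non-operationalized criterion: those four are
    declared in the registry but have no observable signature in either
    schema, and silently returning False would misread absence of evidence.
    """
    if not criterion.operationalized:
        raise ValueError(
            f"criterion {criterion.name!r} is not operationalized")
    cb = codebook or default_codebook()
    if any(criterion.icd_set.matches(code)
           for code in episode.diagnosis_codes):
        return True
    procs = criterion.procedure_set(episode.schema)
    # the curettage code is governed by the conditional rule, not plain match
    if episode.schema == PUBLIC and criterion.derived_rule == "CONDITIONAL_CURETTAGE":
        procs = procs - {cb.curettage_sigtap}
    if not episode.procedure_codes.isdisjoint(procs):
        return True
    if criterion.derived_rule is not None:
        return _DERIVED_DISPATCH[criterion.derived_rule](episode, cb)
    return False


def classify(episode: EpisodeOfCare,
             codebook: Codebook | None = None) -> SMMProfile:
    """Evaluate all operationalized criteria; deterministic, order-independent."""
    cb = codebook or default_codebook()
    hits: set[str] = set()
    for code in episode.diagnosis_codes:
        hits |= cb.criteria_for_icd(code)
    terminology = episode.member_forms[0].terminology
    for code in episode.procedure_codes:
        hits |= cb.criteria_for_procedure(code, terminology)
    for crit in cb.operationalized():
        if crit.derived_rule is not None and crit.name not in hits:
            if _DERIVED_DISPATCH[crit.derived_rule](episode, cb):
                hits.add(crit.name)
    group_of = cb.group_of
    return SMMProfile(
        episode_id=episode.episode_id,
        schema=episode.schema,
        hits=frozenset(hits),
        groups=frozenset(group_of[name] for name in hits),
        outcome=episode.outcome,
    )


def classify_episodes(episodes, codebook: Codebook | None = None
                      ) -> list[SMMProfile]:
    cb = codebook or default_codebook()
    return [classify(ep, cb) for ep in episodes]


def profiles_frame(profiles, codebook: Codebook | None = None) -> pd.DataFrame:
    """Tabulate profiles: one boolean column per criterion, plus counters.

    This is the interchange table consumed by the statistics layer and the
    CSV the `classify` CLI subcommand emits.
    """
    cb = codebook or default_codebook()
    names = cb.criterion_names
    rows = []
    for prof in profiles:
        row = {"episode_id": prof.episode_id, "schema": prof.schema}
        row.update({name: name in prof.hits for name in names})
        row["n_criteria"] = prof.n_criteria
        row["is_smm"] = prof.is_smm
        row["outcome"] = prof.outcome.value
        rows.append(row)
    columns = ["episode_id", "schema", *names, "n_criteria", "is_smm", "outcome"]
    frame = pd.DataFrame(rows, columns=columns)
    if frame.empty:
        frame = frame.astype({name: bool for name in names} |
                             {"n_criteria": int, "is_smm": bool})
    return frame
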