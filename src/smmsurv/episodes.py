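"""Episode-of-care assembly: grouping admission forms into hospitalizations.

In the public schema a single continuous hospitalization can generate more
than one admission form (e.g. a continuation form when care changes from
clinical to surgical mid-stay).  The national linkage algorithm behind the
published episode construction is not reproducible from its description, so
this module implements a documented replacement heuristic: two forms chain
into the same episode when they share the person key and hospital key and
the later admission starts no more than ``max_gap_days`` after the earlier
discharge (default 1 day, i.e. same-day or next-day continuation; an
overlapping stay also chains).  Chaining is transitive.

Private-schema events cannot be linked (the source lacks both the facility
number and the person's date of birth) and always pass through one-to-one.
"""
from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from functools import cached_property
from typing import Iterable, Sequence

from .codebook import IcdCode, ProcedureCode
from .records import PRIVATE, PUBLIC, AdmissionRecord, DischargeOutcome

__all__ = ["EpisodeOfCare", "EpisodeError", "assemble_episodes", "episode_outcome"]


class EpisodeError(ValueError):
    """Raised for structurally invalid episodes (e.g. death mid-episode)."""


def _member_sort_key(rec: AdmissionRecord):
    return (rec.admission_date, rec.discharge_date, rec.form_id)


@dataclass(frozen=True)
class EpisodeOfCare:
    """One hospitalization episode (1+ admission forms, same stay)."""

    episode_id: str
    schema: str
    member_forms: tuple[AdmissionRecord, ...]
    flagged: bool = False

    def __post_init__(self):
        if not self.member_forms:
            raise EpisodeError("episode with no member forms")
        ordered = tuple(sorted(self.member_forms, key=_member_sort_key))
        object.__setattr__(self, "member_forms", ordered)

    @property
    def admission_date(self) -> date:
        return min(m.admission_date for m in self.member_forms)

    @property
    def discharge_date(self) -> date:
        return max(m.discharge_date for m in self.member_forms)

    @property
    def icu_days(self) -> int:
        return sum(m.icu_days for m in self.member_forms)

    @property
    def stay_days(self) -> int:
        return (self.discharge_date - self.admission_date).days

    @cached_property
    def diagnoses(self) -> tuple[tuple[str, IcdCode], ...]:
        """Union of member diagnoses, field provenance kept, first-seen order."""
        seen, out = set(), []
        for member in self.member_forms:
            for fname, code in member.diagnoses:
                key = (fname, code.normalized if code.valid else code.raw)
                if key not in seen:
                    seen.add(key)
                    out.append((fname, code))
        return tuple(out)

    @cached_property
    def procedures(self) -> tuple[ProcedureCode, ...]:
        seen, out = set(), []
        for member in self.member_forms:
            for proc in member.procedures:
                key = (proc.terminology, proc.normalized or proc.raw)
                if key not in seen:
                    seen.add(key)
                    out.append(proc)
        return tuple(out)

    @cached_property
    def diagnosis_codes(self) -> frozenset[str]:
        return frozenset(
            c.normalized for _, c in self.diagnoses if c.valid)

    @cached_property
    def procedure_codes(self) -> frozenset[str]:
        return frozenset(p.normalized for p in self.procedures if p.valid)

    @property
    def type_of_hospitalization(self) -> str | None:
        return self.member_forms[0].type_of_hospitalization

    @cached_property
    def outcome(self) -> DischargeOutcome:
        return episode_outcome(self)


def episode_outcome(episode: EpisodeOfCare) -> DischargeOutcome:
    """Outcome of the chronologically last member form.

    A non-final member recorded as DEATH is structurally impossible (care
    cannot continue after in-hospital death) and raises ``EpisodeError``.
    A final STAY/TRANSFER/UNKNOWN leaves the episode with unknown outcome.
    """
    members = episode.member_forms
    for member in members[:-1]:
        if member.discharge_reason is DischargeOutcome.DEATH:
            raise EpisodeError(
                f"episode {episode.episode_id}: DEATH on non-final form "
                f"{member.form_id}")
    return members[-1].discharge_reason


def assemble_episodes(
    records: Iterable[AdmissionRecord],
    max_gap_days: int = 1,
    require_same_hospital: bool = True,
) -> list[EpisodeOfCare]:
    """Partition admission records into episodes of care.

    Public records chain transitively when they share person and hospital
    keys and the inter-form gap (next admission minus previous discharge)
    is at most ``max_gap_days``; records lacking either key become flagged
    singletons.  Private records always yield singleton episodes.  Every
    input record belongs to exactly one episode.
    """
    episodes: list[EpisodeOfCare] = []
    chainable: dict[tuple, list[AdmissionRecord]] = {}
    for rec in records:
        if rec.schema == PRIVATE:
            episodes.append(EpisodeOfCare(rec.form_id, PRIVATE, (rec,)))
        elif rec.person_key is None or (
                require_same_hospital and rec.hospital_key is None):
            episodes.append(
                EpisodeOfCare(rec.form_id, PUBLIC, (rec,), flagged=True))
        else:
            key = (rec.person_key, rec.hospital_key if require_same_hospital
                   else None)
            chainable.setdefault(key, []).append(rec)

    for key in sorted(chainable):
        group = sorted(chainable[key], key=_member_sort_key)
        current: list[AdmissionRecord] = [group[0]]
        reach = group[0].discharge_date  # latest discharge in the chain
        for rec in group[1:]:
            if (rec.admission_date - reach).days <= max_gap_days:
                current.append(rec)
                reach = max(reach, rec.discharge_date)
            else:
                episodes.append(
                    EpisodeOfCare(current[0].form_id, PUBLIC, tuple(current)))
                current = [rec]
                reach = rec.discharge_date
        episodes.append(
            EpisodeOfCare(current[0].form_id, PUBLIC, tuple(current)))
    return episodes
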