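"""Identification of obstetric hospitalizations, per schema.

Public schema: there is no type-of-hospitalization field, so an episode is
obstetric when any diagnosis field carries a pregnancy/childbirth/puerperium
code (ICD-10 chapter O) or any procedure act is on the obstetric SIGTAP list.

Private schema: the type-of-hospitalization field exists (3 = obstetric) but
is unreliable on its own — newborn admissions in the first days of life are
often billed under the insured woman's event, and obstetric admissions for
abortion or cesarean are under-typed.  The rule therefore combines three
clauses:

(a) type 3, unless some diagnosis is a perinatal (chapter P) code outside
    the maternal-relevant allow-list — that veto flags a neonatal admission
    billed under the mother;
(b) a triggering diagnosis (chapter O, antenatal screening Z34-Z39, or a
    chapter-P allow-list code) in any ICD field, provided the admission is
    not typed pediatric;
(c) any procedure on the obstetric TUSS list.

Because ~30% of private-schema records carry no ICD at all, clause (a) must
fire on type alone when the diagnosis fields are empty.
"""
from __future__ import annotations

from .codebook import Codebook, default_codebook
from .episodes import EpisodeOfCare
from .records import PRIVATE, PUBLIC

__all__ = ["is_obstetric_public", "is_obstetric_private", "is_obstetric"]


def is_obstetric_public(episode: EpisodeOfCare,
                        codebook: Codebook | None = None) -> bool:
    if episode.schema != PUBLIC:
        raise ValueError("is_obstetric_public expects a PUBLIC episode")
    cb = codebook or default_codebook()
    rules = cb.obstetric
    if any(rules.public_icd.matches(code) for code in episode.diagnosis_codes):
        return True
    return not episode.procedure_codes.isdisjoint(rules.public_sigtap)


def is_obstetric_private(episode: EpisodeOfCare,
                         codebook: Codebook | None = None) -> bool:
    if episode.schema != PRIVATE:
        raise ValueError("is_obstetric_private expects a PRIVATE episode")
    cb = codebook or default_codebook()
    rules = cb.obstetric
    diagnoses = episode.diagnosis_codes
    hosp_type = episode.type_of_hospitalization

    # (a) typed obstetric, vetoed by an off-allow-list perinatal code
    if hosp_type == rules.obstetric_type_code:
        neonatal = any(
            code.startswith("P") and not rules.p_allowlist.matches(code)
            for code in diagnoses)
        if not neonatal:
            return True
    # (b) triggering diagnosis, unless typed pediatric
    if hosp_type != rules.pediatric_type_code:
        for code in diagnoses:
            if rules.private_icd.matches(code) or (
                    code.startswith("P") and rules.p_allowlist.matches(code)):
                return True
    # (c) obstetric procedure
    return not episode.procedure_codes.isdisjoint(rules.private_tuss)


def is_obstetric(episode: EpisodeOfCare,
                 codebook: Codebook | None = None) -> bool:
    """Schema-dispatching wrapper."""
    if episode.schema == PUBLIC:
        return is_obstetric_public(episode, codebook)
    return is_obstetric_private(episode, codebook)
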