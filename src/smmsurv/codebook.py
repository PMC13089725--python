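"""Versioned registry of ICD-10 and procedure code sets for SMM surveillance.

The registry holds the operational definitions of the WHO potentially
life-threatening condition (PLTC) criteria for two administrative
hospitalization dialects: the Brazilian public schema (SIGTAP procedure
terminology, fixed-width 10-digit codes) and the private schema (TUSS
terminology, 8-digit codes).  It ships as an editable YAML document so that
alternative operationalizations can be loaded without touching code.

Matching semantics
------------------
ICD-10 entries come in three flavours:

* 4-character entries (``O450``) match a recorded code exactly;
* 3-character entries (``O45``) act as category prefixes and match any
  recorded code sharing the prefix;
* range entries (``Z34-Z39``) match any code whose 3-character prefix sorts
  within the inclusive range (4-character bounds restrict the 4th character).

Procedure codes are plain digit strings: SIGTAP codes are left-zero-padded
to 10 digits after separator removal, TUSS codes to 8 digits.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping

import yaml

__all__ = [
    "GROUPS",
    "SIGTAP",
    "TUSS",
    "CodebookError",
    "IcdCode",
    "IcdCodeSet",
    "ProcedureCode",
    "CriterionDefinition",
    "ObstetricRuleSet",
    "Codebook",
    "normalize_icd",
    "normalize_procedure",
    "default_codebook",
]

GROUPS = ("HAEMORRHAGIC", "HYPERTENSIVE", "OTHER_SYSTEMIC", "MANAGEMENT")
DERIVED_RULES = ("PROLONGED_STAY", "ICU_DAYS_COUNTER", "CONDITIONAL_CURETTAGE")

SIGTAP = "SIGTAP"
TUSS = "TUSS"
_PROC_WIDTH = {SIGTAP: 10, TUSS: 8}

_ICD_RE = re.compile(r"^[A-Z][0-9]{2}[0-9]?$")
_NON_ALNUM_RE = re.compile(r"[^A-Za-z0-9]")
_NON_DIGIT_RE = re.compile(r"[^0-9]")


class CodebookError(ValueError):
    """Raised for invalid codebook documents or invariant violations."""


def normalize_icd(raw: str) -> str | None:
    """Normalize a recorded ICD-10 code; ``None`` flags a malformed value.

    Uppercases and strips dots/whitespace, then validates against the
    letter + 2 digits + optional digit pattern.  Malformed codes are never
    silently matched downstream.

    >>> normalize_icd("O45.0")
    'O450'
    >>> normalize_icd("Z999X") is None
    True
    """
    if raw is None:
        return None
    cleaned = _NON_ALNUM_RE.sub("", str(raw)).upper()
    if not cleaned:
        return None
    return cleaned if _ICD_RE.fullmatch(cleaned) else None


def normalize_procedure(raw: str, terminology: str) -> str | None:
    """Canonical fixed-width digit string for a procedure code, or ``None``.

    Separators (dots, dashes, spaces) are removed and the result is
    left-zero-padded to the terminology's width (SIGTAP 10, TUSS 8).
    Codes with fewer than 7 digits, or more than the width, are flagged
    invalid.
    """
    width = _PROC_WIDTH[terminology]
    if raw is None:
        return None
    digits = _NON_DIGIT_RE.sub("", str(raw))
    if len(digits) < 7 or len(digits) > width:
        return None
    return digits.zfill(width)


@dataclass(frozen=True)
class IcdCode:
    """A recorded ICD-10 value with its normalized form (``None`` = invalid)."""

    raw: str
    normalized: str | None = field(default=None)

    @staticmethod
    def parse(raw: str) -> "IcdCode":
        return IcdCode(raw=raw, normalized=normalize_icd(raw))

    @property
    def valid(self) -> bool:
        return self.normalized is not None


@dataclass(frozen=True)
class ProcedureCode:
    """A recorded procedure act in a specific terminology."""

    raw: str
    terminology: str
    normalized: str | None = field(default=None)

    @staticmethod
    def parse(raw: str, terminology: str) -> "ProcedureCode":
        if terminology not in _PROC_WIDTH:
            raise CodebookError(f"unknown procedure terminology: {terminology!r}")
        return ProcedureCode(raw=raw, terminology=terminology,
                             normalized=normalize_procedure(raw, terminology))

    @property
    def valid(self) -> bool:
        return self.normalized is not None


class IcdCodeSet:
    """A set of ICD-10 entries with exact / prefix / range semantics."""

    __slots__ = ("entries", "_exact", "_prefix", "_ranges")

    def __init__(self, entries: Iterable[str] = ()):
        self.entries: tuple[str, ...] = tuple(entries)
        self._exact: set[str] = set()
        self._prefix: set[str] = set()
        self._ranges: list[tuple[str, str]] = []
        for entry in self.entries:
            entry = str(entry).strip().upper()
            if "-" in entry:
                lo, _, hi = entry.partition("-")
                lo, hi = lo.strip(), hi.strip()
                if not (_ICD_RE.fullmatch(lo) and _ICD_RE.fullmatch(hi)) or lo > hi:
                    raise CodebookError(f"malformed ICD range entry: {entry!r}")
                self._ranges.append((lo, hi))
            else:
                norm = normalize_icd(entry)
                if norm is None:
                    raise CodebookError(f"malformed ICD entry: {entry!r}")
                if len(norm) == 3:
                    self._prefix.add(norm)
                else:
                    self._exact.add(norm)

    def __bool__(self) -> bool:
        return bool(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, IcdCodeSet) and self.entries == other.entries

    def __repr__(self) -> str:  # pragma: no cover
        return f"IcdCodeSet({list(self.entries)!r})"

    def matches(self, code: str | None) -> bool:
        """True iff a normalized code matches any entry."""
        if not code:
            return False
        stem = code[:3]
        if code in self._exact or stem in self._prefix:
            return True
        for lo, hi in self._ranges:
            if not lo[:3] <= stem <= hi[:3]:
                continue
            if len(lo) == 3 and len(hi) == 3:
                return True
            # 4-character bounds restrict the 4th character at the edges;
            # a 3-character recorded code matches on its stem alone.
            if len(code) == 3 or lo <= code <= hi:
                return True
            if lo[:3] < stem < hi[:3]:
                return True
        return False

    def index_keys(self) -> tuple[set[str], set[str]]:
        """(exact 4-char keys, 3-char prefix keys) for reverse indexing.

        Only valid for sets without range entries (criterion sets).
        """
        if self._ranges:
            raise CodebookError("range entries cannot be reverse-indexed")
        return set(self._exact), set(self._prefix)


def _procset(raw: Iterable[str] | None, terminology: str, where: str) -> frozenset[str]:
    out = set()
    for code in raw or ():
        norm = normalize_procedure(code, terminology)
        if norm is None:
            raise CodebookError(f"malformed {terminology} code {code!r} in {where}")
        out.add(norm)
    return frozenset(out)


@dataclass(frozen=True)
class CriterionDefinition:
    """One PLTC criterion: its group, code sets and optional derived rule."""

    name: str
    label: str
    group: str
    icd_set: IcdCodeSet = field(default_factory=IcdCodeSet)
    sigtap_set: frozenset[str] = frozenset()
    tuss_set: frozenset[str] = frozenset()
    derived_rule: str | None = None
    operationalized: bool = True

    def procedure_set(self, schema: str) -> frozenset[str]:
        from .records import PUBLIC  # local import avoids a cycle

        return self.sigtap_set if schema == PUBLIC else self.tuss_set


@dataclass(frozen=True)
class ObstetricRuleSet:
    """Per-schema rules identifying obstetric hospitalizations."""

    public_icd: IcdCodeSet
    public_sigtap: frozenset[str]
    private_icd: IcdCodeSet
    p_allowlist: IcdCodeSet
    private_tuss: frozenset[str]
    obstetric_type_code: str = "3"
    pediatric_type_code: str = "4"


class Codebook:
    """Full registry: criteria, obstetric rules and derived-rule parameters."""

    def __init__(
        self,
        criteria: Mapping[str, CriterionDefinition],
        obstetric: ObstetricRuleSet,
        delivery_sigtap: frozenset[str],
        delivery_tuss: frozenset[str],
        prolonged_stay_days: int,
        newborn_care_sigtap: str,
        curettage_sigtap: str,
        puerperal_icd: IcdCodeSet,
        version: str = "unversioned",
    ):
        self.criteria: dict[str, CriterionDefinition] = dict(criteria)
        self.obstetric = obstetric
        self.delivery_sigtap = delivery_sigtap
        self.delivery_tuss = delivery_tuss
        self.prolonged_stay_days = prolonged_stay_days
        self.newborn_care_sigtap = newborn_care_sigtap
        self.curettage_sigtap = curettage_sigtap
        self.puerperal_icd = puerperal_icd
        self.version = version
        self.validate()
        self._build_indexes()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        if len(self.criteria) != 26:
            raise CodebookError(
                f"registry must define 26 criteria, got {len(self.criteria)}")
        non_op = [c for c in self.criteria.values() if not c.operationalized]
        if len(non_op) != 4:
            raise CodebookError(
                f"exactly 4 criteria must be non-operationalized, got {len(non_op)}")
        expected = {"HAEMORRHAGIC": 4, "HYPERTENSIVE": 4,
                    "OTHER_SYSTEMIC": 7, "MANAGEMENT": 7}
        counts: dict[str, int] = {g: 0 for g in GROUPS}
        for c in self.criteria.values():
            if c.group not in GROUPS:
                raise CodebookError(f"unknown group {c.group!r} ({c.name})")
            if c.derived_rule is not None and c.derived_rule not in DERIVED_RULES:
                raise CodebookError(f"unknown derived rule {c.derived_rule!r}")
            if c.operationalized:
                counts[c.group] += 1
                if not (c.icd_set or c.sigtap_set or c.tuss_set or c.derived_rule):
                    raise CodebookError(f"criterion {c.name} has no trigger")
        if counts != expected:
            raise CodebookError(
                f"operationalized group counts {counts} != {expected}")

    # -- reverse indexes for fast classification ---------------------------
    def _build_indexes(self) -> None:
        self._icd_exact: dict[str, set[str]] = {}
        self._icd_prefix: dict[str, set[str]] = {}
        self._proc_index: dict[str, dict[str, set[str]]] = {SIGTAP: {}, TUSS: {}}
        for crit in self.operationalized():
            exact, prefix = crit.icd_set.index_keys()
            for key in exact:
                self._icd_exact.setdefault(key, set()).add(crit.name)
            for key in prefix:
                self._icd_prefix.setdefault(key, set()).add(crit.name)
            for term, codes in ((SIGTAP, crit.sigtap_set), (TUSS, crit.tuss_set)):
                index = self._proc_index[term]
                for code in codes:
                    index.setdefault(code, set()).add(crit.name)
        # the curettage code only counts under the conditional rule
        self._proc_index[SIGTAP].pop(self.curettage_sigtap, None)

    def criteria_for_icd(self, code: str | None) -> set[str]:
        """Names of operationalized criteria whose ICD set matches ``code``."""
        if not code:
            return set()
        hits = set(self._icd_exact.get(code, ()))
        hits.update(self._icd_prefix.get(code[:3], ()))
        return hits

    def criteria_for_procedure(self, code: str | None, terminology: str) -> set[str]:
        if not code:
            return set()
        return set(self._proc_index[terminology].get(code, ()))

    # -- accessors ---------------------------------------------------------
    def operationalized(self) -> list[CriterionDefinition]:
        return [c for c in self.criteria.values() if c.operationalized]

    @property
    def criterion_names(self) -> list[str]:
        """Operationalized criterion names, in registry (table) order."""
        return [c.name for c in self.operationalized()]

    @property
    def group_of(self) -> dict[str, str]:
        return {c.name: c.group for c in self.criteria.values()}

    def __getitem__(self, name: str) -> CriterionDefinition:
        return self.criteria[name]

    # -- (de)serialization -------------------------------------------------
    @classmethod
    def from_dict(cls, doc: Mapping) -> "Codebook":
        try:
            rules = doc["obstetric_rules"]
            crit_doc = doc["criteria"]
        except KeyError as exc:
            raise CodebookError(f"missing section {exc}") from exc
        criteria: dict[str, CriterionDefinition] = {}
        for name, spec in crit_doc.items():
            if name in criteria:
                raise CodebookError(f"duplicate criterion name {name!r}")
            criteria[name] = CriterionDefinition(
                name=name,
                label=spec.get("label", name),
                group=spec.get("group", ""),
                icd_set=IcdCodeSet(spec.get("icd", ())),
                sigtap_set=_procset(spec.get("sigtap"), SIGTAP, name),
                tuss_set=_procset(spec.get("tuss"), TUSS, name),
                derived_rule=spec.get("derived_rule"),
                operationalized=bool(spec.get("operationalized", True)),
            )
        pub, priv = rules["public"], rules["private"]
        obstetric = ObstetricRuleSet(
            public_icd=IcdCodeSet(pub.get("icd", ())),
            public_sigtap=_procset(pub.get("sigtap"), SIGTAP, "obstetric/public"),
            private_icd=IcdCodeSet(priv.get("icd", ())),
            p_allowlist=IcdCodeSet(priv.get("p_allowlist", ())),
            private_tuss=_procset(priv.get("tuss"), TUSS, "obstetric/private"),
            obstetric_type_code=str(priv.get("obstetric_type_code", "3")),
            pediatric_type_code=str(priv.get("pediatric_type_code", "4")),
        )
        delivery = doc.get("delivery_procedures", {})
        params = doc.get("derived_rule_params", {})
        pls = params.get("prolonged_stay", {})
        cur = params.get("conditional_curettage", {})
        return cls(
            criteria=criteria,
            obstetric=obstetric,
            delivery_sigtap=_procset(delivery.get("sigtap"), SIGTAP, "delivery"),
            delivery_tuss=_procset(delivery.get("tuss"), TUSS, "delivery"),
            prolonged_stay_days=int(pls.get("min_days_exclusive", 7)),
            newborn_care_sigtap=normalize_procedure(
                pls.get("newborn_care_sigtap", "0802010024"), SIGTAP),
            curettage_sigtap=normalize_procedure(
                cur.get("curettage_sigtap", "0411020013"), SIGTAP),
            puerperal_icd=IcdCodeSet(cur.get("puerperal_icd", ("O85-O92",))),
            version=str(doc.get("version", "unversioned")),
        )

    @classmethod
    def from_yaml(cls, path) -> "Codebook":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.load(fh, Loader=_StrictLoader))

    def to_dict(self) -> dict:
        crit_doc = {}
        for c in self.criteria.values():
            spec: dict = {"label": c.label, "group": c.group}
            if c.icd_set:
                spec["icd"] = list(c.icd_set.entries)
            if c.sigtap_set:
                spec["sigtap"] = sorted(c.sigtap_set)
            if c.tuss_set:
                spec["tuss"] = sorted(c.tuss_set)
            if c.derived_rule:
                spec["derived_rule"] = c.derived_rule
            if not c.operationalized:
                spec["operationalized"] = False
            crit_doc[c.name] = spec
        return {
            "version": self.version,
            "obstetric_rules": {
                "public": {
                    "icd": list(self.obstetric.public_icd.entries),
                    "sigtap": sorted(self.obstetric.public_sigtap),
                },
                "private": {
                    "obstetric_type_code": self.obstetric.obstetric_type_code,
                    "pediatric_type_code": self.obstetric.pediatric_type_code,
                    "icd": list(self.obstetric.private_icd.entries),
                    "p_allowlist": list(self.obstetric.p_allowlist.entries),
                    "tuss": sorted(self.obstetric.private_tuss),
                },
            },
            "delivery_procedures": {
                "sigtap": sorted(self.delivery_sigtap),
                "tuss": sorted(self.delivery_tuss),
            },
            "derived_rule_params": {
                "prolonged_stay": {
                    "min_days_exclusive": self.prolonged_stay_days,
                    "newborn_care_sigtap": self.newborn_care_sigtap,
                },
                "conditional_curettage": {
                    "curettage_sigtap": self.curettage_sigtap,
                    "puerperal_icd": list(self.puerperal_icd.entries),
                },
            },
            "criteria": crit_doc,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False,
                           default_flow_style=False)

    def __eq__(self, other) -> bool:
        return isinstance(other, Codebook) and self.to_dict() == other.to_dict()


class _StrictLoader(yaml.SafeLoader):
    """SafeLoader that rejects duplicate mapping keys (duplicate criteria)."""


def _strict_mapping(loader, node, deep=False):
    mapping = {}
    for key_node, value_node in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in mapping:
            raise CodebookError(f"duplicate key in codebook document: {key!r}")
        mapping[key] = loader.construct_object(value_node, deep=deep)
    return mapping


_StrictLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _strict_mapping)


@lru_cache(maxsize=1)
def default_codebook() -> Codebook:
    """The shipped default registry (Brazil 2015-2022 operationalization)."""
    ref = resources.files("smmsurv").joinpath("data/codebook.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return Codebook.from_dict(yaml.load(fh, Loader=_StrictLoader))
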