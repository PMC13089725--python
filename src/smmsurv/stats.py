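"""Frequency tables, odds ratios of death, and deaths by criterion count.

Convergent validity of the SMM operationalization is assessed by the
association between each criterion and in-hospital death: for criterion X,
the 2x2 table opposes episodes meeting X to *all* episodes not meeting X
(including those meeting other criteria), restricted to known-outcome
episodes (live discharge or in-hospital death).  The odds ratio is the plain
cross-product a*d / (b*c) with no continuity correction: a zero-death cell
(a = 0) yields 0, a zero reference cell (b = 0 or c = 0) is undefined and
reported as NaN.

Denominators differ by surface, mirroring surveillance practice: frequency
tables use the full obstetric cohort, the death analyses the known-outcome
subset; both are explicit parameters.

Group totals use union semantics — an episode contributes once to a group
no matter how many of the group's criteria it meets.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .codebook import GROUPS, Codebook, default_codebook
from .records import DischargeOutcome

__all__ = [
    "TwoByTwo",
    "round2",
    "odds_ratio",
    "woolf_ci",
    "known_outcome_filter",
    "frequency_table",
    "criterion_or_table",
    "deaths_by_count",
    "cross_schema_ratio",
]

_KNOWN = (DischargeOutcome.DISCHARGE_ALIVE.value, DischargeOutcome.DEATH.value)


def round2(value: float) -> float:
    """Round half-up to 2 decimal places (the convention of printed tables)."""
    if value is None:
        return float("nan")
    value = float(value)
    if math.isnan(value):
        return float("nan")
    return float(Decimal(repr(value)).quantize(Decimal("0.01"),
                                               rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TwoByTwo:
    """Criterion-by-death contingency counts over known-outcome episodes.

    a: deaths with the criterion;   b: alive with the criterion;
    c: deaths without it;           d: alive without it.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for cell in (self.a, self.b, self.c, self.d):
            if cell < 0:
                raise ValueError(f"negative contingency cell in {self}")

    @staticmethod
    def from_margins(deaths_with: int, alive_with: int,
                     deaths_total: int, alive_total: int) -> "TwoByTwo":
        """Build the table from a criterion's (death, alive) cells and the
        cohort's death/alive totals (the complement is the reference)."""
        return TwoByTwo(a=deaths_with, b=alive_with,
                        c=deaths_total - deaths_with,
                        d=alive_total - alive_with)

    @property
    def deaths_total(self) -> int:
        return self.a + self.c

    @property
    def alive_total(self) -> int:
        return self.b + self.d

    def odds_ratio(self) -> float:
        """Cross-product odds ratio; NaN when undefined (zero reference odds)."""
        if self.b == 0 or self.c == 0:
            return float("nan")
        if self.a == 0:
            return 0.0
        return (self.a * self.d) / (self.b * self.c)

    def complement(self) -> "TwoByTwo":
        """The table of the complementary criterion (rows swapped)."""
        return TwoByTwo(a=self.c, b=self.d, c=self.a, d=self.b)


def odds_ratio(table: TwoByTwo) -> float:
    return table.odds_ratio()


def woolf_ci(table: TwoByTwo, alpha: float = 0.05) -> tuple[float, float]:
    """Woolf (log-normal) confidence interval; provided for completeness,
    not part of the default report surface."""
    from scipy import stats as sps  # optional, used only here

    if min(table.a, table.b, table.c, table.d) == 0:
        return (float("nan"), float("nan"))
    log_or = math.log(table.odds_ratio())
    se = math.sqrt(1 / table.a + 1 / table.b + 1 / table.c + 1 / table.d)
    z = sps.norm.ppf(1 - alpha / 2)
    return (math.exp(log_or - z * se), math.exp(log_or + z * se))


def known_outcome_filter(profiles: pd.DataFrame) -> pd.DataFrame:
    """Retain episodes whose outcome is live discharge or in-hospital death."""
    return profiles[profiles["outcome"].isin(_KNOWN)]


def _criterion_columns(frame: pd.DataFrame, cb: Codebook) -> list[str]:
    return [name for name in cb.criterion_names if name in frame.columns]


def _group_membership(frame: pd.DataFrame, cb: Codebook,
                      group: str) -> pd.Series:
    cols = [n for n in _criterion_columns(frame, cb)
            if cb.group_of[n] == group]
    if not cols:
        return pd.Series(False, index=frame.index)
    return frame[cols].any(axis=1)


def frequency_table(profiles: pd.DataFrame, n_obstetric: int,
                    codebook: Codebook | None = None) -> pd.DataFrame:
    """Per-criterion case counts and shares, with union-semantics group totals.

    ``n_obstetric`` is the full obstetric-cohort denominator (this surface is
    not outcome-filtered).  Percentages are unrounded; apply :func:`round2`
    for display.
    """
    cb = codebook or default_codebook()
    n_smm = int(profiles["is_smm"].sum())
    rows = []

    def _row(name: str, kind: str, n_cases: int, include_smm_share=True):
        rows.append({
            "name": name,
            "kind": kind,
            "n_cases": int(n_cases),
            "pct_hospitalizations":
                100.0 * n_cases / n_obstetric if n_obstetric else float("nan"),
            "pct_smm_cases":
                (100.0 * n_cases / n_smm if n_smm else float("nan"))
                if include_smm_share else float("nan"),
        })

    for group in GROUPS:
        for name in _criterion_columns(profiles, cb):
            if cb.group_of[name] == group:
                _row(name, "criterion", profiles[name].sum())
        _row(group, "group_total",
             _group_membership(profiles, cb, group).sum())
    _row("SMM", "overall", n_smm, include_smm_share=False)
    return pd.DataFrame(rows, columns=["name", "kind", "n_cases",
                                       "pct_hospitalizations", "pct_smm_cases"])


def criterion_or_table(profiles: pd.DataFrame,
                       codebook: Codebook | None = None) -> pd.DataFrame:
    """Per-criterion, per-group and overall-SMM 2x2 cells and odds ratios.

    The reference for each row is the complement within the known-outcome
    cohort (episodes meeting other criteria included).
    """
    cb = codebook or default_codebook()
    known = known_outcome_filter(profiles)
    death = known["outcome"] == DischargeOutcome.DEATH.value
    deaths_total = int(death.sum())
    alive_total = int(len(known) - deaths_total)
    rows = []

    def _row(name: str, kind: str, member: pd.Series):
        a = int((member & death).sum())
        b = int(member.sum()) - a
        table = TwoByTwo.from_margins(a, b, deaths_total, alive_total)
        rows.append({"name": name, "kind": kind, "a": table.a, "b": table.b,
                     "c": table.c, "d": table.d,
                     "odds_ratio": table.odds_ratio()})

    for group in GROUPS:
        for name in _criterion_columns(known, cb):
            if cb.group_of[name] == group:
                _row(name, "criterion", known[name])
        _row(group, "group_total", _group_membership(known, cb, group))
    _row("SMM", "overall", known["is_smm"])
    return pd.DataFrame(rows, columns=["name", "kind", "a", "b", "c", "d",
                                       "odds_ratio"])


def deaths_by_count(profiles: pd.DataFrame) -> pd.DataFrame:
    """Deaths/alive by number of criteria met; rows partition the
    known-outcome cohort."""
    known = known_outcome_filter(profiles)
    death = known["outcome"] == DischargeOutcome.DEATH.value
    rows = []
    max_n = int(known["n_criteria"].max()) if len(known) else 0
    for k in range(max_n + 1):
        member = known["n_criteria"] == k
        total = int(member.sum())
        if total == 0 and k > 0:
            continue
        deaths = int((member & death).sum())
        rows.append({
            "n_criteria": k,
            "deaths": deaths,
            "alive": total - deaths,
            "total": total,
            "pct_death": 100.0 * deaths / total if total else float("nan"),
        })
    return pd.DataFrame(rows, columns=["n_criteria", "deaths", "alive",
                                       "total", "pct_death"])


def cross_schema_ratio(freq_public: pd.DataFrame,
                       freq_private: pd.DataFrame) -> pd.DataFrame:
    """Public/private ratios of the frequency-table shares, per row.

    Ratios are computed from the unrounded percentages; a zero private-side
    denominator yields NaN.
    """
    merged = freq_public.merge(freq_private, on=["name", "kind"],
                               suffixes=("_public", "_private"))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_hosp = np.where(
            merged["pct_hospitalizations_private"] > 0,
            merged["pct_hospitalizations_public"]
            / merged["pct_hospitalizations_private"], np.nan)
        ratio_smm = np.where(
            merged["pct_smm_cases_private"] > 0,
            merged["pct_smm_cases_public"] / merged["pct_smm_cases_private"],
            np.nan)
    return pd.DataFrame({
        "name": merged["name"],
        "kind": merged["kind"],
        "ratio_pct_hospitalizations": ratio_hosp,
        "ratio_pct_smm_cases": ratio_smm,
    })
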