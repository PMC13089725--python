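"""Published national surveillance counts and validity reconstruction.

The package ships the national 2015-2022 per-criterion case and death counts
for both schemas (``data/reference_counts.yaml``).  The microdata behind
them are not redistributable, but the printed margins suffice to rebuild
every criterion's 2x2 death table — the criterion's (death, alive) cells
against the complement of the cohort totals — and therefore to verify the
odds-ratio arithmetic end to end.
"""
from __future__ import annotations

from functools import lru_cache
from importlib import resources

import pandas as pd
import yaml

from .stats import TwoByTwo

__all__ = ["load_reference_counts", "reconstructed_or_table",
           "reference_frequency_shares", "reference_death_percentages"]


@lru_cache(maxsize=1)
def load_reference_counts() -> dict:
    ref = resources.files("smmsurv").joinpath("data/reference_counts.yaml")
    with ref.open("r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def reconstructed_or_table(schema: str) -> pd.DataFrame:
    """Rebuild every published 2x2 death table for ``schema``
    ('public'/'private') and recompute its odds ratio.

    Columns: name, kind, a, b, c, d, odds_ratio (recomputed, unrounded),
    printed_or (as published; NaN where published as undefined).
    """
    doc = load_reference_counts()[schema]
    deaths_total, alive_total = doc["deaths_total"], doc["alive_total"]
    rows = []

    def _row(name, kind, cells):
        a, b, printed = cells
        table = TwoByTwo.from_margins(a, b, deaths_total, alive_total)
        rows.append({
            "name": name, "kind": kind,
            "a": table.a, "b": table.b, "c": table.c, "d": table.d,
            "odds_ratio": table.odds_ratio(),
            "printed_or": float("nan") if printed is None else float(printed),
        })

    for name, cells in doc["death_table"].items():
        _row(name, "criterion", cells)
    for name, cells in doc["group_death_table"].items():
        _row(name, "group_total", cells)
    _row("SMM", "overall", doc["smm_death_table"])
    return pd.DataFrame(rows)


def reference_frequency_shares(schema: str) -> pd.DataFrame:
    """Recompute the percentage columns of the published frequency table
    from its raw counts (share of obstetric hospitalizations and of SMM
    cases, unrounded)."""
    doc = load_reference_counts()[schema]
    n_obst, n_smm = doc["n_obstetric"], doc["smm_cases"]
    rows = []
    for name, cases in doc["criterion_cases"].items():
        rows.append({"name": name, "kind": "criterion", "n_cases": cases,
                     "pct_hospitalizations": 100.0 * cases / n_obst,
                     "pct_smm_cases": 100.0 * cases / n_smm})
    for name, cases in doc["group_cases"].items():
        rows.append({"name": name, "kind": "group_total", "n_cases": cases,
                     "pct_hospitalizations": 100.0 * cases / n_obst,
                     "pct_smm_cases": 100.0 * cases / n_smm})
    rows.append({"name": "SMM", "kind": "overall", "n_cases": n_smm,
                 "pct_hospitalizations": 100.0 * n_smm / n_obst,
                 "pct_smm_cases": float("nan")})
    return pd.DataFrame(rows)


def reference_death_percentages(schema: str) -> pd.DataFrame:
    """Recompute the deaths-by-criterion-count percentages from raw counts."""
    doc = load_reference_counts()[schema]
    rows = []
    for k, deaths, alive in doc["deaths_by_count"]:
        total = deaths + alive
        rows.append({"n_criteria": k, "deaths": deaths, "alive": alive,
                     "total": total, "pct_death": 100.0 * deaths / total})
    return pd.DataFrame(rows)
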