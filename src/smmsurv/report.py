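"""CSV report writer: the three surveillance tables, in registry row order.

Emits, per run: ``frequency.csv`` (cases and shares per criterion, group
totals, overall SMM), ``odds_ratios.csv`` (2x2 cells and odds ratio of
death), and ``deaths_by_count.csv`` (deaths by number of criteria met).
Display columns are rounded half-up to 2 decimals; the unrounded values are
kept alongside.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .pipeline import PipelineResult
from .stats import round2

__all__ = ["write_report"]


def _stack(result: PipelineResult, attribute: str) -> pd.DataFrame:
    frames = []
    for analysis in result.schemas():
        frame = getattr(analysis, attribute).copy()
        frame.insert(0, "schema", analysis.schema)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def write_report(result: PipelineResult, out_dir) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    frequency = _stack(result, "frequency")
    if not frequency.empty:
        for col in ("pct_hospitalizations", "pct_smm_cases"):
            frequency[f"{col}_display"] = frequency[col].map(round2)
    ors = _stack(result, "or_table")
    if not ors.empty:
        ors["odds_ratio_display"] = ors["odds_ratio"].map(round2)
    counts = _stack(result, "deaths_by_count")
    if not counts.empty:
        counts["pct_death_display"] = counts["pct_death"].map(round2)

    paths = {
        "frequency": out_dir / "frequency.csv",
        "odds_ratios": out_dir / "odds_ratios.csv",
        "deaths_by_count": out_dir / "deaths_by_count.csv",
    }
    frequency.to_csv(paths["frequency"], index=False)
    ors.to_csv(paths["odds_ratios"], index=False)
    counts.to_csv(paths["deaths_by_count"], index=False)
    if result.cross_ratio is not None:
        paths["cross_schema_ratio"] = out_dir / "cross_schema_ratio.csv"
        result.cross_ratio.to_csv(paths["cross_schema_ratio"], index=False)
    return paths
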