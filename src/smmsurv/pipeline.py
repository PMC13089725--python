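"""End-to-end orchestration: read -> assemble -> identify -> classify -> tabulate."""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .classify import classify_episodes, profiles_frame
from .codebook import Codebook, default_codebook
from .episodes import assemble_episodes
from .obstetric import is_obstetric
from .records import (PRIVATE, PUBLIC, AdmissionRecord, LoadReport,
                      read_private_pair, read_public_pair)
from .stats import (criterion_or_table, cross_schema_ratio, deaths_by_count,
                    frequency_table)

__all__ = ["SchemaAnalysis", "PipelineResult", "analyze_records", "run_pipeline"]


@dataclass
class SchemaAnalysis:
    """All analysis surfaces for one schema."""

    schema: str
    n_records: int
    n_episodes: int
    n_obstetric: int
    profiles: pd.DataFrame
    frequency: pd.DataFrame
    or_table: pd.DataFrame
    deaths_by_count: pd.DataFrame
    load_report: LoadReport | None = None


@dataclass
class PipelineResult:
    public: SchemaAnalysis | None
    private: SchemaAnalysis | None
    cross_ratio: pd.DataFrame | None

    def schemas(self):
        return [s for s in (self.public, self.private) if s is not None]


def analyze_records(records: list[AdmissionRecord],
                    codebook: Codebook | None = None,
                    max_gap_days: int = 1,
                    load_report: LoadReport | None = None) -> SchemaAnalysis:
    """Run the full analysis for one schema's records."""
    cb = codebook or default_codebook()
    schemas = {r.schema for r in records}
    if len(schemas) > 1:
        raise ValueError("analyze_records expects a single-schema cohort")
    schema = schemas.pop() if schemas else PUBLIC
    episodes = assemble_episodes(records, max_gap_days=max_gap_days)
    obstetric = [ep for ep in episodes if is_obstetric(ep, cb)]
    profiles = profiles_frame(classify_episodes(obstetric, cb), cb)
    return SchemaAnalysis(
        schema=schema,
        n_records=len(records),
        n_episodes=len(episodes),
        n_obstetric=len(obstetric),
        profiles=profiles,
        frequency=frequency_table(profiles, len(obstetric), cb),
        or_table=criterion_or_table(profiles, cb),
        deaths_by_count=deaths_by_count(profiles),
        load_report=load_report,
    )


def run_pipeline(data_dir, codebook: Codebook | None = None,
                 max_gap_days: int = 1) -> PipelineResult:
    """Read both schema pairs from ``data_dir`` (the generator's layout) and
    analyze each; the cross-schema frequency ratios compare the two."""
    cb = codebook or default_codebook()
    data_dir = Path(data_dir)
    public = private = None
    if (data_dir / "public_reduced.csv").exists():
        records, report = read_public_pair(
            data_dir / "public_reduced.csv", data_dir / "public_services.csv")
        public = analyze_records(records, cb, max_gap_days, report)
    if (data_dir / "private_consolidated.csv").exists():
        records, report = read_private_pair(
            data_dir / "private_consolidated.csv",
            data_dir / "private_detailed.csv")
        private = analyze_records(records, cb, max_gap_days, report)
    cross = None
    if public is not None and private is not None:
        cross = cross_schema_ratio(public.frequency, private.frequency)
    return PipelineResult(public=public, private=private, cross_ratio=cross)
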