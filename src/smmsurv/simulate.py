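"""Schema-faithful synthetic cohorts with planted statistical structure.

The generator emulates the two administrative dialects well enough to
exercise every pipeline stage: public episodes may split into several
admission forms (continuation forms with same-day/next-day handoffs),
private records lose their ICD fields at the observed national missingness
rate, and each planted criterion hit is realized as an actual triggering
code drawn from the registry, so a zero-missingness cohort is classifiable
with sensitivity 1 by construction.

When missingness masks an ICD-based hit on a private record, a procedure
trigger is substituted when the criterion has one in the TUSS terminology;
otherwise the hit is planted-but-unobservable and recorded as such in the
truth table.  In-hospital death follows a logistic model on the number of
*observable* hits, logit(p) = beta0 + beta1 * k — an explicitly synthetic
severity gradient (the defaults land near the magnitude ordering of the
national deaths-by-count table; they are not estimates).

Everything is a deterministic function of ``SimConfig.seed``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codebook import (SIGTAP, TUSS, Codebook, IcdCode, ProcedureCode,
                       default_codebook)
from .records import (PRIVATE, PUBLIC, AdmissionRecord, DischargeOutcome,
                      write_private_pair, write_public_pair)

__all__ = ["SimConfig", "SimResult", "DEFAULT_PREVALENCE", "simulate_cohort",
           "recover_parameters", "RecoveryReport"]

# Default per-criterion prevalence among obstetric hospitalizations:
# the national public-schema rates (share of obstetric admissions).
DEFAULT_PREVALENCE: dict[str, float] = {
    "abruptio_placentae": 0.0032,
    "ectopic_pregnancy": 0.0069,
    "postpartum_haemorrhage": 0.0012,
    "ruptured_uterus": 0.0002,
    "severe_preeclampsia": 0.0105,
    "eclampsia": 0.0030,
    "severe_hypertension": 0.0347,
    "hypertensive_encephalopathy": 0.000001,
    "endometritis": 0.0028,
    "pulmonary_oedema": 0.00001,
    "respiratory_failure": 0.0006,
    "seizures": 0.00003,
    "sepsis": 0.0002,
    "shock": 0.00007,
    "thyroid_crisis": 0.000001,
    "blood_transfusion": 0.0099,
    "central_venous_access": 0.0002,
    "hysterectomy": 0.0007,
    "icu_admission": 0.0053,
    "prolonged_stay": 0.0156,
    "non_anaesthetic_intubation": 0.0001,
    "surgical_intervention": 0.0070,
}

# Non-triggering filler codes for non-obstetric admissions.
_NON_OBSTETRIC_ICD = "J18"          # pneumonia: outside every criterion set
_NEONATAL_ICD = "P220"              # newborn respiratory distress, off-allow-list
_FILLER_SIGTAP = "0301010010"
_FILLER_TUSS = "10101012"


@dataclass(frozen=True)
class SimConfig:
    """Generator configuration; defaults are the national study conditions."""

    n_episodes: int = 100_000
    public_fraction: float = 0.83
    prevalence: Mapping[str, float] | Sequence[float] | None = None
    beta0: float = -8.0
    beta1: float = 1.1
    missing_icd_fraction: float = 0.30
    non_obstetric_fraction: float = 0.10
    multi_form_fraction: float = 0.05
    gap_days_choices: tuple[int, ...] = (0, 1)
    delivery_fraction: float = 0.70
    unknown_outcome_fraction: tuple[float, float] = (0.010, 0.052)
    start_date: date = date(2015, 1, 1)
    n_days: int = 2922          # 2015-2022
    seed: int = 0

    def prevalence_vector(self, names: Sequence[str]) -> np.ndarray:
        prev = self.prevalence
        if prev is None:
            prev = DEFAULT_PREVALENCE
        if isinstance(prev, Mapping):
            missing = set(names) - set(prev)
            if missing:
                raise ValueError(f"prevalence missing criteria: {sorted(missing)}")
            vec = np.array([float(prev[n]) for n in names])
        else:
            vec = np.asarray(list(prev), dtype=float)
            if len(vec) != len(names):
                raise ValueError(
                    f"prevalence vector length {len(vec)} != {len(names)}")
        if ((vec < 0) | (vec > 1)).any():
            raise ValueError("prevalences must lie in [0, 1]")
        return vec

    def validate(self) -> None:
        if self.n_episodes <= 0:
            raise ValueError("n_episodes must be positive")
        probs = [self.public_fraction, self.missing_icd_fraction,
                 self.non_obstetric_fraction, self.multi_form_fraction,
                 self.delivery_fraction, *self.unknown_outcome_fraction]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SimResult:
    """Generated file paths plus the in-memory truth table."""

    paths: dict[str, Path]
    truth: pd.DataFrame
    records: list[AdmissionRecord] = field(repr=False, default_factory=list)


def _pick_icd(rng: np.random.Generator, entries: Sequence[str]) -> str:
    return str(entries[rng.integers(len(entries))])


def _pick_proc(rng: np.random.Generator, codes: frozenset[str]) -> str:
    ordered = sorted(codes)
    return ordered[rng.integers(len(ordered))]


def simulate_cohort(config: SimConfig, out_dir,
                    codebook: Codebook | None = None) -> SimResult:
    """Generate both schema pairs and the truth table under ``out_dir``."""
    config.validate()
    cb = codebook or default_codebook()
    names = cb.criterion_names
    prev = config.prevalence_vector(names)
    n = config.n_episodes
    rng = np.random.default_rng(config.seed)

    is_public = rng.random(n) < config.public_fraction
    non_obstetric = rng.random(n) < config.non_obstetric_fraction
    hit_matrix = rng.random((n, len(names))) < prev[None, :]
    hit_matrix[non_obstetric] = False
    masked = (~is_public) & (rng.random(n) < config.missing_icd_fraction)
    has_delivery = rng.random(n) < config.delivery_fraction
    multi_form = is_public & (~non_obstetric) & (
        rng.random(n) < config.multi_form_fraction)
    adm_offsets = rng.integers(0, config.n_days, size=n)

    records: list[AdmissionRecord] = []
    truth_rows: list[dict] = []

    for i in range(n):
        public = bool(is_public[i])
        schema = PUBLIC if public else PRIVATE
        term = SIGTAP if public else TUSS
        episode_id = f"{'A' if public else 'E'}{i:07d}"
        obstetric = not bool(non_obstetric[i])
        adm = config.start_date + timedelta(days=int(adm_offsets[i]))

        diagnoses: list[str] = []
        procedures: list[str] = []
        icu_days = 0
        planted: dict[str, bool] = {}
        observable: dict[str, bool] = {}
        delivery = bool(has_delivery[i]) and obstetric
        stay = int(rng.integers(1, 5))

        if obstetric:
            for j, name in enumerate(names):
                if not hit_matrix[i, j]:
                    planted[name] = False
                    observable[name] = False
                    continue
                planted[name] = True
                crit = cb[name]
                if crit.derived_rule == "PROLONGED_STAY":
                    delivery = True
                    stay = int(rng.integers(8, 15))
                    observable[name] = True
                    continue
                if crit.derived_rule == "ICU_DAYS_COUNTER" and public:
                    icu_days = int(rng.integers(1, 11))
                    observable[name] = True
                    continue
                icd_possible = bool(crit.icd_set) and not (
                    not public and bool(masked[i]))
                proc_set = crit.sigtap_set if public else crit.tuss_set
                if icd_possible and (public or len(diagnoses) < 3):
                    diagnoses.append(_pick_icd(rng, crit.icd_set.entries))
                    observable[name] = True
                elif proc_set:
                    procedures.append(_pick_proc(rng, proc_set))
                    observable[name] = True
                else:
                    observable[name] = False  # planted but unobservable
        else:
            planted = {name: False for name in names}
            observable = dict(planted)

        # delivery context: procedure trigger (also the obstetric marker for
        # public episodes without any other code)
        if delivery:
            dset = cb.delivery_sigtap if public else cb.delivery_tuss
            procedures.append(_pick_proc(rng, dset))

        hosp_type = None
        if public:
            if obstetric and not (bool(masked[i])):
                diagnoses.insert(0, "O80")
            if obstetric and not diagnoses and not procedures:
                procedures.append(_pick_proc(rng, cb.delivery_sigtap))
            if not obstetric:
                diagnoses = [_NON_OBSTETRIC_ICD]
                procedures = [_FILLER_SIGTAP]
        else:
            if obstetric:
                hosp_type = cb.obstetric.obstetric_type_code
                if not bool(masked[i]):
                    diagnoses.insert(0, "O80")
            elif bool(masked[i]):
                hosp_type = "1"
            elif rng.random() < 0.5:
                hosp_type = cb.obstetric.obstetric_type_code
                diagnoses = [_NEONATAL_ICD]     # newborn billed under mother
            else:
                hosp_type = "1"
                diagnoses = [_NON_OBSTETRIC_ICD]
                procedures = [_FILLER_TUSS]

        if not public and bool(masked[i]):
            diagnoses = []                      # record-level missing ICD

        k_observable = sum(observable.values())
        p_death = 1.0 / (1.0 + np.exp(-(config.beta0
                                        + config.beta1 * k_observable)))
        death = bool(rng.random() < p_death)
        unknown_frac = config.unknown_outcome_fraction[0 if public else 1]
        unknown = (not death) and bool(rng.random() < unknown_frac)
        if death:
            outcome = DischargeOutcome.DEATH
        elif unknown:
            outcome = (DischargeOutcome.TRANSFER if rng.random() < 0.5
                       else DischargeOutcome.STAY)
        else:
            outcome = DischargeOutcome.DISCHARGE_ALIVE

        dis = adm + timedelta(days=stay)
        diag_fields = _assign_fields(diagnoses, public)
        proc_objs = tuple(ProcedureCode.parse(p, term) for p in procedures)

        if public:
            forms = _public_forms(
                i, episode_id, adm, dis, diag_fields, proc_objs, icu_days,
                outcome, bool(multi_form[i]), config.gap_days_choices, rng)
            records.extend(forms)
            n_forms = len(forms)
            # the assembler names an episode after its first member form
            episode_id = forms[0].form_id
        else:
            records.append(AdmissionRecord(
                schema=PRIVATE, form_id=episode_id,
                admission_date=adm, discharge_date=dis,
                type_of_hospitalization=hosp_type,
                diagnoses=diag_fields, procedures=proc_objs,
                discharge_reason=outcome))
            n_forms = 1

        row = {
            "episode_id": episode_id,
            "schema": schema,
            "obstetric": obstetric,
            "n_forms": n_forms,
            "death": death,
            "outcome_known": outcome.known,
            "n_planted": int(sum(planted.values())),
            "n_observable": int(k_observable),
        }
        row.update({f"planted_{name}": planted[name] for name in names})
        row.update({f"observable_{name}": observable[name] for name in names})
        truth_rows.append(row)

    truth = pd.DataFrame(truth_rows)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "public_reduced": out_dir / "public_reduced.csv",
        "public_services": out_dir / "public_services.csv",
        "private_consolidated": out_dir / "private_consolidated.csv",
        "private_detailed": out_dir / "private_detailed.csv",
        "truth": out_dir / "truth.csv",
    }
    write_public_pair([r for r in records if r.schema == PUBLIC],
                      paths["public_reduced"], paths["public_services"])
    write_private_pair([r for r in records if r.schema == PRIVATE],
                       paths["private_consolidated"], paths["private_detailed"])
    truth.to_csv(paths["truth"], index=False)
    return SimResult(paths=paths, truth=truth, records=records)


def _assign_fields(diagnoses: Sequence[str], public: bool
                   ) -> tuple[tuple[str, IcdCode], ...]:
    if public:
        fields = ["principal"] + [f"secondary_{k}" for k in range(1, 10)] + \
            ["icd_associated", "icd_notification", "icd_death"]
    else:
        fields = [f"icd_{k}" for k in range(1, 5)]
    out = []
    for fname, code in zip(fields, diagnoses):
        out.append((fname, IcdCode.parse(code)))
    return tuple(out)


def _public_forms(index: int, episode_id: str, adm: date, dis: date,
                  diag_fields, procedures, icu_days: int,
                  outcome: DischargeOutcome, multi: bool,
                  gap_choices: tuple[int, ...], rng: np.random.Generator
                  ) -> list[AdmissionRecord]:
    person = f"P{index:07d}"
    hospital = f"H{int(rng.integers(0, 200)):03d}"
    total_days = (dis - adm).days
    n_forms = 1
    if multi and total_days >= 2:
        n_forms = 2 + int(rng.integers(0, 2))
        n_forms = min(n_forms, total_days)
    if n_forms == 1:
        return [AdmissionRecord(
            schema=PUBLIC, form_id=f"{episode_id}-1",
            person_key=person, hospital_key=hospital,
            admission_date=adm, discharge_date=dis,
            diagnoses=diag_fields, procedures=procedures,
            icu_days=icu_days, discharge_reason=outcome)]
    # split the stay into consecutive segments joined by small gaps drawn
    # from the configured distribution (continuation-form handoffs)
    cuts = sorted(rng.choice(np.arange(1, total_days), size=n_forms - 1,
                             replace=False))
    bounds = [0, *(int(c) for c in cuts), total_days]
    seg_lengths = [bounds[j + 1] - bounds[j] for j in range(n_forms)]
    forms = []
    seg_adm = adm
    for j, length in enumerate(seg_lengths):
        seg_dis = seg_adm + timedelta(days=length)
        last = j == n_forms - 1
        forms.append(AdmissionRecord(
            schema=PUBLIC, form_id=f"{episode_id}-{j + 1}",
            person_key=person, hospital_key=hospital,
            admission_date=seg_adm, discharge_date=seg_dis,
            diagnoses=diag_fields if j == 0 else (),
            procedures=procedures if last else (),
            icu_days=icu_days if last else 0,
            discharge_reason=outcome if last else DischargeOutcome.STAY))
        if not last:
            gap = int(gap_choices[rng.integers(len(gap_choices))])
            seg_adm = seg_dis + timedelta(days=gap)
    return forms


@dataclass
class RecoveryReport:
    """Classification accuracy against the planted truth."""

    per_criterion: pd.DataFrame
    death_slope: float
    death_slope_sign: int
    n_episodes: int

    @property
    def empty(self) -> bool:
        return self.n_episodes == 0


def recover_parameters(profiles: pd.DataFrame,
                       truth: pd.DataFrame) -> RecoveryReport:
    """Per-criterion sensitivity/specificity and prevalence bias vs truth,
    plus the sign of the fitted death gradient over the criterion count.

    Sensitivity is measured against all planted hits (observable or not), so
    under full ICD masking it equals the fraction of hits realizable through
    procedure triggers.  The gradient is a logistic fit of death on the
    classified criterion count over known-outcome obstetric episodes.
    """
    if truth.empty:
        return RecoveryReport(pd.DataFrame(), float("nan"), 0, 0)
    obst = truth[truth["obstetric"]].copy()
    names = [c.removeprefix("planted_") for c in truth.columns
             if c.startswith("planted_")]
    merged = obst.merge(
        profiles[["episode_id", *[n for n in names if n in profiles.columns],
                  "n_criteria", "outcome"]],
        on="episode_id", how="left")
    for name in names:
        if name in merged.columns:
            merged[name] = merged[name].eq(True)
        else:
            merged[name] = False
    merged["n_criteria"] = merged["n_criteria"].fillna(0).astype(int)

    rows = []
    n_obst = len(merged)
    for name in names:
        truth_col = merged[f"planted_{name}"].astype(bool)
        found = merged[name]
        tp = int((truth_col & found).sum())
        fn = int((truth_col & ~found).sum())
        fp = int((~truth_col & found).sum())
        tn = int((~truth_col & ~found).sum())
        rows.append({
            "criterion": name,
            "planted": tp + fn,
            "classified": tp + fp,
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp else float("nan"),
            "prevalence_true": (tp + fn) / n_obst,
            "prevalence_classified": (tp + fp) / n_obst,
            "prevalence_bias": (fp - fn) / n_obst,
        })
    per_criterion = pd.DataFrame(rows)

    slope, sign = _death_gradient(merged)
    return RecoveryReport(per_criterion=per_criterion, death_slope=slope,
                          death_slope_sign=sign, n_episodes=n_obst)


def _death_gradient(merged: pd.DataFrame) -> tuple[float, int]:
    import statsmodels.api as sm

    known = merged[merged["outcome_known"]]
    y = known["death"].astype(float).to_numpy()
    k = known["n_criteria"].to_numpy(dtype=float)
    if len(known) == 0 or y.sum() == 0 or np.ptp(k) == 0:
        return float("nan"), 0
    x = sm.add_constant(k)
    try:
        fit = sm.Logit(y, x).fit(disp=0)
        slope = float(fit.params[1])
    except Exception:
        return float("nan"), 0
    return slope, int(np.sign(slope))
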