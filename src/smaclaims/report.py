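"""Regimen classification, report-table assembly, and pipeline orchestration.

``run_pipeline`` executes simulate? → read → cohort → typing → adherence →
persistence → costs → report and is idempotent for fixed inputs and seed:
report bundles contain no timestamps or environment-dependent content, so
two runs with the same seed are byte-identical.
"""

from __future__ import annotations

import csv
import datetime as dt
import json
from dataclasses import dataclass, field
from importlib.resources import files as _pkg_files
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import __version__
from .adherence import (AGE_BINS_RESULTS, AdherenceResult, compute_adherence)
from .claims import ClaimsBundle, read_bundle, write_bundle
from .cohort import CohortConfig, SelectionLog, StudyWindow, select_cohort
from .costs import (CATEGORIES, CostSummary, InflationIndex, PatientCosts,
                    apply_outlier_exclusion, compute_patient_costs, summarize_costs)
from .persistence import PersistenceRecord, detect_discontinuation, km_estimate
from .sma_types import TypedPatient, TypingRuleTable, classify_patient
from .synth import SimConfig, generate, write_truth

REGIMEN_CLASSES = ("risdiplam_monotherapy", "prior_nusinersen",
                   "prior_nusinersen_switchback", "post_nusinersen_and_onasemnogene",
                   "post_index_dmt_only")

REPORT_FILES = ("table1.csv", "table2.csv", "table3.csv", "km_curve.csv",
                "pdc_band_costs.csv", "regimens.csv", "persistence_summary.csv",
                "manifest.json")


def dmt_event_dates(bundle: ClaimsBundle, patient_id: str
                    ) -> tuple[list[dt.date], list[dt.date]]:
    """(nusinersen claim dates, onasemnogene claim dates) for one patient."""
    nus, oa = [], []
    for c in bundle.medical_for(patient_id):
        if "dmt_nusinersen" in c.flags:
            nus.append(c.service_date)
        if "dmt_onasemnogene" in c.flags:
            oa.append(c.service_date)
    return nus, oa


def classify_regimen(nusinersen_dates: Sequence[dt.date],
                     onasemnogene_dates: Sequence[dt.date],
                     index_date: dt.date) -> str:
    """Assign the treatment-regimen class relative to the index date.

    ``post_index_dmt_only`` covers patients whose first exposure to another
    disease-modifying therapy is after index with no prior exposure — a
    pattern the source cohort did not contain but a generic engine must name.
    """
    nus_before = any(d < index_date for d in nusinersen_dates)
    nus_after = any(d > index_date for d in nusinersen_dates)
    oa_before = any(d < index_date for d in onasemnogene_dates)
    oa_any = bool(onasemnogene_dates)

    if nus_before and oa_before:
        return "post_nusinersen_and_onasemnogene"
    if nus_before and nus_after:
        return "prior_nusinersen_switchback"
    if nus_before:
        return "prior_nusinersen"
    if not nusinersen_dates and not oa_any:
        return "risdiplam_monotherapy"
    return "post_index_dmt_only"


def comorbidity_map_default() -> dict[str, list[str]]:
    text = _pkg_files("smaclaims.data").joinpath("comorbidity_map.csv").read_text()
    out: dict[str, list[str]] = {}
    for row in csv.DictReader(text.splitlines()):
        out.setdefault(row["group"], []).append(row["dx_prefix"])
    return out


def comorbidity_prevalence(bundle: ClaimsBundle, windows: Sequence[StudyWindow],
                           code_map: Mapping[str, Sequence[str]] | None = None,
                           ) -> dict[str, dict[str, bool]]:
    """Per patient, per comorbidity group: any matching diagnosis in the study window."""
    code_map = code_map or comorbidity_map_default()
    out: dict[str, dict[str, bool]] = {}
    for w in windows:
        flags = {g: False for g in code_map}
        for c in bundle.medical_for(w.patient_id):
            if not w.index_date <= c.service_date <= w.end_date:
                continue
            for group, prefixes in code_map.items():
                if any(code.startswith(p) for p in prefixes for code in c.dx_codes):
                    flags[group] = True
        out[w.patient_id] = flags
    return out


@dataclass
class StageOutputs:
    bundle: ClaimsBundle
    windows: list[StudyWindow]
    selection_log: SelectionLog
    typed: dict[str, TypedPatient]
    adherence: list[AdherenceResult]
    persistence: list[PersistenceRecord]
    patient_costs: list[PatientCosts]       # after outlier exclusion
    excluded_costs: list[PatientCosts]
    regimens: dict[str, str]


@dataclass(frozen=True)
class PipelineConfig:
    bundle_dir: Path | None = None
    sim: SimConfig | None = None
    out_dir: Path = Path("out")
    cohort: CohortConfig = field(default_factory=CohortConfig)
    rules_path: Path | None = None
    inflation_path: Path | None = None
    carry_forward: bool = True
    gap_days: int = 30
    outlier_threshold: float = 4_000_000.0
    age_bins: tuple[tuple[int, int | None], ...] = AGE_BINS_RESULTS

    def __post_init__(self) -> None:
        if (self.bundle_dir is None) == (self.sim is None):
            raise ValueError("config must name exactly one of bundle_dir or sim")


def run_stages(bundle: ClaimsBundle, config: PipelineConfig) -> StageOutputs:
    windows, log = select_cohort(bundle, config.cohort)
    rules = (TypingRuleTable.from_csv(config.rules_path)
             if config.rules_path else TypingRuleTable.default())
    typed = {w.patient_id: classify_patient(bundle, w.patient_id, rules,
                                            data_end=config.cohort.data_end)
             for w in windows}
    adh = compute_adherence(bundle, windows, carry_forward=config.carry_forward,
                            bins=config.age_bins)

    persistence = []
    for w in windows:
        nus, oa = dmt_event_dates(bundle, w.patient_id)
        switches = {}
        post_nus = [d for d in nus if d > w.index_date]
        post_oa = [d for d in oa if d > w.index_date]
        if post_nus:
            switches["switch_nusinersen"] = min(post_nus)
        if post_oa:
            switches["switch_onasemnogene"] = min(post_oa)
        persistence.append(detect_discontinuation(
            bundle.pharmacy_for(w.patient_id), switches, w, gap_days=config.gap_days))

    index = (InflationIndex.from_csv(config.inflation_path)
             if config.inflation_path else InflationIndex.default())
    all_costs = [compute_patient_costs(bundle, w, index=index) for w in windows]
    kept, excluded = apply_outlier_exclusion(all_costs, config.outlier_threshold)

    regimens = {}
    for w in windows:
        nus, oa = dmt_event_dates(bundle, w.patient_id)
        regimens[w.patient_id] = classify_regimen(nus, oa, w.index_date)

    return StageOutputs(bundle=bundle, windows=windows, selection_log=log,
                        typed=typed, adherence=adh, persistence=persistence,
                        patient_costs=kept, excluded_costs=excluded,
                        regimens=regimens)


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return repr(x)
    return str(x)


def _write_rows(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for row in rows:
            w.writerow([_fmt(v) for v in row])


def _describe(values: Sequence[float]):
    n = len(values)
    if n == 0:
        return (None,) * 5
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if n > 1 else None
    q1, med, q3 = (float(q) for q in np.percentile(arr, [25, 50, 75]))
    return float(arr.mean()), sd, med, q1, q3


def build_report(stages: StageOutputs, out_dir: str | Path,
                 manifest_extra: Mapping | None = None) -> dict[str, Path]:
    """Write the report tables and a machine-readable run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = stages.bundle
    by_type: dict[str, list[StudyWindow]] = {}
    for w in stages.windows:
        label = str(stages.typed[w.patient_id].sma_type)
        by_type.setdefault(label, []).append(w)

    # table1: demographics + comorbidity prevalence by type
    comorb = comorbidity_prevalence(bundle, stages.windows)
    rows1 = []
    for label in sorted(by_type):
        members = by_type[label]
        n = len(members)
        ages = []
        females = 0
        regions: dict[str, int] = {}
        for w in members:
            demo = bundle.demographics_for(w.patient_id)
            from .adherence import age_in_years
            ages.append(age_in_years(demo.birth_date, w.index_date))
            females += demo.sex == "F"
            regions[demo.region] = regions.get(demo.region, 0) + 1
        mean, sd, med, q1, q3 = _describe(ages)
        rows1 += [(label, n, "age_mean", mean), (label, n, "age_sd", sd),
                  (label, n, "age_median", med), (label, n, "age_q1", q1),
                  (label, n, "age_q3", q3),
                  (label, n, "pct_female", 100.0 * females / n)]
        for region in ("South", "Midwest", "West", "Northeast"):
            rows1.append((label, n, f"region_pct_{region}",
                          100.0 * regions.get(region, 0) / n))
        for group in sorted(next(iter(comorb.values()), {})):
            n_with = sum(comorb[w.patient_id][group] for w in members)
            rows1.append((label, n, f"comorbidity_pct_{group}", 100.0 * n_with / n))
    _write_rows(out / "table1.csv", ("sma_type", "n", "measure", "value"), rows1)

    # table2: adherence overall / by type / by age group
    adh_by_pid = {a.patient_id: a for a in stages.adherence}
    strata2: list[tuple[str, str, list[AdherenceResult]]] = []
    if stages.adherence:
        strata2.append(("overall", "all", list(stages.adherence)))
    for label in sorted(by_type):
        strata2.append(("sma_type", label,
                        [adh_by_pid[w.patient_id] for w in by_type[label]]))
    by_age: dict[str, list[AdherenceResult]] = {}
    for a in stages.adherence:
        by_age.setdefault(a.age_group, []).append(a)
    for label in sorted(by_age):
        strata2.append(("age_group", label, by_age[label]))
    rows2 = []
    for strat, label, members in strata2:
        pdcs = [a.pdc for a in members]
        mean, sd, med, q1, q3 = _describe(pdcs)
        n = len(members)
        n_adh = sum(a.adherent for a in members)
        rows2.append((strat, label, n, mean, sd, med, q1, q3,
                      n_adh, 100.0 * n_adh / n if n else None,
                      n - n_adh, 100.0 * (n - n_adh) / n if n else None))
    _write_rows(out / "table2.csv",
                ("stratification", "stratum", "n", "pdc_mean", "pdc_sd",
                 "pdc_median", "pdc_q1", "pdc_q3", "n_adherent", "pct_adherent",
                 "n_nonadherent", "pct_nonadherent"), rows2)

    # table3: PPPY costs by SMA type × adherence status
    strata3 = {}
    for p in stages.patient_costs:
        t = stages.typed[p.patient_id].sma_type
        adherent = "adherent" if adh_by_pid[p.patient_id].adherent else "nonadherent"
        strata3[p.patient_id] = f"{t}|{adherent}"
    rows3 = []
    for summary in summarize_costs(stages.patient_costs, strata3):
        t, adherent = summary.stratum.split("|")
        for cat in CATEGORIES:
            s = summary.stats[cat]
            rows3.append((t, adherent, summary.n, cat, s.mean, s.sd,
                          s.median, s.q1, s.q3))
    _write_rows(out / "table3.csv",
                ("sma_type", "adherence", "n", "category", "mean", "sd",
                 "median", "q1", "q3"), rows3)

    # km_curve: overall and per type
    rows_km = []
    groups = [("overall", stages.persistence)]
    pers_by_pid = {r.patient_id: r for r in stages.persistence}
    for label in sorted(by_type):
        groups.append((f"type_{label}",
                       [pers_by_pid[w.patient_id] for w in by_type[label]]))
    for label, records in groups:
        if not records:
            continue
        for p in km_estimate(records).points:
            rows_km.append((label, p.time, p.n_risk, p.n_event, p.n_censor, p.survival))
    _write_rows(out / "km_curve.csv",
                ("stratum", "time", "n_risk", "n_event", "n_censor", "survival"),
                rows_km)

    # persistence summary
    from .persistence import summarize_persistence
    type_labels = {w.patient_id: f"type_{stages.typed[w.patient_id].sma_type}"
                   for w in stages.windows}
    rows_p = []
    if stages.persistence:
        for summary in (summarize_persistence(stages.persistence)
                        + summarize_persistence(stages.persistence, by=type_labels)):
            rows_p.append((summary["stratum"], summary["n"], summary["n_events"],
                           summary["pct_discontinued"], summary["median_days"]))
    _write_rows(out / "persistence_summary.csv",
                ("stratum", "n", "n_events", "pct_discontinued", "median_days"), rows_p)

    # pdc band × total costs
    band_strata = {p.patient_id: adh_by_pid[p.patient_id].band
                   for p in stages.patient_costs}
    rows_b = []
    for summary in summarize_costs(stages.patient_costs, band_strata):
        for cat in CATEGORIES:
            s = summary.stats[cat]
            rows_b.append((summary.stratum, summary.n, cat, s.mean, s.sd,
                           s.median, s.q1, s.q3))
    _write_rows(out / "pdc_band_costs.csv",
                ("band", "n", "category", "mean", "sd", "median", "q1", "q3"), rows_b)

    # regimens
    _write_rows(out / "regimens.csv", ("patient_id", "regimen"),
                sorted(stages.regimens.items()))

    manifest = {
        "package_version": __version__,
        "n_cohort": len(stages.windows),
        "selection_log": stages.selection_log.steps,
        "n_cost_outliers_excluded": len(stages.excluded_costs),
        "cost_outlier_patient_ids": sorted(p.patient_id for p in stages.excluded_costs),
        "files": sorted(REPORT_FILES),
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")

    return {name: out / name for name in REPORT_FILES}


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """End-to-end pipeline; deterministic for fixed inputs and seed."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_extra: dict = {}
    if config.sim is not None:
        bundle, truth = generate(config.sim)
        bundle_dir = out / "bundle"
        write_bundle(bundle, bundle_dir)
        write_truth(truth, bundle_dir / "ground_truth.csv")
        manifest_extra["seed"] = config.sim.seed
        manifest_extra["n_patients_simulated"] = config.sim.n_patients
    else:
        bundle = read_bundle(config.bundle_dir)
        manifest_extra["bundle_dir"] = str(config.bundle_dir)

    stages = run_stages(bundle, config)

    cohort_rows = [(w.patient_id, w.index_date.isoformat(), w.end_date.isoformat(),
                    w.end_reason, stages.typed[w.patient_id].sma_type)
                   for w in stages.windows]
    _write_rows(out / "cohort.csv",
                ("patient_id", "index_date", "end_date", "end_reason", "sma_type"),
                cohort_rows)
    _write_rows(out / "selection_log.csv", ("criterion", "n_remaining"),
                stages.selection_log.steps)
    _write_rows(out / "adherence.csv",
                ("patient_id", "pdc", "adherent", "band", "age_group"),
                [(a.patient_id, a.pdc, int(a.adherent), a.band, a.age_group)
                 for a in stages.adherence])
    _write_rows(out / "persistence.csv",
                ("patient_id", "time_days", "event", "reason"),
                [(r.patient_id, r.time_days, int(r.event), r.reason)
                 for r in stages.persistence])

    paths = build_report(stages, out, manifest_extra=manifest_extra)
    paths.update({
        "cohort.csv": out / "cohort.csv",
        "selection_log.csv": out / "selection_log.csv",
        "adherence.csv": out / "adherence.csv",
        "persistence.csv": out / "persistence.csv",
    })
    return paths
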