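"""CSV and JSON readers/writers for cohorts, life tables and curve points.

All cohort files are plain CSV with a header; readers attach row
numbers to every validation error (row 1 = first data row), trim
whitespace, and treat empty fields as missing optionals.
"""

from __future__ import annotations

import csv
import json
from typing import List, Optional, Sequence

import pandas as pd

from .lifeexp import LifeTable
from .metrics import DecisionCurvePoint, MetricReport
from .types import BiopsyRecord, PatientProfile, SurvivalRecord
from .weibull import SurvivalCurvePoints

__all__ = [
    "CohortFormatError",
    "read_biopsy_cohort_csv",
    "write_biopsy_cohort_csv",
    "read_survival_cohort_csv",
    "write_survival_cohort_csv",
    "read_life_table_csv",
    "write_life_table_csv",
    "read_survival_points_csv",
    "write_survival_points_csv",
    "write_decision_curve_csv",
    "write_metrics_json",
]

BIOPSY_COLUMNS = ["age", "psa", "free_psa_pct", "dre_abnormal", "pv_estimate_cc",
                  "family_history", "ipss", "charlson", "outcome"]
SURVIVAL_COLUMNS = ["age", "charlson", "follow_up_months", "status"]


class CohortFormatError(ValueError):
    """A cohort file failed schema or value validation."""


def _clean(value) -> Optional[str]:
    if value is None:
        return None
    s = str(value).strip()
    return s if s else None


def _parse_bool(s: str) -> bool:
    low = s.lower()
    if low in ("1", "true", "yes"):
        return True
    if low in ("0", "false", "no"):
        return False
    raise ValueError(f"not a boolean: {s!r}")


def _check_header(path, fieldnames, required) -> None:
    missing = set(required) - set(fieldnames or ())
    if missing:
        raise CohortFormatError(
            f"{path}: missing required columns {sorted(missing)}"
        )


def read_biopsy_cohort_csv(path) -> List[BiopsyRecord]:
    """Read a biopsy cohort; errors cite the offending data row."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        _check_header(path, reader.fieldnames, ["age", "psa", "free_psa_pct", "outcome"])
        for rownum, row in enumerate(reader, start=1):
            try:
                outcome = _clean(row.get("outcome"))
                if outcome is None:
                    raise ValueError("missing outcome")
                dre = _clean(row.get("dre_abnormal"))
                pv = _clean(row.get("pv_estimate_cc"))
                fh_ = _clean(row.get("family_history"))
                ipss = _clean(row.get("ipss"))
                charlson = _clean(row.get("charlson"))
                profile = PatientProfile(
                    age=int(float(_clean(row["age"]))),
                    psa=float(_clean(row["psa"])),
                    free_psa_pct=float(_clean(row["free_psa_pct"])),
                    dre_abnormal=_parse_bool(dre) if dre is not None else None,
                    pv_estimate_cc=int(float(pv)) if pv is not None else None,
                    family_history=_parse_bool(fh_) if fh_ is not None else None,
                    ipss=int(float(ipss)) if ipss is not None else None,
                    charlson=charlson if charlson is not None else "0",
                )
                records.append(BiopsyRecord(profile=profile, outcome=outcome.lower()))
            except (ValueError, TypeError, KeyError) as exc:
                raise CohortFormatError(f"{path}: row {rownum}: {exc}") from exc
    return records


def write_biopsy_cohort_csv(records: Sequence[BiopsyRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(BIOPSY_COLUMNS)
        for r in records:
            p = r.profile
            writer.writerow([
                p.age,
                f"{p.psa:.6g}",
                f"{p.free_psa_pct:.6g}",
                "" if p.dre_abnormal is None else int(p.dre_abnormal),
                "" if p.pv_estimate_cc is None else p.pv_estimate_cc,
                "" if p.family_history is None else int(p.family_history),
                "" if p.ipss is None else p.ipss,
                p.charlson,
                r.outcome,
            ])


def read_survival_cohort_csv(path) -> List[SurvivalRecord]:
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        _check_header(path, reader.fieldnames, SURVIVAL_COLUMNS[:1] + SURVIVAL_COLUMNS[2:])
        for rownum, row in enumerate(reader, start=1):
            try:
                charlson = _clean(row.get("charlson"))
                status = _clean(row.get("status"))
                if status is None:
                    raise ValueError("missing status")
                records.append(SurvivalRecord(
                    age_at_entry=float(_clean(row["age"])),
                    charlson=charlson,
                    follow_up_months=float(_clean(row["follow_up_months"])),
                    status=status.lower(),
                ))
            except (ValueError, TypeError, KeyError) as exc:
                raise CohortFormatError(f"{path}: row {rownum}: {exc}") from exc
    return records


def write_survival_cohort_csv(records: Sequence[SurvivalRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SURVIVAL_COLUMNS)
        for r in records:
            writer.writerow([
                f"{r.age_at_entry:.6g}",
                "" if r.charlson is None else r.charlson,
                f"{r.follow_up_months:.6g}",
                r.status,
            ])


def read_life_table_csv(path) -> LifeTable:
    df = pd.read_csv(path)
    if not {"age", "hazard"} <= set(df.columns):
        raise CohortFormatError(f"{path}: life table needs columns age, hazard")
    try:
        return LifeTable.from_frame(df)
    except ValueError as exc:
        raise CohortFormatError(f"{path}: {exc}") from exc


def write_life_table_csv(table: LifeTable, path) -> None:
    table.to_frame().to_csv(path, index=False)


def read_survival_points_csv(path) -> List[SurvivalCurvePoints]:
    df = pd.read_csv(path)
    need = {"age_band", "charlson", "gleason_band", "t_years", "survival"}
    if not need <= set(df.columns):
        raise CohortFormatError(f"{path}: survival points need columns {sorted(need)}")
    out = []
    for (band, ch, gl), grp in df.groupby(["age_band", "charlson", "gleason_band"],
                                          sort=True):
        grp = grp.sort_values("t_years")
        try:
            out.append(SurvivalCurvePoints(
                age_band=str(band), charlson=str(ch), gleason_band=str(gl),
                points=tuple(zip(grp["t_years"].astype(float),
                                 grp["survival"].astype(float))),
            ))
        except ValueError as exc:
            raise CohortFormatError(
                f"{path}: stratum ({band}, {ch}, {gl}): {exc}") from exc
    return out


def write_survival_points_csv(strata: Sequence[SurvivalCurvePoints], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["age_band", "charlson", "gleason_band", "t_years", "survival"])
        for s in strata:
            for t, surv in s.points:
                writer.writerow([s.age_band, s.charlson, s.gleason_band,
                                 f"{t:.6g}", f"{surv:.10g}"])


def write_decision_curve_csv(points: Sequence[DecisionCurvePoint], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["threshold", "nb_model", "nb_default", "nb_all", "nb_none",
                         "biopsies_avoided_per_1000"])
        for p in points:
            writer.writerow([
                f"{p.threshold:.4g}", f"{p.net_benefit_model:.8g}",
                f"{p.net_benefit_default:.8g}", f"{p.net_benefit_all:.8g}",
                f"{p.net_benefit_none:.8g}", f"{p.biopsies_avoided_per_1000:.6g}",
            ])


def write_metrics_json(report: MetricReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")
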