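"""Parsing, filtering and per-year aggregation of diagnosis records.

A registry is long-format delimited text with one row per treatment episode
(patient identifier, calendar year, disease code, care setting).  Records are
filtered by ICD-9-CM-style code classes, optionally mapped to analysis-level
codes (e.g. an ICD -> PheCode grouping table supplied by the user), and then
collapsed into per-year binary patient x disease incidence matrices from
which the co-occurrence counts used by the phi-correlation are derived.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SETTINGS = ("inpatient", "outpatient")

#: Numeric 3-digit prefix ranges removed from analysis (inclusive), alongside
#: all E- and V-prefixed codes: pregnancy/childbirth/puerperium 630-679 and
#: the 760-999 block.
EXCLUDED_RANGES: tuple[tuple[int, int], ...] = ((630, 679), (760, 999))


@dataclass(frozen=True)
class DiagnosisRecord:
    """One treatment episode: a patient diagnosed with a code in a year."""

    patient_id: str
    year: int
    code: str
    setting: str

    def __post_init__(self) -> None:
        if self.setting not in SETTINGS:
            raise ValueError(f"setting must be one of {SETTINGS}, got {self.setting!r}")
        if not self.code:
            raise ValueError("code must be non-empty")


@dataclass
class ParseReport:
    """Row accounting for :func:`parse_records`."""

    n_rows: int = 0
    n_parsed: int = 0
    n_rejected: int = 0
    reasons: Counter = field(default_factory=Counter)


@dataclass
class FilterReport:
    """Accounting for code-class filtering."""

    n_in: int = 0
    n_removed: int = 0
    n_unclassifiable: int = 0
    removed_by_class: Counter = field(default_factory=Counter)


@dataclass
class CodeMap:
    """Many-to-one mapping raw code -> analysis code (e.g. ICD-9 -> PheCode)."""

    entries: dict[str, str]

    @classmethod
    def identity(cls) -> "CodeMap":
        return cls(entries={})

    @classmethod
    def from_csv(cls, path: str | Path, *, raw_col: str = "raw", mapped_col: str = "mapped") -> "CodeMap":
        df = pd.read_csv(path, dtype=str)
        for col in (raw_col, mapped_col):
            if col not in df.columns:
                raise ValueError(f"code map {path} lacks required column {col!r}")
        return cls(entries=dict(zip(df[raw_col], df[mapped_col])))

    def __getitem__(self, code: str) -> str:
        return self.entries.get(code, code) if not self.entries else self.entries[code]

    def get(self, code: str) -> str | None:
        if not self.entries:  # identity map
            return code
        return self.entries.get(code)


def parse_records(
    path: str | Path,
    *,
    delimiter: str | None = None,
    patient_col: str = "patient_id",
    year_col: str = "year",
    code_col: str = "code",
    setting_col: str = "setting",
    year_range: tuple[int, int] | None = None,
) -> tuple[list[DiagnosisRecord], ParseReport]:
    """Read a delimited registry file into validated records.

    Malformed rows (unparseable year, empty code, unknown setting, year
    outside ``year_range``) are rejected and counted, not fatal; a missing
    required column is a hard error.
    """
    path = Path(path)
    if delimiter is None:
        delimiter = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    required = [patient_col, year_col, code_col, setting_col]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")

    report = ParseReport(n_rows=len(df))
    records: list[DiagnosisRecord] = []
    for patient, year_s, code, setting in zip(
        df[patient_col], df[year_col], df[code_col], df[setting_col]
    ):
        try:
            year = int(year_s)
        except (TypeError, ValueError):
            report.n_rejected += 1
            report.reasons["bad_year"] += 1
            continue
        if year_range is not None and not (year_range[0] <= year <= year_range[1]):
            report.n_rejected += 1
            report.reasons["year_out_of_range"] += 1
            continue
        code = code.strip()
        setting = setting.strip().lower()
        if not code:
            report.n_rejected += 1
            report.reasons["empty_code"] += 1
            continue
        if setting not in SETTINGS:
            report.n_rejected += 1
            report.reasons["bad_setting"] += 1
            continue
        records.append(DiagnosisRecord(str(patient), year, code, setting))
    report.n_parsed = len(records)
    if report.n_rejected:
        logger.warning("parse_records: rejected %d/%d rows (%s)", report.n_rejected, report.n_rows, dict(report.reasons))
    return records, report


def _numeric_prefix(code: str) -> int | None:
    head = code.split(".", 1)[0]
    return int(head) if head.isdigit() else None


def code_is_excluded(code: str) -> bool:
    """True if the raw code belongs to a removed ICD-9-CM class.

    Removed: E codes (external causes of injury), V codes (supplemental
    classification), and codes whose 3-digit numeric prefix falls in
    :data:`EXCLUDED_RANGES`.  Codes that are neither E/V nor numeric-prefixed
    are retained (only the named classes are filtered).
    """
    if code[:1].upper() in ("E", "V"):
        return True
    prefix = _numeric_prefix(code)
    if prefix is None:
        return False
    return any(lo <= prefix <= hi for lo, hi in EXCLUDED_RANGES)


def filter_codes(records: Iterable[DiagnosisRecord]) -> tuple[list[DiagnosisRecord], FilterReport]:
    """Remove records in the excluded code classes; idempotent."""
    report = FilterReport()
    kept: list[DiagnosisRecord] = []
    for rec in records:
        report.n_in += 1
        if code_is_excluded(rec.code):
            report.n_removed += 1
            key = "EV" if rec.code[:1].upper() in ("E", "V") else "range"
            report.removed_by_class[key] += 1
            continue
        if _numeric_prefix(rec.code) is None:
            report.n_unclassifiable += 1
        kept.append(rec)
    if report.n_unclassifiable:
        logger.info("filter_codes: %d records with non-numeric, non-E/V codes retained", report.n_unclassifiable)
    return kept, report


def apply_code_map(
    records: Iterable[DiagnosisRecord],
    code_map: CodeMap,
    *,
    on_unmapped: str = "keep",
) -> tuple[list[DiagnosisRecord], Counter]:
    """Replace each record's code with its analysis-level code.

    ``on_unmapped`` is one of ``keep`` (pass the raw code through), ``drop``
    (remove the record, counted) or ``error`` (raise, listing offenders).
    """
    if on_unmapped not in {"keep", "drop", "error"}:
        raise ValueError(f"on_unmapped must be keep|drop|error, got {on_unmapped!r}")
    out: list[DiagnosisRecord] = []
    dropped: Counter = Counter()
    unmapped: set[str] = set()
    for rec in records:
        mapped = code_map.get(rec.code)
        if mapped is None:
            if on_unmapped == "error":
                unmapped.add(rec.code)
                continue
            if on_unmapped == "drop":
                dropped[rec.code] += 1
                continue
            mapped = rec.code
        if mapped == rec.code:
            out.append(rec)
        else:
            out.append(DiagnosisRecord(rec.patient_id, rec.year, mapped, rec.setting))
    if unmapped:
        raise ValueError(f"apply_code_map: {len(unmapped)} unmapped code(s): {sorted(unmapped)[:20]}")
    if dropped:
        logger.warning("apply_code_map: dropped %d records with unmapped codes", sum(dropped.values()))
    return out, dropped


@dataclass
class YearlyOccurrence:
    """Binary patient x disease incidence for one calendar year.

    ``incidence[p, d] = 1`` iff patient ``p`` had at least one retained episode
    of disease ``d`` that year, pooling inpatient and outpatient settings.
    Marginals: ``N`` patients, ``P[d]`` patients with disease ``d``, and the
    co-occurrence counts ``C[i, j]`` = patients with both ``i`` and ``j``
    (in the same or different episodes).
    """

    year: int
    patients: list[str]
    diseases: list[str]
    incidence: np.ndarray  # (n_patients, n_diseases) uint8

    @property
    def N(self) -> int:
        return len(self.patients)

    @property
    def P(self) -> pd.Series:
        return pd.Series(self.incidence.sum(axis=0), index=self.diseases, name="P")

    @property
    def C(self) -> np.ndarray:
        inc = self.incidence.astype(np.int64)
        return inc.T @ inc

    def restrict(self, diseases: Sequence[str]) -> "YearlyOccurrence":
        """Restrict columns to ``diseases`` (order as given); patients kept."""
        idx = {d: i for i, d in enumerate(self.diseases)}
        cols = [idx[d] for d in diseases if d in idx]
        keep = [d for d in diseases if d in idx]
        return YearlyOccurrence(self.year, list(self.patients), keep, self.incidence[:, cols])

    def validate(self) -> None:
        inc = self.incidence
        if inc.shape != (len(self.patients), len(self.diseases)):
            raise ValueError("incidence shape does not match patient/disease lists")
        if not np.isin(inc, (0, 1)).all():
            raise ValueError("incidence must be binary")
        C = self.C
        if not np.array_equal(np.diag(C), self.P.to_numpy()):
            raise ValueError("C_ii must equal P_i")


def build_yearly_occurrence(
    records: Iterable[DiagnosisRecord],
    year: int,
    *,
    patients: Sequence[str] | None = None,
    diseases: Sequence[str] | None = None,
) -> YearlyOccurrence:
    """Collapse one year's records into a binary incidence matrix.

    Episode multiplicity collapses to presence/absence.  By default a patient
    enters ``N`` only with >= 1 retained record that year; pass ``patients``
    to impose a fixed cohort instead.  ``diseases`` pins the column universe
    (columns absent that year become all-zero).
    """
    recs = [r for r in records if r.year == year]
    if not recs:
        raise ValueError(f"no records for year {year}")
    pat_list = sorted({r.patient_id for r in recs}) if patients is None else list(patients)
    dis_list = sorted({r.code for r in recs}) if diseases is None else list(diseases)
    p_idx = {p: i for i, p in enumerate(pat_list)}
    d_idx = {d: i for i, d in enumerate(dis_list)}
    inc = np.zeros((len(pat_list), len(dis_list)), dtype=np.uint8)
    for r in recs:
        pi = p_idx.get(r.patient_id)
        di = d_idx.get(r.code)
        if pi is not None and di is not None:
            inc[pi, di] = 1
    return YearlyOccurrence(year, pat_list, dis_list, inc)


def common_disease_filter(yearly: Sequence[YearlyOccurrence]) -> list[str]:
    """Codes with nonzero occurrence in every supplied year, sorted.

    Emulates the common-disease restriction used to stabilise estimates: a
    disease must appear in each calendar year of the study window.
    """
    if not yearly:
        raise ValueError("no yearly occurrences supplied")
    common: set[str] | None = None
    for occ in yearly:
        present = {d for d, p in occ.P.items() if p >= 1}
        common = present if common is None else common & present
    assert common is not None
    if not common:
        raise ValueError("common-disease filter left no diseases (degenerate study)")
    return sorted(common)


def restrict_to_common(yearly: Sequence[YearlyOccurrence]) -> tuple[list[str], list[YearlyOccurrence]]:
    """Apply :func:`common_disease_filter` and restrict every year to it."""
    codes = common_disease_filter(yearly)
    return codes, [occ.restrict(codes) for occ in yearly]


def write_occurrence(occ: YearlyOccurrence, outdir: str | Path) -> tuple[Path, Path]:
    """Serialise as a sparse triplet CSV plus a per-disease marginals CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trip_path = outdir / f"occurrence_{occ.year}.csv"
    rows, cols = np.nonzero(occ.incidence)
    pd.DataFrame(
        {
            "patient_id": [occ.patients[i] for i in rows],
            "code": [occ.diseases[j] for j in cols],
            "present": 1,
        }
    ).to_csv(trip_path, index=False)
    marg_path = outdir / f"marginals_{occ.year}.csv"
    occ.P.rename_axis("code").reset_index().to_csv(marg_path, index=False)
    return trip_path, marg_path
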