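"""Claims table I/O and the AMI case definition.

A *claim* is one inpatient billing record: patient and provider identifiers,
admission/discharge dates, the admission route, ICD-10 diagnosis codes
(primary plus an ordered list of secondary codes) and procedure codes.
This module reads and writes the flat claims CSV, validates records, applies
the acute-myocardial-infarction case definition (ICD-10 I21.X as primary or
secondary diagnosis; I22–I25 do not qualify), and classifies procedure codes
into diagnostic angiography versus therapeutic revascularization.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

__all__ = [
    "ClaimRecord",
    "CaseDefinition",
    "ProcedureFlags",
    "ClaimsSchemaError",
    "ClaimsValidationError",
    "CLAIMS_COLUMNS",
    "read_claims",
    "write_claims",
    "select_ami_claims",
    "qualification_status",
    "classify_procedures",
]

#: Canonical claims CSV column order.
CLAIMS_COLUMNS = [
    "claim_id",
    "patient_id",
    "provider_id",
    "sex",
    "age_years",
    "admission_date",
    "discharge_date",
    "admission_route",
    "dx_primary",
    "dx_secondary",
    "proc_codes",
]

SEX_VALUES = frozenset({"male", "female", "unknown"})
ROUTE_VALUES = frozenset({"emergency", "other", "unknown"})

LIST_SEP = ";"


class ClaimsSchemaError(ValueError):
    """The claims file header does not match the documented schema."""


class ClaimsValidationError(ValueError):
    """A claim row violates a record-level invariant."""


@dataclass(frozen=True)
class ClaimRecord:
    """One hospitalization claim.

    ``dx_secondary`` and ``proc_codes`` are stored as tuples so records are
    immutable and comparable. ``provider_id`` may be the empty string when the
    billing provider is not recorded.
    """

    claim_id: str
    patient_id: str
    provider_id: str
    sex: str
    age_years: int
    admission_date: dt.date
    discharge_date: dt.date
    admission_route: str
    dx_primary: str
    dx_secondary: tuple[str, ...] = ()
    proc_codes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.sex not in SEX_VALUES:
            raise ClaimsValidationError(
                f"claim {self.claim_id}: sex {self.sex!r} not in {sorted(SEX_VALUES)}"
            )
        if self.admission_route not in ROUTE_VALUES:
            raise ClaimsValidationError(
                f"claim {self.claim_id}: admission_route {self.admission_route!r} "
                f"not in {sorted(ROUTE_VALUES)}"
            )
        if self.age_years < 0:
            raise ClaimsValidationError(
                f"claim {self.claim_id}: negative age {self.age_years}"
            )
        if self.discharge_date < self.admission_date:
            raise ClaimsValidationError(
                f"claim {self.claim_id}: discharge {self.discharge_date} "
                f"precedes admission {self.admission_date}"
            )


class ProcedureFlags(NamedTuple):
    """Per-claim invasive-procedure indicators."""

    has_angiography: bool
    has_revascularization: bool
    has_invasive: bool


def _normalize_code(code: str) -> str:
    """Canonical form for code matching: uppercase, dot stripped.

    Both "I21.0" and "I210" dialects occur in claims extracts.
    """
    return code.strip().upper().replace(".", "")


@dataclass(frozen=True)
class CaseDefinition:
    """Code sets defining a qualifying AMI claim and invasive procedures.

    Diagnosis matching is by ICD-10 code *prefix*, dot- and case-insensitive.
    ``strict_exclusion=False`` (the default) lets a qualifying I21 code win
    over a co-occurring excluded I22–I25 code; strict mode drops such claims.
    The procedure code values are configuration, not a standard: the default
    synthetic set matches the bundled claims generator.
    """

    qualifying_dx_prefixes: frozenset[str] = frozenset({"I21"})
    excluded_dx_prefixes: frozenset[str] = frozenset({"I22", "I23", "I24", "I25"})
    angiography_codes: frozenset[str] = frozenset({"CAG01"})
    revascularization_codes: frozenset[str] = frozenset({"PCI01", "CABG1"})
    strict_exclusion: bool = False

    def __post_init__(self) -> None:
        qual = {_normalize_code(p) for p in self.qualifying_dx_prefixes}
        excl = {_normalize_code(p) for p in self.excluded_dx_prefixes}
        if qual & excl:
            raise ValueError(
                f"qualifying and excluded prefixes overlap: {sorted(qual & excl)}"
            )
        ang = {_normalize_code(c) for c in self.angiography_codes}
        rev = {_normalize_code(c) for c in self.revascularization_codes}
        if ang & rev:
            raise ValueError(
                f"angiography and revascularization codes overlap: {sorted(ang & rev)}"
            )

    # -- prefix predicates ---------------------------------------------------

    def _matches_any(self, code: str, prefixes: Iterable[str]) -> bool:
        norm = _normalize_code(code)
        return any(norm.startswith(_normalize_code(p)) for p in prefixes)

    def is_qualifying_code(self, code: str) -> bool:
        return self._matches_any(code, self.qualifying_dx_prefixes)

    def is_excluded_code(self, code: str) -> bool:
        return self._matches_any(code, self.excluded_dx_prefixes)


def qualification_status(claim: ClaimRecord, case_def: CaseDefinition) -> str:
    """Classify why a claim is kept or dropped by the case definition.

    Returns one of:

    ``"qualifying"``
        has an I21-prefixed primary or secondary diagnosis (and, under strict
        exclusion, no excluded code);
    ``"excluded_override"``
        has a qualifying code but also an excluded I22–I25 code, under strict
        exclusion;
    ``"excluded_only"``
        its only AMI-spectrum codes carry excluded prefixes;
    ``"no_ami_code"``
        carries neither qualifying nor excluded codes.

    Every claim maps to exactly one status, so selection never drops silently.
    """
    codes = (claim.dx_primary, *claim.dx_secondary)
    has_qual = any(case_def.is_qualifying_code(c) for c in codes)
    has_excl = any(case_def.is_excluded_code(c) for c in codes)
    if has_qual:
        if has_excl and case_def.strict_exclusion:
            return "excluded_override"
        return "qualifying"
    if has_excl:
        return "excluded_only"
    return "no_ami_code"


def select_ami_claims(
    claims: Iterable[ClaimRecord], case_def: CaseDefinition | None = None
) -> list[ClaimRecord]:
    """Return the claims qualifying as AMI admissions, in input order.

    A claim qualifies when its primary or any secondary diagnosis starts with
    a qualifying prefix (default I21). Claims whose only AMI-spectrum codes
    start with excluded prefixes (default I22–I25, post-AMI and other
    ischaemic heart disease) are dropped, as are claims with no AMI-spectrum
    code at all. Idempotent: re-selecting a selected list is the identity.
    """
    case_def = case_def or CaseDefinition()
    return [c for c in claims if qualification_status(c, case_def) == "qualifying"]


def classify_procedures(claim: ClaimRecord, case_def: CaseDefinition | None = None) -> ProcedureFlags:
    """Flag diagnostic angiography and therapeutic revascularization codes.

    ``has_invasive`` is the disjunction: coronary angiography counts as an
    invasive procedure alongside angioplasty and bypass surgery.
    """
    case_def = case_def or CaseDefinition()
    ang_set = {_normalize_code(c) for c in case_def.angiography_codes}
    rev_set = {_normalize_code(c) for c in case_def.revascularization_codes}
    codes = {_normalize_code(c) for c in claim.proc_codes}
    has_ang = bool(codes & ang_set)
    has_rev = bool(codes & rev_set)
    return ProcedureFlags(has_ang, has_rev, has_ang or has_rev)


# -- CSV I/O -----------------------------------------------------------------


def _parse_date(value: str, claim_id: str, column: str) -> dt.date:
    try:
        return dt.date.fromisoformat(value.strip())
    except ValueError as exc:
        raise ClaimsValidationError(
            f"claim {claim_id}: unparseable {column} {value!r}"
        ) from exc


def _parse_list(value: str) -> tuple[str, ...]:
    value = value.strip()
    if not value:
        return ()
    return tuple(item.strip() for item in value.split(LIST_SEP) if item.strip())


def read_claims(path) -> list[ClaimRecord]:
    """Read a claims CSV into validated :class:`ClaimRecord` objects.

    Raises :class:`ClaimsSchemaError` when a mandatory column is missing and
    :class:`ClaimsValidationError` (citing the claim_id) for unparseable dates,
    discharge-before-admission rows, duplicate claim ids, or enum violations.
    Blank sex or admission route is mapped to ``"unknown"``.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CLAIMS_COLUMNS if c not in header]
        if missing:
            raise ClaimsSchemaError(
                f"claims file {path} is missing mandatory column(s): {', '.join(missing)}"
            )
        claims: list[ClaimRecord] = []
        seen: set[str] = set()
        for row in reader:
            claim_id = (row["claim_id"] or "").strip()
            if not claim_id:
                raise ClaimsValidationError(f"row {reader.line_num}: empty claim_id")
            if claim_id in seen:
                raise ClaimsValidationError(f"duplicate claim_id {claim_id}")
            seen.add(claim_id)
            try:
                age = int(row["age_years"])
            except ValueError as exc:
                raise ClaimsValidationError(
                    f"claim {claim_id}: unparseable age_years {row['age_years']!r}"
                ) from exc
            claims.append(
                ClaimRecord(
                    claim_id=claim_id,
                    patient_id=(row["patient_id"] or "").strip(),
                    provider_id=(row["provider_id"] or "").strip(),
                    sex=(row["sex"] or "").strip().lower() or "unknown",
                    age_years=age,
                    admission_date=_parse_date(row["admission_date"], claim_id, "admission_date"),
                    discharge_date=_parse_date(row["discharge_date"], claim_id, "discharge_date"),
                    admission_route=(row["admission_route"] or "").strip().lower() or "unknown",
                    dx_primary=(row["dx_primary"] or "").strip(),
                    dx_secondary=_parse_list(row["dx_secondary"] or ""),
                    proc_codes=_parse_list(row["proc_codes"] or ""),
                )
            )
    return claims


def write_claims(claims: Iterable[ClaimRecord], path) -> None:
    """Write claims as CSV in the canonical column order.

    ISO-8601 dates; list fields semicolon-joined (empty list -> empty cell).
    ``write_claims`` then :func:`read_claims` is the identity on validated
    claim lists.
    """
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CLAIMS_COLUMNS)
        for c in claims:
            writer.writerow(
                [
                    c.claim_id,
                    c.patient_id,
                    c.provider_id,
                    c.sex,
                    c.age_years,
                    c.admission_date.isoformat(),
                    c.discharge_date.isoformat(),
                    c.admission_route,
                    c.dx_primary,
                    LIST_SEP.join(c.dx_secondary),
                    LIST_SEP.join(c.proc_codes),
                ]
            )
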