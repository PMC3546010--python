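"""Canonical CSV schemas, domain record types, and validated readers/writers.

The four registry tables exchanged between modules are plain CSV files with
ISO 8601 (``YYYY-MM-DD``) calendar dates and no time-of-day component
anywhere.  Missing optional values are empty fields; classification columns
that do not apply to an episode (for example the onset of a contamination
episode) carry the single not-applicable sentinel ``NA``.

Validation is total and collecting: every input row is either accepted or
appears exactly once in the :class:`ValidationReport`, mirroring how registry
extracts are cleaned in practice.  Only structural problems (a missing
required column) abort the read.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: Not-applicable sentinel used for inapplicable classification columns.
NA = "NA"


class SchemaError(ValueError):
    """The file header does not match the named table schema."""


class ContactType(str, Enum):
    INPATIENT = "inpatient"
    OUTPATIENT = "outpatient"


class OnsetAssessment(str, Enum):
    """Physician variable 1: contamination / place of onset."""

    CONTAMINATION = "contamination"
    COMMUNITY_ONSET = "community_onset"
    HEALTHCARE_ASSOCIATED = "healthcare_associated"
    HOSPITAL_ONSET = "hospital_onset"


class MicroAssessment(str, Enum):
    """Physician variable 2: contamination / mono- or polymicrobial."""

    CONTAMINATION = "contamination"
    MONOMICROBIAL = "monomicrobial"
    POLYMICROBIAL = "polymicrobial"


#: Charlson comorbidity score categories (pre-computed upstream).
COMORBIDITY_CATEGORIES = ("0", "1-2", ">2")


# ---------------------------------------------------------------------------
# Domain record types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BloodCultureRecord:
    """One positive-culture observation — one row in the laboratory database.

    A single blood-culture *set* may produce several rows (per bottle and per
    organism, depending on the laboratory's numbering practice); rows are
    never deduplicated here.  ``draw_date`` may be missing, ``receipt_date``
    never is.
    """

    record_id: str
    patient_id: str
    draw_date: date | None
    receipt_date: date
    organism_name: str
    source_site: str | None = None


@dataclass(frozen=True)
class HospitalContact:
    """One inpatient or outpatient (ambulatory/emergency-room) contact."""

    contact_id: str
    patient_id: str
    contact_type: ContactType
    indate: date
    outdate: date


@dataclass(frozen=True)
class PhysicianAssessment:
    """The physicians' two classification variables for one assessed culture.

    ``assessed_date`` is the best-estimate-date of the assessed culture.  The
    two variables must agree on whether the culture is a contamination.
    """

    patient_id: str
    assessed_date: date
    class_onset: OnsetAssessment
    class_micro: MicroAssessment


@dataclass(frozen=True)
class FollowUpRecord:
    """Vital-status follow-up and pre-categorized comorbidity for one patient."""

    patient_id: str
    death_date: date | None = None
    emigration_date: date | None = None
    comorbidity_category: str | None = None


@dataclass
class Episode:
    """A windowed group of positive blood cultures with classification labels.

    ``kind`` is ``"computer"`` for algorithm-derived episodes and
    ``"reference"`` for physician-assessment-anchored episodes.  Label fields
    are ``None`` while unclassified or when inapplicable (onset and
    healthcare-association only exist for bloodstream-infection episodes, the
    HCA flag only for community-onset ones).  Reference episodes additionally
    carry the anchoring assessment's two physician labels.
    """

    episode_id: str
    patient_id: str
    kind: str  # "computer" | "reference"
    index_date: date
    member_record_ids: tuple[str, ...]
    contamination: bool | None = None
    polymicrobial: bool | None = None
    onset: str | None = None  # "community" | "hospital"
    healthcare_associated: bool | None = None
    incident: bool | None = None
    phys_onset: OnsetAssessment | None = None
    phys_micro: MicroAssessment | None = None


# ---------------------------------------------------------------------------
# Validation report
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RowError:
    line: int  # 1-based file line number (header is line 1)
    message: str


@dataclass
class ValidationReport:
    table: str
    n_accepted: int = 0
    errors: list[RowError] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def reject(self, line: int, message: str) -> None:
        self.errors.append(RowError(line, message))

    def summary(self) -> dict:
        return {
            "table": self.table,
            "accepted": self.n_accepted,
            "rejected": len(self.errors),
            "errors": [{"line": e.line, "message": e.message} for e in self.errors],
            "warnings": list(self.warnings),
        }


# ---------------------------------------------------------------------------
# Schemas
# ---------------------------------------------------------------------------

SCHEMAS: dict[str, tuple[str, ...]] = {
    "blood_cultures": (
        "record_id", "patient_id", "draw_date", "receipt_date",
        "organism_name", "source_site",
    ),
    "contacts": ("contact_id", "patient_id", "contact_type", "indate", "outdate"),
    "assessments": ("patient_id", "assessed_date", "class_onset", "class_micro"),
    "followup": ("patient_id", "death_date", "emigration_date", "comorbidity_category"),
    "episodes": (
        "episode_id", "patient_id", "kind", "index_date", "member_record_ids",
        "contamination", "polymicrobial", "onset", "healthcare_associated",
        "incident", "phys_onset", "phys_micro",
    ),
}


def _parse_date(value: str, label: str) -> date:
    try:
        return date.fromisoformat(value.strip())
    except ValueError as exc:
        raise ValueError(f"unparseable {label} {value!r}") from exc


def _parse_opt_date(value: str, label: str) -> date | None:
    value = value.strip()
    if not value:
        return None
    return _parse_date(value, label)


def _open_rows(path: Path | str, table: str):
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = tuple(reader.fieldnames or ())
        missing = [c for c in SCHEMAS[table] if c not in header]
        if missing:
            raise SchemaError(
                f"{path}: missing required column(s) {', '.join(missing)} "
                f"for table {table!r}"
            )
        yield from ((i, row) for i, row in enumerate(reader, start=2))


# ---------------------------------------------------------------------------
# Readers (one per table)
# ---------------------------------------------------------------------------

def read_table(path: Path | str, table: str):
    """Read and validate one registry table.

    Returns ``(records, report)``.  Rows violating a field type or an
    invariant are rejected and enumerated in the report with their file line
    number; a header that does not match the schema raises
    :class:`SchemaError`.
    """
    readers = {
        "blood_cultures": _read_blood_cultures,
        "contacts": _read_contacts,
        "assessments": _read_assessments,
        "followup": _read_followup,
        "episodes": read_episode_table,
    }
    if table not in readers:
        raise KeyError(f"unknown table {table!r}; expected one of {sorted(readers)}")
    if table == "episodes":
        return read_episode_table(path)
    return readers[table](path)


def _read_blood_cultures(path):
    report = ValidationReport("blood_cultures")
    records: list[BloodCultureRecord] = []
    seen_ids: set[str] = set()
    for line, row in _open_rows(path, "blood_cultures"):
        try:
            record_id = row["record_id"].strip()
            if not record_id:
                raise ValueError("empty record_id")
            if record_id in seen_ids:
                raise ValueError(f"duplicate record_id {record_id!r}")
            draw = _parse_opt_date(row["draw_date"], "draw_date")
            receipt_raw = row["receipt_date"].strip()
            if not receipt_raw:
                raise ValueError("receipt_date is required")
            receipt = _parse_date(receipt_raw, "receipt_date")
            if draw is not None and draw > receipt:
                raise ValueError(f"draw_date {draw} after receipt_date {receipt}")
            organism = row["organism_name"].strip()
            if not organism:
                raise ValueError("empty organism_name")
            rec = BloodCultureRecord(
                record_id=record_id,
                patient_id=row["patient_id"].strip(),
                draw_date=draw,
                receipt_date=receipt,
                organism_name=organism,
                source_site=row["source_site"].strip() or None,
            )
        except ValueError as exc:
            report.reject(line, str(exc))
            continue
        seen_ids.add(record_id)
        records.append(rec)
    report.n_accepted = len(records)
    return records, report


def _read_contacts(path):
    report = ValidationReport("contacts")
    contacts: list[HospitalContact] = []
    seen: set[str] = set()
    for line, row in _open_rows(path, "contacts"):
        try:
            cid = row["contact_id"].strip()
            if not cid:
                raise ValueError("empty contact_id")
            if cid in seen:
                raise ValueError(f"duplicate contact_id {cid!r}")
            try:
                ctype = ContactType(row["contact_type"].strip())
            except ValueError:
                raise ValueError(f"invalid contact_type {row['contact_type']!r}")
            indate = _parse_date(row["indate"], "indate")
            outdate = _parse_date(row["outdate"], "outdate")
            if indate > outdate:
                raise ValueError(f"indate {indate} after outdate {outdate}")
            contact = HospitalContact(cid, row["patient_id"].strip(), ctype, indate, outdate)
        except ValueError as exc:
            report.reject(line, str(exc))
            continue
        seen.add(cid)
        contacts.append(contact)
    report.n_accepted = len(contacts)
    return contacts, report


def _read_assessments(path):
    report = ValidationReport("assessments")
    assessments: list[PhysicianAssessment] = []
    for line, row in _open_rows(path, "assessments"):
        try:
            try:
                onset = OnsetAssessment(row["class_onset"].strip())
            except ValueError:
                raise ValueError(f"invalid class_onset {row['class_onset']!r}")
            try:
                micro = MicroAssessment(row["class_micro"].strip())
            except ValueError:
                raise ValueError(f"invalid class_micro {row['class_micro']!r}")
            if (onset is OnsetAssessment.CONTAMINATION) != (
                micro is MicroAssessment.CONTAMINATION
            ):
                raise ValueError(
                    "inconsistent assessment: the two variables disagree on "
                    f"contamination ({onset.value} vs {micro.value})"
                )
            assessment = PhysicianAssessment(
                patient_id=row["patient_id"].strip(),
                assessed_date=_parse_date(row["assessed_date"], "assessed_date"),
                class_onset=onset,
                class_micro=micro,
            )
        except ValueError as exc:
            report.reject(line, str(exc))
            continue
        assessments.append(assessment)
    report.n_accepted = len(assessments)
    return assessments, report


def _read_followup(path):
    report = ValidationReport("followup")
    records: list[FollowUpRecord] = []
    seen: set[str] = set()
    for line, row in _open_rows(path, "followup"):
        try:
            pid = row["patient_id"].strip()
            if not pid:
                raise ValueError("empty patient_id")
            if pid in seen:
                raise ValueError(f"more than one follow-up record for patient {pid!r}")
            cat = row["comorbidity_category"].strip().replace("–", "-") or None
            if cat is not None and cat not in COMORBIDITY_CATEGORIES:
                raise ValueError(f"invalid comorbidity_category {cat!r}")
            rec = FollowUpRecord(
                patient_id=pid,
                death_date=_parse_opt_date(row["death_date"], "death_date"),
                emigration_date=_parse_opt_date(row["emigration_date"], "emigration_date"),
                comorbidity_category=cat,
            )
        except ValueError as exc:
            report.reject(line, str(exc))
            continue
        seen.add(pid)
        records.append(rec)
    report.n_accepted = len(records)
    return records, report


# ---------------------------------------------------------------------------
# Episode table round trip
# ---------------------------------------------------------------------------

def _fmt_bool(value: bool | None) -> str:
    if value is None:
        return NA
    return "true" if value else "false"


def _fmt_opt(value) -> str:
    if value is None:
        return NA
    if isinstance(value, Enum):
        return value.value
    return str(value)


def _parse_opt_bool(value: str, label: str) -> bool | None:
    value = value.strip()
    if value == NA or value == "":
        return None
    if value == "true":
        return True
    if value == "false":
        return False
    raise ValueError(f"invalid boolean {value!r} for {label}")


def write_episode_table(episodes: Iterable[Episode], path: Path | str) -> None:
    """Write classified episodes to CSV, one row per episode.

    Inapplicable labels (all labels of an unclassified episode; onset/HCA of
    a contamination episode) are emitted as the ``NA`` sentinel.  The file
    round-trips losslessly through :func:`read_episode_table`.
    """
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SCHEMAS["episodes"])
        for ep in episodes:
            writer.writerow([
                ep.episode_id,
                ep.patient_id,
                ep.kind,
                ep.index_date.isoformat(),
                ";".join(ep.member_record_ids),
                _fmt_bool(ep.contamination),
                _fmt_bool(ep.polymicrobial),
                _fmt_opt(ep.onset),
                _fmt_bool(ep.healthcare_associated),
                _fmt_bool(ep.incident),
                _fmt_opt(ep.phys_onset),
                _fmt_opt(ep.phys_micro),
            ])


def read_episode_table(path: Path | str):
    """Read an episode table written by :func:`write_episode_table`."""
    report = ValidationReport("episodes")
    episodes: list[Episode] = []
    seen: set[str] = set()
    for line, row in _open_rows(path, "episodes"):
        try:
            eid = row["episode_id"].strip()
            if not eid:
                raise ValueError("empty episode_id")
            if eid in seen:
                raise ValueError(f"duplicate episode_id {eid!r}")
            kind = row["kind"].strip()
            if kind not in ("computer", "reference"):
                raise ValueError(f"invalid kind {kind!r}")
            members = tuple(m for m in row["member_record_ids"].split(";") if m)
            contamination = _parse_opt_bool(row["contamination"], "contamination")
            onset_raw = row["onset"].strip()
            onset = None if onset_raw in (NA, "") else onset_raw
            if onset is not None and onset not in ("community", "hospital"):
                raise ValueError(f"invalid onset {onset!r}")
            hca = _parse_opt_bool(row["healthcare_associated"], "healthcare_associated")
            if contamination and (onset is not None or hca is not None):
                raise ValueError("contamination episode carries onset/HCA labels")
            if hca is not None and onset != "community":
                raise ValueError("healthcare_associated set on a non-community episode")
            phys_onset_raw = row["phys_onset"].strip()
            phys_micro_raw = row["phys_micro"].strip()
            ep = Episode(
                episode_id=eid,
                patient_id=row["patient_id"].strip(),
                kind=kind,
                index_date=_parse_date(row["index_date"], "index_date"),
                member_record_ids=members,
                contamination=contamination,
                polymicrobial=_parse_opt_bool(row["polymicrobial"], "polymicrobial"),
                onset=onset,
                healthcare_associated=hca,
                incident=_parse_opt_bool(row["incident"], "incident"),
                phys_onset=None if phys_onset_raw in (NA, "") else OnsetAssessment(phys_onset_raw),
                phys_micro=None if phys_micro_raw in (NA, "") else MicroAssessment(phys_micro_raw),
            )
        except ValueError as exc:
            report.reject(line, str(exc))
            continue
        seen.add(eid)
        episodes.append(ep)
    report.n_accepted = len(episodes)
    return episodes, report


# ---------------------------------------------------------------------------
# Grouping helpers shared by downstream modules
# ---------------------------------------------------------------------------

def group_by_patient(items: Sequence) -> dict[str, list]:
    """Group records/contacts/episodes by their ``patient_id``, preserving order."""
    out: dict[str, list] = {}
    for item in items:
        out.setdefault(item.patient_id, []).append(item)
    return out
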