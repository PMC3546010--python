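"""Best-estimate-dates, computer episodes, reference episodes, incident flags.

A *computer episode* groups all of a patient's positive blood cultures on an
index date and the following calendar day; the next episode starts at the
first available best-estimate-date after that 2-day span.  A *reference
episode* is anchored by a recorded physician assessment; unassessed cultures
occurring within 30 days after the anchor are attached to it.  A patient's
first reference episode is *incident* when no positive culture (including
lag-year cultures) precedes it within 365 days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta

from .io import (
    BloodCultureRecord,
    Episode,
    PhysicianAssessment,
    group_by_patient,
)

logger = logging.getLogger(__name__)

EPISODE_SPAN_DAYS = 2  # index date plus the day after
ATTACHMENT_WINDOW_DAYS = 30
INCIDENT_LOOKBACK_DAYS = 365


def best_estimate_date(record: BloodCultureRecord) -> date:
    """The culture's draw date, or its receipt date when the draw date is missing."""
    return record.draw_date if record.draw_date is not None else record.receipt_date


def build_computer_episodes(
    records: list[BloodCultureRecord], *, span_days: int = EPISODE_SPAN_DAYS
) -> list[Episode]:
    """Partition one patient's cultures into computer episodes, in date order.

    Every record belongs to exactly one episode.  Episode 1 spans the earliest
    best-estimate-date ``D`` through ``D + span_days - 1``; each subsequent
    episode starts at the earliest best-estimate-date strictly after the
    previous span.  An empty record list yields an empty collection.
    """
    if not records:
        return []
    patient_ids = {r.patient_id for r in records}
    if len(patient_ids) != 1:
        raise ValueError(f"records span multiple patients: {sorted(patient_ids)}")
    patient_id = records[0].patient_id
    if span_days < 1:
        raise ValueError("span_days must be positive")

    by_date: dict[date, list[str]] = {}
    for r in records:
        by_date.setdefault(best_estimate_date(r), []).append(r.record_id)
    dates = sorted(by_date)

    episodes: list[Episode] = []
    i = 0
    while i < len(dates):
        start = dates[i]
        end = start + timedelta(days=span_days - 1)
        members: list[str] = []
        while i < len(dates) and dates[i] <= end:
            members.extend(by_date[dates[i]])
            i += 1
        episodes.append(
            Episode(
                episode_id=f"{patient_id}-C{len(episodes) + 1:02d}",
                patient_id=patient_id,
                kind="computer",
                index_date=start,
                member_record_ids=tuple(sorted(members)),
            )
        )
    return episodes


@dataclass
class ReferenceBuildResult:
    episodes: list[Episode] = field(default_factory=list)
    unattached_record_ids: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)


def build_reference_episodes(
    records: list[BloodCultureRecord],
    assessments: list[PhysicianAssessment],
    *,
    attachment_days: int = ATTACHMENT_WINDOW_DAYS,
) -> ReferenceBuildResult:
    """Derive one patient's reference episodes from the physician assessments.

    Each distinct assessed date anchors one reference episode carrying that
    assessment's two physician labels.  Cultures whose best-estimate-date
    equals an anchor date are members of that episode; unassessed cultures
    within ``attachment_days`` after an anchor attach to the earliest covering
    episode; unassessed cultures predating the first anchor (or falling beyond
    every attachment window) remain unattached.  An assessment whose date
    matches no culture is a validation error; conflicting assessments on the
    same date resolve first-by-order with a warning.
    """
    result = ReferenceBuildResult()
    if not assessments:
        result.unattached_record_ids = [r.record_id for r in records]
        return result
    patient_ids = {a.patient_id for a in assessments} | {r.patient_id for r in records}
    if len(patient_ids) != 1:
        raise ValueError(f"inputs span multiple patients: {sorted(patient_ids)}")
    patient_id = assessments[0].patient_id

    bed_by_record = {r.record_id: best_estimate_date(r) for r in records}
    culture_dates = set(bed_by_record.values())

    chosen: dict[date, PhysicianAssessment] = {}
    for a in assessments:
        if a.assessed_date not in culture_dates:
            result.errors.append(
                f"assessment on {a.assessed_date} matches no culture "
                f"best-estimate-date for patient {patient_id}"
            )
            continue
        if a.assessed_date in chosen:
            if a != chosen[a.assessed_date]:
                msg = (
                    f"conflicting assessments on {a.assessed_date} for patient "
                    f"{patient_id}; keeping the first by file order"
                )
                result.warnings.append(msg)
                logger.warning(msg)
            continue
        chosen[a.assessed_date] = a

    anchors = sorted(chosen)
    episodes = []
    for k, anchor in enumerate(anchors, start=1):
        a = chosen[anchor]
        members = [rid for rid, bed in bed_by_record.items() if bed == anchor]
        episodes.append(
            Episode(
                episode_id=f"{patient_id}-R{k:02d}",
                patient_id=patient_id,
                kind="reference",
                index_date=anchor,
                member_record_ids=tuple(sorted(members)),
                phys_onset=a.class_onset,
                phys_micro=a.class_micro,
            )
        )

    # Attach unassessed cultures to the earliest episode whose window
    # (anchor, anchor + attachment_days] covers them; assessed dates always
    # take the assessed-date rule above.
    anchor_set = set(anchors)
    extra_members: dict[int, list[str]] = {}
    for rid, bed in bed_by_record.items():
        if bed in anchor_set:
            continue
        target = None
        for idx, anchor in enumerate(anchors):
            if anchor < bed <= anchor + timedelta(days=attachment_days):
                target = idx
                break
        if target is None:
            result.unattached_record_ids.append(rid)
        else:
            extra_members.setdefault(target, []).append(rid)
    for idx, extra in extra_members.items():
        ep = episodes[idx]
        ep.member_record_ids = tuple(sorted((*ep.member_record_ids, *extra)))

    result.episodes = episodes
    result.unattached_record_ids.sort()
    return result


def flag_incident(
    reference_episodes: list[Episode],
    records: list[BloodCultureRecord],
    *,
    lookback_days: int = INCIDENT_LOOKBACK_DAYS,
) -> list[Episode]:
    """Set the incident flag on one patient's reference episodes (in place).

    The first reference episode is incident iff no positive culture of the
    patient (lag-year records included) has a best-estimate-date in the
    ``lookback_days`` days strictly before its index date; the boundary is
    inclusive, so a culture exactly ``lookback_days`` days earlier makes the
    episode non-incident.  All later reference episodes are non-incident.
    """
    if not reference_episodes:
        return reference_episodes
    ordered = sorted(reference_episodes, key=lambda e: e.index_date)
    first = ordered[0]
    window_start = first.index_date - timedelta(days=lookback_days)
    prior = any(
        window_start <= best_estimate_date(r) < first.index_date for r in records
    )
    first.incident = not prior
    for ep in ordered[1:]:
        ep.incident = False
    return reference_episodes


# ---------------------------------------------------------------------------
# Cohort-level drivers
# ---------------------------------------------------------------------------

def derive_computer_episodes(
    records: list[BloodCultureRecord], *, span_days: int = EPISODE_SPAN_DAYS
) -> list[Episode]:
    """Build computer episodes for every patient in a cohort."""
    by_pid = group_by_patient(records)
    episodes: list[Episode] = []
    for pid in sorted(by_pid):
        episodes.extend(build_computer_episodes(by_pid[pid], span_days=span_days))
    return episodes


def derive_reference_episodes(
    records: list[BloodCultureRecord],
    assessments: list[PhysicianAssessment],
    *,
    attachment_days: int = ATTACHMENT_WINDOW_DAYS,
    lookback_days: int = INCIDENT_LOOKBACK_DAYS,
) -> ReferenceBuildResult:
    """Build and incident-flag reference episodes for every patient."""
    records_by_pid = group_by_patient(records)
    assessments_by_pid = group_by_patient(assessments)
    result = ReferenceBuildResult()
    for pid in sorted(set(records_by_pid) | set(assessments_by_pid)):
        patient_result = build_reference_episodes(
            records_by_pid.get(pid, []),
            assessments_by_pid.get(pid, []),
            attachment_days=attachment_days,
        )
        flag_incident(
            patient_result.episodes,
            records_by_pid.get(pid, []),
            lookback_days=lookback_days,
        )
        result.episodes.extend(patient_result.episodes)
        result.unattached_record_ids.extend(patient_result.unattached_record_ids)
        result.warnings.extend(patient_result.warnings)
        result.errors.extend(patient_result.errors)
    return result
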