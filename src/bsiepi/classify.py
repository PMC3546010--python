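"""The four rule-based classifiers applied to episodes of positive cultures.

Rules, in the order the pipeline runs them:

1. *Organism class* — a fixed lexicon maps each recorded organism label to
   commensal (common skin flora: coagulase-negative staphylococci and the
   genera *Propionibacterium*, *Bacillus*, *Micrococcus*, *Corynebacterium*,
   plus the laboratories' provisional labels) or pathogen (everything else).
2. *Contamination* — an episode is a contamination when only commensals grew,
   all on the episode's index date, with no further commensal growth from the
   patient in the following four calendar days (a 5-day repeat-growth screen);
   otherwise it is a bloodstream infection (BSI).
3. *Polymicrobial* — a BSI episode with two or more distinct recorded
   organism labels (case-insensitive, trimmed; provisional labels count as
   distinct types).
4. *Onset and healthcare-association* — linkage offsets ``time_in`` (culture
   date minus admission date) and ``time_out`` (culture date minus discharge
   date) are formed for every combination of episode culture date and
   hospital contact, keeping pairs with ``time_in >= -2`` and
   ``time_out <= 30``.  A BSI episode is hospital-onset when the smallest
   inpatient ``time_in`` is >= 2 days, or when it is 0-1 day but an
   intra-hospital transfer pattern is present; otherwise community-onset.
   A community-onset episode is healthcare-associated when any retained
   inpatient or outpatient contact ended 1-30 days before the culture, or
   began more than 30 days before and ended within the 30-day window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Iterable, Sequence

from .io import (
    BloodCultureRecord,
    ContactType,
    Episode,
    HospitalContact,
    group_by_patient,
)
from .episodes import best_estimate_date

logger = logging.getLogger(__name__)

COMMENSAL = "commensal"
PATHOGEN = "pathogen"
CONTAMINATION = "contamination"
BSI = "bsi"
COMMUNITY = "community"
HOSPITAL = "hospital"

CONTAMINATION_WINDOW_DAYS = 5  # index date plus the 4 following days
HCA_WINDOW_DAYS = 30

# Retention bounds for linkage offsets: contacts admitted more than 2 days
# after, or discharged more than 30 days before, the culture date are omitted.
TIME_IN_MIN = -2
TIME_OUT_MAX = 30

#: Coagulase-negative staphylococcal species treated as skin commensals.
_CONS_SPECIES = frozenset({
    "staphylococcus epidermidis",
    "staphylococcus hominis",
    "staphylococcus haemolyticus",
    "staphylococcus capitis",
    "staphylococcus saprophyticus",
    "staphylococcus warneri",
    "staphylococcus lugdunensis",
    "staphylococcus simulans",
    "staphylococcus schleiferi",
    "staphylococcus cohnii",
    "staphylococcus auricularis",
    "staphylococcus pettenkoferi",
})


def normalize_organism(name: str) -> str:
    """Trim and lowercase an organism label (no further normalization)."""
    return name.strip().lower()


@dataclass(frozen=True)
class OrganismLexicon:
    """Commensal lexicon; every label not matched is a pathogen.

    ``genus_prefixes`` match on the first whitespace-delimited token of the
    normalized label (so any ``Corynebacterium ...`` species matches);
    ``exact_labels`` match provisional labels verbatim; ``species_labels``
    list full species names, by default the common coagulase-negative
    staphylococci.  All three sets are overridable through the run
    configuration.
    """

    genus_prefixes: tuple[str, ...] = (
        "propionibacterium",
        "bacillus",
        "micrococcus",
        "corynebacterium",
    )
    exact_labels: frozenset = frozenset(
        {"coagulase-negative staphylococcus", "coryneform rod"}
    )
    species_labels: frozenset = _CONS_SPECIES

    def is_commensal(self, name: str) -> bool:
        norm = normalize_organism(name)
        if norm in self.exact_labels or norm in self.species_labels:
            return True
        first_token = norm.split()[0] if norm.split() else ""
        return first_token in self.genus_prefixes


DEFAULT_LEXICON = OrganismLexicon()


def classify_organism(name: str, lexicon: OrganismLexicon = DEFAULT_LEXICON) -> str:
    """Map one organism label to ``"commensal"`` or ``"pathogen"``."""
    if not name.strip():
        raise ValueError("empty organism name")
    return COMMENSAL if lexicon.is_commensal(name) else PATHOGEN


# ---------------------------------------------------------------------------
# Contamination and polymicrobial rules
# ---------------------------------------------------------------------------

def _member_records(
    episode: Episode, patient_records: Sequence[BloodCultureRecord]
) -> list[BloodCultureRecord]:
    members = set(episode.member_record_ids)
    return [r for r in patient_records if r.record_id in members]


def classify_contamination(
    episode: Episode,
    patient_records: Sequence[BloodCultureRecord],
    lexicon: OrganismLexicon = DEFAULT_LEXICON,
    *,
    window_days: int = CONTAMINATION_WINDOW_DAYS,
) -> str:
    """``"contamination"`` or ``"bsi"`` for one computer episode.

    Contamination requires (a) every episode member to be commensal, (b) no
    commensal-positive culture of the patient — episode member or not — on
    any date in ``(index, index + window_days - 1]``, and (c) no pathogen in
    the episode; any failure makes the episode a bloodstream infection.
    The repeat-growth screen in (b) is evaluated against *all* of the
    patient's cultures because repeat commensal growth shortly after the
    index date speaks against contamination regardless of episode windowing.
    """
    members = _member_records(episode, patient_records)
    if any(classify_organism(r.organism_name, lexicon) == PATHOGEN for r in members):
        return BSI
    screen_end = episode.index_date + timedelta(days=window_days - 1)
    for r in patient_records:
        bed = best_estimate_date(r)
        if episode.index_date < bed <= screen_end:
            if classify_organism(r.organism_name, lexicon) == COMMENSAL:
                return BSI
    return CONTAMINATION


def classify_polymicrobial(
    episode: Episode, patient_records: Sequence[BloodCultureRecord]
) -> bool:
    """True when a BSI episode contains >= 2 distinct organism types.

    Duplicate per-bottle rows of the same organism do not count; provisional
    labels (e.g. ``yeast-like organism``) are distinct types even when they
    may denote an already-listed species.
    """
    names = {
        normalize_organism(r.organism_name)
        for r in _member_records(episode, patient_records)
    }
    return len(names) >= 2


# ---------------------------------------------------------------------------
# Linkage offsets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimeOffsetPair:
    """Linkage offsets for one (episode culture date, hospital contact) pair."""

    time_in: int  # best-estimate-date - indate, days
    time_out: int  # best-estimate-date - outdate, days
    contact: HospitalContact
    episode_date: date

    @property
    def contact_id(self) -> str:
        return self.contact.contact_id

    @property
    def stay_days(self) -> int:
        return (self.contact.outdate - self.contact.indate).days


def episode_member_dates(
    episode: Episode, patient_records: Sequence[BloodCultureRecord]
) -> list[date]:
    """Distinct best-estimate-dates of the episode's member cultures, sorted."""
    return sorted({best_estimate_date(r) for r in _member_records(episode, patient_records)})


def compute_time_offsets(
    episode: Episode,
    patient_records: Sequence[BloodCultureRecord],
    contacts: Sequence[HospitalContact],
    *,
    include_outpatient: bool,
) -> list[TimeOffsetPair]:
    """Retained offset pairs for every episode date x contact combination.

    Pairs with ``time_in < -2`` (admission more than 2 days after the
    culture) or ``time_out > 30`` (discharge more than 30 days before it)
    are omitted.  Outpatient contacts enter only when ``include_outpatient``
    (the healthcare-association rule); the onset rule uses inpatient
    contacts alone.
    """
    pairs: list[TimeOffsetPair] = []
    for bed in episode_member_dates(episode, patient_records):
        for contact in contacts:
            if not include_outpatient and contact.contact_type is not ContactType.INPATIENT:
                continue
            time_in = (bed - contact.indate).days
            time_out = (bed - contact.outdate).days
            if time_in < TIME_IN_MIN or time_out > TIME_OUT_MAX:
                continue
            pairs.append(TimeOffsetPair(time_in, time_out, contact, bed))
    return pairs


# ---------------------------------------------------------------------------
# Onset and healthcare-association rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OnsetResult:
    label: str  # "community" | "hospital"
    branch: str
    warning: str | None = None


def classify_onset(pairs: Iterable[TimeOffsetPair]) -> OnsetResult:
    """Place of onset for one BSI episode from retained inpatient offsets.

    Hospital-onset when the smallest inpatient ``time_in`` is >= 2 days, or
    when it is 0 or 1 day and a transfer pattern is present: (i) some
    retained contact was discharged on a culture date (``time_out = 0``)
    after a stay of >= 2 days (>= 1 day when the minimum is 1), i.e. the
    patient arrived at the culture ward from another ward the same day; or
    (ii) some retained contact spans the culture date (``time_in > 1`` and
    ``time_out < 0``).  Otherwise community-onset.  An episode with no
    retained inpatient contact — or one whose contacts all began after the
    culture date — is community-onset; both carry a distinct provenance
    branch because the source rules do not address them.
    """
    inpatient = [
        p for p in pairs if p.contact.contact_type is ContactType.INPATIENT
    ]
    if not inpatient:
        msg = "no retained inpatient contact; classified community-onset by convention"
        return OnsetResult(COMMUNITY, "no_inpatient_contact", warning=msg)
    lowest = min(p.time_in for p in inpatient)
    if lowest >= 2:
        return OnsetResult(HOSPITAL, "admitted_from_home")
    if lowest in (0, 1):
        required_stay = 2 if lowest == 0 else 1
        if any(p.time_out == 0 and p.stay_days >= required_stay for p in inpatient):
            return OnsetResult(HOSPITAL, "transfer_same_day")
        if any(p.time_in > 1 and p.time_out < 0 for p in inpatient):
            return OnsetResult(HOSPITAL, "transfer_overlapping_ward")
        return OnsetResult(COMMUNITY, "community_direct")
    return OnsetResult(COMMUNITY, "admitted_after_culture")


def classify_hca(
    pairs: Iterable[TimeOffsetPair], *, window_days: int = HCA_WINDOW_DAYS
) -> bool:
    """Healthcare-association of a community-onset episode.

    True when any retained inpatient *or* outpatient pair satisfies
    ``(time_in <= window and time_out > 0)`` or
    ``(time_in > window and 0 < time_out <= window)`` — a hospital contact
    that ended 1-30 days before the culture date, or one that began earlier
    still but likewise ended inside the window.
    """
    return any(
        (p.time_in <= window_days and p.time_out > 0)
        or (p.time_in > window_days and 0 < p.time_out <= window_days)
        for p in pairs
    )


# ---------------------------------------------------------------------------
# Cohort driver
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassificationProvenance:
    episode_id: str
    contamination: bool
    onset_branch: str | None
    warning: str | None


def classify_episodes(
    episodes: Sequence[Episode],
    records: Sequence[BloodCultureRecord],
    contacts: Sequence[HospitalContact],
    lexicon: OrganismLexicon = DEFAULT_LEXICON,
    *,
    contamination_window_days: int = CONTAMINATION_WINDOW_DAYS,
    hca_window_days: int = HCA_WINDOW_DAYS,
) -> list[ClassificationProvenance]:
    """Apply all four rules to every episode in place; return provenance.

    Exhaustive by construction: every BSI episode receives exactly one onset
    label, every community-onset episode exactly one HCA flag, and
    contamination episodes receive neither (their onset/HCA stay ``None``,
    serialized as ``NA``).
    """
    records_by_pid = group_by_patient(records)
    contacts_by_pid = group_by_patient(contacts)
    provenance: list[ClassificationProvenance] = []
    for ep in episodes:
        precords = records_by_pid.get(ep.patient_id, [])
        pcontacts = contacts_by_pid.get(ep.patient_id, [])
        verdict = classify_contamination(
            ep, precords, lexicon, window_days=contamination_window_days
        )
        ep.contamination = verdict == CONTAMINATION
        onset_branch = None
        warning = None
        if ep.contamination:
            ep.polymicrobial = None
            ep.onset = None
            ep.healthcare_associated = None
        else:
            ep.polymicrobial = classify_polymicrobial(ep, precords)
            inpatient_pairs = compute_time_offsets(
                ep, precords, pcontacts, include_outpatient=False
            )
            onset = classify_onset(inpatient_pairs)
            ep.onset = onset.label
            onset_branch = onset.branch
            warning = onset.warning
            if onset.warning:
                logger.warning("%s: %s", ep.episode_id, onset.warning)
            if ep.onset == COMMUNITY:
                all_pairs = compute_time_offsets(
                    ep, precords, pcontacts, include_outpatient=True
                )
                ep.healthcare_associated = classify_hca(
                    all_pairs, window_days=hca_window_days
                )
            else:
                ep.healthcare_associated = None
        provenance.append(
            ClassificationProvenance(ep.episode_id, ep.contamination, onset_branch, warning)
        )
        logger.debug(
            "%s contamination=%s poly=%s onset=%s (%s) hca=%s",
            ep.episode_id, ep.contamination, ep.polymicrobial, ep.onset,
            onset_branch, ep.healthcare_associated,
        )
    return provenance
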