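"""Synthetic linked registries with known ground-truth episode classes.

The generator emulates the data model of two hospital laboratories feeding a
national patient registry: per-bottle duplicate culture rows (site-dependent
multiplicity), ~9% missing draw dates, a commensal/pathogen organism mix
including provisional labels, admissions, same-day ward transfers and
outpatient contacts around the culture dates, physician assessments with
configurable per-comparison discordance, lag-year cultures, and 30-day
deaths.

Planting is *constructive*: for each planted episode the emitted cultures
and contacts are built so that the classification rules provably yield the
planted class — ground truth is exact by construction, never estimated by
rejection sampling.  Missing draw dates are injected so that the
best-estimate-date is unchanged (the receipt date of a masked row equals its
draw date), keeping planted truth exact under missingness.

Identical config + seed reproduces every output table byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    SCHEMAS,
    BloodCultureRecord,
    ContactType,
    FollowUpRecord,
    HospitalContact,
    MicroAssessment,
    OnsetAssessment,
    PhysicianAssessment,
)

PATHOGENS = (
    "Escherichia coli",
    "Staphylococcus aureus",
    "Streptococcus pneumoniae",
    "Klebsiella pneumoniae",
    "Enterococcus faecalis",
    "Pseudomonas aeruginosa",
    "Candida albicans",
    "yeast-like organism",  # provisional label, not in the commensal lexicon
)

COMMENSALS = (
    "Staphylococcus epidermidis",
    "Staphylococcus hominis",
    "Corynebacterium striatum",
    "Propionibacterium acnes",
    "Bacillus cereus",
    "Micrococcus luteus",
    "coagulase-negative staphylococcus",
    "coryneform rod",
)

#: Onset scenarios that tolerate a second culture date on index + 1 without
#: changing the planted onset or HCA class.  Excluded: community_day1 (the
#: day-2 offset pair would fire the overlapping-ward clause), admitted_after
#: (the day-2 pair lifts the minimal time_in to 0), and outpatient_only (the
#: same-day emergency-room contact would count as a prior contact of the
#: day-2 culture date and flip the HCA flag).
_TWO_DATE_SCENARIOS = frozenset(
    {"community_day0", "home_direct", "same_day_transfer", "overlapping_ward"}
)

#: Scenarios safe for an attached unassessed pathogen culture 6-25 days later
#: (the extra culture then provably forms a hospital-onset computer episode).
_ATTACHABLE_SCENARIOS = frozenset(
    {"contamination", "community_day0", "community_day1", "home_direct",
     "same_day_transfer", "overlapping_ward"}
)

# Minimum spacing between a patient's planted episodes: with post-index
# contact durations <= 5 days this keeps every 30-day linkage window, the
# 5-day contamination screen and the 30-day attachment window of one episode
# clear of the next.
_EPISODE_GAP_DAYS = 45


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass
class SyntheticCohortConfig:
    """Distributions and rates governing registry simulation.

    Defaults are loosely calibrated to the shape of a 3-year two-hospital
    cohort: ~20% contamination episodes, ~13% polymicrobial and ~30%
    hospital-onset bloodstream infections, ~9% missing draw dates,
    per-comparison physician discordance matching the observed discrepant
    shares, and ~20% 30-day mortality among episodes.
    """

    n_patients: int = 1800
    study_start: date = date(2006, 1, 1)
    study_end: date = date(2008, 12, 31)
    lag_start: date = date(2005, 1, 1)
    seed: int = 0

    # episode intensity and classes
    extra_episode_prob: float = 0.12
    contamination_prob: float = 0.20
    polymicrobial_prob: float = 0.13
    hospital_onset_prob: float = 0.30
    hca_prob: float = 0.40

    # onset scenario mix
    transfer_same_day_prob: float = 0.15   # share of hospital-onset episodes
    transfer_overlap_prob: float = 0.15    # share of hospital-onset episodes
    community_day1_prob: float = 0.30      # share of community episodes
    outpatient_only_prob: float = 0.03     # share of community episodes
    admitted_after_prob: float = 0.02      # share of community episodes
    commensal_repeat_prob: float = 0.03    # share of BSI episodes
    second_day_prob: float = 0.35          # two-date episodes where allowed

    # laboratory recording quirks
    missing_draw_date_rate: float = 0.088
    receipt_delay_prob: float = 0.30
    herlev_share: float = 0.55
    duplicate_row_distribution: dict = field(default_factory=lambda: {
        "herlev": (0.30, 0.30, 0.25, 0.15),   # 1-4 rows per organism (per bottle)
        "hvidovre": (0.45, 0.55),             # 1-2 rows per organism (per 2 bottles)
    })

    # assessment coverage and discordance
    unassessed_rate: float = 0.10
    attachment_rate: float = 0.08
    lag_culture_rate: float = 0.01
    physician_discordance: dict = field(default_factory=lambda: {
        "contamination": 0.054,
        "polymicrobial": 0.049,
        "onset": 0.169,
        "hca": 0.360,
    })

    # follow-up
    mortality: dict = field(default_factory=lambda: {
        "contamination": 0.10,
        "community": 0.16,
        "hca": 0.22,
        "hospital": 0.30,
    })
    emigration_rate: float = 0.001
    comorbidity_probs: tuple = (0.25, 0.36, 0.39)

    def validate(self) -> None:
        probs = {
            "extra_episode_prob": self.extra_episode_prob,
            "contamination_prob": self.contamination_prob,
            "polymicrobial_prob": self.polymicrobial_prob,
            "hospital_onset_prob": self.hospital_onset_prob,
            "hca_prob": self.hca_prob,
            "transfer_same_day_prob": self.transfer_same_day_prob,
            "transfer_overlap_prob": self.transfer_overlap_prob,
            "community_day1_prob": self.community_day1_prob,
            "outpatient_only_prob": self.outpatient_only_prob,
            "admitted_after_prob": self.admitted_after_prob,
            "commensal_repeat_prob": self.commensal_repeat_prob,
            "second_day_prob": self.second_day_prob,
            "missing_draw_date_rate": self.missing_draw_date_rate,
            "receipt_delay_prob": self.receipt_delay_prob,
            "herlev_share": self.herlev_share,
            "unassessed_rate": self.unassessed_rate,
            "attachment_rate": self.attachment_rate,
            "lag_culture_rate": self.lag_culture_rate,
            "emigration_rate": self.emigration_rate,
            **{f"discordance[{k}]": v for k, v in self.physician_discordance.items()},
            **{f"mortality[{k}]": v for k, v in self.mortality.items()},
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} = {p} outside [0, 1]")
        if self.n_patients <= 0:
            raise ConfigError("n_patients must be positive")
        if self.study_start >= self.study_end:
            raise ConfigError("empty study window")
        if self.lag_start > self.study_start:
            raise ConfigError("lag window must precede the study window")
        if self.hospital_onset_prob >= 1.0 and self.hca_prob > 0.0:
            raise ConfigError(
                "hca_prob > 0 is inconsistent with hospital_onset_prob = 1 "
                "(healthcare-association applies to community-onset episodes only)"
            )
        if self.transfer_same_day_prob + self.transfer_overlap_prob > 1.0:
            raise ConfigError("transfer scenario shares exceed 1")
        if (self.community_day1_prob + self.outpatient_only_prob
                + self.admitted_after_prob) > 1.0:
            raise ConfigError("community scenario shares exceed 1")
        for site, dist in self.duplicate_row_distribution.items():
            if abs(sum(dist) - 1.0) > 1e-9:
                raise ConfigError(f"duplicate_row_distribution[{site}] does not sum to 1")
        if abs(sum(self.comorbidity_probs) - 1.0) > 1e-9:
            raise ConfigError("comorbidity_probs do not sum to 1")

    @classmethod
    def from_dict(cls, data: dict) -> "SyntheticCohortConfig":
        kwargs = dict(data)
        for key in ("study_start", "study_end", "lag_start"):
            if key in kwargs and isinstance(kwargs[key], str):
                kwargs[key] = date.fromisoformat(kwargs[key])
        if "duplicate_row_distribution" in kwargs:
            kwargs["duplicate_row_distribution"] = {
                k: tuple(v) for k, v in kwargs["duplicate_row_distribution"].items()
            }
        if "comorbidity_probs" in kwargs:
            kwargs["comorbidity_probs"] = tuple(kwargs["comorbidity_probs"])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


def plant_transfer_scenario(
    index_date: date, scenario: str, rng: np.random.Generator
) -> list[tuple[str, date, date]]:
    """Contacts exercising exactly one branch of the onset rule.

    Returns ``(contact_type, indate, outdate)`` tuples.  ``home_direct``
    yields a minimal admission-to-culture interval >= 2 days;
    ``same_day_transfer`` a prior-ward stay discharged on the culture date
    (``time_out = 0``) plus the receiving-ward admission;
    ``overlapping_ward`` a ward stay spanning the culture date
    (``time_in > 1``, ``time_out < 0``) plus the same-day admission.
    Community scenarios place the admission on the culture date
    (``community_day0``), the day before (``community_day1``), after it
    (``admitted_after``), or emit an emergency-room contact only
    (``outpatient_only``).
    """
    day = timedelta(days=1)
    stay_end = index_date + day * int(rng.integers(2, 6))
    if scenario in ("community_day0", "contamination"):
        return [("inpatient", index_date, stay_end)]
    if scenario == "community_day1":
        return [("inpatient", index_date - day, stay_end)]
    if scenario == "home_direct":
        gap = int(rng.integers(2, 21))
        return [("inpatient", index_date - day * gap, stay_end)]
    if scenario == "same_day_transfer":
        stay = int(rng.integers(2, 8))
        return [
            ("inpatient", index_date - day * stay, index_date),
            ("inpatient", index_date, stay_end),
        ]
    if scenario == "overlapping_ward":
        before = int(rng.integers(2, 8))
        after = int(rng.integers(2, 5))
        return [
            ("inpatient", index_date - day * before, index_date + day * after),
            ("inpatient", index_date, stay_end),
        ]
    if scenario == "outpatient_only":
        return [("outpatient", index_date, index_date)]
    if scenario == "admitted_after":
        return [("inpatient", index_date + day * 2, index_date + day * 5)]
    raise ValueError(f"unknown scenario {scenario!r}")


@dataclass
class SimulatedCohort:
    """The four registry tables plus the ground-truth label table."""

    cultures: pd.DataFrame
    contacts: pd.DataFrame
    assessments: pd.DataFrame
    followup: pd.DataFrame
    truth: pd.DataFrame
    config: SyntheticCohortConfig

    def write(self, outdir: Path | str) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, frame in [
            ("blood_cultures", self.cultures),
            ("contacts", self.contacts),
            ("assessments", self.assessments),
            ("followup", self.followup),
            ("truth", self.truth),
        ]:
            path = outdir / f"{name}.csv"
            frame.to_csv(path, index=False)
            paths[name] = path
        return paths

    # In-memory conversions so the pipeline can run without touching disk.
    def culture_records(self) -> list[BloodCultureRecord]:
        return [
            BloodCultureRecord(
                record_id=r.record_id,
                patient_id=r.patient_id,
                draw_date=date.fromisoformat(r.draw_date) if r.draw_date else None,
                receipt_date=date.fromisoformat(r.receipt_date),
                organism_name=r.organism_name,
                source_site=r.source_site or None,
            )
            for r in self.cultures.itertuples(index=False)
        ]

    def contact_records(self) -> list[HospitalContact]:
        return [
            HospitalContact(
                contact_id=r.contact_id,
                patient_id=r.patient_id,
                contact_type=ContactType(r.contact_type),
                indate=date.fromisoformat(r.indate),
                outdate=date.fromisoformat(r.outdate),
            )
            for r in self.contacts.itertuples(index=False)
        ]

    def assessment_records(self) -> list[PhysicianAssessment]:
        return [
            PhysicianAssessment(
                patient_id=r.patient_id,
                assessed_date=date.fromisoformat(r.assessed_date),
                class_onset=OnsetAssessment(r.class_onset),
                class_micro=MicroAssessment(r.class_micro),
            )
            for r in self.assessments.itertuples(index=False)
        ]

    def followup_records(self) -> list[FollowUpRecord]:
        return [
            FollowUpRecord(
                patient_id=r.patient_id,
                death_date=date.fromisoformat(r.death_date) if r.death_date else None,
                emigration_date=(
                    date.fromisoformat(r.emigration_date) if r.emigration_date else None
                ),
                comorbidity_category=r.comorbidity_category or None,
            )
            for r in self.followup.itertuples(index=False)
        ]


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _draw_scenario(rng, cfg, contamination: bool) -> tuple[str, bool]:
    """(onset scenario, hospital?) for one episode."""
    if contamination:
        return "contamination", False
    if rng.random() < cfg.hospital_onset_prob:
        u = rng.random()
        if u < cfg.transfer_same_day_prob:
            return "same_day_transfer", True
        if u < cfg.transfer_same_day_prob + cfg.transfer_overlap_prob:
            return "overlapping_ward", True
        return "home_direct", True
    u = rng.random()
    if u < cfg.outpatient_only_prob:
        return "outpatient_only", False
    if u < cfg.outpatient_only_prob + cfg.admitted_after_prob:
        return "admitted_after", False
    if u < (cfg.outpatient_only_prob + cfg.admitted_after_prob
            + cfg.community_day1_prob):
        return "community_day1", False
    return "community_day0", False


def _pick_organisms(rng, cfg, scenario: str, two_date: bool, repeat: bool,
                    poly: bool) -> list[tuple[str, int]]:
    """(organism name, day offset) pairs for one episode's cultures."""
    if scenario == "contamination":
        k = 2 if rng.random() < 0.3 else 1
        idx = rng.choice(len(COMMENSALS), size=k, replace=False)
        return [(COMMENSALS[int(i)], 0) for i in idx]
    if repeat:
        name = COMMENSALS[int(rng.integers(0, len(COMMENSALS)))]
        return [(name, 0), (name, 1)]
    if poly:
        k = 3 if rng.random() < 0.2 else 2
        catalogue = PATHOGENS + COMMENSALS
        first = PATHOGENS[int(rng.integers(0, 7))]  # a speciated pathogen
        others: list[str] = []
        while len(others) < k - 1:
            cand = catalogue[int(rng.integers(0, len(catalogue)))]
            if cand != first and cand not in others:
                others.append(cand)
        out = [(first, 0)]
        for name in others:
            offset = 1 if (two_date and rng.random() < 0.5) else 0
            out.append((name, offset))
        if two_date and not any(off == 1 for _, off in out):
            out[-1] = (out[-1][0], 1)
        return out
    name = PATHOGENS[int(rng.integers(0, 7))]
    out = [(name, 0)]
    if two_date:
        out.append((name, 1))
    return out


def _flip(rng, p: float) -> bool:
    return rng.random() < p


def _physician_labels(rng, cfg, truth: dict) -> tuple[str, str]:
    """Physician (class_onset, class_micro) = truth with configured flips."""
    disc = cfg.physician_discordance
    truth_bsi = not truth["contamination"]
    phys_bsi = truth_bsi != _flip(rng, disc["contamination"])
    if not phys_bsi:
        return ("contamination", "contamination")
    if not truth_bsi:
        # contamination flipped to BSI: default to community-onset monomicrobial
        return ("community_onset", "monomicrobial")
    phys_poly = bool(truth["polymicrobial"]) != _flip(rng, disc["polymicrobial"])
    truth_hospital = truth["onset"] == "hospital"
    phys_hospital = truth_hospital != _flip(rng, disc["onset"])
    if phys_hospital:
        onset_label = "hospital_onset"
    else:
        truth_hca = truth["healthcare_associated"] is True
        phys_hca = truth_hca != _flip(rng, disc["hca"])
        onset_label = "healthcare_associated" if phys_hca else "community_onset"
    return (onset_label, "polymicrobial" if phys_poly else "monomicrobial")


def simulate_cohort(config: SyntheticCohortConfig | None = None,
                    seed: int | None = None) -> SimulatedCohort:
    """Generate the four registry tables and the ground-truth label table.

    ``seed`` overrides ``config.seed`` when given.  Physician labels equal
    the planted truth except for flips at the configured per-comparison
    discordance rates; duplicate bottle rows and missing draw dates are
    injected after construction without disturbing any best-estimate-date.
    """
    cfg = config or SyntheticCohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    day = timedelta(days=1)

    culture_rows: list[dict] = []
    contact_rows: list[dict] = []
    assessment_rows: list[dict] = []
    followup_rows: list[dict] = []
    truth_rows: list[dict] = []

    record_n = 0
    contact_n = 0

    span_days = (cfg.study_end - cfg.study_start).days

    def emit_culture(pid, site, d: date, organism: str) -> None:
        nonlocal record_n
        dist = cfg.duplicate_row_distribution[site]
        n_rows = int(rng.choice(len(dist), p=dist)) + 1
        for _ in range(n_rows):
            record_n += 1
            masked = rng.random() < cfg.missing_draw_date_rate
            if masked:
                draw, receipt = "", d  # best-estimate-date unchanged
            else:
                delay = 1 if rng.random() < cfg.receipt_delay_prob else 0
                draw, receipt = d.isoformat(), d + day * delay
            culture_rows.append({
                "record_id": f"BC{record_n:07d}",
                "patient_id": pid,
                "draw_date": draw,
                "receipt_date": receipt.isoformat(),
                "organism_name": organism,
                "source_site": site,
            })

    def emit_contact(pid, ctype: str, indate: date, outdate: date) -> None:
        nonlocal contact_n
        contact_n += 1
        contact_rows.append({
            "contact_id": f"CT{contact_n:07d}",
            "patient_id": pid,
            "contact_type": ctype,
            "indate": indate.isoformat(),
            "outdate": outdate.isoformat(),
        })

    for p in range(cfg.n_patients):
        pid = f"P{p + 1:05d}"
        site = "herlev" if rng.random() < cfg.herlev_share else "hvidovre"

        n_ep = 1
        while rng.random() < cfg.extra_episode_prob and n_ep < 8:
            n_ep += 1

        all_culture_dates: list[date] = []
        patient_truths: list[dict] = []
        death_date: date | None = None

        index = cfg.study_start + day * int(rng.integers(0, max(span_days - 40, 1)))

        # lag-year culture before the first episode (makes it non-incident)
        if rng.random() < cfg.lag_culture_rate:
            lag_date = index - day * int(rng.integers(_EPISODE_GAP_DAYS, 366))
            if lag_date >= cfg.lag_start:
                emit_culture(pid, site, lag_date, PATHOGENS[0])
                emit_contact(pid, "inpatient", lag_date, lag_date + day * 3)
                all_culture_dates.append(lag_date)
                patient_truths.append({
                    "patient_id": pid, "index_date": lag_date,
                    "in_study": lag_date >= cfg.study_start, "assessed": False,
                    "scenario": "lag_prior", "contamination": False,
                    "polymicrobial": False, "onset": "community",
                    "healthcare_associated": False, "died30": False,
                })

        for _ in range(n_ep):
            if index > cfg.study_end - day:
                break
            contamination = rng.random() < cfg.contamination_prob
            scenario, hospital = _draw_scenario(rng, cfg, contamination)
            hca = (
                not contamination and not hospital
                and rng.random() < cfg.hca_prob
            )
            repeat = (
                not contamination
                and scenario in _TWO_DATE_SCENARIOS
                and rng.random() < cfg.commensal_repeat_prob
            )
            poly = not contamination and not repeat and rng.random() < cfg.polymicrobial_prob
            two_date = repeat or (
                not contamination
                and scenario in _TWO_DATE_SCENARIOS
                and rng.random() < cfg.second_day_prob
            )

            for ctype, indate, outdate in plant_transfer_scenario(index, scenario, rng):
                emit_contact(pid, ctype, indate, outdate)
            if hca:
                # a contact ending 1-30 days before the index date
                hca_type = (
                    "outpatient" if scenario == "outpatient_only"
                    else ("inpatient" if rng.random() < 0.5 else "outpatient")
                )
                time_out = int(rng.integers(1, 31))
                duration = int(rng.integers(0, 15))
                hca_out = index - day * time_out
                emit_contact(pid, hca_type, hca_out - day * duration, hca_out)

            for organism, offset in _pick_organisms(rng, cfg, scenario, two_date,
                                                    repeat, poly):
                emit_culture(pid, site, index + day * offset, organism)
            all_culture_dates.append(index)
            if two_date:
                all_culture_dates.append(index + day)

            if contamination:
                truth_class = "contamination"
            elif hospital:
                truth_class = "hospital"
            elif hca:
                truth_class = "hca"
            else:
                truth_class = "community"
            died = death_date is None and rng.random() < cfg.mortality[truth_class]
            if died:
                death_date = index + day * int(rng.integers(0, 31))

            assessed = rng.random() >= cfg.unassessed_rate
            truth = {
                "patient_id": pid, "index_date": index, "in_study": True,
                "assessed": assessed, "scenario": scenario,
                "contamination": contamination,
                "polymicrobial": None if contamination else poly,
                "onset": None if contamination else ("hospital" if hospital else "community"),
                "healthcare_associated": (
                    hca if (not contamination and not hospital) else None
                ),
                "died30": died,
            }
            patient_truths.append(truth)

            if assessed:
                class_onset, class_micro = _physician_labels(rng, cfg, truth)
                assessment_rows.append({
                    "patient_id": pid, "assessed_date": index.isoformat(),
                    "class_onset": class_onset, "class_micro": class_micro,
                })
                if (not died and scenario in _ATTACHABLE_SCENARIOS
                        and rng.random() < cfg.attachment_rate):
                    # unassessed pathogen culture 6-25 days later: attaches to
                    # the reference episode, forms its own (hospital-onset)
                    # computer episode
                    k = int(rng.integers(6, 26))
                    extra_date = index + day * k
                    if extra_date <= cfg.study_end:
                        emit_culture(pid, site, extra_date, "Escherichia coli")
                        all_culture_dates.append(extra_date)
                        patient_truths.append({
                            "patient_id": pid, "index_date": extra_date,
                            "in_study": True, "assessed": False,
                            "scenario": "attached_unassessed",
                            "contamination": False, "polymicrobial": False,
                            "onset": "hospital", "healthcare_associated": None,
                            "died30": False,
                        })

            if died:
                break
            index = index + day * (_EPISODE_GAP_DAYS + int(rng.integers(0, 60)))

        emigration_date: date | None = None
        if death_date is None and rng.random() < cfg.emigration_rate and patient_truths:
            last_index = max(t["index_date"] for t in patient_truths)
            emigration_date = last_index + day * int(rng.integers(5, 30))

        cat = ("0", "1-2", ">2")[int(rng.choice(3, p=cfg.comorbidity_probs))]
        followup_rows.append({
            "patient_id": pid,
            "death_date": death_date.isoformat() if death_date else "",
            "emigration_date": emigration_date.isoformat() if emigration_date else "",
            "comorbidity_category": cat,
        })

        # incident flag: first assessed episode with no culture in the
        # preceding 365 days (inclusive boundary)
        sorted_dates = sorted(all_culture_dates)
        first_assessed_seen = False
        for t in sorted(patient_truths, key=lambda t: t["index_date"]):
            if t["assessed"] and not first_assessed_seen:
                first_assessed_seen = True
                window_start = t["index_date"] - day * 365
                t["incident"] = not any(
                    window_start <= d < t["index_date"] for d in sorted_dates
                )
            elif t["assessed"]:
                t["incident"] = False
            else:
                t["incident"] = None
            truth_rows.append(t)

    def _fmt(v):
        if v is None:
            return "NA"
        if isinstance(v, bool):
            return str(v).lower()
        if isinstance(v, date):
            return v.isoformat()
        return v

    truth_df = pd.DataFrame(
        [{k: _fmt(v) for k, v in row.items()} for row in truth_rows],
        columns=["patient_id", "index_date", "in_study", "assessed", "scenario",
                 "contamination", "polymicrobial", "onset",
                 "healthcare_associated", "incident", "died30"],
    )
    return SimulatedCohort(
        cultures=pd.DataFrame(culture_rows, columns=list(SCHEMAS["blood_cultures"])),
        contacts=pd.DataFrame(contact_rows, columns=list(SCHEMAS["contacts"])),
        assessments=pd.DataFrame(assessment_rows, columns=list(SCHEMAS["assessments"])),
        followup=pd.DataFrame(followup_rows, columns=list(SCHEMAS["followup"])),
        truth=truth_df,
        config=cfg,
    )
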