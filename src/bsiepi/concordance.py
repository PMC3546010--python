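"""Physician-vs-algorithm concordance: linking, 2x2 tables, kappa, mortality.

The reference episode is the analytical unit.  Each reference episode is
paired with the computer episode derived from the same cultures, and four
2x2 cross-classifications are tabulated (rows = computer algorithm,
columns = physicians' assessment):

* contamination vs bloodstream infection (all linked pairs),
* mono- vs polymicrobial (pairs both sides call BSI),
* community- vs hospital-onset (pairs both sides call BSI),
* healthcare-associated or not (pairs both sides call community-onset).

Agreement is summarised by the raw percent agreement, Cohen's kappa
``(Po - Pe) / (1 - Pe)`` with marginal-product expected agreement, and the
Landis-Koch verbal band.  Crude 30-day-mortality odds ratios contrast each
cell with the concordant cell presumed prognostically worst.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .io import Episode, FollowUpRecord, OnsetAssessment, MicroAssessment

logger = logging.getLogger(__name__)

COMPARISONS = (
    "contamination_vs_bsi",
    "mono_vs_poly",
    "community_vs_hospital",
    "hca_vs_not",
)

#: Concordant cell used as the mortality reference (prognostically worst).
REFERENCE_CELL = {
    "contamination_vs_bsi": "a",  # both bloodstream infection
    "mono_vs_poly": "a",          # both polymicrobial
    "community_vs_hospital": "d", # both hospital-onset
    "hca_vs_not": "a",            # both healthcare-associated
}

MORTALITY_WINDOW_DAYS = 30


class DegenerateTableError(ValueError):
    """The statistic is undefined for this table (empty, or Pe = 1)."""


@dataclass(frozen=True)
class AgreementTable:
    """A 2x2 cross-classification; rows = algorithm, columns = physician.

    ``a`` is the concordant "positive" cell (both BSI, both polymicrobial,
    both community-onset, both healthcare-associated, respectively), ``d``
    the concordant "negative" cell, ``b`` algorithm-positive only and ``c``
    physician-positive only.
    """

    comparison: str
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def percent_agreement(table: AgreementTable) -> float:
    """Observed agreement ``(a + d) / n`` as a fraction in [0, 1]."""
    if table.total == 0:
        raise DegenerateTableError("empty table: percent agreement undefined")
    return (table.a + table.d) / table.total


def cohen_kappa(table: AgreementTable) -> float:
    """Cohen's kappa with marginal-product expected agreement.

    ``Po = (a + d)/n``; ``Pe = [(a+b)(a+c) + (c+d)(b+d)] / n^2``;
    ``kappa = (Po - Pe) / (1 - Pe)``.
    """
    n = table.total
    if n == 0:
        raise DegenerateTableError("empty table: kappa undefined")
    po = (table.a + table.d) / n
    pe = (
        (table.a + table.b) * (table.a + table.c)
        + (table.c + table.d) * (table.b + table.d)
    ) / (n * n)
    if pe == 1.0:
        raise DegenerateTableError("degenerate margins (Pe = 1): kappa undefined")
    return (po - pe) / (1.0 - pe)


def landis_koch(kappa: float) -> str:
    """Landis-Koch verbal band for a kappa value.

    Shared band edges are assigned to the lower band, except 0 which opens
    the slight band; negative values are labelled ``poor``.
    """
    if not -1.0 <= kappa <= 1.0:
        raise ValueError(f"kappa {kappa} outside [-1, 1]")
    if kappa < 0:
        return "poor"
    if kappa <= 0.2:
        return "slight"
    if kappa <= 0.4:
        return "fair"
    if kappa <= 0.6:
        return "moderate"
    if kappa <= 0.8:
        return "substantial"
    return "almost perfect"


# ---------------------------------------------------------------------------
# Linking and cross-tabulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinkedPair:
    reference: Episode
    computer: Episode


@dataclass
class LinkResult:
    pairs: list[LinkedPair]
    unpaired_reference_ids: list[str]


def link_episodes(
    reference: Sequence[Episode], computer: Sequence[Episode]
) -> LinkResult:
    """Pair each reference episode with its computer counterpart.

    Primary rule: the computer episode of the same patient with the same
    index date.  Fallback: the computer episode whose 2-day window contains
    the reference index date.  When both collections derive from the same
    records neither rule can be ambiguous (computer episodes of a patient
    are disjoint); an ambiguous match raises.
    """
    by_patient: dict[str, list[Episode]] = {}
    for ep in computer:
        by_patient.setdefault(ep.patient_id, []).append(ep)

    pairs: list[LinkedPair] = []
    unpaired: list[str] = []
    for ref in reference:
        candidates = by_patient.get(ref.patient_id, [])
        exact = [c for c in candidates if c.index_date == ref.index_date]
        if not exact:
            exact = [
                c for c in candidates
                if (ref.index_date - c.index_date).days in (0, 1)
            ]
        if len(exact) > 1:
            raise ValueError(
                f"ambiguous pairing for reference episode {ref.episode_id}: "
                f"{[c.episode_id for c in exact]}"
            )
        if exact:
            pairs.append(LinkedPair(ref, exact[0]))
        else:
            unpaired.append(ref.episode_id)
    if unpaired:
        logger.warning("%d reference episodes had no computer counterpart", len(unpaired))
    return LinkResult(pairs, unpaired)


def _phys_bsi(ref: Episode) -> bool:
    return ref.phys_onset is not OnsetAssessment.CONTAMINATION


def _phys_community(ref: Episode) -> bool:
    return ref.phys_onset in (
        OnsetAssessment.COMMUNITY_ONSET,
        OnsetAssessment.HEALTHCARE_ASSOCIATED,
    )


def _algo_bsi(comp: Episode) -> bool:
    return comp.contamination is False


def _eligible(pair: LinkedPair, comparison: str) -> bool:
    ref, comp = pair.reference, pair.computer
    if comparison == "contamination_vs_bsi":
        return True
    if comparison in ("mono_vs_poly", "community_vs_hospital"):
        return _phys_bsi(ref) and _algo_bsi(comp)
    if comparison == "hca_vs_not":
        return (
            _phys_bsi(ref)
            and _algo_bsi(comp)
            and _phys_community(ref)
            and comp.onset == "community"
        )
    raise KeyError(f"unknown comparison {comparison!r}")


def _labels(pair: LinkedPair, comparison: str) -> tuple[bool, bool] | None:
    """(algorithm positive, physician positive) or ``None`` if a label is missing."""
    ref, comp = pair.reference, pair.computer
    if comparison == "contamination_vs_bsi":
        if comp.contamination is None or ref.phys_onset is None:
            return None
        return (_algo_bsi(comp), _phys_bsi(ref))
    if comparison == "mono_vs_poly":
        if comp.polymicrobial is None or ref.phys_micro is None:
            return None
        return (
            comp.polymicrobial,
            ref.phys_micro is MicroAssessment.POLYMICROBIAL,
        )
    if comparison == "community_vs_hospital":
        if comp.onset is None or ref.phys_onset is None:
            return None
        return (comp.onset == "community", _phys_community(ref))
    if comparison == "hca_vs_not":
        if comp.healthcare_associated is None or ref.phys_onset is None:
            return None
        return (
            comp.healthcare_associated,
            ref.phys_onset is OnsetAssessment.HEALTHCARE_ASSOCIATED,
        )
    raise KeyError(f"unknown comparison {comparison!r}")


def cross_tabulate(
    pairs: Sequence[LinkedPair], comparison: str
) -> tuple[AgreementTable, int]:
    """2x2 counts for one comparison over its eligible pairs.

    Returns ``(table, n_excluded)`` where the excluded count covers eligible
    pairs missing a required label (reported, never silently dropped into a
    cell).
    """
    a = b = c = d = 0
    excluded = 0
    for pair in pairs:
        if not _eligible(pair, comparison):
            continue
        labels = _labels(pair, comparison)
        if labels is None:
            excluded += 1
            continue
        algo, phys = labels
        if algo and phys:
            a += 1
        elif algo:
            b += 1
        elif phys:
            c += 1
        else:
            d += 1
    if excluded:
        logger.warning(
            "%s: %d eligible pairs excluded for missing labels", comparison, excluded
        )
    return AgreementTable(comparison, a, b, c, d), excluded


# ---------------------------------------------------------------------------
# 30-day mortality
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Mortality30:
    died: bool
    incomplete_followup: bool


def mortality_30d(
    episode: Episode, followup: FollowUpRecord, *, window_days: int = MORTALITY_WINDOW_DAYS
) -> Mortality30:
    """Death within ``window_days`` days of the index date, inclusive.

    Emigration before day ``window_days`` without a recorded death flags the
    episode as incomplete follow-up; such episodes are excluded from
    mortality denominators and reported separately.
    """
    died = (
        followup.death_date is not None
        and 0 <= (followup.death_date - episode.index_date).days <= window_days
    )
    incomplete = (
        not died
        and followup.emigration_date is not None
        and (followup.emigration_date - episode.index_date).days < window_days
    )
    return Mortality30(died, incomplete)


@dataclass(frozen=True)
class OddsRatio:
    estimate: float
    ci_low: float
    ci_high: float


def crude_odds_ratio(
    deaths: int, survivors: int, ref_deaths: int, ref_survivors: int
) -> OddsRatio:
    """Crude OR of a group against the reference group, with 95% CI.

    ``OR = (d1 * s0) / (d0 * s1)``; the CI uses the log-OR normal
    approximation with ``SE = sqrt(1/d1 + 1/s1 + 1/d0 + 1/s0)``.  With a
    single binary covariate this closed form equals the logistic-regression
    estimate.  A zero cell raises: apply an explicit continuity handling
    upstream rather than a silent correction here.
    """
    if min(deaths, survivors, ref_deaths, ref_survivors) <= 0:
        raise ZeroDivisionError(
            "zero cell in the 2x2 mortality table; the crude odds ratio is "
            "undefined — apply a continuity handling explicitly if needed"
        )
    estimate = (deaths * ref_survivors) / (ref_deaths * survivors)
    se = math.sqrt(1 / deaths + 1 / survivors + 1 / ref_deaths + 1 / ref_survivors)
    half = 1.959963984540054 * se
    return OddsRatio(estimate, math.exp(math.log(estimate) - half), math.exp(math.log(estimate) + half))


@dataclass
class MortalityContrast:
    comparison: str
    cell: str  # "a" | "b" | "c" | "d"
    algorithm_positive: bool
    physician_positive: bool
    deaths: int
    survivors: int
    incomplete_followup: int
    is_reference: bool
    odds_ratio: OddsRatio | None
    note: str | None = None


def mortality_contrasts(
    pairs: Sequence[LinkedPair],
    comparison: str,
    followup_by_patient: Mapping[str, FollowUpRecord],
) -> list[MortalityContrast]:
    """Per-cell 30-day death counts and crude ORs against the reference cell."""
    cells: dict[str, dict[str, int]] = {
        cell: {"deaths": 0, "survivors": 0, "incomplete": 0} for cell in "abcd"
    }
    for pair in pairs:
        if not _eligible(pair, comparison):
            continue
        labels = _labels(pair, comparison)
        if labels is None:
            continue
        algo, phys = labels
        cell = "a" if (algo and phys) else "b" if algo else "c" if phys else "d"
        fu = followup_by_patient.get(pair.reference.patient_id)
        if fu is None:
            cells[cell]["incomplete"] += 1
            continue
        status = mortality_30d(pair.reference, fu)
        if status.incomplete_followup:
            cells[cell]["incomplete"] += 1
        elif status.died:
            cells[cell]["deaths"] += 1
        else:
            cells[cell]["survivors"] += 1

    ref_cell = REFERENCE_CELL[comparison]
    ref = cells[ref_cell]
    contrasts: list[MortalityContrast] = []
    for cell in "abcd":
        counts = cells[cell]
        is_ref = cell == ref_cell
        odds = None
        note = None
        if not is_ref:
            try:
                odds = crude_odds_ratio(
                    counts["deaths"], counts["survivors"], ref["deaths"], ref["survivors"]
                )
            except ZeroDivisionError as exc:
                note = str(exc)
        algo_pos = cell in ("a", "b")
        phys_pos = cell in ("a", "c")
        contrasts.append(
            MortalityContrast(
                comparison=comparison,
                cell=cell,
                algorithm_positive=algo_pos,
                physician_positive=phys_pos,
                deaths=counts["deaths"],
                survivors=counts["survivors"],
                incomplete_followup=counts["incomplete"],
                is_reference=is_ref,
                odds_ratio=odds,
                note=note,
            )
        )
    return contrasts
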