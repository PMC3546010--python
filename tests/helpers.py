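"""Shared test builders and independent brute-force oracles.

The oracles re-derive the surveillance rules directly from raw dates and
contact tuples, deliberately structured differently from the package
implementation so the two routes stay independent.
"""

from __future__ import annotations

from datetime import date, timedelta

from bsiepi import BloodCultureRecord, ContactType, Episode, HospitalContact

D0 = date(2006, 3, 10)


def rec(rid, bed, organism="Escherichia coli", pid="P1", draw=True, receipt_lag=0):
    """A blood-culture record with best-estimate-date ``bed``."""
    return BloodCultureRecord(
        record_id=rid,
        patient_id=pid,
        draw_date=bed if draw else None,
        receipt_date=bed + timedelta(days=receipt_lag) if draw else bed,
        organism_name=organism,
        source_site="lab",
    )


def contact(cid, indate, outdate, ctype=ContactType.INPATIENT, pid="P1"):
    return HospitalContact(cid, pid, ctype, indate, outdate)


def episode(records, pid="P1", kind="computer", eid=None):
    """An episode over the given records anchored at their earliest date."""
    beds = [r.draw_date or r.receipt_date for r in records]
    return Episode(
        episode_id=eid or f"{pid}-X01",
        patient_id=pid,
        kind=kind,
        index_date=min(beds),
        member_record_ids=tuple(sorted(r.record_id for r in records)),
    )


def days(n: int) -> date:
    return D0 + timedelta(days=n)


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def oracle_episode_partition(dates, span_days=2):
    """Greedy day-walk over sorted unique dates (independent re-derivation)."""
    groups: list[list[date]] = []
    start: date | None = None
    for d in sorted(set(dates)):
        if start is None or (d - start).days >= span_days:
            groups.append([d])
            start = d
        else:
            groups[-1].append(d)
    return groups


def oracle_onset(member_dates, contacts):
    """Place of onset from every (culture date, contact) pair, rule-text style.

    ``contacts`` are ``(type_str, indate, outdate)`` tuples.
    """
    pairs = []
    for d in member_dates:
        for ctype, indate, outdate in contacts:
            if ctype != "inpatient":
                continue
            t_in = (d - indate).days
            t_out = (d - outdate).days
            if t_in >= -2 and t_out <= 30:
                pairs.append((t_in, t_out, (outdate - indate).days))
    if not pairs:
        return "community"
    lowest = min(p[0] for p in pairs)
    if lowest >= 2:
        return "hospital"
    if lowest in (0, 1):
        need = 2 if lowest == 0 else 1
        same_day = any(t_out == 0 and stay >= need for _, t_out, stay in pairs)
        spanning = any(t_in > 1 and t_out < 0 for t_in, t_out, _ in pairs)
        if same_day or spanning:
            return "hospital"
    return "community"


def oracle_hca(member_dates, contacts, window=30):
    """Healthcare-association from every (culture date, contact) pair."""
    for d in member_dates:
        for _, indate, outdate in contacts:
            t_in = (d - indate).days
            t_out = (d - outdate).days
            if t_in < -2 or t_out > 30:
                continue
            if (t_in <= window and t_out > 0) or (t_in > window and 0 < t_out <= window):
                return True
    return False


def oracle_contamination(index_date, member_organisms, patient_cultures, is_commensal):
    """Contamination vs BSI from the commensal-growth-date set.

    ``patient_cultures`` are ``(best_estimate_date, organism)`` tuples over
    all of the patient's cultures.  A contamination requires commensal growth
    confined to the index date within the 5-day window and an episode free of
    pathogens.
    """
    if not member_organisms:
        return "bsi"
    commensal_dates = {
        bed
        for bed, org in patient_cultures
        if is_commensal(org) and index_date <= bed <= index_date + timedelta(days=4)
    }
    members_all_commensal = all(is_commensal(o) for o in member_organisms)
    if members_all_commensal and commensal_dates <= {index_date}:
        return "contamination"
    return "bsi"
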