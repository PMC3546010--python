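"""End-to-end pipeline and evaluation report.

``run_full_pipeline`` executes episode derivation, classification, linking
and concordance evaluation on the four registry tables and returns a JSON-
serializable report.  Every number in the report is produced by a
concordance-module operation — the reporter does no arithmetic of its own.
Re-running on identical inputs yields identical reports.

Presentation follows the surveillance convention: kappa to 2 decimals,
percentages to 1 decimal; the raw fractions are reported alongside.
"""

from __future__ import annotations

import logging

from . import concordance as cc
from . import episodes as eb
from .classify import classify_episodes
from .config import RunConfig
from .io import Episode, FollowUpRecord, read_table

logger = logging.getLogger(__name__)

#: Documented in every report: how shared Landis-Koch band edges resolve.
_BAND_CONVENTION = (
    "Landis-Koch band edges are assigned to the lower band at shared "
    "boundaries except 0, which opens the slight band; negative kappa is "
    "labelled poor."
)


def _comparison_block(
    pairs: list[cc.LinkedPair],
    comparison: str,
    followup_by_patient: dict[str, FollowUpRecord],
) -> dict:
    table, excluded = cc.cross_tabulate(pairs, comparison)
    block: dict = {
        "counts": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
        "total": table.total,
        "excluded_missing_labels": excluded,
    }
    if table.total == 0:
        block["note"] = "no eligible pairs"
        return block
    agreement = cc.percent_agreement(table)
    kappa = cc.cohen_kappa(table)
    block["percent_agreement"] = round(agreement * 100, 1)
    block["percent_agreement_raw"] = agreement
    block["kappa"] = round(kappa, 2)
    block["kappa_raw"] = kappa
    block["band"] = cc.landis_koch(kappa)
    block["mortality"] = [
        {
            "cell": m.cell,
            "algorithm_positive": m.algorithm_positive,
            "physician_positive": m.physician_positive,
            "deaths": m.deaths,
            "survivors": m.survivors,
            "incomplete_followup": m.incomplete_followup,
            "is_reference": m.is_reference,
            "odds_ratio": None if m.odds_ratio is None else round(m.odds_ratio.estimate, 2),
            "ci_low": None if m.odds_ratio is None else round(m.odds_ratio.ci_low, 2),
            "ci_high": None if m.odds_ratio is None else round(m.odds_ratio.ci_high, 2),
            "note": m.note,
        }
        for m in cc.mortality_contrasts(pairs, comparison, followup_by_patient)
    ]
    return block


def evaluate_cohort(
    records,
    contacts,
    assessments,
    followups,
    config: RunConfig | None = None,
) -> dict:
    """Run episodes -> classify -> evaluate on in-memory record collections."""
    cfg = config or RunConfig()
    cfg.validate()
    notices: list[str] = []

    computer = eb.derive_computer_episodes(records, span_days=cfg.episode_span_days)
    ref_result = eb.derive_reference_episodes(
        records,
        assessments,
        attachment_days=cfg.attachment_window_days,
        lookback_days=cfg.incident_lookback_days,
    )
    classify_episodes(
        computer,
        records,
        contacts,
        cfg.lexicon,
        contamination_window_days=cfg.contamination_window_days,
        hca_window_days=cfg.hca_window_days,
    )

    report: dict = {
        "metadata": {
            "kappa_band_convention": _BAND_CONVENTION,
            "windows": cfg.windows,
        },
        "episodes": {
            "computer": len(computer),
            "reference": len(ref_result.episodes),
            "incident_reference": sum(
                1 for e in ref_result.episodes if e.incident
            ),
            "unattached_records": len(ref_result.unattached_record_ids),
        },
        "reference_build": {
            "errors": ref_result.errors,
            "warnings": ref_result.warnings,
        },
        "comparisons": {},
        "notices": notices,
    }
    if not records:
        notices.append("empty cultures table: no episodes derived")
        return report

    link = cc.link_episodes(ref_result.episodes, computer)
    if link.unpaired_reference_ids:
        notices.append(
            f"{len(link.unpaired_reference_ids)} reference episodes had no "
            "computer counterpart"
        )
    followup_by_patient = {f.patient_id: f for f in followups}
    for comparison in cc.COMPARISONS:
        report["comparisons"][comparison] = _comparison_block(
            link.pairs, comparison, followup_by_patient
        )
    return report


def run_full_pipeline(config: RunConfig) -> dict:
    """Read the four tables per the config and evaluate; add validation summaries."""
    config.validate()
    for name in ("cultures", "contacts", "assessments", "followup"):
        if getattr(config, name) is None:
            raise ValueError(f"run config is missing the {name} table path")

    records, rep_cultures = read_table(config.cultures, "blood_cultures")
    contacts, rep_contacts = read_table(config.contacts, "contacts")
    assessments, rep_assessments = read_table(config.assessments, "assessments")
    followups, rep_followup = read_table(config.followup, "followup")

    report = evaluate_cohort(records, contacts, assessments, followups, config)
    report["validation"] = {
        r.table: r.summary()
        for r in (rep_cultures, rep_contacts, rep_assessments, rep_followup)
    }
    n_rejected = sum(len(r.errors) for r in
                     (rep_cultures, rep_contacts, rep_assessments, rep_followup))
    if n_rejected:
        report["notices"].append(f"{n_rejected} input rows rejected by validation")
    return report


def report_from_counts(counts, comparison: str | None = None) -> dict:
    """Agreement statistics for one 2x2 table given as cell counts (a, b, c, d).

    The counts-only entry point: lets published cross-classifications be
    evaluated without reconstructing a cohort.
    """
    a, b, c, d = (int(x) for x in counts)
    table = cc.AgreementTable(comparison or "counts_only", a, b, c, d)
    agreement = cc.percent_agreement(table)
    kappa = cc.cohen_kappa(table)
    discrepant = table.b + table.c
    return {
        "comparison": table.comparison,
        "counts": {"a": a, "b": b, "c": c, "d": d},
        "total": table.total,
        "percent_agreement": round(agreement * 100, 1),
        "percent_agreement_raw": agreement,
        "kappa": round(kappa, 2),
        "kappa_raw": kappa,
        "band": cc.landis_koch(kappa),
        "discrepant": discrepant,
        "metadata": {"kappa_band_convention": _BAND_CONVENTION},
    }


def render_text(report: dict) -> str:
    """Plain-text summary of a pipeline report."""
    lines: list[str] = []
    ep = report.get("episodes", {})
    lines.append("Episode classification concordance report")
    lines.append("=" * 41)
    if ep:
        lines.append(
            f"computer episodes: {ep.get('computer', 0)}   "
            f"reference episodes: {ep.get('reference', 0)} "
            f"({ep.get('incident_reference', 0)} incident)   "
            f"unattached cultures: {ep.get('unattached_records', 0)}"
        )
    for comparison, block in report.get("comparisons", {}).items():
        lines.append("")
        lines.append(comparison.replace("_", " "))
        counts = block["counts"]
        lines.append(
            f"  a={counts['a']} b={counts['b']} c={counts['c']} d={counts['d']}"
            f"  (n={block['total']})"
        )
        if "kappa" in block:
            lines.append(
                f"  agreement {block['percent_agreement']}%   "
                f"kappa {block['kappa']:.2f} ({block['band']})"
            )
        for m in block.get("mortality", []):
            if m["is_reference"]:
                tag = "reference"
            elif m["odds_ratio"] is not None:
                tag = f"OR {m['odds_ratio']} ({m['ci_low']}-{m['ci_high']})"
            else:
                tag = "OR undefined (zero cell)"
            lines.append(
                f"    cell {m['cell']}: deaths {m['deaths']}/"
                f"{m['deaths'] + m['survivors']}  {tag}"
            )
    for notice in report.get("notices", []):
        lines.append("")
        lines.append(f"NOTE: {notice}")
    return "\n".join(lines) + "\n"
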