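"""Classification rules: lexicon, contamination, polymicrobial, onset, HCA."""

from datetime import timedelta

import numpy as np
import pytest

from bsiepi import (
    ContactType,
    OrganismLexicon,
    classify_contamination,
    classify_episodes,
    classify_hca,
    classify_onset,
    classify_organism,
    classify_polymicrobial,
    compute_time_offsets,
    derive_computer_episodes,
)
from bsiepi.classify import BSI, COMMENSAL, CONTAMINATION, PATHOGEN

from helpers import contact, days, episode, oracle_contamination, oracle_hca, oracle_onset, rec


class TestOrganismLexicon:
    @pytest.mark.parametrize(
        "name, expected",
        [
            ("Staphylococcus epidermidis", COMMENSAL),  # CoNS species list
            ("Escherichia coli", PATHOGEN),
            ("yeast-like organism", PATHOGEN),           # provisional, not listed
            ("Corynebacterium striatum", COMMENSAL),     # genus prefix
            ("  PROPIONIBACTERIUM ACNES  ", COMMENSAL),  # trim + case fold
            ("coagulase-negative staphylococcus", COMMENSAL),
            ("coryneform rod", COMMENSAL),
            ("Bacilluslike organism", PATHOGEN),         # token match, not substring
            ("Staphylococcus aureus", PATHOGEN),         # coagulase-positive
        ],
    )
    def test_default_lexicon(self, name, expected):
        assert classify_organism(name) == expected

    def test_empty_name_rejected(self):
        with pytest.raises(ValueError):
            classify_organism("   ")

    def test_lexicon_override(self):
        lexicon = OrganismLexicon(
            genus_prefixes=("escherichia",), exact_labels=frozenset(),
            species_labels=frozenset(),
        )
        assert classify_organism("Escherichia coli", lexicon) == COMMENSAL
        assert classify_organism("Bacillus cereus", lexicon) == PATHOGEN


class TestContamination:
    def test_commensals_on_index_only(self):
        records = [rec("r1", days(0), "Staphylococcus epidermidis")]
        ep = episode(records)
        assert classify_contamination(ep, records) == CONTAMINATION

    def test_pathogen_in_episode_makes_bsi(self):
        records = [
            rec("r1", days(0), "Staphylococcus epidermidis"),
            rec("r2", days(1), "Escherichia coli"),
        ]
        ep = episode(records)
        assert classify_contamination(ep, records) == BSI

    def test_repeat_commensal_growth_in_five_day_window_makes_bsi(self):
        member = rec("r1", days(0), "Staphylococcus epidermidis")
        later = rec("r2", days(3), "Staphylococcus epidermidis")
        ep = episode([member])
        assert classify_contamination(ep, [member, later]) == BSI

    def test_repeat_growth_inside_episode_window_also_counts(self):
        records = [
            rec("r1", days(0), "Staphylococcus epidermidis"),
            rec("r2", days(1), "Staphylococcus epidermidis"),
        ]
        ep = episode(records)
        assert classify_contamination(ep, records) == BSI

    def test_commensal_growth_beyond_window_does_not_count(self):
        member = rec("r1", days(0), "Micrococcus luteus")
        later = rec("r2", days(5), "Micrococcus luteus")  # day 5 is outside
        ep = episode([member])
        assert classify_contamination(ep, [member, later]) == CONTAMINATION

    def test_pathogen_elsewhere_in_window_is_ignored(self):
        member = rec("r1", days(0), "Bacillus cereus")
        later = rec("r2", days(3), "Escherichia coli")  # separate episode
        ep = episode([member])
        assert classify_contamination(ep, [member, later]) == CONTAMINATION


class TestPolymicrobial:
    def test_duplicate_rows_of_one_organism_are_monomicrobial(self):
        records = [rec(f"r{i}", days(0), "Escherichia coli") for i in range(4)]
        assert classify_polymicrobial(episode(records), records) is False

    def test_provisional_label_counts_as_distinct_type(self):
        records = [
            rec("r1", days(0), "Candida albicans"),
            rec("r2", days(0), "yeast-like organism"),
        ]
        assert classify_polymicrobial(episode(records), records) is True

    def test_two_species_across_both_episode_days(self):
        records = [
            rec("r1", days(0), "Escherichia coli"),
            rec("r2", days(1), "Staphylococcus aureus"),
        ]
        assert classify_polymicrobial(episode(records), records) is True

    def test_case_and_whitespace_variants_are_one_type(self):
        records = [
            rec("r1", days(0), "Escherichia coli"),
            rec("r2", days(0), " ESCHERICHIA COLI "),
        ]
        assert classify_polymicrobial(episode(records), records) is False


class TestTimeOffsets:
    def test_subtraction_definitions(self):
        records = [rec("r1", days(0))]
        ep = episode(records)
        pairs = compute_time_offsets(
            ep, records, [contact("c1", days(-2), days(5))], include_outpatient=False
        )
        assert len(pairs) == 1
        assert pairs[0].time_in == 2 and pairs[0].time_out == -5

    def test_omission_bounds(self):
        records = [rec("r1", days(0))]
        ep = episode(records)
        discharged_long_ago = contact("c1", days(-45), days(-40))  # time_out = 40
        admitted_later = contact("c2", days(3), days(6))           # time_in = -3
        boundary_in = contact("c3", days(2), days(4))              # time_in = -2 kept
        boundary_out = contact("c4", days(-35), days(-30))         # time_out = 30 kept
        pairs = compute_time_offsets(
            ep, records,
            [discharged_long_ago, admitted_later, boundary_in, boundary_out],
            include_outpatient=False,
        )
        assert sorted(p.contact_id for p in pairs) == ["c3", "c4"]

    def test_outpatient_contacts_only_when_requested(self):
        records = [rec("r1", days(0))]
        ep = episode(records)
        contacts = [contact("c1", days(-5), days(-2), ContactType.OUTPATIENT)]
        assert compute_time_offsets(ep, records, contacts, include_outpatient=False) == []
        assert len(compute_time_offsets(ep, records, contacts, include_outpatient=True)) == 1

    def test_pairs_formed_for_every_member_date(self):
        records = [rec("r1", days(0)), rec("r2", days(1))]
        ep = episode(records)
        pairs = compute_time_offsets(
            ep, records, [contact("c1", days(0), days(4))], include_outpatient=False
        )
        assert sorted(p.time_in for p in pairs) == [0, 1]


def _onset(records, contacts):
    ep = episode(records)
    pairs = compute_time_offsets(ep, records, contacts, include_outpatient=False)
    return classify_onset(pairs)


class TestOnset:
    def test_admission_two_or_more_days_before_is_hospital(self):
        result = _onset([rec("r1", days(0))], [contact("c1", days(-3), days(4))])
        assert result.label == "hospital" and result.branch == "admitted_from_home"

    def test_same_day_admission_alone_is_community(self):
        result = _onset([rec("r1", days(0))], [contact("c1", days(0), days(4))])
        assert result.label == "community" and result.branch == "community_direct"

    def test_spanning_ward_contact_triggers_transfer_clause(self):
        contacts = [
            contact("c1", days(0), days(4)),    # time_in = 0
            contact("c2", days(-5), days(2)),   # time_in = 5, time_out = -2
        ]
        result = _onset([rec("r1", days(0))], contacts)
        assert result.label == "hospital"
        assert result.branch == "transfer_overlapping_ward"

    def test_same_day_discharge_from_prior_ward_triggers_transfer_clause(self):
        contacts = [
            contact("c1", days(-3), days(0)),   # time_out = 0, stay 3 days
            contact("c2", days(0), days(5)),    # time_in = 0
        ]
        result = _onset([rec("r1", days(0))], contacts)
        assert result.label == "hospital" and result.branch == "transfer_same_day"

    def test_minimum_one_day_needs_only_one_day_prior_stay(self):
        contacts = [
            contact("c1", days(-1), days(0)),   # time_out = 0, stay 1 day
            contact("c2", days(-1), days(5)),   # time_in = 1
        ]
        result = _onset([rec("r1", days(0))], contacts)
        assert result.label == "hospital" and result.branch == "transfer_same_day"

    def test_short_prior_stay_is_not_a_transfer(self):
        contacts = [
            contact("c1", days(-1), days(0)),   # stay 1 day but minimum time_in 0
            contact("c2", days(0), days(5)),
        ]
        result = _onset([rec("r1", days(0))], contacts)
        assert result.label == "community"

    def test_no_inpatient_contact_is_community_with_warning(self):
        result = _onset(
            [rec("r1", days(0))],
            [contact("c1", days(0), days(0), ContactType.OUTPATIENT)],
        )
        assert result.label == "community"
        assert result.branch == "no_inpatient_contact" and result.warning

    def test_admission_after_culture_is_community(self):
        result = _onset([rec("r1", days(0))], [contact("c1", days(2), days(5))])
        assert result.label == "community" and result.branch == "admitted_after_culture"


class TestHealthcareAssociation:
    def _hca(self, records, contacts):
        ep = episode(records)
        pairs = compute_time_offsets(ep, records, contacts, include_outpatient=True)
        return classify_hca(pairs)

    def test_recent_prior_admission(self):
        assert self._hca([rec("r1", days(0))], [contact("c1", days(-10), days(-5))]) is True

    def test_index_admission_alone_is_not_hca(self):
        assert self._hca([rec("r1", days(0))], [contact("c1", days(0), days(4))]) is False

    def test_long_stay_ending_inside_window(self):
        assert self._hca([rec("r1", days(0))], [contact("c1", days(-40), days(-20))]) is True

    def test_outpatient_contact_counts(self):
        contacts = [contact("c1", days(-7), days(-7), ContactType.OUTPATIENT)]
        assert self._hca([rec("r1", days(0))], contacts) is True

    def test_contact_ending_exactly_thirty_days_before(self):
        assert self._hca([rec("r1", days(0))], [contact("c1", days(-32), days(-30))]) is True


class TestCohortClassification:
    def test_labels_are_exhaustive_and_exclusive(self, small_cohort):
        records = small_cohort.culture_records()
        contacts = small_cohort.contact_records()
        episodes = derive_computer_episodes(records)
        classify_episodes(episodes, records, contacts)
        for ep in episodes:
            assert ep.contamination is not None
            if ep.contamination:
                assert ep.polymicrobial is None
                assert ep.onset is None and ep.healthcare_associated is None
            else:
                assert ep.polymicrobial is not None
                assert ep.onset in ("community", "hospital")
                assert (ep.healthcare_associated is not None) == (ep.onset == "community")

    def test_lexicon_monotonicity(self, small_cohort):
        """Enlarging the commensal set only moves episodes toward contamination."""
        records = small_cohort.culture_records()
        contacts = small_cohort.contact_records()
        base = derive_computer_episodes(records)
        classify_episodes(base, records, contacts)
        wider_lexicon = OrganismLexicon(
            species_labels=frozenset(
                {"escherichia coli", "candida albicans"}
            ) | OrganismLexicon().species_labels
        )
        widened = derive_computer_episodes(records)
        classify_episodes(widened, records, contacts, wider_lexicon)
        for before, after in zip(base, widened):
            if before.contamination:
                assert after.contamination, (
                    "episode moved contamination -> bsi after widening the lexicon"
                )


class TestBruteForceEquivalence:
    def test_onset_and_hca_match_pairwise_enumeration(self):
        """Random patients, <=5 contacts: rule engine vs direct enumeration."""
        rng = np.random.default_rng(2024)
        for _ in range(250):
            n_dates = int(rng.integers(1, 3))
            member_dates = [days(0)] + ([days(1)] if n_dates == 2 else [])
            raw_contacts = []
            objs = []
            for j in range(int(rng.integers(0, 6))):
                ctype = "inpatient" if rng.random() < 0.8 else "outpatient"
                start = days(int(rng.integers(-40, 6)))
                end = start + timedelta(days=int(rng.integers(0, 31)))
                raw_contacts.append((ctype, start, end))
                objs.append(contact(f"c{j}", start, end, ContactType(ctype)))
            records = [rec(f"r{i}", d) for i, d in enumerate(member_dates)]
            ep = episode(records)
            in_pairs = compute_time_offsets(ep, records, objs, include_outpatient=False)
            all_pairs = compute_time_offsets(ep, records, objs, include_outpatient=True)
            assert classify_onset(in_pairs).label == oracle_onset(member_dates, raw_contacts)
            assert classify_hca(all_pairs) == oracle_hca(member_dates, raw_contacts)

    def test_contamination_matches_set_formulation(self):
        rng = np.random.default_rng(99)
        organisms = [
            "Staphylococcus epidermidis", "Micrococcus luteus",
            "Escherichia coli", "coryneform rod", "Staphylococcus aureus",
        ]
        for _ in range(250):
            member_records = [
                rec(f"m{i}", days(int(rng.integers(0, 2))),
                    organisms[int(rng.integers(0, len(organisms)))])
                for i in range(int(rng.integers(1, 4)))
            ]
            others = [
                rec(f"o{i}", days(int(rng.integers(2, 8))),
                    organisms[int(rng.integers(0, len(organisms)))])
                for i in range(int(rng.integers(0, 3)))
            ]
            ep = episode(member_records)
            everything = member_records + others
            got = classify_contamination(ep, everything)
            expected = oracle_contamination(
                ep.index_date,
                [r.organism_name for r in member_records],
                [(r.draw_date, r.organism_name) for r in everything],
                lambda o: classify_organism(o) == COMMENSAL,
            )
            assert got == expected
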