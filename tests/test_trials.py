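"""Trial records: XML parsing and the four screening predicates."""

import pytest

from oncomatch.mesh import NeoplasmVocabulary
from oncomatch.trials import (
    TrialLocation,
    TrialRecord,
    has_drug_intervention,
    is_cancer_trial,
    is_recruiting_in,
    mentions_gene,
    parse_trials,
    screen,
)

VOCAB = NeoplasmVocabulary.from_headings(
    ["Breast Neoplasms", "Triple Negative Breast Neoplasms", "Neoplasms"]
)

US_LOC = TrialLocation(facility="F", country="United States", recruiting=True)
FOREIGN_LOC = TrialLocation(facility="F", country="Japan", recruiting=True)


def make_trial(**overrides):
    base = dict(
        trial_id="NCT02401347",
        title="Talazoparib study",
        conditions=("Breast Neoplasms",),
        status="Recruiting",
        phase="Phase 2",
        interventions=(("drug", "Talazoparib tosylate"),),
        mesh_terms=("Breast neoplasms", "triple negative breast neoplasms"),
        locations=(US_LOC,),
        summary="Cohort with somatic mutations in PTEN, PALB2, CHEK2, ATM, NBN, BARD1.",
    )
    base.update(overrides)
    return TrialRecord(**base)


class TestParseTrials:
    def test_round_trip_of_the_dialect(self, tmp_path):
        xml = """<?xml version="1.0"?>
        <trials><trial>
          <id>NCT00000001</id><title>T</title><status>Recruiting</status>
          <phase>Phase 1</phase><condition>Breast Neoplasms</condition>
          <mesh_term>Breast neoplasms</mesh_term>
          <intervention type="drug">DrugX</intervention>
          <summary>BRCA1 carriers</summary>
          <location recruiting="false"><facility>A</facility><country>United States</country></location>
          <location><facility>B</facility><country>Canada</country></location>
        </trial></trials>"""
        path = tmp_path / "t.xml"
        path.write_text(xml, encoding="utf-8")
        (record,) = parse_trials(path)
        assert record.trial_id == "NCT00000001"
        assert record.interventions == (("drug", "DrugX"),)
        assert record.locations[0].recruiting is False
        # Omitted per-location flag inherits the trial-level status.
        assert record.locations[1].recruiting is True

    def test_duplicate_trial_id_is_fatal(self, tmp_path):
        xml = "<trials>{0}{0}</trials>".format(
            "<trial><id>NCT1</id><status>Recruiting</status>"
            "<location><country>US</country></location></trial>"
        )
        path = tmp_path / "t.xml"
        path.write_text(xml, encoding="utf-8")
        with pytest.raises(ValueError, match="duplicate trial id"):
            parse_trials(path)

    def test_malformed_xml_names_the_file(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text("<trials><trial>", encoding="utf-8")
        with pytest.raises(ValueError, match="bad.xml"):
            parse_trials(path)

    def test_zero_records_is_fatal(self, tmp_path):
        path = tmp_path / "t.xml"
        path.write_text("<trials/>", encoding="utf-8")
        with pytest.raises(ValueError, match="no trial records"):
            parse_trials(path)


class TestPredicates:
    def test_gene_mention_in_cohort_list(self):
        assert mentions_gene(make_trial(), "ATM")
        assert mentions_gene(make_trial(), "atm")

    def test_gene_mention_requires_word_boundary(self):
        trial = make_trial(summary="TREATMENT considerations only")
        assert not mentions_gene(trial, "ATM")

    def test_gene_not_present(self):
        assert not mentions_gene(make_trial(), "EGFR")

    def test_cancer_trial_by_mesh_terms(self):
        assert is_cancer_trial(make_trial(), VOCAB)

    def test_surgery_trial_mesh_terms_are_not_cancer(self):
        trial = make_trial(
            conditions=("Breast Reconstruction",),
            mesh_terms=("Pain, Postoperative", "Breast Diseases"),
        )
        assert not is_cancer_trial(trial, VOCAB)

    def test_no_terms_at_all_is_not_cancer(self):
        assert not is_cancer_trial(make_trial(conditions=(), mesh_terms=()), VOCAB)

    @pytest.mark.parametrize(
        "interventions,expected",
        [
            ((("drug", "Talazoparib tosylate"),), True),
            ((("dietary supplement", "High-fiber diet"),), False),
            ((("device", "Imaging system"),), False),
            ((("drug", ""),), False),
            ((), False),
        ],
    )
    def test_drug_intervention(self, interventions, expected):
        assert has_drug_intervention(make_trial(interventions=interventions)) is expected

    def test_recruiting_with_us_location(self):
        assert is_recruiting_in(make_trial(), ["United States"])

    @pytest.mark.parametrize(
        "status", ["Active, not recruiting", "Not yet recruiting", "Completed"]
    )
    def test_non_recruiting_statuses_fail(self, status):
        assert not is_recruiting_in(make_trial(status=status), [])

    def test_recruiting_only_abroad_fails_us_filter(self):
        trial = make_trial(locations=(FOREIGN_LOC,))
        assert not is_recruiting_in(trial, ["United States"])
        assert is_recruiting_in(trial, [])  # no country filter

    def test_us_location_not_recruiting_fails_filter(self):
        loc = TrialLocation(facility="F", country="United States", recruiting=False)
        assert not is_recruiting_in(make_trial(locations=(loc, FOREIGN_LOC)), ["United States"])


class TestScreen:
    def test_failing_only_the_mesh_test_yields_not_cancer(self):
        trial = make_trial(
            conditions=("Breast Reconstruction",),
            mesh_terms=("Pain, Postoperative",),
        )
        decision = screen(trial, "ATM", VOCAB, ["United States"])
        assert decision.reasons == ("NOT_CANCER",)

    def test_all_predicates_pass(self):
        decision = screen(make_trial(), "ATM", VOCAB, ["United States"])
        assert decision.accepted and decision.reasons == ()

    def test_all_failing_predicates_are_recorded(self):
        trial = make_trial(
            interventions=(("device", "X"),), status="Not yet recruiting"
        )
        decision = screen(trial, "ATM", VOCAB, [])
        assert decision.reasons == ("NO_DRUG", "NOT_RECRUITING")

    def test_each_reason_matches_an_independent_predicate(self, vocab, workspace):
        from oncomatch.trials import (
            has_recruiting_location_in,
            is_recruiting_status,
            parse_trials,
        )

        countries = ["United States"]
        for trial in parse_trials(workspace["trials"]):
            decision = screen(trial, "BRCA1", vocab, countries)
            expected = {
                "NO_GENE_MENTION": not mentions_gene(trial, "BRCA1"),
                "NOT_CANCER": not is_cancer_trial(trial, vocab),
                "NO_DRUG": not has_drug_intervention(trial),
                "NOT_RECRUITING": not is_recruiting_status(trial),
                "NO_LOCATION_IN_COUNTRY": not has_recruiting_location_in(
                    trial, countries
                ),
            }
            assert set(decision.reasons) == {c for c, failed in expected.items() if failed}
            assert decision.accepted == (not decision.reasons)

    def test_multi_gene_trial_is_accepted_under_each_mentioned_gene(self):
        trial = make_trial()
        for gene in ("PTEN", "PALB2", "CHEK2", "ATM", "NBN", "BARD1"):
            assert screen(trial, gene, VOCAB, ["United States"]).accepted

    def test_user_condition_restricts_cancer_type(self):
        trial = make_trial()
        ok = screen(trial, "ATM", VOCAB, [], user_conditions=["Breast Neoplasms"])
        assert ok.accepted
        miss = screen(trial, "ATM", VOCAB, [], user_conditions=["Ovarian Neoplasms"])
        assert miss.reasons == ("NOT_CANCER",)

    def test_screening_is_order_independent(self, vocab, workspace):
        trials = parse_trials(workspace["trials"])
        forward = [screen(t, "BRCA1", vocab, ["United States"]) for t in trials]
        backward = [screen(t, "BRCA1", vocab, ["United States"]) for t in reversed(trials)]
        assert sorted(d.trial_id for d in forward if d.accepted) == sorted(
            d.trial_id for d in backward if d.accepted
        )
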