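import json
import random

import pytest

from trialmatch.criteria_miner import Triplet
from trialmatch.eligibility_db import EligibilityDB, TrialFilters
from trialmatch.errors import MatchJobError, RefineError
from trialmatch.matcher import (
    MatchJob,
    MatchResult,
    apply_filters,
    candidate_trials,
    categorize,
    refine,
    run_match,
)
from trialmatch.synthetic_corpus import generate_patient
from trialmatch.trial_ingest import parse_trial
from trialmatch.variant_profile import ExpandedProfile, PatientProfile, expand_profile

from oracles import brute_force_category, passes_filters

MODES = ("basket", "umbrella", "combination")


def _trial(tid, **metadata):
    return parse_trial({"trial_id": tid, "metadata": metadata, "passages": []})


def _expanded(cancer_entries={"C"}, variation={"A"}, prior=frozenset()):
    return ExpandedProfile(
        profile=PatientProfile(cancer_entry_id="C"),
        cancer_entries=frozenset(cancer_entries),
        alteration_entries=frozenset(variation),
        biomarker_entry_ids=frozenset(),
        prior_entry_ids=frozenset(prior),
        expansions=(),
    )


class TestClassCombinationTable:
    """Exhaustive sweep over alteration-class x cancer-class triplet combos.

    Each trial plants the profile alteration "A" with one class (or not at
    all) and the profile cancer "C" with one class (or not at all); the
    resulting candidacy and category must follow the loose-inclusion /
    tight-exclusion rules in every mode.
    """

    @pytest.mark.parametrize("mode", MODES)
    def test_category_matches_nested_loop_oracle(self, table_db, mode):
        xp = _expanded()
        candidates = candidate_trials(xp, table_db, mode)
        for tid in table_db.trials:
            expected = brute_force_category(
                table_db.triplets, tid, {"C"}, {"A"}, set(), mode
            )
            if expected is None:
                assert tid not in candidates
            else:
                assert tid in candidates
                got = categorize(tid, xp, table_db, mode)
                assert got.category == expected
                assert got.evidence  # every assignment carries evidence

    @pytest.mark.parametrize("mode", MODES)
    def test_exclusion_hit_dominates(self, table_db, mode):
        xp = _expanded()
        for tid in candidate_trials(xp, table_db, mode):
            hits = {
                (t.entry_id, t.criteria_class)
                for t in table_db.by_trial.get(tid, [])
            }
            if {("A", "exclusion"), ("C", "exclusion")} & hits:
                assert categorize(tid, xp, table_db, mode).category == "negative"

    @pytest.mark.parametrize("mode", MODES)
    def test_no_negative_without_exclusion_evidence(self, table_db, mode):
        """Loose inclusion: lacking a mention never makes a trial negative."""
        xp = _expanded()
        for tid in candidate_trials(xp, table_db, mode):
            hits = {t.criteria_class for t in table_db.by_trial.get(tid, [])}
            if "exclusion" not in hits:
                assert categorize(tid, xp, table_db, mode).category != "negative"

    def test_na_candidacy_never_promotes_to_positive(self, table_db):
        """A trial matched only through NA context stays unclassified."""
        xp = _expanded()
        for tid in candidate_trials(xp, table_db, "combination"):
            classes = {t.criteria_class for t in table_db.by_trial.get(tid, [])}
            if classes <= {"NA", "NC"}:
                assert categorize(tid, xp, table_db, "combination").category == "unclassified"

    def test_nc_triplets_invisible_to_matching(self):
        db = EligibilityDB([_trial("NCT1")], triplets=[Triplet("A", "NC", "NCT1")])
        assert candidate_trials(_expanded(), db, "combination") == set()


class TestCandidates:
    def test_basket_selects_inclusion_or_na_variation(self):
        db = EligibilityDB(
            [_trial("T1"), _trial("T2"), _trial("T3")],
            triplets=[
                Triplet("A", "inclusion", "T1"),
                Triplet("A", "exclusion", "T2"),
                Triplet("A", "NA", "T3"),
            ],
        )
        assert candidate_trials(_expanded(), db, "basket") == {"T1", "T3"}

    def test_umbrella_uses_cancer_ancestors(self, db100, bundle100):
        profile = PatientProfile(cancer_entry_id="C_NSCLC")
        xp = expand_profile(profile, bundle100.terminology)
        cands = candidate_trials(xp, db100, "umbrella")
        # a trial enrolling the ancestor "solid tumor" accepts an NSCLC patient
        solid = db100.trials_for_entry("C_SOLID", "inclusion")
        assert solid <= cands

    def test_empty_profile_is_a_job_error(self):
        db = EligibilityDB([_trial("T1")], triplets=[])
        empty = _expanded(cancer_entries=set(), variation=set())
        with pytest.raises(MatchJobError):
            candidate_trials(empty, db, "combination")

    @pytest.mark.parametrize("seed", range(5))
    def test_combination_is_union_of_basket_and_umbrella(self, bundle100, db100, seed):
        profile, _ = generate_patient(bundle100, seed=seed)
        xp = expand_profile(profile, bundle100.terminology, bundle100.gene_models)
        basket = candidate_trials(xp, db100, "basket")
        umbrella = candidate_trials(xp, db100, "umbrella")
        assert candidate_trials(xp, db100, "combination") == basket | umbrella


class TestAgainstOracle:
    @pytest.mark.parametrize("mode", MODES)
    def test_full_agreement_on_random_profiles(self, bundle100, db100, mode):
        for seed in range(20):
            profile, _ = generate_patient(bundle100, seed=seed)
            xp = expand_profile(profile, bundle100.terminology, bundle100.gene_models)
            result = run_match(MatchJob(profile=profile, mode=mode), db100,
                               gene_models=bundle100.gene_models)
            got = {t.trial_id: t.category for t in result.trials}
            expected = {}
            for tid in db100.trials:
                cat = brute_force_category(
                    db100.triplets,
                    tid,
                    set(xp.cancer_entries),
                    set(xp.variation_entries),
                    set(xp.prior_entry_ids),
                    mode,
                )
                if cat is not None:
                    expected[tid] = cat
            assert got == expected

    def test_basket_positive_implies_combination_positive(self, bundle100, db100):
        for seed in range(10):
            profile, _ = generate_patient(bundle100, seed=seed)
            b = run_match(MatchJob(profile=profile, mode="basket"), db100,
                          gene_models=bundle100.gene_models)
            c = run_match(MatchJob(profile=profile, mode="combination"), db100,
                          gene_models=bundle100.gene_models)
            for t in b.trials:
                if t.category == "positive":
                    assert c.category_of(t.trial_id) == "positive"

    def test_reports_are_deterministic(self, bundle100, db100):
        profile, _ = generate_patient(bundle100, seed=3)
        job = MatchJob(profile=profile, mode="combination")
        a = run_match(job, db100, gene_models=bundle100.gene_models)
        b = run_match(job, db100, gene_models=bundle100.gene_models)
        assert json.dumps(a.to_dict(), sort_keys=True) == json.dumps(
            b.to_dict(), sort_keys=True
        )
        assert a.result_id == b.result_id


class TestFilters:
    def test_status_filter_removes_completed(self):
        db = EligibilityDB(
            [_trial("T1", status="Recruiting"), _trial("T2", status="Completed")],
            triplets=[Triplet("A", "inclusion", "T1"), Triplet("A", "inclusion", "T2")],
        )
        xp = _expanded()
        raw = MatchResult(
            mode="basket",
            trials=tuple(categorize(t, xp, db, "basket") for t in sorted(
                candidate_trials(xp, db, "basket"))),
        )
        kept = apply_filters(raw, TrialFilters(statuses=frozenset({"recruiting"})), db)
        assert kept.trial_ids == ["T1"]

    def test_no_filters_is_identity(self, db100, bundle100):
        profile, _ = generate_patient(bundle100, seed=1)
        r = run_match(MatchJob(profile=profile, mode="combination"), db100,
                      gene_models=bundle100.gene_models)
        assert apply_filters(r, TrialFilters(), db100).trial_ids == r.trial_ids

    def test_random_filters_match_predicate_oracle(self, db100, bundle100):
        rng = random.Random(6)
        profile, _ = generate_patient(bundle100, seed=2)
        base = run_match(MatchJob(profile=profile, mode="combination"), db100,
                         gene_models=bundle100.gene_models)
        for _ in range(20):
            filters = TrialFilters(
                statuses=frozenset(rng.sample(
                    ["recruiting", "completed", "terminated", "active_not_recruiting"],
                    rng.randint(1, 3))) if rng.random() < 0.7 else None,
                phases=frozenset(rng.sample(["1", "2", "3"], rng.randint(1, 2)))
                if rng.random() < 0.5 else None,
                countries=frozenset({rng.choice(["US", "CN", "JP"])})
                if rng.random() < 0.5 else None,
                gender=rng.choice([None, "male", "female"]),
                age_years=rng.choice([None, 15.0, 40.0, 90.0]),
            )
            got = apply_filters(base, filters, db100).trial_ids
            expected = [
                tid for tid in base.trial_ids
                if passes_filters(db100.trials[tid].metadata, filters)
            ]
            assert got == expected
            assert set(got) <= set(base.trial_ids)  # anti-monotone


class TestRefine:
    @pytest.fixture()
    def five_trials(self):
        trials = [_trial(f"T{i}") for i in range(5)]
        triplets = [Triplet("A", "inclusion", f"T{i}") for i in range(5)]
        triplets += [Triplet("T_CHEMO", "inclusion", "T0"),
                     Triplet("T_CHEMO", "inclusion", "T1")]
        db = EligibilityDB(trials, triplets=triplets)
        xp = _expanded()
        result = MatchResult(
            mode="basket",
            trials=tuple(
                categorize(t, xp, db, "basket")
                for t in sorted(candidate_trials(xp, db, "basket"))
            ),
        )
        return db, result

    def test_required_entry_already_implied_is_noop(self, five_trials):
        db, result = five_trials
        refined = refine(result, db, required=[("A", "inclusion")])
        assert refined.trial_ids == result.trial_ids

    def test_excluding_failed_therapy_drops_requiring_trials(self, five_trials):
        db, result = five_trials
        refined = refine(result, db, excluded=["T_CHEMO"])
        assert refined.trial_ids == ["T2", "T3", "T4"]

    def test_unknown_entry_raises(self, five_trials):
        db, result = five_trials
        with pytest.raises(RefineError):
            refine(result, db, required=[("NOPE", None)])

    def test_lineage_recorded(self, five_trials):
        db, result = five_trials
        refined = refine(result, db, excluded=["T_CHEMO"])
        assert refined.parent_id == result.result_id

    def test_chained_refines_compose(self, bundle100, db100):
        rng = random.Random(8)
        profile, _ = generate_patient(bundle100, seed=4)
        base = run_match(MatchJob(profile=profile, mode="combination"), db100,
                         gene_models=bundle100.gene_models)
        entry_ids = sorted(db100.by_entry)
        for _ in range(10):
            a = [(rng.choice(entry_ids), rng.choice([None, "inclusion"]))]
            b = [(rng.choice(entry_ids), None)]
            chained = refine(refine(base, db100, required=a), db100, required=b)
            joint = refine(base, db100, required=a + b)
            assert chained.trial_ids == joint.trial_ids
            assert [t.category for t in chained.trials] == [
                t.category for t in joint.trials
            ]

    def test_roundtrip_through_report_json(self, five_trials):
        db, result = five_trials
        again = MatchResult.from_dict(json.loads(json.dumps(result.to_dict())))
        assert again == result
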