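import pytest
from hypothesis import given, settings, strategies as st

from vaxtiming import (
    age_at_dose, classify_fic, classify_fic_os, classify_timeliness,
    default_study_like_config, flag_out_of_sequence, generate, missing_profile,
)

from conftest import ON_TIME, make_child
from oracle import oracle_fic, oracle_flags, oracle_timeliness

ALL_LABELS = ["BCG", "OPV0", "OPV1", "OPV2", "OPV3",
              "PENTA1", "PENTA2", "PENTA3", "PCV1", "PCV2", "PCV3", "MV"]


class TestAgeAtDose:
    def test_whole_day_arithmetic(self, schedule):
        child = make_child({"OPV1": 42, "MV": 274})
        assert age_at_dose(child, "OPV1") == 42
        assert age_at_dose(child, "MV") == 274
        assert age_at_dose(child, "BCG") is None


class TestFic:
    def test_on_time_child_is_fic(self, schedule, on_time_child):
        res = classify_fic(on_time_child, schedule)
        assert res.fic and not res.missing_doses and not res.fic_after_cutoff

    def test_mv_after_cutoff_is_fic_after_cutoff(self, schedule):
        child = make_child({**ON_TIME, "MV": 380})
        res = classify_fic(child, schedule)
        assert not res.fic and res.fic_after_cutoff and not res.missing_doses

    def test_missing_dose(self, schedule):
        events = {k: v for k, v in ON_TIME.items() if k != "OPV3"}
        res = classify_fic(make_child(events), schedule)
        assert not res.fic and res.missing_doses == {"OPV3"}

    def test_opv0_and_pcv_do_not_count(self, schedule):
        events = {k: v for k, v in ON_TIME.items() if k != "OPV0"}
        assert classify_fic(make_child(events), schedule).fic

    @pytest.mark.parametrize("age, fic", [(365, True), (366, False)])
    def test_cutoff_boundary(self, schedule, age, fic):
        child = make_child({**ON_TIME, "MV": age})
        assert classify_fic(child, schedule).fic is fic


class TestTimeliness:
    @pytest.mark.parametrize("dose, age, status", [
        ("OPV1", 37, "early"), ("OPV1", 38, "timely"),       # 4-day early margin
        ("OPV1", 56, "timely"), ("OPV1", 57, "delayed"),     # 14-day delay margin
        ("BCG", 14, "timely"), ("BCG", 15, "delayed"),
        ("BCG", 0, "timely"),                                # birth dose never early
        ("MV", 304, "timely"), ("MV", 305, "delayed"),       # 30-day measles margin
        ("MV", 269, "early"), ("MV", 270, "timely"),
    ])
    def test_window_boundaries(self, schedule, dose, age, status):
        child = make_child({dose: age})
        assert classify_timeliness(child, schedule).status(dose) == status

    @pytest.mark.parametrize("age, strict", [(259, True), (260, False)])
    def test_mv_strict_early_boundary(self, schedule, age, strict):
        # secondary rule: measles more than 14 days before 274
        child = make_child({"MV": age})
        res = classify_timeliness(child, schedule)
        assert res.mv_early_strict is strict
        assert res.status("MV") == "early"

    def test_absent_dose_is_missing(self, schedule):
        res = classify_timeliness(make_child({}), schedule)
        assert all(res.status(lab) == "missing" for lab in ALL_LABELS)


class TestSequenceFlags:
    def test_penta_opv_split(self, schedule):
        child = make_child({"PENTA1": 45, "OPV1": 47})
        flags = flag_out_of_sequence(child, schedule)
        assert flags.penta_opv_split and flags.out_of_sequence
        assert not flags.late_bcg and not flags.penta_after_mv

    def test_late_bcg(self, schedule):
        child = make_child({"BCG": 50, "OPV1": 45, "PENTA1": 45})
        assert flag_out_of_sequence(child, schedule).late_bcg

    def test_bcg_same_day_as_other_dose_counts(self, schedule):
        child = make_child({"BCG": 45, "OPV1": 45, "PENTA1": 45})
        assert flag_out_of_sequence(child, schedule).late_bcg

    def test_opv0_never_triggers_late_bcg(self, schedule):
        child = make_child({"BCG": 0, "OPV0": 0})
        flags = flag_out_of_sequence(child, schedule)
        assert not flags.out_of_sequence

    def test_penta_after_mv(self, schedule):
        child = make_child({"PENTA3": 280, "MV": 275})
        assert flag_out_of_sequence(child, schedule).penta_after_mv

    def test_penta_same_day_as_mv_counts(self, schedule):
        child = make_child({"PENTA3": 275, "MV": 275})
        assert flag_out_of_sequence(child, schedule).penta_after_mv

    def test_doses_after_cutoff_excluded_by_default(self, schedule):
        child = make_child({"PENTA3": 380, "OPV3": 370, "MV": 300})
        assert not flag_out_of_sequence(child, schedule).out_of_sequence
        sensit = flag_out_of_sequence(child, schedule, within_cutoff=False)
        assert sensit.penta_opv_split and sensit.penta_after_mv

    def test_narrow_late_bcg_comparators(self, schedule):
        child = make_child({"BCG": 50, "OPV1": 45})
        assert flag_out_of_sequence(child, schedule).late_bcg
        assert not flag_out_of_sequence(
            child, schedule, late_bcg_comparators="penta_mv").late_bcg

    def test_unrecorded_doses_never_flag(self, schedule):
        assert not flag_out_of_sequence(make_child({}), schedule).out_of_sequence


class TestFicOs:
    def test_fic_with_split_is_fic_os(self, schedule):
        child = make_child({**ON_TIME, "OPV1": 44})
        fic = classify_fic(child, schedule)
        flags = flag_out_of_sequence(child, schedule)
        assert classify_fic_os(fic, flags)

    def test_non_fic_with_flag_is_not_fic_os(self, schedule):
        child = make_child({"BCG": 50, "OPV1": 45, "PENTA1": 45})
        fic = classify_fic(child, schedule)
        flags = flag_out_of_sequence(child, schedule)
        assert flags.late_bcg and not classify_fic_os(fic, flags)


class TestMissingProfile:
    def test_single_missing_dose(self, schedule):
        events = {k: v for k, v in ON_TIME.items() if k != "OPV3"}
        assert missing_profile(make_child(events), schedule) == (
            1, frozenset({"OPV3"}), False)

    def test_fic_after_cutoff_bin(self, schedule):
        child = make_child({**ON_TIME, "MV": 380})
        assert missing_profile(child, schedule) == (0, frozenset(), True)

    def test_dose_after_cutoff_not_in_missing_set(self, schedule):
        events = {k: v for k, v in ON_TIME.items() if k != "OPV3"}
        child = make_child({**events, "MV": 380})
        n, missing, after = missing_profile(child, schedule)
        assert n == 1 and missing == {"OPV3"} and not after

    def test_fic_child_is_contract_violation(self, schedule, on_time_child):
        with pytest.raises(ValueError, match="FIC"):
            missing_profile(on_time_child, schedule)


# -- randomized oracle equivalence and invariants -----------------------------

ages_strategy = st.fixed_dictionaries(
    {}, optional={lab: st.integers(min_value=0, max_value=450) for lab in ALL_LABELS}
)


@settings(max_examples=300, derandomize=True)
@given(ages=ages_strategy)
def test_classification_matches_oracle_on_random_histories(ages):
    from vaxtiming import default_epi_schedule
    schedule = default_epi_schedule()
    child = make_child(ages)
    fic = classify_fic(child, schedule)
    assert (fic.fic, set(fic.missing_doses), fic.fic_after_cutoff) == oracle_fic(child)
    tim = classify_timeliness(child, schedule)
    assert {lab: tim.status(lab) for lab in ALL_LABELS} == oracle_timeliness(child)
    flags = flag_out_of_sequence(child, schedule)
    assert (flags.late_bcg, flags.penta_opv_split, flags.penta_after_mv) == \
        oracle_flags(child)


@settings(max_examples=200, derandomize=True)
@given(ages=ages_strategy)
def test_timeliness_partitions_every_fic_dose(ages):
    from vaxtiming import default_epi_schedule
    schedule = default_epi_schedule()
    tim = classify_timeliness(make_child(ages), schedule)
    for lab in schedule.fic_labels:
        assert tim.status(lab) in {"early", "timely", "delayed", "missing"}
        assert (tim.status(lab) == "missing") == (lab not in ages)


@settings(max_examples=200, derandomize=True)
@given(ages=ages_strategy,
       extra=st.sampled_from(ALL_LABELS), extra_age=st.integers(0, 365))
def test_adding_an_event_never_breaks_fic(ages, extra, extra_age):
    """FIC is monotone in coverage: one more in-window dose cannot unset it."""
    from vaxtiming import default_epi_schedule
    schedule = default_epi_schedule()
    before = classify_fic(make_child(ages), schedule)
    augmented = dict(ages)
    if extra not in augmented:
        augmented[extra] = extra_age
    after = classify_fic(make_child(augmented), schedule)
    assert after.fic >= before.fic


def test_flag_monotonicity_under_event_removal(schedule):
    base = {**ON_TIME, "OPV1": 44, "PENTA3": 280, "MV": 275}
    no_mv = {k: v for k, v in base.items() if k != "MV"}
    assert not flag_out_of_sequence(make_child(no_mv), schedule).penta_after_mv
    no_penta = {k: v for k, v in base.items() if not k.startswith("PENTA")}
    flags = flag_out_of_sequence(make_child(no_penta), schedule)
    assert not flags.penta_opv_split and not flags.penta_after_mv


def test_generated_cohort_matches_oracle(schedule):
    """Classifier vs literal-translation oracle, dose for dose, on 500 children."""
    cohort, _ = generate(default_study_like_config(n_children=500, seed=7))
    for child in cohort:
        fic = classify_fic(child, schedule)
        assert (fic.fic, set(fic.missing_doses), fic.fic_after_cutoff) == \
            oracle_fic(child)
        flags = flag_out_of_sequence(child, schedule)
        assert (flags.late_bcg, flags.penta_opv_split, flags.penta_after_mv) == \
            oracle_flags(child)
        tim = classify_timeliness(child, schedule)
        assert {lab: tim.status(lab) for lab in ALL_LABELS} == \
            oracle_timeliness(child)
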