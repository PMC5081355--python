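import pytest

from mmclaims.cohort import (
    CohortParams,
    GoldLabel,
    build_gold_standard,
    classify_incident,
    note_mentions_mm,
    select_cases,
    select_controls,
    split_sample,
)

from conftest import D


CHEMO = "96400"  # in the default chemotherapy set (9640x)
SCT = "38240"


def _case_builder(builder, birth_year=1950, enroll_start="2012-01-01"):
    return (
        builder.person("p1", birth_year=birth_year)
        .enroll("p1", enroll_start, "2012-12-31")
        .emr("p1", "2012-06-01")
    )


class TestSelectCases:
    def test_qualifying_case_selected(self, builder, codesets):
        bundle = _case_builder(builder).build()
        labels = select_cases(bundle, codesets)
        assert len(labels) == 1
        label = labels[0]
        assert label.label == "case"
        assert label.anchor_date == D("2012-06-01")
        assert label.incident is True

    def test_age_17_excluded(self, builder, codesets):
        bundle = _case_builder(builder, birth_year=1995).build()
        assert select_cases(bundle, codesets) == []

    def test_short_pre_enrollment_excluded(self, builder, codesets):
        # enrollment starts 31 days before the EMR diagnosis: < 90 required
        bundle = _case_builder(builder, enroll_start="2012-05-01").build()
        assert select_cases(bundle, codesets) == []

    def test_missing_visit_date_excluded(self, builder, codesets):
        bundle = (
            builder.person("p1")
            .enroll("p1", "2012-01-01", "2012-12-31")
            .emr("p1", "2012-06-01", visit=False)
            .build()
        )
        assert select_cases(bundle, codesets) == []

    def test_abutting_spans_cover_after_merge(self, builder, codesets):
        bundle = (
            builder.person("p1")
            .enroll("p1", "2012-01-01", "2012-05-31")
            .enroll("p1", "2012-06-01", "2012-12-31")
            .emr("p1", "2012-06-01")
            .build()
        )
        assert len(select_cases(bundle, codesets)) == 1


class TestClassifyIncident:
    def _label(self):
        return GoldLabel(
            patient_id="p1", label="case", anchor_date=D("2012-06-01"),
            incident=True, observation_start=D("2012-01-01"),
            observation_end=D("2012-12-31"),
        )

    def test_prior_chemo_with_mm_dx_is_prevalent(self, builder, codesets):
        h = (
            _case_builder(builder)
            .proc("p1", "2012-05-02", CHEMO, dx=("20300",))
            .histories()
        )
        assert classify_incident(self._label(), h["p1"], codesets) is False

    def test_prior_chemo_without_mm_dx_stays_incident(self, builder, codesets):
        h = _case_builder(builder).proc("p1", "2012-05-02", CHEMO).histories()
        assert classify_incident(self._label(), h["p1"], codesets) is True

    def test_chemo_after_anchor_stays_incident(self, builder, codesets):
        h = (
            _case_builder(builder)
            .proc("p1", "2012-06-11", CHEMO, dx=("20300",))
            .histories()
        )
        assert classify_incident(self._label(), h["p1"], codesets) is True

    def test_same_day_association_mode(self, builder, codesets):
        # chemo claim and MM dx claim on the same day but separate records
        h = (
            _case_builder(builder)
            .proc("p1", "2012-05-02", CHEMO)
            .dx("p1", "2012-05-02", "20300")
            .histories()
        )
        label = self._label()
        assert classify_incident(label, h["p1"], codesets) is True
        same_day = CohortParams(chemo_association="same_day")
        assert classify_incident(label, h["p1"], codesets, same_day) is False


def _control_builder(builder, pid="p1"):
    return (
        builder.person(pid, birth_year=1950)
        .enroll(pid, "2010-01-01", "2011-12-31")
        .note(pid, "2010-01-01", "annual physical")
        .note(pid, "2011-12-31", "follow-up")
        .dx(pid, "2010-06-15", "20300")
    )


class TestSelectControls:
    def test_qualifying_control_selected(self, builder, codesets):
        labels = select_controls(_control_builder(builder).build(), codesets)
        assert len(labels) == 1
        assert labels[0].label == "control"
        assert labels[0].observation_start == D("2010-01-01")
        assert labels[0].observation_end == D("2011-12-31")

    def test_sct_claim_excludes(self, builder, codesets):
        bundle = _control_builder(builder).proc("p1", "2010-08-01", SCT).build()
        assert select_controls(bundle, codesets) == []

    def test_mm_note_excludes(self, builder, codesets):
        bundle = (
            _control_builder(builder)
            .note("p1", "2010-09-01", "pt with multiple myeloma")
            .build()
        )
        assert select_controls(bundle, codesets) == []

    def test_chemo_with_mm_dx_excludes(self, builder, codesets):
        bundle = (
            _control_builder(builder)
            .proc("p1", "2010-08-01", CHEMO, dx=("20300",))
            .build()
        )
        assert select_controls(bundle, codesets) == []

    def test_chemo_without_mm_dx_does_not_exclude(self, builder, codesets):
        bundle = _control_builder(builder).proc("p1", "2010-08-01", CHEMO).build()
        assert len(select_controls(bundle, codesets)) == 1

    def test_short_overlap_excluded(self, builder, codesets):
        bundle = (
            builder.person("p1")
            .enroll("p1", "2010-01-01", "2011-12-31")
            .note("p1", "2010-01-01", "visit")
            .note("p1", "2010-06-30", "visit")  # EMR coverage < 12 months
            .dx("p1", "2010-03-01", "20300")
            .build()
        )
        assert select_controls(bundle, codesets) == []

    def test_no_mm_claim_excluded(self, builder, codesets):
        bundle = (
            builder.person("p1")
            .enroll("p1", "2010-01-01", "2011-12-31")
            .note("p1", "2010-01-01", "visit")
            .note("p1", "2011-12-31", "visit")
            .build()
        )
        assert select_controls(bundle, codesets) == []


class TestNoteScan:
    @pytest.mark.parametrize(
        "text,hit",
        [
            ("Hx of Multiple Myeloma, stable", True),
            ("myelodysplastic syndrome", False),
            ("r/o smoldering myeloma", True),
            ("unremarkable exam", False),
        ],
    )
    def test_examples(self, text, hit):
        assert note_mentions_mm(text) is hit

    def test_empty_terms_rejected(self):
        with pytest.raises(ValueError):
            note_mentions_mm("anything", [])


def _labels(n):
    return [
        GoldLabel(
            patient_id=f"p{i:03d}", label="control", anchor_date=D("2010-01-01"),
            incident=None, observation_start=D("2010-01-01"),
            observation_end=D("2011-01-01"),
        )
        for i in range(n)
    ]


class TestSplitSample:
    def test_odd_n_sizes(self):
        assignments = split_sample(_labels(7), seed=0)
        counts = {"development": 0, "validation": 0}
        for a in assignments:
            counts[a.sample] += 1
        assert counts == {"development": 4, "validation": 3}

    def test_deterministic(self):
        assert split_sample(_labels(20), seed=5) == split_sample(_labels(20), seed=5)

    def test_seeds_differ(self):
        a = split_sample(_labels(30), seed=1)
        b = split_sample(_labels(30), seed=2)
        assert a != b

    def test_input_order_irrelevant(self):
        labels = _labels(15)
        assert split_sample(labels, seed=3) == split_sample(labels[::-1], seed=3)

    def test_partition(self):
        labels = _labels(21)
        assignments = split_sample(labels, seed=9)
        assert {a.patient_id for a in assignments} == {l.patient_id for l in labels}
        assert len(assignments) == len(labels)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            split_sample([], seed=0)


class TestGoldStandard:
    def test_no_patient_both_case_and_control(self, small_population, codesets):
        bundle, _, _ = small_population
        labels, assignments = build_gold_standard(bundle, codesets, seed=0)
        cases = {l.patient_id for l in labels if l.label == "case"}
        controls = {l.patient_id for l in labels if l.label == "control"}
        assert not cases & controls
        assert {a.patient_id for a in assignments} == cases | controls

    def test_controls_have_no_chemo_or_sct_in_observation(
        self, small_population, codesets
    ):
        from mmclaims.codesets import claim_in_codeset

        bundle, _, histories = small_population
        labels, _ = build_gold_standard(bundle, codesets, seed=0)
        chemo, sct = codesets["chemotherapy"], codesets["stem_cell_transplant"]
        for l in labels:
            if l.label != "control":
                continue
            h = histories[l.patient_id]
            for c in h.medical_claims:
                if l.observation_start <= c.service_date <= l.observation_end:
                    assert not (
                        claim_in_codeset(c, chemo)
                        and claim_in_codeset(c, codesets.mm_diagnosis)
                    )
                    assert not claim_in_codeset(c, sct)
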