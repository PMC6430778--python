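import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dentalage import (
    AGE_GROUPS,
    ChildRecord,
    Stage,
    assign_age_group,
    compute_chronological_age,
    exclude_below_min_age,
    read_cohort,
    read_cohort_lenient,
    write_cohort,
)
from dentalage.errors import (
    InvalidRecordError,
    OutOfRangeError,
    ValidationError,
)


class TestChronologicalAge:
    @pytest.mark.parametrize(
        "dob, dor, expected",
        [
            (dt.date(2010, 1, 1), dt.date(2010, 1, 1), 0.00),
            (dt.date(2010, 1, 1), dt.date(2017, 1, 1), 7.00),  # 2557 d / 365.25
            (dt.date(2010, 1, 1), dt.date(2017, 7, 1), 7.50),  # 2738 d / 365.25
        ],
    )
    def test_day_count_convention(self, dob, dor, expected):
        assert compute_chronological_age(dob, dor) == expected

    def test_rounding_convention_and_precision(self):
        # 2738/365.25 = 7.49623... truncates to 7.49; half-up carries to 7.50
        dob = dt.date(2010, 1, 1)
        dor = dob + dt.timedelta(days=2738)
        assert compute_chronological_age(dob, dor) == 7.50
        assert compute_chronological_age(dob, dor, decimals=4) == 7.4962
        # the alternative banker's-rounding convention is accepted
        assert compute_chronological_age(dob, dor, rounding="half-even") == 7.50

    def test_radiograph_before_birth_rejected(self):
        with pytest.raises(InvalidRecordError):
            compute_chronological_age(dt.date(2010, 1, 2), dt.date(2010, 1, 1))

    @settings(derandomize=True, max_examples=50)
    @given(days=st.integers(min_value=0, max_value=5000), shift=st.integers(-3000, 3000))
    def test_translation_invariance(self, days, shift):
        base = dt.date(2005, 6, 15)
        a = compute_chronological_age(base, base + dt.timedelta(days=days))
        b = compute_chronological_age(
            base + dt.timedelta(days=shift), base + dt.timedelta(days=shift + days)
        )
        assert a == b


class TestAgeGroups:
    def test_boundary_belongs_to_lower_closed_group(self):
        assert assign_age_group(3.00).label == "3 to <4"
        assert assign_age_group(4.00).label == "4 to <5"
        assert assign_age_group(10.99).label == "10 to <11"

    @pytest.mark.parametrize("ca", [2.99, 11.00, 11.5, -1.0])
    def test_out_of_range_rejected(self, ca):
        with pytest.raises(OutOfRangeError):
            assign_age_group(ca)

    @settings(derandomize=True, max_examples=100)
    @given(ca=st.floats(min_value=3.0, max_value=10.999))
    def test_assignment_total_and_disjoint(self, ca):
        group = assign_age_group(ca)
        assert ca in group
        assert sum(ca in g for g in AGE_GROUPS) == 1


class TestCohortIO:
    def _write(self, tmp_path, text):
        p = tmp_path / "cohort.csv"
        p.write_text(text)
        return p

    def test_header_only_gives_empty_cohort(self, tmp_path):
        p = self._write(tmp_path, "child_id,sex,dob,dor,t31\n")
        assert read_cohort(p) == []

    def test_single_valid_row(self, tmp_path):
        p = self._write(
            tmp_path,
            "child_id,sex,dob,dor,t36,t46\nk1,M,2010-01-01,2017-01-01,E,\n",
        )
        (rec,) = read_cohort(p)
        assert rec.child_id == "k1"
        assert rec.sex == "M"
        assert rec.ca == 7.00
        assert rec.stages == {36: Stage.E}

    def test_unknown_stage_letter_names_the_cell(self, tmp_path):
        p = self._write(
            tmp_path,
            "child_id,sex,dob,dor,t36\nk1,M,2010-01-01,2017-01-01,Z\n",
        )
        with pytest.raises(ValidationError) as exc:
            read_cohort(p)
        assert exc.value.problems[0][:2] == (2, "t36")

    @pytest.mark.parametrize(
        "row, column",
        [
            ("k1,X,2010-01-01,2017-01-01,E", "sex"),
            ("k1,M,01/02/2010,2017-01-01,E", "dob"),
            ("k1,M,2010-01-01,bogus,E", "dor"),
        ],
    )
    def test_bad_cells_reported_with_location(self, tmp_path, row, column):
        p = self._write(tmp_path, f"child_id,sex,dob,dor,t36\n{row}\n")
        with pytest.raises(ValidationError) as exc:
            read_cohort(p)
        assert any(c == column for _, c, _ in exc.value.problems)

    def test_lenient_mode_collects_problems_and_keeps_valid_rows(self, tmp_path):
        p = self._write(
            tmp_path,
            "child_id,sex,dob,dor,t36\n"
            "good,M,2010-01-01,2017-01-01,E\n"
            "bad,M,2010-01-01,2017-01-01,Z\n",
        )
        records, problems = read_cohort_lenient(p)
        assert [r.child_id for r in records] == ["good"]
        assert len(problems) == 1

    def test_round_trip_preserves_fields(self, tmp_path, make_record):
        recs = [
            make_record(child_id="a", sex="M", stages={31: Stage.H, 46: Stage.C}),
            make_record(child_id="b", sex="F", stage=Stage.S0),
        ]
        path = tmp_path / "out.csv"
        write_cohort(recs, path)
        back = read_cohort(path)
        for orig, new in zip(recs, back):
            assert (orig.child_id, orig.sex, orig.dob, orig.dor, orig.stages) == (
                new.child_id,
                new.sex,
                new.dob,
                new.dor,
                new.stages,
            )


class TestExclusionFilter:
    def _records(self, make_record, edas):
        out = []
        for i, eda in enumerate(edas):
            r = make_record(child_id=f"r{i}")
            r.eda = eda
            out.append(r)
        return out

    def test_nine_of_169_below_threshold_leaves_160(self, make_record):
        edas = [2.0] * 9 + [5.0] * 160
        retained, excluded, log = exclude_below_min_age(self._records(make_record, edas))
        assert (len(retained), len(excluded)) == (160, 9)
        assert len(log) == 9 and all(e.value < 2.5 for e in log)

    def test_none_below_threshold(self, make_record):
        retained, excluded, log = exclude_below_min_age(self._records(make_record, [3.0, 4.0]))
        assert len(retained) == 2 and excluded == [] and log == []

    def test_all_below_threshold(self, make_record):
        retained, excluded, _ = exclude_below_min_age(self._records(make_record, [1.0, 2.0]))
        assert retained == [] and len(excluded) == 2

    def test_missing_eda_is_a_precondition_error(self, make_record):
        with pytest.raises(InvalidRecordError):
            exclude_below_min_age([make_record()])

    @settings(derandomize=True, max_examples=30)
    @given(edas=st.lists(st.floats(min_value=0.5, max_value=12.0), max_size=40))
    def test_partition_property(self, edas):
        records = [
            ChildRecord(f"r{i}", "M", dt.date(2010, 1, 1), dt.date(2016, 1, 1), eda=eda)
            for i, eda in enumerate(edas)
        ]
        retained, excluded, _ = exclude_below_min_age(records)
        assert len(retained) + len(excluded) == len(edas)
        assert all(r.eda >= 2.5 for r in retained)
        assert all(r.eda < 2.5 for r in excluded)


def test_record_rejects_unknown_sex_and_bad_stage_keys():
    with pytest.raises(InvalidRecordError):
        ChildRecord("x", "Q", dt.date(2010, 1, 1), dt.date(2015, 1, 1))
    with pytest.raises(InvalidRecordError):
        ChildRecord(
            "x", "M", dt.date(2010, 1, 1), dt.date(2015, 1, 1), stages={18: Stage.A}
        )
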