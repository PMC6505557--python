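import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vocalid import (
    ClipRecord,
    Dataset,
    Provenance,
    Role,
    Split,
    load_manifest,
    restrict_per_individual,
    save_manifest,
    temporal_split,
)
from vocalid.manifest import ManifestError

from conftest import make_record


class TestClipRecord:
    def test_year_derived_from_date(self):
        rec = make_record(date=dt.date(2013, 3, 15))
        assert rec.year == 2013

    def test_background_cannot_carry_mix_provenance(self):
        with pytest.raises(ManifestError):
            make_record(
                role=Role.BACKGROUND,
                provenance=Provenance.STRATIFIED_MIX,
                mixed_with_individual="ind01",
            )

    def test_mixed_with_set_iff_mixed_provenance(self):
        with pytest.raises(ManifestError):
            make_record(mixed_with_individual="ind01")  # original provenance
        with pytest.raises(ManifestError):
            make_record(provenance=Provenance.STRATIFIED_MIX)  # no donor
        with pytest.raises(ManifestError):
            make_record(
                provenance=Provenance.STRATIFIED_MIX, mixed_with_individual="ind00"
            )  # own background


class TestDataset:
    def test_counts_individuals_from_foreground_records(self):
        ds = Dataset(
            [
                make_record(path="a.wav", individual="x"),
                make_record(path="b.wav", individual="y"),
                make_record(path="c.wav", individual="x", role=Role.BACKGROUND),
            ]
        )
        assert ds.K == 2
        assert len(ds) == 3

    def test_background_only_labels_do_not_count_toward_K(self):
        ds = Dataset([make_record(path="c.wav", individual="z", role=Role.BACKGROUND)])
        assert ds.K == 0

    def test_duplicate_records_rejected(self):
        rec = make_record()
        with pytest.raises(ManifestError):
            Dataset([rec, rec])


class TestManifestIO:
    def test_save_then_load_small_manifest(self, tmp_path):
        ds = Dataset(
            [
                make_record(path="a.wav", individual="x"),
                make_record(path="b.wav", individual="y", role=Role.BACKGROUND),
            ]
        )
        p = save_manifest(ds, tmp_path / "m.csv")
        loaded = load_manifest(p)
        assert loaded.records == ds.records

    def test_empty_dataset_writes_header_only(self, tmp_path):
        p = save_manifest(Dataset([]), tmp_path / "m.csv")
        assert p.read_text().strip().count("\n") == 0
        assert load_manifest(p).records == []

    def test_schema_error_names_missing_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("path,individual,role,date,split,provenance\n")
        with pytest.raises(ManifestError, match="mixed_with_individual"):
            load_manifest(p)

    def test_bad_date_reports_row_number(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "path,individual,role,date,split,provenance,mixed_with_individual\n"
            "a.wav,x,foreground,not-a-date,train,original,\n"
        )
        with pytest.raises(ManifestError, match="row 2"):
            load_manifest(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.raises(ManifestError):
            load_manifest(p)

    @settings(deadline=None, max_examples=30)
    @given(data=st.data())
    def test_round_trip_identity_on_randomized_manifests(self, data, tmp_path_factory):
        inds = ["ind%02d" % i for i in range(4)]
        n = data.draw(st.integers(1, 12))
        records = []
        for i in range(n):
            role = data.draw(st.sampled_from(list(Role)))
            prov = (
                Provenance.ORIGINAL
                if role is Role.BACKGROUND
                else data.draw(st.sampled_from(list(Provenance)))
            )
            ind = data.draw(st.sampled_from(inds))
            mixed = None
            if prov is not Provenance.ORIGINAL:
                mixed = data.draw(st.sampled_from([x for x in inds if x != ind]))
            records.append(
                ClipRecord(
                    path=f"clips/{i}.wav",
                    individual=ind,
                    role=role,
                    date=data.draw(
                        st.dates(dt.date(2012, 1, 1), dt.date(2015, 12, 31))
                    ),
                    split=data.draw(st.sampled_from(list(Split))),
                    provenance=prov,
                    mixed_with_individual=mixed,
                )
            )
        ds = Dataset(records)
        p = save_manifest(ds, tmp_path_factory.mktemp("rt") / "m.csv")
        assert load_manifest(p).records == ds.records


class TestTemporalSplit:
    def _days(self, days, year=2013):
        return Dataset(
            [
                make_record(path=f"d{d}.wav", date=dt.date(year, 4, d))
                for d in days
            ]
        )

    def test_within_year_boundary_is_half_open(self):
        ds = temporal_split(self._days([1, 2, 3]), "within_year", dt.date(2013, 4, 3))
        splits = [r.split for r in ds.records]
        assert splits == [Split.TRAIN, Split.TRAIN, Split.EVAL]

    def test_across_year_assigns_later_years_to_eval(self):
        ds = Dataset(
            [
                make_record(path="a.wav", date=dt.date(2013, 4, 1)),
                make_record(path="b.wav", date=dt.date(2014, 4, 1)),
            ]
        )
        out = temporal_split(ds, "across_year", 2013)
        assert [r.split for r in out.records] == [Split.TRAIN, Split.EVAL]

    def test_boundary_before_all_dates_gives_all_eval(self):
        out = temporal_split(self._days([5, 6]), "within_year", dt.date(2013, 4, 1))
        assert all(r.split is Split.EVAL for r in out.records)

    def test_mode_boundary_type_mismatch_rejected(self):
        ds = self._days([1])
        with pytest.raises(ValueError):
            temporal_split(ds, "across_year", dt.date(2013, 4, 1))
        with pytest.raises(ValueError):
            temporal_split(ds, "within_year", 2013)

    def test_split_is_a_partition_with_ordered_dates(self):
        ds = self._days([1, 2, 3, 4, 5])
        out = temporal_split(ds, "within_year", dt.date(2013, 4, 4))
        train = [r for r in out.records if r.split is Split.TRAIN]
        ev = [r for r in out.records if r.split is Split.EVAL]
        assert len(train) + len(ev) == len(ds)
        assert max(r.date for r in train) < min(r.date for r in ev)


class TestRestrictPerIndividual:
    def _ds(self, counts, split=Split.TRAIN):
        recs = []
        for ind, n in counts.items():
            for j in range(n):
                recs.append(
                    make_record(
                        path=f"{ind}_{j}.wav",
                        individual=ind,
                        date=dt.date(2013, 4, 1) + dt.timedelta(days=j),
                        split=split,
                    )
                )
        return recs

    def test_keeps_chronologically_earliest(self):
        ds = Dataset(self._ds({"a": 5}))
        out = restrict_per_individual(ds, 2)
        assert sorted(r.path for r in out.records) == ["a_0.wav", "a_1.wav"]

    def test_eval_and_background_untouched(self):
        recs = self._ds({"a": 4}) + [
            make_record(path="ev.wav", individual="a", split=Split.EVAL),
            make_record(path="bg.wav", individual="a", role=Role.BACKGROUND, split=Split.TRAIN),
        ]
        out = restrict_per_individual(Dataset(recs), 1)
        paths = {r.path for r in out.records}
        assert {"ev.wav", "bg.wav", "a_0.wav"} == paths

    def test_n_larger_than_counts_is_identity(self):
        ds = Dataset(self._ds({"a": 3, "b": 2}))
        assert restrict_per_individual(ds, 10).records == ds.records

    def test_n_one_leaves_K_records(self):
        ds = Dataset(self._ds({"a": 3, "b": 2, "c": 4}))
        assert len(restrict_per_individual(ds, 1)) == 3

    def test_idempotent(self):
        ds = Dataset(self._ds({"a": 6, "b": 4}))
        once = restrict_per_individual(ds, 3)
        assert restrict_per_individual(once, 3).records == once.records

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            restrict_per_individual(Dataset(self._ds({"a": 2})), 0)
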