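"""Manifest I/O, exclusion rules, and stratified splitting."""

import numpy as np
import pandas as pd
import pytest

from palmdx.records import (HandRecord, ManifestSchemaError, ManifestValidationError,
                            RecordSet, apply_exclusions, load_manifest,
                            split_records, write_manifest)


def make_record(i, m=0, p=0, flags=frozenset(), side=20):
    img = np.full((side, side, 3), 100, dtype=np.uint8)
    return HandRecord(record_id=f"r{i}", image_ref=img, x1=15.0, x2=5.0,
                      y1=16.0, y2=4.0, label_m=m, label_p=p, flags=flags)


def make_set(labels, flags=None):
    flags = flags or [frozenset()] * len(labels)
    return RecordSet([make_record(i, m, p, f)
                      for i, ((m, p), f) in enumerate(zip(labels, flags))],
                     provenance="synthetic")


class TestRecordValidation:
    def test_non_binary_label_rejected(self):
        with pytest.raises(ManifestValidationError, match="label_m"):
            make_record(0, m=2)

    def test_landmark_convention_enforced(self):
        img = np.zeros((20, 20, 3), dtype=np.uint8)
        with pytest.raises(ManifestValidationError, match="x1 > x2"):
            HandRecord("r", img, x1=5, x2=15, y1=16, y2=4, label_m=0, label_p=0)

    def test_unknown_flag_rejected(self):
        with pytest.raises(ManifestValidationError, match="blurry"):
            make_record(0, flags=frozenset({"blurry"}))

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ManifestValidationError, match="duplicate"):
            RecordSet([make_record(0), make_record(0)])


class TestManifestIO:
    @pytest.mark.parametrize("fmt", ["csv", "json"])
    def test_round_trip(self, tmp_path, fmt):
        rs = make_set([(0, 0), (1, 0), (1, 1)],
                      flags=[frozenset(), frozenset({"scar"}), frozenset()])
        path = tmp_path / f"manifest.{fmt}"
        write_manifest(rs, path)
        back = load_manifest(path)
        assert len(back) == 3
        for orig, loaded in zip(rs, back):
            assert loaded.record_id == orig.record_id
            assert loaded.landmarks == orig.landmarks
            assert (loaded.label_m, loaded.label_p) == (orig.label_m, orig.label_p)
            assert loaded.flags == orig.flags
            np.testing.assert_array_equal(loaded.load_image(), orig.load_image())

    def test_missing_column_names_the_column(self, tmp_path):
        df = pd.DataFrame({"record_id": ["a"], "image_path": ["x.png"]})
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ManifestSchemaError, match="x1"):
            load_manifest(path)

    def test_non_binary_label_in_file(self, tmp_path):
        rs = make_set([(0, 0)])
        path = write_manifest(rs, tmp_path / "m.csv")
        df = pd.read_csv(path)
        df.loc[0, "label_m"] = 2
        df.to_csv(path, index=False)
        with pytest.raises(ManifestValidationError, match="r0"):
            load_manifest(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_manifest(tmp_path / "nope.csv")


class TestExclusions:
    def test_flagged_records_removed_and_counted(self):
        flags = [frozenset({"scar"})] * 3 + [frozenset()] * 7
        rs = make_set([(0, 0)] * 10, flags=flags)
        kept, report = apply_exclusions(rs)
        assert len(kept) == 7
        assert report.counts["scar"] == 3
        assert report.n_retained == 7

    def test_record_with_two_flags_counted_per_criterion_removed_once(self):
        rs = make_set([(0, 0), (0, 0)],
                      flags=[frozenset({"scar", "peeling"}), frozenset()])
        kept, report = apply_exclusions(rs)
        assert len(kept) == 1
        assert report.counts["scar"] == 1
        assert report.counts["peeling"] == 1
        assert report.n_input - report.n_retained == 1

    def test_identity_when_no_flags_and_idempotent(self):
        rs = make_set([(0, 1), (1, 0)])
        kept, _ = apply_exclusions(rs)
        assert [r.record_id for r in kept] == [r.record_id for r in rs]
        kept2, _ = apply_exclusions(kept)
        assert [r.record_id for r in kept2] == [r.record_id for r in kept]

    def test_empty_input(self):
        kept, report = apply_exclusions(RecordSet([]))
        assert len(kept) == 0 and report.n_input == 0


class TestSplit:
    def test_study_sized_split_counts(self):
        # four strata sized like the observed class counts, padded to 2414
        sizes = {(1, 1): 570, (0, 1): 530, (1, 0): 522, (0, 0): 792}
        labels = [combo for combo, n in sizes.items() for _ in range(n)]
        rs = make_set(labels)
        res = split_records(rs, train_fraction=1931 / 2414, seed=0)
        assert len(res.train) == 1931
        assert len(res.val) == 483

    def test_single_stratum_fraction(self):
        rs = make_set([(0, 0)] * 10)
        res = split_records(rs, train_fraction=0.8, seed=3)
        assert (len(res.train), len(res.val)) == (8, 2)

    def test_deterministic_and_seed_sensitive(self):
        rs = make_set([(m, p) for m in (0, 1) for p in (0, 1)] * 10)
        a = split_records(rs, 0.8, seed=7)
        b = split_records(rs, 0.8, seed=7)
        c = split_records(rs, 0.8, seed=8)
        ids = lambda s: [r.record_id for r in s.train]
        assert ids(a) == ids(b)
        assert len(c.train) == len(a.train)
        assert ids(c) != ids(a)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("frac", [0.5, 0.7, 0.8])
    def test_partition_property(self, seed, frac):
        rs = make_set([(m, p) for m in (0, 1) for p in (0, 1)] * 7 + [(0, 0)] * 3)
        res = split_records(rs, frac, seed=seed)
        train_ids = {r.record_id for r in res.train}
        val_ids = {r.record_id for r in res.val}
        assert not (train_ids & val_ids)
        assert train_ids | val_ids == {r.record_id for r in rs}
        # per-stratum proportions within one record of the global fraction
        for s in res.strata:
            n_s = sum(1 for r in rs if r.stratum == s)
            t_s = sum(1 for r in res.train if r.stratum == s)
            if n_s:
                assert abs(t_s - n_s * frac) <= 1.0 + 1e-9

    def test_size_one_stratum_goes_to_train(self):
        rs = make_set([(0, 0)] * 9 + [(1, 1)])
        res = split_records(rs, 0.5, seed=0)
        assert any(r.stratum == (1, 1) for r in res.train)
        assert not any(r.stratum == (1, 1) for r in res.val)

    def test_invalid_fraction(self):
        rs = make_set([(0, 0)] * 4)
        with pytest.raises(ValueError):
            split_records(rs, 1.0, seed=0)
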