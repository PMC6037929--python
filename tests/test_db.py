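"""Five-table relational store: idempotency, round trips, reader isolation."""

import numpy as np
import pytest

from lesiontrack.db import LesionStore, StoreError
from lesiontrack.geometry import ImageVolume
from lesiontrack.mask import LesionMask
from lesiontrack.measure import measure_lesion

from conftest import make_geometry


def make_volume(patient="P1", study="S1", series="SER1", date="20240101"):
    g = make_geometry()
    return ImageVolume(
        geometry=g,
        intensities=np.zeros(g.shape, dtype=np.int16),
        patient_id=patient, study_uid=study, series_uid=series,
        acquisition_date=date,
    )


def make_mask(volume, seed=0, label="L1", user="reader1"):
    rng = np.random.default_rng(seed)
    v = np.zeros(volume.geometry.shape, dtype=np.uint8)
    z, y, x = (rng.integers(1, s - 5) for s in volume.geometry.shape)
    v[z:z + 3, y:y + 4, x:x + 4] = 1
    return LesionMask(volume.geometry, v, lesion_id=label,
                      series_uid=volume.series_uid, user_id=user)


@pytest.fixture
def store():
    with LesionStore(":memory:") as s:
        yield s


class TestHierarchy:
    def test_repeat_ingestion_is_idempotent(self, store):
        vol = make_volume()
        store.upsert_hierarchy(vol)
        before = store.counts()
        store.upsert_hierarchy(vol)
        assert store.counts() == before
        assert before["patient"] == before["study"] == before["series"] == 1

    def test_two_studies_one_patient(self, store):
        store.upsert_hierarchy(make_volume(study="S1", series="SER1"))
        store.upsert_hierarchy(make_volume(study="S2", series="SER2",
                                           date="20240301"))
        counts = store.counts()
        assert counts["patient"] == 1 and counts["study"] == 2

    def test_uid_collision_across_patients_rejected(self, store):
        store.upsert_hierarchy(make_volume(patient="P1"))
        with pytest.raises(StoreError, match="P1"):
            store.upsert_hierarchy(make_volume(patient="P2"))

    def test_row_counts_match_distinct_uids(self, store, rng):
        uids = set()
        for i in range(12):
            p, s, ser = (f"P{rng.integers(3)}", f"S{rng.integers(6)}",
                         f"SER{i % 8}")
            try:
                store.upsert_hierarchy(make_volume(patient=p, study=s, series=ser))
                uids.add((p, s, ser))
            except StoreError:
                pass  # random collisions with a different parent
        counts = store.counts()
        assert counts["series"] == len({u[2] for u in uids})
        assert counts["study"] == len({u[1] for u in uids})


class TestLesionPersistence:
    def test_save_then_load_round_trip(self, store):
        vol = make_volume()
        store.upsert_hierarchy(vol)
        store.add_user("reader1")
        mask = make_mask(vol)
        rec = measure_lesion(mask, timepoint="20240101")
        store.save_lesion(mask, rec, "reader1")
        ((loaded, loaded_rec),) = store.load_lesions(series_uid=vol.series_uid)
        assert np.array_equal(loaded.voxels, mask.voxels)
        assert loaded_rec.unidimensional == pytest.approx(rec.unidimensional)
        assert loaded_rec.volume == pytest.approx(rec.volume)

    def test_unknown_series_or_user_rejected(self, store):
        vol = make_volume()
        mask = make_mask(vol)
        rec = measure_lesion(mask, "t")
        with pytest.raises(StoreError, match="series"):
            store.save_lesion(mask, rec, "reader1")
        store.upsert_hierarchy(vol)
        with pytest.raises(StoreError, match="user"):
            store.save_lesion(mask, rec, "reader1")

    def test_resave_replaces_row(self, store):
        vol = make_volume()
        store.upsert_hierarchy(vol)
        store.add_user("reader1")
        m1 = make_mask(vol, seed=1)
        m2 = make_mask(vol, seed=2)
        store.save_lesion(m1, measure_lesion(m1, "t"), "reader1")
        store.save_lesion(m2, measure_lesion(m2, "t"), "reader1")
        lesions = store.load_lesions(series_uid=vol.series_uid)
        assert len(lesions) == 1
        assert np.array_equal(lesions[0][0].voxels, m2.voxels)

    def test_two_readers_kept_separate(self, store):
        vol = make_volume()
        store.upsert_hierarchy(vol)
        store.add_user("readerA")
        store.add_user("readerB")
        ma = make_mask(vol, seed=1, user="readerA")
        mb = make_mask(vol, seed=2, user="readerB")
        store.save_lesion(ma, measure_lesion(ma, "t"), "readerA")
        store.save_lesion(mb, measure_lesion(mb, "t"), "readerB")
        (a,) = store.load_lesions(user_id="readerA")
        (b,) = store.load_lesions(user_id="readerB")
        assert np.array_equal(a[0].voxels, ma.voxels)
        assert np.array_equal(b[0].voxels, mb.voxels)
        # overwriting A's contour leaves B untouched
        ma2 = make_mask(vol, seed=3, user="readerA")
        store.save_lesion(ma2, measure_lesion(ma2, "t"), "readerA")
        (b_after,) = store.load_lesions(user_id="readerB")
        assert np.array_equal(b_after[0].voxels, mb.voxels)

    def test_many_save_load_cycles_bit_exact(self, store, rng):
        vol = make_volume()
        store.upsert_hierarchy(vol)
        store.add_user("reader1")
        for i in range(50):
            v = (rng.random(vol.geometry.shape) < 0.2).astype(np.uint8)
            m = LesionMask(vol.geometry, v, lesion_id=f"L{i % 5}",
                           series_uid=vol.series_uid)
            store.save_lesion(m, measure_lesion(m, "t"), "reader1")
            found = [lm for lm, _ in store.load_lesions(series_uid=vol.series_uid)
                     if lm.lesion_id == f"L{i % 5}"]
            assert np.array_equal(found[0].voxels, v)

    def test_filter_by_patient_unions_studies(self, store):
        v1 = make_volume(study="S1", series="SER1")
        v2 = make_volume(study="S2", series="SER2", date="20240301")
        other = make_volume(patient="P2", study="S9", series="SER9")
        for v in (v1, v2, other):
            store.upsert_hierarchy(v)
        store.add_user("reader1")
        for v in (v1, v2, other):
            m = make_mask(v)
            store.save_lesion(m, measure_lesion(m, "t"), "reader1")
        assert len(store.load_lesions(patient_id="P1")) == 2
        assert len(store.load_lesions(patient_id="P2")) == 1
        full = store.load_lesions()
        assert len(full) == 3


class TestIntegrity:
    def _populated(self, store):
        vol = make_volume()
        store.upsert_hierarchy(vol)
        store.add_user("reader1")
        m = make_mask(vol)
        store.save_lesion(m, measure_lesion(m, "t"), "reader1")
        return vol

    def test_fresh_store_clean(self, store):
        self._populated(store)
        assert store.integrity_check().clean

    def test_corrupted_payload_flagged(self, store):
        self._populated(store)
        store._conn.execute("UPDATE lesion SET payload = X'0011'")
        store._conn.commit()
        report = store.integrity_check()
        assert not report.clean
        assert any("lesion" in f for f in report.findings)

    def test_orphan_series_flagged(self, store):
        self._populated(store)
        store._conn.execute("DELETE FROM study")
        store._conn.commit()
        report = store.integrity_check()
        assert any("orphan series" in f for f in report.findings)
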