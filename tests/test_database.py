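import numpy as np
import pytest

from cytoagi.database import (ANALYSIS_MARKERS, init_database,
                              classify_and_merge, consistency_check,
                              save_database, load_database)
from cytoagi.simdata import simulate_sample, SampleSpec
from cytoagi.taxonomy import boolean_gate


def _labelled(model, seed, n=20_000, **kw):
    em, truth = simulate_sample(model, SampleSpec(n_events=n, seed=seed,
                                                  sample_id=f"f{seed}", **kw))
    return em, truth


class TestInit:
    def test_templates_match_per_population_medians(self, tax, model):
        em, truth = _labelled(model, 61)
        db = init_database(em, truth, tax)
        x = em.submatrix(ANALYSIS_MARKERS)
        for name in ("neutrophils", "T cells CD5+", "memory B"):
            if name not in db.templates:
                continue
            expect = np.median(x[truth == name], axis=0)
            np.testing.assert_array_equal(db.templates[name].location, expect)

    def test_absent_populations_absent(self, tax, model):
        em, truth = _labelled(model, 62, n=5_000, frequency_overrides={
            l: 0.0 for l in tax.leaf_names("PC")})
        db = init_database(em, truth, tax)
        assert not any(p.startswith("PC ") for p in db.templates)

    def test_single_population_file(self, tax, model):
        em, truth = _labelled(model, 63, n=2_000, doublet_rate=0,
                              debris_rate=0)
        keep = truth == "neutrophils"
        em2 = em.with_values(em.values[keep])
        db = init_database(em2, truth[keep], tax)
        assert list(db.templates) == ["neutrophils"]

    def test_empty_labels_rejected(self, tax, model):
        em, _ = _labelled(model, 64, n=1_000)
        em0 = em.with_values(em.values[:0])
        with pytest.raises(ValueError):
            init_database(em0, [], tax)

    def test_unknown_label_rejected(self, tax, model):
        em, truth = _labelled(model, 65, n=1_000)
        truth = truth.copy()
        truth[0] = "weird cells"
        with pytest.raises(ValueError, match="weird"):
            init_database(em, truth, tax)


class TestMerge:
    def test_merge_commutative_on_counts_and_location(self, tax, model):
        em1, t1 = _labelled(model, 66)
        em2, t2 = _labelled(model, 67)
        ab = classify_and_merge(init_database(em1, t1, tax), em2, t2)
        ba = classify_and_merge(init_database(em2, t2, tax), em1, t1)
        for pop in ab.templates:
            assert pop in ba.templates
            assert ab.templates[pop].n_events == ba.templates[pop].n_events
            np.testing.assert_allclose(ab.templates[pop].location,
                                       ba.templates[pop].location, atol=1e-9)

    def test_merging_identical_file_multiplies_counts_only(self, tax, model):
        em, truth = _labelled(model, 68)
        db1 = init_database(em, truth, tax)
        em2 = em.with_values(em.values)
        em2.sample_id = "copy"
        db2 = classify_and_merge(db1, em2, truth)
        for pop, t in db2.templates.items():
            assert t.n_events == 2 * db1.templates[pop].n_events
            np.testing.assert_allclose(t.location,
                                       db1.templates[pop].location, atol=1e-9)

    def test_same_model_merge_moves_locations_little(self, tax, model):
        em1, t1 = _labelled(model, 69, n=40_000)
        em2, t2 = _labelled(model, 70, n=40_000)
        db1 = init_database(em1, t1, tax)
        db2 = classify_and_merge(db1, em2, t2)
        for pop in ("neutrophils", "T cells CD5+", "monocytes"):
            shift = np.abs(db2.templates[pop].location
                           - db1.templates[pop].location).max()
            assert shift < 0.1

    def test_new_population_creates_template(self, tax, model):
        em1, t1 = _labelled(model, 71, n=5_000, frequency_overrides={
            l: 0.0 for l in tax.leaf_names("PC")})
        db = init_database(em1, t1, tax)
        em2, t2 = _labelled(model, 72, n=50_000)
        db2 = classify_and_merge(db, em2, t2)
        assert any(p.startswith("PC ") for p in db2.templates)
        # input database untouched
        assert not any(p.startswith("PC ") for p in db.templates)

    def test_headless_merge_labels_via_classifier(self, tax, model):
        # without confirmed labels the new file is labelled by the two-step
        # classifier against the current database and accepted as-is
        em1, t1 = _labelled(model, 75, n=20_000)
        db = init_database(em1, t1, tax)
        em2, t2 = _labelled(model, 76, n=5_000)
        db2 = classify_and_merge(db, em2, confirmed_labels=None)
        grown = sum(db2.templates[p].n_events for p in db2.templates) \
            - sum(db.templates[p].n_events for p in db.templates)
        assert grown > 0.9 * em2.n_events   # nearly all events were merged
        assert "neutrophils" in db2.templates

    def test_provenance_traces_every_stored_event(self, tax, model):
        em1, t1 = _labelled(model, 73, n=10_000)
        em2, t2 = _labelled(model, 74, n=10_000)
        db = classify_and_merge(init_database(em1, t1, tax), em2, t2)
        for pop, files in db.events.items():
            assert set(files) <= {"f73", "f74"}
            total = sum(len(v) for v in files.values())
            assert total <= db.templates[pop].n_events


@pytest.fixture(scope="module")
def five_file_db(tax, model):
    db = None
    for s in range(5):
        em, truth = _labelled(model, 80 + s, n=15_000)
        db = init_database(em, truth, tax) if db is None \
            else classify_and_merge(db, em, truth)
    return db


class TestConsistency:
    def test_homogeneous_cohort_passes(self, five_file_db):
        rep = consistency_check(five_file_db)
        big = rep[(rep.status == "ok")]
        big = big[big.population.isin(
            ["neutrophils", "monocytes", "T cells CD5+", "NK cells CD5-",
             "eosinophils", "other nucleated cells"])]
        assert len(big) > 0
        assert (~big.flagged).mean() >= 0.95

    def test_shifted_file_flagged(self, tax, model, five_file_db):
        em, truth = _labelled(model, 90, n=15_000)
        vals = em.values.copy()
        shift = np.isin(truth, tax.leaf_names("MBC"))
        vals[shift, em.marker_index("CD27")] += 2.0
        em_s = em.with_values(vals)
        em_s.sample_id = "shifted"
        db = classify_and_merge(five_file_db, em_s, truth)
        rep = consistency_check(db)
        mbc_rows = rep[(rep.file == "shifted")
                       & rep.population.isin(["MBC IgMD CD21+CD20+ CD27-"])]
        assert mbc_rows.flagged.any()

    def test_single_file_population_skipped(self, tax, model):
        em1, t1 = _labelled(model, 91, n=8_000)
        em2, t2 = _labelled(model, 92, n=8_000, frequency_overrides={
            l: 0.0 for l in tax.leaf_names("PC")})
        db = classify_and_merge(init_database(em1, t1, tax), em2, t2)
        rep = consistency_check(db)
        pc_rows = rep[rep.population.str.startswith("PC ")]
        assert (pc_rows.status == "skipped").all()


class TestSerialisation:
    def test_save_load_round_trip(self, tmp_path, tax, model, small_db):
        path = str(tmp_path / "db")
        save_database(small_db, path)
        back = load_database(path, tax)
        assert set(back.templates) == set(small_db.templates)
        for pop, t in small_db.templates.items():
            assert back.templates[pop].n_events == t.n_events
            np.testing.assert_allclose(back.templates[pop].location,
                                       t.location, rtol=1e-12)
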