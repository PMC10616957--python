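import numpy as np
import pytest

from cytoagi.agi_core import (DegenerateScopeError, knn_density,
                              cluster_events, fit_canonical_plane,
                              classify_cluster, two_step_classify,
                              maturation_assign, hierarchical_classify,
                              SEPARATION_SCALE)
from cytoagi.database import PopulationTemplate
from cytoagi.fcs_io import EventMatrix, default_panel
from cytoagi.simdata import (simulate_sample, SampleSpec,
                             simulate_maturation_continuum)
from cytoagi.taxonomy import UNCLASSIFIED, DEBRIS


# ---------------------------------------------------------------------------
# independent brute-force oracle (all-pairs, plain loops)
# ---------------------------------------------------------------------------

def oracle_knn(x, k):
    n = len(x)
    dens = np.empty(n)
    neigh = np.empty((n, k), dtype=int)
    for i in range(n):
        d = np.sqrt(((x - x[i]) ** 2).sum(axis=1))
        order = np.argsort(d, kind="stable")
        order = order[order != i][:k]
        neigh[i] = order
        md = d[order].mean()
        dens[i] = 1.0 / md if md > 0 else 1e12
    return dens, neigh


def oracle_cluster(x, k, cutoff, mean_rounds=3):
    dens, neigh = oracle_knn(x, k)
    n = len(x)
    link = np.arange(n)
    for i in range(n):
        nb = neigh[i]
        best = nb[np.argmax(dens[nb])]
        if dens[best] > dens[i]:
            link[i] = best
    mode = link.copy()
    for i in range(n):
        while link[mode[i]] != mode[i]:
            mode[i] = link[mode[i]]
    sm = dens.copy()
    for _ in range(mean_rounds):
        sm = np.array([(sm[i] + np.sum(sm[neigh[i]])) / (k + 1)
                       for i in range(n)])
    saddle = {}
    for i in range(n):
        for j in neigh[i]:
            if mode[i] != mode[j]:
                key = (min(mode[i], mode[j]), max(mode[i], mode[j]))
                s = min(sm[i], sm[j])
                saddle[key] = max(saddle.get(key, -np.inf), s)
    peak = {int(a): max(sm[mode == a]) for a in np.unique(mode)}
    parent = {int(a): int(a) for a in np.unique(mode)}

    def find(a):
        while parent[a] != a:
            a = parent[a]
        return a

    while True:
        live = {}
        for (a, b), s in saddle.items():
            ra, rb = find(a), find(b)
            if ra == rb:
                continue
            key = (min(ra, rb), max(ra, rb))
            live[key] = max(live.get(key, -np.inf), s)
        cand = [(SEPARATION_SCALE * max(0.0, 1 - s / min(peak[a], peak[b])),
                 a, b) for (a, b), s in live.items()]
        if not cand:
            break
        sep, a, b = min(cand)
        if sep >= cutoff:
            break
        parent[b] = a
        peak[a] = max(peak[a], peak[b])
        saddle = {k2: v for k2, v in live.items() if k2 != (a, b)}
    return dens, np.array([find(int(m)) for m in mode])


def partitions_equal(a, b):
    a = np.asarray(a)
    b = np.asarray(b)
    pair = {}
    for x, y in zip(a, b):
        if pair.setdefault(x, y) != y:
            return False
    return len(set(pair.values())) == len(pair)


class TestKnnDensity:
    def test_three_collinear_points_hand_oracle(self):
        x = np.array([[0.0], [1.0], [3.0]])
        dens, neigh, _ = knn_density(x, k=1)
        np.testing.assert_allclose(dens, [1.0, 1.0, 0.5])

    def test_duplicate_events_capped(self):
        x = np.zeros((5, 2))
        dens, _, _ = knn_density(x, k=2)
        assert np.all(np.isfinite(dens)) and np.all(dens >= 1e10)

    def test_uniform_grid_interior_equal(self):
        g = np.array([[i, j] for i in range(6) for j in range(6)], float)
        dens, _, _ = knn_density(g, k=4)
        interior = [i * 6 + j for i in range(1, 5) for j in range(1, 5)]
        assert np.allclose(dens[interior], dens[interior][0])
        # and matches the brute-force oracle
        od, _ = oracle_knn(g, 4)
        np.testing.assert_array_equal(dens, od)

    def test_degenerate_scope_rejected(self):
        with pytest.raises(DegenerateScopeError):
            knn_density(np.zeros((5, 2)), k=10)


class TestClustering:
    def test_two_separated_blobs(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal(0, 1, (1000, 5)),
                       rng.normal(10, 1, (1000, 5))])
        cs = cluster_events(x, k=10, cutoff=0.9)
        assert cs.n_clusters == 2
        truth = np.repeat([0, 1], 1000)
        assert partitions_equal(cs.labels, truth)

    def test_single_blob_merges_to_one(self):
        # 5-D, the typical dimensionality of a stage marker subspace;
        # saddle ~ peak inside one Gaussian, so separation ~ 0 < 0.9
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, (2000, 5))
        cs = cluster_events(x, k=10, cutoff=0.9)
        assert cs.n_clusters == 1

    def test_cutoff_boundaries_of_scale(self):
        # separation 0 <=> indistinguishable modes, so merging happens while
        # separation < cutoff: cutoff 0 keeps every raw mode, cutoff 20
        # collapses every K-NN-connected region
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (500, 2))
        dens, neigh, _ = knn_density(x, k=10)
        cs0 = cluster_events(x, k=10, cutoff=0.0)
        from cytoagi.agi_core import _find_modes
        assert len(cs0.merge_trace) == 0
        assert cs0.n_clusters == len(np.unique(_find_modes(dens, neigh)))
        cs20 = cluster_events(x, k=10, cutoff=SEPARATION_SCALE)
        assert cs20.n_clusters <= cs0.n_clusters

    @pytest.mark.parametrize("seed", range(6))
    def test_oracle_equivalence_random_scopes(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(200, 800))
        centers = rng.normal(0, 6, (int(rng.integers(1, 5)), 3))
        x = np.vstack([rng.normal(c, 1.0, (n // len(centers) + 1, 3))
                       for c in centers])[:n]
        dens, _, _ = knn_density(x, k=10)
        od, omode = oracle_cluster(x, 10, 0.9)
        np.testing.assert_array_equal(dens, od)
        cs = cluster_events(x, k=10, cutoff=0.9)
        assert partitions_equal(cs.labels, omode)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        x = np.vstack([rng.normal(0, 1, (400, 4)),
                       rng.normal(8, 1, (400, 4))])
        a = cluster_events(x, k=10, cutoff=0.9)
        b = cluster_events(x * 37.5, k=10, cutoff=0.9)
        assert partitions_equal(a.labels, b.labels)


def _tmpl(name, loc, cov, n=1000):
    return PopulationTemplate(name, n, np.asarray(loc, float),
                              np.asarray(cov, float))


class TestCanonicalPlane:
    def test_two_spherical_populations_axis_is_difference(self):
        d = 5
        a = _tmpl("a", np.zeros(d), np.eye(d))
        loc_b = np.zeros(d)
        loc_b[2] = 4.0        # differ only in marker 2
        b = _tmpl("b", loc_b, np.eye(d))
        plane = fit_canonical_plane([a, b])
        e2 = np.zeros(d)
        e2[2] = 1.0
        assert abs(abs(plane.axes[:, 0] @ e2) - 1.0) < 1e-9

    def test_closed_form_whitened_oracle(self):
        # axis 1 for two classes is proportional to Sw^-1 (mu1 - mu0)
        sw = np.diag([1.0, 4.0, 0.25])
        mu0, mu1 = np.zeros(3), np.array([2.0, 2.0, 2.0])
        a = _tmpl("a", mu0, sw)
        b = _tmpl("b", mu1, sw)
        plane = fit_canonical_plane([a, b])
        expect = np.linalg.solve(sw, mu1 - mu0)
        expect /= np.linalg.norm(expect)
        assert min(np.linalg.norm(plane.axes[:, 0] - expect),
                   np.linalg.norm(plane.axes[:, 0] + expect)) < 1e-8

    def test_three_collinear_means(self):
        sw = np.eye(4)
        line = np.array([1.0, -1.0, 0.5, 0.0])
        tmpls = [_tmpl(f"p{i}", i * line, sw) for i in range(3)]
        plane = fit_canonical_plane(tmpls)
        direction = line / np.linalg.norm(line)
        assert min(np.linalg.norm(plane.axes[:, 0] - direction),
                   np.linalg.norm(plane.axes[:, 0] + direction)) < 1e-8

    def test_identical_templates_rejected(self):
        a = _tmpl("a", np.zeros(3), np.eye(3))
        b = _tmpl("b", np.zeros(3), np.eye(3))
        with pytest.raises(ValueError, match="between-population"):
            fit_canonical_plane([a, b])

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            fit_canonical_plane([_tmpl("a", np.zeros(3), np.eye(3))])

    def test_axes_orthonormal_for_two_populations(self):
        a = _tmpl("a", np.zeros(4), np.diag([1, 2, 3, 4.0]))
        b = _tmpl("b", np.array([3.0, 0, 0, 0]), np.diag([1, 2, 3, 4.0]))
        plane = fit_canonical_plane([a, b])
        assert plane.axes.shape == (4, 2)
        assert abs(plane.axes[:, 0] @ plane.axes[:, 1]) < 1e-9


class TestClassifyCluster:
    def test_cluster_from_template_gets_its_label(self):
        rng = np.random.default_rng(0)
        cov = np.eye(4) * 0.04
        a = _tmpl("a", np.zeros(4), cov)
        b = _tmpl("b", np.full(4, 8 * 0.2), cov)   # 8 SD away per axis
        pts = rng.multivariate_normal(a.location, cov, 500)
        assert classify_cluster(np.median(pts, axis=0), [a, b]) == "a"

    def test_midpoint_between_distant_templates_unclassified(self):
        cov = np.eye(4)
        a = _tmpl("a", np.zeros(4), cov)
        b = _tmpl("b", np.full(4, 8.0 / np.sqrt(4)), cov)  # 8 SD apart
        mid = (a.location + b.location) / 2
        assert classify_cluster(mid, [a, b]) == UNCLASSIFIED

    def test_single_candidate_within_two_sd(self):
        a = _tmpl("a", np.zeros(3), np.eye(3))
        assert classify_cluster(np.array([1.0, 0, 0]), [a]) == "a"
        assert classify_cluster(np.array([5.0, 0, 0]), [a]) == UNCLASSIFIED

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            classify_cluster(np.zeros(3), [])


class TestMaturation:
    def _stages(self):
        return [_tmpl("s1", [0.0, 0.0], np.eye(2)),
                _tmpl("s2", [2.0, 0.0], np.eye(2)),
                _tmpl("s3", [4.0, 2.0], np.eye(2))]

    def test_event_at_first_stage_location(self):
        labels, pos = maturation_assign(np.array([[0.0, 0.0]]), self._stages())
        assert labels[0] == "s1" and pos[0] == 0.0

    def test_tie_at_cutoff_goes_to_later_stage(self):
        labels, _ = maturation_assign(np.array([[1.0, 0.0]]), self._stages())
        assert labels[0] == "s2"       # exactly midway between s1 and s2

    def test_continuum_recovers_planted_change_points(self, model):
        stages = ["immature B", "naive CD5+ B", "naive CD5- B"]
        markers = ["CD38", "CD24", "CD5", "IgD", "IgM", "CD21"]
        x, t, truth = simulate_maturation_continuum(
            model, stages, markers, 4000, [0.35, 0.65], seed=12)
        tmpls = [_tmpl(s, model.location(s, markers), np.eye(len(markers)))
                 for s in stages]
        labels, pos = maturation_assign(x, tmpls, cutoffs=[0.35, 0.65])
        # positions are uniform, so recovered stage fractions locate the
        # boundaries; each must sit within 0.05 normalised units
        for stage, planted in (("immature B", 0.35),
                               ("naive CD5- B", 1 - 0.65)):
            assert abs(np.mean(labels == stage) - planted) < 0.05

    def test_duplicate_stage_locations_rejected(self):
        s = [_tmpl("a", [0.0, 0.0], np.eye(2)),
             _tmpl("b", [0.0, 0.0], np.eye(2))]
        with pytest.raises(ValueError):
            maturation_assign(np.zeros((1, 2)), s)


class TestTwoStepAndHierarchical:
    def test_pure_debris_scope(self, tax, model, small_db):
        em, _ = simulate_sample(model, SampleSpec(
            n_events=2_000, seed=31, debris_rate=0.99, doublet_rate=0.0))
        res = two_step_classify(em, small_db, seed=1)
        frac = np.mean(res.labels == DEBRIS)
        assert frac > 0.95

    def test_empty_scope(self, small_db):
        em = EventMatrix(np.empty((0, 22)), default_panel(), "transformed")
        res = two_step_classify(em, small_db)
        assert res.n_events == 0

    def test_partition_every_event_labelled(self, small_db, model):
        em, _ = simulate_sample(model, SampleSpec(n_events=20_000, seed=33))
        res = hierarchical_classify(em, small_db, seed=2)
        assert len(res.labels) == em.n_events
        assert all(l in small_db.taxonomy or l in (DEBRIS, "doublet",
                                                   UNCLASSIFIED)
                   for l in np.unique(res.labels))

    def test_determinism_same_seed(self, small_db, model, small_sample):
        em, _ = small_sample
        a = hierarchical_classify(em, small_db, seed=9).labels
        b = hierarchical_classify(em, small_db, seed=9).labels
        np.testing.assert_array_equal(a, b)

    def test_sample_without_pc(self, tax, small_db, model):
        em, truth = simulate_sample(model, SampleSpec(
            n_events=20_000, seed=34,
            frequency_overrides={l: 0.0 for l in tax.leaf_names("PC")}))
        res = hierarchical_classify(em, small_db, seed=3)
        cum = res.cumulative_counts()
        assert cum["plasma cells"] <= 5    # classification noise only

    def test_leaf_recovery_small_scale(self, tax, small_db, model):
        em, truth = simulate_sample(model, SampleSpec(n_events=30_000,
                                                      seed=35))
        res = hierarchical_classify(em, small_db, seed=4)
        leaves = set(tax.leaf_names())
        mask = np.isin(truth, list(leaves))
        assert np.mean(res.labels[mask] == truth[mask]) >= 0.9
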