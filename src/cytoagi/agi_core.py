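"""Automated gating and identification (AGI) core.

Two-step classification: (1) agglomerative density clustering of events —
K-nearest-neighbour densities, density-peak mode finding, and merging of
modes whose separation score (0-20 scale, from the density dip between
adjacent modes) falls below a cut-off; (2) classification of every cluster
against the reference-database templates by Mahalanobis ranking followed
by a pairwise canonical-analysis acceptance test (the cluster's projected
median must fall within the winning template's 2-SD ellipse).

The hierarchical classifier applies the two-step algorithm stage by stage
with cell-type-specific marker subsets, and a maturation (trajectory)
classifier for the continuous pre-germinal-centre and plasma-cell stage
axes.

Numerical conventions: density = 1 / mean distance to the K nearest
neighbours (K=10 by default); separation between adjacent modes =
20 * (1 - saddle/min(peak densities)); default merge cut-off 0.9.
Scopes above ``EXACT_KNN_LIMIT`` events are clustered on a seeded uniform
subsample and the remaining events inherit their nearest sampled
neighbour's label.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from sklearn.neighbors import NearestNeighbors

from .fcs_io import EventMatrix
from .taxonomy import (PopulationTaxonomy, LabelledResult,
                       DOUBLET, DEBRIS, UNCLASSIFIED,
                       MBC_ISOTYPES, PC_ISOTYPES, PC_STAGES)
from .database import ReferenceDatabase, PopulationTemplate

__all__ = [
    "DegenerateScopeError", "ClusterSet", "CanonicalPlane", "Stage",
    "knn_density", "cluster_events", "fit_canonical_plane",
    "classify_cluster", "two_step_classify", "maturation_assign",
    "hierarchical_classify", "default_stage_plan",
]

K_DEFAULT = 10
CUTOFF_DEFAULT = 0.9          # on the 0-20 separation scale
SEPARATION_SCALE = 20.0
DENSITY_CAP = 1e12            # guard for coincident events
# Density-field smoothing before saddle scoring: K-NN averaging passes
# shrink estimation noise; peaks are taken on the same smoothed field.
# A neighbourhood-max pass is available but off by default — it closes
# spurious valleys at the price of erasing genuine ones between close
# populations.
SMOOTH_MEAN_ROUNDS = 3
SMOOTH_MAX_ROUNDS = 0
EXACT_KNN_LIMIT = 100_000
#: Clustering operates on at most this many events per scope; remaining
#: events inherit the nearest sampled neighbour's label. Cluster-level
#: statistics lose little at this size while K-NN graph construction stays
#: tractable on a single core.
CLUSTER_SAMPLE_CAP = 50_000
ACCEPT_SD = 2.0               # canonical-plane acceptance ellipse
MAX_CANDIDATE_PAIRS = 6


class DegenerateScopeError(ValueError):
    """Too few events in scope for K-neighbour clustering."""


# ---------------------------------------------------------------------------
# Step 1: density clustering
# ---------------------------------------------------------------------------

def knn_density(x: np.ndarray, k: int = K_DEFAULT):
    """Per-event density (inverse mean K-NN distance) and neighbour lists.

    Exact neighbours; ``x`` is the scope already restricted to the selected
    marker subspace. Returns ``(density, neighbours, distances)`` with
    neighbour arrays of shape (n, k), self excluded.
    """
    n = len(x)
    if n <= k:
        raise DegenerateScopeError(f"scope of {n} events needs > {k} events")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    dist, idx = nn.kneighbors(x)
    dist, idx = dist[:, 1:], idx[:, 1:]       # drop self
    mean_d = dist.mean(axis=1)
    density = np.where(mean_d > 0, 1.0 / np.maximum(mean_d, 1.0 / DENSITY_CAP),
                       DENSITY_CAP)
    return density, idx, dist


@dataclass
class ClusterSet:
    """A partition of the scope into density clusters."""

    labels: np.ndarray             # per-event cluster id (0..n_clusters-1)
    centroids: np.ndarray          # cluster medians in the scope subspace
    covariances: np.ndarray
    sizes: np.ndarray
    peak_density: np.ndarray
    merge_trace: list = field(default_factory=list)  # (mode_a, mode_b, separation)

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def _find_modes(density, neigh):
    """Density-peak mode assignment: each event follows its densest
    neighbour uphill; events with no denser neighbour are mode apices.
    Uphill links are strictly density-increasing, so pointer doubling
    converges to the apices."""
    n = len(density)
    nb_dens = density[neigh]
    best = np.argmax(nb_dens, axis=1)
    link = neigh[np.arange(n), best]
    uphill = nb_dens[np.arange(n), best] > density
    link = np.where(uphill, link, np.arange(n))
    while True:
        nxt = link[link]
        if np.array_equal(nxt, link):
            return link
        link = nxt


def cluster_events(x: np.ndarray, k: int = K_DEFAULT,
                   cutoff: float = CUTOFF_DEFAULT,
                   precomputed=None) -> ClusterSet:
    """Agglomerative density clustering of a scope.

    Modes adjacent in the K-NN graph are merged, lowest separation first,
    while their separation score stays below ``cutoff`` (0-20 scale); a
    cutoff of 20 keeps every mode, a cutoff of 0 merges nothing either
    (separation is >= 0, merging requires separation < cutoff).
    """
    if not 0.0 <= cutoff <= SEPARATION_SCALE:
        raise ValueError("cutoff must lie on the 0-20 scale")
    density, neigh, _ = precomputed or knn_density(x, k)
    n = len(x)
    mode = _find_modes(density, neigh)
    apices = np.unique(mode)

    # Saddle scoring runs on a smoothed density field; peaks are the
    # per-mode maxima of the same field, so noise dips inside one
    # homogeneous region score ~0 while genuine density valleys survive.
    smooth = density.copy()
    for _ in range(SMOOTH_MEAN_ROUNDS):
        smooth = (smooth + smooth[neigh].sum(axis=1)) / (neigh.shape[1] + 1)
    for _ in range(SMOOTH_MAX_ROUNDS):
        smooth = np.maximum(smooth, smooth[neigh].max(axis=1))
    peak = {}
    for a in apices:
        peak[int(a)] = float(smooth[mode == a].max())

    rows = np.repeat(np.arange(n), neigh.shape[1])
    cols = neigh.ravel()
    cross = mode[rows] != mode[cols]
    ma, mb = mode[rows[cross]], mode[cols[cross]]
    key = np.minimum(ma, mb).astype(np.int64) * n + np.maximum(ma, mb)
    smin = np.minimum(smooth[rows[cross]], smooth[cols[cross]])
    ukey, inv = np.unique(key, return_inverse=True)
    smax = np.full(len(ukey), -np.inf)
    np.maximum.at(smax, inv, smin)

    nbrs: dict = {int(a): {} for a in apices}
    for kk, s in zip(ukey.tolist(), smax.tolist()):
        a, b = divmod(kk, n)
        nbrs[a][b] = s
        nbrs[b][a] = s

    parent = {int(a): int(a) for a in apices}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def separation(a, b, s):
        return SEPARATION_SCALE * max(0.0, 1.0 - s / min(peak[a], peak[b]))

    import heapq
    heap = [(separation(a, b, s), a, b) for a in nbrs
            for b, s in nbrs[a].items() if a < b]
    heapq.heapify(heap)
    trace = []
    while heap:
        sep, a, b = heapq.heappop(heap)
        if parent[a] != a or parent[b] != b or b not in nbrs[a]:
            continue
        cur = separation(a, b, nbrs[a][b])
        if cur != sep:              # stale entry: re-queue at its true score
            heapq.heappush(heap, (cur, a, b))
            continue
        if sep >= cutoff:
            break
        trace.append((a, b, sep))
        parent[b] = a
        peak[a] = max(peak[a], peak[b])
        bn = nbrs.pop(b)
        del nbrs[a][b], bn[a]
        for c, s in bn.items():
            nbrs[c].pop(b, None)
            s2 = max(s, nbrs[a].get(c, -np.inf))
            nbrs[a][c] = s2
            nbrs[c][a] = s2
            lo, hi = min(a, c), max(a, c)
            heapq.heappush(heap, (separation(lo, hi, s2), lo, hi))

    roots = sorted({find(int(a)) for a in apices})
    relabel = {r: i for i, r in enumerate(roots)}
    labels = np.array([relabel[find(int(m))] for m in mode], dtype=np.int64)

    m = len(roots)
    d = x.shape[1]
    centroids = np.empty((m, d))
    covs = np.empty((m, d, d))
    sizes = np.empty(m, dtype=np.int64)
    peaks = np.empty(m)
    for r, i in relabel.items():
        rows_i = x[labels == i]
        sizes[i] = len(rows_i)
        centroids[i] = np.median(rows_i, axis=0)
        covs[i] = np.cov(rows_i, rowvar=False) if len(rows_i) > 1 \
            else np.eye(d) * 1e-6
        peaks[i] = peak[r]
    return ClusterSet(labels, centroids, covs, sizes, peaks, trace)


# ---------------------------------------------------------------------------
# Step 2: canonical-analysis classification
# ---------------------------------------------------------------------------

@dataclass
class CanonicalPlane:
    """2-D discriminant projection with per-population 2-SD ellipses."""

    axes: np.ndarray               # (d, 2), unit columns
    means: dict                    # population -> projected mean (2,)
    inv_covs: dict                 # population -> inverse projected covariance

    def project(self, x: np.ndarray) -> np.ndarray:
        return np.atleast_2d(x) @ self.axes

    def mahalanobis(self, pop: str, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        d = pts - self.means[pop]
        out = np.sqrt(np.einsum("ij,jk,ik->i", d, self.inv_covs[pop], d))
        return out if len(out) > 1 else out[0]


def fit_canonical_plane(templates: list[PopulationTemplate],
                        markers=None) -> CanonicalPlane:
    """Linear-discriminant (canonical) 2-D projection of >= 2 templates.

    Axis 1 (and 2, when available) solve the between- vs pooled-within
    scatter generalised eigenproblem; with exactly two populations the
    second axis is the leading within-scatter principal direction
    orthogonal to axis 1, so the result is always a plane.
    """
    if len(templates) < 2:
        raise ValueError("canonical analysis needs at least 2 templates")
    locs = np.array([t.location for t in templates])
    ns = np.array([t.n_events for t in templates], dtype=float)
    grand = np.sum(ns[:, None] * locs, axis=0) / ns.sum()
    d = locs.shape[1]
    sw = np.zeros((d, d))
    sb = np.zeros((d, d))
    for t, w in zip(templates, ns):
        sw += w * t.scatter_matrix
        diff = t.location - grand
        sb += w * np.outer(diff, diff)
    sw /= ns.sum()
    sb /= ns.sum()
    if np.allclose(sb, 0):
        raise ValueError("zero between-population scatter (identical templates)")
    sw = sw + np.eye(d) * 1e-9
    vals, vecs = eigh(sb, sw)
    order = np.argsort(vals)[::-1]
    n_axes = min(2, len(templates) - 1)
    axes = vecs[:, order[:n_axes]]
    axes = axes / np.linalg.norm(axes, axis=0)
    if n_axes == 1:
        a1 = axes[:, 0]
        proj = np.eye(d) - np.outer(a1, a1)
        m = proj @ sw @ proj
        w_vals, w_vecs = np.linalg.eigh(m)
        a2 = w_vecs[:, -1]
        a2 = a2 - a1 * (a1 @ a2)
        a2 /= np.linalg.norm(a2)
        axes = np.column_stack([a1, a2])
    for j in range(axes.shape[1]):       # sign convention
        lead = np.argmax(np.abs(axes[:, j]))
        if axes[lead, j] < 0:
            axes[:, j] = -axes[:, j]

    means, inv_covs = {}, {}
    for t in templates:
        means[t.name] = t.location @ axes
        c2 = axes.T @ t.scatter_matrix @ axes + np.eye(2) * 1e-9
        inv_covs[t.name] = np.linalg.inv(c2)
    return CanonicalPlane(axes, means, inv_covs)


def _template_mahalanobis(centroid: np.ndarray,
                          t: PopulationTemplate) -> float:
    diff = centroid - t.location
    return float(np.sqrt(diff @ np.linalg.solve(t.scatter_matrix, diff)))


def classify_cluster(centroid: np.ndarray,
                     candidates: list[PopulationTemplate],
                     accept_sd: float = ACCEPT_SD) -> str:
    """Assign a cluster (by its median) to a reference population.

    Candidates are ranked by Mahalanobis distance to their templates; the
    nearest pairs are examined in a pairwise canonical plane, where the
    cluster goes to the nearer template iff its projection falls inside
    that template's ``accept_sd`` ellipse; otherwise the next competitor
    pair is tried, and ``unclassified`` is returned if none admits it.
    Ties break towards the larger template, then lexicographic name.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    from .database import ellipse_radius
    ranked = sorted(candidates,
                    key=lambda t: (_template_mahalanobis(centroid, t),
                                   -t.n_events, t.name))
    if len(ranked) == 1:
        t = ranked[0]
        radius = ellipse_radius(accept_sd, len(centroid))
        return t.name if _template_mahalanobis(centroid, t) <= radius \
            else UNCLASSIFIED
    radius = ellipse_radius(accept_sd, 2)
    n_pairs = min(len(ranked) - 1, MAX_CANDIDATE_PAIRS)
    for i in range(n_pairs):
        a, b = ranked[i], ranked[i + 1]
        try:
            plane = fit_canonical_plane([a, b])
        except ValueError:
            continue
        p = plane.project(centroid)[0]
        da = plane.mahalanobis(a.name, p)
        db = plane.mahalanobis(b.name, p)
        near, dist = (a, da) if da <= db else (b, db)
        if dist <= radius:
            return near.name
    return UNCLASSIFIED


# ---------------------------------------------------------------------------
# Two-step classification of a scope
# ---------------------------------------------------------------------------

def _slice_template(t: PopulationTemplate, idx) -> PopulationTemplate:
    return PopulationTemplate(t.name, t.n_events, t.location[idx],
                              t.scatter_matrix[np.ix_(idx, idx)],
                              list(t.source_files))


def _classify_scope(x, templates, label_of, k, cutoff, seed, force_assign):
    """Cluster ``x`` and label every event; subsample above the exact-KNN
    limit, with out-of-sample events inheriting the nearest sampled label."""
    n = len(x)
    labels = np.full(n, UNCLASSIFIED, dtype=object)
    if n == 0:
        return labels
    rng = np.random.default_rng(seed)
    if n <= k:
        for i in range(n):
            name = classify_cluster(x[i], templates)
            if name == UNCLASSIFIED and force_assign:
                name = min(templates,
                           key=lambda t: _template_mahalanobis(x[i], t)).name
            labels[i] = label_of.get(name, name)
        return labels

    cap = min(EXACT_KNN_LIMIT, CLUSTER_SAMPLE_CAP)
    if n > cap:
        sample = rng.choice(n, cap, replace=False)
    else:
        sample = np.arange(n)
    xs = x[sample]
    # small scopes: shrink the neighbourhood so that few-event populations
    # can still form their own density modes
    k_eff = k if n >= 8 * k else max(2, n // 8)
    clusters = cluster_events(xs, k=k_eff, cutoff=cutoff)
    cluster_names = []
    for c in range(clusters.n_clusters):
        name = classify_cluster(clusters.centroids[c], templates)
        if name == UNCLASSIFIED and force_assign:
            name = min(templates,
                       key=lambda t: _template_mahalanobis(
                           clusters.centroids[c], t)).name
        cluster_names.append(label_of.get(name, name))
    sample_labels = np.array([cluster_names[c] for c in clusters.labels],
                             dtype=object)
    labels[sample] = sample_labels
    if len(sample) < n:
        rest = np.setdiff1d(np.arange(n), sample, assume_unique=False)
        nn = NearestNeighbors(n_neighbors=1).fit(xs)
        _, nearest = nn.kneighbors(x[rest])
        labels[rest] = sample_labels[nearest[:, 0]]
    return labels


def two_step_classify(em: EventMatrix, db: ReferenceDatabase,
                      markers: list[str] | None = None,
                      k: int = K_DEFAULT, cutoff: float = CUTOFF_DEFAULT,
                      seed: int = 0, force_assign: bool = False) -> LabelledResult:
    """Flat two-step AGI: cluster all events, classify every cluster against
    all reference populations (debris and doublet templates included)."""
    markers = markers or db.markers
    idx = [db.markers.index(m) for m in markers]
    templates = [_slice_template(t, idx) for t in db.templates.values()]
    x = em.submatrix(markers)
    labels = _classify_scope(x, templates, {}, k, cutoff, seed, force_assign)
    prov = np.full(len(labels), "two_step", dtype=object)
    return LabelledResult(labels, db.taxonomy, prov)


# ---------------------------------------------------------------------------
# Maturation (trajectory) classification
# ---------------------------------------------------------------------------

def maturation_assign(x: np.ndarray,
                      stage_templates: list[PopulationTemplate],
                      cutoffs: list[float] | None = None):
    """Assign events to ordered maturation stages.

    Events are projected onto the piecewise-linear trajectory through the
    stage template locations; the normalised arc-length position in [0, 1]
    is cut at the given (or default midpoint) cut-offs, ties going to the
    later stage. Returns ``(stage_labels, positions)``.
    """
    if len(stage_templates) < 2:
        raise ValueError("need >= 2 ordered stage templates")
    locs = np.array([t.location for t in stage_templates])
    seg_vec = np.diff(locs, axis=0)
    seg_len = np.linalg.norm(seg_vec, axis=1)
    if np.any(seg_len < 1e-12):
        raise ValueError("duplicate consecutive stage template locations")
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    if cutoffs is None:
        cutoffs = [(cum[i] + cum[i + 1]) / 2 / total
                   for i in range(len(stage_templates) - 1)]
    cutoffs = np.asarray(cutoffs, dtype=float)
    if len(cutoffs) != len(stage_templates) - 1:
        raise ValueError("need len(stages) - 1 cutoffs")

    x = np.atleast_2d(x)
    n = len(x)
    best_d = np.full(n, np.inf)
    pos = np.zeros(n)
    for s in range(len(seg_len)):
        rel = x - locs[s]
        tproj = np.clip(rel @ seg_vec[s] / seg_len[s] ** 2, 0.0, 1.0)
        foot = locs[s] + tproj[:, None] * seg_vec[s]
        dist = np.linalg.norm(x - foot, axis=1)
        better = dist < best_d
        best_d[better] = dist[better]
        pos[better] = (cum[s] + tproj[better] * seg_len[s]) / total
    stage_idx = np.searchsorted(cutoffs, pos, side="right")
    names = [t.name for t in stage_templates]
    return np.array([names[i] for i in stage_idx], dtype=object), pos


# ---------------------------------------------------------------------------
# Hierarchical multi-step AGI
# ---------------------------------------------------------------------------

@dataclass
class Stage:
    """One step of the hierarchical plan."""

    name: str
    scope: list          # labels whose events this stage refines; ["*"] = all
    markers: list
    method: str = "two_step"             # or "maturation"
    targets: list = field(default_factory=list)
    # two_step: (label, [taxonomy nodes/aggregates backing its template])
    # maturation: ordered (label, [nodes]) stages
    cutoffs: list | None = None          # maturation only
    fallback: str | None = None          # tree node residual labels map to


def default_stage_plan(tax: PopulationTaxonomy) -> list[Stage]:
    """The shipped hierarchical strategy for the B / plasma-cell panel."""
    plan = [
        Stage("majors", ["*"],
              ["FSC-A", "FSC-H", "SSC-A", "CD45", "CD19", "CD38", "CD24",
               "CD27", "CD5"],
              targets=[
                  ("neutrophils", ["neutrophils"]),
                  ("eosinophils", ["eosinophils"]),
                  ("monocytes", ["monocytes"]),
                  ("T cells CD5+", ["T cells CD5+"]),
                  ("NK cells CD5-", ["NK cells CD5-"]),
                  ("other nucleated cells", ["other nucleated cells"]),
                  ("B-lineage", ["B-lymphocytes", "plasma cells"]),
                  (DOUBLET, [DOUBLET]),
                  (DEBRIS, [DEBRIS]),
              ]),
        Stage("B-compartments", ["B-lineage"],
              ["CD19", "CD20", "CD38", "CD24", "CD21", "CD27", "CD45",
               "CD138", "IgD"],
              targets=[
                  ("pre-GC B", ["immature B", "naive CD5+ B", "naive CD5- B"]),
                  ("memory B", ["memory B"]),
                  ("plasma cells", ["plasma cells"]),
              ],
              fallback="B-lymphocytes"),
        Stage("preGC-maturation", ["pre-GC B"],
              ["CD38", "CD24", "CD5", "IgD", "IgM", "CD21"],
              method="maturation",
              targets=[("immature B", ["immature B"]),
                       ("naive CD5+ B", ["naive CD5+ B"]),
                       ("naive CD5- B", ["naive CD5- B"])]),
        Stage("PC-maturation", ["plasma cells"],
              ["CD20", "CD138", "CD38", "CD19"],
              method="maturation",
              targets=[(f"PC stage {s}",
                        [f"PC {iso} {s}" for iso in PC_ISOTYPES])
                       for s in PC_STAGES]),
        Stage("naive-CD5pos-split", ["naive CD5+ B"],
              ["CD62L", "CD5", "CD38"],
              targets=[("naive CD5+ CD62L+ B", ["naive CD5+ CD62L+ B"]),
                       ("naive CD5+ CD62L- B", ["naive CD5+ CD62L- B"])],
              fallback="naive CD5+ B"),
        Stage("naive-CD5neg-split", ["naive CD5- B"],
              ["CD21", "CD62L"],
              targets=[(n, [n]) for n in
                       ["naive CD5- CD21+ CD62L+ B",
                        "naive CD5- CD21+ CD62L- B",
                        "naive CD5- CD21lo CD62L+ B",
                        "naive CD5- CD21lo CD62L- B"]],
              fallback="naive CD5- B"),
        Stage("MBC-isotype", ["memory B"],
              ["IgM", "IgD", "IgG1", "IgG2", "IgG3", "IgG4", "IgA1", "IgA2"],
              targets=[(f"MBC {iso}", [f"MBC {iso}"]) for iso in MBC_ISOTYPES],
              fallback="memory B"),
    ]
    for iso in MBC_ISOTYPES:
        leaves = ([f"MBC {iso} CD21+CD20+ CD27{t}" for t in "-+"]
                  + [f"MBC {iso} CD21-CD20hi CD24{a} CD27{b}"
                     for a in "-+" for b in "-+"])
        plan.append(Stage(f"MBC-{iso}-split", [f"MBC {iso}"],
                          ["CD21", "CD20", "CD27", "CD24"],
                          targets=[(n, [n]) for n in leaves],
                          fallback=f"MBC {iso}"))
    for s in PC_STAGES:
        plan.append(Stage(f"PC-{s}-isotype", [f"PC stage {s}"],
                          ["IgM", "IgD", "IgG1", "IgG2", "IgG3", "IgG4",
                           "IgA1", "IgA2"],
                          targets=[(f"PC {iso} {s}", [f"PC {iso} {s}"])
                                   for iso in PC_ISOTYPES],
                          fallback="plasma cells"))
    return plan


#: Residual working labels that are not taxonomy nodes map to these gates.
_GROUP_FALLBACK = {"B-lineage": "B-lymphocytes", "pre-GC B": "B-lymphocytes"}
for _s in PC_STAGES:
    _GROUP_FALLBACK[f"PC stage {_s}"] = "plasma cells"


def _stage_templates(db: ReferenceDatabase, stage: Stage):
    """Leaf-level candidate templates sliced to the stage's markers, plus
    the mapping from leaf name to the stage's output label."""
    idx = [db.markers.index(m) for m in stage.markers]
    tax = db.taxonomy
    templates, label_of = [], {}
    for label, members in stage.targets:
        leaves = []
        for m in members:
            if m in (DOUBLET, DEBRIS):
                leaves.append(m)
                continue
            sub = [n for n in [m] + (tax.descendants(m) if m in tax else [])
                   if n in db.templates and
                   (n not in tax or tax.node(n).is_leaf)]
            leaves.extend(sub or ([m] if m in db.templates else []))
        for leaf in leaves:
            if leaf in db.templates:
                templates.append(_slice_template(db.templates[leaf], idx))
                label_of[leaf] = label
    return templates, label_of


def hierarchical_classify(em: EventMatrix, db: ReferenceDatabase,
                          plan: list[Stage] | None = None,
                          k: int = K_DEFAULT, cutoff: float = CUTOFF_DEFAULT,
                          seed: int = 0,
                          force_assign: bool = False) -> LabelledResult:
    """Hierarchical multi-step AGI with per-stage marker configurations.

    Stage results nest: each stage refines only the events its scope labels
    selected, so per-stage counts are conserved across refinement. Residual
    working labels (events whose deeper stage could not place them) are
    mapped back to their enclosing taxonomy gate.
    """
    plan = plan or default_stage_plan(db.taxonomy)
    rng = np.random.default_rng(seed)
    n = em.n_events
    labels = np.full(n, "*", dtype=object)
    prov = np.full(n, "", dtype=object)
    x_all = em.submatrix(db.markers)

    for stage in plan:
        scope_mask = np.isin(labels, stage.scope)
        idx = np.where(scope_mask)[0]
        if idx.size == 0:
            continue
        midx = [db.markers.index(m) for m in stage.markers]
        x = x_all[np.ix_(idx, midx)]
        stage_seed = int(rng.integers(0, 2**31 - 1))
        if stage.method == "maturation":
            templates = []
            for label, members in stage.targets:
                t = _pool_group(db, members)
                templates.append(PopulationTemplate(
                    label, t.n_events, t.location[midx],
                    t.scatter_matrix[np.ix_(midx, midx)], t.source_files))
            new, _ = maturation_assign(x, templates, stage.cutoffs)
        else:
            templates, label_of = _stage_templates(db, stage)
            if not templates:
                raise ValueError(f"stage {stage.name!r}: no templates in "
                                 "database for its targets")
            new = _classify_scope(x, templates, label_of, k, cutoff,
                                  stage_seed, force_assign)
            if stage.fallback is not None:
                new = np.where(new == UNCLASSIFIED, stage.fallback, new)
        labels[idx] = new
        prov[idx] = stage.name

    tax = db.taxonomy
    for name in np.unique(labels):
        if name not in tax and name not in (DOUBLET, DEBRIS, UNCLASSIFIED):
            labels[labels == name] = _GROUP_FALLBACK.get(name, UNCLASSIFIED)
    return LabelledResult(labels, tax, prov)


def save_stage_plan(plan: list[Stage], path: str) -> None:
    import yaml
    doc = [{"name": s.name, "scope": list(s.scope), "markers": list(s.markers),
            "method": s.method,
            "targets": [[l, list(m)] for l, m in s.targets],
            "cutoffs": list(s.cutoffs) if s.cutoffs else None,
            "fallback": s.fallback} for s in plan]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_stage_plan(path: str) -> list[Stage]:
    import yaml
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return [Stage(s["name"], list(s["scope"]), list(s["markers"]),
                  s.get("method", "two_step"),
                  [(l, list(m)) for l, m in s.get("targets", [])],
                  s.get("cutoffs"), s.get("fallback")) for s in doc]


def _pool_group(db: ReferenceDatabase, members: list[str]) -> PopulationTemplate:
    from .database import _pool_templates
    tax = db.taxonomy
    leaves = []
    for m in members:
        leaves.extend(n for n in [m] + (tax.descendants(m) if m in tax else [])
                      if n in db.templates)
    parts = [db.templates[l] for l in dict.fromkeys(leaves)]
    if not parts:
        raise KeyError(f"no templates for group {members}")
    if len(parts) == 1:
        return parts[0]
    return _pool_templates("+".join(members), parts)
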