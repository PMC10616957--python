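"""Reference database: per-population statistical templates + merged events.

The database is built file by file, mirroring how reference datafiles are
accumulated in practice: the first fully gated file seeds one template per
population; each further file is classified against the current database
(or comes with confirmed labels), then pooled into a new database. Templates
keep a location vector and a shrinkage-regularised covariance in transformed
marker space, so that even small plasma-cell populations (>20 events) stay
usable in canonical analysis. The merged event store retains per-file
provenance, thinned to a bounded number of events per population per file;
templates are always computed from full data before thinning.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.covariance import ledoit_wolf

from .fcs_io import EventMatrix, PANEL_MARKERS
from .taxonomy import PopulationTaxonomy, DOUBLET, DEBRIS, UNCLASSIFIED

__all__ = [
    "ANALYSIS_MARKERS", "PopulationTemplate", "ReferenceDatabase",
    "init_database", "classify_and_merge", "consistency_check",
    "save_database", "load_database", "template_from_events",
]

#: The transformed-space coordinates templates and classification use.
ANALYSIS_MARKERS = ["FSC-A", "FSC-H", "SSC-A"] + list(PANEL_MARKERS)

#: Events kept per population per file in the merged store.
THIN_LIMIT = 10_000

#: Covariance estimation subsample cap (estimation only; counts are exact).
COV_SAMPLE_CAP = 20_000

# Variance floor for template covariances: no real population is narrower
# than the instrument/staining spread (~0.2 transformed units SD per
# channel), so few-event templates are floored here instead of collapsing.
MIN_SHRINK_VAR = 0.04


@dataclass
class PopulationTemplate:
    """Summary statistics of one population in transformed marker space."""

    name: str
    n_events: int
    location: np.ndarray            # len(ANALYSIS_MARKERS)
    scatter_matrix: np.ndarray      # shrinkage covariance, positive definite
    source_files: list = field(default_factory=list)

    def __post_init__(self):
        self.location = np.asarray(self.location, dtype=float)
        self.scatter_matrix = np.asarray(self.scatter_matrix, dtype=float)
        if self.n_events < 1:
            raise ValueError("template needs at least one event")


def ellipse_radius(nominal_sd: float, dim: int = 2) -> float:
    """Mahalanobis radius of the '<nominal_sd> SD' region in ``dim``
    dimensions, defined as the ellipsoid holding the same probability mass
    as the +/- nominal_sd interval of a 1-D Gaussian (e.g. 95.45% for 2 SD,
    radius ~2.49 in 2-D). Keeps the 'events within 2 SD' convention
    dimension-consistent."""
    from scipy.stats import chi2, norm
    mass = 2.0 * norm.cdf(nominal_sd) - 1.0
    return float(np.sqrt(chi2.ppf(mass, dim)))


def _shrink_cov(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Ledoit-Wolf shrinkage covariance, floored so it is positive definite
    even for single-event or constant populations."""
    d = x.shape[1]
    if len(x) < 3:
        return np.eye(d) * MIN_SHRINK_VAR
    if len(x) > COV_SAMPLE_CAP:
        x = x[rng.choice(len(x), COV_SAMPLE_CAP, replace=False)]
    cov, _ = ledoit_wolf(x)
    return cov + np.eye(d) * MIN_SHRINK_VAR


def template_from_events(name: str, x: np.ndarray, source: str,
                         seed: int = 0) -> PopulationTemplate:
    """Median location + shrinkage covariance from one file's events."""
    rng = np.random.default_rng(seed)
    loc = np.median(x, axis=0)
    return PopulationTemplate(name, len(x), loc, _shrink_cov(x, rng), [source])


@dataclass
class ReferenceDatabase:
    templates: dict                 # population -> PopulationTemplate
    markers: list
    taxonomy: PopulationTaxonomy
    events: dict = field(default_factory=dict)   # pop -> {file -> ndarray (thinned)}
    build_log: list = field(default_factory=list)

    def populations(self, include_artifacts: bool = True) -> list[str]:
        names = list(self.templates)
        if not include_artifacts:
            names = [n for n in names if n not in (DOUBLET, DEBRIS)]
        return names

    def pooled_events(self, pop: str) -> np.ndarray:
        store = self.events.get(pop, {})
        return np.vstack(list(store.values())) if store else np.empty(
            (0, len(self.markers)))

    def group_template(self, name: str) -> PopulationTemplate:
        """Template for a taxonomy node or aggregate, pooled over the leaf
        templates below it (n-weighted location, pooled covariance)."""
        if name in self.templates:
            return self.templates[name]
        tax = self.taxonomy
        if name in tax:
            members = [n for n in [name] + tax.descendants(name)
                       if n in self.templates]
        else:
            agg = next(a for a in tax.aggregates if a.name == name)
            members = [n for m in agg.members
                       for n in [m] + tax.descendants(m) if n in self.templates]
        if not members:
            raise KeyError(f"no templates under {name!r}")
        parts = [self.templates[m] for m in members]
        return _pool_templates(name, parts)


def _pool_templates(name: str, parts: list[PopulationTemplate]) -> PopulationTemplate:
    n = sum(p.n_events for p in parts)
    loc = sum(p.n_events * p.location for p in parts) / n
    d = len(loc)
    s = np.zeros((d, d))
    for p in parts:
        diff = p.location - loc
        s += p.n_events * (p.scatter_matrix + np.outer(diff, diff))
    files = sorted({f for p in parts for f in p.source_files})
    return PopulationTemplate(name, n, loc, s / n, files)


def _thin(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if len(x) <= THIN_LIMIT:
        return x
    return x[rng.choice(len(x), THIN_LIMIT, replace=False)]


def init_database(em: EventMatrix, labels, tax: PopulationTaxonomy,
                  seed: int = 0) -> ReferenceDatabase:
    """Seed a database from one fully gated (labelled) datafile."""
    labels = np.asarray(labels, dtype=object)
    if len(labels) != em.n_events:
        raise ValueError("labels length must equal event count")
    if len(labels) == 0:
        raise ValueError("cannot initialise a database from an empty file")
    for name in np.unique(labels):
        if name not in (DOUBLET, DEBRIS, UNCLASSIFIED) and name not in tax:
            raise ValueError(f"label {name!r} is not in the taxonomy")
    rng = np.random.default_rng(seed)
    x = em.submatrix(ANALYSIS_MARKERS)
    file_id = em.sample_id or "file-0"
    templates, events = {}, {}
    for name in np.unique(labels):
        if name == UNCLASSIFIED:
            continue
        rows = x[labels == name]
        templates[str(name)] = template_from_events(str(name), rows, file_id,
                                                    seed)
        events[str(name)] = {file_id: _thin(rows, rng)}
    return ReferenceDatabase(templates, list(ANALYSIS_MARKERS), tax,
                             events, [f"init from {file_id} "
                                      f"({em.n_events} events)"])


def classify_and_merge(db: ReferenceDatabase, new_em: EventMatrix,
                       confirmed_labels=None, seed: int = 0) -> ReferenceDatabase:
    """Merge a new (QC-passed) datafile into a copy of the database.

    Without ``confirmed_labels`` the file is labelled by the two-step
    classifier against the current database and the labels accepted as-is
    (headless mode); with labels, they model the expert-confirmed
    assignment. The input database is left untouched.
    """
    if new_em.markers[:len(db.markers)] != db.markers and \
            sorted(set(db.markers) - set(new_em.markers)):
        raise ValueError("panel mismatch between database and new file")
    if confirmed_labels is None:
        from .agi_core import two_step_classify
        confirmed_labels = two_step_classify(new_em, db, seed=seed).labels
    labels = np.asarray(confirmed_labels, dtype=object)
    if len(labels) != new_em.n_events:
        raise ValueError("labels length must equal event count")
    rng = np.random.default_rng(seed)
    x = new_em.submatrix(db.markers)
    file_id = new_em.sample_id or f"file-{len(db.build_log)}"

    templates = dict(db.templates)
    events = {p: dict(files) for p, files in db.events.items()}
    for name in np.unique(labels):
        if name == UNCLASSIFIED:
            continue
        name = str(name)
        rows = x[labels == name]
        new_t = template_from_events(name, rows, file_id, seed)
        if name in templates:
            templates[name] = _pool_templates(name, [templates[name], new_t])
        else:
            templates[name] = new_t
        events.setdefault(name, {})[file_id] = _thin(rows, rng)
    log = db.build_log + [f"merged {file_id} ({new_em.n_events} events)"]
    return ReferenceDatabase(templates, list(db.markers), db.taxonomy,
                             events, log)


def consistency_check(db: ReferenceDatabase, sd: float = 2.0,
                      min_fraction: float = 0.95) -> pd.DataFrame:
    """Leave-one-file-out internal consistency of every population.

    For each population and source file, the held-out file's events are
    projected into (a) the 2-D principal-component plane and (b) the 2-D
    canonical plane (population vs its nearest neighbour) fitted on the
    remaining files; a population/file pair is flagged when the held-out
    median falls outside the 2-SD ellipse or fewer than 95% of its events
    fall within 2 SD. Populations present in a single file are skipped.
    """
    from .agi_core import fit_canonical_plane

    radius = ellipse_radius(sd, 2)
    rows = []
    for pop in db.populations():
        store = {f: v for f, v in db.events.get(pop, {}).items() if len(v) >= 5}
        if len(store) < 2:
            rows.append({"population": pop, "file": None, "status": "skipped",
                         "flagged": False})
            continue
        others = {q: db.templates[q] for q in db.populations() if q != pop}
        for file_id in store:
            held = store[file_id]
            rest = np.vstack([v for f, v in store.items() if f != file_id])
            rest_t = template_from_events(pop, rest, "rest")

            # (a) principal-component plane of the remaining files
            mu = rest.mean(axis=0)
            centred = rest - mu
            _, _, vt = np.linalg.svd(centred, full_matrices=False)
            basis = vt[:2].T
            ref2 = centred @ basis
            held2 = (held - mu) @ basis
            pca_med, pca_frac = _ellipse_stats(ref2, held2, radius)

            # (b) canonical plane against the nearest other population
            dists = {q: float(np.linalg.norm(t.location - rest_t.location))
                     for q, t in others.items()}
            near = min(dists, key=dists.get)
            plane = fit_canonical_plane([rest_t, others[near]], db.markers)
            held_ca = plane.project(held)
            ca_med = plane.mahalanobis(pop, np.median(held_ca, axis=0)) <= radius
            ca_frac = float(np.mean(plane.mahalanobis(pop, held_ca) <= radius))

            flagged = not (pca_med and ca_med) or \
                min(pca_frac, ca_frac) < min_fraction
            rows.append({"population": pop, "file": file_id, "status": "ok",
                         "pca_median_in": pca_med, "pca_fraction": pca_frac,
                         "ca_median_in": ca_med, "ca_fraction": ca_frac,
                         "nearest": near, "flagged": flagged})
    return pd.DataFrame(rows)


def _ellipse_stats(ref2: np.ndarray, held2: np.ndarray, sd: float):
    cov = np.cov(ref2, rowvar=False) + np.eye(2) * 1e-9
    inv = np.linalg.inv(cov)
    mu = ref2.mean(axis=0)

    def maha(pts):
        d = pts - mu
        return np.sqrt(np.einsum("ij,jk,ik->i", d, inv, d))

    med_in = bool(maha(np.median(held2, axis=0)[None, :])[0] <= sd)
    frac = float(np.mean(maha(held2) <= sd))
    return med_in, frac


# ---------------------------------------------------------------------------
# Serialisation (directory of CSV/JSON)
# ---------------------------------------------------------------------------

def save_database(db: ReferenceDatabase, path: str) -> None:
    os.makedirs(path, exist_ok=True)
    meta = {"markers": db.markers, "build_log": db.build_log,
            "populations": db.populations()}
    with open(os.path.join(path, "meta.json"), "w") as fh:
        json.dump(meta, fh, indent=1)
    rows = []
    for t in db.templates.values():
        row = {"population": t.name, "n_events": t.n_events,
               "source_files": "|".join(t.source_files)}
        row.update({f"loc_{m}": v for m, v in zip(db.markers, t.location)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(os.path.join(path, "templates.csv"), index=False)
    cov ={t.name: t.scatter_matrix.tolist() for t in db.templates.values()}
    with open(os.path.join(path, "covariances.json"), "w") as fh:
        json.dump(cov, fh)
    ev_rows = []
    for pop, files in db.events.items():
        for file_id, arr in files.items():
            df = pd.DataFrame(arr, columns=db.markers)
            df.insert(0, "file", file_id)
            df.insert(0, "population", pop)
            ev_rows.append(df)
    if ev_rows:
        pd.concat(ev_rows, ignore_index=True).to_csv(
            os.path.join(path, "events.csv"), index=False)


def load_database(path: str, tax: PopulationTaxonomy) -> ReferenceDatabase:
    with open(os.path.join(path, "meta.json")) as fh:
        meta = json.load(fh)
    markers = meta["markers"]
    tdf = pd.read_csv(os.path.join(path, "templates.csv"))
    with open(os.path.join(path, "covariances.json")) as fh:
        cov = json.load(fh)
    templates = {}
    for _, row in tdf.iterrows():
        name = row["population"]
        loc = np.array([row[f"loc_{m}"] for m in markers])
        templates[name] = PopulationTemplate(
            name, int(row["n_events"]), loc, np.array(cov[name]),
            str(row["source_files"]).split("|"))
    events: dict = {}
    ev_path = os.path.join(path, "events.csv")
    if os.path.exists(ev_path):
        edf = pd.read_csv(ev_path)
        for (pop, file_id), grp in edf.groupby(["population", "file"]):
            events.setdefault(pop, {})[file_id] = grp[markers].to_numpy()
    return ReferenceDatabase(templates, markers, tax, events,
                             meta.get("build_log", []))
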