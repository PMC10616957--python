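"""Datafile quality control: the four sequential inclusion criteria.

A datafile qualifies for reference-database construction when, in order:

i.   it contains enough CD19+ CD45+ FSClo/SSClo B-cell singlets;
ii.  the flow rate was stable during acquisition (events-per-bin CV over
     100 equal-duration bins, plus a longest-dead-time rule);
iii. the compensation profile is clean (positive control populations show
     no median shift in every other fluorescence channel);
iv.  each marker's median fluorescence intensity in its positive and
     negative control populations falls inside its expected range.

All four criteria are always evaluated and reported; the failure stage
attributed to a file is the first criterion it fails.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fcs_io import EventMatrix, PANEL_MARKERS, ConfigError
from .taxonomy import PopulationTaxonomy, LabelledResult, boolean_gate

__all__ = [
    "QCCriteria", "QCReport", "QCNotAssessable", "DEFAULT_CONTROLS",
    "count_b_gate_singlets", "assess_flow_stability", "assess_compensation",
    "assess_mfi_ranges", "run_qc", "default_mfi_ranges",
]

N_FLOW_BINS = 100
MIN_FLOW_EVENTS = 1000
MIN_CONTROL_EVENTS = 50


class QCNotAssessable(ValueError):
    """The input cannot support the requested QC metric."""


#: marker -> (positive control population, negative control population)
DEFAULT_CONTROLS = {
    "CD19":  ("memory B", "T cells CD5+"),
    "CD45":  ("T cells CD5+", "debris"),
    "CD38":  ("immature B", "memory B"),
    "CD20":  ("B-lymphocytes", "T cells CD5+"),
    "CD24":  ("neutrophils", "T cells CD5+"),
    "CD21":  ("naive CD5- CD21+ CD62L+ B", "T cells CD5+"),
    "CD27":  ("eosinophils", "naive CD5- B"),
    "CD5":   ("T cells CD5+", "NK cells CD5-"),
    "CD62L": ("naive CD5+ CD62L+ B", "naive CD5+ CD62L- B"),
    "CD138": ("PC IgMD CD20-CD138+", "B-lymphocytes"),
    "IgM":   ("naive CD5- B", "T cells CD5+"),
    "IgD":   ("naive CD5- B", "T cells CD5+"),
    "IgG1":  ("MBC IgG1", "T cells CD5+"),
    "IgG2":  ("MBC IgG2", "T cells CD5+"),
    "IgG3":  ("MBC IgG3", "T cells CD5+"),
    "IgG4":  ("MBC IgG4", "T cells CD5+"),
    "IgA1":  ("MBC IgA1", "T cells CD5+"),
    "IgA2":  ("MBC IgA2", "T cells CD5+"),
}


@dataclass
class QCCriteria:
    """Thresholds for the four datafile inclusion criteria."""

    min_b_singlets: int = 100_000
    flow_cv_max: float = 0.25
    flow_gap_max: float = 2.0          # seconds
    comp_tolerance: float = 0.15       # transformed units
    mfi_ranges: dict = field(default_factory=dict)
    # marker -> {"pos": (low, high), "neg": (low, high)}, transformed units
    controls: dict = field(default_factory=lambda: dict(DEFAULT_CONTROLS))
    min_control_events: int = MIN_CONTROL_EVENTS

    def __post_init__(self):
        for v in (self.min_b_singlets, self.flow_cv_max, self.flow_gap_max,
                  self.comp_tolerance):
            if v <= 0:
                raise ConfigError("QC thresholds must be positive")
        for marker, ranges in self.mfi_ranges.items():
            for side, (lo, hi) in ranges.items():
                if lo >= hi:
                    raise ConfigError(
                        f"mfi range for {marker}/{side}: low must be < high")


STAGES = ("cell_count", "flow_stability", "compensation", "mfi_range")


@dataclass
class QCReport:
    criteria: dict                    # stage -> {metric, threshold, passed, detail}
    overall_pass: bool
    failure_stage: str                # "none" or first failing stage
    sample_id: str = ""

    def as_frame(self) -> pd.DataFrame:
        rows = [(s, d.get("metric"), d.get("threshold"), d["passed"])
                for s, d in self.criteria.items()]
        return pd.DataFrame(rows, columns=["criterion", "metric",
                                           "threshold", "passed"])


def _pop_mask(labels: np.ndarray, tax: PopulationTaxonomy, pop: str) -> np.ndarray:
    if pop in tax:
        names = [pop] + tax.descendants(pop)
        return np.isin(labels, names)
    return labels == pop   # doublet / debris


def _expected_negative(tax: PopulationTaxonomy, pop: str, marker: str) -> bool:
    """True when every leaf of ``pop`` is phenotypically negative for
    ``marker`` (unlisted markers default to negative)."""
    if pop not in tax:
        return True                      # debris / doublet controls
    node = tax.node(pop)
    leaves = [n for n in tax.walk()
              if n.is_leaf and (n is node or node in n.chain())]
    for leaf in leaves:
        pheno = {}
        for anc in leaf.chain():
            pheno.update(anc.phenotype)
        if pheno.get(marker, "neg") != "neg":
            return False
    return True


def _pop_median(em, labels, tax, pop, marker, min_events):
    mask = _pop_mask(labels, tax, pop)
    if mask.sum() < min_events:
        return None
    return float(np.median(em.column(marker)[mask]))


def count_b_gate_singlets(em: EventMatrix, tax: PopulationTaxonomy,
                          gated: LabelledResult | None = None) -> int:
    """Singlet events inside the B-lymphocyte gate (criterion i numerator)."""
    gated = gated if gated is not None else boolean_gate(em, tax)
    return gated.cumulative_counts()["B-lymphocytes"]


def assess_flow_stability(em: EventMatrix, criteria: QCCriteria):
    """Events-per-bin CV over 100 equal-duration bins + longest dead time.

    Returns ``(metrics, passed)``; raises :class:`QCNotAssessable` when no
    time channel is present or fewer than 1000 events were acquired.
    """
    ti = em.time_index()
    if ti is None:
        raise QCNotAssessable("no time channel in datafile")
    if em.n_events < MIN_FLOW_EVENTS:
        raise QCNotAssessable(
            f"flow stability needs >= {MIN_FLOW_EVENTS} events")
    t = np.sort(em.values[:, ti])
    span = t[-1] - t[0]
    if span <= 0:
        raise QCNotAssessable("degenerate acquisition time span")
    counts, _ = np.histogram(t, bins=N_FLOW_BINS, range=(t[0], t[-1]))
    cv = float(np.std(counts) / np.mean(counts))
    max_gap = float(np.max(np.diff(t)))
    passed = cv <= criteria.flow_cv_max and max_gap <= criteria.flow_gap_max
    return {"cv": cv, "max_gap_s": max_gap}, passed


def assess_compensation(em: EventMatrix, tax: PopulationTaxonomy,
                        criteria: QCCriteria,
                        gated: LabelledResult | None = None):
    """Median shift of each positive control population in every other
    fluorescence channel, against that channel's negative control."""
    gated = gated if gated is not None else boolean_gate(em, tax)
    labels = gated.labels
    markers = [m for m in PANEL_MARKERS if m in criteria.controls]
    med_cache: dict = {}

    def med(pop, marker):
        key = (pop, marker)
        if key not in med_cache:
            med_cache[key] = _pop_median(em, labels, tax, pop, marker,
                                         criteria.min_control_events)
        return med_cache[key]

    metrics, uncheckable = {}, []
    for primary in markers:
        pos_pop = criteria.controls[primary][0]
        for spill in markers:
            if spill == primary:
                continue
            # a valid compensation control must be biologically negative in
            # the spill channel, otherwise true expression masks spillover
            if not _expected_negative(tax, pos_pop, spill):
                continue
            neg_pop = criteria.controls[spill][1]
            a = med(pos_pop, spill)
            b = med(neg_pop, spill)
            if a is None or b is None:
                uncheckable.append((primary, spill))
                continue
            metrics[(primary, spill)] = abs(a - b)
    passed = all(v <= criteria.comp_tolerance for v in metrics.values())
    return {"pairs": metrics, "uncheckable": uncheckable}, passed


def assess_mfi_ranges(em: EventMatrix, tax: PopulationTaxonomy,
                      criteria: QCCriteria,
                      gated: LabelledResult | None = None):
    """Positive/negative control population medians against expected ranges."""
    markers = [m for m in PANEL_MARKERS if m in criteria.controls]
    missing = [m for m in markers if m not in criteria.mfi_ranges]
    if missing:
        raise ConfigError(f"no MFI range configured for markers: {missing}")
    gated = gated if gated is not None else boolean_gate(em, tax)
    labels = gated.labels
    metrics, uncheckable = {}, []
    passed = True
    for marker in markers:
        pos_pop, neg_pop = criteria.controls[marker]
        for side, pop in (("pos", pos_pop), ("neg", neg_pop)):
            m = _pop_median(em, labels, tax, pop, marker,
                            criteria.min_control_events)
            if m is None:
                uncheckable.append((marker, side))
                continue
            lo, hi = criteria.mfi_ranges[marker][side]
            ok = lo <= m <= hi
            metrics[(marker, side)] = {"median": m, "range": (lo, hi), "ok": ok}
            passed &= ok
    return {"medians": metrics, "uncheckable": uncheckable}, passed


def run_qc(em: EventMatrix, tax: PopulationTaxonomy,
           criteria: QCCriteria) -> QCReport:
    """Evaluate all four criteria; attribute failure to the first one broken."""
    gated = boolean_gate(em, tax)
    report: dict = {}

    n_b = count_b_gate_singlets(em, tax, gated)
    report["cell_count"] = {"metric": n_b, "threshold": criteria.min_b_singlets,
                            "passed": n_b >= criteria.min_b_singlets}

    try:
        flow, ok = assess_flow_stability(em, criteria)
        report["flow_stability"] = {"metric": flow["cv"],
                                    "threshold": criteria.flow_cv_max,
                                    "passed": ok, "detail": flow}
    except QCNotAssessable as exc:
        report["flow_stability"] = {"metric": None,
                                    "threshold": criteria.flow_cv_max,
                                    "passed": False, "detail": str(exc)}

    comp, ok = assess_compensation(em, tax, criteria, gated)
    worst = max(comp["pairs"].values(), default=0.0)
    report["compensation"] = {"metric": worst,
                              "threshold": criteria.comp_tolerance,
                              "passed": ok, "detail": comp}

    mfi, ok = assess_mfi_ranges(em, tax, criteria, gated)
    n_out = sum(not v["ok"] for v in mfi["medians"].values())
    report["mfi_range"] = {"metric": n_out, "threshold": 0,
                           "passed": ok, "detail": mfi}

    failure = next((s for s in STAGES if not report[s]["passed"]), "none")
    return QCReport(report, failure == "none", failure, em.sample_id)


def default_mfi_ranges(model, margin: float = 0.5,
                       controls: dict | None = None) -> dict:
    """Surrogate expected MFI ranges derived from the population model.

    For each marker, the expected median of its positive / negative control
    population is the frequency-weighted template location, and the accepted
    range is that value +/- ``margin`` transformed units. These stand in for
    instrument-qualified reference ranges and are fully user-editable.
    """
    controls = controls or DEFAULT_CONTROLS
    tax = model.taxonomy
    out = {}
    for marker, (pos_pop, neg_pop) in controls.items():
        ranges = {}
        for side, pop in (("pos", pos_pop), ("neg", neg_pop)):
            mu = _expected_location(model, tax, pop, marker)
            ranges[side] = (mu - margin, mu + margin)
        out[marker] = ranges
    return out


def desk_qc_criteria(model, min_b_singlets: int = 3000,
                     margin: float = 0.5) -> QCCriteria:
    """QC thresholds for desk-scale (1e5-event) files: the B-singlet
    threshold scales with file size (3% of a 1e5-event file, matching the
    1e5-of-several-million proportion of full-size acquisitions); all other
    thresholds keep their defaults."""
    return QCCriteria(min_b_singlets=min_b_singlets,
                      mfi_ranges=default_mfi_ranges(model, margin=margin))


def _expected_location(model, tax, pop, marker):
    if pop in model.templates:
        return float(model.location(pop, [marker])[0])
    node = tax.node(pop)
    leaves = [n for n in [node.name] + tax.descendants(pop)
              if n in model.templates]
    w = np.array([model.frequencies.get(n, 0.0) for n in leaves])
    if w.sum() <= 0:
        w = np.ones(len(leaves))
    locs = np.array([model.location(n, [marker])[0] for n in leaves])
    return float(np.sum(w * locs) / w.sum())
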