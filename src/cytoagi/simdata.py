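"""Synthetic lysed-whole-blood samples with planted population labels.

The generator realises each taxonomy leaf's symbolic phenotype (neg / lo /
het / pos / hi per marker) as a numeric template in transformed space and
draws events from independent per-marker distributions: Gaussians around
the band level, or a uniform-plus-Gaussian mixture for heterogeneous (het)
markers. Scatter is drawn on the linear min-max analysis scale, with FSC-H
tied to FSC-A so singlets keep an area/height ratio near 1. Acquisition
artifacts (doublets, debris, flow gaps, residual spillover, per-marker MFI
shifts) are planted on demand so each datafile QC criterion can be flipped
in isolation.

Default study conditions: total B lymphocytes 4.9% and plasma cells 0.06%
of nucleated cells; within-compartment subset frequencies uniform; cohort
generation jitters compartment frequencies log-normally inside the observed
population ranges (B 0.5-13%, PC <0.001-0.8% of nucleated cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fcs_io import (EventMatrix, default_panel, PANEL_MARKERS)
from .taxonomy import (PopulationTaxonomy, build_default_taxonomy,
                       DOUBLET, DEBRIS, PC_STAGES)

__all__ = [
    "PopulationModel", "SampleSpec", "default_panel_model",
    "simulate_sample", "simulate_cohort", "simulate_maturation_continuum",
]

# Numeric centres of the symbolic bands (transformed units). Breakpoints in
# the default taxonomy are 1.05 / 2.30 / 3.80 (fluorescence) and
# 0.70 / 2.05 / 3.20 (scatter); levels sit >= 2.5 SD from the nearest
# breakpoint so each rule term holds with probability >= 0.99.
FLUOR_LEVELS = {"neg": 0.5, "lo": 1.6, "pos": 3.0, "hi": 4.6}
SCATTER_LEVELS = {"neg": 0.3, "lo": 1.5, "pos": 2.6, "hi": 3.8}
HET_RANGE = (1.5, 3.3)
FLUOR_SD = 0.20
SCATTER_SD = 0.22
FSC_H_CV = 0.03       # FSC-H = FSC-A * (1 + N(0, cv)) for singlets

#: Fractions of nucleated cells (study conditions; "other" absorbs the rest).
COMPARTMENT_FREQS = {
    "B": 0.049,
    "PC": 0.0006,
    "neutrophils": 0.55,
    "eosinophils": 0.03,
    "monocytes": 0.08,
    "T cells CD5+": 0.20,
    "NK cells CD5-": 0.05,
}
PREGC_SHARE_OF_B = 0.55   # remainder of the B compartment is memory

#: Cohort frequency jitter: log-normal sigma and hard range per compartment.
COHORT_JITTER = {
    "B": (0.45, 0.005, 0.13),
    "PC": (1.0, 1e-5, 0.008),
}
MAJOR_JITTER_SIGMA = 0.15
LEAF_JITTER_SIGMA = 0.25


@dataclass
class PopulationModel:
    """Per-leaf generative templates + expected frequencies."""

    taxonomy: PopulationTaxonomy
    templates: dict          # leaf name -> {marker -> ("normal", mu, sd) | ("het", a, b, sd)}
    frequencies: dict        # leaf name -> fraction of nucleated cells
    maturation: dict = field(default_factory=dict)  # pathway -> ordered stage names

    def location(self, name: str, markers: list[str]) -> np.ndarray:
        """Template centre (het markers at their span midpoint); internal
        taxonomy nodes pool their leaves weighted by expected frequency."""
        if name not in self.templates and name in self.taxonomy:
            leaves = [l for l in [name] + self.taxonomy.descendants(name)
                      if l in self.templates]
            w = np.array([self.frequencies.get(l, 0.0) for l in leaves])
            if w.sum() <= 0:
                w = np.ones(len(leaves))
            locs = np.array([self.location(l, markers) for l in leaves])
            return (w[:, None] * locs).sum(axis=0) / w.sum()
        t = self.templates[name]
        out = []
        for m in markers:
            spec = t[m]
            if spec[0] == "normal":
                out.append(spec[1])
            else:
                out.append(0.5 * (spec[1] + spec[2]))
        return np.array(out)


def _marker_kind(marker: str) -> str:
    if marker in ("FSC-A", "FSC-H", "SSC-A"):
        return "scatter"
    if marker == "Time":
        return "time"
    return "fluorescence"


def _level_value(token: str, kind: str) -> float:
    table = SCATTER_LEVELS if kind == "scatter" else FLUOR_LEVELS
    return table[token]


def default_panel_model(tax: PopulationTaxonomy | None = None,
                        seed: int = 0,
                        location_jitter: float = 0.0) -> PopulationModel:
    """Realise every taxonomy leaf's phenotype as a numeric template.

    Template locations are a deterministic function of the phenotype
    grammar; ``location_jitter`` (transformed units, default 0) adds
    seeded per-template displacement for robustness experiments.
    """
    tax = tax or build_default_taxonomy()
    rng = np.random.default_rng(seed)
    templates = {}
    sim_markers = ["FSC-A", "SSC-A"] + list(PANEL_MARKERS)

    for leaf in tax.leaves():
        if leaf.compartment == "aggregate":
            continue
        pheno = {}
        for node in leaf.chain():
            pheno.update(node.phenotype)
        spec = {}
        for m in sim_markers:
            kind = _marker_kind(m)
            token = pheno.get(m, "lo" if kind == "scatter" else "neg")
            sd = SCATTER_SD if kind == "scatter" else FLUOR_SD
            jit = rng.normal(0.0, location_jitter) if location_jitter else 0.0
            if token == "het":
                spec[m] = ("het", HET_RANGE[0] + jit, HET_RANGE[1] + jit, sd)
            else:
                spec[m] = ("normal", _level_value(token, kind) + jit, sd)
        spec["FSC-H"] = spec["FSC-A"]     # singlet pulse height ~ area
        templates[leaf.name] = spec

    templates[DEBRIS] = {m: ("normal", 0.25 if m in ("FSC-A", "FSC-H", "SSC-A")
                             else 0.3,
                             0.12 if m in ("FSC-A", "FSC-H", "SSC-A") else 0.15)
                         for m in sim_markers + ["FSC-H"]}

    freqs = _default_frequencies(tax)
    maturation = {
        "preGC": ["immature B", "naive CD5+ B", "naive CD5- B"],
        "PC": list(PC_STAGES),
    }
    return PopulationModel(tax, templates, freqs, maturation)


def _default_frequencies(tax: PopulationTaxonomy) -> dict:
    freqs = {}
    pre_leaves = tax.leaf_names("preGC")
    mbc_leaves = tax.leaf_names("MBC")
    pc_leaves = tax.leaf_names("PC")
    b_total = COMPARTMENT_FREQS["B"]
    for name in pre_leaves:
        freqs[name] = b_total * PREGC_SHARE_OF_B / len(pre_leaves)
    for name in mbc_leaves:
        freqs[name] = b_total * (1 - PREGC_SHARE_OF_B) / len(mbc_leaves)
    for name in pc_leaves:
        freqs[name] = COMPARTMENT_FREQS["PC"] / len(pc_leaves)
    fixed = ("neutrophils", "eosinophils", "monocytes",
             "T cells CD5+", "NK cells CD5-")
    for name in fixed:
        freqs[name] = COMPARTMENT_FREQS[name]
    freqs["other nucleated cells"] = max(0.0, 1.0 - sum(freqs.values()))
    return freqs


@dataclass
class SampleSpec:
    """What one synthetic datafile should contain."""

    n_events: int = 100_000
    seed: int = 0
    frequency_overrides: dict = field(default_factory=dict)  # leaf -> fraction
    doublet_rate: float = 0.02
    debris_rate: float = 0.03
    duration_s: float = 300.0
    flow_gap: tuple | None = None          # (start_s, length_s) dead window
    residual_spillover: list = field(default_factory=list)  # (src, dst, frac)
    mfi_shift: dict = field(default_factory=dict)            # marker -> delta
    sample_id: str = ""

    def __post_init__(self):
        if self.n_events <= 0:
            raise ValueError("n_events must be positive")
        for r in (self.doublet_rate, self.debris_rate):
            if not 0.0 <= r < 1.0:
                raise ValueError("rates must lie in [0, 1)")


def _draw_population(rng, spec: dict, markers: list[str], n: int) -> np.ndarray:
    out = np.empty((n, len(markers)))
    for j, m in enumerate(markers):
        s = spec[m]
        if s[0] == "normal":
            out[:, j] = rng.normal(s[1], s[2], n)
        else:  # het
            out[:, j] = rng.uniform(s[1], s[2], n) + rng.normal(0.0, s[3], n)
    return out


def simulate_sample(model: PopulationModel, spec: SampleSpec):
    """Draw one labelled sample.

    Returns ``(EventMatrix(stage=transformed), labels)`` with events sorted
    by acquisition time. Doublets are raw-space sums of two singlets with
    FSC-A added and FSC-H kept near the larger singlet's value.
    """
    rng = np.random.default_rng(spec.seed)
    tax = model.taxonomy
    sim_markers = ["FSC-A", "SSC-A"] + list(PANEL_MARKERS)

    freqs = dict(model.frequencies)
    freqs.update(spec.frequency_overrides)
    names = sorted(freqs)
    p = np.array([freqs[n] for n in names], dtype=float)
    if p.sum() <= 0:
        raise ValueError("population frequencies sum to zero")
    p = p / p.sum()

    n_debris = int(round(spec.n_events * spec.debris_rate))
    n_doublet = int(round(spec.n_events * spec.doublet_rate))
    n_nucleated = spec.n_events - n_debris - n_doublet
    counts = rng.multinomial(n_nucleated, p)

    blocks, labels = [], []
    for name, k in zip(names, counts):
        if k == 0:
            continue
        blocks.append(_draw_population(rng, model.templates[name],
                                       sim_markers, k))
        labels.extend([name] * k)
    singlets = np.vstack(blocks) if blocks else np.empty((0, len(sim_markers)))

    if n_debris:
        blocks.append(_draw_population(rng, model.templates[DEBRIS],
                                       sim_markers, n_debris))
        labels.extend([DEBRIS] * n_debris)

    if n_doublet and len(singlets):
        ia = rng.integers(0, len(singlets), n_doublet)
        ib = rng.integers(0, len(singlets), n_doublet)
        a, b = singlets[ia], singlets[ib]
        dbl = np.arcsinh(np.sinh(a) + np.sinh(b))   # raw-space sum, fluor cols
        for j, m in enumerate(sim_markers):
            if _marker_kind(m) == "scatter":
                dbl[:, j] = a[:, j] + b[:, j]       # pulse area adds
        blocks.append(dbl)
        labels.extend([DOUBLET] * n_doublet)

    values = np.vstack(blocks) if blocks else np.empty((0, len(sim_markers)))
    labels = np.array(labels, dtype=object)
    n = len(values)

    # FSC-H: ~= FSC-A for singlets/debris, ~= half the summed area for doublets
    fsc_a = values[:, sim_markers.index("FSC-A")]
    fsc_h = fsc_a * (1.0 + rng.normal(0.0, FSC_H_CV, n))
    dbl_mask = labels == DOUBLET
    fsc_h[dbl_mask] = 0.5 * fsc_a[dbl_mask] * (1.0 + rng.normal(0.0, FSC_H_CV,
                                                                dbl_mask.sum()))

    for marker, delta in spec.mfi_shift.items():
        values[:, sim_markers.index(marker)] += delta

    for src, dst, frac in spec.residual_spillover:
        si = sim_markers.index(src)
        di = sim_markers.index(dst)
        raw_src = np.sinh(values[:, si])
        values[:, di] = np.arcsinh(np.sinh(values[:, di]) + frac * raw_src)

    times = _draw_times(rng, n, spec.duration_s, spec.flow_gap)
    order = np.argsort(times, kind="stable")

    full = np.column_stack([
        fsc_a, fsc_h,
        values[:, sim_markers.index("SSC-A")],
        values[:, 2:],           # the 18 fluorescence markers, panel order
        times,
    ])[order]
    labels = labels[order]

    em = EventMatrix(full, default_panel(), "transformed",
                     spec.sample_id or f"sim-{spec.seed}")
    return em, labels


def _draw_times(rng, n, duration, gap):
    if gap is None:
        return rng.uniform(0.0, duration, n)
    start, length = gap
    live = duration - length
    t = rng.uniform(0.0, live, n)
    return np.where(t < start, t, t + length)


def simulate_cohort(model: PopulationModel, n_samples: int,
                    seed: int = 0, n_events: int = 100_000,
                    jitter: float = 1.0):
    """Draw a cohort with per-sample frequency jitter.

    Compartment totals are drawn log-normally around the model medians and
    clipped to the observed population ranges; subset weights within each
    compartment get independent milder jitter. ``jitter=0`` reproduces the
    model frequencies exactly in every sample. Per-sample seeds derive
    deterministically from ``seed``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    master = np.random.default_rng(seed)
    tax = model.taxonomy
    groups = {
        "B": tax.leaf_names("preGC") + tax.leaf_names("MBC"),
        "PC": tax.leaf_names("PC"),
    }
    majors = ["neutrophils", "eosinophils", "monocytes",
              "T cells CD5+", "NK cells CD5-", "other nucleated cells"]
    out = []
    for i in range(n_samples):
        sub_seed = int(master.integers(0, 2**31 - 1))
        rng = np.random.default_rng(sub_seed)
        freqs = dict(model.frequencies)
        if jitter > 0:
            targets = {}
            for comp, (sigma, lo, hi) in COHORT_JITTER.items():
                base = sum(model.frequencies[l] for l in groups[comp])
                targets[comp] = float(np.clip(
                    base * np.exp(rng.normal(0.0, sigma * jitter)), lo, hi))
            major_w = {m: model.frequencies[m]
                       * np.exp(rng.normal(0.0, MAJOR_JITTER_SIGMA * jitter))
                       for m in majors}
            rest = max(1e-9, 1.0 - sum(targets.values()))
            scale = rest / sum(major_w.values())
            for m in majors:
                freqs[m] = major_w[m] * scale
            for comp, leaves in groups.items():
                w = np.array([model.frequencies[l] for l in leaves])
                w = w * np.exp(rng.normal(0.0, LEAF_JITTER_SIGMA * jitter,
                                          len(w)))
                w = w / w.sum() * targets[comp]
                for l, f in zip(leaves, w):
                    freqs[l] = float(f)
        sspec = SampleSpec(n_events=n_events, seed=sub_seed,
                           frequency_overrides=freqs,
                           sample_id=f"cohort-{seed}-{i:02d}")
        out.append(simulate_sample(model, sspec))
    return out


def qc_flowchart_fixture(model: PopulationModel, seed: int = 0,
                         n_events: int = 100_000):
    """A 36-file cohort violating the datafile inclusion criteria in the
    canonical flowchart proportions: 8 files short of B-cell singlets, 2
    with unstable flow, none miscompensated, 12 with an out-of-range
    marker staining, 14 clean. Each artifact is planted alone so the
    first-failure attribution is unambiguous. Returns a list of
    ``(EventMatrix, expected_failure_stage)``.

    Designed for desk-scale files (default 1e5 events) together with a
    proportionally scaled B-singlet threshold (see
    :func:`cytoagi.qc.desk_qc_criteria`).
    """
    rng = np.random.default_rng(seed)
    tax = model.taxonomy
    b_leaves = (tax.leaf_names("preGC") + tax.leaf_names("MBC")
                + tax.leaf_names("PC"))
    out = []
    plans = ["cell_count"] * 8 + ["flow_stability"] * 2 + \
        ["mfi_range"] * 12 + ["none"] * 14
    for i, expected in enumerate(plans):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        kw = {}
        if expected == "cell_count":
            kw["frequency_overrides"] = {
                l: model.frequencies[l] * 0.15 for l in b_leaves}
        elif expected == "flow_stability":
            kw["flow_gap"] = (100.0, 30.0)
        elif expected == "mfi_range":
            kw["mfi_shift"] = {"CD20": 3.0}
        em, _ = simulate_sample(model, SampleSpec(
            n_events=n_events, seed=sub_seed,
            sample_id=f"qcfix-{i:02d}", **kw))
        out.append((em, expected))
    return out


def simulate_maturation_continuum(model: PopulationModel, stages: list[str],
                                  markers: list[str], n: int,
                                  change_points: list[float], seed: int = 0):
    """Events spread continuously along the polyline through stage template
    locations; the planted stage label switches at the given normalised
    arc-length positions. Used to exercise the maturation classifier on
    genuinely continuous phenotypes."""
    if len(change_points) != len(stages) - 1:
        raise ValueError("need len(stages)-1 change points")
    rng = np.random.default_rng(seed)
    locs = np.array([model.location(s, markers) for s in stages])
    seg = np.linalg.norm(np.diff(locs, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    t = rng.uniform(0.0, 1.0, n)
    values = np.empty((n, len(markers)))
    for i, ti in enumerate(t):
        d = ti * total
        k = min(np.searchsorted(cum, d, side="right") - 1, len(seg) - 1)
        frac = (d - cum[k]) / seg[k]
        values[i] = locs[k] + frac * (locs[k + 1] - locs[k])
    values += rng.normal(0.0, FLUOR_SD, values.shape)
    stage_idx = np.searchsorted(np.asarray(change_points), t, side="right")
    labels = np.array([stages[i] for i in stage_idx], dtype=object)
    return values, t, labels
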