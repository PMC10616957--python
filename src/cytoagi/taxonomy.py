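"""Population taxonomy and expert Boolean gating for blood B cells and PC.

The taxonomy is a strict gating tree: every node carries a conjunction of
(marker, band) terms applied to events that already satisfy its parent's
rule, and sibling rules are pairwise disjoint (verified at load time via a
shared marker whose bands do not intersect). Pure-union populations that
the field reports but that are not gates of their own (e.g. "IgG memory
B cells" across the IgG1-4 subclasses) are declared as aggregates over
tree nodes and only enter subset counting and counts tables.

Default tree (subset arithmetic, auditable below in
:func:`build_default_taxonomy`):

* pre-germinal-centre B cells: 10 subsets (7 leaves + 3 aggregates-in-tree)
* memory B cells: 9 IgH classes x 8 + 3 class aggregates = 75 subsets
* plasma cells: 8 IgH classes x (1 + 3 maturation stages) = 32 subsets
* B-lymphocyte + PC total: 10 + 75 + 32 = 117
* plus 6 non-B leukocyte populations = 123 populations overall
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .fcs_io import EventMatrix, PanelMismatchError, ConfigError

__all__ = [
    "BANDS",
    "PopulationNode",
    "AggregateDef",
    "PopulationTaxonomy",
    "TaxonomyError",
    "LabelledResult",
    "build_default_taxonomy",
    "load_taxonomy",
    "save_taxonomy",
    "boolean_gate",
    "count_subsets",
    "is_quantifiable",
    "DOUBLET", "DEBRIS", "UNCLASSIFIED",
]

DOUBLET = "doublet"
DEBRIS = "debris"
UNCLASSIFIED = "unclassified"


class TaxonomyError(ValueError):
    """Structurally invalid taxonomy (overlapping siblings, broken tree...)."""


# Band tokens over per-marker breakpoints (t1, t2, t3), transformed units:
#   neg < t1 <= lo < t2 <= pos < t3 <= hi;  het spans lo..pos.
# Composite tokens exist so that splits like "bright vs dim-or-negative"
# stay expressible as a single disjoint pair.
BANDS = {
    "neg":     (0, 1),
    "lo":      (1, 2),
    "het":     (1, 3),
    "pos":     (2, 3),
    "hi":      (3, 4),
    "negorlo": (0, 2),
    "nothi":   (0, 3),
    "nonneg":  (1, 4),
    "posorhi": (2, 4),
    "any":     (0, 4),
}


def _band_interval(token: str, breaks) -> tuple[float, float]:
    lo_i, hi_i = BANDS[token]
    edges = (-np.inf, breaks[0], breaks[1], breaks[2], np.inf)
    return edges[lo_i], edges[hi_i]


def bands_disjoint(a: str, b: str) -> bool:
    (a0, a1), (b0, b1) = BANDS[a], BANDS[b]
    return a1 <= b0 or b1 <= a0


@dataclass
class PopulationNode:
    """One gate in the taxonomy tree."""

    name: str
    parent: "PopulationNode | None" = None
    rule: dict = field(default_factory=dict)        # marker -> band token
    compartment: str = "aggregate"                  # preGC|MBC|PC|nonB|aggregate|artifact
    is_subset: bool = False
    phenotype: dict = field(default_factory=dict)   # full marker -> band (simulation)
    children: list = field(default_factory=list)

    @property
    def min_quantifiable(self) -> int:
        return 20 if self.compartment == "PC" else 50

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def chain(self) -> list["PopulationNode"]:
        """Ancestor rule chain, root first, self last."""
        out, node = [], self
        while node is not None:
            out.append(node)
            node = node.parent
        return out[::-1]

    def merged_rule(self) -> dict:
        """Conjunction of the full ancestor chain (later terms override)."""
        rule: dict = {}
        for node in self.chain():
            rule.update(node.rule)
        return rule


@dataclass
class AggregateDef:
    """A counted population that is a union of tree nodes, not a gate."""

    name: str
    compartment: str
    members: list[str]


_COMPARTMENTS = ("preGC", "MBC", "PC", "nonB", "aggregate", "artifact")


@dataclass
class PopulationTaxonomy:
    root: PopulationNode
    aggregates: list[AggregateDef] = field(default_factory=list)
    breakpoints: dict = field(default_factory=dict)   # marker -> (t1, t2, t3)
    doublet_ratio: float = 1.5
    debris_fsc_band: str = "neg"

    def __post_init__(self):
        self._index = {}
        for node in self.walk():
            if node.name in self._index:
                raise TaxonomyError(f"duplicate node name {node.name!r}")
            self._index[node.name] = node
        for agg in self.aggregates:
            if agg.name in self._index:
                raise TaxonomyError(f"aggregate {agg.name!r} shadows a node")
            for m in agg.members:
                if m not in self._index:
                    raise TaxonomyError(f"aggregate member {m!r} unknown")
        self.validate()

    # -- structure ---------------------------------------------------------
    def walk(self):
        stack = [self.root]
        while stack:
            node = stack.pop(0)
            yield node
            stack = node.children + stack

    def node(self, name: str) -> PopulationNode:
        try:
            return self._index[name]
        except KeyError:
            raise TaxonomyError(f"unknown population {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def leaves(self, compartment: str | None = None) -> list[PopulationNode]:
        out = [n for n in self.walk() if n.is_leaf]
        if compartment is not None:
            out = [n for n in out if n.compartment == compartment]
        return out

    def leaf_names(self, compartment: str | None = None) -> list[str]:
        return [n.name for n in self.leaves(compartment)]

    def descendants(self, name: str) -> list[str]:
        node = self.node(name)
        out, stack = [], list(node.children)
        while stack:
            n = stack.pop()
            out.append(n.name)
            stack.extend(n.children)
        return out

    def subset_names(self, compartments=None) -> list[str]:
        comps = _expand_filter(compartments)
        names = [n.name for n in self.walk() if n.is_subset and n.compartment in comps]
        names += [a.name for a in self.aggregates if a.compartment in comps]
        return names

    def marker_coverage(self) -> set[str]:
        used = set()
        for n in self.walk():
            used.update(n.rule)
        return used

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        for node in self.walk():
            if node.compartment not in _COMPARTMENTS:
                raise TaxonomyError(
                    f"{node.name}: unknown compartment {node.compartment!r}")
            for marker, token in node.rule.items():
                if token not in BANDS:
                    raise TaxonomyError(f"{node.name}: unknown band {token!r}")
            kids = node.children
            for i in range(len(kids)):
                for j in range(i + 1, len(kids)):
                    if not _rules_disjoint(kids[i].rule, kids[j].rule):
                        raise TaxonomyError(
                            "overlapping sibling rules: "
                            f"{kids[i].name!r} vs {kids[j].name!r}")

    def check_panel(self, markers: list[str]) -> None:
        missing = sorted(self.marker_coverage() - set(markers))
        if missing:
            raise PanelMismatchError(
                f"taxonomy needs markers not in the event matrix: {missing}")


def _expand_filter(compartments) -> set[str]:
    if compartments is None or compartments == "all":
        return {"preGC", "MBC", "PC", "nonB"}
    if isinstance(compartments, str):
        alias = {
            "B": {"preGC", "MBC"},
            "B+PC": {"preGC", "MBC", "PC"},
        }
        if compartments in alias:
            return alias[compartments]
        if compartments not in _COMPARTMENTS:
            raise TaxonomyError(f"unknown compartment filter {compartments!r}")
        return {compartments}
    return set(compartments)


def _rules_disjoint(a: dict, b: dict) -> bool:
    return any(bands_disjoint(a[m], b[m]) for m in set(a) & set(b))


def count_subsets(tax: PopulationTaxonomy, compartments=None) -> int:
    """Number of counted subset labels in the filtered compartments."""
    return len(tax.subset_names(compartments))


def is_quantifiable(node: PopulationNode, count: int) -> bool:
    """>50 identified cells, except >20 for plasma-cell subsets."""
    if count < 0:
        raise ValueError("count must be >= 0")
    return count > node.min_quantifiable


# ---------------------------------------------------------------------------
# Default taxonomy
# ---------------------------------------------------------------------------

FLUOR_BREAKS = (1.05, 2.30, 3.80)
SCATTER_BREAKS = (0.70, 2.05, 3.20)

MBC_ISOTYPES = ("IgMD", "IgMonly", "IgDonly",
                "IgG1", "IgG2", "IgG3", "IgG4", "IgA1", "IgA2")
PC_ISOTYPES = ("IgMD", "IgG1", "IgG2", "IgG3", "IgG4", "IgA1", "IgA2", "IgHneg")
PC_STAGES = ("CD20+CD138-", "CD20-CD138-", "CD20-CD138+")

_IG_MARKERS = ("IgM", "IgD", "IgG1", "IgG2", "IgG3", "IgG4", "IgA1", "IgA2")


def _isotype_rule(isotype: str) -> dict:
    """Full IgH signature: own chain(s) positive, every other one negative."""
    rule = {m: "neg" for m in _IG_MARKERS}
    if isotype == "IgMD":
        rule["IgM"] = "pos"; rule["IgD"] = "pos"
    elif isotype == "IgMonly":
        rule["IgM"] = "pos"
    elif isotype == "IgDonly":
        rule["IgD"] = "pos"
    elif isotype == "IgHneg":
        pass
    else:
        rule[isotype] = "pos"
    return rule


def build_default_taxonomy() -> PopulationTaxonomy:
    """The shipped BIgH-IMM gating tree (117 B+PC subsets, 123 populations)."""

    def N(name, parent, rule, compartment="aggregate", is_subset=False, pheno=None):
        node = PopulationNode(name, parent, dict(rule), compartment,
                              is_subset, dict(pheno or {}))
        if parent is not None:
            parent.children.append(node)
        return node

    root = PopulationNode("nucleated cells", None, {}, "aggregate", False,
                          {"FSC-A": "lo", "SSC-A": "lo"})

    lym = {"FSC-A": "lo", "SSC-A": "lo", "CD45": "hi"}

    # --- non-B major leukocyte populations (6) ---
    N("neutrophils", root,
      {"CD19": "neg", "CD45": "lo", "SSC-A": "hi", "CD24": "pos"},
      "nonB", True,
      {"FSC-A": "pos", "SSC-A": "hi", "CD45": "lo", "CD24": "pos"})
    N("eosinophils", root,
      {"CD19": "neg", "CD45": "pos", "SSC-A": "hi", "CD27": "pos", "IgM": "pos"},
      "nonB", True,
      {"FSC-A": "pos", "SSC-A": "hi", "CD45": "pos", "CD27": "pos", "IgM": "pos"})
    N("monocytes", root,
      {"CD19": "neg", "CD45": "hi", "SSC-A": "pos"},
      "nonB", True,
      {"FSC-A": "pos", "SSC-A": "pos", "CD45": "hi", "CD62L": "pos"})
    N("T cells CD5+", root,
      {"CD19": "neg", "CD45": "hi", "SSC-A": "lo", "CD5": "pos"},
      "nonB", True, {**lym, "CD5": "pos", "CD27": "pos", "CD62L": "pos"})
    N("NK cells CD5-", root,
      {"CD19": "neg", "CD45": "hi", "SSC-A": "lo", "CD5": "neg"},
      "nonB", True, {**lym, "CD5": "neg"})
    N("other nucleated cells", root,
      {"CD19": "neg", "CD45": "pos", "SSC-A": "lo"},
      "nonB", True, {"FSC-A": "lo", "SSC-A": "lo", "CD45": "pos"})

    # --- B lymphocytes (CD19+ CD45hi FSClo/SSClo) ---
    b = N("B-lymphocytes", root,
          {"CD19": "pos", "CD45": "hi", "SSC-A": "lo", "CD38": "nothi"},
          "aggregate", False, {**lym, "CD19": "pos", "CD20": "pos"})

    bbase = {**lym, "CD19": "pos", "CD20": "pos", "CD138": "neg"}

    # pre-GC: immature/transitional + naive CD5+ / CD5-  (10 subsets)
    N("immature B", b, {"CD38": "pos", "CD24": "pos", "CD27": "neg"},
      "preGC", True,
      {**bbase, "CD38": "pos", "CD24": "pos", "CD21": "het", "IgM": "pos",
       "IgD": "pos", "CD27": "neg", "CD5": "lo", "CD62L": "pos"})

    n5p = N("naive CD5+ B", b,
            {"CD38": "neg", "IgD": "hi", "CD27": "neg", "CD5": "pos"},
            "preGC", True,
            {**bbase, "CD38": "neg", "CD24": "het", "CD21": "het",
             "IgM": "pos", "IgD": "hi", "CD27": "neg", "CD5": "pos"})
    for lvl in ("pos", "neg"):
        tag = "+" if lvl == "pos" else "-"
        N(f"naive CD5+ CD62L{tag} B", n5p, {"CD62L": lvl}, "preGC", True,
          {"CD62L": lvl})

    n5n = N("naive CD5- B", b,
            {"CD38": "neg", "IgD": "hi", "CD27": "neg", "CD5": "neg"},
            "preGC", True,
            {**bbase, "CD38": "neg", "CD24": "pos", "IgM": "pos",
             "IgD": "hi", "CD27": "neg", "CD5": "neg"})
    for lvl in ("pos", "neg"):
        tag = "+" if lvl == "pos" else "-"
        N(f"naive CD5- CD21+ CD62L{tag} B", n5n,
          {"CD21": "pos", "CD62L": lvl}, "preGC", True,
          {"CD21": "pos", "CD62L": lvl})
    n5n_lo = N("naive CD5- CD21lo B", n5n, {"CD21": "lo"}, "preGC", True,
               {"CD21": "lo"})
    for lvl in ("pos", "neg"):
        tag = "+" if lvl == "pos" else "-"
        N(f"naive CD5- CD21lo CD62L{tag} B", n5n_lo, {"CD62L": lvl},
          "preGC", True, {"CD62L": lvl})

    # memory B cells: 9 IgH classes x 8 = 72 tree subsets (+3 aggregates)
    mbc = N("memory B", b, {"CD38": "neg", "IgD": "nothi", "CD138": "neg"},
            "MBC", False,
            {**bbase, "CD38": "neg", "CD5": "neg", "CD62L": "pos"})
    for iso in MBC_ISOTYPES:
        iso_node = N(f"MBC {iso}", mbc, _isotype_rule(iso), "MBC", True,
                     _isotype_rule(iso))
        for c27 in ("neg", "pos"):
            tag = "+" if c27 == "pos" else "-"
            N(f"MBC {iso} CD21+CD20+ CD27{tag}", iso_node,
              {"CD21": "pos", "CD20": "pos", "CD27": c27}, "MBC", True,
              {"CD21": "pos", "CD20": "pos", "CD24": "pos", "CD27": c27})
        act = N(f"MBC {iso} CD21-CD20hi", iso_node,
                {"CD21": "neg", "CD20": "hi"}, "MBC", True,
                {"CD21": "neg", "CD20": "hi"})
        for c24 in ("neg", "pos"):
            for c27 in ("neg", "pos"):
                t24 = "+" if c24 == "pos" else "-"
                t27 = "+" if c27 == "pos" else "-"
                N(f"MBC {iso} CD21-CD20hi CD24{t24} CD27{t27}", act,
                  {"CD24": c24, "CD27": c27}, "MBC", True,
                  {"CD24": c24, "CD27": c27})

    # plasma cells: 8 IgH classes x (1 + 3 stages) = 32 subsets
    pc = N("plasma cells", root,
           {"CD19": "lo", "CD45": "lo", "CD38": "hi", "CD24": "neg",
            "CD21": "neg", "SSC-A": "lo"},
           "PC", False,
           {"FSC-A": "lo", "SSC-A": "lo", "CD19": "lo", "CD45": "lo",
            "CD38": "hi", "CD24": "neg", "CD21": "neg", "CD27": "pos"})
    stage_rules = {
        "CD20+CD138-": {"CD20": "pos", "CD138": "neg"},
        "CD20-CD138-": {"CD20": "neg", "CD138": "neg"},
        "CD20-CD138+": {"CD20": "neg", "CD138": "pos"},
    }
    for iso in PC_ISOTYPES:
        iso_node = N(f"PC {iso}", pc, _isotype_rule(iso), "PC", True,
                     _isotype_rule(iso))
        for stage in PC_STAGES:
            N(f"PC {iso} {stage}", iso_node, stage_rules[stage], "PC", True,
              stage_rules[stage])

    aggregates = [
        AggregateDef("MBC unswitched", "MBC",
                     ["MBC IgMD", "MBC IgMonly", "MBC IgDonly"]),
        AggregateDef("MBC IgG", "MBC", [f"MBC IgG{i}" for i in range(1, 5)]),
        AggregateDef("MBC IgA", "MBC", ["MBC IgA1", "MBC IgA2"]),
    ]

    breaks = {m: FLUOR_BREAKS for m in
              ("CD19", "CD45", "CD38", "CD20", "CD24", "CD21", "CD27", "CD5",
               "CD62L", "CD138", "IgM", "IgD", "IgG1", "IgG2", "IgG3", "IgG4",
               "IgA1", "IgA2")}
    breaks.update({m: SCATTER_BREAKS for m in ("FSC-A", "FSC-H", "SSC-A")})

    return PopulationTaxonomy(root, aggregates, breaks)


# ---------------------------------------------------------------------------
# Config round-trip
# ---------------------------------------------------------------------------

def save_taxonomy(tax: PopulationTaxonomy, path: str) -> None:
    nodes = []
    for n in tax.walk():
        nodes.append({
            "name": n.name,
            "parent": n.parent.name if n.parent else None,
            "rule": dict(n.rule),
            "compartment": n.compartment,
            "is_subset": bool(n.is_subset),
            "phenotype": dict(n.phenotype),
        })
    doc = {
        "breakpoints": {m: list(v) for m, v in tax.breakpoints.items()},
        "doublet_ratio": tax.doublet_ratio,
        "nodes": nodes,
        "aggregates": [{"name": a.name, "compartment": a.compartment,
                        "members": list(a.members)} for a in tax.aggregates],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_taxonomy(path: str | None = None,
                  panel_markers: list[str] | None = None) -> PopulationTaxonomy:
    """Load a taxonomy config, or the shipped default when ``path`` is None."""
    if path is None:
        tax = build_default_taxonomy()
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        index: dict[str, PopulationNode] = {}
        root = None
        for spec in doc["nodes"]:
            parent = None
            if spec["parent"] is not None:
                if spec["parent"] not in index:
                    raise TaxonomyError(
                        f"node {spec['name']!r} declared before parent")
                parent = index[spec["parent"]]
            node = PopulationNode(spec["name"], parent, dict(spec.get("rule", {})),
                                  spec.get("compartment", "aggregate"),
                                  bool(spec.get("is_subset", False)),
                                  dict(spec.get("phenotype", {})))
            if parent is not None:
                parent.children.append(node)
            elif root is not None:
                raise TaxonomyError("multiple root nodes")
            else:
                root = node
            index[spec["name"]] = node
        if root is None:
            raise TaxonomyError("empty taxonomy config")
        aggs = [AggregateDef(a["name"], a["compartment"], list(a["members"]))
                for a in doc.get("aggregates", [])]
        breaks = {m: tuple(v) for m, v in doc.get("breakpoints", {}).items()}
        tax = PopulationTaxonomy(root, aggs, breaks,
                                 doc.get("doublet_ratio", 1.5))
    if panel_markers is not None:
        unknown = sorted(tax.marker_coverage() - set(panel_markers))
        if unknown:
            raise ConfigError(f"taxonomy uses markers outside panel: {unknown}")
    return tax


# ---------------------------------------------------------------------------
# Boolean gating
# ---------------------------------------------------------------------------

@dataclass
class LabelledResult:
    """Per-event population assignment plus counting helpers."""

    labels: np.ndarray            # object array of population names
    taxonomy: PopulationTaxonomy
    provenance: np.ndarray | None = None   # per-event deciding stage (AGI)

    @property
    def n_events(self) -> int:
        return len(self.labels)

    def direct_counts(self) -> dict:
        names, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(names.tolist(), counts.tolist()))

    def cumulative_counts(self) -> dict:
        """name -> events labelled at the node or any of its descendants;
        aggregates sum their members."""
        direct = self.direct_counts()
        out = {}
        for node in self.taxonomy.walk():
            total = direct.get(node.name, 0)
            for d in self.taxonomy.descendants(node.name):
                total += direct.get(d, 0)
            out[node.name] = total
        for agg in self.taxonomy.aggregates:
            out[agg.name] = sum(out[m] for m in agg.members)
        for special in (DOUBLET, DEBRIS, UNCLASSIFIED):
            out[special] = direct.get(special, 0)
        return out

    def n_leukocytes(self) -> int:
        direct = self.direct_counts()
        return self.n_events - direct.get(DOUBLET, 0) - direct.get(DEBRIS, 0) \
            - direct.get(UNCLASSIFIED, 0)

    def counts_table(self, compartments=None,
                     include_gates: bool = True) -> pd.DataFrame:
        """Counts and % of leukocytes for every counted subset.

        ``include_gates`` adds the enclosing gates that are not counted
        subsets themselves (total B-lymphocytes, memory B, plasma cells).
        """
        cum = self.cumulative_counts()
        denom = max(self.n_leukocytes(), 1)
        names = []
        if include_gates and compartments is None:
            names += [n.name for n in self.taxonomy.walk()
                      if not n.is_subset and n.parent is not None]
        names += self.taxonomy.subset_names(compartments)
        rows = [(name, cum[name], 100.0 * cum[name] / denom)
                for name in names]
        return pd.DataFrame(rows, columns=["population", "n", "pct_of_leukocytes"])


def rule_mask(values: np.ndarray, markers: list[str], rule: dict,
              breakpoints: dict) -> np.ndarray:
    """Vectorised conjunction of band-membership terms."""
    mask = np.ones(values.shape[0], dtype=bool)
    for marker, token in rule.items():
        try:
            j = markers.index(marker)
        except ValueError:
            raise PanelMismatchError(f"marker {marker!r} missing") from None
        lo, hi = _band_interval(token, breakpoints[marker])
        col = values[:, j]
        mask &= (col >= lo) & (col < hi)
    return mask


def boolean_gate(em: EventMatrix, tax: PopulationTaxonomy) -> LabelledResult:
    """Expert sequential Boolean gating.

    Doublets (FSC-A/FSC-H ratio above threshold) and debris (very low FSC-A
    with negative CD45) are excluded first; every remaining event then
    descends the tree to the deepest node whose full ancestor rule chain it
    satisfies. Events matching no child of a mandatory split stay at the
    parent node; events matching nothing at root level are ``unclassified``.
    """
    if em.stage != "transformed":
        raise ValueError("boolean_gate expects a transformed event matrix")
    tax.check_panel(em.markers)
    markers = em.markers
    values = em.values
    n = em.n_events
    labels = np.full(n, UNCLASSIFIED, dtype=object)
    if n == 0:
        return LabelledResult(labels, tax)

    fsc_a = em.column("FSC-A")
    fsc_h = em.column("FSC-H")
    ratio = fsc_a / np.maximum(fsc_h, 1e-12)
    doublet = ratio > tax.doublet_ratio

    lo, hi = _band_interval(tax.debris_fsc_band, tax.breakpoints["FSC-A"])
    c_lo, c_hi = _band_interval("neg", tax.breakpoints["CD45"])
    cd45 = em.column("CD45")
    debris = (~doublet) & (fsc_a >= lo) & (fsc_a < hi) & \
        (cd45 >= c_lo) & (cd45 < c_hi)

    labels[doublet] = DOUBLET
    labels[debris] = DEBRIS
    live = np.where(~doublet & ~debris)[0]

    stack = [(tax.root, live)]
    while stack:
        node, idx = stack.pop()
        if idx.size == 0:
            continue
        if node is not tax.root:
            labels[idx] = node.name
        remaining = np.ones(idx.size, dtype=bool)
        for child in node.children:
            sub = rule_mask(values[idx], markers, child.rule, tax.breakpoints)
            sub &= remaining            # disjoint by validation; first match wins
            remaining &= ~sub
            stack.append((child, idx[sub]))
    return LabelledResult(labels, tax)


def count_b_singlets(em: EventMatrix, tax: PopulationTaxonomy) -> int:
    """Events in the CD19+ CD45+ FSClo/SSClo single-cell B gate (doublets
    excluded). Used by the datafile QC cell-count criterion."""
    res = boolean_gate(em, tax)
    return res.cumulative_counts()["B-lymphocytes"]
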