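# cytoagi

Automated database-guided gating and identification (AGI) of circulating
B-lymphocyte and plasma-cell (PC) populations from multiparameter flow
cytometry data.

Conventional analysis of deep B-cell panels — 18 antibodies resolving more
than a hundred subsets — relies on expert manual gating: sequential 2-D
Boolean gates that are slow, subjective and hard to reproduce across
laboratories. `cytoagi` implements the alternative workflow in which a
reference database of expert-gated datafiles drives fully automated
per-event classification of new samples, and ships everything needed to
exercise that workflow end to end: strict datafile quality control, the
full B/PC gating taxonomy, reference-database construction with internal
consistency checks, two classification algorithms (flat two-step and
hierarchical multi-step), a synthetic whole-blood data generator with
planted ground truth, and the method-comparison statistics used to validate
automated against manual analysis.

It is aimed at computational immunologists and cytometry software
developers who want an open, testable implementation of database-guided
gating to study, extend, or benchmark against.

## The method

**Population taxonomy.** A strict gating tree over the 18-marker B-cell
immune-monitoring panel (CD19, CD45, CD38, CD20, CD24, CD21, CD27, CD5,
CD62L, CD138, IgM, IgD, IgG1–4, IgA1–2 plus scatter). Each node carries a
conjunction of (marker, band) terms — bands neg / lo / het / pos / hi over
per-marker breakpoints in arcsinh-transformed space — and sibling rules are
pairwise disjoint. The default tree enumerates 117 B-lymphocyte + PC
subsets (10 pre-germinal-centre, 75 memory, 32 plasma-cell) plus 6 non-B
leukocyte populations: 123 populations in all. A subset is *quantifiable*
in a sample when more than 50 cells are assigned to it (more than 20 for
PC subsets).

**Datafile QC.** Four sequential inclusion criteria: (i) ≥ 10⁵ CD19⁺CD45⁺
FSC^lo/SSC^lo B-cell singlets; (ii) stable flow rate (events-per-bin CV
over 100 equal-duration bins, plus a longest-dead-time rule); (iii) clean
compensation (median shift of positive control populations in every other
channel); (iv) control-population median fluorescence intensities within
expected ranges. A file's failure is attributed to the first broken
criterion.

**Reference database.** Expert-gated files are merged one at a time; each
population keeps a template — event count *n*, location vector, and
Ledoit–Wolf-shrunk covariance Σ in transformed space — plus the pooled
labelled events with per-file provenance. A leave-one-file-out check
projects every population of every file into 2-D principal-component and
canonical planes fitted on the remaining files and flags it unless the
median and ≥ 95% of events fall within the 2-SD ellipse.

**Two-step AGI.** Step 1 clusters events by K-nearest-neighbour density
(density of event *i* is 1 / mean distance to its K = 10 nearest
neighbours): events link uphill to their densest neighbour, forming modes,
and adjacent modes are merged while their separation score

&nbsp;&nbsp;&nbsp;&nbsp;sep(A, B) = 20 · (1 − s(A,B) / min(p_A, p_B))

stays below 0.9 on the 0–20 scale, where *s* is the saddle (highest
min-density K-NN edge between the modes) and *p* the mode peaks, both on a
noise-smoothed density field. Step 2 classifies every cluster against the
database: candidates ranked by Mahalanobis distance, then a pairwise
canonical (linear-discriminant) plane per competitor pair; the cluster
joins the nearer template iff its projected median falls inside that
template's 2-SD ellipse, else it is `unclassified`.

**Hierarchical AGI.** The same two-step algorithm applied stage by stage
with cell-type-specific marker subsets — major leukocyte lineages first,
then B-cell compartments, then isotype and surface-marker splits — with a
maturation (trajectory) classifier for the continuous pre-GC
(immature → naive CD5⁺ → naive CD5⁻) and PC (CD20⁺CD138⁻ → CD20⁻CD138⁻ →
CD20⁻CD138⁺) axes: events are projected onto the piecewise-linear path
through stage template locations and cut at pre-established positions.

**Validation statistics.** Per-population squared Pearson correlation of
paired counts across samples (restricted to quantifiable populations),
regression slope, Bland–Altman bias with 95% limits of agreement,
coefficient of variation across replicate analyses, and rank-based method
comparisons (Mann-Whitney U, Wilcoxon signed-rank, Kruskal–Wallis).

Because no public event-level data accompany this workflow, the package
generates its own: synthetic lysed-whole-blood samples in which every
taxonomy leaf becomes a numeric template (B cells 4.9% and PC 0.06% of
nucleated cells by default), with planted doublets, debris, flow gaps,
residual spillover and staining shifts, and per-event ground-truth labels.

## Worked example

```python
import numpy as np
from cytoagi import (build_default_taxonomy, default_panel_model, simulate_sample,
                     SampleSpec, boolean_gate, init_database, classify_and_merge,
                     hierarchical_classify)

tax = build_default_taxonomy()
model = default_panel_model(tax)

# train a reference database from two expert-gated files
db = None
for seed in (1, 2):
    em, _ = simulate_sample(model, SampleSpec(n_events=100_000, seed=seed,
                                              sample_id=f"train-{seed}"))
    labels = boolean_gate(em, tax).labels
    db = init_database(em, labels, tax) if db is None \
        else classify_and_merge(db, em, labels)

# classify a new sample and compare with the planted truth
em, truth = simulate_sample(model, SampleSpec(n_events=100_000, seed=42))
result = hierarchical_classify(em, db, seed=0)

table = result.counts_table().set_index("population")
for pop in ("B-lymphocytes", "memory B", "plasma cells", "neutrophils"):
    row = table.loc[pop]
    print(f"{pop:20s} n={int(row.n):6d}  {row.pct_of_leukocytes:6.2f}% of leukocytes")

leaves = set(tax.leaf_names())
mask = np.isin(truth, list(leaves))
print(f"planted-label recovery: {100 * np.mean(result.labels[mask] == truth[mask]):.1f}%")
```

prints

```
B-lymphocytes        n=  4728    4.96% of leukocytes
memory B             n=  2021    2.12% of leukocytes
plasma cells         n=    60    0.06% of leukocytes
neutrophils          n= 52169   54.77% of leukocytes
planted-label recovery: 99.8%
```

The classifier recovers the planted compartment structure — B cells near
their 4.9% simulation frequency, plasma cells at 0.06% — and assigns 99.8%
of events in population leaves back to their generating population.

The same workflow is scriptable from the shell:

```bash
cytoagi simulate --outdir sim --n-events 100000 --cohort 3 --seed 5
cytoagi qc sim/*.fcs --min-b-singlets 3000
cytoagi build-db sim/sample_000.fcs sim/sample_001.fcs --out refdb
cytoagi classify --db refdb --batch sim --seed 1 --out counts.csv
cytoagi taxonomy-report
```

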