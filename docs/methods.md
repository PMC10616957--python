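# Methods

This note records the models, numerical conventions and design choices
behind `cytoagi`, in the order the pipeline runs. Wherever a published
description of database-guided gating leaves the underlying primitive
unspecified (the density/affinity score, the classification acceptance
rule, the working scale), the reconstruction chosen here is stated
explicitly and, where practical, left configurable.

## Analysis space

All clustering, template statistics and discriminant projections operate on
*transformed* data: fluorescence as `asinh(x / c)` with a common cofactor
`c = 150` (configurable per channel), scatter divided by a fixed full-scale
constant (10 000 raw units → a 0–5 analysis scale), time untouched.
Rationale: Euclidean distances and covariances are only meaningful on a
variance-stabilised scale; the arcsinh keeps negative compensated values
finite. Compensation right-multiplies the fluorescence block by the inverse
spillover matrix before transformation; stages advance strictly
raw → compensated → transformed.

## Taxonomy and band grammar

Phenotype levels are bands over per-marker breakpoints (t₁, t₂, t₃):
neg < t₁ ≤ lo < t₂ ≤ pos < t₃ ≤ hi, with `het` spanning lo–pos. Composite
tokens (`nothi`, `posorhi`, `negorlo`, `nonneg`) exist so that every
sibling split in the gating tree is disjoint on at least one shared marker;
this disjointness is verified at load time. Default breakpoints are
1.05 / 2.30 / 3.80 transformed units for fluorescence and
0.70 / 2.05 / 3.20 for scatter.

The default tree's subset arithmetic, chosen to make the printed tallies
auditable by traversal:

* pre-GC: immature (1) + naive CD5⁺ [aggregate + 2 CD62L leaves] (3) +
  naive CD5⁻ [aggregate + 2 CD21⁺CD62L± leaves + CD21^lo aggregate +
  2 CD62L± leaves] (6) = **10**
* memory: 9 IgH classes (IgM⁺D⁺, IgM-only, IgD-only, IgG1–4, IgA1–2) ×
  [isotype aggregate + 2 CD21⁺CD20⁺CD27± leaves + CD21⁻CD20^hi aggregate +
  4 CD24±CD27± leaves] (8) + 3 class aggregates (unswitched/IgG/IgA) =
  **75**
* plasma cells: 8 IgH classes (IgM-D, IgG1–4, IgA1–2, IgH⁻) ×
  [isotype aggregate + 3 maturation-stage leaves] = **32**
* B + PC total **117**; with 6 non-B leukocyte populations, **123**.

Pure-union aggregates (the three memory class groups) are declared outside
the gating tree so the tree itself stays strictly disjoint; they enter
subset counting and counts tables as sums over their members. Counts in all
tables are cumulative over subtrees, matching how gated counts are read.

Doublets are excluded first by FSC-A/FSC-H ratio > 1.5, debris by very low
FSC-A with negative CD45; both thresholds are config entries. An event
descends the tree to the deepest node whose full rule chain it satisfies
and is retained at a node when it matches none of its children.

## Datafile QC

Criterion order is fixed (cell count → flow stability → compensation → MFI
ranges); all four are always evaluated and failure is attributed to the
first broken one. Operationalisations of the two visually-defined criteria:

* *Flow stability*: CV of events-per-bin over 100 equal-duration bins
  (pass ≤ 0.25) and longest inter-event gap (pass ≤ 2 s). For a uniform
  acquisition the CV concentrates near √(bins/n).
* *Compensation*: for every ordered channel pair, |median of the primary
  channel's positive control population in the spill channel − median of
  the spill channel's negative control| ≤ 0.15 transformed units. A pair is
  only checked when the positive control population is phenotypically
  negative for the spill marker (true expression would mask spillover);
  control populations under 50 events make a pair "uncheckable", never
  "failed".
* *MFI ranges*: expected ranges are not published, so the package ships
  surrogates computed from the synthetic population model (expected control
  median ± 0.5 transformed units), clearly labelled and fully editable.

The desk-scale criteria helper scales the 10⁵ B-singlet threshold to 3 000
for 10⁵-event files, preserving the proportion of a full-size acquisition.

## Reference database

Templates: per-marker median location and Ledoit–Wolf shrinkage covariance
(estimated on at most 20 000 events; counts stay exact), floored at 0.04
variance per channel — the generator's staining spread — so few-event
plasma-cell templates keep physically plausible acceptance regions.
Merging pools templates exactly: n-weighted mean location and pooled
second-moment covariance, which makes merge order irrelevant (commutative
to 1e-9). The merged event store keeps at most 10⁴ events per population
per file (seeded uniform thinning) with per-file provenance; templates are
computed before thinning.

The leave-one-file-out consistency check projects each held-out file into
the 2-D principal-component plane of the remaining files and into the
canonical plane against the nearest other population, and flags the pair
unless the held-out median lies inside the 2-SD ellipse and ≥ 95% of its
events do.

**The "2-SD" convention.** A bivariate Gaussian holds only 86.5% of its
mass within Mahalanobis 2, so a literal 2-SD ellipse cannot contain 95% of
a well-behaved population's events. Throughout the package the k-D "2-SD"
region is therefore the ellipsoid holding the same probability mass as the
±2 SD interval of a 1-D Gaussian (95.45%; Mahalanobis radius ≈ 2.49 in
2-D), which makes the convention dimension-consistent.

## Clustering and the separation score

Density of event *i* is 1 / (mean Euclidean distance to its K = 10 nearest
neighbours) in the selected marker subspace; coincident events are capped
at 10¹². Events link uphill to the densest of their K neighbours; link-free
events are mode apices. The saddle between two adjacent modes is the
highest min-density K-NN edge crossing their boundary, and

  separation = 20 · (1 − saddle / min(peaks)),  clamped to [0, 20],

with modes merged lowest-separation-first while separation < 0.9.

Raw K = 10 densities are far too noisy for this rule — a single Gaussian
fragments into dozens of modes whose apparent dips exceed the cutoff — so
saddles and peaks are evaluated on a smoothed field: three K-NN averaging
passes, peaks taken as the per-mode maxima of the smoothed field. With
this, one Gaussian collapses to a single cluster and populations separated
by ≥ 4 SD keep their own clusters in the ≥ 4-dimensional marker subspaces
the stage plan uses. In 3-D an isolated Gaussian can still split into a few
contiguous fragments; this is harmless downstream because fragments of one
population classify to the same label. The 0–20 scale and the 0.9 cutoff
are preserved as the interface; the score itself is a documented
reconstruction and both smoothing depths are module constants.

Scopes above 50 000 events are clustered on a seeded uniform subsample and
the remaining events inherit their nearest sampled neighbour's label;
cluster statistics change negligibly at this size while K-NN graph
construction stays tractable on one core. For scopes below 8 K events the
neighbourhood shrinks (K′ = max(2, n/8)) so few-event populations — e.g.
plasma-cell isotypes at desk scale — can still form their own modes;
scopes of ≤ K events are classified per event as singleton clusters.

## Cluster classification and the hierarchy

Candidates are ranked by Mahalanobis distance from the cluster median to
each template; for successive competitor pairs a 2-D canonical plane is
fitted (generalised eigenproblem of between- vs pooled-within scatter; with
two populations the second axis is the leading within-scatter principal
direction orthogonal to axis 1), and the cluster joins the nearer template
iff its projected median falls inside that template's 2-SD ellipse.
Exhausting six pairs yields `unclassified` — or the nearest template when
force-assignment is enabled. Ties break toward the larger template, then
lexicographically.

The default stage plan: (1) major leukocyte lineages on scatter + CD45,
CD19, CD38, CD24, CD27, CD5 (doublet and debris templates compete here);
(2) B-lineage → pre-GC / memory / PC; (3) maturation classification of the
pre-GC and PC stage axes — events projected onto the piecewise-linear
trajectory through stage template locations, normalised arc-length cut at
the midpoints between stages (configurable), ties to the later stage;
(4–) per-compartment splits on their discriminating markers (CD62L/CD21
for naive, IgH class then CD21/CD20/CD27/CD24 for memory, IgH class per PC
stage). Events whose deeper stage rejects them keep the enclosing gate's
label, so per-stage counts are conserved. Classification at every stage is
against leaf-level templates, mapped up to the stage's output label.

The flat two-step comparator clusters all events once in the full marker
space against all templates. On synthetic cohorts it matches the
hierarchical strategy for abundant populations but degrades sharply for
rare ones (plasma-cell subsets), reproducing the qualitative advantage of
staged marker selection.

## Synthetic data

Each taxonomy leaf's symbolic phenotype becomes a numeric template:
band centres 0.5 / 1.6 / 3.0 / 4.6 (fluorescence neg/lo/pos/hi, SD 0.20),
1.5 / 2.6 / 3.8 for scatter (SD 0.22), `het` uniform on [1.5, 3.3] plus
Gaussian noise. These place every level ≥ 2.5 SD from its nearest
breakpoint so each rule term holds with probability ≥ 0.99 — a sharper
version of the generic level map one might first write down (SD 0.35 with
closer levels), which would violate the per-term self-consistency the
generator is required to have. Draws are independent per marker
(multivariate normal with diagonal covariance in transformed space);
FSC-H = FSC-A·(1 + ε), ε ~ N(0, 0.03), so singlets keep an area/height
ratio near 1.

Default frequencies (fractions of nucleated cells): B-lymphocytes 4.9%
(55% pre-GC / 45% memory, uniform across leaves within a compartment), PC
0.06%, neutrophils 55%, monocytes 8%, T cells 20%, NK 5%, eosinophils 3%,
remainder "other nucleated cells"; doublets 2% and debris 3% of total
events. Doublets are raw-space sums of two random singlets with pulse
areas added and height kept near the larger singlet. Cohort generation
jitters the B and PC totals log-normally (σ = 0.45 and 1.0) clipped to the
observed population ranges (0.5–13% and < 0.001–0.8% of nucleated cells),
major populations mildly (σ = 0.15), and within-compartment leaf weights
independently (σ = 0.25).

Maturation compartments are drawn as discrete stage blobs by default; the
dedicated continuum generator (`simulate_maturation_continuum`) spreads
events along the stage trajectory with planted change-points and is what
the maturation classifier is validated against. Keeping the default
discrete preserves an exact Boolean-gating oracle; real maturation
continua will blur stage boundaries in ways these tests do not measure.

What passing tests on this generator do **not** show about real data:
departures from per-marker Gaussianity (spectral spillover residue, batch
effects, autofluorescence tails), correlated marker expression within
populations, instrument drift other than the planted artifacts, and
phenotypes intermediate between taxonomy leaves.

## Statistics

Pearson r² on paired per-sample counts, with a sample entering a
population's pair set only when the population is quantifiable (> 50
cells; > 20 for PC subsets) in both tables and populations with < 3 pairs
or zero variance flagged not evaluable. CV = 100·SD/mean (sample SD).
Bland–Altman bias = mean difference, limits = bias ± 1.96 SD. Paired data
get the Wilcoxon signed-rank test (the paired analogue of the Mann-Whitney
U reported for unpaired data); Kruskal–Wallis is reported alongside.
P-values are raw by default — matching common practice of reporting
uncorrected per-population correlations — with Benjamini–Hochberg
adjustment available but off.

## Problem sizes

Defaults used by the shipped tests and the acceptance script: reference
databases from 5 training samples of 10⁵ events; validation cohorts of 20
samples × 10⁵ events; one 10⁶-event sample for label-recovery checks; the
36-file QC fixture at 10⁵ events per file with the proportionally scaled
B-singlet threshold. These sizes keep every full run in the minutes range
on a single core while leaving all quantifiable-population machinery
(including the > 20-cell plasma-cell rule) exercised.

## Known limitations

* The density/affinity separation score, the classification acceptance
  rule, and the stage marker subsets are reconstructions of an
  incompletely published procedure; all are config-accessible and the
  package's numbers should be read as properties of these definitions.
* The panel is modelled as 18 independent detectors; real 14-colour
  detector sharing among the 18 antibodies is not printed anywhere and is
  therefore not modelled.
* Expert review is modelled as an optional label-override input; headless
  auto-accept mode is what all tests exercise.
* Spillover handling is linear; no spectral unmixing.
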