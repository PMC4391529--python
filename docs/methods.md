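# Methods

This note documents the models, rules and numerical choices behind each
pipeline stage, what the synthetic-data generators do and do not emulate,
and the design decisions taken where the underlying procedure left room.

## Ortholog screen

**Model.** Presence of an osmolyte gene in a target organism is decided by
reciprocal best hit (RBH): align the seed protein against every protein of
the target proteome with local Smith–Waterman under affine gap penalties;
keep subjects with score ≥ `min_score` (default 100) and subject coverage
≥ `min_overlap` (default 0.75); among those, the hit with the highest
percent identity wins; the call is *present* only if that hit's own best
hit in the source proteome is the seed itself (exact id match — a paralog
winning the back-search yields *absent*). Identity is reported from the
forward alignment.

**Parameters and conventions.**

- Substitution matrix BLOSUM62, gap open 11, gap extend 1 (a gap of length
  L costs 11 + L). These are the most widely reproduced protein-alignment
  defaults; all three are configurable. The alignment engine is Biopython's
  `PairwiseAligner` in local mode; the test suite checks its scores against
  an independently coded full Gotoh dynamic-programming oracle, exactly, on
  hundreds of random pairs.
- Identity = identical columns / total alignment columns *including gap
  columns*. Conventions differ across tools, so this is fixed here.
- Overlap = subject-aligned span / full subject length ("75% of the hit's
  length", the hit being the found ORF).
- Tie-breaking in best-hit ranking: higher identity, then higher score,
  then lexicographically smallest subject id — output is deterministic.
- Comparison is protein-level only; nucleotide mode, domain annotation and
  remote database queries are out of scope (proteomes are local FASTA).

A score-only pass screens each subject before any traceback is computed;
tracebacks are only built for subjects that reach `min_score`, which keeps
full-proteome screens fast without changing any call.

## Transcriptome DE caller

**Model.** Arrays carry 9–11 probes per gene tiled across (−300, +200)
around the translational start (+1 = first base; there is no position 0).
Probe coordinates are *midpoint* offsets — the positional rule "downstream
of the start" is operationalized as midpoint offset ≥ +1. Passing probes
are averaged per gene and replicate (arithmetic mean of log2 ratios), and
a gene is differentially expressed iff its mean log2 ratio is > +1 (up) or
< −1 (down) **in every one of the three biological replicates**. The
inequality is strict, matching the printed rule; there is no p-value and no
multiple-testing correction — replicate-consistent fold change is the whole
criterion. Genes with no qualifying probes are reported `not_evaluated`
rather than `unchanged`, to keep downstream counts honest.

**Stress-comparison groups.** The direct sucrose-vs-NaCl contrast is
called with the same rule on sucrose/NaCl ratios. Group assignment, with
the direct-contrast route taking precedence:

- G1 — up in the direct contrast (higher under sucrose), else up only
  under sucrose;
- G2 — down only under sucrose;
- G3 — down in the direct contrast (higher under NaCl), else up only under
  NaCl;
- G4 — down only under NaCl.

The verbal definitions of these groups describe "lower under NaCl" and
"higher under sucrose" with the same direct-contrast direction; resolving
both to G1 (direct route) keeps the groups disjoint, and the
condition-exclusive routes then populate G1–G4 unambiguously. Genes regulated the same way under both
stresses with no direct difference belong to no group. Category summaries
count up and down calls separately per condition under the TIGR main role,
with unannotated genes pooled as "unknown".

## Proteome spot statistics

**Pipeline order.** (1) Normalize each spot volume to percent of its gel's
total detected quantity (the per-gel normalized sum is exactly 100). (2)
Eliminate spots whose normalized volume is < 0.02% on *all* images — one
image above the floor rescues the spot. (3) Standardize each spot's
relative volumes (mean-centre, divide by sample n−1 SD; a constant vector
is a flagged error). (4) One-factorial ANOVA per spot with a single
three-level condition factor (control, NaCl, sucrose) — both stresses
enter one analysis — at α = 0.1, p from the F distribution with
(k−1, N−k) df. F is scale- and shift-invariant, so it is identical on raw
and standardized values; the tests assert this identity rather than
guessing which variant was fed to the ANOVA. (5) Fold changes are ratios
of condition means of *normalized* volumes (standardized values are
dimensionless per spot and unsuitable for ratios); substantial iff the
ratio strictly exceeds 2-fold either way. (6) RSD = 100·sd/mean per spot
and condition; the QC summary reports the fraction of spots with
RSD < 35%. All printed cut-offs keep their printed strictness ("less
than", "exceeding", "at least").

**Identification rule.** A spot identification is accepted iff at least
two spectra reach a Mowse score ≥ 50 *and* sequence coverage is ≥ 30%;
if the score criterion holds but coverage fails, the spot is routed to
MS/MS (`needs_msms`); otherwise rejected. Spectrum processing and database
searching happen upstream and are out of scope.

## Metabolome quantification

Relative quantity = analyte peak area / ribitol peak area (ribitol is the
only standard used for normalization; norvaline and camphorsulfonic acid
are carried as QC columns). Condition means over three replicates are
tested against the control with a two-sided pooled-variance Student's
t-test (n₁+n₂−2 df); a Welch variant is available behind a flag but is not
the default, since the classic test matches the stated analysis and the
balanced n = 3 design. Significance is strict p < 0.05. Degenerate groups
(all values equal in both groups) give p = 1 for equal means and p = 0
otherwise; equality is detected by all-values-equal rather than zero
computed variance, which floating-point mean subtraction never achieves
exactly. Printed p values from the original experiments cannot be
recomputed without the per-replicate values, so they are not used as
oracles; the t-test is instead validated against an independently coded
closed-form (incomplete-beta) oracle to 1e-12.

## Treemap

The hierarchy is role → sub-role → operon → gene with leaf weight 1 per
gene (no other weighting rule exists) and internal weights as sums. The
layout is an ordered slice-and-dice partition: at each depth the parent
rectangle splits along one axis — alternating with level — into strips
proportional to child weights. This guarantees exact area-to-weight
proportionality, sibling disjointness, parent containment, and
edge-adjacency of genome-consecutive leaves within an operon (they are
laid along a single axis in genome order); published treemaps of this kind
often use Voronoi cells, and the rectangular layout is a deliberate
divergence chosen for testability of exactly those geometric guarantees.
Sibling order at every level follows the smallest genome-order index in
the subtree, so consecutive genes map to consecutive cells. Aspect ratios
are unconstrained by the algorithm; `min_leaf_aspect` exposes the worst
leaf for layout sanity checks.

Colors: a diverging blue (−) – grey (0) – orange (+) ramp, linear per RGB
channel, saturating at |log2| = `clip` (default 2.0 — two-fold beyond the
DE threshold); missing values are dark grey. Exact hues are configurable;
the defaults are mid-grey (150,150,150), blue (0,80,220), orange
(235,130,0), dark grey (70,70,70). mRNA values color the gene circles
(radius 30% of the shorter cell side) and the operon connectors (drawn
centroid-to-centroid beneath the circles); protein values color the cells.
SVG output is plain deterministic markup — identical inputs give
byte-identical files, and element classes (cell/gene/connector/border)
make rendered counts machine-checkable.

## Synthetic data

The generators produce the post-extraction tables each stage consumes,
with the planted truth returned alongside. Defaults describe the intended
study conditions: 3 replicates, 9–11 probes per gene on (−300, +200),
log2 effect 2.0, probe noise SD 0.2 log2 units, 200 genes/spots, 10% spot
and peak CV, 3-fold planted spot changes, orthologs planted at identities
0.4–1.0 with length 300 and 20 random decoys. The magnitude of probe-level
noise is not prescribed anywhere; 0.2 log2 units is a typical two-color
array replicate scatter and is a free parameter.

- **Genome pairs.** Orthologs are planted by substitution-only point
  mutation (no indels), so realized identity is exactly 1 − mutations/length
  (within 1/(2L) of the request); indel robustness is exercised by
  handcrafted fixtures instead. Decoys are i.i.d. random residues.
- **Probe tables.** Per-gene true levels are 0 or ±effect, drawn
  independently per stress; the direct contrast is their difference;
  Normal noise on the log2 scale is added per probe, replicate and
  contrast. Offsets are drawn uniformly from the window minus position 0,
  so ~40% of probes survive the positional filter.
- **Spot tables.** Abundances are planted in compositional space: gel
  shares sum to 1 by construction, planted spots get share × fold under
  stress and the rest are uniformly rescaled — this mirrors the closure
  that 100%-of-gel normalization enforces and makes the noiseless
  normalized ratio of a planted spot exactly the planted fold. Planting is
  restricted to below-median-abundance spots so the closure shift of
  unplanted spots stays well inside the two-fold window (regulated
  synthesis spots are rarely the dominant housekeeping spots). A few faint
  spots are planted below 0.02% on every gel. Volumes are lognormal
  (mean-one multiplicative noise at the requested CV).
- **Peak tables.** The ribitol area is fixed per sample; analyte areas are
  ribitol × target mean × mean-one lognormal noise, so the expected ratio
  equals the target and CV = 0 reproduces the targets exactly. The default
  targets are the published condition means of the six metabolites that
  change under hyperosmotic stress in *C. crescentus* (glucose, glutamate,
  phenylalanine, isoleucine, leucine, proline).
- **Annotation.** Genes in genome order are grouped into operons of 1–5
  consecutive genes sharing a (main role, sub-role) pair from a small
  TIGR-style catalogue.

All generators are deterministic under a fixed seed (byte-identical
outputs). What they do **not** emulate: scanner images, spot detection and
matching, chromatograms and spectra, array normalization and dye bias,
probe-specific affinity differences, correlated noise between replicates,
and operon-level expression correlation. Passing tests therefore
demonstrate that the statistical rules are implemented exactly and recover
planted structure under the stated noise models — not that the pipeline is
robust to the artefacts upstream image- and spectrum-processing software
must handle.

## Problem sizes and numerics

The test suite and the acceptance script run at desk scale, chosen to make
every check sharp while completing in seconds: 500 random pairs (length
≤ 30) for the exact alignment-oracle comparison, 50 planted orthologs
(length 200, identities 0.4–1.0) among 20 decoys for RBH recovery, 200
genes (20 up / 15 down) for the DE oracle, 2000 null spots for the ANOVA
α-calibration (binomial SE ≈ 0.007 at α = 0.1, checked within ±0.02), and
100 random hierarchies (≤ 50 leaves) for treemap geometry. Exact
identities (normalization sums, F = t², standardization invariance,
closed-form t-test) are asserted at 1e-9–1e-12; planted-truth recoveries
are exact set equalities. Headline counts from the original experiments
(e.g. hundreds of DE genes from the deposited arrays) depend on the real
array design and images and are outside what synthetic data can or should
reproduce.
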