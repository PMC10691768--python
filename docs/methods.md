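# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the simulator does and does not emulate, and
the numerical conventions that make runs deterministic.

## Study design and data model

The transcriptomic arm assumes a 2×2 factorial: an early-life adversity
(ELA) background factor crossed with an acute-stress factor, giving four
conditions (Bl Ctrl, Bl Stress, ELA Ctrl, ELA Stress).  Each of three
replicate groups contributes one sample per condition (12 samples), and the
group doubles as the batch: condition contrasts are estimated *within* a
model that carries the group as a covariate, never by batch-correcting the
expression values themselves.  Cluster labels are an input — clustering and
cell-type annotation are upstream concerns of standard toolchains and are
deliberately not reimplemented here.

## Synthetic data

`simulate.generate_counts` draws counts from a gamma–Poisson (negative
binomial) model: for gene *j*, cell *c* in cluster *k*, sample of condition
*t* and group *g*,

    mu = exp(base_jk + template_j[t] * effect * ln 2 + batch_g) * s_c
    count ~ NB(mean = mu, dispersion = theta)

* **base_jk** — per-gene baseline log-mean, uniform on (−2, 1.5), plus a
  per-cluster N(0, 0.3) shift so clusters are distinct.  These defaults
  give a median cell depth of roughly 2,500 counts with a spread that
  straddles the 1,000-count QC floor, so the QC stage always has real work
  to do.
* **templates** — each of the eight pattern types is encoded as a template
  over the four condition means with entries in {0, ½, 1} (the inverted
  types put both controls at the intermediate level with
  opposite-direction stress responses); `effect_size` scales the template
  in log2 units.  Injected genes are given a fixed baseline log-mean of
  0.5 (count mean ≈ 1.6) so a 1.5-log2FC effect clears the DEG
  mean-expression filter; detection power is then a property of the
  method, not of an invisible baseline lottery.
* **dispersion** — shared theta = 2 (variance = mu + mu²/2), a typical
  droplet-data value; per-gene dispersion is not modelled because no
  downstream stage estimates it.
* **batch** — one N(0, 0.15) additive log-offset per group, shared by the
  group's four samples, reproducing the group-confounded batch structure
  the DE model is built to absorb.
* **size factors** — lognormal(0, 0.35) per cell.  Library-size
  variability across samples is not separately modelled; the per-cell
  factor subsumes it.
* **mitochondrial genes** — 5% of genes; each cell's expected
  mitochondrial share is Beta-distributed with mean 0.08 and concentration
  30, so a few percent of cells exceed the 0.2 QC ceiling.

Default cluster sizes are (120, 60, 20) cells per sample — totals 1440,
720, 240 — the smallest design that exercises the 300-cell cluster
eligibility rule in both directions.

Not emulated: doublets, ambient RNA, UMI saturation, per-gene dispersion
heterogeneity, zero inflation beyond NB, spatial or temporal structure.
Passing recovery tests therefore demonstrate correctness of the analysis
logic under the stated noise model, not robustness to every artefact of
real droplet data.

The behavioural generators follow the same philosophy: chases are binomial
within dyads with win probability logistic in rank difference (steepness 0
= fair coin; large steepness = deterministic transitive hierarchy), and
tube-test behaviours are built so a pair's dominant animal has expected
forward time above its retreat time.

## QC and normalization

Cells are removed when depth < 1000 or > 30,000, detected genes < 500, or
mitochondrial fraction > 0.2; genes expressed in fewer than 10 surviving
cells are then removed.  All inequalities are strict, so a cell exactly at
a threshold is kept — the literal reading of "below/above" wording, and
the convention the boundary tests pin down.  Filtering only ever subsets;
it never modifies counts, and applying it twice equals applying it once.

Normalization divides each cell by a size factor and applies log(x+1)
(natural log; the base is recorded in the matrix provenance, and fold
changes are re-expressed in log2 units where reported).  The default
factor is depth / median depth; externally computed factors (e.g. from
pooled deconvolution) can be injected instead — the algorithm itself
belongs to its published implementation and is not cloned here.  Doublet
detection is likewise out of scope and recorded as skipped in the QC
report.

## Differential expression

Within each eligible cluster (≥ 300 cells) and each of the four pairwise
comparisons, every gene is fit by ordinary least squares on
`1 + condition + batch` using the log-normalized values, and the condition
coefficient's Wald statistic (coefficient / standard error) is referred to
the standard normal.  A Gaussian model on log expression was chosen over
an NB count model because the modelled response is explicitly the
log-normalized value; with a single batch level the statistic collapses
exactly to the pooled two-sample t statistic, which the tests assert to
1e-10.  Pairwise fitting (rather than one four-level model) is used
because condition and batch are categorical and the design confounds
nothing across pairs, so pairwise fits give the same contrasts at lower
cost.

Degenerate genes (zero variance in both condition groups) get p = 1 and
log2FC = 0 with a flag.  Designs where condition is nested within batch
are rejected as unidentifiable rather than silently dropped to a smaller
model.  P values are BH-adjusted within each (cluster, comparison) stratum.
DEGs require q < 0.05, mean log-normalized expression ≥ 0.5 in at least
one condition, and |log2FC| ≥ 0.5 (boundary kept); log2FC is the
difference of per-condition means of log-normalized expression divided by
ln 2 — consistent with modelling log expression, and identical to the
model coefficient in balanced single-batch designs.

## Patterning

For each cluster the four comparisons' DEGs are unified (sorted set
union); genes missing any of the four fold changes are excluded rather
than imputed with 0, which would deflate the interaction score
asymmetrically.  The PatternScore |FC_a − FC_d| + |FC_b| + |FC_c| is
non-negative by construction and needs no clamping.

The eight type scores are evaluated on the four per-condition means of
log-normalized expression — the same means used in DEG filtering — scaled
so the maximum is 1.  The two-condition combiner ‖x, y‖ is the arithmetic
mean (a "max" alternative is available but non-default): the mean is the
symmetric choice under which each canonical template reaches a score of
exactly 1 for its own type.  Scores are clamped at zero (the defined
minimum); raw pre-clamp values are kept for diagnostics.  Classification
takes the argmax of the clamped scores, with ties broken in the fixed
label order Chronic < Inverted < Primed < Blunted (Up before Down) and
flagged.

**Known limitation — classification degeneracy.**  The type-score algebra
does not separate all eight types at their own canonical templates: a pure
primed-up gene with means (c, c, c, 1) scores exactly (1 − c) for *both*
PrimedUp and InvertedUp, and a pure blunted-up gene ties BluntedUp with
InvertedDown the same way.  Under sampling noise the Inverted scores are
systematically favoured (they subtract one absolute-noise penalty term
where Primed/Blunted subtract two), so argmax classification of true
primed/blunted genes resolves to an Inverted label in roughly 70% of
cases at *any* noise level — the effect is scale-free and does not vanish
with more cells.  Chronic and Inverted genes classify essentially
perfectly; for Primed/Blunted biology the per-type score totals and
distributions (`cluster_patterning_summary`) are the meaningful readout,
and the assigned label should be interpreted jointly with the tied family.
The test suite asserts this degeneracy explicitly.

Ranking returns the top (or bottom) *n* genes by PatternScore, ties
lexicographic by gene id.  The score tiers used for enrichment export are
top floor(n/4), bottom floor(n/4), middle remainder, assigned on the
global (score desc, gene id) order so boundary ties never change tier
sizes.

## Dominance statistics

Dyadic proportions P_ij = wins_ij / (wins_ij + wins_ji); dyads that never
interacted contribute 0 in both directions (the plain David's-score
variant; the dyad-frequency-corrected variant is deliberately not the
default).  David's score DS = w + w2 − l − l2 sums to zero over the group
— asserted exactly against a brute-force reimplementation.  Cumulative
scores sum daily scores; ranks break ties by total wins, then id order,
and flag them.

Tube-test z-scores use the population (divisor n) standard deviation: the
tested cohort is the entire population of interest, and the ±1 result for
a pair is the natural reading.  The composite divides the sum of the four
behaviour z-scores by the number of behaviours (4).  The retreat component
enters with sign +1 by default — exactly as the formula is stated — with a
configurable sign for users who prefer retreating to count against rank;
constant behaviours z-score to 0 with a degeneracy flag.

## Determinism and numerics

Every generator consumes a single integer seed through
`numpy.random.default_rng`; the pipeline writes CSVs with a fixed `%.10g`
float format, so identical config + seed gives byte-identical data
outputs (the run manifest differs only in its recorded output path).
Degenerate inputs (all-zero condition means, constant vectors, empty
strata) return flagged zeros or explicit errors, never NaNs.  Test and
acceptance problem sizes (2,000 genes, 2,400 cells, 10–20 simulation
replicates) were chosen as the smallest sizes at which the recovery
properties are stable.
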