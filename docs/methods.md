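# Methods

`scfate` models the earliest fate-commitment events of cytokine-stimulated
human CD34+ hematopoietic stem and progenitor cells along two coupled axes:
population structure in single-cell qRT-PCR expression snapshots, and
dynamic morphology phenotypes in time-lapse clone pedigrees. This note
records the models, the defaults and why they were chosen, the numerical
conventions, and what the synthetic-data generator does and does not
emulate.

## Spike-referenced expression values

A Biomark-style run reports a cycle-threshold Ct per (cell, assay) reading
with a quality flag, plus two exogenous spike-in channels added at a fixed
amount per cell. Quality filtering proceeds in two steps: `Failed` or
`Inconsistent` readings become missing per gene, and any cell whose spike1
or spike4 reading is missing or flagged is dropped entirely (without a
valid reference, nothing in that cell is interpretable). Expression is
then

    dCt = sqrt(Ct_spike1 · Ct_spike4) − Ct_gene,

the geometric mean of exactly two spike channels; tables offering more
spike channels are rejected rather than silently averaged, to stay
bit-faithful to the two-channel rule. Higher dCt means higher expression —
the subtraction order matters and is asserted in tests to prevent sign
drift. Values below the detection floor of −17 cycles, and genes not
detected at all, are assigned −17. The QC report distinguishes
`assigned_floor` (non-detected) from `measured_below_floor` so the two
cannot be conflated downstream. "Inconsistent" is operationalised as
duplicate assay readings disagreeing by more than one cycle (or disagreeing
in detection) when duplicate columns exist; single readings are never
inconsistent.

## Cluster-number selection: the gap statistic

For candidate k = 1..k_max, `W_k` is the within-cluster sum of squares of a
k-means fit (10 restarts inside the gap loop; the final fit at the selected
k uses 25 restarts, ties broken by inertia). The reference null draws B
datasets uniformly over the bounding box of the data expressed in its
principal-component basis — the rotation-robust variant, chosen because
panel genes are strongly correlated and an axis-aligned box would inflate
the reference dispersion. With `Gap(k) = E*[log W_k] − log W_k` and
`s_k = sd*[log W_k]·sqrt(1 + 1/B)`, the selected k is the smallest k with
`Gap(k) ≥ Gap(k+1) − s_{k+1}`; a constant matrix short-circuits to k = 1
with a warning. Defaults: k_max = 6, B = 50. Floored (−17) values
participate in k-means, PCA and t-SNE as ordinary numbers, matching how
dense heat maps treat them.

## Correlation-burst transition indicator

Within a cell group, the indicator is the number of gene pairs whose
Pearson r exceeds 0.8 (signed; an absolute-value mode is available). A
transient rise in this count inside one cluster marks an imminent state
transition. Genes detected in fewer than `min_detected` (default 10) cells
of the group are excluded: a floor-dominated gene is nearly constant and
yields spurious r. By default each pair's r is computed over the cells in
which **both** genes are detected, and pairs with fewer than
`min_detected` jointly detected cells carry no edge. The floor value is a
censoring sentinel rather than a measurement, and including it is not
innocuous: a single floored reading in one gene of a genuinely coupled
pair (population r ≈ 0.9) drags the sample r to ≈ 0.65 and erases the
edge. The literal all-cells computation remains available via
`observations='all'`. Groups smaller than 10 cells are skipped with a
warning.

## Expression simulator

Each simulated cell occupies one of five states. Per state, a gene's
detected dCt is

    mean + sd · (ℓ·z_cell + sqrt(1 − ℓ²)·ε),

with one standard-normal latent factor `z_cell` shared by all genes of the
state's active module, so the population correlation between two module
genes is ℓ². Defaults (dCt cycles):

| state       | active module | detection | mean | sd  | loading ℓ |
|-------------|---------------|-----------|------|-----|-----------|
| quiescent   | —             | 0.15      | −10  | 2   | 0         |
| multiprimed | —             | 0.70      | −4   | 3   | 0         |
| lineage1    | lineage1      | 1.00      | 2    | 2   | 0.80      |
| lineage2    | lineage2      | 1.00      | 2    | 2   | 0.80      |
| transition  | lineage1      | 1.00      | 2    | 2   | 0.95      |

Genes outside the active module follow a baseline law (detection 0.30,
mean −8, sd 2, uncorrelated). The quiescent state is sparse and silent;
the multiprimed state up-regulates the whole panel promiscuously but
without coordination (loading 0 by construction — config validation
rejects a moduleless state with positive loading); the two lineage-primed
states express disjoint modules; the transition state shares the lineage1
module with a stronger coupling, producing the correlation burst. Active
modules are detected with probability 1: strongly expressed transcripts
are essentially always above threshold, and occasional floor dropouts
would otherwise dominate the pairwise correlations that define these
states. The default 90-gene panel splits 10/15/15/50 into
stem/lineage1/lineage2/background. Spike Cts are drawn independently per
channel around 13.5 ± 0.25 cycles, and a configurable fraction of gene
readings (default 2%) is flagged `Failed` to exercise QC.

Sorted fractions emulate gating on a surface marker: `high` draws from
lineage1, `low` from lineage2, and `medium` mixes both plus a configurable
share of cells with interpolated parameters loading both modules on one
shared factor — intermediate cells that co-locate with both clusters.

## Pedigree simulator

Each clone starts from one founder at t = 0. The first cell cycle is
log-normal parameterised by its median (58 h, log-sd 0.16) and truncated
by rejection to [35, 80] h — strictly positive, right-skewed, and spanning
the observed founder-division window. Later cycles are normal (21 ± 2 h,
truncated below at 8 h). Dynamic phenotypes P (stable-polarised),
S (frequent-switcher) and R (stable-round) are heritable: at each division
both daughters draw their phenotype from the mother's row of a
row-stochastic 3×3 inheritance matrix, independently by default
(`correlated_sisters` makes them share one draw; sister concordance then
emerges from the shared phenotype rather than being imposed). The default
matrix is

    P → (0.60, 0.25, 0.15)
    S → (0.00, 0.25, 0.75)
    R → (0.00, 0.00, 1.00)

Only the S→S entry (a quarter of switcher daughters conserve the
phenotype) and the absorbing R row (round mothers only ever produce round
daughters) are empirically anchored; the other entries are free defaults
and overridable. The two anchored constraints are in mild tension with
the observation that switchers arise only from polarised mothers; the
default honours the quantitative 25% statement, and the stricter
behaviour is reachable by setting the S row's S entry to zero.

Morphology within a cell's lifetime is a two-state continuous-time Markov
chain between `polarised` and `round` with phenotype-specific rates
(per hour): P (0.01, 0.50), S (0.50, 0.50), R (0, 0) starting round.
These reproduce the three archetypes — P: roundness ≈ 0.02 and ≈ 0.02
switches/h; S: roundness 0.5 and 0.5 switches/h (rapid switching with no
stable intermediate); R: roundness 1, no switches. Exact jump times are
simulated and then *observed* on a 1-minute frame grid, as a time-lapse
camera would; excursions shorter than one frame are unobservable by
construction. Cells alive at `observation_end` (default 168 h, a 7-day
recording) are right-censored with no division time. All randomness flows
from a single seed through `numpy` SeedSequence spawning; per-clone
streams are independent.

## Lineage analysis

Tracks are normalised on load: consecutive same-shape intervals are
merged and gaps shorter than one frame are closed by extending the
earlier interval, so annotation artefacts cannot inflate the switch
count. Per cell, roundness = time round / (time round + time polarised)
over the observed lifetime (not the cycle length, so censored cells
remain usable), switch frequency = shape-change boundaries per observed
hour, and cycle length is reported only for division-ended cells.
Founders may optionally have their first hours trimmed (recovery from
isolation stress); default off.

Phenotype classification runs k-means (k = 3, 25 restarts) on z-scored
(roundness, switch frequency) — cycle length is display-only by default,
with a 3-feature mode available — and maps clusters to labels by centroid
rules: highest mean switch frequency → S; of the rest, lower roundness →
P, higher → R. Because R denotes morphological *stability*, cells swept
into the R cluster despite switching more often than 0.12/h are
relabelled S; without this rule a few round-biased true switchers would
acquire P/S daughters "from an R mother" and break the closure property.
A fixed-cutoff mode (`thresholds`) is also provided. An input in which
all cells are identical is refused rather than labelled arbitrarily.

The inheritance matrix is estimated by counting labelled mother→daughter
edges (founders enter only as mothers) and row-normalising; rows with no
edges are flagged `no_data`. Sister pairs with complete cycle lengths are
compared by Euclidean distance over z-scored (cycle length, roundness,
switch frequency) — standardisation is the default because hours would
otherwise dominate two dimensionless features; a raw mode exists — and
split by k-means (k = 2) on the distances, the lower-centroid group being
"similar". Switching rates are recovered by the exact CTMC maximum
likelihood for continuously observed paths: rate = transitions out of a
shape / total time in it, with standard error rate/√count; a direction
with zero time in the source shape is reported as undefined (NaN), not 0.

## What the generator does not emulate

No image formation, segmentation or tracking noise; no apoptosis; no
surface-marker intensities beyond the high/medium/low fraction labels; no
donor or batch structure (labels are carried through but no correction is
applied); no pre-amplification efficiency differences between assays.
Passing tests therefore demonstrate correctness of the statistical
machinery under the generative assumptions above, not robustness to
segmentation errors or assay-specific amplification bias in real exports.

## Numerical conventions and degenerate inputs

Non-detected readings are encoded as an empty Ct field, never 0 or 999.
Geometric means require strictly positive spike Cts; violations raise.
k-means ties resolve by lowest inertia; the gap loop derives per-fit seeds
from one generator so runs are reproducible end to end. Correlation of a
constant gene is treated as 0 (no edge). `cycle_length_stats` on fully
censored input returns an empty table with a warning rather than raising.
The published per-cell spreadsheet behind the founder-cohort statistics is
not redistributed; `scfate.reference` carries a synthetic 32-founder
cohort constructed to satisfy exactly the printed summary statistics
(median 58 h, range 35–80 h, 11 divided by 48 h, 3 undivided at 72 h) so
that the summarising code can be exercised against them.

## Problem sizes used in the shipped checks

The test-suite and acceptance-script runs use 100 cells per expression
state (90 genes), 200–450 clones over three generations for pedigree
statistics (yielding ≥ 400 switcher-mother edges and ≥ 500 total
transitions), 50 seeded repetitions for the single-blob gap-statistic
calibration, and 200 tracks × 20 h for switching-rate recovery. These
sizes put Monte-Carlo error comfortably inside each asserted tolerance.
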