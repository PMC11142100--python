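# Methods

## Model and procedure

### PSI quantification

An annotated splicing event consists of ≥2 sub-junctions (1-based inclusive
genomic coordinates internally; BED-like files on disk are 0-based
half-open and say so in their header). For each event and sample, the usage
of sub-junction *j* is reads(j) / Σ reads over the event's annotated
sub-junctions — no gene-level normalization. The whole (event, sample) cell
is **missing** (not 0) when the denominator falls below
`junction_min_reads` (default 5, matching the junction-read floor used by
junction-centric splicing callers). PSI is the usage of the event's
*representative* sub-junction:

| class | representative sub-junction |
|---|---|
| cassette exon, intron retention | the flagged inclusion/retention junction |
| alt. 5'/3' splice site, mutually exclusive exons | the transcript-upstream junction (smallest genomic coordinate on +, largest on −) |
| composite | the most upstream sub-junction by genomic (start, end) |

An event is *detected* in a cell type when PSI is non-missing in ≥ n−1 of
its n replicates, the standard tolerance for one failed replicate. An event
is *alternative* when its replicate-mean PSI within at least one cell type
lies in [0.10, 0.90], boundaries inclusive; the band is applied to
cell-type means rather than single replicates because means are more
stable at 2–8 replicates (per-replicate application is the plausible
alternative). Alternative 5'/3' splice-site events with more than two
candidate coordinates are excluded from splice-site analyses; the rule is
deliberately scoped to those two classes.

### Pairwise differential splicing

Every ordered pair of cell types is compared (N·(N−1) comparisons; both
orders are reported, and each unordered pair is computed once and mirrored,
which makes ΔPSI antisymmetry exact). Per pair and per detected-in-both
event, replicate PSI values are compared with a two-group location test:

- both groups constant: p = 0 if the means differ, p = 1 if equal
  (degenerate inputs, used by the exact bound constructions);
- both groups ≥2 replicates: Welch t-test;
- a group reduced to one replicate: exact permutation test over all
  C(n₁+n₂, n₁) relabelings of the difference of means (two-sided,
  observed labeling included).

Welch is the primary test deliberately. The exact permutation p at 4v4
replicates cannot go below 2/70 ≈ 0.029; after BH correction within a
family of tens of events the smallest attainable q is ≈ 1, i.e. a discrete
permutation p combined with small BH families has no power at all. The
Welch p is continuous and approximately calibrated at these replicate
counts (the null simulation below confirms type-I control after the BH and
effect-size gates). The permutation test is kept as a public method
(`two_group_test(..., method="permutation")`), is validated against
explicit enumeration, and serves as a rank-order cross-check of the Welch
p in the test suite.

q-values are Benjamini–Hochberg step-up within each (pair × splicing
class) family, mirroring per-run FDR reporting of pairwise splicing
callers. A call is significant iff |ΔPSI| > `delta_psi_min` (0.10, strict)
AND p < 0.05 AND q < 0.05. Events undetected in either cell of a pair are
skipped for that pair, not failed.

### Uniqueness index

For focal cell *c* and event *e*: U(e,c) = Σ over other cells c′ of the
**oriented first ΔPSI** of the (c, c′) comparison when significant, else 0.
The first ΔPSI is the ΔPSI of the sub-junction with the smallest genomic
start (ties broken by smaller end — a convention; exact start ties with
distinct ends occur for alternative 3' splice sites, where all candidate
junctions share a donor). Orientation: the first ΔPSI of A3S events on the
+ strand and A5S events on the − strand is negated before summation, which
makes the index of one splice-site preference identical on both strands
(verified end-to-end in the tests). Composite events use the same
most-upstream rule with no reversal. The reversal is an involution;
applying it twice restores the raw ΔPSI.

Because non-significant and undetected comparisons contribute exactly 0
(while still counted in `n_compared`), |U| ≤ n_significant ≤ N−1, in
fractional PSI units — hence the printed bound of ±45 at 46 cell types,
attained exactly by the constant 1.0-vs-0.0 construction, and U = 0 for an
event spliced identically everywhere.

The expression variant replaces ΔPSI by log₂FC = log₂((mean CPM₁ + 1) /
(mean CPM₂ + 1)) with the same location test applied to log₂(CPM+1), gated
at p < 0.01 and |log₂FC| > 2, and sums significant log₂FC over the focal
cell's pairs. Summing log₂FC (rather than counting significant pairs) was
an open design choice, made for symmetry with the splicing index; it is
this package's convention, with the planted-gene expectation
(N−1)·log₂(fold) for a clean separation. An optional gene-subset filter
supports restricted analyses (e.g. RNA-binding proteins only).

### Global summaries

- **Per-pair count matrix**: significant events per (class, cell, cell);
  the single-count floor applies because an event can be called at most
  once within one comparison.
- **Global totals**: an event (and its gene) enters class totals only when
  called differential in ≥ `global_min_comparisons` (5) pairwise
  comparisons. The source wording ("minimum threshold of 5 counts of
  alternative splicing events") is ambiguous — it could mean 5 junction
  reads, but that floor already exists separately — so it is read as 5
  pairwise calls.
- **Class correlations**: OLS adjusted R² = 1 − (1−R²)(m−1)/(m−2) between
  per-comparison counts of each pair of categories over m unordered cell
  pairs (unordered, to avoid double-counting antisymmetric duplicates);
  constant vectors yield 0 with a warning.
- **Outlier cells**: per-cell totals over its N−1 comparisons with robust
  z = (total − median)/MAD, flagged at |z| > 3.5. The cutoff is a defined
  stand-in for what is visually evident in per-cell scatter.
- **Directional bias**: among a cell's nonzero-index events of one class,
  the fraction with positive (upstream after orientation) index; undefined
  (None, never 0) when no nonzero records exist. Mirroring every PSI
  x → 1−x maps bias b → 1−b, which is tested.
- **Mega matrices**: per class, event × cell-type matrix of replicate-mean
  representative usage; a cell entry is missing unless the event passes
  the (n−1) detection rule there. The per-cell spatial export prints the
  same values in percent (one decimal).

## Synthetic data

The generator emulates the structure of deep sorted-cell RNA-seq: defaults
of 46 cell types × 4 replicates, six event classes with 40 events each
(240 events — a desk-scale stand-in for datasets with tens of thousands of
events), mean total junction depth 200 reads/event/sample, and 5% of
events planted as cell-unique with a PSI shift Δ = 0.6.

Per event, a baseline mean PSI is drawn uniform on [0.1, 0.9]; planted
events shift the focal cell's mean by ±Δ, choosing the direction that
avoids clipping to [0.02, 0.98] where possible (the clip bounds avoid
degenerate zero-variance groups except in the explicit bound
constructions; a configuration that clips >50% of planted events raises).
Replicate PSI ~ Beta(μκ, (1−μ)κ) with κ = 100 (replicate SD ≈ 0.04 at
μ = 0.5, the "reproducible cell" regime; lower κ mimics variable cells);
total reads ~ Poisson(depth); representative-junction reads ~
Binomial(total, PSI), remaining reads split across the other
sub-junctions. Strands alternate within every class so both reversal paths
are exercised. Coordinates follow class-appropriate geometry (shared donor
for A3S, shared acceptor for A5S). Expression counts are negative binomial
(lognormal gene means around 100, dispersion 0.1) with planted genes up
16-fold in one cell type.

The ground-truth table records, per planted event, the
representative-junction effect and the expected *oriented* index sign
(derived from the planted shift, the first-junction identity and the
reversal rule), making sign-recovery checks well-defined for
reversal-class events; orientation correctness itself is established
against hand-computed cases, not against the generator.

What the simulation does **not** capture: mapping and annotation errors,
shared splicing programs across related cell types (every non-planted
event has one global mean), correlated replicates, library-size variation
within a cell type, >2-coordinate splice-site events, and expression–
splicing coupling. Passing recovery tests therefore demonstrates the
pipeline's correctness and power under idealized noise, not performance on
real libraries.

## Numerical choices and degenerate inputs

- PSI stored as fractions; percent only at display boundaries.
- Missing ≠ 0 everywhere (empty TSV fields, NaN internally).
- Permutation ties counted with a 1e−12 absolute tolerance; pooled n for
  the exact test capped at 16 (12,870 relabelings).
- A Welch p of NaN (possible only for degenerate inputs outside the
  permutation branch) is mapped to 1.0, conservatively.
- Ranking tie-breaks are deterministic: |index| descending, then
  feature id, then cell. Writers emit fixed column orders and fixed float
  formats, so identical inputs give byte-identical files.
- All randomness flows from a single integer seed per run.

## Problem sizes used in the checks

The bound constructions run the full 46-type pipeline (2,070 ordered
comparisons) on one event. Planted-event recovery uses the full default
configuration (46 × 4, 240 events, Δ = 0.6, 5% planted; top-decile and
≥95% sign-agreement checks). Type-I control uses a 12-cell-type null
simulation (Δ = 0, nothing planted) and checks the significant-call
fraction against the nominal q with binomial slack. Oracle equivalence
re-sums 200 random comparison sets of ≤6 cell types with an independent
double loop.

## Known limitations

- The two-group Welch test stands in for a full count-based (e.g.
  beta-binomial GLM) differential-splicing model; it ignores depth
  differences between replicates beyond the detection floor.
- The expression test is a CPM/Welch emulation of a negative-binomial DE
  model, not a reimplementation of one; shrinkage and dispersion sharing
  are out of scope.
- With 2 replicates the n−1 detection rule admits single-replicate cells,
  where the location test has little power and falls back to permutation.
- The ≥5-comparison global threshold and the MAD outlier rule are defined
  interpretations of informally stated criteria; both are configurable.
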