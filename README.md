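# spliceuniq

Cell-specific alternative splicing analysis: all-pairs differential PSI
across cell types and the signed **uniqueness index** that pinpoints
splicing events (or genes) regulated uniquely in a single cell type.

The package is aimed at analyses of deep, sorted-cell-type RNA-seq
resources — the motivating case is *C. elegans* neuron-type transcriptomes
(46 neuron types, 2–8 biological replicates each) — where the question is
not "which events are alternative?" but "which events mark exactly one
cell type?".

## The method

For every splicing event, junction-spanning read counts per replicate are
normalized into **PSI** (percent spliced in): the usage fraction of the
event's representative sub-junction — the inclusion junction for cassette
exons and retained introns, the transcript-upstream junction for
alternative 5'/3' splice sites and mutually exclusive exons. An event is
detected in a cell type when ≥5 junction reads are present in at least
n−1 of its n replicates.

Differential splicing is then called for **every ordered pair** of cell
types (N cell types → N·(N−1) comparisons; 46 types → 2,070). An event is
significant in a pair when |ΔPSI| > 0.10, p < 0.05 and Benjamini–Hochberg
q < 0.05, with q-values computed within each (pair × splicing-class)
family.

The **uniqueness index** of event *e* in focal cell *c* is

&nbsp;&nbsp;&nbsp;&nbsp;U(e, c) = Σ′ over other cells *c′* of ΔPSI₁(e; c, c′)

where ΔPSI₁ is the "first ΔPSI" — the ΔPSI of the event's most upstream
sub-junction by genomic coordinate — and Σ′ sums significant comparisons
only (everything else contributes exactly 0). To keep the sign convention
consistent across strands, the first ΔPSI of alternative 3' splice sites
on the + strand and of alternative 5' splice sites on the − strand is
reversed before summation. With N cell types the index is bounded by
±(N−1): with 46 cell types, +45 means 100% inclusion in the focal cell and
0% everywhere else, −45 the mirror image, and 0 no systematic difference.

The same construction applies to gene expression (sum of significant
log₂ fold changes, p < 0.01 and |log₂FC| > 2), e.g. to rank RNA-binding
proteins or GPCRs uniquely expressed in one cell type.

A beta-binomial simulator generates study-shaped datasets (46 cell types ×
4 replicates, six event classes, ~200 junction reads per event-sample)
with planted cell-unique events, so every stage is testable without any
sequencing data.

## Worked example

```python
from spliceuniq import synthetic, events, pairwise, uniqueness

config = synthetic.SimConfig(n_cell_types=8, n_replicates=4,
                             events_per_type={t: 10 for t in synthetic.AS_TYPES},
                             planted_fraction=0.1, seed=4)
counts, annotations, sample_map, truth = synthetic.simulate_splicing(config)
psi = events.compute_psi(counts, annotations, sample_map)
comparisons = pairwise.run_all_pairs(psi, annotations)
records = uniqueness.rank_by_magnitude(
    uniqueness.uniqueness_table(comparisons, annotations))

print(f"{comparisons.n_ordered_pairs} ordered comparisons, "
      f"{int(comparisons.frame['significant'].sum())} significant calls")
for r in records[:6]:
    print(f"{r.feature_id:16s} {r.focal_cell}  index={r.index:+6.2f}  "
          f"significant in {r.n_significant}/{r.n_compared}")
```

prints

```
56 ordered comparisons, 84 significant calls
COMPOSITE_0000   CT2  index= -4.39  significant in 7/7
COMPOSITE_0005   CT7  index= +4.30  significant in 7/7
COMPOSITE_0004   CT1  index= -4.19  significant in 7/7
CASSETTE_0005    CT6  index= +4.04  significant in 7/7
A5S_0007         CT4  index= -3.97  significant in 7/7
A3S_0004         CT8  index= -3.93  significant in 7/7
```

The six records with the largest |index| are exactly the six planted
cell-unique events (compare `truth`): each was shifted by ΔPSI 0.6 in one
focal cell, was called significant against all 7 other cell types, and its
index ≈ ±7 × 0.6 with the expected sign.

The same pipeline is available from the shell:

```sh
spliceuniq run-all --workdir out --seed 4 --cell-types 8 --replicates 4
spliceuniq export --workdir out --event-id CASSETTE_0005   # spatial-heatmap TSV
```

which writes `psi.tsv`, `comparisons.tsv`, `uniqueness.tsv`, per-pair count
matrices, splice-class correlations, outlier-cell z-scores, directional-
bias fractions and one usage "mega matrix" per splicing class.

## Documentation

See `docs/methods.md` for the model, its assumptions, all tunable
parameters, and known limitations.
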