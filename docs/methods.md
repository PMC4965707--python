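# Methods

This note records the models, parameter choices and numerical decisions
behind omsweep, in the spirit of a software methods appendix: what is
computed, under which assumptions, and what the defaults mean.

## Data model

A **molecule** is a length `L` (bp) plus strictly increasing label
positions in `(0, L]` — the digital form of one imaged, nick-labeled DNA
molecule.  A **consensus map** (contig or reference) additionally carries
per-label `occurrence` (molecules in which the label was observed) and
`coverage` (molecules spanning its position), with
`occurrence ≤ coverage`.  Files use the standard text formats of the
platform: single-channel BNX 1.x for molecules (a `0` line with id and
length, a `1` line with positions, `QX` quality rows accepted and
ignored) and 9-column CMAP for consensus maps.  Positions are written
with one decimal, so round trips are stable to 0.1 bp; unknown header
keys survive round trips verbatim.

## Error model and simulator

The simulator draws molecules from a reference map and corrupts them with
exactly the error structure the aligner assumes:

* **False positives** — a Poisson process along the molecule at
  `fp_per_100kbp` (default 1.5), positions uniform.
* **False negatives** — independent dropout of true sites with
  probability `fn_rate` (default 0.15).  The defaults are the
  platform-recommended upper bounds for usable data; both are the
  assumption of *uniformly random* error placement that the alignment
  model shares.
* **Sizing error** — each inter-label gap `g` is perturbed by
  `N(0, (s·g/1000)²)` with `s = sizing_sd_bp_per_kbp`, then all gaps are
  rescaled to preserve molecule length (gaps are floored at 1 bp so label
  order is always preserved — no rejection sampling).  The default
  `s = 40` gives ≈400 bp at a 10 kbp interval, matching the magnitude of
  the standard variance-linear sizing model
  (`var = sf² + sd²·L`, `sf ≈ 0.2 kb`, `sd ≈ 0.1 kb^½` → ≈374 bp at
  10 kbp) at the modal interval length of an ~10.5 labels/100 kbp map.
  The linear-in-interval form is slightly pessimistic for long intervals
  and optimistic for very short ones.
* **Stretch** — a single global scale factor (default 1.0).  Only one
  factor is simulated; stretch is not a swept parameter.
* **Lengths** — `min + Exponential(mean − min)` in kbp, defaults
  `min = 100`, `mean = 163`.  The length-weighted median (molecule N50)
  of this law solves `(x + β)·e^{−(x−min)/β} = (min + β)/2`; at the
  defaults x ≈ 165 kbp, the N50 of the dataset the package's bundled run
  table summarizes.
* **References** — either in-silico digestion of a FASTA sequence (both
  strands, motifs merged into one channel, duplicate positions collapsed;
  defaults are the Nt.BspQ1/Nt.BbvCI motif pair) or a Poisson-placed
  synthetic map with a 500 bp minimum site separation emulating the
  optical resolution floor.

A truth sidecar records each molecule's origin interval, orientation, and
per-label provenance (true-site index or FP), enabling exact recovery
oracles.  Chimeric molecules, image-level artifacts and two-color
channels are not simulated; a `chimera_rate` knob is deliberately absent
rather than untested.  Everything is reproducible from `ErrorProfile.seed`.

What passing simulation-based tests shows is therefore internal
consistency: the pipeline recovers structure from data generated under
its own error assumptions.  Real data violate these assumptions (site-
and sequence-dependent enzyme efficiency, fragile-site breakage,
chimeras), so measured recovery rates are upper bounds, not forecasts.

## Pairwise alignment

Ends-free (overlap) dynamic programming over label indices, both
orientations; only the second map is ever reversed (reflected through its
length).  The score is a log-likelihood ratio between "shared locus under
the error model" and "chance":

* matched interval pair `(da, db)` spanning `(k, l)` label steps:
  `−z²/2 − ln(σ√2π) + ln W`, with `σ = (s/1000)·√(da²/k + db²/l)`
  (both maps contribute gap noise; an interval spanning `k` gaps of
  roughly equal size has variance `≈ c²da²/k`), floored at
  `σ_min = 50 bp`; the chance term takes the competing label position as
  a Poisson process at the pooled observed density, `W` = pooled mean
  inter-label distance;
* per matched pair: `ln((1−p_fp)(1−fn))`, where
  `p_fp = (fp/10⁵)/density` is the expected FP fraction of observed
  labels (clipped to [10⁻⁴, 0.9]);
* per skipped label inside the overlap: `ln(p_fp + (1−p_fp)·fn)` — the
  label is explained as an FP on its own map or a dropout on the other.

The DP keeps two layers (best chain of ≥1 and ≥2 matched pairs) so the
optimum over all monotone matchings with at least two pairs is exact even
when every extension is penalized; this is verified against exhaustive
enumeration on small instances.  Skips are bounded per step
(`max_skip = 3` per side by default) for speed; tests that compare
against enumeration raise it so the bound is not binding.  Ties are
broken toward more matched pairs, then smaller |offset|, then forward
orientation, making results deterministic.  Reported alignments with
fewer than two matched pairs do not exist by construction; maps with
fewer than two labels yield no alignment.

**Significance.**  The reference method is a permutation null: the
partner's inter-label gaps (including flanks) are shuffled, the pair is
realigned, and `p = (1 + #{null ≥ observed})/(reps + 1)`.  Because the
sweep grid's thresholds reach 1.11e-12 while permutation resolves only to
`1/(reps+1)`, a Gumbel distribution fitted to the null scores provides
the tail beyond resolution (`method="auto"` switches to it exactly when
the count is zero).  For all-pairs screening, a pooled null
(`ScoreNull`) is fitted once per dataset and (FP, FN) pair on shuffled
molecule pairs drawn deterministically from the *unfiltered* input set —
the seed derives from the data content hash and the error rates, which is
what makes memoized and naive sweep runs bit-identical.  The pooled fit
ignores the dependence of null scores on label counts; p-values for
unusually label-dense molecules are therefore mildly anti-conservative,
which the downstream layout-consistency check absorbs.

Confidence is `−log10(p)`; the inverse conversion is provided.

## Assembly

The four classical steps, unrefined (no refinement, extension, haplotype
separation or chimera splitting):

1. **filter** — keep molecules with length ≥ `min_length_kbp` and labels
   ≥ `min_labels`, both inclusive;
2. **sort** — descending length, ties by id (stable);
3. **split** — round-robin over the sorted order into `n_chunks` files of
   near-equal total length; the alignment result is provably independent
   of the chunking and tested to be;
4. **all-pairs + OLC** — every unordered pair is aligned once; alignments
   with `p ≤` threshold become edges of an overlap graph.  Layout is
   greedy best-edge-first: edges in increasing p-value order are merged
   by union-find with per-molecule affine coordinate transforms
   (orientation ± offset); an edge contradicting the existing layout by
   more than `placement_tolerance_bp` (default 2000) is rejected.
   Components with ≥ 2 molecules become contigs, anchored with the
   longest member forward and the leftmost molecule start at 0; contig
   ids are assigned in descending contig length.

**Consensus.**  Member labels are transformed into the contig frame and
clustered by single linkage at `merge_radius_bp` (default 800), with
chains wider than twice the radius split recursively at their largest
internal gaps; the consensus position is the cluster mean, `occurrence`
the number of distinct molecules in the cluster, `coverage` the number of
molecules spanning the position.  A cluster is kept when
`occurrence ≥ max(1, ⌈0.25·coverage⌉)`.  Plain single linkage at a fixed
radius fails in both directions at depth: FP labels pooled across ~50
molecules sit ~1.3 kb apart and chain into clusters that swallow true
sites, while a radius large enough to pool one site's noise merges
genuinely distinct sites 0.5–1.5 kb apart (~10% of sites at this
density).  The gap-splitting cap plus the local-coverage occurrence
filter resolves both: at coverage 2 the threshold is 1 (a two-molecule
contig keeps the union of its sites), at coverage 50 it is 13 (no FP
cluster survives).  The 800 bp radius resolves sites down to the
simulator's 500 bp resolution floor while exceeding per-site position
noise.

A **singleton** is a filtered molecule on no accepted layout edge; the
singleton proportion is reported against the post-filter molecule count
(the pre-filter denominator would conflate filtering with assembly
failure).

## The sweep engine

Effective parameters per step: sort {}, split {}, pairwise {FP, FN},
assembly {all five}; the threshold and molecule filters act on the other
steps only as output filters.  Filter-only parameters are executed at the
most lenient value in the active grid (min length, min labels, max
threshold), so one shared run dominates all dependents; each assembly
node re-filters molecules and alignments to its own values.  Node results
are cached on disk keyed by a SHA-256 content hash of (step type,
effective parameters, execution context, input data hash, code version);
the pairwise context includes the lenient dominator triple, since the
stored alignment set depends on it — reusing a pairwise run across grids
with different dominators would be unsound even though the step key
matches.  Payloads carry a checksum; corruption triggers a re-run with a
warning, never silent reuse.  A warm re-run executes zero nodes.
`run_naive` executes every combination end-to-end with no reuse and is
the correctness oracle: memoized and naive outputs are asserted
field-identical in the tests.  Execution is sequential; cluster-scale
parallel scheduling is out of scope.

## Quality metrics

Contiguity: total length; contig N50 as the length at which the
descending cumulative sum first reaches half the total (the dominant N50
convention; ties resolve toward the longer contig); longest contig.
Internal consistency: mean per-label `occurrence` (label depth; 0 for an
empty assembly) and the non-singleton proportion.  Accuracy: each contig
is aligned to the reference, its confidence is `−log10` of the best
permutation p-value, and the aggregate is the **contig-length-weighted**
mean over aligned contigs; contigs with no alignment are excluded from
the mean and reported as a count (weighting by length is a choice — the
alternative, alignment-length or molecule-support weighting, is not
implemented).  `rank_correlation` reports the Spearman correlation
between contig N50 and weighted confidence across a sweep; it is
reported, never asserted, because whether contiguity predicts accuracy is
a property of the data, not of the code.

The bundled flow-cell run table (19 runs: date, quantity in Mbp, molecule
N50 in kbp, labels per 100 kbp) feeds `dataset_stats`: total Gbp,
quantity-weighted means, maximum density, and fold coverage of a given
genome size rounded to the nearest integer.

## Problem sizes and tolerances in the tests

The suites run at desk scale by design: unit tests use 0.4–1 Mbp
references with 40–80 molecules; the reuse-equivalence check uses 200
molecules on 1 Mbp with a 2×2×1×1×1 grid; the recovery check uses 50×
coverage of 2 Mbp (~600 molecules, ~190k pair alignments) at FP 1.5/100
kbp and FN 0.15 with the most lenient grid threshold (1.11e-4) — at
these error rates the per-shared-site score gain is ~0.5–1 LLR units, so
deeper thresholds leave nearly all molecule pairs untestable, which is
also why real datasets at comparable error levels assemble >90% of
molecules as singletons.  Alignment scores are compared to enumeration at
1e-6 absolute; round trips to the written precision (0.1 bp); stochastic
rate checks at 3 binomial standard deviations.  Numerical guards: sizing
σ floored at 50 bp, p-values clipped to [1e-300, 1], degenerate null fits
(fewer than 10 finite scores) fall back to the permutation count.

## Known limitations

* The aligner's chance model and pooled Gumbel null are calibrated per
  dataset, not per label-count stratum.
* Layout is greedy; a contradicted edge is dropped rather than triggering
  re-layout, so an early wrong edge (possible at lenient thresholds on
  repetitive references) can seed a chimeric contig.  Synthetic Poisson
  references have essentially no repeats; real genomes do.
* Consensus position error accumulates along transform chains (no global
  refinement), visible as kbp-scale coordinate drift on Mbp contigs; it
  cancels in interval space, which is why contig-to-reference alignment
  still matches site-for-site.
* Molecule stretch is simulated but not estimated or swept.
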