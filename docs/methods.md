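# Methods

This note records how svrec's procedures are defined, the tunable
parameters and their defaults, what the synthetic generators emulate, and
the design choices made where the underlying method left details open.

## 1. Meta-feature scanning

The scanner estimates dataset-level descriptors without calling SVs.

**Soft-clip signatures.** For each mapped primary alignment, a leading
soft clip of at least `min_clip` bases yields a START-side signature at the
mapped position; a trailing clip yields an END-side signature at the end of
the reference-consumed span (M/D/N/=/X operations). Secondary and
supplementary alignments are excluded everywhere so each sequenced read
contributes once.

**Clustering.** Signatures are grouped per (chromosome, side) by single
linkage: two signatures share a cluster iff a chain of members with
successive gaps ≤ `cluster_window` connects them. On sorted positions this
reduces to splitting at gaps larger than the window, which is what the
implementation does; the test suite checks it against an all-pairs
union-find oracle. The cluster representative is the median member (lower
of the two middles for even counts) — robust to a stray mis-clipped read.

**Pairing.** Candidate events are (END-cluster, START-cluster) pairs on the
same chromosome with the START representative strictly downstream and a gap
in `[min_sv, max_sv]`. Pairs are accepted greedily by increasing gap (ties
by left coordinate), each cluster joining at most one event. The greedy
order makes the common nested/adjacent-cluster cases resolve to the
tightest plausible event. Paired clusters model deletion-like signals;
insertions are not separately detected — the scanner's output feeds only
the aggregate feature vector, where an approximate size distribution is
what matters.

**Features.**

* `avg_read_length`: mean query length (clips included) over mapped records.
* `avg_depth`: total reference-consumed bases divided by the length of the
  merged union of aligned intervals. Using the covered span rather than the
  chromosome length keeps sparse toy genomes from diluting the estimate.
* size-class proportions with boundaries [50, 200) / [200, 1000] /
  (1000, ∞). The conventional printed ranges "50–200" and "200–1,000"
  overlap at 200; 200 is assigned to the middle class, and since "large"
  is defined as >1,000, the value 1000 also falls to middle.
* `prop_sv_tr`: fraction of events intersecting a tandem-repeat interval by
  ≥ 1 bp.
* `rvb` / `prop_high_rvb`: windows of width round(`avg_read_length`) are
  placed over each covered interval at step width/2, the first window
  reaching the interval end being the last (partial windows kept). A
  window's burden is the number of events intersecting it; `rvb` is the
  mean burden (a window is the proxy for "one read") and `prop_high_rvb`
  the fraction of windows with burden ≥ `rvb_high_threshold`. Both are 0
  when there are no events or no windows. The same window grid serves both
  features.

Defaults: `min_clip` 20 bp (below this, clips on long reads are mostly
sequencing artifacts), `cluster_window` 100 bp (long-read breakpoint
jitter), `min_sv` 50 bp (the conventional SV floor), `max_sv` 100 kb,
`rvb_high_threshold` 2 events. All are exposed in `ScanConfig` and on the
CLI.

Degenerate inputs: a file with no mapped records is an error; a dataset
with no events yields (0, 0, 0) size proportions (their sum is 0 or 1,
never anything else), zero TR proportion and zero RVB.

## 2. Caller evaluation

Matching is one-to-one between call set and benchmark. Interval SVs match
when the intersection covers ≥ `min_overlap` (default 0.8) of *both*
intervals — reciprocal overlap, the standard in SV benchmarking; the
denominator choice (reciprocal vs reference-anchored) is exposed only
through `min_overlap` itself since the rule is symmetric. Insertions match
on breakpoint proximity (≤ 100 bp) and smaller/larger size ratio ≥
`min_overlap`. Admissible pairs are taken greedily by descending overlap
quality; the test suite verifies on random instances that this equals the
exact maximum-cardinality matching.

Precision is defined as 0 when no calls are made, keeping the f-measure
defined; an empty benchmark is an error. Meta-target ranking sorts callers
by the chosen metric descending with lexicographic tie-breaks, so labels
are deterministic. RA at `p_optimal == p_worst` is defined as 1: when every
caller performs identically, any recommendation is optimal (the raw ratio
is 0/0 there). Win/draw/loss uses an absolute draw tolerance of 1e-9;
metric values are ratios of small integers, so genuine ties are exactly
representable.

## 3. The recommender

The meta-model is a bagged decision-tree ensemble
(`sklearn.ensemble.RandomForestClassifier`, default 500 trees, bootstrap
sampling, random feature subsets per split) over the eight features in a
fixed canonical order. Prediction takes the largest vote fraction with
lexicographic tie-breaks. Out-of-bag accuracy is reported as the training
summary.

Determinism contracts: training rows are sorted by dataset id before
fitting (forest bootstraps depend on row order), and in leave-one-out
evaluation the per-fold seed is `crc32(held_out_id) XOR base_seed`, so the
evaluation is invariant to corpus entry order and reproducible under a
fixed base seed.

Leave-one-out protocol: each dataset is held out, the ensemble retrained on
the rest, the recommendation scored by RA on the held-out dataset's
realized per-caller performances. Baselines: fixed-pick RA per caller, and
random-pick as the uniform *expectation* over callers (mean RA across
callers per dataset) rather than one realized draw — the expectation
removes needless variance from the comparison; a realized-draw variant is
available (`LOOResults.random_pick_realized_ra`). Win/draw/loss counts
compare realized metric values of the recommendation against each baseline
per dataset.

Similarity gate: features are standardized to zero mean/unit variance over
the corpus and neighbours counted within Euclidean radius 1.0 (radius
configurable); augmentation fires unless the count strictly exceeds 100.
Semi-simulated augmentation perturbs the query feature vector with Gaussian
noise (sd = 5 % of each feature's corpus sd; the size-class triple is
clipped to [0,1] and renormalized) and obtains per-caller performances from
an injected provider — in the original workflow this step re-runs the SV
callers on semi-simulated reads, which is outside this package's scope, so
the provider contract delegates it explicitly.

## 4. Synthetic data

**Alignment simulator.** A single-chromosome toy genome (default 500 kb)
carries non-overlapping planted deletions separated by at least one mean
read length. Reads (default 8 kb ± 400 bp, 20×) tile the *deleted* genome
uniformly; a read crossing a deletion junction is emitted as split records
soft-clipped toward the two breakpoints, each boundary jittered by
N(0, 8 bp) to mimic alignment ambiguity, and split segments shorter than
50 aligned bases are dropped as an aligner would. Reads are error-free away
from junctions and carry no sequence (`SEQ *`): every implemented statistic
reads only CIGAR geometry and positions. What passing recovery tests show
is therefore that the scanning arithmetic is right — not that the scanner
is robust to base-level noise, chimeric alignments or real repeat
structure, which the toy generator does not model. Outputs (SAM, truth
VCF, repeat BED, planting log) are byte-identical under a fixed seed.

**Corpus simulator.** Feature vectors are drawn from typical long-read
ranges: read length U(1,000, 25,000) bp, depth U(10, 150)×, size-class
triple Dirichlet(1,1,1), the remaining fractions U(0,1), RVB U(0,4). The
optimal caller is assigned by a declarative decision list over features
(default: a five-region rule on `avg_depth` and `prop_large`, echoing how
real callers separate on coverage and SV size). Per metric, the rule's
caller receives `base + spread` (defaults 0.5 + 0.4) and the others fall
uniformly in a band just below `base`; Gaussian noise (default sd 0.05) is
added, values are clipped to [0,1], and the stored meta-target is
re-derived from the noisy table — so with large noise relative to spread,
some targets flip and the corpus is deliberately imperfectly separable.

## 5. Problem sizes and numerical choices

The standard evaluation conditions are 200-dataset corpora with five
pseudo-callers, spread 0.4 and noise 0.05, evaluated over five corpus
seeds with a 500-tree ensemble (seed 42); the recovery tests run the
alignment simulator at 50 planted SVs over 500 kb across 20 seeds. The test
suite uses 100-tree ensembles where the check being made (label recovery,
dominance ordering) is insensitive to ensemble size. All comparisons of
floating proportions use absolute tolerances stated in the tests; exact
equality is asserted only where the arithmetic is exact (oracle
equivalence, determinism contracts).

## 6. Known limitations

* The scanner detects deletion-like paired-clip signals only; insertion,
  inversion and translocation signatures contribute at most one-sided
  clips and are not paired into events.
* Depth normalizes by covered span, which overestimates genome-wide depth
  on fragmentary coverage.
* The greedy cluster pairing is a heuristic; adversarial breakpoint
  configurations could pair across events, though the tested regimes
  (events separated by a read length) do not produce them.
* The pluggable performance-table interface means svrec never runs real SV
  callers itself; real-data corpora must be assembled externally.
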