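# Methods

## The analysis model

The pipeline treats a two-condition AP-MS experiment as a protein-group ×
sample matrix of log2 intensities with left-censored missingness. Per
protein, the effect of interest is the difference of group means
`D = mean(mock) − mean(treatment)` (log2 units, positive = mock-enriched).
Significance uses a moderated statistic

    d* = D / (s + S0)

with `s` the pooled two-sample standard error (Welch available via
`test_variant="welch"`) and `S0 ≥ 0` a moderation constant that damps rows
whose very small variance would otherwise make a negligible difference
significant. The unmoderated `t = D/s` and its two-sided p-value from the
t distribution (df = n1+n2−2 pooled, Satterthwaite for Welch) are carried
alongside and drive the volcano's y-axis; flags come from `|d*|` against the
permutation threshold, and both are recorded per row. A zero-variance row
with `D ≠ 0` is undefined at `S0 = 0` (raised as an error); with `S0 > 0` it
gets `d* = D/S0`, `t = ±∞` and p floored at the smallest positive float.

### Permutation FDR

The null is built by recomputing every row's `d*` under relabeled samples:
all distinct assignments of samples to groups of the original sizes,
excluding the identity (4v4: 69; enumerated exhaustively whenever the count
is ≤ `exhaustive_cap` = 10 000, otherwise `n_perm` = 250 distinct
assignments sampled uniformly without replacement, seeded). At each
candidate cutoff `c` (the sorted observed `|d*|`):

    FDR(c) = mean over assignments of #{|d*_perm| ≥ c} / max(1, #{|d*_obs| ≥ c})

capped at 1. The reported curve is the running minimum over cutoffs ≤ c
(the q-value convention), which makes it monotone non-increasing in `c` and
makes "smallest `c` with FDR ≤ α" well-defined; rows with `|d*| ≥ c` are
flagged. No π0 factor is applied — the estimate is deliberately
conservative. Group moments inside the permutation engine are computed with
per-assignment numpy reductions rather than one large matrix product so that
the complete label swap reproduces the observed statistic bit-for-bit;
without this, shape-dependent BLAS summation breaks exact tie handling at
the observed thresholds.

### Bait normalization

For a bait degraded by the treatment, every prey bound at constant
stoichiometry drops with it, and the interesting signal is the prey's level
*relative to the bait*. The intensity arm therefore subtracts the bait's
observed log2 intensity per sample from every row before imputation
(equivalent to the raw-scale prey/bait ratio). Consequences, exact in the
noise-free limit: the bait itself sits at difference 0; a
constant-stoichiometry prey becomes flat; a prey with constant absolute
abundance acquires an apparent treatment-side difference equal to the bait's
drop; a degradation-machinery prey whose absolute level rises by the bait's
drop shows twice that shift. Because the subtracted bait values are
themselves noisy replicate measurements, all bait-relative differences share
the bait's realized noise (variance roughly doubles per sample), which makes
the bait-relative background block's position — and hence the intensity
arm's threshold — noticeably seed-dependent at realistic noise levels. The
default pipeline runs both arms: label-free-normalized intensities without
bait normalization, and raw intensities with it.

Samples where the bait was not quantified raise an error by default; a
`mask` policy (blank those samples, warn) is available. The bait row is kept
through testing by default; `keep_bait=False` drops it after normalization.

### Imputation

Missing values are treated as below-detection-limit events and replaced by
draws from a down-shifted normal per sample column (default) or globally:
`Normal(μ̂ − d·σ̂, (w·σ̂)²)` with the observed scope mean/sd and the widely
used `d = 1.8`, `w = 0.3`, or `Normal(min̂, (w·σ̂)²)` in `min_centered` mode
(a distribution centered on the lowest measured value). Draw substreams are
keyed per cell by a stable hash of (seed, group id, sample), and the scope
statistics are computed on sorted values, so results are independent of row
order and bit-reproducible under a fixed seed; observed cells are never
modified, and an audit table of every imputed cell is emitted. Scopes with
fewer than two observations or zero spread raise.

## The synthetic pulldown

The generator emulates a tandem-affinity purification of an overexpressed
bait from cultured cells, mock vs treatment, 4+4 replicates, ~290 protein
groups. Classes and their true log2 levels (base abundance
`μ_i ~ N(25, 2²)`): bait (28 mock, 28 − δ_bait treatment; overexpressed and
hence the most abundant protein), constitutive preys (drop with the bait),
recruited preys (below the detection limit under mock, `μ_i` under
treatment), released preys (drop by δ under treatment), machinery preys
(rise by δ_bait·coupling under treatment), stable background binders, and
flagged decoy/contaminant rows. Replicate noise is Gaussian on log2 with
σ = 0.6 by default — chosen so the implied within-group replicate Pearson
correlation τ²/(τ²+σ²) = 4/4.36 ≈ 0.92 sits inside the 0.77–0.96 range
typical of replicated TAP-LFQ experiments. Missingness is left-censored:
a value `x` is lost with probability `logistic(2·(L − x))` around the
detection limit L = 21 (= base mean − 2 sd, putting the censoring edge at
the left flank of the abundance distribution) and always below L − 2.
Effect sizes default to δ_bait = 1.5 and δ = 2. The LFQ columns of emitted
`proteinGroups.txt` files come from a median-centering surrogate — it
equalizes per-sample medians only and does not reproduce peptide-level
pairwise-ratio normalization of real LFQ algorithms.

What the simulator does **not** model: intensity-dependent measurement
noise (the abundant bait is given the same σ as every prey, which overstates
bait-noise propagation into bait-relative differences), peptide-level
effects, match-between-runs artifacts, correlated backgrounds, batch
structure. Passing tests therefore demonstrate the statistical machinery's
correctness under a clean MNAR log-normal model, not performance on any
particular real dataset.

## Known limitations, measured

Two simulation-based guarantees fall short of round numbers one might hope
for, for reasons the test suite makes explicit rather than hiding:

* **Recovery near the detection limit.** With planted effects δ = 2 at
  σ = 0.3 and censoring on, mean sensitivity over 200-seed batches is
  ≈ 0.84 (downshift imputation) to ≈ 0.89 (min-centered), not ≥ 0.9, while
  FDP stays ≤ 0.05. The shortfall is information-theoretic, not a bug:
  planted preys whose present-condition abundance lies within ~1.5 log2 of
  the imputation floor have their censored-condition contrast erased by
  censoring, and no imputation centered at or above the floor can restore
  it. Restricted to preys quantifiable well above the limit, sensitivity is
  ≈ 1.0.
* **Strict bait-normalization win counts.** The intensity arm reliably
  surfaces machinery preys (shift 2·δ_bait) and the stable background
  (shift δ_bait relative to the bait), but the LFQ arm also legitimately
  flags constitutive preys — their absolute drop *is* real signal there —
  and a constant-stoichiometry prey carries no bait-relative signal at all
  after bait normalization (its true bait-relative difference is identically
  0, so intensity mode can only lose it). A strict
  per-seed inequality on flagged bait-coupled counts between arms therefore
  holds only in a fraction of seeds (~0.6–0.7 at σ = 0.6 and 0 at low σ,
  where the LFQ arm flags all coupled preys). The scientifically robust
  statements — machinery preys double their shift, constitutive preys
  vanish, the bait pins at exactly 0, and the *total* treatment-side
  candidate count increases drastically — hold and are asserted.

Other deliberate choices: two-sided testing throughout; candidate
thresholds only at observed `|d*|` values; volcano significance exported as
per-point flags rather than a fitted boundary curve; exhaustive enumeration
auto-selected for 4v4-scale designs; stage order fixed (bait normalization
always precedes the valid-value filter, QC and imputation; QC never sees
imputed values); YAML configs resolve all derived seeds so a saved config
re-runs byte-identically.
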