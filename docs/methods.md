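# Methods

This note records the models, defaults, and design choices behind
`hicsaga`, in the order the pipeline runs.

## Coordinate system and input handling

All analysis happens on an ordered, fixed-width binning of named
chromosomes (default 100 kb; the last bin of a chromosome may be
short). Coordinates are 0-based half-open everywhere, matching the BED
/ bedGraph / BEDPE dialects read and written. Strand is ignored: this
is domain-scale analysis and genes are treated as intervals.

Signal tracks are binned by coverage-weighted aggregation with
uncovered bases counted as value 0; a bin with no covering data at all
gets 0 plus a no-data flag, and bins flagged in at least half of the
functional tracks are masked genome-wide. This symmetric, conservative
mask keeps every downstream matrix aligned on the same usable bins.
Contacts arrive as sparse triplet text (or a single-resolution cooler
HDF5 file); duplicate pairs are summed and storage is canonical
(i ≤ j), so input row order and (i,j) orientation never matter.

## O/E graph construction

Bins whose raw contact marginal falls below 0.25 × the median marginal
of their chromosome are masked (low-coverage bins produce unreliable
O/E ratios). The expected model is the standard Hi-C convention:

- intra-chromosomal: per chromosome, the mean observed count over all
  unmasked bin pairs at the same bin distance, **zeros included** — an
  unobserved pair is an observation of zero, so sparse chromosomes are
  not inflated;
- inter-chromosomal: one global mean over all unmasked inter pairs.

Distance strata with fewer than 10 unmasked pairs are pooled with the
adjacent longer-distance stratum to stabilize the mean. Edge weight is
observed/expected; edges are kept when O/E ≥ 1 (configurable, 0 keeps
every positive-count pair) because the embedding should be driven by
enriched contacts; the diagonal is excluded and weights are not
log-transformed — they enter the edge sampler linearly.

## Second-order embedding

Per node, an embedding vector u and a context vector u′ (both
dimension 8 by default — enough to capture genome-wide
compartmentalization; exposed as a flag). The training objective is
the degree-weighted KL divergence between the softmax model
distribution p₂(·|i) and the empirical neighbour distribution
wᵢⱼ/dᵢ, which reduces to O₂ = −Σ_E wᵢⱼ log p₂(j|i) when node weights
equal degree. Optimization is stochastic:

- edges drawn with probability ∝ weight via an alias table (this is
  exactly what realizes the λᵢ = dᵢ node weighting — no separate
  handling needed);
- each drawn undirected edge trains both directions (contact is
  symmetric);
- 5 negative samples per positive from a noise distribution ∝
  degree^0.75;
- total samples T = max(100·|E|, 10⁶); learning rate 0.025 decaying
  linearly to 10⁻⁴ of its start; u initialized Uniform(−0.5/d, 0.5/d),
  u′ at zero.

The trainer is single-threaded and bit-reproducible for a fixed seed
(numba-compiled loop with an explicitly seeded generator). Only u is
exported as structural features; u′ is an auxiliary quantity of the
factorized softmax. Exact softmax, exact objective, and an analytic
full gradient are provided for small-graph verification; they are
quadratic in |V| and never used in training.

## SAGA annotation

Functional tracks are transformed x → asinh(x) = ln(x + √(x²+1))
(linear near 0, logarithmic in the tail — appropriate for
non-negative, heavy-tailed coverage signals) and z-scored per track
over unmasked bins; embedding tracks are z-scored without the asinh
(they are already roughly symmetric around 0). Constants are stored in
the model so decode-time inputs are transformed identically.
Zero-variance tracks are dropped with a warning.

The annotation model is a K-state hidden Markov model with diagonal
Gaussian emissions (a per-state mixture size M is exposed for the
GMM-HMM variant; M = 1 by default because ~20 tracks at 100 kb leave
limited data per state). Each chromosome is an independent observation
sequence and masked bins split a chromosome into separate sequences,
so no transition is learned across gaps. Fitting is Baum–Welch from a
seeded k-means initialization, one run (no restarts) for
reproducibility, stopping when the relative log-likelihood improvement
drops below 10⁻⁴ or after 500 iterations; a variance floor of 10⁻³
(post-standardization units) prevents state collapse. Decoding is the
Viterbi path. An unstructured Gaussian mixture (GMM) is available as
the no-transition baseline.

K is chosen by the user (6 reproduces the classic domain-type count;
8 gives finer combinatorial types); a sweep over K with the evaluation
statistics is the intended selection procedure rather than any
automated criterion.

States are interchangeable by construction, so `relabel_by_enrichment`
renames them 1..K by descending enrichment in the most-active label of
a reference annotation, or by descending state mean of a ranking track
(ties: larger coverage, then original index).

## Evaluation statistics

**Variance explained.** VE = 1 − Σdᵢ²/Σ(sᵢ−s̄)² with dᵢ the residual
of the label-mean predictor. The variance convention (n vs n−1)
cancels; VE is bounded in [0,1] because group means can never do worse
than the global mean on the same data. Gene expression VE assigns each
gene the majority label over the annotated bins its interval overlaps
(ties to the lowest label index) and computes VE over genes on
asinh-transformed expression. Replication-timing VE averages the
fine-resolution (1 kb) 6-phase proportions into working bins,
renormalizes each bin's phase vector to sum 1 (zero-mass bins
excluded), computes VE per phase, and reports the unweighted mean;
phases that coarsen to a constant are skipped with a warning.

**Loop enrichment.** Each anchor maps to the bin containing its
midpoint (deterministic and resolution-robust for anchors spanning
bins); loops with an unannotated anchor are dropped and counted.
Observed counts accumulate per unordered label pair; expected counts
put totalO·Cᵢ² on the diagonal and 2·totalO·CᵢCⱼ on unordered pairs
i<j, so ΣE = totalO exactly. The OE score is ΣᵢOᵢᵢ/ΣᵢEᵢᵢ. The
unordered-pair convention is this package's choice; an ordered
convention would halve off-diagonal expectations but leave the score's
diagonal ratio unchanged.

**Bootstrap.** Per-bin statistics use a moving-block bootstrap
(blocks of 10 bins = 1 Mb by default, resampled with replacement to
the original length) to respect spatial autocorrelation; gene and loop
statistics resample units i.i.d. SE is the standard deviation of
replicate statistics with denominator n−1; the SE is declared
undefined if more than 20% of replicates fail.

**Overlap.** fold_change[a,b] = P(a,b)/(P(a)P(b)) over jointly
annotated bins plus the adjusted Rand index. Welch two-sample t-tests
on transformed expression between label pairs are offered as
descriptive output without multiple-testing correction.

## Synthetic data

The generator plants a per-bin combined state — a first-order Markov
chain with self-transition 0.9 (expected run 10 bins = 1 Mb) — that
factors into a functional state (3 by default) and a structural state
(2 by default). The factorization is the point: functional states are
visible only in the 1D tracks, structural states only in the contact
affinities, so recovering the combined states requires integrating
both views, and the single-view baselines have a hard ceiling.

- Contacts: Poisson with rate depth·|i−j|^(−1)·affinity[sᵢ,sⱼ] intra
  (affinity 3 within vs 1 between structural states) and
  depth·0.01·affinity inter; depth 60 gives realistic sparsity at
  100 kb. O/E normalization cancels depth by construction.
- Signals: 12 tracks; per-(functional state, track) latent means ~
  N(0,1), Gaussian noise sd 0.6, exponentiated to be non-negative and
  heavy-tailed like coverage tracks.
- Genes: 400 genes, uniform placement, lognormal lengths (median
  30 kb), lognormal expression around a combined-state mean (log-means
  spread over 0..2).
- Loops: 2000 loops; with probability 0.9 the second anchor shares the
  first anchor's structural state; closed forms for the OE score under
  this design (≈ number of structural states at fraction 1, ≈ 1 at
  fraction 0) calibrate the statistic.
- Replication timing: each combined state has a Gaussian-bump phase
  profile over 6 phases (active states early); fine bins draw
  Dirichlet proportions around their state profile.

The default scale, 2 chromosomes × 500 bins (100 Mb at 100 kb), keeps
a full pipeline run around tens of seconds while leaving enough bins
for state recovery; the test suite and acceptance script use this
scale, with 10⁴ bins for null-calibration checks where bias decays as
1/n. What these simulations do **not** emulate: restriction-fragment
artifacts, copy-number variation, translocations, TAD/loop
microstructure, overdispersed (non-Poisson) counts, and assay-specific
noise; passing tests demonstrate correctness of the algorithms under
the stated generative assumptions, not performance on real tissue
data.

## Numerical and degenerate-input choices

- Softmax and sigmoid evaluations are overflow-guarded (max
  subtraction; |logit| clipped at 35 in the trainer).
- A distance stratum whose expected value is 0 emits no edges (with a
  warning); a chromosome with zero contacts is masked entirely.
- Isolated nodes cannot be embedded and are rejected; graph nodes are
  defined as edge endpoints, so the pipeline never produces them.
- VE is undefined (error) for constant signals or fewer than 2 usable
  positions; the RT mean skips undefined phases.
- EM raises on a non-finite likelihood, naming the iteration.
- Gene majority-label ties resolve to the lowest label index; anchor
  midpoints falling at a chromosome end clamp to the last bin.

## Known limitations

- The O/E recipe is a single explicit convention (no ICE/KR balancing,
  no significant-interaction calling); results on real data will
  depend on upstream matrix processing.
- Embedding training is asymptotically stochastic: two seeds give
  different (rotated/reflected) feature spaces. Downstream clustering
  quality is stable but feature values are not comparable across
  seeds.
- Multi-resolution cooler files are not parsed; export a single
  resolution first.
- The HMM uses geometric state durations; methods with explicit
  duration models produce longer domains at equal K.
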