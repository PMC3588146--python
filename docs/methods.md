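# Methods

## The model

A mutational process operating in a cancer genome leaves a *signature*: a
discrete probability distribution over a fixed alphabet of K mutation
types. Writing the signatures of N processes as the columns of a
nonnegative K×N matrix P (each column summing to 1) and the number of
mutations each process contributed to each of G genomes as a nonnegative
N×G exposure matrix E, the observed K×G catalog matrix M of mutation-type
counts satisfies

    M ≈ P × E,

with the approximation error coming from sampling noise and nonsystematic
sequencing/analysis errors. Recovering P and E from M alone is a
nonnegative blind-source-separation problem; `sigdecipher` solves it with
nonnegative matrix factorization (NMF) wrapped in a bootstrap-consensus
procedure that separates stable structure from factorization noise.

## Mutation-type alphabets

Substitutions are reported on the pyrimidine of the mutated base pair, so
a G>A event equals a C>T event read on the opposite strand. Supported
alphabets: the 6 substitution classes (SBS6); 96 trinucleotide types
(SBS96: 6 classes × 4 5′-bases × 4 3′-bases); 192 stranded types (SBS192:
SBS96 split by transcriptional strand, restricted to mutations inside
annotated gene footprints); 1,536 pentanucleotide types (SBS1536: two
flanking bases each side); and SBS96 plus four extended classes (SBS96_EXT4,
K=100): kataegis, dinucleotide substitutions, indels at mono/polynucleotide
repeats, and indels at microhomologies. Labels are ordered by substitution
class and then lexicographically by context, which fixes the row order of
every matrix in the package.

Decisions the data formats leave open, fixed here:

- **Kataegis** is called from intermutation distances alone: maximal
  same-sample, same-chromosome runs of ≥ 6 substitutions with consecutive
  distances ≤ 1,000 bp (both configurable; the defaults are the
  operational definition used in the breast-cancer literature). Kataegis
  substitutions are excluded from all other substitution classes, so
  kataegis calling precedes dinucleotide pairing, which precedes indel
  classification and ordinary substitution typing.
- **Dinucleotide substitutions** are two substitutions at consecutive
  positions in one sample; runs of three or more are paired greedily left
  to right (deterministic; the leftover substitution is typed normally).
- **Indels** are repeat-mediated when the inserted/deleted sequence
  exactly copies the immediately adjacent sequence on either side, else
  microhomology-mediated when a deletion's sequence shares at least 1
  leading base (configurable) with its 3′ flank; insertions are never
  microhomology-classified.
- **Transcriptional strand**: a substitution is "transcribed" when the
  pyrimidine of the mutated pair lies on the template strand of the
  overlapping gene. Input positions are 1-based (MAF convention); gene
  footprints are half-open 0-based (BED convention).
- Unclassifiable records are skipped with a logged count by default;
  `strict=True` raises instead.

## The extraction pipeline

For a catalog M and a chosen rank N:

1. **Dimension reduction.** The largest set of mutation-type rows whose
   grand total is ≤ 1% of all mutations is removed (taking rows in
   ascending order of their totals maximizes the number removed). The
   factorization then runs on the reduced matrix Ṁ.
2. **Bootstrap.** Each genome's column is redrawn multinomially with
   probabilities proportional to its observed counts; per-genome totals
   are preserved exactly. Bootstrapping decouples the consensus from any
   single realization of the counts and guards against overfitting.
3. **NMF.** Ṁ's bootstrap replicate is factorized by the multiplicative
   updates for the Frobenius objective, E ← E∘(PᵀM̆)/(PᵀPE),
   P ← P∘(M̆Eᵀ)/(PEEᵀ), from random nonnegative initialization.
4. **Iterate** steps 2–3 for I iterations (default 500; `I="auto"` adds
   batches of 100 until the consensus stops moving — maximum centroid
   shift in 1 − cosine below 1e-3 between consecutive batch averages).
5. **Consensus clustering.** The I×N signatures are partitioned into N
   clusters by a k-means variation in which the N signatures of each
   iteration are matched one-to-one to the N clusters (optimal bipartite
   assignment under cosine similarity, preventing cluster collapse;
   centroids start from the first iteration's signatures, making the
   step deterministic). Centroids are member averages renormalized to
   unit column sum; each exposure row follows its signature, and Ē is
   the member average of the rescaled exposure rows.
6. **Evaluation.** Reproducibility is the average silhouette width of
   the clusters with distance 1 − cosine (1.00 means the same signature
   was found in every iteration); accuracy is the squared Frobenius
   reconstruction error ‖Ṁ − P̄×Ē‖²_F.

Consensus signatures are re-expanded to the full alphabet with zeros in
the removed rows (preserving unit column sums), per-entry error bars are
the standard deviations across each cluster's members, and clusters are
ordered by decreasing silhouette width. The reconstruction error is
reported against Ṁ, the matrix actually factorized; it can differ from
the full-matrix error by at most the removed mass (≤ 1% of mutations).

With N = 1 the consensus is the normalized average of rank-1 fits and the
silhouette width is defined as 1 (no second cluster exists); model
selection never relies on that rank alone.

## Model selection

The pipeline is run for each candidate N in [1, min(K̇, G) − 1] (or a
user-supplied subrange), each rank with an independent seed derived from
the master seed by a fixed offset. The automated rule codifies reading
the two curves by eye: a rank qualifies when its average silhouette width
is ≥ 0.85, and the selected rank is the largest qualifying N whose step
from N−1 (when swept) reduced the reconstruction error by ≥ 5%
(relative). Both thresholds are parameters, and the raw curves are always
returned so a human can override the automated choice. The step-in form
of the flattening condition selects the elbow of the error curve rather
than the top of a plateau, and collapses correctly to the degenerate
single-rank sweep.

## Numerical choices

- **NMF convergence** is declared when the relative objective decrease
  over a trailing 10,000-iteration window falls below `conv_tol`
  (checked every 10 iterations), or at 1,000,000 iterations. The default
  `conv_tol = 1e-4` follows convergence diagnostics on count-scale
  catalogs: the objective and the recovered signatures are flat well
  before that point (tightening to 1e-9 changed matched cosines by
  < 0.001 while requiring ~10× the iterations), and inside the pipeline
  the bootstrap resampling noise dominates the remaining optimization
  residual. Tighten it for standalone factorizations.
- Multiplicative-update denominators are floored at machine epsilon.
  Factor entries decaying toward zero are flushed to exact zero at
  checkpoints: zero is absorbing under the updates, and sustained
  subnormal values slow the floating-point units by an order of
  magnitude. The update loop itself is JIT-compiled (numba).
- Initialization is i.i.d. uniform on (0, 1] scaled by mean(Ṁ)/N, which
  speeds convergence without changing the fixed points; avoiding exact
  zeros matters because zeros are absorbing.
- Integer totals are split across signatures by largest-remainder
  rounding, so simulated exposure columns sum exactly to the drawn
  per-genome totals.
- All randomness flows from `numpy` `SeedSequence` spawning: one master
  seed reproduces the entire pipeline bit-for-bit, and per-iteration /
  per-rank streams are independent.

## The simulator

`simulate_truth` generates cohorts with known ground truth: signatures
are symmetric-Dirichlet draws (concentration 0.5, giving peaked,
signature-like profiles whose pairwise cosine similarities resemble those
of signatures extracted from real breast-cancer genomes); per-genome
totals are log-uniform on [500, 50,000], spanning the substitution counts
observed across human cancer genomes with realistic skew; each
signature's mutations are typed multinomially from its profile; and the
finished catalog is Poisson-resampled cell by cell (the default noise
model). Alternatives: additive white noise (uniformly-typed extra
mutations at a configurable fraction of each genome's total, the
construction behind the three-process worked example whose catalog totals
3,315 mutations) or no noise (useful for exact-recovery tests). Pairs of
signatures with a prescribed cosine similarity are built by convexly
mixing a base signature with an independent draw and bisecting the mixing
weight. Exposure models: flat-Dirichlet random splits (default), a fixed
per-genome share for signature 1, or a fixed cohort-wide share for
signature 1 (per-genome contributions then vary randomly under a
water-filling cap).

What the simulator does *not* emulate: genomic positions (so kataegis and
dinucleotide calling are exercised on hand-built record lists, not
simulated coordinates), sample-specific sequencing error profiles,
correlated exposures between processes, and signature profiles tied to
real mutagens. Passing the recovery tests therefore shows that the
algorithm separates multinomial-Poisson mixtures of the assumed form at
realistic sizes — not that any particular biological signature is
correct.

## Problem sizes used in the checks

The headline reproduction uses 100 genomes × 10 signatures with I = 100
bootstrap iterations and the rank sweep N ∈ {8..12} at the same scale; at
these sizes the consensus is already stable (the auto-I criterion
typically stops at 100–200 iterations on such cohorts) and a full run
completes in minutes on one core. Scenario power analyses default to 10
replicates per scenario, configurable upward.

## Known limitations

- Exposures are averaged across cluster members rather than re-fit
  against the final P̄; on near-collinear signatures the two choices can
  differ noticeably.
- The k-means variation is deterministic given the iteration set but,
  like all k-means schemes, can settle in a local optimum when clusters
  overlap heavily; the silhouette width flags such solutions rather than
  repairing them.
- No sparsity or other structural constraints are imposed on P or E.
- Rearrangement and copy-number mutation classes are out of scope; the
  extended alphabet covers kataegis, dinucleotides, and two indel
  classes only.
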