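# Methods

## Problem setting and model

Given an n × m matrix of biallelic genotypes coded −1/+1 (a
haploid-style biparental cross: each marker carries one of the two
parental alleles) and a real-valued quantitative trait, the goal is the
smallest SNP subset that predicts the trait well, together with the
prediction itself. The predictor is always a linear model with
automatically tuned L2 shrinkage (scikit-learn's `BayesianRidge`, which
maximizes the marginal likelihood over the penalty). A ridge-type model
is deliberate: an L1 penalty would itself zero out coefficients and
interfere with the wrapper search, whereas ridge leaves redundancy
removal entirely to the selection objective.

The selection objective is the adjusted coefficient of determination of
the in-sample fit,

    R²_adj = 1 − (1 − R²)(n − 1)/(n − p − 1),   R² = 1 − RSS/TSS,

with p the number of selected SNPs. R²_adj is implemented exactly as
printed above and is *not* clipped at 0, although for useful fits it
lies in (0, 1]: a badly overfit or mis-specified mask may legitimately
score negative and should lose to better masks. Masks with p = 0 or
p ≥ n − 1 (formula undefined or degenerate) receive a sentinel worst
score rather than raising, which keeps the search operators total.

## Stage 1: pre-processing

SNPs are ranked by |PCC| with the trait. The absolute value is used
because a strong negative allele effect is as informative as a positive
one; a signed option exists behind `use_absolute_pcc=False` for
diagnostics. Ties break toward the lower column index, making the
ranking a deterministic total order. Constant columns get PCC 0 (their
correlation is undefined), rank last, and never block other SNPs.

The ranked list is scanned greedily: a SNP is kept iff its LD with
every already-kept SNP satisfies r² ≤ α, where r² is the squared
Pearson correlation of the coded genotype columns — the standard
biallelic LD statistic, and the one that makes cutoffs in (0,1)
meaningful. The boundary is inclusive-keep, so α = 1.0 degenerates
cleanly to keeping everything. The certificate of correctness is
checkable directly: the kept set is pairwise conflict-free at α, and
every dropped SNP conflicts with a kept, higher-ranked SNP.

Both statistics are computed on the **training partition only**; the
resulting candidate index set is then applied to both partitions. No
top-k truncation is applied unless configured — LD pruning alone
controls the candidate count.

## Stage 2: the genetic algorithm

Chromosomes are bit masks over the candidate set. The steady-state
loop holds a pool of S = 10 chromosomes, initialized with cardinality
drawn uniformly from [1, min(20, m)] — small initial masks, because
R²_adj punishes large p and n − p − 1 must stay positive. Each
iteration (K = 5000 by default; one iteration = one operator
application) visits a pool member round-robin and applies exactly one
operator:

- **mutate** — up to L = 10 variants, each flipping 1–3 uniformly
  chosen bits (count uniform);
- **crossover** — up to L children by uniform per-gene inheritance from
  the member and a uniformly chosen distinct pool partner; positions
  where the parents agree are fixed in the child.

Variants already in the tabu registry are skipped without a model fit;
the best fresh variant is proposed, and replaces the pool's worst
member only on strict improvement, with ties broken toward fewer
features (the parsimony objective). The pool's best therefore never
degrades, and the best-fitness trace is non-decreasing.

The operator is chosen adaptively: P(crossover) = c/w clamped to
[0.2, 0.8], where c counts crossover entries among the last w = 3
improvements. An empty history yields 0.5 (uninformative prior). Both
clamp bounds follow from the 20 % floor applied to each operator.

The tabu registry is unbounded within a run (candidate spaces are
~10²–10³ bits, visited sets stay small); its key is the bit pattern
itself. Fits are bounded by L·K + S per run, and the model-fit count
equals the number of distinct non-degenerate masks ever scored —
revisits are cache hits.

Because the GA is stochastic it is repeated (3 runs; run r uses seed +
r) and the intersection of the selected sets is the final QTL set. An
empty intersection falls back to the best single run's set by R²_adj
and is flagged in the report. The I/U ratio quantifies stability.
When consensus sets from several LD cutoffs are combined, intersection
across cutoffs is the default (strict); union is available.

## Evaluation

The consensus features are refitted on the training partition and
scored on the held-out partition (10 % by default, seeded shuffle,
|test| = round(fraction × usable n)) with MAE, MSE and PCC. A k-fold
driver (5 folds by default, contiguous seeded assignment) exports
per-fold metrics for standard paired-comparison routines. LD
concordance against a reference QTL list reports, per reference locus,
the maximum r² to any detected SNP; reference loci absent from the
genotype matrix are skipped with a warning, since real reference lists
come from other call sets.

## Synthetic data

The simulator emulates the LD structure of a biparental cross without
claiming coalescent realism. Markers come in mutually independent
blocks; within a block adjacent SNPs form a first-order Markov chain —
SNP j+1 equals SNP j with probability (1 + ρ)/2, flipped otherwise —
which preserves exact ±1 marginals and gives adjacent correlation
exactly ρ (LD decays as ρ^d with distance d). This closed form is what
the simulator's tests assert. The chain model was chosen over
multivariate-Gaussian thresholding precisely for those two exact
properties.

Traits are y = Σ βᵢ gᵢ + Σ γₐᵦ gₐ gᵦ + ε with causal SNPs drawn one
per block while blocks remain, effects of equal magnitude and
alternating sign by default (avoiding sign-cancellation artifacts), and
Gaussian noise scaled so the genetic variance fraction equals the
target h². With the true support and large n, held-out PCC approaches
√h² — the closed-form ceiling used in testing. Pure epistatic pairs
produce near-zero marginal correlations, which is exactly the regime
where the PCC ranking (and a linear fitness model) is expected to fail;
passing tests on additive architectures say nothing about detection of
non-additive QTLs.

What the simulator does **not** model: population structure, allele
frequency spectra (marginals are balanced ±1), dominance, missingness
patterns, genotyping error. Results on it demonstrate algorithmic
correctness and additive-signal recovery, not field performance.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| α (`ld_cutoff`) | 0.4 | max pairwise r² among candidates; higher → larger, more redundant search space |
| K (`iterations`) | 5000 | operator applications per run |
| S (`pool_size`) | 10 | steady-state pool size |
| L (`operator_budget`) | 10 | max fresh fitness evaluations per operator application |
| `rate_floor` | 0.2 | lower clamp on each operator probability |
| `window` | 3 | improvement memory for adaptive rates |
| `runs` | 3 | GA repetitions intersected into the consensus |
| `seed` | required | no hidden default; every stochastic step derives from it |

The default *study conditions* for synthetic experiments are n = 500,
30 blocks × 10 SNPs, ρ = 0.9, five additive QTLs, h² = 0.8 — a panel
whose LD-block count and signal strength are large enough that pruning
and search behaviour are non-trivial, yet small enough for exhaustive
cross-checks. Test and acceptance runs reduce K to 1000–2000 and use
8–10-SNP candidate spaces where exhaustive enumeration provides an
oracle; at those sizes the GA's optimum can be verified exactly.

## Numerical and design choices

- Missing genotypes are imputed per SNP to the more frequent code (the
  count is logged); missing phenotypes drop the sample before the
  split. This keeps PCC/LD defined without inventing an imputation
  model the data cannot support.
- The {0,2} genotype dialect maps order-preservingly (0 → −1, 2 → +1);
  heterozygous or multi-allelic VCF records are rejected rather than
  guessed at — the intended data are haploid-style crosses.
- Sample alignment is by identifier join; mismatched identifier sets
  raise with the orphan lists rather than trusting file order.
- Positions are 1-based; locus ids are `chrN_P`.
- Splitting, initialization, and all operator draws flow from one
  `numpy.random.default_rng` root seed per run; identical seeds give
  bit-identical results.
- I/U of all-empty runs is defined as 1 (and warned): identical runs,
  however empty, are perfectly stable.
- PCC of constant predictions is reported as 0 with a warning.

## Known limitations

- The PCC ranking is marginal: QTLs visible only through interactions
  are invisible to stage 1, and a ridge fitness cannot reward them in
  stage 2. The epistatic simulator options exist to demonstrate this
  limitation, not to overcome it.
- Greedy LD pruning keeps the first-ranked member of each LD clique;
  with noisy rankings the kept representative may be a neighbour of the
  causal SNP rather than the causal SNP itself. Concordance is
  therefore measured in LD terms (max r²), not exact identity.
- Candidate-set size is not monotone in α per instance (the greedy rule
  only guarantees the trend on average).
- The GA offers no optimality guarantee beyond the small-space oracle
  checks; K, S and L trade runtime against search quality.
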