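# Methods

`domcrf` predicts protein–protein interactions (PPI) from domain–domain
interactions (DDI), combining two signals: coevolution between domain
alignment columns, summarized as a per-domain-pair mutual information score,
and a conditional random field (CRF) over protein-pair and latent domain-pair
variables trained on labeled interaction data.

## Mutual information between domains

For domains D_m and D_n with multiple sequence alignments, rows are paired by
organism: within each organism, rows of the two alignments are matched
greedily in file order, up to the smaller per-organism count; unmatched rows
are excluded from every frequency count. How multiple same-organism rows
should be matched is underdetermined in general; file-order greedy matching
is deterministic and reproducible, which we prioritize. M denotes the number
of paired rows.

Column statistics use a 21-letter alphabet (20 amino acids plus the gap,
treated as a residue type). Ambiguity codes and Stockholm insert-state
characters ('.', lowercase) are normalized to the gap so the alphabet stays
exactly 21. Frequencies are pseudocounted with the normalization-preserving
mixture

    f~ = (f_raw + η/q) / (1 + η),   q = 21 (marginals), 441 (joint tables),

with η = 1 by default. Two consequences worth noting:

* the pseudocounted joint marginalizes *exactly* to the pseudocounted
  marginals, so MI decomposes as H_i + H_j − H_ij; the implementation uses
  this for speed (count-indexed entropy lookup tables) and the test suite
  cross-checks it against the literal 441-cell KL sum;
* η = 1 mixes half of the probability mass to uniform, which caps the
  measurable MI well below ln 21 ≈ 3.04: even a perfect permutation coupling
  over the full alphabet measures ≈ 0.92 nats in the infinite-data limit.
  Practical M_mn values therefore live on a compressed scale ending slightly
  above 0.8 — consistent with published M_mn distributions that are almost
  entirely below ≈ 0.8.

MI for a column pair is the KL divergence between the joint and the product
of marginals, in nats. Finite-sample MI is biased upward, so a shuffle null
is subtracted per column pair: the row pairing is permuted uniformly at
random, MI is recomputed, and the mean over 400 repetitions is taken.
Columns with a gap fraction above 20% (computed over paired rows, the
population the frequencies use) are excluded. The domain score is

    M_mn = max over kept column pairs (i, j) of [ MI_ij − ⟨MI_ij^shuffle⟩ ].

The null is subtracted *before* the max and negative corrected values are not
clamped, so M_mn ≤ 0 is possible when no column pair beats its null. For a
domain paired with itself the diagonal i = j is excluded (its MI is the
column entropy, not coevolution). The per-pair RNG is seeded from the global
seed and the sorted domain ids, making the score symmetric and bit-for-bit
reproducible; inside `compute_domain_mi` one permutation per repetition is
shared by all column pairs, reflecting that a shuffle re-pairs whole
sequences, not individual columns. Because every shuffle MI is non-negative,
corrected MI never exceeds raw MI; column pairs are scanned in decreasing
raw-MI order and the scan stops when no remaining pair can beat the current
best — an exact pruning, asserted against the exhaustive scan in tests.

Degenerate inputs (fewer than two paired rows, or all columns masked) yield
an explicit "MI unavailable" result; downstream, such pairs fall back to the
MI-free local feature.

## The CRF

Proteins are multisets of domains; a labeled protein pair (P_i, P_j) is
coupled to one latent binary variable D_mn per unordered domain-type pair
contained in it (D_m in P_i and D_n in P_j, or swapped; repeated domains do
not multiply variables). The joint model is

    Pr(p_ij | M) ∝ Σ_d exp( Σ_mn λ_mn g^{(mn)}(p_ij, d_mn) ),

with one weight λ_mn per domain pair. The additive exponent factorizes the
latent sum: S_p = Π_mn (e^{λ g(p,0)} + e^{λ g(p,1)}), Z = S_1 + S_0, all in
log space. The local feature is

    with MI:     g(1,1) = σ(M_mn − c),  g(0,1) = −1,  g(1,0) = g(0,0) = 0
    without MI:  g(1,1) = +1,           g(0,1) = −1,  g(1,0) = g(0,0) = 0

where σ is the logistic function and c > 0 a threshold on the M_mn scale
(package default 0.8). The −1 entry penalizes a domain pair "interacting"
inside a non-interacting protein pair. When M_mn is unavailable the with-MI
variant uses the MI-free row for that pair.

Training maximizes the conditional log-likelihood l(λ) = Σ [log S_{p_ij} −
log Z_ij] with limited-memory BFGS from λ = 0 (history 6, gradient tolerance
1e-5, 500 iterations). The gradient has the standard observed-minus-expected
form with latent expectations E[g | p=1] = g11·σ(λ·g11) and E[g | p=0] =
−σ(−λ), verified against central finite differences. An optional l1 penalty
(off by default) is implemented exactly via the positive/negative split with
bound-constrained L-BFGS-B. Prediction returns S_1/Z; domain pairs unseen in
training contribute neutral λ = 0 factors.

A structural fact guides interpretation: l depends on λ only through each
pair's logit Σ_mn [log(1+e^{λ g11}) − log(1+e^{−λ})], and each summand is a
strictly increasing bijection of λ_mn. The feature variants are therefore
reparameterizations of one model class — at the exact optimum they induce
the same fitted pair probabilities wherever the optimum is unique. They can
differ only through how the optimizer resolves credit-assignment ridges
(domain pairs that co-occur across the same protein pairs), which is where
the MI conditioning acts: it tilts ridge splits toward high-MI pairs.

### Choosing c

The threshold c separates the bulk of (mostly non-interacting) domain scores
from the high-MI tail. On curated full-scale alignments the bulk ends near
0.8, hence the package default. On other inputs the M_mn scale differs (see
the pseudocount ceiling above), so the benchmark pipeline calibrates c from
the observed score distribution — the 95th percentile of all M_mn, i.e. the
upper edge of the background bulk — via `pipeline.calibrate_c`.

## Baselines

Association: λ_mn = I_mn/N_mn, the interacting fraction among protein pairs
containing the domain pair. On binary labels this coincides exactly with the
APM weighted estimator (the test suite checks this against a literal APM
implementation). EM: maximum likelihood in the noisy-OR generative model
Pr(P=1) = 1 − Π(1 − λ_mn) with observation noise Pr(O=1|P=1) = 1 − fn
(fn = 0.8 by default) and Pr(O=1|P=0) = fp. fp is required by the model but
rarely reported; the default 1e-4 avoids the degeneracy where an observed
interaction with all-zero λ has probability zero. EM starts from the
association solution and iterates the posterior-mean update; the observed-
data log-likelihood trace is recorded and asserted non-decreasing.

## Evaluation protocol

Negatives are sampled uniformly without replacement from unordered protein
pairs outside the positive set, as many as there are positives. Labeled
pairs are split into five stratified folds (the split method is otherwise
unspecified; stratified shuffling keeps folds balanced). Per fold, methods
are fit on four folds; the held-out fold keeps only pairs containing at
least one domain pair present in that fold's training data (the rest carry
no estimated parameter). AUC uses the rank statistic with midrank ties; a
fold whose filtered test labels are single-class records a missing test AUC
rather than an arbitrary 0.5.

## Synthetic data generator

The generator produces desk-scale inputs with the statistical structure the
method assumes. Defaults define the standard study and were fixed once, on
realism grounds:

* **Network.** 200 proteins over 60 domains, 1–2 domains per protein, domain
  usage Zipf-weighted (exponent 0.7) — real domain families are heavy-tailed.
  Five "truly interacting" domain pairs, placed on domains whose carrier
  product gives at least 50 supporting protein pairs, each with interaction
  probability λ* = 0.75. Labels follow the noisy-OR law; 150 observed
  positives and 150 uniformly sampled negatives are returned. Observation
  noise (fn*, fp*) is available but defaults to zero: at this scale the
  λ* < 1 Bernoulli draws already provide label stochasticity.
* **Architecture coupling.** Each interacting domain travels with a fixed
  companion domain (probability 0.9), emulating conserved multi-domain
  architectures. Companion pairs co-occur with interaction labels without
  causing them — the credit-assignment ambiguity that motivates conditioning
  on MI.
* **Alignments.** 100 organisms × 1 sequence, 8 columns per domain, gap rate
  0.05, background columns i.i.d. from Dirichlet(0.5) profiles. Each true
  pair has exactly one coevolving column pair drawn from the mixture
  ε·(uniform product) + (1−ε)·(permutation coupling) over q = 5 residues,
  with ε solved so the population MI is 1.5 nats (q = 5 keeps 1.5 ≤ ln q
  while minimizing pseudocount shrinkage; contact-constrained positions
  explore restricted residue repertoires). Under η = 1 and the shuffle
  correction this measures as M_mn ≈ 0.55–0.65 at M = 100, an order of
  magnitude above the ≈ 0.05 background.
* Organisms are i.i.d. — no phylogeny, no shared-ancestry MI inflation. The
  generator therefore exercises the estimator, not the phylogenetic
  confounding that real alignments add; passing tests bound correctness, not
  field performance.

Everything is driven by one seed; identical configurations produce
byte-identical files.

## What the recovery study shows — and a known limitation

On five seeded replicates of the standard study, both CRF variants recover
the planted interactions with mean test AUC ≈ 0.96–0.97, well above EM and
association (≈ 0.83), and all methods are near-perfect on training folds —
matching the qualitative behavior reported for real interactome data.

The two CRF variants, however, are statistically indistinguishable here, with
the MI-free variant marginally ahead (Δ ≈ 0.005). This follows from the
reparameterization fact above: with only five true domain pairs, each
supported by ~30 positive pairs, the optimum pins their weights, and the
remaining ridges lie between background pairs, where σ(M_mn − c) injects
estimation noise rather than signal. The MI conditioning earns its keep in
the sparse-support regime of real curated data — hundreds of distinct domain
pairs, most seen once or twice, where nearly every positive pair is its own
ridge and MI is the only tie-breaker. That regime cannot be emulated with
five well-supported true pairs, and we report the limitation rather than
re-weighting the benchmark around it.

## Numerical choices

* Natural logarithms throughout; c is interpreted on the same nat scale.
* log-sum-exp / `logaddexp` for all likelihood terms; probabilities via the
  logistic of logit differences, never via ratios of exponentials.
* Tiny negative MI values (float noise) are clamped to zero; corrected MI is
  not clamped.
* Midrank tie handling in AUC; trapezoidal curve integration agrees to
  1e-10 in tests.
* Per-domain-pair RNG streams derive from (global seed, CRC32 of the sorted
  domain ids), so results are independent of evaluation order.

## Problem sizes

Unit and property tests run on toy instances (alignments of 3–100 rows,
factor graphs of tens of pairs; enumeration oracles up to 2^13 states and
5! pairings). The recovery study uses the full default configuration above,
five replicates, ~55 s each on one core; the acceptance script runs one
replicate.
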