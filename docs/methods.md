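# Methods

## Model and hypotheses

Sequences are modelled as stationary, homogeneous Markov chains over a
finite alphabet of C symbols (DNA, C = 4, by default; every degrees-of-
freedom formula is parameterized by C).  An order-r chain is a
row-stochastic table mapping each of the C^r contexts to a next-symbol law,
plus an initial law over contexts, taken to be the stationary law unless
given explicitly.  The stationary law is obtained by solving v·P = v on the
chain lifted to C^r context states (least squares with a sum-to-one row,
after a rank check that rejects reducible chains); this is exact and cheap
for the orders the method targets (r ≤ 3).

Two sources are compared by testing H₀ "same transition matrix" against H₁
"different matrices" at word length k, i.e. as order-(k−1) chains.  The
log-likelihood ratio (long sequences only) and the chi-square statistic S_k
follow the standard pooled-count construction; for k = 1 the statistic
reduces to the frequency-difference form with the window totals playing the
role of the prefix counts, and the two printed forms are one algebraic
identity (verified exactly in the tests).  Under H₀, S_k is approximately
χ² with df = (C−1)·C^(k−1).

The first k−1 positions of each sequence enter only through the initial
law and are ignored by the likelihood, exactly as in the pooled-count
construction; this affects only O(k/L) terms.

## Reads

The statistic depends on counts alone, so read sets are handled by counting
each read's κ−k+1 windows separately (never across read boundaries).
Overlapping reads are positively dependent; if the genome splits into
regions of constant per-base coverage r_i occupying fractions f_i, the
statistic is inflated by d = Σ r_i² f_i / Σ r_j f_j, and S_k^R/d has the
same χ² limit.  Under uniform (Lander–Waterman) sampling at mean depth
λ = Mκ/L, coverage is approximately Poisson(λ) and d = 1+λ.  The package
never guesses d silently: callers supply it as 1+λ, as a number, or via a
coverage profile recomputed from a read layout (read id, start, length
TSV).  The log-likelihood ratio is deliberately unavailable for reads —
the product-form likelihood does not hold under overlap.

The read simulator draws fixed-length reads with replacement from the
forward strand, starts restricted to {0, …, L−κ} (no wrap-around; the edge
effect is O(κ/L)).  Heterogeneous coverage cuts the genome into equal
blocks (default 100), assigns each an independent Gamma(shape 1, scale 20)
intensity — an exponential; after normalization only the shape matters —
and weights each start position by its block's intensity.  A read spanning
a block boundary is weighted by the block of its start.  Sequencing errors
are substitution-only, each base independently miscalled with the given
rate (default 0.005), uniformly over the other C−1 symbols; no indels, no
quality model.

## Order estimation

Six estimators, all scanning word lengths and locating where an order-(k−2)
fit starts explaining the length-k counts.  AIC/BIC minimize the penalized
likelihood over k = 0..k_max (long sequences only).  The count-based scans
(Peres–Shields Δ^k, the goodness-of-fit sum T_k, its log tail probability
log p_k, and the maximal standardized deviation Z_max) evaluate
k = 1..k_max+1 and search ratios over k = 1..k_max, so orders 0..k_max−1
are estimable; k_max defaults to 6, the largest word length the comparison
method realistically uses.  Ties break toward the smallest k (parsimony),
and an exactly zero ratio denominator — a perfect fit at that level — maps
the ratio to +infinity so that larger orders are not chosen on 0/0 noise.

Numerical choices that matter:

* **k = 1 baseline.**  E_w needs length-(k−2) marginals and is undefined at
  k = 1; there the uniform law E_w = total/C is used (with both marginals
  replaced by total/C in the variance), the natural degenerate extension
  that makes order 0 estimable.  This baseline is a package choice, not
  part of the classical estimators.
* **Log-space tails.**  For k ≤ r+1 on multi-kilobase inputs T_k's tail
  probability underflows double precision; log p_k is evaluated directly in
  log space, with an asymptotic upper-incomplete-gamma expansion taking
  over where even `logsf` underflows (below log p ≈ −745).  Without this
  the p-ratio scan degenerates to ±inf/±inf.
* **Sparse-table df.**  T_k is a sum of per-middle-word independence
  statistics; each stratum m contributes (r_m−1)(c_m−1) df over its
  observed first/last-letter support.  For dense tables this is exactly
  (C−1)²C^(k−2); on sparse tables (large k, desk-scale L) tiny strata are
  fitted exactly — zero contribution to T_k — and counting them in the df
  would saturate p_k at 1 and break the ratio scan.  Cells with zero
  expectation or zero variance are likewise excluded from T_k, Δ^k, and
  Z_max, since the asymptotics assume positive cell expectations.

On reads, AIC/BIC are rejected (the likelihood is intractable under
overlap); the four count-based estimators apply unchanged.  Coverage
overlap inflates T_k by ≈ d at every k, which visibly degrades the
Δ-, T- and Z-ratio scans; the log-p ratio is the one estimator that stays
reliable on reads, and it is the recommended default there.

## Power protocol

Power at word length k is estimated by Monte Carlo: simulate replicate
pairs under H₀ (both sources from one model, stationary start), take the
empirical 95th percentile of the statistic as the threshold, then report
the fraction of H₁ replicates (two different models) above it.  Because
the threshold is an empirical quantile of the same statistic, the coverage
scaling d cancels and the raw statistic is used; the χ² threshold route is
kept separately for calibration checks.  Null and alternative replicates
are shared across word lengths (each simulated pair is scored at every k),
matching the single-threshold protocol and reducing Monte Carlo variance;
thresholds are computed once per configuration.

`power_loss_experiment` estimates the orders of both simulated sources per
replicate, scores the statistic at k̂ = max(r̂₁, r̂₂)+1 against the
matching per-k threshold, and reports power(k_opt) − power(k̂), where
k_opt = max(r₁, r₂)+1 uses the *effective* orders of the generating models
(a structurally second-order table whose rows depend only on the last
symbol counts as first order).

Default study conditions mirror the simulation design the statistics were
developed under: the doubly stochastic first-order base chain (uniform
stationary law); its second-order perturbation family with offsets
(+p1, −p1, +p2, −p2) per first-context-symbol group — all pairs 0.05 for a
first-order alternative, (0.05, −0.05, 0.03, −0.03) by group for a
second-order alternative; L = 10–30 kb; 2000 null replicates for
calibration and 500 per arm for power curves; nominal level 0.05; reads
with κ = 200, M = 100–200 (λ = 1–2), homogeneous or 100-block Γ(1,20)
heterogeneous sampling; error rate 0.005.  The acceptance suite runs these
problem sizes directly; they are desk-scale by construction.

## Reproducibility

Every stochastic operation takes an explicit integer seed (or numpy
Generator).  Experiments derive independent child streams from the base
seed via `SeedSequence`: one per simulated source for the replicate-batched
sequence engine (the per-position loop is vectorized across replicates,
which is what makes 2000-replicate studies take seconds), and one per
replicate index for read sampling and errors.  Statistics sum words in
lexicographic order, so results are bit-for-bit reproducible across runs.

## What the simulations do and do not show

The generators emulate the idealized conditions of the theory: exactly
Markov sources, stationary starts, independent fixed-length single-end
reads, substitution-only errors.  Real genomes are not Markov chains, are
related by descent rather than independent, have composition and repeat
structure that varies along the sequence, and real libraries have
length-varying, strand-symmetric, indel-bearing reads with position-biased
coverage.  Passing tests therefore validate the statistics, the estimators
and their calibration under the stated model — not the adequacy of that
model for any particular biological comparison.  Known limitations: no
reverse-complement symmetrization (single-strand convention), dense count
tables guard k ≤ 12, the coverage scaling for real unmapped reads must be
supplied by the caller, and selectivity/sensitivity is provided as a
generic ranking metric without any bundled reference data.
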