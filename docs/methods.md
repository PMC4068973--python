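# Methods

This note documents the statistical model, the numerical choices, and the
limits of what the synthetic benchmarks demonstrate.

## Probe-sequence similarity

Two probes are compared by a global Needleman–Wunsch alignment with an
affine gap model (match +1, mismatch −1, gap open −2, gap extend −1).
End gaps are penalised like internal gaps. This matters: because the length
difference between two probes must appear as gaps somewhere, the end-gap
cost is constant across placements, so a 60-mer still aligns against its
best-matching window inside a 250-mer; but with *unpenalised* end gaps the
optimal alignment of two unrelated sequences degenerates to a tiny perfect
overlap (score = overlap length, zero mismatches), which would assign
similarity 1.0 to essentially every random pair and erase the intra-gene /
inter-gene contrast the whole bridge depends on. `N` bases never match,
including against another `N`.

The evolutionary distance is the two-sequence maximum-likelihood branch
length under the Jukes–Cantor (JC69) substitution model, which has the
closed form `d = −(3/4)·ln(1 − (4/3)·p)` with `p` the mismatch proportion
over aligned (non-gap) columns. JC69 was chosen because it is the simplest
model with the required behaviour and its closed form gives the test suite
an independent oracle. `d` is clamped into [0, 1]; `p ≥ 0.75` (where the
log saturates) and alignments with no overlapping columns map to `d = 1`.
Similarity is `1 − d`. Note the clamp makes similarity 0 for any
`p ≳ 0.55`, so unrelated sequences score 0 rather than small positive
values.

## Panel resolution

A panel element is a `platform–probe–gene` identifier. On a target platform
that carries the gene, the same-gene probe most similar to the source probe
is used (relevant when a platform carries several probes for one gene); on
a platform lacking the gene, the most similar probe overall acts as a
substitute. Ties break to the smallest canonical probe index, making
resolution deterministic. No similarity floor is imposed on substitutes:
a panel bridged through a poor substitute simply scores a poor likelihood
and loses in the search. Two panel genes may resolve to the same probe; the
resulting rank-deficient design is fitted with a pseudo-inverse step and
flagged rather than rejected.

## Logit fitting

Coefficients are estimated by Newton–Raphson on internally standardised
predictors with step-halving, so the log likelihood is non-decreasing
across iterations; convergence is `max |score| < 1e-8` or 100 iterations.
Results are reported on the original predictor scale. Small panels on small
samples frequently separate perfectly, where the true MLE is at infinity:
any standardised coefficient beyond ±30 is clamped and the fit flagged
`separated`, as is any converged fit whose training probabilities all sit
within 1e-6 of the labels. The log likelihood is evaluated in log space
with probabilities clipped to `[1e-12, 1 − 1e-12]`, so it is always finite
and strictly negative; a separated fit therefore scores very close to zero
and the search still prefers separating panels, without overflow.

The score of a multi-dataset panel is the unweighted arithmetic mean of the
per-dataset sibling log likelihoods, even when sample sizes differ: each
dataset contributes one sibling model, and the average ranks panels rather
than pooling samples. Because every fit happens within a single dataset, no
cross-platform intensity normalisation is required, and intensities are
used exactly as supplied.

## Genetic algorithm

Defaults: population `PS = 300`, generations `MG = 50`, crossover rate
`TXR = 0.5`, stopping threshold `TLC = 0`, panel size `k = 8`. Since log
likelihoods are negative, `TLC = 0` disables early stopping in practice.
Design points the search fixes where several readings were possible:

* **Roulette weights.** Fitness-proportional selection needs positive
  weights; log likelihoods are min-shifted and floored at
  `eps = 1e-6·(max − min + 1)`, preserving strict monotonicity while
  keeping the worst panel selectable.
* **Crossover.** Kept panels are paired sequentially (1–2, 3–4, …) and each
  locus position swaps between the pair with probability `TXR`. A swap that
  would duplicate a gene within a panel is skipped, since panels hold
  pairwise-distinct genes by construction.
* **Replacement.** With probability 0.5 per panel per generation, the locus
  with the smallest mean |standardised coefficient| across the panel's
  sibling fits — the member least associated with the outcome anywhere —
  is replaced by a uniformly drawn identifier whose gene is not already in
  the panel. Standardised coefficients are used because they are comparable
  across predictors of different scales.
* **Elitism and caching.** The best panel ever evaluated is tracked and
  returned, so the reported optimum never degrades; fitness is memoised on
  the panel's identifier set, so re-visited panels are never refitted.

All randomness flows from one integer seed through a single generator, so
identical seeds reproduce identical elites bit for bit.

`exhaustive_search` enumerates every distinct-gene panel (each gene
represented by its first identifier in canonical order) and serves as the
optimum oracle on small instances; it refuses instances above 1e5 panels.

## Evaluation

The reciprocal test mines a panel on all datasets but one and scores the
held-out dataset by leave-one-out cross-validation: per fold, coefficients
are refitted on the remaining samples and the held-out sample is classified
at threshold 0.5. Refitting is the default because coefficients are
dataset-specific by design; `refit=False` instead transfers the average of
the training siblings' standardised coefficients, for the reading in which
the trained model itself carries over. The defective-model ablation
re-scores each of the k leave-one-member-out panels the same way (always
refitted — a reduced panel has no meaningful transferred coefficients).

## Synthetic worlds

The generator emulates the structural heterogeneity of multi-platform
inputs: per gene a random reference region (twice the longest probe
length); per platform, genes covered independently with probability
`gene_coverage`, each covered gene contributing probes that are mutated
(`mut_rate`, default 0.02) random windows of the reference; per-platform
probe lengths (default 250/250/60, mirroring target-sequence versus
spotted-oligo designs). Labels follow a logistic law on latent standard-
normal gene values; probe intensities are the latent value plus
`N(0, noise_sd²)` noise, so same-gene probes correlate. Unplanted genes
carry no label effect and act as decoys for the ablation.

Benchmark configurations, fixed once:

* **Recovery benchmark** — 10 genes, 3 platforms, 60 samples, planted pair
  with standardised log-odds (4, 4), noise SD 0.1. Used for
  GA-versus-exhaustive equivalence and planted-pair recovery.
* **Accuracy benchmark** — identical except log-odds (15, 15). At (4, 4)
  the label law itself has a Bayes-optimal accuracy of only ≈0.906 (Monte
  Carlo), so no method can reliably exceed 0.9 held-out accuracy; at
  (15, 15) the Bayes rate is ≈0.974 and any shortfall measures the method,
  not irreducible label noise. Used for held-out accuracy, null
  calibration (effects zeroed), and the defective-panel gap.
* **Search benchmarks** run at PS = 30, MG = 25 (and PS = 8, MG = 3 for the
  k-scaling measurement on a 20-gene world) — the 45-panel search space of
  the 10-gene benchmark is saturated many times over at these sizes, and
  they keep the suite fast; the CLI retains the full defaults.

What passing these benchmarks does **not** show: robustness to platform-
specific intensity scales and batch effects, probe GC/affinity biases,
many-probes-per-gene summarisation choices, or gene panels whose signal is
weaker than the planted effects. The generator's label law matches the
fitted model family, so benchmark accuracy is an upper bound on what
misspecified real data would give.

## Degenerate inputs and edge cases

Single-class datasets are rejected by the fitter and named by
`identify_clm`. LOOCV requires at least two samples per class; a fold whose
training half loses a class is skipped with a warning and counted.
Constant predictor columns are flagged and their coefficients pinned to
zero. The similarity matrix file stores the full square matrix; on read the
upper triangle is authoritative, asymmetry beyond 1e-6 and values outside
[0, 1] are errors, and the diagonal is pinned to exactly 1.0.
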