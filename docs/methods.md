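# Methods

## Problem and model

Super-enhancers (SEs) are clusters of enhancers with exceptionally high
coactivator and transcription-factor occupancy; typical enhancers (TEs)
are everything below the cutoff on the ranked-signal curve. `seforge`
implements the full analysis chain used to define and classify them:

1. **Signal quantification.** ChIP-seq-style reads are extended 200 bp
   from their 5′ end in the 3′ direction (a fragment-length proxy), and a
   region's density is the number of extended reads overlapping it by at
   least one base, normalized to reads per million mapped reads per base
   pair (rpm/bp). ChIP densities are background-subtracted against a
   matched input and floored at zero; DNase-style inputs skip
   subtraction. Counting is per-read, not per-base pileup averaging: it
   matches the read-count semantics of the rpm/bp unit and is exactly
   testable against the closed form, at the cost of a small divergence
   from per-base pileup tools on reads partially overlapping a boundary.

2. **SE calling.** Constituents fully contained within ±2 kb of a TSS are
   removed, the remainder stitched per chromosome when the inter-
   constituent gap is ≤ 12.5 kb (inclusive at the boundary, for
   determinism), and each stitched region scored by the sum over members
   of background-subtracted density × member length (constituent-centric,
   not whole-span density). With signals sorted ascending s₀…s₍N₋₁₎ and
   both axes normalized to [0, 1] (xᵢ = i/(N−1), yᵢ = sᵢ/max s), the
   hockey-stick cutoff is argminᵢ (yᵢ − xᵢ) — the tangency point of a
   slope-1 line on the curve. Ties break toward the largest index, so
   flat or exactly linear curves yield zero SEs; the SE rule is strict
   (signal > cutoff signal), so the tangency region itself is a TE.
   TSS exclusion runs before stitching and removes only fully contained
   constituents; partial overlaps are kept.

3. **Feature engineering.** Sequence features per constituent: size (bp),
   GC fraction (N excluded from the denominator), softmask repeat
   fraction, base-weighted mean conservation (uncovered bases count 0),
   TRAP motif affinity per PWM, thresholded motif hit counts, and
   canonical k-mer spectra (k = 5 by default, lexicographic min of k-mer
   and reverse complement, window counts normalized by valid window
   count). TRAP computes expected occupancy: per window,
   Eᵢ = (1/λ) Σⱼ ln(p_max,j / p_base,j) and the window contributes
   R₀e^(−Eᵢ)/(1 + R₀e^(−Eᵢ)) with R₀ = exp(0.584·L − 5.66), λ = 0.7 —
   the method's published defaults, all configurable. Windows containing
   N contribute 0 (TRAP) or are skipped (k-mer/motif counting); no
   probabilistic imputation. The motif-hit threshold is a fraction
   (default 0.8) of the maximum achievable log-odds against a uniform
   background, since no absolute threshold is canonical.

4. **Class balancing.** SMOTE with Weka semantics: oversampling
   percentage a multiple of 100 (whole passes over the minority set in
   row order), each synthetic point interpolated uniformly between a
   minority row and one of its k = 5 nearest minority neighbours
   (Euclidean on raw features, ties by row order). The hybrid scheme
   grows the minority to m·(1 + pct/100) rows and under-samples the
   majority to exactly that size, giving a 50/50 output; synthetic rows
   carry a `synthetic_` id prefix.

5. **Feature ranking.** Shadow-feature (Boruta-style) ranking: per
   iteration a shuffled copy of every feature is appended, one random
   forest (20 trees) is fitted, and real and shadow impurity importances
   come from that same fit; a feature "hits" when it beats the best
   shadow. A two-sided binomial test of hits vs Binomial(iterations, 0.5)
   at α = 0.01 classifies Confirmed/Tentative/Rejected. This is the
   single-pass variant (no iterative removal), with 50 iterations by
   default. The out-of-bag check is a hand-built bagged forest (own
   bootstrap indices, √p feature subsampling per tree): importance is the
   mean OOB accuracy drop after permuting one feature within the OOB rows.

6. **Classification benchmark.** Six models: random forest (20 trees),
   linear-kernel SVM (C = 1), k-NN (k = 5), AdaBoost (50 stumps),
   Gaussian naive Bayes, decision tree; RBF and polynomial SVMs are in
   the closed set for comparison. Stratified k-fold CV (per class,
   seeded shuffle dealt round-robin; folds shared across models). Pooled
   metrics on concatenated held-out scores are the headline numbers;
   per-fold means ± SD are also retained. ROC AUC is the Mann-Whitney
   rank statistic (ties 1/2), identical to trapezoidal integration;
   PR AUC is step-wise (average precision). SVM decision values are
   min-max rescaled to [0, 1] per fold. The AUC permutation test swaps
   paired scores per row with probability 1/2 and reports
   p = (1 + #{d ≥ d_obs})/(1 + n_perm), so p is never 0.

7. **Gene assignment.** Every transcriptionally active gene
   (RPKM ≥ 1.0 by default; the activity threshold is not canonical and is
   exposed) is assigned to every region whose nearest edge is within
   50 kb of its TSS — all genes in the window, not nearest-only.

## Synthetic data

The generator plants ground truth so every stage is testable offline:
two 6-Mb chromosomes (12 Mb total) of i.i.d. sequence at GC 0.42 with a
0.3 softmasked fraction; 600 TE constituents placed singly and 60 SE
constituents in 20 clusters of 3, with log-normal sizes (medians 700 bp
TE, 860 bp SE), SE spans rewritten at GC +0.05, and all planted units
separated by more than the stitching distance so each maps to exactly one
stitched region. Read libraries (100,000 reads of 36 bp, Bernoulli
strand) split half uniform background, half across constituents with
weight length × effect (SE:TE density ratio 8 for the informative factor;
effect 0 gives a uniform input library) via one multinomial draw — a
conditioned-Poisson placement that conserves the library size exactly.
200 TSS are placed in inter-unit gaps; RPKM is log-normal (σ = 1) with
SE-adjacent genes (within 50 kb of a planted SE) shifted by 2 natural-log
units. A separate class-conditional Gaussian table (660 rows, 45
features, 6 informative at Δ = 1.5 SD) feeds the ranking and
classification tests directly.

What the generator does **not** emulate: fragment-length and GC bias,
mappability, duplicate reads, correlated features, dependent enhancer
spacing, and realistic conservation tracks. Passing tests therefore show
the arithmetic and algorithms are correct and well calibrated on clean
class structure — not that the classifiers would reach the same
performance on real chromatin data.

## Numerical choices and degenerate inputs

- The hockey-stick cutoff requires ≥ 2 regions and a positive maximum;
  all-zero signal vectors are an error. Scale invariance (signals × c)
  is exact.
- Densities floored at 0 after subtraction keep downstream features
  non-negative; the floor can be disabled.
- Reads of unknown strand are a hard error when extension is requested
  (no silent symmetric extension).
- Wilcoxon uses exact enumeration for pooled n ≤ 12 (ties handled via
  midranks), the tie-corrected normal approximation above.
- Feature-matrix text round trips are bitwise stable at 6-decimal fixed
  precision; constant columns in correlation matrices are reported as
  missing with a warning rather than silently dropped.
- All stochastic components take explicit seeds; generators draw from
  independent substreams of the config seed, so outputs are mutually
  deterministic and the end-to-end pipeline manifest is bitwise
  reproducible.

## Problem sizes

Tests and the acceptance script run the default simulation (660
constituents, 100k reads per factor) over 5–10 seeds, ranking recovery at
n = 500 rows × 50 iterations, null calibration over 20 seeds, and the
classifier null at n = 2,000 — sizes chosen so the full chain exercises
every code path at desk scale while the planted effects (8× density,
2 SD feature shift) remain comfortably detectable.

## Known limitations

- Per-read overlap counting diverges from per-base pileup averaging for
  reads partially overlapping region edges.
- The SMOTE neighbour search is O(m²) in the minority size — fine at the
  thousands scale this problem has.
- No BAM/CRAM-native input; reads are consumed as BED6 (convert with
  `bedtools bamtobed`).
- The TRAP and motif-threshold parameterizations are sensible defaults,
  not fitted values; absolute affinity scales should not be compared
  across differently parameterized runs.
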