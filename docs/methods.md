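# Methods

`bandnet` implements a frequency-resolved functional-connectome
classification pipeline for two-group resting-state fMRI studies, together
with a synthetic-cohort generator used to validate every stage of the
pipeline when the motivating clinical data (two sub-stages of mild
cognitive impairment, EMCI vs LMCI, 33 + 29 subjects, 90-ROI AAL
parcellation at TR = 3 s) cannot be redistributed.

## Pipeline

1. **Band decomposition.** Each ROI time series is split into a full band
   (0.01–0.08 Hz), slow-4 (0.027–0.08 Hz) and slow-5 (0.01–0.027 Hz).  The
   filter is implemented as the orthogonal projection onto the intersection
   of the band-limited subspace (rFFT bins inside the closed interval) and
   the trend-free subspace (orthogonal complement of span{1, t}).  This is
   equivalent to ideal frequency-domain masking with built-in linear
   detrending, but unlike the naive detrend-then-mask composition it is
   exactly idempotent; it is also exactly linear and zero-phase.  The
   slow-4 upper edge follows the 0.08 Hz convention used alongside the full
   band (some decompositions print 0.073 Hz); it is configurable.

2. **Connectivity.** Pearson correlation between every ROI pair,
   variance-stabilized by Fisher's r-to-z (atanh) with |r| clipped at
   0.999999 so the matrix stays finite.  A zero-variance ROI is a hard
   error naming the ROI.

3. **Binarization at cost.** At cost c the round-half-up(c·n(n−1)/2)
   strongest edges are kept.  Ranking is by signed z by default — the
   literal reading of keeping the *largest* weights, and the safer choice
   on global-signal-regressed data where strong negative correlations are
   ambiguous; `rank_by="absolute"` is available for sensitivity analysis.
   Ties break by lexicographic (i, j), which makes edge sets exactly
   monotone in cost and the whole operation invariant to any strictly
   increasing transform of the weights.

4. **Graph measures.** Binary undirected definitions throughout
   (Rubinov–Sporns conventions): BFS hop distances; nodal path length as
   the mean distance to *reachable* nodes (isolated nodes score 0 with a
   warning); degree; unnormalized fractional-count betweenness over
   unordered pairs (Brandes accumulation, O(nm)); triangle clustering;
   global efficiency with 1/∞ = 0; local efficiency as the mean global
   efficiency of neighborhood subgraphs; characteristic path length over
   reachable unordered pairs with the excluded fraction reported alongside
   (cost-8% networks on 90 nodes are routinely disconnected, so this
   convention keeps the measure finite and comparable); small-worldness
   σ = (C/C_rand)/(L/L_rand) against degree-preserving rewired surrogates
   (default 100 surrogates, 10×edges swap attempts each, seeded).

5. **Nodal feature tables.** Per band: degree, betweenness and nodal path
   length for each of the 90 ROIs in the fixed block order ND | BC | NL —
   270 features; the "all" table concatenates full | slow-4 | slow-5
   blocks — 810 features.

6. **Feature selection.**
   * *mRMR*: features are discretized to three levels at mean ± sd (the
     canonical mRMR convention; the estimator is exposed in config),
     mutual information is the plug-in estimate in nats, and selection is
     the standard greedy first-order incremental search: max relevance
     first, then relevance minus mean redundancy against the selected set.
     The set-level objective is NP-hard; the greedy search approximates it
     and coincides with the exhaustive subset optimum on most but not all
     instances (measured ~77–97% on random 5-feature instances, exactly
     100% when pairwise redundancies vanish).  Ties break to the lower
     feature index.
   * *SS-LR (stability selection)*: an L1-penalized linear regression on
     ±1 labels (objective (1/n)‖Xw−y‖² + λ‖w‖₁, columns standardized
     internally) is fit on 100 half-sized subsamples over the penalty grid
     λ ∈ {0.055, 0.060, …, 0.295} (the open interval (0.05, 0.3) at step
     0.005); a feature's score is the maximum over λ of its
     selection frequency, and features are ranked by score.  No frequency
     threshold is applied because the pipeline consumes top-K rankings.
     The coordinate-descent solve is delegated to scikit-learn's Lasso
     (α = λ/2 maps the objectives exactly); subsamples with one class are
     redrawn and logged.
   * *Fisher Score*: n₁(m₁ᵢ−mᵢ)² + n₂(m₂ᵢ−mᵢ)² over n₁σ₁ᵢ² + n₂σ₂ᵢ²,
     population (class-size) variances.  Zero pooled variance scores 0
     when the class means agree and +∞ (ranked first) when they differ.

7. **Classification.** RBF-SVM with K(x₁,x₂) = exp(−‖x₁−x₂‖²/σ²) — note σ²
   in the denominator and no factor 2 — evaluated by nested
   cross-validation: outer leave-one-out; feature selection, feature
   standardization and hyperparameter tuning run on each outer training
   set only; inner stratified 10-fold grid search over
   C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵} and σ ∈ {2⁻⁴, …, 2⁶} maximizing inner accuracy,
   ties toward smaller C then smaller σ.  Stratified inner folds are used
   because a 29/33-style imbalance makes unstratified 10-fold unstable.
   The margin solver is scikit-learn's SVC on our precomputed Gram matrix.
   ACC/SEN/SPE come from the pooled leave-one-out confusion counts
   (zero-denominator metrics are NaN and flagged, never silently 0); AUC
   is the tie-aware Mann–Whitney statistic of the pooled decision scores,
   identical to the trapezoidal ROC area.  One ROC is pooled across all
   held-out scores because per-fold ROCs are undefined under LOOCV.
   The positive class is configurable; the default takes the second group
   (the LMCI-like group in the motivating study) as positive, which is the
   reading consistent with the published integer confusion counts —
   86.21% sensitivity is an integer count only on 29 subjects.  The same
   source prints specificity as 81.21% in one place and 81.82% in another;
   only 81.82% (27/33) is integer-consistent, and the worked example in
   the tests uses it.

8. **Statistics.** Pooled-variance two-sample t-tests computed from group
   summaries (n, mean, sample SD); Pearson chi-square on 2×2 tables
   *without* continuity correction (the published gender p = 0.316
   reproduces only without it; χ² ≈ 1.004); exact binomial McNemar test on
   discordant pairs (p = min(1, 2·BinomCDF(min(b,c); b+c, ½)) — valid at
   the small discordant counts a 62-subject cohort produces; the
   asymptotic variant is available by flag); per-cost two-sample t-tests
   of the global metrics at α = 0.05, uncorrected by default (matching the
   reference analysis), with a Bonferroni flag.

## Synthetic cohort generator

Each subject's 90 × T signal is a sum of latent band-limited Gaussian
components — slow-5, slow-4, and an out-of-analysis high band — plus white
observation noise.  Component construction: white noise filtered into the
band, standardized row-wise, mixed through the Cholesky factor of the
group's target correlation matrix, and scaled so that component variances
are proportional to bandwidth (what filtered white noise physically
produces; equal-power components would make the wide full band a uniformly
better estimator of any sub-band effect, defeating the purpose of band
localization).  Both groups share a random sparse positive-definite
correlation template (density 0.10, entry magnitudes ~0.25); group B
differs by `delta_correlation` on the configured effect edges, carried
exclusively by the effect band's component (a "full"-band effect is
carried by both sub-band components).  Template entries on effect pairs
are zeroed so the injected delta *is* the group difference, and the
template is shrunk toward identity until both groups' targets are positive
definite with margin; an effect that is infeasible even on an identity
template (or pushes |r| ≥ 1) raises an error naming the offending edges.
Generation is bit-deterministic given the seed.

**Reference validation effect.** The packaged validation scenario
(`module_effect_edges()`) elevates all 15 within-module correlations among
ROIs {5, 7, 9, 11, 13, 15} by +0.50 in the slow-5 band, with 30 subjects
per group, T = 130 at TR = 3 s (a typical run length after discarding
equilibration volumes), and noise SD 0.5.  The module design reflects an
estimation-noise reality: a 130-sample slow-5 series holds only ~7
independent frequency bins, so a single-edge correlation difference —
even a large one — is statistically invisible at n = 30 + 30; detectable
group differences in such data necessarily span many connections, which
is also what the motivating study reported (ten discriminative regions).
Under these conditions the slow-5 band wins the band ranking decisively
(mean nested-CV AUC ≈ 0.7 vs ≈ 0.5 for the diluted full band and ≈ 0.4
for slow-4 across replicate cohorts), and all three selectors place
ground-truth features in their top-10 in essentially every replicate.

**What the generator does not emulate:** voxel-level structure, head
motion, physiological noise, scanner drift, 1/f spectral shape within
bands, hemodynamic autocorrelation, or site effects.  Passing tests
demonstrate that the pipeline recovers known band-localized covariance
structure at realistic noise levels — not that it would achieve any
particular accuracy on clinical data.

## Numerical and protocol choices

* Edge-count rounding is round-half-up; r-clipping at 0.999999; all
  tie-breaks (edge ranking, feature ranking, grid search) are documented
  and deterministic, so every result is bit-reproducible given seeds.
* The lasso convergence tolerance is 1e−8 on scikit-learn's criterion with
  a 100k-iteration cap; non-convergence raises with diagnostics rather
  than returning silently.
* Stability-selection subsamples are ⌈n/2⌉ without replacement.
* Nested-CV fold seeds derive from one `SeedSequence`, so selector
  subsampling and inner-fold shuffling are reproducible per fold.

## Known limitations

* **Pooled LOOCV AUC is very noisy at n ≈ 60.**  Under the null its
  spread (SD ≈ 0.11) is roughly 1.5× the independent-scores value, and it
  carries a systematic pessimistic bias (mean ≈ 0.42–0.47): each held-out
  subject's class is the minority of its training set, so null-data
  predictions tilt against it (the familiar LOOCV "anti-learning"
  artifact).  Observed per-cohort null AUCs range from ~0.15 to ~0.75.
  Consequently single-cohort AUC comparisons between bands are unreliable
  at this sample size; the validation tests average over replicate
  cohorts.  This is a property of the protocol, not an implementation
  fault — it reproduces with a data-independent selector and a single
  hyperparameter point.
* The greedy mRMR search does not always attain the NP-hard set-level
  optimum (see above); the package implements the standard incremental
  algorithm deliberately.
* Test and validation runs use reduced problem sizes chosen for desk-scale
  runtimes: a 3×3 (C, σ) grid (tests) instead of the 11×11 default, 25–30
  stability subsamples instead of 100, and 20 surrogate rewirings in
  small-world unit tests instead of 100.  Library defaults keep the full
  settings.
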