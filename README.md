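# bandnet

Frequency-resolved functional brain-network classification for two-group
resting-state fMRI studies — and a synthetic-cohort generator to validate
every stage when the clinical data cannot be shared.

The package targets the question faced in staging mild cognitive
impairment (early vs late MCI): given per-subject ROI time series (90 AAL
regions, TR = 3 s), can graph-theoretic features of band-limited
functional networks separate the groups, and in which frequency band is
the signal concentrated?  The pipeline is:

1. split each ROI signal into full (0.01–0.08 Hz), slow-4 (0.027–0.08 Hz)
   and slow-5 (0.01–0.027 Hz) bands (ideal zero-phase projection filter);
2. build the Fisher-z Pearson connectivity matrix
   z_ij = atanh r(x_i, x_j), and binarize it at a connection cost
   c ∈ [8%, 20%] by keeping the round(c·n(n−1)/2) strongest edges;
3. compute global measures (E_glob, E_loc, characteristic path length L,
   clustering C, small-worldness σ = (C/C_rand)/(L/L_rand)) and 270 nodal
   features per band — degree K_i = Σ_j b_ij, betweenness
   B_i = Σ_{j≠m≠i} S_jm(i)/S_jm, and nodal path length
   L_i = Σ_{j≠i} L_ij/(V−1);
4. rank features with three selectors: greedy mRMR
   (max relevance I(x_i; c) minus mean redundancy I(x_i, x_j)),
   stability-selection sparse regression (selection frequencies of
   (1/n)‖Xw−y‖² + λ‖w‖₁ over subsamples and a λ grid), and the Fisher
   Score;
5. classify with an RBF-SVM, K(x₁,x₂) = exp(−‖x₁−x₂‖²/σ²), under nested
   cross-validation — outer leave-one-out, inner stratified 10-fold grid
   search over (C, σ), selection and tuning strictly inside each training
   fold — reporting ACC/SEN/SPE from pooled confusion counts and AUC from
   pooled decision scores;
6. compare groups (pooled t-tests from summaries, chi-square without
   continuity correction) and classifiers (exact McNemar test).

See `docs/methods.md` for the model details, conventions and limitations.

## Worked example

```python
import bandnet as bn

# a synthetic two-group cohort whose slow-5 connectivity differs on a
# 6-ROI module (the packaged validation effect, +0.50 per edge)
spec = bn.CohortSpec(
    n_group_a=30, n_group_b=30, n_timepoints=130, seed=5000,
    effect_edges=bn.module_effect_edges(), effect_band="slow5", noise_sd=0.5,
)
subjects = bn.generate_cohort(spec)

cfg = bn.SvmConfig(c_grid=(0.5, 4.0, 32.0), sigma_grid=(1.0, 4.0, 16.0),
                   inner_folds=10, seed=1)
for band in ("full", "slow4", "slow5"):
    table = bn.build_feature_table(subjects, band=band, cost=0.15)
    res = bn.nested_cv(table, "mrmr", k_features=10, cfg=cfg)
    print(f"{band:6s} ACC={res.acc:5.1f}%  AUC={res.auc:.3f}")
```

prints

```
full   ACC= 43.3%  AUC=0.496
slow4  ACC= 45.0%  AUC=0.451
slow5  ACC= 66.7%  AUC=0.743
```

— the band carrying the injected effect classifies well while the diluted
full band and the unaffected slow-4 band sit at chance, reproducing the
qualitative band ranking the pipeline is designed to expose.  Checking
which features the selector used:

```python
table = bn.build_feature_table(subjects, band="slow5", cost=0.15)
truth = bn.ground_truth_features(spec)          # ND/BC/NL of ROIs 5..15
top10 = set(bn.mrmr_rank(table, 10).top(10).tolist())
print(sorted(top10 & truth))                    # [4, 12, 14, 194]
```

the top-10 contains ground-truth features of the perturbed module at far
above the chance rate (10·K/270 with K = 18 truth features).

A command-line interface mirrors the stages:

```bash
bandnet simulate --spec spec.json --out cohort/
bandnet features --data cohort/ --band slow5 --cost 0.15 --out features.tsv
bandnet rank     --features features.tsv --method mrmr --k 10 --out ranking.tsv
bandnet classify --features features.tsv --selector mrmr --k 10 --out results.json
bandnet report   --spec spec.json --out report/     # full pipeline bundle
```

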