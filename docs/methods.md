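# Methods

## Model and pipeline

The package estimates, per group of participants, a Gaussian graphical
model over p = 21 ordinal questionnaire items. Item scores are first
OLS-residualized on intercept + age + sex (per group by default;
`scope="pooled"` fits one regression over the whole sample and is what the
descriptive per-group residual means use). Pearson correlations of the
residuals are the estimation input: residuals are continuous after
adjustment, and no polychoric or nonparanormal transform is applied
(Spearman can be substituted via the correlation step if desired; this is
deliberately out of the core path). The graphical LASSO then maximizes

    log det Θ − tr(RΘ) − λ Σ_{i≠j} |θ_ij|

over positive-definite precision matrices Θ; the diagonal is not
penalized, matching the convention of the widely used EBIC-glasso
implementations. The penalty path is 100 log-spaced values from
λ_max = max_{i<j} |r_ij| (where the graph is exactly empty) down to
0.01·λ_max, and the extended BIC

    EBIC(λ) = −2ℓ(Θ̂_λ) + E log n + 4 γ E log p,   ℓ = (n/2)(log det Θ − tr(RΘ))

selects the final model, with γ = 0.5 and E the number of nonzero pairs
i < j. Penalized estimates are reported directly — no post-selection
refit — so small conditional associations are shrunk to exact zeros and
"nonzero edge count" is well-defined (solver zeros are exact; after
symmetrizing the two column-wise estimates, any residue below 1e-10 is
hard-thresholded). Edge weights are partial correlations
w_ij = −θ_ij/√(θ_ii θ_jj).

### Solver

The solver is a Friedman-style block coordinate descent over columns of
the working covariance, with an inner soft-thresholding coordinate descent
for each column's lasso subproblem, compiled with numba. Convergence is
declared when the mean absolute change of the off-diagonal covariance
entries in a full sweep falls below 1e-4 (cap 10,000 sweeps;
non-convergence raises). The permutation comparison test and the bootstrap
stages refit the entire penalty path tens of thousands of times, which is
why the solver is compiled rather than delegated; the test suite
cross-checks solutions and selected edge sets against
scikit-learn's `graphical_lasso` on fixtures.

A note on the penalty path: the nonzero-edge count is *not* strictly
monotone in λ. Lasso active sets may shed a variable as the penalty
decreases (the analogue of LARS drop steps); in practice the departing
edges sit at boundary magnitude (|w| ~ 1e-4). The tests assert exactly
this corrected property, and scikit-learn reproduces the same drops at the
same penalties.

## Centrality

Strength is Σ_j |w_ij| (absolute values; the raw-sum variant is available
via `signed=True` but absolute weights are the field's convention and the
two coincide on predominantly positive networks). Distances use edge
length 1/|w| with Dijkstra all-pairs shortest paths; closeness of a node
is the inverse mean of its *finite* distances, and 0 for an isolated node
— near-empty control-group networks make this case routine, and the
convention avoids propagating infinities. Betweenness is Brandes
betweenness with fractional credit over tied shortest paths, reported as
raw counts (and optionally as the fraction of the (p−1)(p−2)/2 pairs).
Z-scores standardize each measure across the p nodes (sample SD); a
constant column yields zeros with a warning. Standardization is
within-group.

## Group comparison

Edge-ratio tests: for each pair of groups, a Pearson chi-square (no
continuity correction — expected counts are large at p = 21; a flag
restores Yates) on the 2×2 table (nonzero, zero) out of the 210 possible
edges, Holm-corrected across the pairs tested. Treating the 210 pairs as
independent trials is a simplification inherited from the ratio-test
formulation itself; it is reported as such.

NCT: residualization happens once, before pooling; permutations reassign
residual rows to pseudo-groups of the original sizes without replacement
and re-run the full path estimation on both pseudo-groups. Statistics are
the absolute global-strength difference and the maximum absolute
single-edge difference. p-values use the add-one convention
(1 + #{perm ≥ obs})/(B + 1), so they are never zero; B defaults to 5,000.
Pooled rows are put in a canonical sort order first, which makes the
p-values exactly invariant to swapping the two input groups. The six
strength tests and the six structure tests are Holm-corrected as two
separate families. A permutation whose estimation fails (e.g. a
zero-variance pseudo-group column) is redrawn and counted.

## Stability

Edge accuracy uses the nonparametric row bootstrap (B = 2,500 by default)
with 2.5/97.5 percentile CIs; a parametric bootstrap is deliberately not
offered because LASSO regularization biases it. Centrality stability uses
the case-dropping subset bootstrap on the grid q ∈ {0.05, 0.10, …, 0.75}
(B = 1,000 by default): at each drop proportion q, subsamples of size
⌈(1−q)n⌉ are re-estimated and each centrality vector is Pearson-correlated
with its full-sample counterpart. The CS-coefficient per measure is the
largest q at which at least 95% of the defined correlations are ≥ 0.7;
undefined correlations (constant centrality vectors, typical of empty
networks) are excluded from the denominator but counted, and a proportion
with no defined correlation cannot qualify — so an empty-model fixture
yields CS = 0 by construction. CS is non-increasing in both the 0.7 floor
and the 95% level.

Percentile CIs of a penalized estimator cover the *procedure's* estimand,
not the unshrunk truth: coverage of a true edge weight is near-nominal
only where shrinkage bias is small against the sampling SD (strong,
well-connected signals and a penalty path that reaches small λ). The
coverage check in the test suite uses such a regime (p = 5, n = 300,
dense strong model) and documents that weak-edge CIs undercover — the
same reason the field treats "CI excludes zero" as a strength flag, not
an exact test.

## Synthetic cohorts

Ordinal items arise by thresholding latent Gaussians: a ground-truth
sparse partial-correlation matrix is drawn (edge set uniform at random at
the target density; magnitudes uniform in a weight range; signs positive
with probability 0.5 by default, 1.0 available for the all-positive
connectivity typical of estimated symptom networks), converted to a
unit-diagonal precision, and — if not positive-definite — its
off-diagonals are scaled by 0.98 repeatedly until it is. The fine 0.98
step (rather than a coarser one) stops near the PD boundary, which keeps
dense models at a consistent, strong general-factor-like marginal
correlation structure across seeds; coarser steps overshoot by a
seed-dependent amount and make downstream detectability erratic. True
partials are always recomputed from the adjusted precision.

Latent vectors are standardized to unit marginal variance (partials are
scale-invariant), shifted by `mean_shift + age_effect·(age − mean age) +
sex_effect·sex`, and cut at thresholds (−0.5, 0.5, 1.5), giving
right-skewed 0–3 items. Covariate effects act linearly on the latent
scale so that the linear residualization downstream removes them
approximately — exactly in the latent limit, approximately after
discretization.

The default four-group preset fixes the study conditions: sizes
294/118/184/257; CD and RD share one dense model (119 of 210 edges,
weights drawn in 0.10–0.40 before PD adjustment; attained mean |partial|
≈ 0.17) and differ only in severity (latent shifts 1.0 vs 0.0); SD has a
sparse model (20 edges, 0.25–0.45, shift 0.4); HC is empty (shift 0.0);
age effect 0.01/year, sex effect 0.15, age ~ N(45, 15²), sex ~
Bernoulli(0.5). Under these conditions the estimated nonzero-edge counts
land near 110/100/30/0 — the dense ≈ dense > sparse > empty ordering that
motivates the preset.

What the generator does *not* emulate: real BDI-II marginals calibrated
to published norms, item-specific severity profiles, longitudinal
structure, and any non-Gaussian dependence beyond thresholding. Passing
tests therefore certify recovery of the generator's own ground truth and
the internal consistency of the pipeline, not claims about real patient
data.

## Problem sizes in tests and the acceptance script

Simulation-based tests use scaled-down settings chosen as the package's
own defaults for desk-scale verification: permutation and bootstrap
replicate counts of 200 where the analysis default is 2,500–5,000, and
shorter penalty paths (20 values, min ratio 0.05) inside resampling loops.
`scripts/acceptance.py` runs the four-group analysis with the full
100-value path, 1,000 NCT permutations, the full 2,500-replicate edge
bootstrap and 250 case-dropping subsamples per drop proportion. All
randomness in both derives from a single seed.

## Known limitations

- Pearson-on-residuals ignores the ordinal nature of the items;
  discretization attenuates correlations by roughly 10–15% under the
  default thresholds, so absolute edge weights are conservative.
- EBIC with γ = 0.5 has a sharp empty-vs-dense selection cliff at small
  n for weakly connected truths; near that cliff, estimated edge counts
  are bimodal across samples.
- The chi-square edge-ratio test treats edges as independent trials.
- Betweenness and closeness are materially less stable than strength
  under case-dropping, as the CS-coefficients show; conclusions about
  them deserve caution.
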