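# Methods

This note records the models, algorithms and design choices behind
`urinmr`, in the order data flows through the package.

## Synthetic cohorts

**What is emulated.** One-dimensional ¹H-NMR spectra of urine from a
two-group biomonitoring design: 64 exposed workers and 78 residents by
default. Each metabolite contributes a set of multiplets — binomially
weighted combs of Lorentzian lines (the natural solution-NMR lineshape) —
centred at literature-plausible chemical shifts stored in an editable YAML
config (`synth/metabolite_shifts.yaml`). The default panel carries the 27
discriminant metabolites with their group-association signs (9 worker- and
18 resident-elevated).

**Concentration model.** For a metabolite with sign s and effect size e
(|log-fold-change|, default 0.5 ≈ 1.65-fold — a moderate single-metabolite
change), workers draw log-concentrations centred at `log(base) + s·e/2`,
residents at `log(base) − s·e/2`; everyone gets `conc_log_sd = 0.2` of
between-subject biological variability. With 27 metabolites shifted
simultaneously the cohort-level separation saturates (rdCV accuracy ≈
100%); that is a property of carrying 27 simultaneous markers, not of any
single marker being strong.

**Dilution.** A per-sample log-normal factor (σ = 0.4) multiplies the whole
spectrum — urine concentration varies strongly between voids — giving the
quotient-normalization stage something real to remove.

**Background.** Real urine spectra are crowded: beyond any assigned panel
there are hundreds of unassigned compounds plus broad macromolecule
envelopes, and even "empty" regions carry dilution-scaled signal with its
own biological variability. The generator therefore adds 250 background
compounds (1–3 sharp peaks each, log-normal abundances around 0.3) and 30
broad humps (widths 0.01–0.06 ppm), all confined below 9.35 ppm — urine
carries essentially no signal beyond ~9.3 ppm, which is precisely what
makes the high-field end usable as a noise-reference region. Without this
layer, quotient-normalized signal-free bins would all collapse onto
1/dilution: one shared random variable, duplicated across bins, whose
chance correlation with the labels would be flagged coherently by any
discriminant model. That artifact is a property of unrealistic emptiness,
not of the methods.

**Other ingredients.** Per-metabolite chemical-shift jitter (σ = 0.002 ppm,
emulating pH/ionic-strength effects), a slow sinusoidal baseline
(amplitude 5), additive Gaussian noise (σ = 0.5, giving the weakest panel
lines signal-to-noise well above detection), and covariates drawn to match
the cohort structure (workers 47 ± 8 y with 24/64 smokers; residents
57 ± 10 y with 7/78 smokers; sex, alcohol and BMI near-homogeneous). By
default covariates have no causal link to the spectra; `confounded_by`
couples a binary covariate to part of the panel for negative controls.

**Ground-truth bin labels** (`flag_truth_bins`) are content-based: a bin is
*planted* with sign s when metabolites of that sign contribute ≥ 50% of its
expected content at base concentrations (Lorentzian tails included — a bin
that is mostly creatinine tail is a creatinine bin), *null* when
discriminants contribute ≤ 5%, and *ambiguous* otherwise. Ambiguous bins
belong to neither set in recovery studies.

**What the generator does not emulate:** peak-shape distortions, radiation
damping, solvent-suppression artifacts beyond a baseline hump, 2D spectra,
relaxation effects, and metabolite-metabolite correlation structure
(concentrations are drawn independently). Passing tests therefore
demonstrate correctness of the statistical machinery under a plausible
spectral model, not performance on any particular real cohort.

## Preprocessing

* **FID processing** — exponential apodization (`lb` in Hz adds that much
  to the Lorentzian FWHM; default 0.3), zero-fill to a power of two, FFT,
  and automatic zero/first-order phasing by entropy minimization of the
  first-derivative distribution with a negative-intensity penalty.
* **Baseline** — asymmetric least squares: minimise
  `Σ w_i (y_i − z_i)² + λ Σ (Δ²z)²` with `w = p` above and `1 − p` below
  the current baseline (λ = 1e7, p = 0.001, 10 iterations; pentadiagonal
  system solved in banded form). This is a documented, reproducible
  stand-in for proprietary baseline-reconstruction procedures with the
  same goal: removing solvent/digitization humps while preserving peaks.
* **Alignment** — interval-correlation-shifting style: the axis is cut
  into ~0.12 ppm segments with boundaries snapped to low-intensity points
  of the mean spectrum; each segment of each spectrum is shifted by the
  integer lag (±0.02 ppm) maximising Pearson correlation with the
  reference (default: mean spectrum), edge-filling the gaps. Correlation
  is normalised deliberately: a raw inner product rewards duplicating a
  large edge value on monotone peak flanks and would shift already-aligned
  segments.
* **AI binning** — recursive bisection scored by the bin-value index
  `BV(s, e) = Σ_samples [(max − I[s]) · (max − I[e])]^r` (r = 0.5). The
  best split of a bin is accepted only when the sub-bin values sum to more
  than the parent value *and* both sub-bins exceed a noise threshold —
  the expected BV of a pure-noise bin of the same length,
  `n_samples · (4 σ² · 2 ln L)^r`, with σ estimated robustly (median
  absolute first difference) from a signal-free region (default
  9.5–10 ppm). The length-aware threshold matters: noise extremes grow
  with bin length, so a single fixed threshold either over-splits long
  noise stretches or suppresses genuine short bins. On axes ≤ 64 points
  the recursion provably coincides with exhaustive split search (tested).
* **Exclusion** — residual water (4.7–4.9 ppm) and TSP (−0.05–0.05 ppm)
  windows by default; studies additionally trim the signal-free edge
  above 9.3 ppm.
* **Quotient normalization (PQN)** — each sample is divided by the median
  of its bin-wise quotients against the median spectrum. Default:
  quotients over all positive reference bins (the standard estimator).
  `quotient_band=(lo, hi)` restricts the vote to bins whose reference
  intensity lies between those percentiles; see *Known limitations* for
  when and why this matters.
* **Scaling** — element-wise log with offset (default: half the smallest
  positive value, admitting zero bins) then per-column mean 0 / SD 1.
  The offset intentionally breaks exact column-scaling equivariance
  (log(cx + o) ≠ log x + const); with strictly positive data `offset=0`
  restores it. Near-constant columns are zeroed rather than amplified.

## Unsupervised random forest and confounder screen

Per iteration, the real samples (class 1) are discriminated from a
synthetic class (every column independently permuted: marginals intact,
covariance destroyed) by a random forest (defaults 1500 trees, final
leaves of 8, √p features per split). The proximity of two real samples is
the fraction of trees in which they share a terminal node; dissimilarity
is `1 − proximity` averaged over 50 iterations (each iteration redraws
both the synthetic class and the forest seed; a √(1 − proximity) variant
and an out-of-bag-only proximity are options). PCoA uses classical scaling
via scikit-bio; explained percentages are relative to the positive
inertia, and each axis is oriented so its largest-magnitude coordinate is
positive.

The confounder screen is a distance-based pseudo-F (McArdle–Anderson
decomposition of the Gower matrix `G = −½ J D² J`): for each covariate
(dummy-coded if categorical), `F = (tr(HGH)/m) / (tr((I−H)G(I−H))/(n−m−1))`
with p-values from covariate permutations (add-one estimator). For
categorical covariates the statistic equals scikit-bio's PERMANOVA
(cross-checked in a test); the regression form additionally handles
continuous covariates such as age and BMI.

## PLS-LDA with repeated double cross-validation

NIPALS PLS1 against the centred class indicator; a ridge-stabilised
two-class LDA on the first A score columns; classification by the LDA
posterior with observed class frequencies as priors. Metric conventions:
workers are the positive class; sensitivity = correct workers / workers,
specificity = correct residents / residents, accuracy = their mean
(balanced accuracy), CCR = raw fraction correct.

rdCV: per repetition a stratified outer split (default 7 folds); per outer
fold an inner CV (default 6 folds) picks the number of components by
minimum misclassification with a one-standard-error tie-break toward
fewer components; the outer model is refit on the full outer-training set
and scored on the held-out fold. Means ± SDs are reported over
repetitions. The permutation test reruns a reduced-repetition rdCV on
shuffled labels; p-values use the add-one estimator.

**Variable selection.** Each outer-training refit contributes a CV1 weight
vector; a variable is *significant* when its weight sign is identical in
every submodel and the 95% percentile interval across submodels excludes
zero. Stability is judged on individual submodels, not repetition
averages: averaging the folds of a repetition shrinks cross-validation
jitter ~√(n_folds)-fold, and the chance correlation any null variable has
with the labels in a finite sample (SE ≈ 1/√n ≈ 0.084 at n = 142) would
then pass as "stable". With overlapping training sets the jitter is
smaller still, which motivates the recovery-study configuration below.

## Validation studies (sizes and rationale)

* **Null calibration** — 500 no-effect cohorts (null panel, 64+78, 200
  bins); observed and permuted rdCV run at identical settings (1
  repetition, 7/6 folds, 5-component search, 99 permutations), making the
  permutation p-value exactly exchangeable; the study checks mean
  accuracy ≈ 50% and a 5%-level rejection rate within Monte-Carlo error
  of 5%. The 5-component search keeps the ~50 000 rdCV runs affordable;
  calibration is component-count-invariant by exchangeability.
* **Sign recovery** — 20 default cohorts through the full pipeline
  (baseline, alignment, fixed-width 0.04 ppm bins for a deterministic
  bin↔truth mapping, water/TSP/edge exclusion, band-quotient PQN, log +
  auto-scale), then rdCV with **2 outer folds × 200 repetitions**:
  stability selection over 400 *disjoint half-sample* submodels. With the
  default 7 folds, outer-training sets overlap 6/7 and their jitter
  (≈ 0.034 in correlation units) cannot expose chance correlations
  (≈ 0.084) as unstable; halves can. The quotient uses the 10–60th
  intensity-percentile band (see below). Reported: fraction of planted
  bins flagged with the planted sign, and flagged fraction among
  content-null bins.
* **Dilution recovery** — correlation between PQN factors and planted
  dilution over 5 default noisy cohorts.
* **URF separation** — 20 planted two-cluster datasets (15+15, shift 2.5
  SD) at reduced forest size (3 iterations × 100 trees — the statistic is
  a coarse ordering, insensitive to forest size); expected: within <
  between in every seed.
* **Screen calibration** — 1000 independent-covariate nulls (n = 20, 99
  permutations).
* **Oracles** — PCoA reconstruction of Euclidean toy distances (< 1e-8),
  the one-step NIPALS weight against its closed form on a 5 × 3 fixture,
  and recursive-vs-exhaustive AI binning agreement on 64-point axes.

## Known limitations

* **PQN group leakage.** When treatment effects are asymmetric (here 18
  metabolites up in one group vs 9 in the other), the strong,
  discriminant-dominated bins drag the quotient median and a fraction of
  the group effect enters the normalization factors; every bin then
  inherits a small coherent class correlation (measured at r ≈ −0.2
  between factor residuals and group under full-spectrum PQN at effect
  0.5). This is a property of quotient normalization itself, visible here
  because the ground truth is known. The mid-intensity quotient band used
  in the recovery study estimates dilution from the spectral background —
  the part of the spectrum least likely to carry coherent treatment
  effects — and roughly halves the leakage; an ablation normalizing by the
  true dilution bounds what any label-free normalization could achieve.
* Sign-stable selection controls stability under resampling, not a
  false-discovery rate in the formal sense; the reported null-bin flag
  rates quantify its behaviour under this generator only.
* The generator draws metabolite concentrations independently; real
  urinary metabolites are correlated (shared pathways), which would make
  variable selection harder than these studies suggest.
* rdCV with 2 outer folds trains on half samples, biasing the *metric*
  estimates pessimistically; the package therefore keeps 7/6 folds as the
  default for performance estimation and uses halves only where submodel
  disjointness is the point.
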