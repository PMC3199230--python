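# Methods

This note records, in the package's own words, the statistical methods
implemented in `bprsig` and the conventions fixed by the implementation.

## Data model

Expression data are log2-scale feature-by-sample matrices with string
feature and sample identifiers and an optional feature→gene-set annotation.
Phenotype tables carry a binary label (1 = case), a patient identifier
(patients may contribute paired upper/lower-lobe samples), a lobe field and
a sample-type field (`biopsy`, `explant`, `control`). Cohort summaries
count each patient once, report mean ± SE with the sample standard
deviation (n−1 denominator), leave the SE missing for singleton groups, and
round percentages half-up to integers.

## Synthetic cohorts

For feature *g* and sample *s*,

x(g,s) = baseline(g) + δ(g)·1[s is case, g differential]
       + γ·1[s is explant, g batch-affected] + u(patient(s)) + ε(g,s),

with baseline(g) ~ N(7, 1.5²), δ(g) = ±effect_size (default 1.5, random
sign), γ = batch_effect (default 1.0), ε ~ N(0, σ²) with σ = 1, and a
patient random effect u with variance τ² = ρσ²/(1−ρ) so that the
within-patient correlation of repeated samples is ρ (default 0.7).
Defaults mirror the study conditions: 11 cases (6 with paired lobes,
5 explants) and 6 controls in training; 31 cases and 15 controls in
validation. Feature-level truth (which genes are differential, baselines)
is drawn from the configuration seed while samples and noise are drawn from
a separate cohort seed, so validation cohorts share the truth of their
training cohort. A "second platform" re-measurement partitions features
into one-to-one, many-to-one, one-to-many and dropped classes, then applies
a per-feature affine distortion (scale ~ N(1, 0.2²) floored at 0.2, shift ~
N(0, 0.5²)) plus optional measurement noise.

## Preprocessing

Features are retained when they are annotated to at least one gene **and**
their mean log2 expression strictly exceeds 4.0. For unsupervised views, the
top fraction of features by coefficient of variation (sd/mean on the log2
scale) is selected with a stable tie-break. For supervised analysis, paired
lobes are collapsed to one sample per patient (preferring the upper lobe by
default) so samples are independent across patients.

## Exploratory analysis

Sample distance is 1 − Pearson correlation over features. Hierarchical
clustering is UPGMA (unweighted average linkage) implemented with the
size-weighted Lance–Williams update, which equals recomputing unweighted
cross-pair mean distances; ties are broken deterministically by the
lexicographically smallest member label. PCA is the SVD of the
feature-centered matrix; explained variance is σᵢ²/Σσ². Lobe-pair agreement
is quantified by matched vs unmatched case-pair correlations and by the
one-way random-effects intraclass correlation ICC(1) =
(MSB − MSW)/(MSB + (k−1)MSW) with its F-test.

## Differential expression

Gene ranking for the classifier uses the pooled-variance two-sample Student
t (effect = case mean − control mean), ranked by |t| with a stable
tie-break. A singleton class is tolerated (it contributes zero sum of
squares) so that minimal leave-one-out folds remain well defined; at least
one residual degree of freedom is required.

Hypothesis testing uses an empirical-Bayes moderated t: a scaled
inverse-chi-square prior on the residual variance gives the posterior
variance s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g) and a t statistic with
d₀ + d_g degrees of freedom. The hyperparameters (d₀, s₀²) are fitted by
method of moments on log s²_g using digamma/trigamma matching (trigamma
inverted numerically); when the observed spread of log-variances does not
exceed sampling noise, d₀ = ∞ and s₀² is the mean variance, so
constant-variance data reduce exactly to the ordinary t test. Zero
variances are floored at the smallest positive variance and flagged. Both
unpaired (case vs control) and paired (within-patient lobe difference)
designs are supported. Multiplicity is controlled by Benjamini–Hochberg:
the step-up adjusted value q(i) = min_{j≥i} (n/j) p(j) capped at 1.

## The classifier

**Factors.** The k genes with largest |pooled t| are standardized
(per-gene training mean and sd) and decomposed as X̃ = U S Vᵀ. The first
r = 2 right singular vectors (equivalently S⁻¹Uᵀx̃ per sample) are the
metagene factor scores; U, S and the standardization constants form the
frozen factor basis used for all later projection.

**Probit regression.** Pr(y = 1) = Φ(β₀ + βᵀf) with prior
β ~ N(0, diag(100, 4, 4)). Posterior sampling uses latent-variable data
augmentation: z_i ~ N(w_iᵀβ, 1) truncated to (0, ∞) when y_i = 1 and to
(−∞, 0) otherwise, followed by the conjugate multivariate-normal update
β | z ~ N(A⁻¹Wᵀz, A⁻¹), A = WᵀW + V⁻¹. Truncated normals are drawn by
inverse-CDF with separate CDF/survival-function branches for numerical
stability. Defaults: 10 000 iterations, 2 000 burn-in. Predictions report
either the posterior mean of Φ(η) (default) or Φ at the posterior-mean η.

**Model size.** k is chosen by leave-one-out cross-validation minimizing
the sum of deviances Σ −2[y log p + (1−y) log(1−p)] (p clipped to
[10⁻⁶, 1−10⁻⁶]) over a grid (default 50–250 by 10); the smallest k attaining
the minimum wins. Gene selection, standardization and the SVD are re-run
inside every fold (nested selection) to avoid selection bias; fold f uses
MCMC seed base + f. A cheaper non-nested variant (`fixed_selection`) is
available and documented as optimistically biased.

## Cross-platform transfer

Validation features are linked to training features through shared gene
identifiers (many-by-many). Each signature feature's validation value is
the unweighted mean (or median) of its linked features; unlinked signature
features are reported as unmapped. Each mapped feature is then scale/shift
normalized: z-scored with the validation cohort's own moments and rescaled
to the training feature's mean and sd, which exactly undoes any per-feature
affine distortion. Factor scores are recovered by least squares on the
available rows of the training loadings (pseudo-inverse), divided by the
singular values — identical to the training-time projection at full
coverage and robust to moderate feature dropout. Training labels are never
used and nothing is refit.

## Validation

ROC curves sweep the unique predicted probabilities as cutoffs (positive
when probability ≥ cutoff). AUC is the Mann–Whitney concordance
probability, computed from midranks so ties count one half. The operating
point maximizes the Youden index J = sensitivity + specificity − 1, with
ties broken toward the smallest cutoff. Confusion metrics report
sensitivity, specificity, PPV, NPV and accuracy (PPV/NPV undefined when the
denominator is empty). Case/control separation is tested by the two-sided
Wilcoxon rank-sum: exact permutation enumeration for n ≤ 20, otherwise
the normal approximation with tie and continuity corrections.

## Determinism

Every stochastic component takes an explicit seed; derived seeds are small
offsets of the configuration seed. Pipeline runs write a JSON manifest with
a SHA-256 hash of the configuration and all stage outputs; rerunning the
same configuration reproduces the manifest bit-for-bit.
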