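# Methods

`resilsense` implements an end-to-end analysis of stress resilience from
wearable and EMA (ecological momentary assessment) data collected around a
medical internship: a high-stress year during which a majority of interns
show minimal depression-symptom change ("stress-resilient") while the rest
worsen or fluctuate ("stress-sensitive"). The pipeline (i) builds hourly
behavioural features and cleans them, (ii) summarises each participant's
baseline (BL) and internship (INTERN) periods into 37 distributional
indicators, (iii) labels resilience from quarterly PHQ-9 trajectories with a
growth mixture model, (iv) screens indicators for association with
resilience via GEE, (v) predicts the during-internship hourly distribution —
and hence the internship-side indicators — from baseline data with multitask
conditional GANs, and (vi) validates that predicted indicators carry the
same associations as the actual ones. Because no raw study data are
publicly deposited, the package ships a synthetic cohort generator whose
defaults define the test-bed conditions.

## Hourly features and cleaning

Five hourly features are modelled: step count, seconds asleep, seconds in
bed, mean heart rate, and an interpolated daily mood rating (1–10). The
mood EMA arrives once per evening; it is spread over the waking day it
describes — from the wake time ending the previous sleep cycle to the wake
time ending the next sleep cycle longer than two hours, capped 24 h after
the EMA — with independent Uniform(0, 0.2) noise per filled hour so the
0.5-grid of averaged ratings becomes continuous but remains recoverable.
Sleep-cycle anchors are contiguous runs of hours with positive sleep
seconds; a run qualifies as a full cycle when its summed sleep exceeds
7200 s. Same-day EMAs are averaged before filling. A switch
(`noise_per_hour=False`) draws one noise value per EMA instead; both
conventions preserve the grid-recoverability property.

Missing-data rules mirror the non-random-missingness assumption of wearable
streams: hours with classified sleep but no steps get zero steps (the wearer
was asleep), hours with steps but no sleep get zero sleep/in-bed time
(awake), and hours still missing any feature (no heart-rate record, no mood
within 24 h) are dropped. Multivariate hourly outliers are removed with one
isolation forest over the pooled cohort (250 trees, per-tree feature budget
equal to the full five-feature dimension). The forest's contamination
budget defaults to 3%: scikit-learn's automatic offset flags roughly a
fifth of realistic zero-inflated hourly data, which is far outside the
few-percent regime hourly wearable pipelines operate in, so a fixed
few-percent budget is used instead (the automatic offset remains available
via `contamination="auto"`). Participants need ≥ 100 cleaned baseline
hours, ≥ 100 cleaned internship hours and nonzero variance on every
feature.

## Indicators

For each feature j, the baseline distribution A_j and internship
distribution B_j are summarised by mean, standard deviation (sample, n−1),
Pearson skew 3·(mean − median)/SD, and the between-period Cohen's

    d_sj = (mean(B_j) − mean(A_j)) / sqrt(((n_A−1)·SD_Aj² + (n_B−1)·SD_Bj²) / (n_A+n_B−2)),

plus the two hour counts n_A and n_B: 5 × (3 × 2 + 1) + 2 = 37 indicators.
Sample SDs are used throughout, including inside the skew; the median of an
even-sized sample is the mean of the central order statistics.

## Trajectory mixture and resilience labels

ΔPHQ-9 (change from baseline) on the quarter grid t ∈ {1..4} follows a
K-class quadratic growth mixture: class curves γ0k + γ1k·t + γ2k·t², a
shared participant random intercept (variance τ²) and shared residual
variance σ², so a participant's observed vector is N(Xγ_k, σ²I + τ²J)
within class k. The random-intercept-only structure is the smallest that
separates within- from between-person variance. EM treats class and
intercept jointly as latent; missing quarters enter through the marginal
likelihood over observed timepoints; initialisation is k-means on the
mean-imputed ΔPHQ vectors with 10 restarts by default. Model complexity is
p = 3K + (K−1) + 2. K is chosen over 2–5 by AIC; when AIC and BIC disagree
BIC wins with a warning (information criteria agreed in the motivating
setting, and BIC guards against AIC's tendency to overselect). The class
whose fitted curve stays closest to zero (ties to the largest class) is
labelled stress-resilient; all others pool as stress-sensitive.

## GEE screening

Each standardised indicator (z-scored with sample SD; constant intercept
appended) is tested in a binomial logit GEE of the resilient label with sex
(binary) and age (continuous) as controls, clustered by internship
specialty with an exchangeable working correlation. Inference uses the
bias-reduced (Mancl–DeRouen) sandwich with a t reference on G−2 degrees of
freedom: with only ~13 specialty clusters the plain robust sandwich is
materially anti-conservative (measured ~80% coverage of a planted effect
and ~12% type-I error versus 95%/5% with the correction). When the
exchangeable correlation update fails to converge or degenerates — which
happens routinely when the true within-cluster correlation is near zero —
the fit falls back to the independence working structure; GEE point
estimates remain consistent under any working structure and the robust
covariance retains validity. Significant indicators (α = 0.05, unadjusted;
a Benjamini–Hochberg option exists but is off by default) are pruned
greedily for collinearity: visiting candidates by ascending p, a candidate
is dropped when |Spearman ρ| > 0.7 with any survivor. Survivors enter one
multivariate GEE. Actual and predicted indicator tables are compared by
stacking both copies with a source flag and a source×indicator interaction
in the same GEE; a significant interaction coefficient means the predicted
indicator's association differs from the actual one. Indicators observed
at baseline are excluded from that contrast (their predicted copy is the
actual data).

## Generative models

The prediction target is the participant's multivariate internship hourly
distribution B, generated pointwise from baseline hours. Families: MLP /
P-MLP regress the five d_s values from the five baseline means; GEN / P-GEN
map a baseline hour to an internship hour by squared error on random
within-participant pairs; CGAN / F-CGAN / P-CGAN / FP-CGAN are conditional
GANs — generator (baseline hour, 8-dim noise) → internship hour with an
identity skip, discriminator scores (baseline hour, candidate hour) pairs
(plus a cluster one-hot for P-families), non-saturating loss, real pairs
re-sampled within participant each epoch. Multitasking splits the output
stage of a shared 2×64 trunk: one 32-unit head per feature (F), per
behaviour-shift cluster (P), or per (cluster, feature) (FP).

Participant clusters are found on the training participants' d_s profiles,
standardised first (the mood d_s carries roughly triple the estimation
noise of the duration features because mood is constant within a day, and
unscaled PCA otherwise buries the cluster structure under that noise), then
swept over 1–5 principal components / no reduction × Ward-linkage
agglomerative and k-means × k, keeping the silhouette-best configuration.
Held-out participants are routed to the cluster whose generated d_s best
matches their actual first-quarter d_s (mean absolute difference over
features; ties to the larger cluster; the larger cluster is the fallback
when no Q1 data exists).

Two stabilisers augment the generator objective, both standard practice for
conditional GANs on tabular targets: a paired-sample reconstruction term
(the L1-plus-adversarial pattern of image-translation GANs, here squared
error toward the randomly paired internship hour, whose minimiser is the
conditional mean E[y|x]) and a per-cluster batch moment-matching term
(first and second moments of the generated marginal against epoch-level
real targets), plus an exponential-moving-average generator for sampling.
Without them the generated variance collapses — which directly corrupts
the scale of d_s computed from generated data — or the minority cluster's
heads fail to learn their shift. Because adversarial training remains
restart-sensitive and the stabiliser weighting that suits a spiky
zero-inflated duration feature differs from what suits a smooth
near-Gaussian one, GAN families train several restarts under different
stabiliser weightings (profiles multiplying the reconstruction/moment
weights); for every feature the two restarts with the best training-set
d_s fit (variance-normalised error minus training skipped correlation) are
kept and their d_s predictions averaged. Selection uses training
participants only. All downstream indicator statistics are per-feature
marginals, so per-feature restart composition is exact, not an
approximation. Minority-cluster participants are over-sampled during
training so every cluster head receives a comparable gradient budget.
Generated points are de-normalised and clipped to the feature ranges
observed in training, so impossible negative durations or out-of-range
heart rates cannot distort skew. A mode-diversity guard warns when the
generated/actual SD ratio of any feature drops below 0.5 in an epoch.

## Evaluation statistics

Prediction quality per feature is the skipped correlation between actual
and predicted per-participant d_s on held-out participants: bivariate
outliers are flagged from a minimum-covariance-determinant centre by
projection distances exceeding the ideal-fourths boxplot bound
(median ± sqrt(χ²₀.₉₇₅,₂)·(q₂−q₁), union over the data-defined projection
directions), and Pearson's r is computed on the survivors with a t-based
p-value on the reduced n (no adjustment for the data-dependent removal — a
known limitation of the estimator). A Spearman-on-survivors switch exists.
Squared d_s errors are compared against the mean-assignment baseline
(assigning every test participant the training-mean d_s) with a one-sided
Wilcoxon signed-rank test. Two-sample location contrasts are gated on
Shapiro–Wilk normality (t-test when both samples pass at α = 0.05,
Mann–Whitney U otherwise), and the outlier-burden check asks, one-sided,
whether stress-sensitive participants shed more isolation-forest outliers
than resilient ones.

## Synthetic cohorts

The generator emulates the qualitative structure of intern wearable/EMA
data; no marginal parameters of the real streams are published, so defaults
aim at shape realism and at the few printed summary statistics of the
motivating cohort. Steps are a circadian Bernoulli gate × negative
binomial (zero mode, right skew); sleep fills nightly cycles whose seconds
occasionally book wholly into the start hour, reproducing the multi-hour
cycle-logging quirk that makes single hours carry tens of thousands of
seconds until outlier filtering removes them; heart rate is bounded to
[35, 204] BPM with sleep dips and activity surges; mood is a discrete
evening rating with imperfect completion. PHQ-9 series follow four
quadratic ΔPHQ classes (68% minimal-change majority; peak separations of
several PHQ points; residual SD 2, intercept SD 1). Two behaviour-shift
clusters change generating parameters between periods: a mildly affected
majority (~80%) and a disrupted minority (~20%) that sleeps about half as
much during internship, runs a markedly higher heart rate, and walks
slightly less, with no mood contrast — the near-disjoint sleep separation
and the significant-but-weaker step contrast mirror the cluster anatomy
reported for real interns. Within clusters, participants jitter around the
cluster shift with scales set so the per-feature d_s spreads approach the
printed training interquartile ranges (sleep/in-bed ≈ 0.18, heart rate ≈
0.33, mood widest; the step and mood spreads are approached but not fully
reached, since pushing them further would bury every planted signal in
unpredictable noise). Part of the heterogeneity is predictable from
baseline: internship means regress toward the population mean (mood most,
heart rate and steps mildly) and 70% of the sleep-shift jitter is explained
by baseline sleep duration — the long sleepers lose the most — which is
what gives baseline-conditional models genuine signal, as observed for the
real cohort's no-cluster baselines. Couplings to resilience are planted two
ways: disrupted-cluster membership is less likely (configurable log-odds)
for minimal-change-class participants, and explicit planted indicator
values are drawn so a logistic fit of resilience on them recovers a
configured log-odds exactly (`simulate_indicator_cohort` generates that
analytic surface directly for calibration studies). Adherence decays by a
per-quarter dropout hazard and an EMA completion rate. What the generator
does not emulate: minute-level device output, sleep staging, weekday/
weekend structure, seasonality, autocorrelated mood, or demographic
confounding — so green tests certify the pipeline's statistical machinery
under the planted structure, not performance on real cohorts.

## Problem sizes and numerical choices

Tests and the acceptance script run cohorts of 765–775 participants — the
analysis scale of the motivating study — but with compressed calendars
(4-week baseline, 14-day quarters, ~600 baseline and ~1200 internship
cleaned hours per participant) so the full pipeline fits in minutes of CPU.
GAN training uses Adam (generator 5e-4, discriminator 4e-4), batch 512,
~44 pairs per participant per epoch, 90 epochs, 4 restarts. EM stops when
the relative log-likelihood gain falls below 1e-7 (300-iteration cap, best
of the restarts); variances are floored at 1e-8 to avoid degenerate
components. Ties in resilience labelling break toward the larger class;
ties in cluster matching toward the larger training cluster. The
train/test split is participant-level (leave-subject-out), stratified by
trajectory class with largest-remainder rounding of the test share.

## Known limitations

GAN results, while stabilised by restarts and ensembling, retain more
run-to-run variance than the rest of the pipeline; borderline Wilcoxon
p-values near 0.05 can cross the line between seeds. The skipped
correlation deletes whole minority clusters when predictions are tightly
bimodal, so it rewards models that express within-cluster conditional
signal and penalises pure cluster-mean predictors even when their squared
error is excellent — the estimator, not the error, drives some model
rankings. The mood indicator's daily granularity caps its d_s precision.
The GEE small-sample correction assumes the specialty clusters are
exchangeable units; with very unbalanced specialty sizes the t(G−2)
reference is approximate.
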