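# Methods

This note documents the models and procedures implemented in `evopharm`,
the assumptions behind them, the defaults that matter, and what the
synthetic cohort does and does not establish.

## Variant presence and evolution typing

Presence of a variant in a sample is a deterministic read-level rule:
`alt_count ≥ min_alt` (default 3) **and** VAF ≥ `min_vaf` (default 0.02).
This replaces probabilistic phylogeny-based clonality calling with a rule
that is conservative at the targeted-sequencing depths the pipeline
assumes (~200×): at depth 200, three alt reads and 2% VAF bound the false
presence rate from sequencing error well below one call per sample while
keeping sensitivity for subclonal variants near 10% VAF.

Truncal variants are those present at *every* timepoint of a patient;
private variants are present in a proper nonempty subset, keyed by the
timepoints where they appear. Evolution typing per focal gene compares
the distinct `(gene, protein_change)` sets A (earlier timepoint) and B
(later): persistence (A = B ≠ ∅), extinction (A ≠ ∅, B = ∅), expansion
(B ⊋ A, or A = ∅ ≠ B), absent (both empty), and *complex* for equal-size
but different-identity turnover — a case the three-class scheme leaves
undefined and which we surface rather than fold into another class.
Counting distinct protein changes (not clone counts) is what makes the
`1>2` pattern of a secondary same-gene mutation come out naturally.

## Heterogeneity and selection statistics

**MATH.** `100 · 1.4826 · median(|VAF_i − median VAF|) / median(VAF)`.
The 1.4826 factor is the usual MAD consistency constant; the score is
zero iff all VAFs are equal and invariant under rescaling all VAFs by a
positive constant. Requires ≥2 VAFs (flagged not-computable otherwise).

**dN/dS.** A counting estimator in the Nei–Gojobori style: every
mutation is classified synonymous/nonsynonymous by standard-genetic-code
codon translation; expected sites are counted per codon by enumerating
all nine single-nucleotide changes, each contributing 1/3 site, with
stop-gaining changes counted nonsynonymous. By construction
N_sites + S_sites = 3 × codons. ω = (n_obs/N)/(s_obs/S), flagged
undefined when s_obs = 0. No multiple-hit or coverage correction is
applied: per-sample mutation counts in this setting are low (median ~5),
where such corrections are immaterial. A uniform mutation process gives
ω = 1 by construction, which the tests verify by Monte Carlo.

**Fusions and metastasis association.** Maintained/vanished/acquired are
plain set intersections/differences between timepoints, satisfying
maintained + vanished = |F_early| and maintained + acquired = |F_late|.
The 2×2 association uses OR = ad/bc (flagged infinite when bc = 0) and
the Pearson χ² without continuity correction, df = 1 — chosen so the
closed form n(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) holds exactly.

## Paired longitudinal drug test

Per drug and patient group, the effect measure is the mean of per-patient
paired log ratios log2(AUC_late/AUC_early) — pairing first, then
averaging, which is scale-robust and immune to between-patient baseline
differences. The default test is the paired t-test on log2 AUC; the
Wilcoxon signed-rank test is available as a config option because both
conventions are common in paired drug-screen analyses, and we surface
the choice rather than fix it silently. Candidates:
p < 0.1 and |log2FC| > 0.2, read as a two-sided magnitude rule with the
sign giving direction (negative = sensitization). No multiple-testing
correction is applied, matching the exploratory candidate-screen intent.
Degenerate cases (fewer than two complete pairs, zero-variance
differences) are flagged not-testable rather than given a p-value.

## Response-prediction network and gene signatures

The regression model is a small feedforward network: ReLU hidden layers
(default one layer of 64 units), linear output, mean-squared-error loss
with L2 penalty (default 1e-3), inverted dropout (default 0), Adam
(lr 1e-2, batch 64, default 150 epochs), with the target internally
standardized. It is written in numpy so that (a) the dropout dimension of
the hyperparameter grid is honored, (b) training is bit-deterministic
given the seed (init, shuffling and dropout masks share one generator),
and (c) permutation importance can reuse cached first-layer
pre-activations — shuffling gene g only shifts them by an outer product,
making the per-gene evaluation O(samples × width). A constant target is a
degenerate case: the network predicts the mean exactly and skips
training.

Hyperparameters are selected by grid search on k-fold (default 3)
cross-validated RMSE with a fixed fold split; ties keep the earlier grid
point in declared order. Gene importance is permutation importance (mean
RMSE increase over repeats when one gene's column is shuffled, floored at
0) — a deliberate, model-agnostic replacement for framework-internal
importance measures, chosen because it has a testable definition. The
signature is the top-K genes (K = 100 by default, with a 500-gene
override for broader pathway interpretation), ties broken by gene symbol.

## Enrichment

**Preranked GSEA.** Genes sorted by statistic descending (ties by
symbol). Hits increment the running sum by |stat|^p normalized over set
members (p = 1 default), misses decrement by 1/(N − |set|); ES is the
signed maximum deviation. The null permutes gene labels (random same-size
sets), NES = ES / mean(|permuted ES| of the same sign), and
p = (1 + same-sign exceedances)/(n_perm + 1), so the smallest attainable
p is exactly 1/(n_perm + 1). A set covering the whole list has no misses
and is rejected.

**Per-sample set scores.** An ssGSEA-style rank statistic: per sample,
genes ordered by expression descending, hit weights (normalized rank)^α
with α = 0.25, score = sum of running-sum deviations; optionally min–max
normalized across samples per set. This intentionally replaces GSVA's
kernel-CDF statistic with a simpler per-sample rank score: both are
rank-based, and this one is exactly invariant under strictly monotone
transforms of a sample's expression vector — the property the tests
assert. Score deltas between paired timepoints use a paired t-test by
default (Welch's t available for unpaired contrasts).

## Subclone profiling

Single-cell QC drops cells with mitochondrial UMI fraction strictly
greater than 0.30, or detected features strictly below 200 or strictly
above 6,000 — boundary cells are kept, and the per-cell report names the
triggering rule(s); the filter is idempotent. Cluster signatures use
counts-per-10k normalization, a two-sided Wilcoxon rank-sum per gene, and
log2((mean+1)/(mean+1)) fold changes, ranked by p then fold change.

Bulk deconvolution solves, per sample, min‖bulk − fᵀ·ref‖₂ subject to
f ≥ 0 (scipy NNLS) and renormalizes f to sum to one. This is a documented
stand-in for cross-subject-weighted deconvolution (MuSiC-style) with the
same input/output contract: with a full-rank reference it recovers exact
mixtures exactly and 5%-noise mixtures to well under 0.05 mean absolute
error. Rank-deficient references are rejected.

Treatment staging applies the precedence POST3 (osimertinib or 3rd-gen
TKI) > POST2 (T790M after TKI) > POST1 (1st/2nd-gen TKI) > BASELINE
(naive), with contradictory histories (naive + osimertinib, T790M without
TKI) rejected. Prediction performance is the Mann–Whitney ROC AUC.

## Synergy

Inhibition is 1 − viability normalized to the untreated (0,0) well,
replicates averaged, clipped to [0,1]. The HSA score is 100 × the mean
excess of each combination well over the better single agent — the mean
over all combination wells, so appending null wells pulls the score
toward zero. Median-effect fits regress log10(fa/(1−fa)) on log10(dose)
over wells with 0 < fa < 1 (saturated wells carry no information on the
log-odds scale and are excluded with a warning); m is the slope and
Dm = 10^(−intercept/m). CI = d1/Dx1 + d2/Dx2 at a stated effect level,
and for grids the CI is reported per combination well at that well's
*achieved* fa, with the median CI as the plate summary.

## Synthetic cohort: what it emulates, and what it does not

Defaults mirror the study conditions: 34 patients at 2–4 timepoints,
48-drug screen, focal-gene evolution classes drawn 13:4:1
(persistence:extinction:expansion), depth ~Poisson(200), truncal VAF
~Beta(8,12) (mean 0.40), private VAF ~Beta(2,18) (mean 0.10), ~3 private
variants per sample (at least one, so every screened sample carries a
variant profile), 7 cell types, exponential survival with per-unit-score
hazard ratio 2 and independent exponential censoring.

Design choices worth knowing:

- **Guaranteed presence.** Planted-present variants resample alt counts
  until they clear the presence rule, so classification tests measure the
  classifier, not binomial read noise. Consequently the *typing* tests
  say nothing about sensitivity at marginal depth.
- **Log-scale AUC effects.** The planted shift δ is applied on the log2
  scale (AUC_T2 = AUC_T1 · 2^(δ+ε)), making δ literally the planted
  log2FC and the paired-t null exactly calibrated — which the 200-cohort
  calibration experiment confirms (fraction of null drugs at p < 0.1
  within [0.06, 0.14]).
- **Identifiable gene→response links.** The signature-recovery design
  adds per-gene independent noise at 50% of mean signal on top of the
  cell-type mixtures. With only mixture variation (7 latent dimensions),
  a sparse 20-gene link is not identifiable — any correlated gene carries
  the signal — so low-noise expression would test the wrong thing. The
  bundle's deconvolution expression keeps 5% noise, the stated
  noisy-mixture condition for fraction recovery.
- **Additive combination grids.** At zero synergy offset, combination
  wells are Loewe-additive for the shared Hill slope
  (fa from u = d1/Dm1 + d2/Dm2), so CI = 1 by construction; the offset
  adds excess inhibition and drives CI below 1. HSA, by contrast, is
  positive even for additive grids — the two scores answer different
  questions and the analysis driver shows both.

What passing tests do **not** show about real data: no sequencing-error
model, no copy-number or purity effects on VAF, no batch effects or
dropout in expression, fusion sets without breakpoint structure, and a
single-cell toy generator (negative binomial with planted markers) that
does not emulate droplet artifacts. Results on this cohort bound the
statistical behavior of the methods, not their robustness to assay
artifacts.

## Numerical choices and degenerate inputs

Quartile dichotomization uses type-7 (linear interpolation) quantiles,
subjects tied with a quartile value included in the corresponding group,
and accepts n ≥ 4 (at n = 4 distinct scores each group gets one
subject). Follow-up truncation sets times beyond 60 months to 60 with the
event censored, and is idempotent. The Cox fit uses Efron tie handling
via lifelines with tightened Newton precision (1e-10), so relabeling
groups inverts the HR to machine accuracy; monotone likelihoods are
flagged, not raised. All stochastic stages derive child seeds from one
global seed via SHA-256, so every artifact is bit-reproducible from the
config.

## Known limitations

- The dN/dS estimator ignores trinucleotide context and coverage; it is
  a selection *indicator*, not a calibrated selection intensity.
- Permutation importance underestimates duplicated/correlated predictors
  (importance splits between copies); the recovery experiment plants
  independent gene noise partly for this reason.
- At n = 500 subjects the Cox log-HR sampling sd for a balanced binary
  contrast is ~0.105, so recovery bands much tighter than ±1.65 of that
  sd cannot be met in expectation; see the test suite for the one
  recovery band asserted and documented as out of reach.
- NNLS deconvolution has no cross-subject variance weighting; with
  strongly collinear reference profiles fractions become unstable even
  when the rank check passes.

## Problem sizes in the test suite and acceptance script

Simulation-backed checks use the sizes stated in their tests: 30-patient
typing cohorts, 200 replicate cohorts for calibration/power, 20 seeds ×
(500 samples × 2,000 genes) for signature recovery, 100 noisy mixtures,
100 survival cohorts of n = 500 (25 in the acceptance script, which
reports the median HR), and 1,000-instance oracle sweeps for GSEA and
ROC identities. These sizes were chosen to give stable Monte Carlo
estimates at interactive runtimes.
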