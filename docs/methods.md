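# Methods

`trpquant` implements the quantitative procedures used to measure
light-dependent phosphorylation of the *Drosophila* TRP channel: label-free
LC-MS phosphopeptide quantification, quantitative Western-blot
densitometry, phosphate-occupancy estimation from phospho-IP experiments,
and the hit-calling logic of a kinase/phosphatase candidate screen.  All
stages are exercised on synthetic data with known ground truth; this note
records the models, the defaults, and the reasoning behind the open design
choices.

## Label-free quantification (module `lfq`)

**Input.** An aligned feature table: one row per LC-MS feature (m/z,
retention time, charge, peptide annotation, phosphosite assignment) with
one abundance column per run, `NA` for features not detected in a run.
Chromatographic alignment, deisotoping and identification are upstream of
this package.

**Charge filter.** Only features with charge +2 to +5 are quantified;
singly and ≥6-fold charged signals are dominated by non-peptidic
contaminants and poorly fragmenting species.

**Normalization.** Run-level scaling (loading, injection, ionisation
drift) is removed by a robust median-ratio method.  For run *r* against a
reference run, over the features detected in both, compute
d·i = log(ref·i / r·i).  The location of this distribution is estimated by
an *iterated MAD-trimmed median*: take the median, discard points farther
than 1.48 × MAD (the MAD scaled to a normal σ) from it, re-take the
median of the surviving subset, and repeat until the median moves by less
than `tol` (default 1e-10) or `max_iter` (50) is reached.  The run's
factor is exp(median) and its abundances are multiplied by it.  The
estimate is valid when most features do not change between runs; the
trimming makes it insensitive to a minority (<50%, in practice ≤10–20%) of
genuinely changing features.  A plain-median variant is available
(`method="median"`).  The commercial software used for the original
alignment implements a proprietary "recursive median" of this family;
equivalence with that exact implementation is not claimed.  The reference
run is user-specified or the lexicographically first run, and is logged.

**Eligibility and variant selection.**  A phosphosite is quantifiable only
through peptide variants that are (i) singly phosphorylated, (ii)
unambiguously site-localized (a boolean provided upstream), and (iii)
detected in *every* run of at least one light condition.  Among eligible
variants, the one with the highest mean normalized abundance over all its
non-missing runs is used; ties break to the lowest feature id.  Missing
values are never imputed.

**Relative abundance and significance.**  Per condition, the mean
normalized abundance over that condition's runs is computed (n = 9 per
condition in the default design); the higher condition is set to 100%.
Significance is a two-sided unpaired t-test, pooled-variance by default
("Student's"), Welch optional.  Stars code p < 0.05 / 0.01 / 0.001.  A
site is `light_elevated` (or `dark_elevated`) when the corresponding mean
is higher and p < 0.05, `not_light_dependent` otherwise, and
`not_quantifiable` when no variant is eligible or a condition has fewer
than two detected values.  Zero-variance degenerate inputs resolve to
p = 1 when the means agree and p = 0 otherwise rather than NaN.

When the run design contains both trypsin and chymotrypsin digests, sites
are selected and quantified per enzyme (tryptic and chymotryptic peptides
are different molecules); with a single enzyme the split is skipped.

**Replication structure.**  Technical replicates are treated as
independent runs within their condition, matching how the original
experiments were quantified (n = 9 runs per condition).  This reproduces a
pseudo-replication the t-test inherits; the synthetic generator applies
noise independently per run, where the approximation is exact.  The
default design is 3 biological × 3 technical replicates of one enzyme per
condition; a two-enzyme layout (3 biological × 2 technical per enzyme) is
available through `make_run_design`.

## Densitometry (module `densitometry`)

Lane signals are integrated band densities, background-subtracted
upstream.  The phospho signal of a lane is divided by the total (generic
antibody) signal of the same lane; genotype or timepoint comparisons
divide by a control lane **on the same membrane** (light-adapted wild type
= 100% for genotype panels; the 4-h-light timepoint = 100% for time
courses), which cancels membrane-specific gains and exposures.
Percentages above 100 are meaningful (enhanced phosphorylation) and are
not clipped.  Replicate membranes are summarised as mean ± SEM
(SD/√k); for time courses the per-membrane anchoring is the primary
result and a pooled-mean variant is reported alongside.

Linearity QC regresses signal on loaded amount (fly-head equivalents;
default series 3, 1.5, 0.75, 0.375 heads at constant total protein) by
ordinary least squares with intercept (forced-zero optional); r² is the
squared Pearson correlation and the default pass threshold is 0.95, below
the r² ≈ 0.98–0.99 observed for well-behaved antibody/film combinations.

## Phosphate occupancy (module `occupancy`)

The measured occupancy of a site is

    OC = (pTRP_input / TRP_input) × (TRP_IP / pTRP_IP) × 100%

The first ratio compares phosphospecific and generic antibody signals in
the extract; the second, taken on the immunoprecipitate obtained with the
phosphospecific antibody, corrects for the two antibodies' different
reactivities under the assumption that the IP contains only
phosphorylated molecules.

That assumption fails for an oligomeric channel: TRP is a tetramer and is
precipitated as one, so non-phosphorylated subunits ride along whenever at
least one subunit of their channel is phosphorylated, and OC overestimates
the per-subunit phosphorylation probability *p*.  The package formalises
this with a binomial co-capture model: subunits phosphorylated i.i.d.
Bernoulli(p), channels with k phospho-subunits captured with probability
1 − (1 − c)^k (capture efficiency c per phospho-epitope, default 1).
Antibody signals are proportional to epitope counts.  Then

    OC_app = 100 · p · n · E[P_cap(K)] / E[K · P_cap(K)],  K ~ Binomial(n, p)

with the closed form OC_app = 100·(1 − (1 − p)^n) at c = 1 and no bias
for monomers (n = 1).  `invert_occupancy` recovers p from a measured OC —
closed-form at c = 1, monotone bisection (tol 1e-10) otherwise.  Under
this model, measured occupancies of 56% and 34% correspond to per-subunit
probabilities of ≈ 18.6% and ≈ 9.9%.  These corrected values are
model-based: the independence and proportional-signal assumptions are not
themselves testable from the four signals, the per-epitope capture model
is the simplest of several plausible mechanisms (an all-or-nothing
threshold variant is available for sensitivity analysis), and residual
dark-condition signal (cross-reactivity) is not modelled by default
(additive fraction parameter, default 0).

Monte-Carlo standard errors for simulated experiments come from a
nonparametric bootstrap over channels (200 resamples).

## Candidate screen (module `screen`)

Each mutant is blotted against a same-membrane wild-type control; the
screen statistic is the mutant's relative phosphorylation (wild type =
100%) per site (T849, T864) and light condition.  Initial hits are called
from a single experiment with literal boundary semantics: fold ≥ 2.0
(inclusive) or fold < 0.5 (exclusive).  Hits are rescreened to three
experiments total; confirmation requires the fold criterion on the mean
**and** a two-sided one-sample t-test against 100% with p < 0.05.  A
pure threshold-on-mean mode is provided because "significant" in a
three-replicate screen can reasonably mean either; neither mode is claimed
to be the original study's exact rule.  Mutants with fewer than three
rescreen replicates are flagged `unconfirmable`, never silently dropped.

A property worth knowing: with multiplicative constant-CV noise the
one-sample t statistic at n = 3 is bounded for up-regulation (t → √3/CV as
the fold grows, ≈ 6.1 at CV 0.28) but unbounded for down-regulation, so
reductions are confirmed with near-certain power while even large
enhancements sit near the df = 2 critical value (4.30).  The default
planted truth for recovery tests therefore uses down-regulated effects
(folds 0.1–0.25, including a 6.7-fold reduction mirroring the strongest
known kinase-null effect), four mutants per site out of 85.

## Synthetic data (module `synthetic`)

One master seed drives deterministic per-generator substreams; identical
config + seed reproduces every table bit for bit.

* **Feature tables.**  Abundance(feature, run) = base × condition effect ×
  run scale factor × unit-mean log-normal noise (σ² = ln(1 + CV²), default
  CV 0.20, a typical label-free run-to-run variability); detection is
  missing-at-random after noise (default detect probability 0.95 per
  run; an abundance-dependent logistic option exists).  Sites emit two
  singly-phosphorylated localized variants by default plus, with
  probability 0.2 each, a doubly-phosphorylated and an
  ambiguous-localization variant that the eligibility rules must reject.
  Background features (default 300) mostly have no condition effect; a
  minority (default 10%, must stay < 50% for the normalization assumption)
  change 2–8-fold in a random direction.  Charge states are drawn from a
  configurable distribution including +1 and +6 signals that the charge
  filter must remove.  Run scale factors default to log-uniform in
  [1/2, 2] in the pipeline, emulating loading differences the
  normalization must remove.
* **Default truth.**  13 light-elevated sites and one dark-elevated site
  (S936), 4-fold effects — the wild-type pattern the MS stage should
  recover.
* **Blot panels.**  signal = gain × amount × (phospho fraction) ×
  log-normal noise, independent per signal (default CV 0.15; the original
  assay's noise level is not published, so this is a plausible placeholder,
  not an estimate).  A dilution-series layout (3 → 0.375 heads) feeds the
  linearity QC.
* **Screen panels.**  One membrane per mutant × site × condition ×
  replicate with random membrane gains.  Here `noise_cv` parameterises the
  CV of a lane's phospho/total *ratio* (split σ/√2 per signal), since that
  ratio is the measurement the screen scores and reports error bars on.
* **IP experiments.**  Channels simulated subunit-wise per the binomial
  model; per-channel counts are retained so estimators can be
  bootstrapped.

**What the generators do not emulate** — retention-time drift and
alignment errors, intensity-dependent (heteroscedastic) MS noise,
informative missingness beyond the logistic option, antibody saturation
and film nonlinearity, inter-biological-replicate variance components
distinct from technical noise, and correlated multi-site phosphorylation
within a channel.  Passing recovery tests therefore demonstrates the
correctness and calibration of the estimators under the stated model, not
robustness to every artefact of the real assays.

## Numerical and testing choices

* Ratios are taken in natural log; factors are reported linear.
* Zero-MAD subsets terminate the trimmed median immediately (the median is
  then exact).
* Acceptance-style checks run at the study's working sizes: 9 runs per
  condition; 200 simulation seeds for fold-change recovery (2×/4×/8×,
  median within 10%); ≥2000 null sites for t-test calibration (type-I in
  [0.03, 0.07] at α = 0.05); 100 seeds for the 13 + 1 site-pattern
  (≥90% of site × seed pairs recovered — individual sites are occasionally
  unquantifiable by the generator's own dropout and charge draws, which is
  part of the modelled reality); 10⁵–10⁶ channels for the occupancy model
  (59.04% apparent occupancy at p = 0.2, n = 4); 100 seeds of the
  85-mutant screen (exact 4 + 4 recovery in ≥95% of seeds).
* The end-to-end pipeline writes TSV/JSON only, with fixed float
  formatting, so identical config + seed produces byte-identical bundles.
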