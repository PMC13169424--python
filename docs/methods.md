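# Methods

## Problem and model

`echoagree` analyzes *duplicate reads*: the same echocardiographic study
measured by two readers — typically an automated deep-learning reader
(`DL`) against a view-agnostic core-laboratory reference (`CL1`), with a
same-view core-lab reader (`CL2`) and, in the referral setting, clinical
reports (`CLINICAL`) as additional comparators. Seven right-heart
parameters are handled: peak TRV (m/s), RV basal diameter (mm), TAPSE
(mm), RA area, RVEDA, RVESA (cm²), and RVFAC (%).

For one parameter and a (reference, comparator) pair, paired differences
are `d_i = comp_i − ref_i` (positive when the comparator reads higher),
or relative differences `r_i = 100·d_i / m_i` with `m_i = (ref_i +
comp_i)/2` the pair mean. The pair mean is also the measurement-range
axis. The denominator choice is genuinely open (reference value vs pair
mean); the pair mean is the default because it is symmetric in the two
readers and standard in agreement analysis, and the scale is exposed as
an argument everywhere.

### Agreement statistics

- **Relative yield**: 100 × (subjects read by both) / (subjects read by
  the reference).
- **Robust bias**: the sample median of the differences (linear
  interpolation at even n).
- **Percentile precision**: `½(P84 − P16)`, half the central-68% spread,
  which equals 1 SD for normal data but resists outliers. Dividing by √2
  converts the dispersion of a *difference of two reads* into per-read
  dispersion (`scaled=True`, the default in summaries). Percentiles use
  linear interpolation with the k-th of n points at probability
  (k−1)/(n−1) (numpy's default; R type 7). The convention matters only
  at small n and is fixed so results are reproducible across
  implementations.
- **Bootstrap CIs**: percentile method, resampling the paired difference
  (the subject) with replacement, B = 1000 by default, fully determined
  by the seed. Percentile rather than BCa because it is the minimal,
  seed-reproducible reading of "bootstrap CI"; for the median and the
  percentile spread at n ≈ 200–400 its coverage is measured at ~94–95%
  in the acceptance suite.
- **Companions**: Bland-Altman limits of agreement (mean ± 1.96·sample
  SD), RMS error (satisfying the exact identity RMS² = mean² +
  population variance), Spearman correlation (midranks), and the
  reference change value `RCV = √2·z·√(CV_a² + CV_i²)` (%), the smallest
  serial change distinguishable from combined analytic and within-subject
  biological variation.

### Precision across the range and image quality

Straight quantile-regression lines at τ = 0.16, 0.50, 0.84 are fitted by
*exactly* minimizing the pinball loss `Σ ρ_τ(d_i − a − b·x_i)`: for
n ≤ 200 by enumerating all lines through data-point pairs (the LP
optimum is at such a vertex), with ties broken by smallest |slope| then
smallest intercept; for larger n by linear programming (HiGHS). The
LP route does not apply the vertex tie-break; on continuous data optima
are unique almost surely. An exact solver was chosen over iterative
approximations so fits can be verified against a brute-force oracle.
The precision-range curve is `½(q84(x) − q16(x))`, by default divided by
√2 like the pointwise precision (flag-controlled, since the unscaled
variant is equally defensible); crossing quantile lines yield negative
values that are *reported with a warning*, never clipped, because the
three quantiles are deliberately fitted independently.

Image quality is graded 1–5 (Likert) and collapsed to low (1–2),
moderate (3), good (4–5). Quality strata are compared with the
Kruskal-Wallis test (median differences; all-identical data returns
H = 0, p = 1) and the Levene test for equality of variance,
median-centered (Brown-Forsythe) by default to match the robust theme;
mean centering is available. The stratum of a pair is the reference
reader's recorded score, since quality belongs to the acquired image,
which readers share.

### Discrimination

AUC uses the midrank (Mann-Whitney) estimator; variances, CIs and the
paired AUC comparison use DeLong's structural components computed via
midranks (`V10_i = (TZ_i − TX_i)/n`, `V01_j = 1 − (TZ_j − TY_j)/m`),
two-sided normal p-values, no small-sample correction. The
implementation agrees with R's `pROC::roc.test` to 6 decimals on spot
checks and with brute-force pair counting exactly. A self-comparison
returns z = 0, p = 1; a degenerate difference-variance with unequal
AUCs is reported as non-computable (NaN with a warning). Parameters
where lower values mean disease (TAPSE, RVFAC) are sign-flipped through
an orientation registry before ranking.

Case-control ROC is preceded by greedy 1:1 age/sex matching: sex exact,
nearest age within an optional caliper, hardest cases (fewest eligible
controls) matched first, all ties broken lexicographically by id so the
result is order-independent. PH labeling from hemodynamics is strict:
PH iff MPAP > 20 mm Hg (20.0 itself is no-PH); subjects with MPAP > 35
mm Hg fall outside the mild-PH referral band. The guideline TRV bands
for the echocardiographic probability category (≤ 2.8 / 2.8–3.4 / > 3.4
m/s, with ≥ 2 supporting signs raising the category one level) live in
an editable module constant because they originate in external
guidelines, not in this package's statistics.

## Synthetic cohorts

The generator exists so that every stage can be exercised, and its
estimators checked for parameter recovery, without clinical data.

**Case-control cohort** (defaults: 213 healthy, 221 PAH). Each subject
draws a latent severity `z ~ N(0,1)`; parameter truth is
`θ_p = μ_g + σ_g(λ_p z + √(1−λ_p²) ε)`, truncated to physiologic
bounds. Default group means/SDs are the conventional healthy-vs-PAH
values (e.g. TRV 2.1 ± 0.5 vs 4.1 ± 0.7 m/s; RVFAC 39.9 ± 3.6 vs
19.7 ± 6.5%); loadings are ±0.7, negative for TAPSE and RVFAC, which
fall as the right heart deteriorates. One shared factor is the simplest
structure producing the jointly shifted parameter distributions and
matched-ROC behavior seen in such cohorts.

Readers act multiplicatively: a present read is `θ(1 + δ)`,
`δ ~ N(bias/100, (sd·q_mult/100)²)`, matching the relative scale on
which bias and precision are primarily reported. Default per-read SDs
are *good-image* SDs derived from target pairwise precisions: since the
scaled precision of a pair is `√((s_ref² + s_comp²)/2)`, each core-lab
reader gets the CL2-vs-CL1 precision value and the automated reader
`s_DL = √(2p_DL² − s_CL²)`, reproducing both pairwise targets at once
(feasible for all seven parameters). Image quality is drawn once per
(subject, parameter) — it is a property of the image, shared across
readers — with default mix 60/25/15% good/moderate/low and SD
multipliers 1 / 1.25 / 1.5; at the cohort level this inflates precision
by ~15% over the good-image value. Optional per-quality bias offsets
and a contamination component (small probability of a large-SD read,
emulating gross failures such as non-modal Doppler tracing) are exposed
in config and off by default. Yields are independent Bernoulli draws
per reader and parameter; core-lab defaults come from observed read
counts out of 434 studies and automated-reader defaults from the
relative yields, so empirical relative yield recovers the comparator's
probability under independent missingness.

**Referral cohort** (default n = 196). MPAP is a two-piece uniform on
(10, 20) and (20, 35) mm Hg with 89/196 mass below 20 (matching the
observed split in a mild-PH referral population; values above 35 are
excluded by construction). Truth TRV follows `sPAP = 1.5·MPAP`
(config-overridable; any monotone map suffices for ROC structure),
RAP fixed at 5 mm Hg, and `TRV = √((sPAP − RAP)/4)` (simplified
Bernoulli). Other parameters interpolate between healthy and case means
with the MPAP position as the severity axis plus residual healthy-SD
noise. Echo-to-RHC delay is exponential with median 23 days.

Randomness: one root seed; each subject's stream is an independent
deterministic child (`default_rng([seed, i])`, referral `[seed, 7, i]`),
so cohorts are bit-reproducible and any subject can be regenerated in
isolation.

**What the generator does not emulate**: real image-quality physics
(only its statistical footprint as SD inflation), reader correlation
beyond the shared truth and shared image quality, biological drift
between echo and RHC dates, and outlier taxonomy beyond the optional
contamination switch. Because truth TRV is deterministically coupled to
MPAP, referral-cohort AUCs come out near 0.95, higher than the ~0.75–0.8
seen with real clinical discordance; passing discrimination tests
therefore show estimator correctness and ordering, not realistic
clinical effect sizes.

## Numerical and testing choices

Tests pin the statistical contracts at these scales: yield arithmetic
exactly from printed-style counts; bias/precision recovery with 200
replicates of 400 pairs (per-reader relative SD 6.7/√2%, comparator
bias +0.9%; median bias within ±0.3 points, precision within 10%
relative); bootstrap coverage with 500 simulations of n = 200 at
B = 1000 (observed 94.2%, required 93–97%); AUC vs pair-counting on
1000 random datasets (exact); quantile fits vs two-point-line oracle on
200 datasets × 3 τ (exact optimality); 10 000-replicate type-I checks
for Kruskal-Wallis, Levene and the DeLong null comparison (observed
0.045 / 0.042 / 0.048 at α = 0.05). These sizes keep the full suite
under a minute while leaving Monte Carlo error well inside the asserted
bands.

Degenerate inputs are contracts, not accidents: constant differences
give zero precision and a width-zero bootstrap interval; all-identical
group data gives H = 0, p = 1; zero deviations give Levene 0, p = 1;
all-x-identical quantile fits fall back to intercept-only with a
warning; relative differences drop nonpositive pair means with a
recorded count.

## Known limitations

- Pairwise comparisons only; no variance-components model for three or
  more readers simultaneously.
- Percentile bootstrap CIs can undercover for extreme quantile-based
  statistics at small n; B and the method are config-visible.
- The LP quantile path inherits HiGHS tolerances (~1e-9 on the loss);
  the vertex path is exact up to floating-point arithmetic.
- The supporting-criteria category upgrade is one defensible encoding of
  how guideline signs modify the TRV band; it is isolated behind a
  single function and constant table.
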