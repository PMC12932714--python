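# Methods

## Standardization

All niche fitting happens in a standardized δ-space computed per calendar
year. Carbon is centred and range-scaled over **all non-baseline
individuals of that year pooled across groups** (the formulas operate on
individual values, so pooling individuals — not group means — is the
consistent reading), giving each year mean 0 and max − min = 1 by
construction. Nitrogen becomes trophic position: the mean δ¹⁵N of the
baseline guild (primary consumers such as filter-feeders and shredders) is
anchored at position 2 and each TDF (trophic discrimination factor,
default 3.23 ‰ of ¹⁵N per trophic step) above it adds one position.

The printed form of the nitrogen correction circulating in the literature
is occasionally typeset with unbalanced parentheses; this package uses the
standard trophic-position form (δ¹⁵Nᵢ − δ¹⁵N_baseline)/TDF + 2 and does not
support other groupings.

The baseline mean is computed **per year** by default, matching the
per-year carbon constants; `pooled_baseline=True` averages the baseline
guild over all years instead, for designs where the baseline is assumed
temporally stable. Both TDF and the baseline anchor (2) are parameters.

A consequence worth knowing: because the carbon range is re-estimated from
each year's sample, standardized areas inherit range-estimation noise on
top of covariance noise. With many groups spanning a wide δ¹³C interval the
range is anchored by between-group spread and this effect is small; in a
single-group design at small n it can move between-year area ratios by
tens of percent even when the raw-space niches are identical. The null
tests account for this.

## The ellipse model

Each (group, year) with n ≥ 3 individuals is one fit unit (units below a
soft threshold of 10 warn; below `min_n` they are flagged and skipped with
a log entry, never silently dropped). The ML fit uses the sample mean and
the n−1 covariance; SEA = π√det(Σ̂) and SEAc = SEA·(n−1)/(n−2). SEA is the
1-sd ellipse: it contains 1 − e^(−1/2) ≈ 39.35% of the mass of the true
normal (χ²₂ closed form), which is the "≈ 40% of central points" property
quoted for standard ellipses. 95% enters only as the credible level used
to report SEAb uncertainty, never as an ellipse scaling.

## SEAb: Bayesian model and sampler

Likelihood: xᵢ ~ N(μ, Σ) i.i.d. Prior: normal–inverse-Wishart,
μ | Σ ~ N(μ₀, Σ/κ₀), Σ ~ IW(ν₀, Λ₀), with vague defaults μ₀ = 0,
κ₀ = 10⁻³, ν₀ = 2, and the prior Wishart scale on the *precision* set to
10³·I (i.e. Λ₀ = 10⁻³·I) — the conventional vague setup for standard
ellipse models; all four hyperparameters are configurable because vague is
a convention, not a law. A blocked Gibbs sampler alternates the exact full
conditionals

    μ | Σ, x ~ N((κ₀μ₀ + n x̄)/(κ₀+n), Σ/(κ₀+n))
    Σ | μ, x ~ IW(ν₀ + n + 1, Λ₀ + Σᵢ(xᵢ−μ)(xᵢ−μ)ᵀ + κ₀(μ−μ₀)(μ−μ₀)ᵀ)

with inverse-Wishart draws via a 2×2 Bartlett decomposition (exact; its
moments are cross-checked against scipy's distribution in the tests). Each
SEAb draw is π√det(Σ draw). Defaults mirror common reporting practice:
3 chains × 20,000 iterations, burn-in 1,000, thinning 10 → 1,900 retained
draws per chain, 5,700 pooled. Retained draws per chain are exactly
(n_iter − burn_in) // thin for every configuration. Chains start from the
sample moments perturbed by a seeded log-uniform factor in [e^−1.5, e^1.5]
so the Gelman–Rubin diagnostic is informative; per-chain generators are
spawned deterministically from the master seed, making runs bit-identical.

Gibbs is used although the model admits direct sampling precisely so that
chains, thinning and R̂ are meaningful; `method="direct"` draws i.i.d. from
the closed-form conjugate posterior (Σ | x ~ IW(ν₀+n, Λ₀+S+κ₀n/(κ₀+n)
(x̄−μ₀)(x̄−μ₀)ᵀ)) and serves as the oracle: the Gibbs posterior mean of Σ
must match Λₙ/(νₙ−3) within Monte-Carlo error.

**Convergence.** R̂ is the potential scale reduction factor in its
classical between/within form on whole (unsplit) chains:
W = mean within-chain variance, B = n·var(chain means),
V̂ = ((n−1)/n)W + B/n, R̂ = √(V̂/W), monitored for log SEAb and both mean
coordinates; values above 1.1 raise a warning and are written to the run
log. Numerically degenerate covariance draws are retried with escalating
jitter on the conditional scale matrix (logged); persistent failure aborts
the unit with a named error.

## Comparison

`prob_less(a, b)` is the proportion of aligned pooled draws with aᵢ < bᵢ,
strict inequality, ties counting zero — a paired-index comparison over the
single pooled posterior vector per year (not an all-pairs product), the
convention of the original ellipse software. For continuous draws ties have
measure zero; comparing a vector with itself gives 0 by the strictness
rule. Unequal draw counts are a contract error, never silently truncated.

SEAc ratios divide each year's SEAc by the reference year's (first year by
default). The posterior mode is the argmax of a Gaussian KDE (Silverman
bandwidth) on a 512-point grid over the draw range — recorded in the report
metadata since the mode of continuous draws is estimator-dependent.
Credible intervals are highest-density intervals (shortest window over the
sorted draws; exact for unimodal posteriors), with an equal-tailed option;
nesting 50% ⊆ 75% ⊆ 95% is enforced by widening the outer interval by the
at-most-one-order-statistic overhang that independent window searches can
produce.

## Synthetic studies

The generator emulates exactly what the model assumes: each consumer
(group, year) is bivariate normal with a covariance built from a target
standard-ellipse area, an eigenvalue ratio ("eccentricity", ≥ 1 — note
this is the ratio of covariance eigenvalues; the geometric axis ratio is
its square root) and an orientation angle; points are mean + L·z with L the
Cholesky root. The baseline guild is univariate normal in δ¹⁵N with δ¹³C
uniform on a stated interval (baseline carbon never enters any formula).
Per-cluster seeds are SeedSequence([master, crc32("group|year")]), so
editing one cluster's spec leaves every other cluster's records
bit-identical across platforms.

The default template mirrors a three-year, five-group reservoir study:
group totals 19 (predatory fish), 23 (omnivorous fish), 29 (omnivorous
crayfish), 20 (predatory zoobenthos), 14 (detritivorous zoobenthos), split
across years as evenly as possible with the remainder to earlier years
(per-year splits are an assumption; only totals are fixed), first-year raw
areas of 0.8–3 ‰², and between-year area trajectories matching the
reported SEAc ratios (e.g. predatory fish ×1 → ×1.85 → ×4.46; crayfish
×1 → ×3.51 → ×1.55). Baseline: n = 8 per year, δ¹⁵N 3.0 ± 0.8 ‰, δ¹³C
uniform on (−29, −25) — plausible for primary-consumer molluscs in an
oligotrophic reservoir whose basal sources sit near δ¹⁵N 0. Group δ-means
are constant across years; only areas change. A heavy-tailed contamination
mixture (off by default) exists solely for robustness testing.

What passing tests on these data do **not** show: robustness to
non-normal niches (skewed or multimodal clusters), tissue- or
lipid-related biases, baseline taxa turnover between years, or correlated
sampling of individuals — real isotope data can violate all of these.

## Problem sizes and numerical choices in the test suite

Calibration suites were sized to give clear verdicts at interactive cost:
the coverage check uses 10⁶ Monte-Carlo points (MC error ≈ 0.0005 against
a ±0.002 band); parameter recovery uses 10 preset seeds × 3 group-years at
n = 50 with 5,000-iteration chains; null calibration uses 200 replicates
of two n = 50 arms with 1,200-iteration chains, testing uniformity of
p_less with a Kolmogorov–Smirnov bound of 0.12 fixed in advance for that
replicate count. At n = 50 the sampling noise of the area itself is
substantial — sd(log SEA) ≈ 0.145, so even a perfectly centred posterior
median lands within 15% of the *true* area only ≈ 70% of the time per
group-year; recovery expectations for small-n designs must be read against
that floor, and the decisive pairwise probabilities (fourfold area change)
are the robust signal. Degenerate inputs are rejected, not patched:
collinear points, zero carbon range, missing baselines, n < 3, unequal
draw vectors and absent reference years all raise typed errors naming the
offending unit.

## Known limitations

- Bivariate only; no ≥3-dimensional ellipsoids, no niche overlap or
  Layman community metrics.
- One TDF for all guilds and years; no per-group discrimination.
- The range-standardization noise described above is inherent to the
  method, not removable by this implementation.
- Prior sensitivity: with n in the teens, vague-prior details can shift
  SEAb by a few percent; hyperparameters are exposed so users can check
  their own data rather than assume it away.
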