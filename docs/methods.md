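# Methods

## Process model

A respondent's unobserved symptom severity is a single latent variable
X ~ Exp(λ), density λe^{−λx} on x ≥ 0, with mean and standard deviation
both 1/λ.  The instrument is CIS-R-like: 14 items, each scored through
four binary questions (five for "depressive ideas"), 57 questions in all,
so the total score is an integer in [0, 57].  Question q carries a
respondent- and question-specific threshold T_q; the question is endorsed
iff X > T_q (strict; ties have probability zero under the continuous
model and are scored 0).  Thresholds are drawn independently per
respondent **and** per question: items are treated as locally independent,
and nothing in the model couples one respondent's thresholds across
questions.  Negative threshold draws are retained — a below-zero threshold
is always exceeded by the nonnegative latent trait — because truncation
would distort exactly the large-σ regime in which the distributional
findings live.

Model assumptions, stated plainly: unidimensionality (one latent trait
drives all 57 questions), an exponential latent law, normal (or uniform)
threshold noise with a standard deviation shared across questions, and
independence of latent trait and thresholds.  None of these is estimated
from data here; the package explores their consequences.

## Calibration

A question with population prevalence p gets threshold mean
μ = −ln(p)/λ, the upper-tail quantile solving P(X > μ) = p.  The
upper-tail (survival-inverse) reading of the percentile point is fixed by
the worked anchor pair: −ln(0.0549) = 2.902 matches the published 2.90,
whereas the lower-tail quantile would not.  The closed form is used in
production; a bisection root of the survival function serves as an
independent oracle in tests.  σ = 0 is allowed as the degenerate
noise-free limit, in which the simulated endorsement rate of every
question converges to its table prevalence — the calibration-exactness
check.

Under threshold noise the marginal endorsement probability has the closed
form

    P(X > T) = Φ(−μ/σ) + exp(λ²σ²/2 − λμ) · Φ(μ/σ − λσ),

evaluated in log space so large λσ cannot overflow; it is verified against
adaptive quadrature to 1e−6 over μ ∈ [−2, 6], σ ∈ {0.5, 1, 2, 4},
λ ∈ {1, 2, 3}.

## Analytic oracle

Conditional on X = x the total score is Poisson-binomial with success
probabilities Φ((x − μ_q)/σ) (normal family; a step function at σ = 0) or
clamp((x − a)/(b − a), 0, 1) (uniform family).  The conditional pmf is
computed by O(Q²) iterative convolution — exact and cheap at Q ≤ 57; FFT
or characteristic-function methods would buy nothing here — and
marginalised over the latent density by adaptive vector quadrature
(`scipy.integrate.quad_vec`) to absolute tolerance 1e−8 (default; far
below any comparison tolerance used) on [0, U], where U is the latent
quantile of 1 − 1e−10; the residual 1e−10 of latent mass is assigned by
evaluating the conditional pmf at U.  The pmf must sum to 1 within 10×
the tolerance.  This oracle is the noise-free reference the Monte-Carlo
engine is validated against (total-variation distance ≤ 0.01 at
n = 100,000 on a 10-question instrument, all grid conditions).

## Diagnostics

* **Skewness** — adjusted Fisher–Pearson standardized third moment,
  g₁·√(n(n−1))/(n−2) (`scipy.stats.skew(bias=False)`).
* **Log-linearity** — unweighted OLS of ln(count) on score.  The
  `right_tail` policy starts at the modal score (the low-score region is
  where both real surveys and this model deviate from the exponential
  pattern); `full_range` starts at 0.  Bins with count below 5 (default)
  are excluded: log of a near-empty bin is noise, and far-tail sparse bins
  would dominate the fit.  Natural logs, so the slope is directly
  comparable to the latent decay rate.  Unweighted OLS mirrors a
  straight-line assessment of a semi-log plot; a Poisson GLM would be the
  inferential alternative but is deliberately not the default.
* **Ceiling bin.** The maximum attainable score is excluded from every
  fit.  Under a bounded threshold family (uniform(0, 5)) every respondent
  whose latent severity exceeds the whole threshold range piles up at the
  top score — an atom of mass e^{−5λ·…} ≈ e^{−5} at λ = 1, about ten
  times the log-linear trend — which is a censoring artifact of the
  bounded instrument, not curvature of the distribution.  With the
  ceiling excluded the uniform-condition analytic pmf is log-linear over
  the full range to R² = 0.9999; with it included R² drops to 0.95 for
  that one bin.
* Fewer than 8 usable bins raises an explicit error instead of a silent
  fit: a line through fewer points says nothing about linearity.
* R² conventions: the noise-free (analytic) uniform condition is required
  to reach R² ≥ 0.98 over the full range; for Monte-Carlo runs the tested
  claims are *orderings* (R² rising with σ, and with λ at fixed σ),
  because linearity of a simulated histogram is inherently a relative,
  not absolute, statement.

## Synthetic prevalence table

The per-question endorsement rates the calibration consumes are not
publicly tabulated, so the package generates stand-ins: log-uniform draws
on [0.01, 0.35].  General-population symptom endorsement rates are
right-skewed and span roughly 1–35%, and the one published value (5.49%)
sits comfortably inside that range.  Values are rounded to six decimals
at generation so CSV round trips are bit-exact.  The committed fixture
(`prevalence_fixture_synthetic.csv`) was produced once with seed 2007 and
its first row pinned to 0.0549; beyond that single value the fixture
claims no resemblance to any real survey.  What passing tests therefore
show is that the *mechanism* (calibration → comparison scoring →
aggregation) behaves as modelled — not that any particular real
instrument's rates were reproduced.  Real item-response features the
generator does not emulate: within-person threshold correlation,
item-specific noise scales, measurement error on the latent trait, and
guessing.

## Simulation grid and problem sizes

The grid runs λ = 1 with σ ∈ {1, 2, 3, 4}, λ ∈ {2, 3} with σ ∈ {1, 2},
and uniform(0, 5) at λ = 1 — the panels actually reported — at n = 10,000
respondents per condition, the scale of the population surveys the model
is benchmarked against.  Validation tests raise n to 100,000 where
tighter Monte-Carlo bounds are needed (TV comparisons, prevalence
recovery, ordering checks).  Per-condition seeds are derived from a master
seed by SHA-256 hashing of the condition identifier, so adding a
condition never shifts another condition's random stream; rerunning the
grid with the committed fixture and master seed 0 reproduces the committed
summary CSV byte-for-byte.  Plots are generated artifacts only — tests
assert on numbers, never on rendered output — and log-scale plots drop
zero-count bins rather than adding pseudo-counts, matching the fit policy.

## Statistical test calibration

Binomial-proportion checks compare 57 (or 80) questions/conditions
simultaneously.  The acceptance-level prevalence-recovery check uses the
conventional 3-standard-error band per question at its fixed derived
seed; the broader unit-test sweeps use a 3.9 SE band, the Šidák-style
per-comparison bound that keeps the familywise false-alarm rate of ~80
simultaneous comparisons at the level a single 3 SE check would have.
Seeds for stochastic tests follow one uniform convention — the package's
own `derive_seed(0, <check name>)` — rather than per-test magic numbers.

## Known limitations

* Only an exponential latent law is simulated; the model does not rule
  out other latent distributions producing similar total-score shapes.
* λ and σ are illustrative, not estimated: fitting them to real survey
  microdata is outside scope.
* Likert (polytomous) scoring appears only through threshold-count
  arithmetic (a 16-item, four-point scale has 48 thresholds); the
  simulator itself is binary.
* The skewness and R² orderings are established at fixed seeds and
  n = 100,000; they are properties of this model at these sample sizes,
  not survey estimates.
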