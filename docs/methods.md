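# Methods

This note documents the statistical model behind `sedrisk`, the defaults
that matter, and the choices made where the design was genuinely open.

## Data model and units

All concentrations are strictly positive dry-weight mass fractions. The
canonical internal unit is mg/kg dw; ng/g appears only at I/O boundaries
and in hazard/target report tables (the customary unit for SSD-derived
quantities). Conversion is a factor of 1000 and same-unit conversion is an
exact identity, so round trips are bit-exact. CSV dialect everywhere:
comma-separated, header row, period decimals, UTF-8, with `round_trip`
float parsing so write-then-read reproduces values exactly.

Exposure tables carry one composite mean per station (the packaged estuary
survey pools three cores per station); replicate standard deviations are
metadata only. All fitting operates on the station means — typically n = 20
— never on replicates.

Guideline anomalies (a high trigger not strictly above the low one, as in
the packaged Zn row) are preserved as printed and surfaced as warnings,
never silently corrected.

## Distribution families

Two families serve both the exposure (PDD) and effect (SSD) sides:

* **Log-normal**: location μ and scale σ of log-concentration. MLE is
  closed-form: μ̂ = mean(log x), σ̂ = SD(log x) with divisor n.
* **Burr Type III**: F(x) = (1 + (b/x)^c)^(−k), scale b > 0 and shapes
  c, k > 0; the log-logistic at k = 1. CDF, quantile and log-density are
  computed in log space so deep-tail arguments neither overflow nor lose
  precision; quantiles that genuinely fall below double range are clamped
  to the smallest positive float (only reachable with extreme shape
  parameters at extreme probabilities).

The Burr III likelihood is ridge-shaped in (c, k) — very different (c, k)
pairs give nearly identical CDFs at moderate sample sizes. The optimizer
therefore works on log-parameters with data pre-scaled to geometric mean 1,
starts from a log-logistic (k = 1) fit expanded into a 3×3 grid of (c, k)
scalings {1/2, 1, 2}, uses L-BFGS-B with bounds 10^±3 on each log-scale
parameter, and guarantees the achieved log-likelihood is never below the
log-logistic initialiser's. Because raw (c, k) are weakly identified, fit
quality is judged on quantiles, not parameters. Bootstrap refits use a
single start seeded at the parent fit's parameters — the standard fast path.

## Goodness of fit and family selection

The KS statistic evaluates both one-sided gaps at every order statistic
(ties allowed). Its p-value comes from a parametric bootstrap (default 999
replicates, seeded): draw n points from the fitted law, refit the same
family, recompute D. The classical KS table is anti-conservative when
parameters are estimated from the same sample, which is why the bootstrap
correction is not optional. Synthetic refits that fail count as extreme
(conservative). Calibration is verified in the suite at 300 repetitions ×
199 bootstrap replicates — sized to keep the default test run fast — with
the rejection rate required to sit in a ±3-binomial-SD band around the
nominal 5%.

`fit_pdd` fits both families and selects the smaller KS D (ties →
log-normal). Note that the three-parameter Burr III almost always achieves
a smaller *in-sample* D, even on truly log-normal data, so the selection
favours Burr III more often than a generalisation comparison would; both
fits are always reported, mirroring the two curves of a standard fitted-CDF
plot.

## Hazardous concentrations

HC_n is the n/100 quantile of the SSD — the concentration expected to
affect n% of species. Uncertainty comes from a nonparametric species
bootstrap (default 2000 replicates; at least 500 required for 95% limits):
resample species with replacement, refit, recompute HC_n. Replicates whose
refit fails are dropped and counted; more than 20% failures aborts.

Two lower-limit constructions are implemented:

* **bootstrap-t (default).** On the log scale, each replicate contributes
  t_b = (log HC_b − log HC&#770;)/se_b, and the p% lower limit is
  exp(log HC&#770; − se&#770; · t_(p)). Standard errors are analytic for the
  log-normal (σ√(1/n + z_q²/2n)) and delta-method from the observed
  information (numerical Hessian of the log-likelihood) for the Burr III.
* **percentile.** The limit is the (100−p)th percentile of the replicate
  HC values, so the 50% limit is the replicate median.

The percentile method is the simpler and more widespread convention, but it
materially undercovers extreme quantiles at SSD-typical species counts: in
this package's own experiment (200 synthetic 30-species log-normal SSDs,
500 replicates each) the true HC5 exceeded the percentile HC5;95 in only
~82% of datasets instead of the nominal 95%, with basic and BCa corrections
reaching only ~90–92%. The studentized limit restores ~94–95% coverage,
which is why it is the default; the percentile method remains available via
`limit_method="percentile"`. A consequence of the default is that the 50%
"limit" is a median-t-corrected estimate rather than the raw replicate
median.

HC tables computed over a grid of (n, confidence) share one replicate set,
and monotonicity — HC nondecreasing in n, nonincreasing in confidence — is
verified on every output; a violation raises rather than being silently
rearranged.

## Convolution and remediation

The expected fraction of species affected is E[F_SSD(X)], X ~ PDD,
integrated in probability space as ∫₀¹ F_SSD(Q_PDD(p)) dp by adaptive
quadrature (absolute tolerance 1e−6); this equals quadrature over
log-concentration under the change of variables p = F_PDD(x) and is exact
to tolerance for the identity E[F(X)] = 1/2 when the two laws coincide.
Bootstrap-replicate convolutions use a fixed 256-node Gauss–Legendre rule
instead — replicate noise dwarfs quadrature error there — and exploit the
fact that PDD quantiles scale linearly under remediation scaling, so they
are computed once per replicate.

At confidence 50 the reported % affected is the MLE convolution; above 50
it is the stated percentile of paired-bootstrap replicates (stations and
species resampled independently, both sides refitted, convolved) — an
upper, protective reading of estimation uncertainty. The % affected depends
only on the current exposure, so it is identical across requested
protection levels by construction.

Remediation scales all concentrations by s ∈ (0, 1] — a log-location shift
that preserves the fitted shape — and bisects to |Δs| ≤ 1e−4 for the
largest s whose convolved risk, at the stated confidence, meets the
criterion; the compliant endpoint is returned, so recomputing risk at the
reported s always satisfies the criterion. The required reduction is
100(1−s)% and the median target is s × current median (the empirical survey
median). The degenerate mode "reduce the median to a given target" is the
closed form 100·max(0, 1 − target/median), rendered "NIL" at zero.
Reductions are reported to 1 dp (round-half-even). If the criterion is
unattainable even at s = 1e−12 (a possibility with the Burr III's
polynomial lower tail), the search aborts with an error rather than
reporting a fictitious target.

## Synthetic scenarios

Measured sediment toxicity compilations are rarely published alongside
surveys, so the effect side of the demonstration pipeline is an emulation:
i.i.d. per-species endpoints drawn from a chosen Burr III or log-normal
SSD. The `wami_like_scenario` defaults are 20 stations, 40 species, three
replicates per composite with ~7% replicate CV (matching the packaged
survey's SD-to-mean ratios), exposure parameters set to the log-normal fit
of the chosen element's survey column, and an SSD (c = 1.8, k = 1.2 — the
shape used throughout the package's synthetic examples) whose HC5 sits 1.5
orders of magnitude below the exposure median: a contaminated-site geometry
in the middle of the plausible 1–3-order range. Every generator is a pure
function of its spec; the random stream is split per station/species so
enlarging a scenario preserves earlier draws. Emulated datasets are
labelled as such in species names and run logs.

What passing tests on synthetic data do and do not show: they verify the
estimation machinery (parameter and quantile recovery, bootstrap coverage,
convolution identities, ordering invariants) under known truth; they say
nothing about any real toxicity compilation, and the absolute HC/risk
numbers of emulation runs are not comparable to published assessments of
the same survey. Real SSD inputs also violate the i.i.d. assumption in ways
the generator does not model (taxonomic correlation, endpoint heterogeneity,
censoring).

## Pipeline determinism and problem sizes

Every stochastic stage consumes an explicit seed; per-element, per-stage
substreams are derived deterministically, and pipeline outputs are
byte-identical across reruns of the same configuration. Library defaults
are 2000 bootstrap replicates for HC limits and 999 for KS p-values; the
orchestrated pipeline defaults to 500/199 with 200 paired replicates for
risk limits, and the test suite exercises the full six-element pipeline at
500/99/100 — sizes chosen so the distributional conclusions are stable at
the reported precision while a complete run stays interactive.

## Known limitations

* No censored-data likelihoods (`<LOD` values must be resolved upstream).
* No additional SSD families (Weibull, Burr XII, log-triangular), no
  Bayesian or model-averaged fitting.
* Single-element risk only; no mixture additivity across elements.
* The Burr III observed-information standard error can fail on ridge-flat
  refits; such replicates are dropped and counted, and more than 20%
  failures aborts the estimate.
* The 99th-percentile screening guard and family selection both key off the
  smaller-KS-D fit; with n = 20 stations the selection itself is noisy,
  which is why both families' percentiles are always reported.
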