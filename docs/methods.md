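# Methods

## The Beta-Binomial validation model

A significant list carries an unknown true false-discovery proportion Π₀.
Each of *n* randomly sampled, independently confirmed features fails
validation with probability Π₀ (per-feature failure probabilities may vary;
only their mean enters the likelihood, since the Bernoulli mixture
marginalizes to Bernoulli(Π₀)). The failure count is therefore
Binomial(*n*, Π₀), and a Beta(*a*, *b*) prior yields the closed-form
posterior Beta(*a* + *n*<sub>FP</sub>, *b* + *n* − *n*<sub>FP</sub>).

Assumptions worth stating:

* **Random sampling.** The validated features must be a random draw from the
  list. Validating only the top hits answers a different (and much harder)
  question — the claimed FDR of the extreme tail is tiny, and no feasible
  sample can support it, which the worked examples quantify.
* **Independent confirmations.** Batch effects in the validation assay would
  correlate the indicators; the model assumes they have been handled
  upstream.
* **A single claim level.** One α̂ applies to the whole list; per-feature
  claim levels are out of scope.

Strict versus non-strict inequality in Pr(Π₀ ≤ α̂) is immaterial: the
posterior is continuous, and both are implemented as the CDF at α̂.

### Priors

The default is uniform, Beta(1, 1) — conservative in the sense that it
assigns half its mass to Π₀ > 1/2 and so never manufactures support for the
claim. The optional *adaptive* prior sets the prior mean to the claimed FDR
with a small first shape (a = 0.01, b = (1 − α̂)/α̂ · a), near-maximal
variance for that mean. It encodes optimism that the list will validate and
is measurably anti-conservative in simulation (higher validation
probabilities, lower credible-interval coverage), which is why it is opt-in.

### Credible intervals

Equal-tailed: the (1 − level)/2 and 1 − (1 − level)/2 posterior quantiles,
computed by `scipy.stats.beta.ppf`. Highest-posterior-density intervals were
deliberately not used — the equal-tailed convention matches the quantiles a
reader can reproduce with any Beta table, and for the skewed posteriors
arising here the two differ visibly. The interval-mass invariant
(CDF(upper) − CDF(lower) = level) holds to 1e-8 for shape parameters ≥ 0.5;
with the adaptive prior's a = 0.01 and no data, quantile inversion is
accurate to about 1e-6, a scipy numerics limit with no practical effect.

Non-integer failure counts are accepted everywhere (real-valued posterior
shapes); the binomial-tail identity I_x(a, b) = Pr(Bin(a+b−1, x) ≥ a) used
as a test oracle applies only to integer shapes.

## Bootstrap intervals for the validation probability

Resample the n outcome indicators with replacement B times (default
B = 10,000, chosen for stable 95% quantiles); each replicate's failure count
gives a replicate validation probability; report type-7 (linearly
interpolated) empirical 2.5/97.5 percentiles. The point estimate is the
probability on the original vector. Because the statistic is a monotone
*decreasing* function of the failure count, the upper interval endpoint
corresponds to the low-failure tail of the Binomial(n, n_FP/n) resampling
distribution — a direction that is easy to get backwards. Tests pin the
endpoints to exact enumeration of that distribution. The bootstrap is
unreliable for small n; the function warns (but proceeds) below n = 10.

## Sample-size design

The minimum validation sample size at cutoff q is the smallest n such that
Pr(Π₀ < q | n_fp(n), n) exceeds the target, with n at most the number of
features significant at q (Benjamini-Hochberg). Two conventions for the
expected failure count:

* **floor** (default): n_fp = ⌊q·n⌋. This is the convention under which
  finite design sizes exist; it reflects that an actual experiment observes
  whole failures.
* **continuous**: n_fp = q·n. Under a uniform prior the posterior then has
  mode exactly q and mean above q (for q < 1/2), so its median exceeds q and
  the validation probability never reaches 0.5: a 0.5 target is provably
  unachievable at any n. The design scan reports this as "not achievable"
  rather than looping forever (vectorized scan, capped at 10⁶ by default).

The scan is linear with early exit: under the floor rule the probability is
sawtoothed in n (it jumps down each time ⌊q·n⌋ increments), so bisection is
unsafe. An `fp_multiplier` generalizes the expected count to m·q·n for
what-if curves; the probability-versus-n curves default to m = 0.7
(validation somewhat better than the claim), under which the probability
increases with n and with q.

## qPCR cost model

TaqMan: 3 genes + a reference multiplexed per well, triplicate reactions, so
plates = ⌊n_genes·n_samples/96⌋ (the 3-plex and the 3 replicates cancel);
$250 per gene for probes. SYBrGreen: no multiplexing, a gene well and a
reference well per gene-sample pair in triplicate — six times the wells, no
probe cost. Both: $154 consumables per plate, and personnel at $40,000/year
for a technician running 4 plates/day, 22 days/month (1,056 plates/year);
time in years is plates/1056 and the personnel charge uses the exact
fractional year. The floor on the plate count is kept as such — adding genes
that do not complete a plate changes nothing — because the published budget
figures this model reproduces follow exactly that arithmetic, even though a
real lab would round up. All constants live in `CostParameters` and can be
overridden (YAML via the CLI).

## Simulation of operating characteristics

Each replicate experiment: 1,000 genes, 300 differentially expressed, two
groups of 10 samples, per-gene values = group shift + Gaussian noise
(sd 1), DE shifts uniform on [0.5, 2] with random sign. These generative
details are this package's choices; they produce a realistic power mix in
which lists at 5-50% FDR are nonempty and imperfect. P-values are two-sided
two-sample t-tests; q-values are Benjamini-Hochberg with π₀ = 1 (Storey's
π₀ estimate at λ = 0.5 is available but not the default, to keep the
pipeline deterministic and conservative). Every gene significant at a
cutoff is validated — exhaustive validation. 100 replicates per scenario;
replicates with an empty list at a cutoff are excluded from that cutoff's
summaries and counted.

Scenarios:

* **errorless** — the validation assay is an oracle: δ = 1 exactly for
  truly-null listed genes.
* **noisy_validation** — each listed gene is re-tested on freshly simulated
  data with 3× the per-group sample size at level 0.05; δ = 1 on failure to
  reject. Truly-DE genes fail at the rate set by power (mean miss rate
  ≈ 0.075 under the default effect mix); nulls fail ~95% of the time. The
  3× factor and the 0.05 level are package defaults for an
  under-determined mechanism.
* **misspecified** — the original technology is systematically wrong:
  a random third of the genes generated with signal are declared truly null
  for validation purposes, so about a third of discoveries are false
  regardless of the claimed FDR. This relabeling is one interpretation of
  "wrong one-third of the time"; alternatives (e.g. corrupting the data
  rather than the labels) would differ in detail but not in the qualitative
  conclusion.

What the simulations show — and their limits. Medians, IQRs,
credible-interval coverage of the claimed level, and median posterior-mean
FDR are summarized per cutoff. The qualitative pattern is robust: validation
probabilities rise with the cutoff and reach 1 at 50% when validation should
succeed; corruption drives them to ~0 at 5-10% with posterior FDR above the
claim; coverage falls as the cutoff grows (BH's conservative bias moves the
realized Π₀, roughly π₀·q, further below the claim); the adaptive prior is
uniformly more optimistic. The *exact* summary values depend on the
generative parameters above, so they characterize this generator, not any
particular dataset: Gaussian, independent, equal-variance genes with a
single two-group design are an idealization, and real validation assays have
structured (not merely sampling) error.

## Numerical and interface conventions

* All randomness flows through `numpy.random.default_rng` seeds;
  replicate seeds derive from a master seed via `SeedSequence`.
* Tabular I/O is strict TSV with a header (`feature_id`/`delta` for outcome
  tables, `pvalue` for p-value lists); parse errors name the offending
  lines. JSON reports keep full precision; the text renderer rounds to the
  2-3 decimals customary in write-ups.
* The design scan treats "probability exceeds target" as strict up to a
  1e-12 slack so that a posterior sitting exactly at the target (the
  symmetric q = 1/2, continuous-rule case) does not count as achievable.
* Degenerate t-tests (zero variance in both groups) yield p = 1 with a
  warning rather than NaN.
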