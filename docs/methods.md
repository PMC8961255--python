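# Methods

## Model and assumptions

The package treats reproducibility as a predictive-inference problem: the
reproducibility probability of a test is the probability that an identically
repeated experiment — same sample sizes, same test, same level — reaches the
same reject / not-reject outcome. Inference is nonparametric predictive
inference (NPI), a frequentist framework whose only structural assumption is
exchangeability of past and future observations, expressed through Hill's
A(n): after observing n ordered, tie-free values, the next observation falls
in each of the n + 1 intervals between consecutive cut points with
probability 1/(n+1). Multiple future observations use A(n), A(n+1), …
consecutively, which makes all C(n+m, n) interleavings of m future values
with the n data equally likely.

Exact NPI would quantify uncertainty with lower and upper probabilities by
enumerating those interleavings; that enumeration grows combinatorially and
is not attempted here. Instead the NPI bootstrap (NPI-B) simulates the
consecutive-A(n) process directly and yields a single (precise)
reproducibility estimate that lies between the imprecise envelope.

### Support bounds

NPI-B here uses a bounded support per group: L = x₍₁₎ − G and R = x₍ₙ₎ + G
with G the maximum consecutive gap of that group's sorted values, so the
two outer intervals are as wide as the widest interior gap. Bounds are
computed once from the original sample and held fixed while the working set
grows — they define the support, not the partition. Each group in a
multi-group analysis gets its own bounds. Sampling from the unbounded real
line is possible in principle but changes results little and costs much
more, so it is not implemented.

### Ties

A(n) presumes no ties. Tied values are broken by adding i·ε to the i-th
member of each tied run, with ε defaulting to 1e-9 × the sample range; this
perturbs each value by at most n·ε and preserves the order of distinct
values. Automatic tie-breaking logs a warning. ε must stay below the
smallest nonzero gap divided by n + 1 so previously distinct values cannot
cross.

## Algorithms

**Single-test reproducibility** (`TestReproducibility.fit`): perform the
original upper-sided test once; for each run k = 1…h draw N independent
pairs of NPI-B future samples (sizes nₓ and nᵧ, per-group bounds), apply the
same test at the same α, and set rpₖ = (#replicates matching the original
outcome)/N. Report min/mean/max of rp₁…rp_h; the mean is the NPI-B-RP value.
The N replicates within a run are i.i.d. — every future sample restarts from
the original partition — so the h-fold replication quantifies the
Monte-Carlo spread of a proportion estimate, which is what the min/max
summarise. Matching is on the binary reject / not-reject decision at the
fixed one-sided direction.

**Decision reproducibility** (`DecisionReproducibility.fit`): compute the
original outcome vector (g − 1 adjacent upper-sided t-tests,
Benjamini–Hochberg adjusted) and the original decision; then N times draw
one NPI-B future sample per group, re-run the adjusted tests, and record the
outcome vector. RPD is the proportion of runs whose vector maps, through the
first-non-rejection rule, to the original decision. BH is re-applied inside
every bootstrap run, mirroring the original analysis; this is exposed as
`adjust=` and was checked to reproduce the published repeat-to-repeat RPD
range on the case study, whereas skipping the inner adjustment centres RPD
visibly higher.

**Decision rule.** The selected dose is the lower-dose label of the first
'N' scanning from the control end. An all-'Y' vector certifies no plateau;
by convention it selects the highest dose, configurable via
`all_reject_label`.

## Statistical components

- Upper-sided pooled-variance t-test: p from the upper tail of Student's t
  with nₓ + nᵧ − 2 df (scipy). Rejection is strict: p < α; p = α does not
  reject.
- WMT: exact null distribution of U when nₓ + nᵧ ≤ 20 and tie-free, else
  normal approximation with continuity correction (scipy). Bootstrap
  replicates are almost surely tie-free, so the switch depends on sizes
  only.
- Effect size: difference of sample means. Cohen's d divides by the
  averaged-variance pooled sd √((sₓ² + sᵧ²)/2) with n − 1 denominators —
  appropriate when group sizes are equal or nearly so, as in both the
  simulation design and the case study. This is deliberately not the
  df-weighted pooled sd.
- BH adjustment: statsmodels' step-up `fdr_bh`. The vectorised row-wise
  implementation used on the bootstrap path is tested to agree with
  statsmodels exactly.

## Numerical and implementation choices

The sequential NPI-B scheme is vectorised across bootstrap replicates by
storing each replicate's current intervals as unordered (left, right)
arrays: interval selection is uniform over the set, so the array order is
irrelevant, and splitting an interval writes the left half in place and
appends the right half. This is the exact sequential process, not an
approximation; m draws cost m vectorised steps regardless of the number of
replicates. Replicate tests are evaluated in closed form over whole
matrices (pooled-t tail probabilities; rank-based U with exact or
corrected-normal p), cross-checked against the scalar scipy routes.

Randomness: one master seed per analysis; run k of Algorithm 1 and each
simulation run use deterministically spawned child streams
(`numpy.random.SeedSequence.spawn`), so results are bit-reproducible and any
single run can be regenerated in isolation.

Degenerate inputs: groups need n ≥ 2; a zero pooled variance with equal
means has no t statistic and raises; both-constant groups have no effect
size and raise; p-values outside [0, 1] are rejected.

## Synthetic data and what the tests show

The simulation module generates two independent normal samples per run —
N(0, 1) vs N(0, 1) under the null, N(1, 1) vs N(0, 1) under the
alternative, per-group sizes 6, 10 or 20, 200 runs — and couples each run's
test statistics with its reproducibility estimate. These conditions probe
the qualitative laws: the rejection rate under the null equals α; NPI-B-RP
dips where the p-value approaches α and is lower for just-rejections than
just-non-rejections; against Cohen's d the reproducibility traces a V shape
whose arms rise away from the rejection threshold. Real measurement data
are not normal, may be heteroscedastic, skewed, or tied; passing these
tests shows the machinery behaves correctly under the stated ideal
conditions, not that reproducibility of any particular real assay is high.
The default simulation bootstrap effort is reduced (N = 200, h = 20, 50
runs in the CLI default) because the qualitative relationships are robust
to effort; full effort (N = 1000, h = 100) is a config change.

## Problem sizes

The case-study analyses run at the published effort: N = 1000 bootstrap
pairs per run and h = 100 runs for single tests (100 000 replicate tests
per pair), and N = 1000 runs for the decision bootstrap. The acceptance
script re-runs all of these from scratch in a few seconds thanks to the
vectorised sampler. The qualitative simulation check uses 400
alternative-hypothesis runs of size n = 10 at reduced bootstrap effort.

## Known limitations

- Precise (single-valued) reproducibility only; NPI lower/upper
  reproducibility envelopes are out of scope.
- The upper-sided, equal-variance scenario is fixed by design: no Welch
  variant, no two-sided alternatives, no decision rules other than
  first-non-rejection, no multiplicity procedures other than BH.
- Statistics computed from the bundled case-study table inherit its
  4-decimal printing; derived values can differ from an unrounded source by
  a couple of units in the last printed digit.
- Reproducibility here is about outcome stability, not correctness: a test
  can be highly reproducible and still wrong about the population.
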