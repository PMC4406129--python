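# Methods

This note records the statistical model, the algorithmic and numerical
choices, what the synthetic-data generator does and does not emulate,
and the known limitations. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## The model

Let `z_i` be individual `i`'s arrival time into the study area
(first-detection week, standardized to zero mean and unit variance with
the population (1/n) standard deviation so the phenotypic variance `P`
is exactly 1), and `w_i ∈ {0,1}` whether it acquired a breeding
territory. The social environment is

    z̄_i = Σ_{k≠i} ω_ik z_k / Σ_{k≠i} ω_ik ,

with ω_ik the simple-ratio-index edge weight. Gradients come from the
logit-link binomial GLM

    w_i ~ α + β_N z_i + β_S z̄_i ,

(a Gaussian option on relative fitness `w/mean(w)` gives the classical
linear partial regression gradients), and total selection on the trait
decomposes as

    s = P β_N + C^I β_S ,

where the interaction covariance `C^I` equals, for a single trait, the
weighted network assortativity

    r̂ = weighted Pearson correlation of (j_e, k_e) over directed edges e,

each undirected edge contributing both orientations with weight ω_e.
The two-orientation convention makes the endpoint marginals identical,
hence r̂ symmetric, and reduces to Newman's continuous assortativity at
equal weights. The decomposition identity `s = Pβ_N + C^Iβ_S` holds to
machine precision by construction; coefficients stay on the logit
scale, multiplied by P and C^I exactly as the field reports them — no
conversion to linear-scale selection differentials is attempted.

## Association inference

- **Event detection.** Feeder visits come in bursts. The default
  detector opens a new gathering event whenever the inter-detection gap
  at a feeder exceeds `max_gap_s` (600 s); location-days are processed
  independently (no cross-midnight events, matching discrete sampling
  days). A 1-D Gaussian-mixture detector (components by minimum BIC
  over 1..k_max, hard assignment, components merged when means are
  closer than `max_gap_s`) is provided for bursty streams where a fixed
  gap misleads; the gap rule is the default because it is deterministic
  and, on generator truth, recovers event partitions with adjusted Rand
  index ≥ 0.9 at the default read jitter (1.0 when true bursts are
  separated by more than the gap threshold). When consecutive true
  flocks arrive within the gap threshold of each other the detector
  merges them — an intrinsic resolution limit of any temporal detector.
- **Simple ratio index.** `w = x/(x+y)` with event-based denominators:
  the index estimates co-membership probability per flock either bird
  joins. Singleton events are kept (they inflate y and correctly dilute
  the index); edges are retained at any positive weight, since observed
  network densities in this kind of data are sparse without
  thresholding.

## The permutation null

Statistical significance of assortment uses data-stream permutations: a
serial Markov chain of pairwise swaps in the GBI. A swap picks
incidences (e1, i) and (e2, j) with `i ∉ e2`, `j ∉ e1` and exchanges
them, conserving every event size and every individual's observation
count exactly (asserted over 10^5 swaps in the suite). Defaults: 1000
burn-in swaps, then the statistic recorded every 20 accepted swaps.

Two choices here deviate from common first instincts and matter:

- **Strata are sampling days, not feeder-days.** Swaps restricted to a
  single feeder-day cannot change the trait composition at any feeder,
  so the null would equal the observed network and the test would have
  no power against spatial assortment (measured: null sd ~5e-4 with
  null mean at the observed value). Day-level strata preserve each
  bird's temporal presence — and hence arrival censoring — while
  letting swaps cross feeders, which is exactly the structure the
  assortment hypothesis is about.
- **Thinning.** Recording after every accepted swap gives null draws so
  autocorrelated that null p-values are visibly non-uniform. With 20
  swaps between records the null p-value distribution passes a
  Kolmogorov–Smirnov uniformity test (α = 0.01) across 100 seeded runs
  of 200 permutations each.

An important structural fact, reproduced by the generator: **arrival
censoring alone induces positive weighted assortativity.** A bird
absent before week 7 cannot share the early-season events of a week-1
bird, so early–late pairs have diluted simple-ratio denominators and
within-cohort edges carry systematically more weight; with no spatial
structure at all (`spatial_assortment_strength = 0`) the raw r̂ is
≈ 0.25, not 0. The day-stratified permutation conserves presence
patterns and therefore tests assortment *beyond* censoring. For
p-value calibration the generator's true null is the condition matching
the permutation reference distribution — a single shared site where
flock membership is random among the birds present — under which
membership is exchangeable given the margins.

- The jackknife SE of r̂ deletes one undirected edge at a time (the SE
  method behind published ±values of this statistic is rarely stated;
  delete-one-edge jackknife is the package's choice, computed in O(E)
  by downdating the weighted moment sums).
- The p-value is upper-tailed with the add-one correction,
  `(#{null ≥ obs}+1)/(n+1)`: the hypothesis is stronger-than-chance
  assortment.

## Selection estimation

- The trait is standardized over **all** networked individuals (adults
  and juveniles) because z̄ draws on the full winter roster, while the
  regression is fitted on first-winter birds only (prior breeders'
  territory acquisition is confounded by site dominance). A flag allows
  juvenile-only standardization.
- Binary fitness enters the binomial fit directly (no relative-fitness
  rescaling, which the logit link makes redundant up to the intercept).
- Isolates (weighted degree 0) have undefined z̄ and are excluded with
  a reported count. Collinearity |cor(z, z̄)| > 0.999 and non-binary
  fitness are errors; complete separation is detected and flagged.
- statsmodels provides the IRLS machinery; an independently written
  IRLS loop serves as the oracle in the tests (agreement to 1e-6 on a
  hand dataset), and the Gaussian family reproduces OLS partial
  coefficients to 1e-10.

## Spatial analyses

- Nestboxes map to their nearest feeder by Euclidean distance, ties to
  the lowest feeder id (deterministic). Coordinates are planar metres.
- The dyad-distance comparison uses Welch's t-test by default (a
  pooled-variance option exists). Dyads are not independent; as in
  standard practice the test is reported uncorrected and should be read
  descriptively. Mates breeding in the same box (distance 0) are
  excluded by default, with a flag to include them.
- The weight–distance slope test reallocates each breeder an
  independent uniform draw from the full box list (with replacement
  across breeders; an exclusive-assignment option exists), 1000 times
  by default; `p_rand` is lower-tailed (more negative than expected).
- The competition index estimates the proportion of time a bird spends
  at each feeder by its share of detections there — detections are the
  only time-use proxy available. Local competition is local expected
  population divided by the number of nestboxes assigned to that
  feeder; the pipeline divides by all boxes by default because with
  sparse synthetic breeding the used-boxes-only divisor leaves feeders
  with birds but no box, where the index is undefined (an error in the
  library function). With a single feeder the index collapses to the
  global birds-per-box ratio for every bird.

## Brood/year variance partitioning

An intercept-only Gaussian model with crossed random intercepts for
natal brood and year is fitted by maximum likelihood using
parameter-expanded EM (PX-EM): the working model carries a free scale
per factor that is collapsed back into the variances each M-step. Plain
EM creeps interminably near the optimum when a component is weakly
identified (the year factor has very few levels); PX-EM retains EM's
monotone-likelihood guarantee and converges in tens of iterations.
Convergence is |Δ log-likelihood| < 1e-8 within 500 iterations;
non-convergence raises with the iteration trace. Negative components
are truncated at zero. A design with one observation per brood warns of
non-identifiability. On balanced one-factor data the ML fit tracks the
one-way ANOVA method-of-moments estimator within 5%; fractions are
invariant to affine transforms of the response. REML correction is a
possible extension; at the tested scales the ML small-sample bias is
inside the validation tolerances.

## The synthetic generator

Defaults describe the emulated field conditions: ~1000 birds, 65
feeders on a 250 m square grid (the real deployment's stratified grid
is approximated; exact coordinates are unpublished), 13 weeks sampled
2 days/week, 62.8% of birds present at first sampling, late arrivals
discretized from N(7.2, 3.0²) clipped to [2, n_weeks] (the sd chosen so
roughly a tenth of birds arrive in the final month, matching the
reported second wave), ~49% juveniles of which ~54% carry a known natal
brood. Settlement picks feeders with probability ∝
`exp(s·(quality − occupancy/expected))`: early birds crowd attractive
sites, later birds are pushed to emptier ones, spatially assorting
arrival time; `s = 0` is uniform settlement. Flocks are Poisson bursts
per feeder-day (40/day, thinned to ≥300 s separation), sized
1 + Poisson(4), drawn from the feeder's pool with grid-adjacent birds
eligible at relative weight 0.08 — the cross-feeder edges this creates
are what gives the weight–distance slope its signal. Reads are jittered
N(0, 20 s) around the event time. Defaults for `s`, flock size and
neighbour weight were fixed so the default winter sits in the
empirically reported regime (r̂ ≈ 0.27, density ≈ 0.10, jackknife SE a
few thousandths). Territory outcomes are Bernoulli with
logit⁻¹(α + β_N z + β_S z̄) at configured gradients; breeders take the
nearest free nestbox to their home feeder.

The **multi-year brood generator** used for variance partitioning
applies year/brood/residual effects to the latent arrival time in the
configured proportions (0.027 / 0.12 / remainder of 9 weeks²) and then
discretizes. It deliberately has no week-one point mass: the
variance-partition analysis concerns *when* birds arrive; under the
two-wave mixture with independent wave membership, brood effects
confined to the late wave are diluted to a ~1% share and no estimator
could recover the generating fraction. Rounding adds ~1/12 week² to the
residual and clipping mildly attenuates both tails, so the recovered
brood fraction centres slightly below the generating 0.12 (median
≈ 0.11 over 50 seeds).

What the generator does **not** emulate: mortality, within-winter home
range turnover, dominance interactions, mate choice, double-tag reads
or antenna noise, and real nestbox geography. Passing recovery tests
therefore demonstrate the estimators are correct under the stated
model, not that the model captures every feature of field data.

## Problem sizes in the validation suite

Chosen as the package's validation design: gradient recovery runs 100
replicates at n = 5000 (home-site flocking only, isolating the fit);
permutation-null calibration 100 runs × 200 permutations on the
single-site null (n = 120, 8 weeks); brood recovery 50 seeds at 200
broods × 6 chicks over 3 years; spatial positive controls at n = 300
with 1000 box randomizations and null calibration over 40 random-box
runs at 99 randomizations. The complete suite runs in ~5 minutes on one
CPU.

## Known limitations

- The simple ratio index conflates spatial overlap with social
  preference; the package measures "association" in the
  spatiotemporal-overlap sense its edge definition implies.
- Dyadic spatial tests ignore dyad non-independence (kept for
  comparability with standard practice).
- The burst detectors have no sub-gap temporal resolution, and the GMM
  variant inherits the usual mixture-fitting sensitivity to
  initialization (fixed seed, BIC selection).
- Assortativity jackknife SEs treat edges as the resampling unit; a
  bootstrap over gathering events would propagate sampling error more
  faithfully and is left as an extension.
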