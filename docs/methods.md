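# Methods

This note documents the models, priors, numerical choices and known
limitations of `paleoclock`, in the spirit of a package methods appendix.

## 1. Percent identity and the linear decay chronometer

**Identity convention.** For an aligned pair, the denominator is the number
of columns in which *both* sequences carry a residue; gap–residue and
gap–gap columns are excluded. A column counts as a match only when both
residues are the same unambiguous amino-acid letter; `X` never matches,
including against another `X`. Input is case-insensitive and `.` is read as
a gap. Online identity tools differ in their gap/denominator rules by
fractions of a percent; this convention was chosen because it is symmetric,
standard, and exactly testable. Identities are kept at full precision
internally and rounded to one decimal only for presentation.

**The chronometer.** The model is a straight line: identity loss is
proportional to elapsed time. Calibrating on an anchor divergence of age
`t_a` Ma that has accumulated `d_a` percent divergence gives a rate
`r = t_a / d_a` (Ma per 1% identity loss), and then

- forward: `identity(t) = 100 − t / r`, clamped at 0 rather than allowed to
  go negative (beyond `100·r` Ma the line is meaningless anyway);
- backward: `age(I) = (100 − I) · r`.

No saturation (multiple-hit) correction is applied, deliberately: the
method is a transparent first approximation whose job is an
order-of-magnitude consistency argument, and its raw linearity is part of
the design. Because of saturation, backward extrapolations at low
identities are *underestimates* of the true age, which only strengthens an
"older than" conclusion.

**Reporting conventions.** Rates are quoted floored to integer Ma/%
(2000/30 → "66"), and the sensitivity scan extrapolates with the quoted
rate — matching how such arithmetic is done in print (57.5 × 66 = 3795 Ma).
Full-precision rates are available (`use_reported_rate=False`). Ages are
reported in Ga to two decimals, Ma to the nearest integer. One published
figure is not reproducible from its own inputs: the red-algae bracket "1.42
to 1.58 Ga" — 82.2% identity at 80 Ma/% gives 1.42 Ga, but 80.9% gives 1.53
Ga, not 1.58; the package reproduces 1.42/1.53 and does not force-fit.

**Anchor divergence.** The default anchor is the simplified 30% divergence
of the Photosystem I core subunits at the MRCA of Cyanobacteria; the
averaged exact figure (30.35 = mean of 33.5% and 27.2%) is exposed through
`anchor_divergence`.

## 2. Relaxed molecular clock

### Substitution model

Poisson (equal-input) amino-acid model: equal exchangeabilities, stationary
frequencies 1/20. Transition probabilities are closed-form
(`p_same(d) = 1/20 + (19/20)·exp(−(20/19)d)`), which the likelihood kernel
exploits — no matrix exponentials in the hot path; the explicit generator
and `expm` serve as an independent oracle in the tests. Among-site rate
variation uses four equal-probability discrete-gamma categories with
mean-of-category rates (they average exactly 1 for any shape α). Gaps and
`X` are missing data (all-ones conditional vectors).

A site-heterogeneous profile mixture (CAT-style) is *not* implemented; the
homogeneous Poisson+Γ4 model is a documented fidelity gap. Deep posterior
ages from profile-mixture analyses of the real 59-sequence reaction-centre
dataset are therefore not expected to be reproduced numerically; the
package's correctness claims rest on the property checks below. A generic
column-mask option on the alignment reader side (slice before passing the
dict) covers antenna-vs-core domain splits without hard-coding ranges.

### Rate prior

Thorne–Kishino autocorrelated log-normal rates: along a branch of duration
Δt (Ma), `log r_child ~ N(log r_parent − σ²Δt/2, σ²Δt)`. The −σ²Δt/2 shift
makes the process mean-preserving (`E[r_child|r_parent] = r_parent`); the
forward simulator draws from exactly the density the sampler scores, and a
test checks that correspondence by KS. The likelihood uses the arithmetic
mean of the two endpoint rates on each branch (symmetric and continuous;
the parent-only alternative was rejected for its discontinuity at nodes).

### Node-age prior and calibrations

- Root age: Normal(mean, sd); the defaults 3500 ± 50 Ma encode "reaction
  centres existed by 3.5 Ga" with ±0.05 Ga read as a standard deviation.
  Support below the oldest descendant age is removed by the ordering
  constraint itself.
- Other internal ages: uniform on the order polytope conditional on the
  root. The polytope volume scales as `root^(m−1)` for m internal nodes,
  contributing a `−(m−1)·log(root)` term. This is the simplest proper
  tree-process prior; no birth–death hyperprior is attempted.
- Calibrations: a two-sided bound [min, max] multiplies in a proper density
  with a uniform core carrying mass 1 − 2τ and exponential tails carrying
  exactly τ = 2.5% each, tail scale 10% of the core width (a smoothing
  choice; the density is allowed a step at the bound so that the tail
  masses are *exact*). A minimum-only bound uses τ = 5% below the minimum
  (tail scale 10% of the minimum) and a uniform core on [min, root age],
  renormalised as the root moves — the root is the natural upper limit for
  any interior node. Calibrating the root itself is rejected: that is the
  root prior's job.

### Sampler

Metropolis–Hastings, one sweep = root age (Gaussian random walk), every
other internal node age, every node's rate (log-scale multiplier), σ²
(multiplier; prior-only, no likelihood), α (multiplier; full likelihood
refresh). Internal node ages are drawn uniformly between the oldest child
and the parent, so an age-order violation can never be accepted — it is
never proposed. Calibrated nodes use a 50/50 mixture of that window draw
and an independence draw from the soft-bound density via its inverse CDF
(with the exact Hastings correction); without it, the window draw accepts
at a rate of roughly calibration-width/window-width and the calibrated
marginals decorrelate far too slowly for distribution-level checks.

Hyperpriors: σ² ~ Exponential(mean 10⁻³ per Ma = 1 per Ga), α ~
Exponential(mean 1), root rate ~ log-normal centred at 1.25×10⁻⁴
subs/site/Ma (0.125/Ga — the order of magnitude of deep photosystem
proteins) with log-sd 1.5, i.e. two orders of magnitude of prior spread.

Multiplier step sizes adapt every 100 iterations of burn-in toward ~30%
acceptance and are frozen afterwards (preserving detailed balance in the
retained portion). A proposal that only changes one node dirties exactly
the pruning path from that node to the root; the engine recomputes that
path in one compiled kernel call and restores it on rejection. Conditional
likelihoods are rescaled per pattern and category, so underflow cannot
occur even on long branches.

Each chain has its own `numpy` Generator seeded `seed + chain_index` with a
fixed update order, so runs are bit-reproducible. With multiple chains
(default four), split-R̂ is reported for the root age, the deepest non-root
node age and σ²; R̂ above the threshold (default 1.05) flags the posterior
as unconverged but is not fatal.

**Posterior summaries** report mean, sd, and the central 95% interval both
as percentile bounds and as a half-width, since "±" tables in the
literature ambiguously mean either. Rates-versus-time tables convert
subs/site/Ma to subs/site/Ga (×1000).

## 3. Synthetic data

The generator emulates the statistical structure of deep reaction-centre
datasets: Yule topologies rescaled to an exact root age (the inference
prior deliberately does *not* match the Yule process — a documented,
harmless mismatch, since dating conditions on the topology); rates from the
same autocorrelated process the sampler assumes; sequences evolved
site-by-site with per-site gamma categories held constant along the tree.
No indels are simulated — missing-data handling is tested by masking
residues instead.

The benchmark condition, used by the test-suite and the acceptance script,
is the generator default: 8 taxa, root 3500 Ma, σ² = 10⁻⁴/Ma (0.1/Ga),
α = 0.5, 200 sites, root rate 1.25×10⁻⁴ subs/site/Ma. The duplication
fixture places a duplication-analogue node at 0.85 × root age carrying two
mirrored paralogue clades (crown at half the duplication age) over a
two-leaf outgroup, and brackets the two clade crowns and the outgroup split
with two-sided calibrations at truth ± 20%. With a strict clock and a root
rate of 4×10⁻⁴/Ma the cross-paralogue leaf identity sits in the
empirically observed ~40–45% band; the default (slower) rate keeps the
alignment informative without saturation.

What passing these tests shows — and does not. Recovery and widening
results demonstrate the sampler is correct and well-calibrated *under its
own model* (matched generator). They do not certify accuracy under model
violation (site-heterogeneous profiles, non-Yule trees, alignment error),
which is exactly the gap the identity-decay track's fossil cross-checks
and the calibration-sensitivity machinery are meant to probe on real data.

## 4. Problem sizes and numerical tolerances

- Pruning is verified against brute-force state enumeration (4 taxa, 10
  sites, 5 seeds) to 10⁻⁹ relative; transition matrices satisfy
  Chapman–Kolmogorov to 10⁻⁹ and row-stochasticity to 10⁻¹².
- Prior fidelity: 10⁴ thinned likelihood-off samples against the analytic
  soft-bound density (KS), with per-side tail masses within ±1 percentage
  point of 2.5%.
- Recovery: 20 replicates at the benchmark condition, 3000 iterations
  (1000 burn-in, thinned to 500 samples) per run — chosen as the smallest
  chains whose credible intervals are stable enough for paired width
  comparisons; the acceptance script uses 12 replicates.
- MCMC degenerate checks: near-point root prior + strict clock recovers
  the prior mean; identical seeds give bit-identical traces.

## 5. Known limitations

- Homogeneous Poisson model: no empirical exchangeabilities (WAG/LG) and
  no site profiles; absolute deep ages on real proteins will differ.
- Linear identity decay ignores saturation; its backward extrapolations are
  systematically young at low identity.
- The uniform order-polytope age prior is informative for deep unanchored
  nodes (it pulls them toward the middle of the root interval); with few
  calibrations this matters, which is why calibration-removal sensitivity
  is a first-class operation.
- Single-threaded; chains run sequentially.
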