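# paleoclock

Dating ancient gene duplications from protein sequences — built around the
question of when the two core subunits of Photosystem I (PsaA and PsaB, a
heterodimer born of a gene duplication) diverged, and whether that event
predates the Great Oxidation Event (~2.4 Ga).

The package implements two complementary dating tracks plus a synthetic
ground-truth generator so that every inference stage is testable end to end:

1. **Identity-decay chronometry** (`paleoclock.identity_decay`).
   Percent identity between slowly evolving orthologues decays roughly
   linearly over geological time. Anchoring the decay rate at a
   fossil-dated divergence — e.g. the MRCA of Cyanobacteria at 2.4 Ga, by
   which point PsaA and PsaB had each diverged ~30% from their plant
   orthologues — gives a rate *r* in Ma per 1% identity loss:

       r = t_anchor / d_anchor          (e.g. 2400 / 30 = 80 Ma per 1%)

   Run forwards, the expected identity after time *t* is `100 − t/r`; run
   backwards, an observed identity *I* dates to `(100 − I) · r`. No
   multiple-hit correction is applied — the method is a deliberately raw
   first approximation, validated against fossil-bracketed species pairs.

2. **Bayesian relaxed molecular clock** (`paleoclock.mcmc` and friends).
   Node dating on a fixed rooted topology by Metropolis–Hastings MCMC:

   - Poisson amino-acid substitution (equal exchangeabilities, frequencies
     1/20) with 4 discrete-gamma rate categories, scored by Felsenstein
     pruning with site-pattern compression;
   - autocorrelated log-normal branch rates (geometric Brownian motion:
     `log r_child ~ N(log r_parent − σ²Δt/2, σ²Δt)`, mean-preserving);
   - soft-bound fossil calibrations: uniform core on [min, max] with
     exponential tails holding 2.5% of the mass per side (5% below a
     minimum-only bound);
   - a normal root-age prior (e.g. 3500 ± 50 Ma) and a conditional-uniform
     prior on the remaining node ages.

3. **Synthetic benchmarks** (`paleoclock.synthetic`). Yule chronograms,
   forward-simulated autocorrelated rates and alignments, and a
   duplication-analogue fixture (mirrored paralogue clades under the oldest
   post-root node) with a truth file for recovery scoring.

## Worked example

The identity-decay track on the published Photosystem I identity table:

```bash
paleoclock identity-track --out-dir out/identity
```

prints the anchor-age sensitivity scan:

```
 mrca_age_ga  rate_ma_per_pct  rate_ma_per_pct_reported  duplication_age_ma  duplication_age_ga
         2.0        66.666667                        66                3795                3.79
         2.4        80.000000                        80                4600                4.60
         3.0       100.000000                       100                5750                5.75
```

Reading: if the MRCA of Cyanobacteria lived 2.4 Ga ago, PsaA/PsaB lose 1%
identity per 80 Ma, and their present ~42.5% mutual identity extrapolates to
a duplication 4.6 Ga ago; moving the anchor anywhere in 2.0–3.0 Ga keeps the
duplication far older than the Great Oxidation Event. The same run writes
`fossil_consistency.tsv`, which checks the rate against fossil-bracketed
pairs (e.g. at 80 Ma/% the observed 92.5% identity of the
*Arabidopsis*–*Marchantia* pair extrapolates to 600 Ma, inside its 410–680
Ma molecular-clock bracket).

A relaxed-clock run on a synthetic benchmark:

```bash
paleoclock simulate --n-taxa 8 --n-sites 200 --seed 1 --out-dir out/fixture
paleoclock date-track --config config.yaml --out-dir out/dating
```

where `config.yaml` points at the fixture's alignment, topology and
calibration TSV. Outputs are per-chain trace TSVs, per-node posterior
summaries (mean, sd, 95% credible interval), a rates-versus-time table, and
a manifest with input/output digests; identical seeds give bit-identical
traces.

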