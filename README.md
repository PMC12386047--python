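# cbdcoin

Contextuality-by-Default (CbD) analysis of forced-choice "generalized coin"
judgment data.

## The problem

Can a human judgment be reduced to a causal story about the stimulus, or does
it behave like a quantum observable — indeterminate until measured and
sensitive to the measurement context?  One behavioral test case: people are
shown a pair of face images, one real and one AI-generated, and must pick the
fake.  Four faces {F0, R1, F2, R3} (two fake, two real) yield four pairings

    C0 = {F0, R1}, C1 = {R1, F2}, C2 = {F2, R3}, C3 = {R3, F0},

a **cyclic system of rank 4**: each face is judged in two different contexts.
Forced choice makes the two outcomes in a context perfectly anti-correlated
— exactly one face of the pair is called fake — so each image set
("coin") is fully described by four marginals p0..p3, the per-context
probabilities that the fake member of the pair is (correctly) judged fake.

CbD theory diagnoses contextuality even when the system is *disturbed*
(marginals shift between contexts).  For a cyclic system the criterion is

    s_odd − (n − 2) − Δ > 0

where `s_odd` aggregates the context correlations with an odd number of sign
flips and the disturbance is

    Δ = |p0 − p3| + |p1 − p0| + |p1 − p2| + |p3 − p2|.

Under the study's convention, four perfect anticorrelations give s_odd = 3,
so the criterion value reduces to **1 − Δ** for every forced-choice coin.
(The canonical cyclic-systems convention, under which the same correlations
give s_odd = 2, is also implemented and kept clearly separate.)  Uncertainty
is quantified by a percentile bootstrap (10,000 binomial resamples per coin);
a coin is classified contextual when its criterion value lies inside the 95%
interval *and* the interval's lower endpoint is strictly positive.

The package is for quantitative cognitive scientists who want to run this
analysis on their own forced-choice data, reproduce the published face-study
numbers, or simulate generalized coins and study-shaped synthetic datasets.

## Worked example

```python
from cbdcoin import BootstrapConfig, analyze_counts, reconstruct_counts
from cbdcoin.reference import study_marginals

study = study_marginals()                      # the 20 published coins
counts = reconstruct_counts(study)             # k = round(50 * p) per context
results = analyze_counts(counts, BootstrapConfig(n_iter=10_000, seed=0),
                         {c: m.gender_group for c, m in study.items()})
r = results[0]                                 # coin 1
print(round(r.delta, 2), round(r.cbd_value, 2),
      (round(r.ci_lower, 2), round(r.ci_upper, 2)), r.contextual)
```

prints

```
0.28 0.72 (0.24, 0.88) True
```

Coin 1's marginals (0.56, 0.46, 0.42, 0.46) give disturbance Δ = 0.28, a
criterion value of 1 − 0.28 = 0.72 with 95% bootstrap interval [0.24, 0.88];
since 0.72 lies inside the interval and the lower endpoint is positive, the
coin is contextual.  Across all 20 coins this run classifies nine as
contextual (coins 1, 2, 6, 8, 12, 13, 15, 16, 17).

The same pipeline is available from the shell:

```bash
cbdcoin reproduce --seed 0 --outdir out/        # full study regeneration
cbdcoin generate --seed 0 --out judgments.csv   # synthetic raw data
cbdcoin analyze --in judgments.csv --out results.tsv --summary summary.tsv
cbdcoin simulate-coin --n-tosses 100000 --seed 0
cbdcoin summarize                               # fake/real accuracy means
```

`reproduce` writes a per-coin results table and accuracy summary both from
the published marginals (exact reconstruction) and from a sampled synthetic
dataset, plus a comparison report and a run manifest.

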