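# dmnull

Neutral-model analysis of per-host microbiome count data: Dirichlet-multinomial
fitting, structure-matched null simulation, and correlation-quantile tests,
with the supporting diversity and ordination statistics.

## The scientific problem

In small, tractable host–microbiome systems — the motivating case is
individual *Caenorhabditis elegans* worms colonized from a defined
eight-species bacterial metacommunity and plated as CFU counts per worm —
community composition varies enormously between genetically identical hosts.
A central question is whether that variation reflects **interspecies
interactions** (competition, facilitation) or is just what a **neutral
sampling process** would produce: species differ in their probability of
colonizing, but not in their ability to compete once inside.

The package operationalizes that question. The neutral model is the
**Dirichlet-multinomial (DMN)**: for host *i* with total count
*N<sub>i</sub>*,

> p<sub>i</sub> ~ Dirichlet(γ),  x<sub>i</sub> ~ Multinomial(N<sub>i</sub>, p<sub>i</sub>),  γ<sub>j</sub> = π<sub>j</sub>(1−θ)/θ,

where π is the expected relative-abundance vector and θ ∈ (0,1) the
overdispersion (θ→0 recovers the multinomial). After fitting (π, θ) by
maximum likelihood, the package simulates *B* **structure-matched** data sets
— same number of hosts, same per-host totals — and compares the 20th/80th
quantiles of the empirical pairwise Spearman correlations against their null
distributions. One-tailed p-values are the fraction of null data sets with a
lower 20th (resp. higher 80th) quantile: an excess of negative correlations
signals competition beyond sampling noise; an excess of positive ones signals
facilitation beyond the common-species-are-common-together artifact.

Supporting analyses: Shannon diversity vs log₁₀(community size) regression
with a pooled-vs-per-lineage likelihood-ratio test, and
log-transform → PCA / Bray-Curtis → ANOSIM / PERMANOVA lineage comparisons.
A synthetic-data generator (neutral DMN and an interacting
logistic-normal-multinomial alternative) makes the entire pipeline runnable
and testable with no external data.

## Worked example

```python
import dmnull

# 164 synthetic hosts at the wild-type-like preset (8 MYb species,
# theta = 0.1698, totals 1,680-67,200 CFU/worm)
m = dmnull.generate_neutral(dmnull.n2_neutral_spec(n_hosts=164, seed=1))

fit = dmnull.fit_dmn(m)
print(f"theta = {fit.theta:.4f}")
res = dmnull.neutral_correlation_test(m, B=2000, seed=42)
print(f"q20 = {res.empirical_q[0]:+.3f}, q80 = {res.empirical_q[1]:+.3f}")
print(f"p_lower = {res.p_lower:.3f}, p_upper = {res.p_upper:.3f}")
```

prints

```
theta = 0.1563
q20 = -0.011, q80 = +0.154
p_lower = 0.828, p_upper = 0.023
```

The fitted overdispersion is close to the generating value 0.1698. Because
this data set *is* neutral, its p-values are draws from (approximately) a
uniform distribution — a single neutral data set can land anywhere in [0, 1],
including near the tails as here; the package's calibration test checks
uniformity over 200 such data sets rather than any single draw. On data
generated with a competitive trade-off axis
(`dmnull.n2_interacting_spec`), `p_lower` collapses to ~0 in nearly every
repetition.

The same pipeline is scriptable from the shell:

```bash
dmnull generate --preset n2-neutral --n-hosts 164 --seed 1 --out synth.csv
dmnull fit-dmn  --input synth.csv --out fit.json
dmnull null-test --input synth.csv --b 10000 --seed 42 --out test.json
```

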