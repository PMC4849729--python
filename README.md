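# drugspread

A drug-centric view of drug development: tools for analyzing how drugs
accumulate studies over their lifetime and how they spread from disease to
disease.

Instead of asking which drug treats a disease, this package asks how a
*drug* — once born into a first disease — propagates across the diseasome.
It is aimed at computational drug-discovery researchers working with
timestamped (drug, study, date) and (drug, disease, first-pairing date)
event tables, such as those derived from literature or clinical-trial
registries.

## What it computes

**Study accumulation.** Align every drug at its *birth* (first recorded
study) and average the cumulative study count across drugs at each age
t′.  The mean curve follows a power law

    F(t′) = α t′^β

whose exponent β separates accelerating (β > 1) from stagnating (β < 1)
drugs.  Within-cohort quintile assignment and the quintile transition
matrix quantify the *momentum* of a drug's early success.

**Drug-centric disease taxonomy.**  Each disease D_i is characterized by
the set of drugs d^i it has adopted.  For a pair (D_i, D_j) the
co-adoption pattern over the drug universe **d** is a 2×2 Bernoulli
distribution, and the similarity is its mutual information (in nats)

    I(D_i; D_j) = Σ_{x,y} p_ij(x,y) log[ p_ij(x,y) / (p_i(x) p_j(y)) ].

Ward minimum-variance clustering of the distance d = I_max − I yields a
disease hierarchy (exportable as Newick), and per-disease drug
*exclusivity* measures how differentiated its therapies are.

**Propagation network.**  Diseases communicate like nodes of a network
sending messages (drugs) at Poisson rates: after disease i adopts a drug,
a non-adopter j receives it with exponential delay, P(Δt > t) = e^(−λ_ij t).
Drugs adopted by i but never by j are right-censored at the last
observation time t_max and contribute survival terms.  The pairwise
maximum-likelihood estimate is closed-form:

    λ̂_ij = n_observed / ( Σ observed Δt  +  Σ censored (t_max − t_i) )

and the mean propagation delay is T_ij = 1/λ̂_ij.  A fuller
competing-sources model estimates all incoming rates of a target disease
jointly, crediting every adopter that preceded the target.  Edges with
T < 100 yr form a directed network whose in/out-degrees and Dijkstra
shortest delays identify "early adopter" and "late adopter" diseases.

**Synthetic cascades.**  A seeded simulator generates drug births, cascade
propagation over a latent rate matrix, and per-drug study histories with
E[count at age t] = α t^β — the ground truth used to validate every stage.

## Worked example

```python
from drugspread.synthetic_data import SimulationConfig, simulate_dataset
from drugspread.accumulation import aligned_curve, fit_power_law
from drugspread.propagation import infer_network_rates, build_network

cfg = SimulationConfig(n_diseases=4, edge_density=0.5, drugs_per_year=25.0, rng_seed=7)
events, adoptions, truth = simulate_dataset(cfg)

fit = fit_power_law(aligned_curve(events, window=cfg.window))
print(f"accumulation fit: alpha={fit.alpha:.2f} beta={fit.beta:.2f} R2={fit.r_squared:.3f}")

estimates = infer_network_rates(adoptions, window=cfg.window, model="full")
net = build_network(estimates, t_cut=100.0)
for i, j in sorted(net.edges):
    est = estimates[(i, j)]
    print(f"  {i} -> {j}: T_hat={est.t_hat:5.1f} yr, n_obs={est.n_observed}")
```

prints

```
accumulation fit: alpha=1.64 beta=1.21 R2=0.998
  D00 -> D03: T_hat=  2.2 yr, n_obs=157
  D01 -> D00: T_hat= 11.7 yr, n_obs=201
  D01 -> D02: T_hat=  4.9 yr, n_obs=230
  D02 -> D01: T_hat=  5.9 yr, n_obs=120
  D02 -> D03: T_hat=  2.6 yr, n_obs=201
  D03 -> D00: T_hat=  4.5 yr, n_obs=254
  D03 -> D01: T_hat=  6.2 yr, n_obs=264
```

The fitted exponent β = 1.21 sits inside the simulated per-drug range
[0.7, 1.6]; the recovered mean delays T̂ agree with the latent matrix
(e.g. the true D01→D00 delay is 12.2 yr) because the competing-sources
likelihood matches the cascade generator.

The same stages run from the shell:

```sh
drugspread simulate --seed 7 --n-diseases 4 --out out/
drugspread accumulate --studies out/studies.tsv --out out/curve.tsv
drugspread fit-powerlaw --curve out/curve.tsv
drugspread taxonomy --adoptions out/adoptions.tsv --min-drugs 10 --out out/tree.nwk
drugspread infer-network --adoptions out/adoptions.tsv --model full --out out/edges.tsv
drugspread run --config pipeline.yaml     # full chain + manifest
```

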