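# plateletabc

Personalised platelet-function analysis by simulation-based inference.

Blood from patients with chronic systemic inflammation (here: dialysis
and COPD patients) deposits platelets differently from healthy blood when
sheared over a substrate in a cone-and-plate platelet function analyzer.
`plateletabc` turns that deposition pattern into **biologically
interpretable per-subject parameters** and group-level tests:

1. a stochastic particle simulator of platelet deposition under shear —
   activated platelets (AP) random-walk to the wall and seed clusters,
   AP and non-activated platelets (NAP) aggregate beside and on top of
   clusters, and serum albumin competes for the surface, attenuating
   deposition by `exp(-a_T * rho_albumin)`;
2. discriminative summary statistics: a 2-D projection of the observed
   time series learned by large-margin nearest-neighbor (LMNN) metric
   learning on a labelled cohort, whose Euclidean distance separates the
   clinical groups;
3. likelihood-free posterior inference (rejection ABC, reference-table
   rejection, and simulated-annealing ABC) of the seven model parameters
   θ = (adhesion rate, aggregation rate, on-top rate, albumin rate,
   albumin attenuation, AP velocity, NAP velocity) per subject, with the
   MAP estimate taken as the mode of a Gaussian-KDE-smoothed posterior
   cloud (bandwidth 0.45, Nelder-Mead);
4. group analysis: Kruskal-Wallis H-tests (global + pairwise post hoc)
   with Benjamini-Hochberg correction identify the discriminating
   parameters, and a nearest-median pathology test classifies subjects
   with sensitivity/specificity reporting;
5. posterior predictive checks: 95% predictive bands and the energy score
   `ES = 2 Σ_i ||x_i - x0||^β - Σ_ij ||x_i - x_j||^β`.

The real clinical data are not distributed; a synthetic cohort generator
(three groups, configurable centers and dispersions, simulator-generated
series) makes every stage testable end-to-end. See `docs/methods.md` for
the model, defaults, study conditions and known limitations.

## Worked example

```python
import plateletabc as pa

params = pa.DepositionParams(
    adhesion_rate=0.5,          # 1/s, AP seeding on free substrate
    aggregation_rate=1.0,       # 1/s, deposition beside a cluster
    top_rate=0.2,               # 1/s, deposition on top of a cluster
    albumin_rate=3e-3,          # 1/s, albumin site filling
    albumin_attenuation=3e-4,   # per albumin particle per cell
    velocity_ap=1.5e-3,         # m/s
    velocity_nap=6e-4,          # m/s
)
config = pa.DeviceConfig(scale=0.1, dt=0.05)   # 100x100 um desk-scale window
series = pa.simulate(params, config, seed=1)
for t, n, s, npl in zip(series.times, series.n_clusters,
                        series.mean_cluster_size, series.n_platelet):
    print(f"t={t:5.0f}s  clusters/mm2={n:8.1f}  mean size={s:6.1f} cells  NAP/ul={npl:9.0f}")
```

prints

```
t=    0s  clusters/mm2=     0.0  mean size=   0.0 cells  NAP/ul=   172195
t=   20s  clusters/mm2=  2469.1  mean size=   9.5 cells  NAP/ul=   140488
t=  120s  clusters/mm2=  1481.5  mean size=  30.9 cells  NAP/ul=    87195
t=  300s  clusters/mm2=  1481.5  mean size=  30.9 cells  NAP/ul=    86585
```

Early on, many small clusters seed (2469 per mm² of ~10 cells at 20 s);
as albumin accumulates, seeding stops and clusters grow and merge (fewer,
larger clusters by 120 s), while the suspended NAP count drops as
platelets deposit.  After ~2 minutes the albumin attenuation has shut the
deposition channels and the pattern freezes — exactly the competition the
attenuation parameter quantifies.

Inference for one subject, and a full synthetic study:

```python
from plateletabc.inference import (PriorSpec, build_reference_table,
                                   FullDataDistance, sabc_from_table)

prior = PriorSpec()                                   # wide defaults
table = build_reference_table(prior, config, n=2000, seed=7)
posterior = sabc_from_table(series, table, FullDataDistance.from_table(table),
                            config, n_particles=64, n_generations=8, seed=0)
estimate = pa.map_estimate(posterior, prior=prior)    # KDE mode, the MAP
```

The same stages are scriptable from the shell (`plateletabc simulate`,
`generate-cohort`, `learn-summaries`, `infer`, `map`, `analyze`,
`classify`, `ppc`); every run writes a manifest with seeds and input
hashes.

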