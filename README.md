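# stsir — spatiotemporal disease mapping for county-level count panels

`stsir` implements the full analysis pipeline used in small-area cancer
surveillance when all you have is a region-by-year panel of case counts and
populations at risk: crude and Bayesian-smoothed standardized incidence
ratios (SIR), Kulldorff-style space-time cluster detection, and formal
comparison of hierarchical Bayesian space-time models. It was built around
a county-level study of colorectal and gastric cancer incidence over a
9-county province and a 10-year period, whose registry data are not public;
a first-class synthetic-data generator reproduces the statistical structure
of such a panel so that every stage is testable end to end.

It is aimed at spatial epidemiologists and biostatisticians who want a
scriptable, fully seeded alternative to stitching together SaTScan and
INLA runs.

## The statistics

**Standardization.** With counts `Y_ij` and populations `n_ij` per region
`i` and year `j`, indirect standardization allocates the pooled cases in
proportion to population, `E_ij = n_ij (Σ_i Y_ij / Σ_i n_ij)` (per year by
default), and the crude SIR is `Y_ij / E_ij`.

**Space-time scan.** Cylinders (a k-nearest-regions base by centroid
distance × a run of consecutive years, capped at 50% of the population at
risk and 50% of the period) are scored with the discrete-Poisson
log-likelihood ratio

    LLR = c ln(c/e) + (C−c) ln((C−c)/(C−e)),

where `c, e` are the cylinder's observed/expected counts and `C` the study
total. High- and low-rate clusters are ranked per direction; pseudo
p-values come from 999 conditional multinomial replicates, so the smallest
attainable p is 0.001.

**Bayesian smoothing.** `Y_ij ~ Poisson(E_ij θ_ij)` with six variants of
`log θ_ij`: the additive model `α + v_i + u_i + γ_j + φ_j` (iid `v`,
intrinsic-CAR `u`, RW2 `γ`, iid `φ`), the four Knorr-Held interaction
extensions `+ δ_ij` (types I–IV, crossing unstructured/structured space and
time), and a parametric trend `α + u_i + v_i + (β + s_i) t_j`. Precisions
carry the classical Gamma(1, 5e-5) disease-mapping default. Inference is
by a purpose-built MCMC sampler (dense-preconditioned MALA with conjugate
Gibbs, rescaling and mode-swap moves; see `docs/methods.md`). Fits are
compared by DIC, WAIC, Σlog CPO, PIT uniformity (Anderson–Darling) and R².

## Worked example

```python
from stsir import (hamadan_fixture, simulate_panel, inject_cluster,
                   expected_counts, scan, ScanConfig)

skel, graph, centroids = hamadan_fixture()          # 9 counties x 2010-2019
panel, truth = simulate_panel(skel, graph, seed=2,
                              hyper={"sd_v": 0, "sd_u": 0,
                                     "sd_gamma": 0, "sd_phi": 0})
panel, truth = inject_cluster(panel, truth, ["Tuyserkan", "Hamadan"],
                              (2015, 2019), 1.82, seed=3)
expected = expected_counts(panel, "per_year")
for r in scan(panel, centroids, expected, ScanConfig(seed=4)):
    if r.rank == "primary":
        cyl = r.cylinder
        print(r.direction, [panel.region_ids[i] for i in cyl.member_regions],
              cyl.start_year, cyl.end_year,
              f"RR={r.rr:.2f} LLR={r.llr:.2f} p={r.p_value}")
```

prints

```
high ['Tuyserkan', 'Hamadan'] 2015 2019 RR=1.51 LLR=39.92 p=0.001
low ['Malayer', 'Nahavand'] 2015 2019 RR=0.69 LLR=17.45 p=0.001
```

The injected cylinder is recovered exactly as the primary high-rate
cluster. RR is the risk inside the cylinder relative to outside; it reads
1.51 rather than the injected 1.82 because the year-stratified expecteds
are recalculated from the contaminated panel, exactly as in a real
retrospective analysis. The mirror-image low-rate cluster is the same
contamination seen from outside the cylinder. p = 0.001 is the smallest
pseudo p attainable with 999 Monte Carlo replicates.

The scripted analysis in `analysis/` (numbered steps: simulate panels,
crude SIRs, scan, model fits and comparison, scan operating
characteristics, parameter recovery) writes its tables to `results/`. On
the bundled synthetic panels, step 04 reports, for example, WAIC 519.9 for
the type II interaction model against 540.1 for the no-interaction model
on the colorectal-like panel, with R² rising from 0.40 to 0.55 — the same
qualitative ordering the motivating study reports for its registry data.

A `stsir` CLI mirrors the pipeline (`stsir sir|scan|fit|compare|simulate|run`);
`stsir run --config run.yaml` executes everything with one seeded config.

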