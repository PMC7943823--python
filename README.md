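# canopyedge

Tools for asking how fragmented, logged tropical forest responds to a hot
drought: did the canopy keep growing, and how far do oil-palm edge effects
reach?  The package re-creates a repeat airborne-LiDAR analysis of
canopy-height change across a forest / oil-palm mosaic as a fully synthetic,
seeded pipeline, so every stage — terrain metrics, pixel filtering, plot
statistics, microclimate, and the spatial regression at the core — can be
exercised and tested without any external download.  It is aimed at forest
ecologists and remote-sensing researchers who want a transparent, testable
implementation of the method, or a simulation harness for power and
sensitivity analysis.

## The model

Per 30 m pixel, the change in top-of-canopy height between two surveys
(ΔTCH, metres) is modelled as a function of topographic position (TPI),
initial canopy height (TCH₂₀₁₄) and distance to the nearest oil-palm edge
(D, metres):

    ΔTCH_i = β₀ + β₁·TPI_i + β₂·TCH₂₀₁₄,i − b·exp(−c·D_i) + ε_i

The exponential term is an edge-effect penalty that decays with distance at
rate c (1/m); its amplitude b is the extra height loss right at the edge.
Residuals ε may carry an exponential spatial correlogram
corr(i,j) = exp(−d_ij/ρ).  The package fits this model by nonlinear least
squares or by maximum likelihood with the spatial correlation structure,
selects among linear and asymptotic candidates by AIC, quantifies
uncertainty with an ensemble of 24 random pixel subsets (3000/4000/5000
pixels), and rescales subset confidence intervals to the full dataset by
√(n/N).  The reference coefficients used as generating truth throughout are

    β₀ = 0.6576, β₁ = −0.02142, β₂ = −0.0172, b = 0.8553, c = 0.0049

which put the zero-growth crossing of a 5 m-tall regenerating canopy at
ln(b/A)/c ≈ 82 m from the edge (A = β₀ + 5β₂).

## Worked example

The package's central computation is a parameter-recovery experiment at
study scale: simulate the landscape from the reference coefficients, apply
the pixel exclusion ledger, draw the 36,655-pixel analysis set, and
re-estimate the model on 24 random 5000-pixel subsets.

```python
from canopyedge.pipeline import parameter_recovery_experiment

res = parameter_recovery_experiment(seed=1)
print(res["audit"].to_frame().to_string(index=False))
print("analysis pixels used:", len(res["rows"]))
ens = res["ensembles"][5000]
print(ens.summary().to_string(index=False, float_format=lambda v: f"{v:.5f}"))
```

prints the exclusion audit and the ensemble summary (about 30 s):

```
           rule  rows_removed  rows_remaining
         nodata             0          285156
       oil_palm        114062          171094
       clearcut           243          170851
clearcut_buffer           960          169891
    road_buffer          9858          160033
    low_density        102204           57829
analysis pixels used: 36655
parameter     mean   median      sd   cv_pct
    beta0  0.62727  0.62889 0.03207  5.11325
 beta_tpi -0.02119 -0.02153 0.00189  8.92979
 beta_tch -0.01670 -0.01672 0.00063  3.77899
 edge_amp  0.77442  0.77606 0.05592  7.22069
edge_rate  0.00459  0.00468 0.00061 13.19825
```

Reading the summary: the ensemble medians recover the generating
coefficients within the ensemble spread — interior growth of a zero-height,
flat-terrain pixel ≈0.63 m over the survey interval, an ≈0.78 m penalty at
the oil-palm edge decaying at ≈0.0047 per metre, with ridges (positive TPI)
and taller canopies growing less.  The exclusion counts mirror the survey
conditions the generator emulates: the lowland oil-palm conversion, the
clear-cut and road buffers, and the removal of ~60% of pixels whose
first-survey point density falls below 10 points/m² (exact numbers depend
on the seed; these are from the command shown).

The same chain is available from the shell:

```bash
canopyedge simulate --seed 1 --out-dir scene/
canopyedge terrain --dtm scene/dtm.asc --cover scene/cover.asc --out-tpi tpi.asc
canopyedge pipeline --out-report report.txt
canopyedge predict --params '{"beta0": 0.6576, "beta_tpi": -0.02142,
  "beta_tch": -0.0172, "edge_amp": 0.8553, "edge_rate": 0.0049}' --tch 5 --tpi 0
```

`canopyedge verify-deposited` computes summary statistics (pixel counts,
edge-distance and TPI ranges, event-month temperature and VPD anomalies)
from externally deposited pixel / microclimate CSVs supplied by the user.

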