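# pvsalps

Perivascular-space (PVS) function markers for cerebral small vessel
disease (CSVD): computation of the **DTI-ALPS index** from diffusion
MRI, **PVS volumetry** from tissue-class maps, and the **longitudinal
statistical battery** that relates these markers to CSVD burden,
cognitive decline and incident dementia. Every stage is exercised on
synthetic phantoms and synthetic cohorts with known ground truth, so
the whole pipeline is testable without any patient data.

Intended users: neuroimaging and clinical-research groups who want a
reproducible, oracle-tested reference implementation of the ALPS/PVS
workflow and its downstream statistics.

## The markers

**DTI-ALPS** (diffusion tensor image analysis along the perivascular
space) measures water diffusivity along the perivascular spaces of the
medullary veins at the level of the lateral-ventricle body. Four
6-mm-diameter spherical ROIs are placed in MNI space at
(24, −12, 24), (−28, −12, 24), (36, −12, 24) and (−40, −12, 24) mm —
per side one in the projection-fiber area (corona radiata, fibers along
z, the medial ROI) and one in the association-fiber area (superior
longitudinal fasciculus, fibers along y). With Dxx, Dyy, Dzz the ROI
means of the directional diffusivity maps,

```
ALPS_side = (Dxx_proj + Dxx_assoc) / (Dyy_proj + Dzz_assoc)
ALPS      = (ALPS_left + ALPS_right) / 2
```

Higher values indicate better presumed perivascular/glymphatic
function. The tensor is fitted per voxel by log-linear least squares
(ln S = ln S0 − b gᵀDg); FA, MD, median white-matter MD and a
simplified PSMD (p95 − p5 of MD on a supplied skeleton) come from the
same fit.

**PVS volume** is obtained by set subtraction from the CSF tissue
class — removing ventricles, lacunes and extra-cerebral/large-vessel
CSF — then summed per region (whole brain, basal ganglia, white
matter), normalized by total brain volume (GM + WM) and log
transformed.

**Statistics**: cross-sectional OLS with standardized β; linear mixed
models (random intercept + slope on time, ML) with empirical-Bayes
slope extraction; logistic models for binary marker change; Cox
proportional hazards (Efron ties) with nested covariate sets;
Benjamini–Hochberg FDR per results table; optimal-cutpoint (Youden's J)
survival stratification with Kaplan–Meier/log-rank; and seeded
random-forest permutation importance (out-of-bag).

## Worked example

```python
from pvsalps import generate_alps_phantom, fit_tensor, derive_maps, compute_alps

# plant Dxx_proj=Dxx_assoc=1.5e-3, Dyy_proj=Dzz_assoc=0.5e-3 mm^2/s
ph = generate_alps_phantom(1.5e-3, 1.5e-3, 0.5e-3, 0.5e-3)
maps = derive_maps(fit_tensor(ph.acquisition))
res = compute_alps(maps, ph.rois)
print(res.mean, ph.expected["mean"])
```

prints

```
3.0000000000000027 3.0
```

— the full DWI → tensor-fit → maps → ROI-means chain returns the
planted arithmetic (1.5+1.5)/(0.5+0.5) = 3.0 to machine precision.

The end-to-end demo generates phantoms and a 120-subject synthetic
cohort, runs both stages and writes a markdown report:

```bash
pvsalps demo --seed 1 --out demo_out
```

From the seed-1 report: the three phantoms return mean ALPS
1.000000 / 3.000000 / 2.000000 against planted 1.0 / 3.0 / 2.0; the
cohort battery estimates an annual ALPS decline of −0.0104/yr
(p ≈ 1e-32), a dementia hazard ratio of 0.26 per SD of baseline ALPS
(95% CI 0.17–0.42), no PVS-volume change over time (p = 0.32), and an
optimal baseline-ALPS cutpoint of 1.288 whose low/high groups separate
on the Kaplan–Meier curves (log-rank p ≈ 2.5e-6) — the same qualitative
pattern the markers are designed to detect, here recovered from known
generating parameters (decline −0.010/yr, HR 0.328, 18.2% 5-year
incidence).

Other CLI entry points: `pvsalps simulate` (cohort CSV + phantom DWI as
NIfTI with FSL bval/bvec), `pvsalps imaging` (ALPS from a DWI on disk),
`pvsalps analyze` (battery over a cohort CSV).

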