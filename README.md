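# qqoef

Oxygen extraction fraction (OEF) mapping from multi-echo gradient-echo MRI
by the joint QSM + qBOLD ("QQ") model with cluster analysis of time
evolution (CAT), plus the downstream ischemic-stroke lesion analysis:
contralateral-mirror metrics, diffusion-reversal classification,
stroke-phase binning and group statistics. A digital phantom generates
every input (mGRE magnitudes, susceptibility maps, CBF maps, lesion masks,
a screening roster), so the whole pipeline runs on a laptop with no data
downloads.

Intended users: researchers working on MRI-based brain oxygenation
mapping who want a tested, reproducible reference implementation of the
CAT-QQ estimator and of the lesion ROI analysis built on top of it.

## The model

Each voxel carries five parameters — venous oxygenation `Y`, venous blood
volume fraction `ν`, relaxation rate `R2`, amplitude `S0` and non-blood
susceptibility `χ_nb` — linked to the data by two forward models:

- susceptibility:
  `F_QSM = [χ_ba/α + Ψ_Hb·Δχ_Hb·(−Y + 1 − (1−α)·Ya)/α]·ν + (1 − ν/α)·χ_nb`
- magnitude decay (static dephasing regime):
  `S(t) = S0 · e^(−R2·t) · exp(−ν·fs(δω·t)) · G(t)`

The estimate minimizes

    w·‖F_QSM − χ‖² + ‖S(t) − S_qBOLD(t)‖² + λ·(mean OEF − OEF_wb)²

under box bounds, where `OEF = 1 − Y/Ya` and the whole-brain target
`OEF_wb = Hct_vt · OEF_ss` comes from inverting `F_QSM` on the mean
straight-sinus susceptibility. Voxels are first clustered by decay shape
(X-means with a BIC-driven cluster count); each cluster's mean decay is
fit by multi-start bounded least squares and its members share the
resulting (Y, ν, R2) while (S0, χ_nb) are refined per voxel. See
`docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate a diffusion-reversal (DR) stroke case, fit OEF maps for both
scans, and analyze the lesion regions:

```bash
qqoef run --case dr --seed 5 --output out_dr
```

or in Python:

```python
import numpy as np
from qqoef import (PhantomConfig, make_longitudinal_case, simulate_mgre,
                   estimate_whole_brain_oef, fit_voxelwise, FitConfig,
                   relative_metric)
from qqoef.clustering import decay_features, xmeans
from dataclasses import replace

cfg = replace(PhantomConfig(seed=2), snr=None)
case = make_longitudinal_case("DR", cfg=cfg, seed=2)
tissue = case.masks["brain"] & ~case.masks["sinus"]
rr = case.idl & ~case.fi                      # reversal region
for scan in (0, 1):
    echoes = simulate_mgre(case.truths[scan], snr=None, seed=2 + scan)
    oef_wb = estimate_whole_brain_oef(case.chis[scan], case.masks["sinus"])
    feats = decay_features(echoes, brain_mask=tissue)
    clusters = xmeans(feats.features, seed=3)
    clusters.voxel_index = feats.voxel_index
    maps = fit_voxelwise(echoes, case.chis[scan], clusters, tissue,
                         FitConfig(seed=3), oef_wb)
    roef = relative_metric(maps.oef, rr, case.midline, case.masks["brain"])
    print(f"scan {scan + 1}: reversal-region rOEF = {roef:.3f}")
```

prints

```
scan 1: reversal-region rOEF = 0.737
scan 2: reversal-region rOEF = 0.902
```

The reversal region — initially diffusion-restricted tissue that escaped
infarction — starts with a relative OEF well below its mirrored
contralateral area (0.74) and recovers toward normal by the second scan
(0.90), while the scan-1 lesion CBF sits ~1.46× above the contralateral
level (`relative_metric(case.cbfs[0], case.idl, ...)`): the hyperperfused,
oxygen-under-extracting signature of salvageable tissue. A non-reversal
case (`--case ndr-equal`) shows the opposite trajectory, relative OEF
falling from 0.82 to 0.65 as the tissue completes infarction.

The cohort arm screens a 137-record roster down to 115 analyzable
patients (8 brainstem/cerebellum infarcts, 2 lesions under 250 mm³,
4 hemorrhagic transformations, 8 pre-MRI reperfusion therapies) and
summarizes lesion OEF by stroke phase:

```bash
qqoef run --case cohort --seed 3 --output out_cohort
# out_cohort/phase_summary.csv: acute 26.04 ± 7.24 %, early subacute
# 21.92 ± 3.86 %, late subacute 21.87 ± 4.07 %, chronic 21.58 ± 5.04 %
```

## Layout

| path | contents |
|------|----------|
| `src/qqoef/constants.py` | physiological constants, OEF/CMRO2 conversions, sinus inversion |
| `src/qqoef/forward.py` | F_QSM, SDR kernel, qBOLD signal, macroscopic field factor |
| `src/qqoef/clustering.py` | decay features, seeded k-means, BIC, X-means |
| `src/qqoef/fitting.py` | cluster-stage and voxel-stage QQ estimation |
| `src/qqoef/phantom.py` | geometry, truth maps, χ/mGRE/CBF simulation, rosters |
| `src/qqoef/roi.py` | mask algebra, mirror metrics, case classification, screening |
| `src/qqoef/stats.py` | paired t, ANOVA+Bonferroni, partial correlation, KS/Levene |
| `src/qqoef/{config,io,pipeline,cli,plots}.py` | YAML config, NIfTI/CSV I/O, stage runner, CLI |
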