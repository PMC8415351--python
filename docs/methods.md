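# Methods

`qqoef` maps the oxygen extraction fraction (OEF) of brain tissue from two
MRI-derived inputs — a multi-echo gradient-echo (mGRE) magnitude series and
a quantitative susceptibility map (QSM) — using the joint QSM+qBOLD ("QQ")
model with cluster analysis of time evolution (CAT), and then runs a
stroke-lesion ROI analysis (contralateral-mirror metrics, diffusion-reversal
classification, phase binning, group statistics) on the resulting maps.
A digital phantom supplies every input, so the entire analysis runs at desk
scale with no external data.

## The signal model

Each voxel is described by five parameters: venous oxygenation `Y`, venous
blood volume fraction `ν`, transverse relaxation rate `R2` (1/s), signal
amplitude `S0`, and non-blood susceptibility `χ_nb` (ppb). Two forward
models connect them to data.

**Susceptibility.** The two-compartment model

    F_QSM(Y, ν, χ_nb) = [χ_ba/α + Ψ_Hb·Δχ_Hb·(−Y + 1 − (1−α)·Ya)/α]·ν
                        + (1 − ν/α)·χ_nb

with arteriole oxygenation `Ya = 0.98`, venous-to-total blood volume ratio
`α = 0.77`, hemoglobin volume fraction `Ψ_Hb = 0.0909` (tissue, Hct = 0.357)
or `0.1197` (large vein), deoxy–oxyhemoglobin susceptibility difference
`Δχ_Hb = 12522 ppb`, and fully oxygenated blood susceptibility `χ_ba`
(config default −108.3 ppb; this value is not fixed by the printed constants
and is exposed in the configuration, as is the arteriolar heme concentration
`[H]a = 7.377 µmol/ml` used by the CMRO2 utility).

**Magnitude decay.** `S(t) = S0·e^(−R2·t)·F_BOLD(t)·G(t)`, where the blood
attenuation follows the static dephasing regime (SDR):
`F_BOLD = exp(−ν·fs(δω·t))` with

    fs(x) = (1/3) ∫₀¹ (2+u)·√(1−u)·[1 − J₀(1.5·x·u)]/u² du,
    δω = (1/3)·γ·B0·(Ψ_Hb·Δχ_Hb·(1−Y) + χ_ba − χ_nb)·1e−9.

`fs` is evaluated by adaptive quadrature with a series expansion of
`1 − J₀` below `u ≈ 1e−3` (absolute tolerance 1e−12); the fitting hot path
uses a cubic-spline table of the same function (3201 knots on [0, 80],
linear asymptotic extension, ≈1e−9 accuracy — far below fit tolerances).
Negative `δω` brackets are clipped to zero with a warning so optimizer
excursions cannot crash a fit. The exact composition of `δω` (how `χ_ba`
enters) varies across the qBOLD literature; the form above is this
package's choice and all constants feeding it are configurable.

**Macroscopic field.** `G(t)` is either unity (phantom default) or a
separable |sinc| product modeling a linear background gradient across the
voxel. Estimating G from measured field maps is out of scope; the
parametric model preserves its algebraic role.

## The inverse problem

Per voxel the estimate minimizes

    w·‖F_QSM − χ‖² + ‖S(t) − S_qBOLD(t)‖² + λ·(mean OEF − OEF_wb)²

subject to box bounds (`Y ∈ [0.01·Ya, Ya]`, `ν ∈ [0.001, 0.1]`,
`R2 ∈ [1, 100] s⁻¹`, `S0 > 0`, `χ_nb ∈ [−200, 200] ppb`), where
`OEF = 1 − Y/Ya` and `OEF_wb = Hct_vt·(1 − Y_ss/Ya)` (`Hct_vt = 0.75`) is
the whole-brain target obtained by inverting `F_QSM` at `ν = 1, χ_nb = 0`
on the mean straight-sinus susceptibility.

Because no printed values exist for `w` and `λ`, the residuals are
normalized — signal residuals by the mean brain first-echo signal, the QSM
residual by the brain susceptibility standard deviation — making both
weights dimensionless; defaults are `w = 1` and `λ = 1000`.

Estimation is two-stage (CAT):

1. **Cluster stage.** Voxels are grouped by decay shape (below) and each
   cluster's mean signal and mean χ are fit by bounded trust-region least
   squares from five seeded starts spanning the (Y, ν) box, keeping the
   lowest cost. A nested-model check then refits with ν pinned at its
   lower bound; if that reduced model explains the data essentially as
   well (cost within 0.1%), the blood compartment is declared
   non-identifiable, the reduced fit is kept and the cluster is flagged.
2. **Voxel stage.** By default (`voxel_refine="s0_chi_nb"`) the cluster's
   (Y, ν, R2) are shared by its member voxels — the defining CAT
   assumption — and only (S0, χ_nb) are refit per voxel. A full
   five-parameter per-voxel refit (`voxel_refine="all"`) is available but
   is not the default: at realistic SNR the per-voxel problem is
   ill-conditioned along a Y–ν–χ_nb valley and single-voxel refits drift.

The global mean-OEF penalty is handled by constraint splitting: each outer
iteration computes the offset `mean OEF − OEF_wb` and refits clusters (or
voxels, in "all" mode) against privately shifted targets, which keeps the
subproblems independent. The true global objective is recorded each
iteration; if an iteration would increase it, the step is reverted and the
loop stops, so the recorded history is non-increasing by construction.
Convergence is declared when the OEF map changes by less than 1e−3.
Straight-sinus voxels are excluded from the fitted tissue mask: a whole
vein (ν = 1) violates the tissue bounds by an order of magnitude.

## Clustering (CAT)

Features are the G-corrected, first-echo-normalized log decays
`f_j = ln[(S_j/G_j)/(S_1/G_1)]`, so a mono-exponential voxel maps to the
line `−R2·(t_j − t_1)` and amplitude drops out. The cluster count is chosen
by X-means: recursive seeded 2-means splits accepted when the local
Bayesian information criterion improves, with deterministic child-seed
derivation, nearest-centroid ties broken to the lowest index, and empty
clusters re-seeded at the farthest point. `k_max` defaults to 50.

One deliberate departure from the textbook X-means: the *split decision*
uses a full-covariance Gaussian BIC on the parent's points rather than the
spherical one. The decay features share the first-echo noise term, so
their within-cluster covariance is strongly correlated; a spherical
criterion splits homogeneous clusters along those correlated-noise
directions, while the full-covariance likelihood is affine invariant and
splits only on genuine multimodality. The spherical hard-assignment BIC
(pooled variance `σ² = Σ‖x−μ‖²/(d(N−K))`, `p = (K−1) + dK + 1` parameters,
variance floor 1e−12) remains available as `bic_score` and governs the
small-cluster fallback. Each split takes the best of three seeded 2-means
restarts; clusters with fewer than `d+2` members per child are not split.

A consequence worth knowing: a small region whose decay differs only
subtly (the phantom's stroke lesion at 32³, ~3% of brain voxels, ΔR2 of
2 s⁻¹) may merge into a neighboring cluster at SNR 100. The whole-brain
recovery metrics are insensitive to this (the median sits in the large
white/gray clusters), but region-level OEF contrasts at realistic noise
carry the cluster-fit uncertainty, measured at σ(OEF) ≈ 0.03 for a
~1600-voxel cluster at SNR 100.

## The phantom

An ellipsoidal brain on a 64×64×32 grid of 2 mm voxels (a 32³ variant for
fast runs), mirror-symmetric about the midsagittal index plane except for
a single-hemisphere ellipsoidal lesion; inside it sit a ventricular CSF
region (the susceptibility zero reference), a posterior midline
straight-sinus tube, and a white/gray split that gives clustering real
structure. Default tissue parameters:

| class  | OEF  | ν    | R2 (1/s) | S0   | χ_nb (ppb) | CBF |
|--------|------|------|----------|------|------------|-----|
| WM     | 0.30 | 0.02 | 17       | 900  | −30        | 25  |
| GM     | 0.30 | 0.04 | 12       | 1000 | +10        | 60  |
| CSF    | 0.00 | 0    | 2        | 1200 | 0          | 5   |
| sinus  | 0.40 | 1.0  | 30       | 500  | 0          | —   |
| lesion | phase-dependent | 0.03 | 14 | 950 | +20    | profile |

The sinus OEF of 0.40 makes the vessel-derived tissue target
`0.75 × 0.40 = 0.30` equal to the contralateral tissue OEF. Lesion OEF
follows the stroke phase (acute 0.26, early/late subacute 0.22, chronic
0.216 — the cohort group means used as generator settings, against a
contralateral 0.30). The default lesion volume (13.1 ml) matches the scale
of the reported reversal case, and the reversal geometry uses an FI/IDL
volume ratio of 8.3/13.2.

χ maps are generated through `F_QSM` (vein fraction inside the sinus) and
re-zeroed to the ventricular mean; with the default CSF parameters the
reference is exactly zero, keeping the χ and mGRE outputs mutually
consistent (the fit model and the generator share one χ_nb). mGRE noise is
Rician — the magnitude of a complex Gaussian perturbation with
`σ = mean brain S(TE₁)/SNR` — which is the correct magnitude-MRI model and
matters at late echoes. Default SNR 100; echo protocol TE₁ = 4.5 ms,
ΔTE = 4.9 ms, 8 echoes. CBF maps are class-constant plus smooth seeded
jitter (SD 1 ml/100 g/min), with the lesion painted at its designed rCBF
times the mirrored contralateral mean.

Longitudinal cases follow three templates — DR (final infarct strictly
inside the initial diffusion lesion; reversal-region relative OEF rising
0.73 → 0.90 between scans; lesion rCBF 1.45 → 0.99), NDR-equal (lesion
rOEF falling 0.82 → 0.64; rCBF 0.95 → 0.99) and NDR-enlarged (adds a
mismatch region at rOEF ≈ 1.0 falling to 0.85) — and the eleven-case
roster assigns five DR, two enlarged and four equal cases. The cohort
roster generator emits 137 records whose screening attributes reduce to
115 after the exclusion rules (8 brainstem/cerebellum, 2 lesions under
250 mm³, 4 hemorrhagic transformations, 8 pre-MRI reperfusion therapies)
with onset-to-scan times placing 14/54/22/25 records in the
acute/early-subacute/late-subacute/chronic bins. Phase-level OEF and rOEF
columns use moment-matched sampling — standardized draws rescaled so each
group's sample mean and SD equal the designed values exactly — so summary
tables reproduce the designed group statistics while records keep
realistic spread.

What the phantom does **not** emulate: anatomical geometry, within-class
parameter heterogeneity (jitter defaults to 0; piecewise-constant truth is
the best case for CAT), field-map-derived macroscopic dephasing, partial
volume at lesion borders, registration error between time points, and
χ reconstruction from phase. Passing recovery tests therefore demonstrate
correctness of the estimator on model-consistent data, not performance on
patient data.

## ROI analysis and statistics

RR = IDL \ FI and mismatch = FI \ IDL; relative metrics divide the ROI
mean by the mean over the index-reflected contralateral mask, with the
brain mask eroded by one voxel to exclude edge voxels (count reported).
Case classification compares volumes with a 1% tolerance (measured volumes
are never bit-equal). Phase bins are (0,1], (1,7], (7,14], (14,∞) days;
the gap the day-based definition leaves between 7 and 8 days is closed at
7. Exclusion screening tallies each record once, under the first matching
reason in the reporting order.

The statistical battery wraps scipy.stats: two-tailed paired t, one-way
ANOVA with Bonferroni-corrected pairwise t tests (raw p × number of
comparisons, capped at 1), partial Pearson correlation by the residual
method (p from the t transform, df = n−3), a Kolmogorov–Smirnov normality
check against a normal with estimated parameters (approximate in the
Lilliefors sense), Levene's test in the median-centered (Brown–Forsythe)
variant, and Kruskal–Wallis/chi-square for demographics. OEF is formatted
as percent with two decimals only at reporting time; p < 0.05 is a
reporting flag, never a filter.

## Problem sizes and determinism

Parameter-recovery runs use the 32³ phantom (~11k brain voxels); the
longitudinal end-to-end demonstrations use the default 64×64×32 grid
(~45k voxels) with noiseless signals, so the recovered trajectories
isolate method bias from realization noise — noise robustness is
characterized separately by the SNR-100 recovery metric. Every stochastic
step (noise, jitter, k-means seeding, split recursion, multi-start) is
driven by explicit seeds recorded in the output provenance; rerunning a
pipeline with the same config and seed reproduces CSV outputs byte for
byte.

## Known limitations

- OEF identifiability per voxel is weak at clinical SNR; accuracy rests on
  the CAT cluster structure matching true tissue homogeneity. Violations
  (pathology smaller than the cluster detection limit) bias regional OEF.
- The SDR kernel assumes static dephasing around randomly oriented
  vessels; diffusion-regime corrections are not modeled.
- `χ_ba` and `[H]a` defaults are literature-informed, not fixed by the
  constant set above; CMRO2 values scale directly with `[H]a`.
- The CSF zero reference must hold for the straight-sinus inversion to be
  on an absolute scale; a shifted reference propagates into OEF_wb.
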