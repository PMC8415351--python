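"""Digital phantom: every input the pipeline consumes, generated at desk scale.

The phantom is an ellipsoidal "brain" that is mirror-symmetric about the
midsagittal index plane except for a single-hemisphere ischemic lesion.
It carries a ventricular CSF region (the susceptibility zero reference),
a straight-sinus tube on the posterior midline (the whole-brain OEF
anchor), a white/gray tissue split that gives the decay clustering real
structure, and lesion OEF/CBF values following the stroke-phase and
longitudinal (diffusion-reversal vs non-reversal) profiles the analysis
is designed to detect.  Susceptibility and multi-echo magnitude outputs
are mutually consistent: both derive from the same ground-truth parameter
maps through the package's forward models.

Magnitude noise is Rician (magnitude of a complex Gaussian perturbation),
the physically correct model for magnitude MRI; it matters at late echoes
where the signal approaches the noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .constants import DEFAULT_CONSTANTS, PhysioConstants, y_from_oef
from .forward import (EchoSeries, MacroFieldModel, default_echo_times, fs_sdr_fast,
                      g_macro)

__all__ = [
    "TissueClass",
    "PhantomConfig",
    "GroundTruth",
    "LongitudinalCase",
    "DEFAULT_TISSUE_TABLE",
    "PHASE_LESION_OEF",
    "build_geometry",
    "assign_params",
    "simulate_chi",
    "simulate_mgre",
    "simulate_cbf",
    "make_phantom",
    "case_masks",
    "make_longitudinal_case",
    "make_cohort_roster",
]

LABELS = {"background": 0, "wm": 1, "gm": 2, "csf": 3, "sinus": 4, "lesion": 5}

#: Lesion OEF by stroke phase (generator settings; contralateral tissue 0.30).
PHASE_LESION_OEF = {
    "acute": 0.26,
    "early_subacute": 0.22,
    "late_subacute": 0.22,
    "chronic": 0.216,
}


@dataclass(frozen=True)
class TissueClass:
    """Ground-truth parameters of one tissue class."""

    oef: float
    nu: float
    r2: float       # 1/s
    s0: float       # a.u.
    chi_nb: float   # ppb
    cbf: float      # ml/100 g/min


DEFAULT_TISSUE_TABLE: dict[str, TissueClass] = {
    "wm": TissueClass(oef=0.30, nu=0.02, r2=17.0, s0=900.0, chi_nb=-30.0, cbf=25.0),
    "gm": TissueClass(oef=0.30, nu=0.04, r2=12.0, s0=1000.0, chi_nb=10.0, cbf=60.0),
    "csf": TissueClass(oef=0.0, nu=0.0, r2=2.0, s0=1200.0, chi_nb=0.0, cbf=5.0),
    # straight sinus: whole vein (nu = 1), OEF_ss = 0.40 so the tissue target
    # Hct_vt * OEF_ss = 0.30 matches the contralateral tissue OEF
    "sinus": TissueClass(oef=0.40, nu=1.0, r2=30.0, s0=500.0, chi_nb=0.0, cbf=0.0),
    "lesion": TissueClass(oef=0.26, nu=0.03, r2=14.0, s0=950.0, chi_nb=20.0, cbf=60.0),
}


@dataclass
class PhantomConfig:
    """Geometry, tissue table, lesion placement and noise of one phantom."""

    shape: tuple[int, int, int] = (64, 64, 32)
    voxel_size_mm: float = 2.0
    tissue_table: dict[str, TissueClass] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_TABLE))
    lesion_center_frac: tuple[float, float, float] = (0.30, 0.55, 0.50)
    # semi-axes; default volume 13.1 ml, the scale of the printed reversal case
    lesion_axes_mm: tuple[float, float, float] = (13.0, 16.0, 15.0)
    phase: str = "acute"
    snr: float | None = 100.0           # None = noiseless
    jitter_rel: float = 0.0             # smooth within-class parameter jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phase not in PHASE_LESION_OEF:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.snr is not None and self.snr <= 0:
            raise ValueError("snr must be positive (or None for noiseless)")

    def small(self) -> "PhantomConfig":
        """32^3 variant for fast runs."""
        return replace(self, shape=(32, 32, 32),
                       lesion_axes_mm=(8.0, 9.0, 8.0))


@dataclass
class GroundTruth:
    """Label volume, masks and true parameter maps of one phantom scan."""

    labels: np.ndarray
    masks: dict[str, np.ndarray]
    midline: float                     # midsagittal plane index (axis 0)
    voxel_size_mm: float
    oef: np.ndarray
    Y: np.ndarray
    nu: np.ndarray
    R2: np.ndarray
    S0: np.ndarray
    chi_nb: np.ndarray
    cfg: PhantomConfig


def _ellipsoid(shape: tuple[int, int, int], center: tuple[float, float, float],
               semiaxes: tuple[float, float, float]) -> np.ndarray:
    idx = np.indices(shape, dtype=float)
    q = sum(((idx[a] - center[a]) / semiaxes[a]) ** 2 for a in range(3))
    return q <= 1.0


def build_geometry(cfg: PhantomConfig) -> tuple[np.ndarray, dict[str, np.ndarray], float]:
    """Label volume plus brain/ventricle/sinus/lesion masks and midline index.

    The brain is mirror-symmetric about the midsagittal plane (axis 0
    index ``(nx - 1)/2``) except for the lesion, which must lie strictly
    within one hemisphere.
    """
    nx, ny, nz = cfg.shape
    center = ((nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0)
    midline = center[0]

    brain = _ellipsoid(cfg.shape, center, (0.44 * nx, 0.44 * ny, 0.42 * nz))
    inner = _ellipsoid(cfg.shape, center, (0.31 * nx, 0.31 * ny, 0.30 * nz))
    ventricle = _ellipsoid(cfg.shape, center, (0.10 * nx, 0.14 * ny, 0.10 * nz))

    idx = np.indices(cfg.shape, dtype=float)
    sinus = (
        ((idx[0] - center[0]) ** 2 + (idx[2] - center[2]) ** 2 <= 1.3 ** 2)
        & (idx[1] >= 0.12 * ny) & (idx[1] <= 0.30 * ny) & brain
    )

    vx = cfg.voxel_size_mm
    lesion_center = tuple(f * (n - 1) for f, n in zip(cfg.lesion_center_frac, cfg.shape))
    lesion_axes = tuple(a / vx for a in cfg.lesion_axes_mm)
    if all(a > 0 for a in lesion_axes):
        lesion = _ellipsoid(cfg.shape, lesion_center, lesion_axes) & brain
        lesion &= ~ventricle & ~sinus
    else:
        lesion = np.zeros(cfg.shape, dtype=bool)
    if lesion.any():
        xs = np.flatnonzero(lesion.any(axis=(1, 2)))
        crosses = (xs.max() >= midline) if lesion_center[0] < midline else (xs.min() <= midline)
        if crosses:
            raise ValueError("lesion crosses the midsagittal plane")

    labels = np.zeros(cfg.shape, dtype=np.int16)
    labels[brain] = LABELS["gm"]
    labels[inner & brain] = LABELS["wm"]
    labels[ventricle & brain] = LABELS["csf"]
    labels[sinus] = LABELS["sinus"]
    labels[lesion] = LABELS["lesion"]

    masks = {
        "brain": brain,
        "ventricle": ventricle & brain,
        "sinus": sinus,
        "lesion": lesion,
    }
    return labels, masks, midline


def assign_params(labels: np.ndarray, cfg: PhantomConfig,
                  masks: dict[str, np.ndarray] | None = None,
                  midline: float | None = None,
                  consts: PhysioConstants = DEFAULT_CONSTANTS) -> GroundTruth:
    """Ground-truth parameter maps from the tissue table.

    Class-wise constant values, optionally perturbed by a smooth seeded
    within-class jitter (``cfg.jitter_rel`` relative amplitude).  The
    lesion OEF follows the phase profile; all other parameter maps are
    mirror-symmetric outside the lesion.
    """
    if masks is None or midline is None:
        _, masks, midline = build_geometry(cfg)
    table = dict(cfg.tissue_table)
    table["lesion"] = replace(table["lesion"], oef=PHASE_LESION_OEF[cfg.phase])

    shape = labels.shape
    maps = {k: np.zeros(shape) for k in ("oef", "nu", "R2", "S0", "chi_nb")}
    for name, tc in table.items():
        sel = labels == LABELS[name]
        maps["oef"][sel] = tc.oef
        maps["nu"][sel] = tc.nu
        maps["R2"][sel] = tc.r2
        maps["S0"][sel] = tc.s0
        maps["chi_nb"][sel] = tc.chi_nb

    if cfg.jitter_rel > 0:
        rng = np.random.default_rng(cfg.seed + 101)
        brain = masks["brain"]
        for key in ("oef", "nu", "R2", "S0"):
            noise = gaussian_filter(rng.standard_normal(shape), sigma=1.5)
            noise /= max(noise.std(), 1e-12)
            maps[key] = maps[key] * (1.0 + cfg.jitter_rel * noise * brain)
            np.clip(maps[key], 0.0, None, out=maps[key])

    Y = np.zeros(shape)
    brain = masks["brain"]
    Y[brain] = y_from_oef(np.clip(maps["oef"][brain], 0.0, 1.0), consts)
    return GroundTruth(labels=labels, masks=masks, midline=float(midline),
                       voxel_size_mm=cfg.voxel_size_mm, oef=maps["oef"], Y=Y,
                       nu=maps["nu"], R2=maps["R2"], S0=maps["S0"],
                       chi_nb=maps["chi_nb"], cfg=cfg)


def simulate_chi(truth: GroundTruth,
                 consts: PhysioConstants = DEFAULT_CONSTANTS) -> np.ndarray:
    """Susceptibility map (ppb) from the truth maps via the QSM forward model.

    Tissue voxels use the tissue hemoglobin fraction; the straight sinus
    is modeled as whole vein (nu = 1, chi_nb = 0) with the large-vessel
    fraction.  The map is re-zeroed to the ventricular-CSF mean, matching
    a CSF-zero-referenced susceptibility reconstruction.
    """
    from .forward import f_qsm

    brain = truth.masks["brain"]
    sinus = truth.masks["sinus"]
    chi = np.zeros(truth.labels.shape)
    tissue = brain & ~sinus
    chi[tissue] = f_qsm(truth.Y[tissue], truth.nu[tissue], truth.chi_nb[tissue],
                        consts=consts)
    chi[sinus] = f_qsm(truth.Y[sinus], 1.0, 0.0, psi_hb=consts.psi_hb_vein,
                       consts=consts)
    vent = truth.masks["ventricle"]
    if vent.any():
        chi[brain] -= chi[vent].mean()
    return chi


def _forward_signals(truth: GroundTruth, echo_times: np.ndarray,
                     gmodel: MacroFieldModel,
                     consts: PhysioConstants) -> np.ndarray:
    """Noiseless magnitude volume (x, y, z, echo); zero outside the brain."""
    brain = truth.masks["brain"]
    sinus = truth.masks["sinus"]
    Y = truth.Y[brain]
    nu = truth.nu[brain]
    psi = np.where(sinus[brain], consts.psi_hb_vein, consts.psi_hb_tissue)
    chi_nb = np.where(sinus[brain], 0.0, truth.chi_nb[brain])
    bracket = np.clip(psi * consts.dchi_hb * (1.0 - Y) + consts.chi_ba - chi_nb, 0.0, None)
    dw = consts.gamma * consts.B0 * bracket * 1e-9 / 3.0
    g = np.asarray(g_macro(gmodel, echo_times))
    fs = fs_sdr_fast(dw[:, None] * echo_times[None, :])
    sig = (truth.S0[brain][:, None]
           * np.exp(-truth.R2[brain][:, None] * echo_times[None, :] - nu[:, None] * fs)
           * g[None, :])
    out = np.zeros(truth.labels.shape + (len(echo_times),))
    out[brain] = sig
    return out


def simulate_mgre(truth: GroundTruth, echo_times: np.ndarray | None = None,
                  gmodel: MacroFieldModel | None = None,
                  snr: float | None = 100.0, seed: int = 0,
                  consts: PhysioConstants = DEFAULT_CONSTANTS) -> EchoSeries:
    """Multi-echo GRE magnitude volume with Rician noise at the given SNR.

    sigma = (mean brain signal at TE1) / SNR; the noisy magnitude is
    |S + n1 + i n2| with n1, n2 ~ N(0, sigma^2).  ``snr=None`` disables
    noise.  Deterministic under ``seed``.
    """
    if echo_times is None:
        echo_times = default_echo_times()
    if gmodel is None:
        gmodel = MacroFieldModel()
    clean = _forward_signals(truth, np.asarray(echo_times, dtype=float), gmodel, consts)
    if snr is None:
        return EchoSeries(echo_times=echo_times, magnitudes=clean)
    brain = truth.masks["brain"]
    sigma = float(clean[brain][:, 0].mean()) / snr
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, clean.shape)
    n2 = rng.normal(0.0, sigma, clean.shape)
    noisy = np.hypot(clean + n1, n2)
    noisy[~brain] = 0.0
    return EchoSeries(echo_times=echo_times, magnitudes=noisy)


def simulate_cbf(truth: GroundTruth, rcbf_lesion: float = 1.45,
                 jitter_sd: float = 1.0, seed: int = 0) -> np.ndarray:
    """CBF map (ml/100 g/min): class-constant plus smooth seeded jitter.

    The lesion is painted at ``rcbf_lesion`` times the mean CBF of its
    mirrored contralateral region, so the analyzer's relative-CBF metric
    recovers the profile by construction.
    """
    from .roi import mirror_mask

    table = truth.cfg.tissue_table
    cbf = np.zeros(truth.labels.shape)
    for name, tc in table.items():
        cbf[truth.labels == LABELS[name]] = tc.cbf
    lesion = truth.masks["lesion"]
    if lesion.any():
        mirror = mirror_mask(lesion, truth.midline)
        cbf[lesion] = rcbf_lesion * cbf[mirror & truth.masks["brain"]].mean()
    if jitter_sd > 0:
        rng = np.random.default_rng(seed + 202)
        noise = gaussian_filter(rng.standard_normal(cbf.shape), sigma=1.5)
        noise /= max(noise.std(), 1e-12)
        cbf = cbf + jitter_sd * noise * truth.masks["brain"]
        np.clip(cbf, 0.0, None, out=cbf)
    return cbf


def make_phantom(cfg: PhantomConfig,
                 consts: PhysioConstants = DEFAULT_CONSTANTS
                 ) -> tuple[GroundTruth, np.ndarray, EchoSeries]:
    """Convenience: geometry + truth maps + chi map + mGRE volume."""
    labels, masks, midline = build_geometry(cfg)
    truth = assign_params(labels, cfg, masks, midline, consts)
    chi = simulate_chi(truth, consts)
    echoes = simulate_mgre(truth, snr=cfg.snr, seed=cfg.seed, consts=consts)
    return truth, chi, echoes


# ----------------------------------------------------------------------
# longitudinal cases
# ----------------------------------------------------------------------

#: (rOEF scan1, rOEF scan2) per region and (rCBF scan1, rCBF scan2) for the
#: lesion, following the diffusion-reversal / non-reversal trajectories.
_CASE_PROFILES: dict[str, dict[str, Any]] = {
    "DR": {
        "regions": {"fi_core": (0.61, 0.79), "rr": (0.73, 0.90)},
        "rcbf": (1.45, 0.99),
        "fi_scale": 0.86,        # FI/IDL volume ratio ~ 8.3/13.2 ml
    },
    "NDR-enlarged": {
        "regions": {"idl": (0.82, 0.64), "mismatch": (1.01, 0.85)},
        "rcbf": (0.95, 0.99),
        "fi_scale": 1.30,
    },
    "NDR-equal": {
        "regions": {"idl": (0.82, 0.64)},
        "rcbf": (0.95, 0.99),
        "fi_scale": 1.0,
    },
}

BASE_TISSUE_OEF = 0.30   # contralateral tissue OEF the relative profiles refer to


@dataclass
class LongitudinalCase:
    """Two-scan phantom with IDL/FI masks and per-scan truth/chi/CBF."""

    case_type: str
    times_days: tuple[float, float]
    idl: np.ndarray
    fi: np.ndarray
    truths: tuple[GroundTruth, GroundTruth]
    chis: tuple[np.ndarray, np.ndarray]
    cbfs: tuple[np.ndarray, np.ndarray]
    midline: float
    masks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        idl, fi = self.idl.astype(bool), self.fi.astype(bool)
        if self.case_type == "DR":
            if not (fi & idl).sum() == fi.sum() < idl.sum():
                raise ValueError("DR case requires FI strictly inside IDL")
        elif self.case_type == "NDR-enlarged":
            if not (fi & idl).sum() == idl.sum() < fi.sum():
                raise ValueError("NDR-enlarged case requires IDL strictly inside FI")
        elif self.case_type == "NDR-equal":
            if not np.array_equal(idl, fi):
                raise ValueError("NDR-equal case requires IDL == FI")
        else:
            raise ValueError(f"unknown case_type {self.case_type!r}")


def case_masks(case_type: str, cfg: PhantomConfig | None = None
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, np.ndarray], float]:
    """(labels, IDL, FI, masks, midline) for one longitudinal case geometry.

    Cheap (no signal simulation); the IDL is the configured lesion and the
    FI is a concentric ellipsoid scaled by the case profile.
    """
    if case_type not in _CASE_PROFILES:
        raise ValueError(f"unknown case_type {case_type!r}; "
                         f"choose from {sorted(_CASE_PROFILES)}")
    if cfg is None:
        cfg = PhantomConfig()
    prof = _CASE_PROFILES[case_type]
    labels, masks, midline = build_geometry(cfg)
    idl = masks["lesion"]
    if not idl.any():
        raise ValueError("configured lesion is empty")
    center = tuple(f * (n - 1) for f, n in zip(cfg.lesion_center_frac, cfg.shape))
    fi_axes = tuple(prof["fi_scale"] * a / cfg.voxel_size_mm for a in cfg.lesion_axes_mm)
    if case_type == "NDR-equal":
        fi = idl.copy()
    else:
        fi = _ellipsoid(cfg.shape, center, fi_axes) & masks["brain"]
        fi &= ~masks["ventricle"] & ~masks["sinus"]
        if case_type == "DR":
            fi &= idl
            shell = idl & ~fi
            if not (fi.any() and shell.any()):
                raise ValueError("DR geometry degenerate: adjust lesion axes")
        else:
            fi |= idl
            if not (fi & ~idl).any():
                raise ValueError("NDR-enlarged geometry degenerate")
    return labels, idl, fi, masks, midline


def make_longitudinal_case(case_type: str, times_days: tuple[float, float] = (2.5, 10.0),
                           cfg: PhantomConfig | None = None, seed: int = 0,
                           consts: PhysioConstants = DEFAULT_CONSTANTS) -> LongitudinalCase:
    """Two-scan phantom following a DR / NDR lesion trajectory.

    DR: the final infarct is a strict subset of the initial diffusion
    lesion and the reversal-region rOEF rises between scans.  NDR: the
    lesion rOEF falls; the enlarged variant adds a mismatch region
    (FI beyond IDL).  CBF follows the corresponding relative profiles.
    """
    if times_days[0] >= times_days[1]:
        raise ValueError("scan times must be strictly increasing")
    if cfg is None:
        cfg = PhantomConfig(seed=seed)
    labels, idl, fi, masks, midline = case_masks(case_type, cfg)
    prof = _CASE_PROFILES[case_type]

    regions: dict[str, np.ndarray] = {}
    if case_type == "DR":
        regions["fi_core"] = fi
        regions["rr"] = idl & ~fi
    elif case_type == "NDR-enlarged":
        regions["idl"] = idl
        regions["mismatch"] = fi & ~idl
    else:
        regions["idl"] = idl

    lesion_support = idl | fi
    truths, chis, cbfs = [], [], []
    for scan in (0, 1):
        scan_labels = labels.copy()
        scan_labels[masks["lesion"]] = LABELS["gm"]   # repaint; regions set below
        scan_labels[lesion_support] = LABELS["lesion"]
        scan_cfg = replace(cfg, seed=cfg.seed + scan)
        truth = assign_params(scan_labels, scan_cfg,
                              masks={**masks, "lesion": lesion_support},
                              midline=midline, consts=consts)
        for name, (r1, r2) in prof["regions"].items():
            roef = (r1, r2)[scan]
            truth.oef[regions[name]] = roef * BASE_TISSUE_OEF
        brain = masks["brain"]
        truth.Y[brain] = y_from_oef(np.clip(truth.oef[brain], 0.0, 1.0), consts)
        truths.append(truth)
        chis.append(simulate_chi(truth, consts))
        cbfs.append(simulate_cbf(truth, rcbf_lesion=prof["rcbf"][scan],
                                 seed=cfg.seed + 10 * scan))

    return LongitudinalCase(case_type=case_type, times_days=tuple(times_days),
                            idl=idl, fi=fi, truths=tuple(truths),
                            chis=tuple(chis), cbfs=tuple(cbfs),
                            midline=midline,
                            masks={**masks, "lesion": lesion_support})


#: The eleven longitudinal cases by type (five reversals of eleven).
LONGITUDINAL_CASE_TYPES: dict[int, str] = {
    1: "NDR-equal", 2: "NDR-equal", 3: "DR", 4: "DR", 5: "NDR-equal",
    6: "NDR-enlarged", 7: "NDR-equal", 8: "DR", 9: "DR", 10: "DR",
    11: "NDR-enlarged",
}


# ----------------------------------------------------------------------
# cohort roster
# ----------------------------------------------------------------------

_SCREENING = [("brainstem_cerebellum", 8), ("small_lesion", 2),
              ("hemorrhagic_transformation", 4), ("pre_mri_reperfusion_therapy", 8)]
_PHASE_PLAN = [("acute", 14, (0.3, 0.95), 6), ("early_subacute", 54, (1.5, 6.5), 5),
               ("late_subacute", 22, (8.5, 13.5), 4), ("chronic", 25, (16.0, 35.0), 2)]
#: Designed (mean, SD) of lesion OEF, mirror OEF and rOEF by phase.
_PHASE_OEF_STATS = {
    "acute": ((0.2604, 0.0724), (0.3095, 0.0765), (0.85, 0.14)),
    "early_subacute": ((0.2192, 0.0386), (0.3027, 0.0425), (0.73, 0.13)),
    "late_subacute": ((0.2187, 0.0407), (0.3048, 0.0623), (0.73, 0.12)),
    "chronic": ((0.2158, 0.0504), (0.2906, 0.0572), (0.75, 0.13)),
}


def _moment_match(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    """Rescale draws so the sample mean and SD (ddof=1) are exact."""
    z = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * z


def make_cohort_roster(seed: int = 0) -> pd.DataFrame:
    """Screening roster of 137 stroke patient records.

    22 records carry exactly one exclusion attribute (8 brainstem or
    cerebellum infarcts, 2 lesions under 250 mm^3, 4 hemorrhagic
    transformations, 8 pre-MRI reperfusion therapies); the remaining 115
    are clean and fall into the four onset-to-scan phase bins with
    14/54/22/25 members.  Phase-level lesion OEF / mirror OEF / rOEF
    columns are moment-matched to the designed group statistics.
    Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict[str, Any]] = []

    for reason, count in _SCREENING:
        for _ in range(count):
            rows.append({
                "onset_to_scan_days": float(rng.uniform(0.5, 20.0)),
                "nihss": int(rng.integers(1, 15)),
                "lesion_volume_mm3": (float(rng.uniform(60.0, 240.0))
                                      if reason == "small_lesion"
                                      else float(rng.lognormal(9.0, 0.8)) + 300.0),
                "brainstem_cerebellum": reason == "brainstem_cerebellum",
                "hemorrhagic_transformation": reason == "hemorrhagic_transformation",
                "pre_mri_reperfusion_therapy": reason == "pre_mri_reperfusion_therapy",
                "other_disease": False,
                "motion_artifact": False,
                "phase_designed": "",
                "lesion_oef": np.nan, "mirror_oef": np.nan, "roef": np.nan,
            })

    for phase, n, (t_lo, t_hi), nihss_med in _PHASE_PLAN:
        (m_l, s_l), (m_m, s_m), (m_r, s_r) = _PHASE_OEF_STATS[phase]
        lesion_oef = _moment_match(rng.standard_normal(n), m_l, s_l)
        mirror_oef = _moment_match(rng.standard_normal(n), m_m, s_m)
        roef = _moment_match(rng.standard_normal(n), m_r, s_r)
        for i in range(n):
            rows.append({
                "onset_to_scan_days": float(rng.uniform(t_lo, t_hi)),
                "nihss": int(max(0, rng.poisson(nihss_med))),
                "lesion_volume_mm3": float(rng.lognormal(8.8, 1.0)) + 300.0,
                "brainstem_cerebellum": False,
                "hemorrhagic_transformation": False,
                "pre_mri_reperfusion_therapy": False,
                "other_disease": False,
                "motion_artifact": False,
                "phase_designed": phase,
                "lesion_oef": float(lesion_oef[i]),
                "mirror_oef": float(mirror_oef[i]),
                "roef": float(roef[i]),
            })

    order = rng.permutation(len(rows))
    df = pd.DataFrame([rows[i] for i in order])
    df.insert(0, "id", np.arange(1, len(df) + 1))
    return df
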