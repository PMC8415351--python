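"""The QQ inverse problem: joint QSM + qBOLD parameter estimation.

Per voxel (or per decay cluster) the five parameters (Y, nu, R2, S0,
chi_nb) minimize

    w * ||F_QSM(Y, nu, chi_nb) - chi||^2
      + ||S(t) - S_qBOLD(S0, Y, nu, R2, chi_nb, t)||^2
      + lambda * (mean OEF(Y) - OEF_wb)^2

subject to box bounds, where OEF_wb = Hct_vt * OEF_ss is the whole-brain
target derived from the straight-sinus susceptibility.  Estimation is
two-stage (CAT): cluster-mean signals are fit first with multi-start
bounded least squares, then every voxel is refined from its cluster's
solution.  The global penalty is handled by constraint splitting: each
outer iteration shifts every voxel's private OEF target by the current
whole-brain offset (mean OEF - OEF_wb), keeping the per-voxel problems
independent.

Term normalization (the weights w and lambda have no canonical values in
the literature): signal residuals are divided by a reference
signal s_ref (mean brain signal at the first echo) and the susceptibility
residual by chi_ref (std of chi over the brain), so w (default 1) and
lambda (default 1e3) are dimensionless.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
from scipy.optimize import least_squares

from .constants import (DEFAULT_CONSTANTS, PhysioConstants, oef_from_y,
                        oef_wb_target, y_from_oef)
from .forward import EchoSeries, MacroFieldModel, VoxelParams, fs_sdr_fast, g_macro

__all__ = [
    "FitConfig",
    "TissueParamMaps",
    "qq_objective",
    "estimate_whole_brain_oef",
    "fit_cluster",
    "fit_voxelwise",
    "compute_oef_map",
]

logger = logging.getLogger(__name__)


@dataclass
class FitConfig:
    """Weights, bounds and iteration controls of the QQ fit."""

    w: float = 1.0                  # weight on the (normalized) QSM term
    lam: float = 1.0e3              # weight on the whole-brain OEF penalty
    y_bounds: tuple[float, float] = (0.0098, 0.98)   # [0.01*Ya, Ya]
    nu_bounds: tuple[float, float] = (0.001, 0.1)
    r2_bounds: tuple[float, float] = (1.0, 100.0)
    s0_bounds: tuple[float, float] = (1e-6, np.inf)
    chi_nb_bounds: tuple[float, float] = (-200.0, 200.0)
    max_outer: int = 5
    tol_oef: float = 1.0e-3         # convergence: max abs OEF change
    n_starts: int = 5               # multi-start count at the cluster stage
    voxel_refine: str = "s0_chi_nb"  # "s0_chi_nb" (CAT: freeze cluster Y, nu, R2) or "all"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.w < 0 or self.lam < 0:
            raise ValueError("w and lam must be nonnegative")
        if self.voxel_refine not in ("s0_chi_nb", "all"):
            raise ValueError("voxel_refine must be 's0_chi_nb' or 'all'")
        for name in ("y_bounds", "nu_bounds", "r2_bounds", "s0_bounds", "chi_nb_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be well-ordered, got ({lo}, {hi})")

    @property
    def lower(self) -> np.ndarray:
        return np.array([self.y_bounds[0], self.nu_bounds[0], self.r2_bounds[0],
                         self.s0_bounds[0], self.chi_nb_bounds[0]])

    @property
    def upper(self) -> np.ndarray:
        return np.array([self.y_bounds[1], self.nu_bounds[1], self.r2_bounds[1],
                         self.s0_bounds[1], self.chi_nb_bounds[1]])

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["s0_bounds"] = [self.s0_bounds[0], None if np.isinf(self.s0_bounds[1]) else self.s0_bounds[1]]
        return d


@dataclass
class TissueParamMaps:
    """Fitted voxelwise parameter maps over a brain mask.

    Parameter volumes are float arrays shaped like the mask with NaN
    outside it.  ``quality`` flags voxels whose venous volume pinned at
    the lower bound (OEF there is not identifiable from the data).
    """

    Y: np.ndarray
    nu: np.ndarray
    R2: np.ndarray
    S0: np.ndarray
    chi_nb: np.ndarray
    mask: np.ndarray
    quality: np.ndarray | None = None
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def oef(self) -> np.ndarray:
        return compute_oef_map(self)


def compute_oef_map(maps: TissueParamMaps,
                    consts: PhysioConstants = DEFAULT_CONSTANTS) -> np.ndarray:
    """Voxelwise OEF = 1 - Y/Ya (NaN outside the mask)."""
    out = np.full(maps.Y.shape, np.nan)
    m = maps.mask.astype(bool)
    out[m] = oef_from_y(maps.Y[m], consts)
    return out


# ----------------------------------------------------------------------
# objective
# ----------------------------------------------------------------------

def _model_pieces(x: np.ndarray, te: np.ndarray, g: np.ndarray,
                  consts: PhysioConstants, psi_hb: float) -> tuple[float, np.ndarray]:
    """(chi_model, signal_model) for parameter vector x = (Y, nu, R2, S0, chi_nb)."""
    Y, nu, R2, S0, chi_nb = x
    blood = (
        consts.chi_ba / consts.alpha
        + psi_hb * consts.dchi_hb * (-Y + 1.0 - (1.0 - consts.alpha) * consts.Ya) / consts.alpha
    )
    chi_model = blood * nu + (1.0 - nu / consts.alpha) * chi_nb
    bracket = psi_hb * consts.dchi_hb * (1.0 - Y) + consts.chi_ba - chi_nb
    dw = consts.gamma * consts.B0 * max(bracket, 0.0) * 1e-9 / 3.0
    sig = S0 * np.exp(-R2 * te - nu * fs_sdr_fast(dw * te)) * g
    return chi_model, sig


def qq_objective(params: VoxelParams, echo_times: np.ndarray, signal: np.ndarray,
                 chi: float, oef_target: float, cfg: FitConfig,
                 consts: PhysioConstants = DEFAULT_CONSTANTS,
                 gmodel: MacroFieldModel | None = None,
                 s_ref: float = 1.0, chi_ref: float = 1.0) -> float:
    """Scalar QQ cost for one voxel/cluster at the given parameters."""
    te = np.asarray(echo_times, dtype=float)
    g = g_macro(gmodel, te) if gmodel is not None else np.ones_like(te)
    x = np.array([params.Y, params.nu, params.R2, params.S0, params.chi_nb])
    chi_model, sig = _model_pieces(x, te, g, consts, consts.psi_hb_tissue)
    oef = 1.0 - params.Y / consts.Ya
    return float(
        cfg.w * ((chi_model - chi) / chi_ref) ** 2
        + np.sum(((sig - np.asarray(signal)) / s_ref) ** 2)
        + cfg.lam * (oef - oef_target) ** 2
    )


def estimate_whole_brain_oef(chi_map: np.ndarray, sinus_mask: np.ndarray,
                             consts: PhysioConstants = DEFAULT_CONSTANTS) -> float:
    """Whole-brain OEF target from the mean straight-sinus susceptibility."""
    sinus_mask = np.asarray(sinus_mask, dtype=bool)
    if not sinus_mask.any():
        raise ValueError("sinus mask is empty")
    chi_ss = float(np.nanmean(np.asarray(chi_map, dtype=float)[sinus_mask]))
    return oef_wb_target(chi_ss, consts)


# ----------------------------------------------------------------------
# solvers
# ----------------------------------------------------------------------

def _residual_fn(te, g, signal, chi, s_ref, chi_ref, sqrt_w, sqrt_lam,
                 oef_target, consts, psi_hb):
    inv_ya = 1.0 / consts.Ya

    def fun(x):
        chi_model, sig = _model_pieces(x, te, g, consts, psi_hb)
        r = np.empty(len(te) + 2)
        r[0] = sqrt_w * (chi_model - chi) / chi_ref
        r[1:-1] = (sig - signal) / s_ref
        r[-1] = sqrt_lam * ((1.0 - x[0] * inv_ya) - oef_target)
        return r

    return fun


def _solve_one(x0, fun, cfg: FitConfig, x_scale) -> tuple[np.ndarray, float, bool]:
    res = least_squares(fun, x0, bounds=(cfg.lower, cfg.upper), method="trf",
                        x_scale=x_scale, xtol=1e-10, ftol=1e-10, gtol=1e-10,
                        max_nfev=200)
    return res.x, float(res.cost * 2.0), bool(res.success)


def _init_r2_s0(te: np.ndarray, signal: np.ndarray) -> tuple[float, float]:
    """Log-linear decay estimate of (R2, S0) for initialization."""
    pos = signal > 0
    if pos.sum() < 2:
        return 15.0, float(max(signal.max(), 1.0))
    slope, intercept = np.polyfit(te[pos], np.log(signal[pos]), 1)
    return float(np.clip(-slope, 1.0, 100.0)), float(np.exp(intercept))


def _chi_nb_init(chi: float, Y: float, nu: float, consts: PhysioConstants,
                 cfg: FitConfig) -> float:
    blood = (
        consts.chi_ba / consts.alpha
        + consts.psi_hb_tissue * consts.dchi_hb
        * (-Y + 1.0 - (1.0 - consts.alpha) * consts.Ya) / consts.alpha
    )
    denom = 1.0 - nu / consts.alpha
    val = (chi - blood * nu) / denom if abs(denom) > 1e-6 else 0.0
    return float(np.clip(val, *cfg.chi_nb_bounds))


@dataclass
class ClusterFit:
    """Result of fitting one cluster-mean signal."""

    params: VoxelParams
    cost: float
    converged: bool
    nu_at_bound: bool


def fit_cluster(cluster_mean_signal: np.ndarray, cluster_mean_chi: float,
                echo_times: np.ndarray, cfg: FitConfig, oef_wb: float,
                consts: PhysioConstants = DEFAULT_CONSTANTS,
                gmodel: MacroFieldModel | None = None,
                s_ref: float | None = None, chi_ref: float = 1.0) -> ClusterFit:
    """Multi-start bounded least squares on one cluster-mean decay.

    The whole-brain penalty is not applied at this stage (it constrains
    the brain mean, handled in the voxel stage); ``oef_wb`` centers the
    initialization grid over Y.
    """
    signal = np.asarray(cluster_mean_signal, dtype=float)
    te = np.asarray(echo_times, dtype=float)
    if signal.shape != te.shape:
        raise ValueError("signal and echo_times shapes differ")
    g = g_macro(gmodel, te) if gmodel is not None else np.ones_like(te)
    if s_ref is None:
        s_ref = float(signal[0]) if signal[0] > 0 else 1.0

    fun = _residual_fn(te, g, signal, cluster_mean_chi, s_ref, chi_ref,
                       np.sqrt(cfg.w), 0.0, oef_wb, consts, consts.psi_hb_tissue)
    r2_0, s0_0 = _init_r2_s0(te, signal)
    y_wb = float(np.clip(y_from_oef(np.clip(oef_wb, 0.0, 1.0), consts),
                         *cfg.y_bounds))
    starts = [
        (y_wb, 0.03),
        (0.5 * consts.Ya, 0.02),
        (0.8 * consts.Ya, 0.02),
        (0.5 * consts.Ya, 0.06),
        (0.8 * consts.Ya, 0.06),
    ][: max(cfg.n_starts, 1)]
    x_scale = np.array([0.1, 0.01, 10.0, max(s0_0, 1.0), 50.0])

    best: tuple[np.ndarray, float, bool] | None = None
    for y0, nu0 in starts:
        x0 = np.array([
            np.clip(y0, *cfg.y_bounds),
            np.clip(nu0, *cfg.nu_bounds),
            r2_0,
            np.clip(s0_0, cfg.s0_bounds[0], 1e12),
            _chi_nb_init(cluster_mean_chi, y0, nu0, consts, cfg),
        ])
        try:
            x, cost, ok = _solve_one(x0, fun, cfg, x_scale)
        except Exception:      # pragma: no cover - solver pathologies
            continue
        if best is None or cost < best[1]:
            best = (x, cost, ok)
    if best is None:
        logger.warning("fit_cluster: all starts failed; returning initialization")
        x0 = np.array([y_wb, 0.03, r2_0, s0_0,
                       _chi_nb_init(cluster_mean_chi, y_wb, 0.03, consts, cfg)])
        best = (x0, float(np.sum(fun(x0) ** 2)), False)
    x, cost, ok = best

    # parsimony check: if a reduced model with the venous volume pinned at
    # its lower bound explains the data essentially as well, the blood
    # parameters are not identifiable and the reduced fit is preferred
    x0r = x.copy()
    x0r[1] = cfg.nu_bounds[0]
    cfg_r = dataclasses.replace(
        cfg, nu_bounds=(cfg.nu_bounds[0], cfg.nu_bounds[0] * (1 + 1e-9)))
    try:
        xr, cost_r, ok_r = _solve_one(x0r, fun, cfg_r, x_scale)
        if cost_r <= cost * (1.0 + 1e-3) + 1e-12:
            x, cost, ok = xr, cost_r, ok and ok_r
    except Exception:   # pragma: no cover
        pass

    nu_low = x[1] <= cfg.nu_bounds[0] * (1.0 + 1e-6)
    params = VoxelParams(Y=float(x[0]), nu=float(x[1]), R2=float(x[2]),
                         S0=float(x[3]), chi_nb=float(x[4]))
    return ClusterFit(params=params, cost=cost, converged=ok, nu_at_bound=nu_low)


def fit_voxelwise(echoes: EchoSeries, chi_map: np.ndarray, clusters,
                  brain_mask: np.ndarray, cfg: FitConfig, oef_wb: float,
                  consts: PhysioConstants = DEFAULT_CONSTANTS,
                  gmodel: MacroFieldModel | None = None) -> TissueParamMaps:
    """Two-stage CAT + voxelwise QQ estimation over a brain mask.

    ``clusters`` is a :class:`~qqoef.clustering.ClusterModel` whose
    ``voxel_index`` addresses voxels of ``brain_mask``.  Each voxel starts
    from its cluster's fitted parameters; the whole-brain OEF penalty is
    enforced by outer-loop constraint splitting.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    te = echoes.echo_times
    g = g_macro(gmodel, te) if gmodel is not None else np.ones_like(te)
    chi_map = np.asarray(chi_map, dtype=float)

    coords = clusters.voxel_index
    if coords is None:
        raise ValueError("clusters must carry voxel_index into the volume")
    vox_sig = echoes.magnitudes[tuple(coords.T)]            # (n_vox, nTE)
    vox_chi = chi_map[tuple(coords.T)]
    n_vox = len(coords)

    s_ref = float(np.mean(vox_sig[:, 0]))
    s_ref = s_ref if s_ref > 0 else 1.0
    chi_ref = float(np.std(vox_chi))
    chi_ref = chi_ref if chi_ref > 1e-6 else 1.0

    # --- stage 1: cluster fits ---------------------------------------
    cluster_fits: dict[int, ClusterFit] = {}
    cluster_data: dict[int, tuple[np.ndarray, float, int]] = {}
    for k in range(clusters.K):
        members = clusters.assignment == k
        if not members.any():
            continue
        mean_sig = vox_sig[members].mean(axis=0)
        mean_chi = float(vox_chi[members].mean())
        cluster_data[k] = (mean_sig, mean_chi, int(members.sum()))
        cluster_fits[k] = fit_cluster(mean_sig, mean_chi, te, cfg, oef_wb,
                                      consts=consts, gmodel=gmodel,
                                      s_ref=s_ref, chi_ref=chi_ref)

    x = np.empty((n_vox, 5))
    for k, cf in cluster_fits.items():
        members = clusters.assignment == k
        p = cf.params
        x[members] = [p.Y, p.nu, p.R2, p.S0, p.chi_nb]
    # per-voxel S0 scaling from the first echo keeps stage-2 starts close
    model_first = np.array([
        _model_pieces(x[i], te[:1], g[:1], consts, consts.psi_hb_tissue)[1][0]
        for i in range(n_vox)
    ])
    scale = np.where(model_first > 0, vox_sig[:, 0] / model_first, 1.0)
    x[:, 3] = np.clip(x[:, 3] * scale, cfg.s0_bounds[0], 1e12)

    # --- stage 2: refinement with constraint splitting -----------------
    sqrt_w = np.sqrt(cfg.w)
    inv_ya = 1.0 / consts.Ya
    x_scale = np.array([0.1, 0.01, 10.0, max(s_ref, 1.0), 50.0])
    n_failed = 0
    objective_history: list[float] = []
    max_outer = 1 if cfg.lam == 0 else cfg.max_outer
    oef_prev = 1.0 - x[:, 0] * inv_ya

    def _total(xcur):
        return _global_objective(xcur, vox_sig, vox_chi, te, g, s_ref, chi_ref,
                                 cfg, oef_wb, consts)

    if cfg.voxel_refine == "all":
        # full five-parameter refit per voxel; the global penalty is split
        # into per-voxel targets shifted by the current whole-brain offset
        prev_total = np.inf
        for outer in range(max_outer):
            offset = float(np.mean(oef_prev) - oef_wb) if cfg.lam > 0 else 0.0
            targets = oef_prev - offset
            sqrt_lam = np.sqrt(cfg.lam)
            x_backup = x.copy()
            for i in range(n_vox):
                fun = _residual_fn(te, g, vox_sig[i], vox_chi[i], s_ref, chi_ref,
                                   sqrt_w, sqrt_lam, targets[i], consts,
                                   consts.psi_hb_tissue)
                try:
                    xi, _, ok = _solve_one(x[i], fun, cfg, x_scale)
                    x[i] = xi
                    if not ok:
                        n_failed += 1
                except Exception:   # pragma: no cover
                    n_failed += 1
            total = _total(x)
            if total > prev_total:      # split targets overshot: revert, stop
                x = x_backup
                logger.info("outer %d: objective would rise (%.6g); reverting", outer, total)
                break
            prev_total = total
            oef_now = 1.0 - x[:, 0] * inv_ya
            objective_history.append(total)
            delta = float(np.max(np.abs(oef_now - oef_prev)))
            oef_prev = oef_now
            logger.info("outer %d: global objective %.6g, max |dOEF| %.2e",
                        outer, total, delta)
            if delta < cfg.tol_oef:
                break
    else:
        # CAT mode: (Y, nu, R2) stay shared within a cluster.  The global
        # penalty is split across clusters (member-weighted targets); the
        # per-voxel minimization then refines (S0, chi_nb) only.
        cluster_x = {k: np.array([cf.params.Y, cf.params.nu, cf.params.R2,
                                  cf.params.S0, cf.params.chi_nb])
                     for k, cf in cluster_fits.items()}
        counts = {k: cluster_data[k][2] for k in cluster_x}
        if cfg.lam > 0:
            prev_total = np.inf
            for outer in range(max_outer):
                oef_k = {k: 1.0 - cluster_x[k][0] * inv_ya for k in cluster_x}
                mean_oef = sum(oef_k[k] * counts[k] for k in cluster_x) / n_vox
                offset = mean_oef - oef_wb
                delta = 0.0
                backup = {k: v.copy() for k, v in cluster_x.items()}
                for k in cluster_x:
                    mean_sig, mean_chi, n_k = cluster_data[k]
                    fun = _residual_fn(te, g, mean_sig, mean_chi, s_ref, chi_ref,
                                       sqrt_w, np.sqrt(cfg.lam * n_k / n_vox),
                                       oef_k[k] - offset, consts,
                                       consts.psi_hb_tissue)
                    try:
                        xk, _, ok = _solve_one(cluster_x[k], fun, cfg, x_scale)
                        delta = max(delta, abs(xk[0] - cluster_x[k][0]) * inv_ya)
                        cluster_x[k] = xk
                        if not ok:
                            n_failed += 1
                    except Exception:   # pragma: no cover
                        n_failed += 1
                for k in cluster_x:
                    x[clusters.assignment == k, :3] = cluster_x[k][:3]
                total = _total(x)
                if total > prev_total:  # split targets overshot: revert, stop
                    cluster_x = backup
                    for k in cluster_x:
                        x[clusters.assignment == k, :3] = cluster_x[k][:3]
                    logger.info("outer %d (cluster): objective would rise; reverting", outer)
                    break
                prev_total = total
                objective_history.append(total)
                logger.info("outer %d (cluster): objective %.6g, max |dOEF| %.2e",
                            outer, total, delta)
                if delta < cfg.tol_oef:
                    break
        for i in range(n_vox):
            try:
                xi, ok = _solve_s0_chinb(x[i], te, g, vox_sig[i], vox_chi[i],
                                         s_ref, chi_ref, sqrt_w, cfg, consts)
                x[i] = xi
                if not ok:
                    n_failed += 1
            except Exception:   # pragma: no cover
                n_failed += 1
        objective_history.append(
            _global_objective(x, vox_sig, vox_chi, te, g, s_ref, chi_ref,
                              cfg, oef_wb, consts))

    # --- assemble volumes ---------------------------------------------
    shape = brain_mask.shape
    maps = {name: np.full(shape, np.nan) for name in ("Y", "nu", "R2", "S0", "chi_nb")}
    fitted_mask = np.zeros(shape, dtype=bool)
    fitted_mask[tuple(coords.T)] = True
    for j, name in enumerate(("Y", "nu", "R2", "S0", "chi_nb")):
        maps[name][tuple(coords.T)] = x[:, j]
    quality = np.zeros(shape, dtype=bool)
    quality[tuple(coords.T)] = x[:, 1] <= cfg.nu_bounds[0] * (1.0 + 1e-6)

    provenance = {
        "seed": cfg.seed,
        "cluster_seed": int(clusters.seed),
        "K": int(clusters.K),
        "oef_wb": float(oef_wb),
        "outer_iterations": len(objective_history),
        "objective_history": objective_history,
        "failed_voxel_fits": int(n_failed),
        "config": cfg.to_dict(),
    }
    return TissueParamMaps(mask=fitted_mask, quality=quality,
                           provenance=provenance, **maps)


def _solve_s0_chinb(x0: np.ndarray, te, g, signal, chi, s_ref, chi_ref,
                    sqrt_w, cfg: FitConfig,
                    consts: PhysioConstants) -> tuple[np.ndarray, bool]:
    """Per-voxel (S0, chi_nb) refinement with (Y, nu, R2) frozen."""
    Y, nu, R2 = x0[:3]

    def fun(p):
        xfull = np.array([Y, nu, R2, p[0], p[1]])
        chi_model, sig = _model_pieces(xfull, te, g, consts, consts.psi_hb_tissue)
        r = np.empty(len(te) + 1)
        r[0] = sqrt_w * (chi_model - chi) / chi_ref
        r[1:] = (sig - signal) / s_ref
        return r

    res = least_squares(fun, x0[3:5],
                        bounds=([cfg.s0_bounds[0], cfg.chi_nb_bounds[0]],
                                [cfg.s0_bounds[1], cfg.chi_nb_bounds[1]]),
                        method="trf", x_scale=[max(s_ref, 1.0), 50.0],
                        xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=100)
    out = x0.copy()
    out[3:5] = res.x
    return out, bool(res.success)


def _global_objective(x, vox_sig, vox_chi, te, g, s_ref, chi_ref,
                      cfg: FitConfig, oef_wb: float,
                      consts: PhysioConstants) -> float:
    """Total objective with the true global mean-OEF penalty."""
    total = 0.0
    for i in range(len(x)):
        chi_model, sig = _model_pieces(x[i], te, g, consts, consts.psi_hb_tissue)
        total += cfg.w * ((chi_model - vox_chi[i]) / chi_ref) ** 2
        total += float(np.sum(((sig - vox_sig[i]) / s_ref) ** 2))
    mean_oef = float(np.mean(1.0 - x[:, 0] / consts.Ya))
    return total + cfg.lam * (mean_oef - oef_wb) ** 2
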