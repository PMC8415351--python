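"""Physiological constants and closed-form oxygenation conversions.

The QQ (QSM + qBOLD) model expresses tissue oxygenation through the venous
oxygenation fraction ``Y``; everything downstream reports the oxygen
extraction fraction ``OEF = 1 - Y/Ya`` where ``Ya`` is the arteriole
oxygenation.  The whole-brain OEF constraint is anchored on the straight
sinus, a large draining vein: inverting the susceptibility model at
``nu = 1, chi_nb = 0`` with the large-vessel hemoglobin volume fraction
gives the sinus oxygenation ``Y_ss``, and ``OEF_wb = Hct_vt * (1 - Y_ss/Ya)``
converts it to a brain-tissue target through the vessel-to-tissue
hematocrit ratio.

All fractions are stored as fractions in [0, 1]; percent formatting is a
reporting concern only.  Susceptibilities are in ppb throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Any, Mapping

import numpy as np

__all__ = [
    "PhysioConstants",
    "DEFAULT_CONSTANTS",
    "oef_from_y",
    "y_from_oef",
    "cmro2",
    "yss_from_chi_ss",
    "oef_wb_target",
]

#: Proton gyromagnetic ratio, rad / s / T.
GAMMA_PROTON = 2.0 * np.pi * 42.5774785e6


@dataclass(frozen=True)
class PhysioConstants:
    """Physiological constants of the QQ model.

    Parameters
    ----------
    Ya
        Arteriole oxygenation fraction.
    alpha
        Ratio between venous and total blood volume.
    psi_hb_tissue
        Hemoglobin volume fraction in tissue blood (at Hct = 0.357).
    psi_hb_vein
        Hemoglobin volume fraction used for the straight sinus.
    dchi_hb
        Susceptibility difference between deoxy- and oxyhemoglobin, ppb.
    hct_vt
        Hematocrit ratio between large vessels and brain tissue.
    chi_ba
        Fully oxygenated blood susceptibility, ppb.
    heme_conc
        Oxygenated heme molar concentration in the arteriole [H]a,
        umol/ml.
    gamma
        Proton gyromagnetic ratio, rad/s/T.
    B0
        Main field strength, T.
    """

    Ya: float = 0.98
    alpha: float = 0.77
    psi_hb_tissue: float = 0.0909
    psi_hb_vein: float = 0.1197
    dchi_hb: float = 12522.0
    hct_vt: float = 0.75
    chi_ba: float = -108.3
    heme_conc: float = 7.377
    gamma: float = GAMMA_PROTON
    B0: float = 3.0

    def __post_init__(self) -> None:
        if not 0.0 < self.Ya <= 1.0:
            raise ValueError(f"Ya must lie in (0, 1], got {self.Ya}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.dchi_hb <= 0:
            raise ValueError("dchi_hb must be positive")
        if self.hct_vt <= 0:
            raise ValueError("hct_vt must be positive")
        for name in ("psi_hb_tissue", "psi_hb_vein", "heme_conc", "B0", "gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "PhysioConstants":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise KeyError(f"unknown constant keys: {sorted(unknown)}")
        return cls(**dict(d))

    def replace(self, **kwargs: float) -> "PhysioConstants":
        return replace(self, **kwargs)


DEFAULT_CONSTANTS = PhysioConstants()


def oef_from_y(Y, consts: PhysioConstants = DEFAULT_CONSTANTS):
    """Convert venous oxygenation ``Y`` to OEF = 1 - Y/Ya.

    Accepts scalars or arrays; ``Y`` must lie in [0, Ya].
    """
    Y = np.asarray(Y, dtype=float)
    if np.any(Y < 0):
        raise ValueError("Y below lower bound 0")
    if np.any(Y > consts.Ya + 1e-12):
        raise ValueError(f"Y above upper bound Ya = {consts.Ya}")
    out = 1.0 - Y / consts.Ya
    return float(out) if out.ndim == 0 else out


def y_from_oef(oef, consts: PhysioConstants = DEFAULT_CONSTANTS):
    """Inverse of :func:`oef_from_y`: Y = Ya * (1 - OEF)."""
    oef = np.asarray(oef, dtype=float)
    if np.any(oef < 0) or np.any(oef > 1):
        raise ValueError("OEF must lie in [0, 1]")
    out = consts.Ya * (1.0 - oef)
    return float(out) if out.ndim == 0 else out


def cmro2(oef, cbf, consts: PhysioConstants = DEFAULT_CONSTANTS):
    """Cerebral metabolic rate of oxygen, CMRO2 = OEF * CBF * [H]a.

    ``cbf`` in ml/100 g/min, result in umol/100 g/min.
    """
    oef = np.asarray(oef, dtype=float)
    cbf = np.asarray(cbf, dtype=float)
    if np.any(oef < 0):
        raise ValueError("OEF must be nonnegative")
    if np.any(cbf < 0):
        raise ValueError("CBF must be nonnegative")
    out = oef * cbf * consts.heme_conc
    return float(out) if out.ndim == 0 else out


def yss_from_chi_ss(chi_ss: float, consts: PhysioConstants = DEFAULT_CONSTANTS) -> float:
    """Straight-sinus oxygenation from its mean susceptibility (ppb).

    Closed-form inversion of the susceptibility forward model at
    ``nu = 1, chi_nb = 0`` with the large-vessel hemoglobin fraction:

        Y_ss = 1 - (1 - alpha)*Ya - (alpha*chi_ss - chi_ba) / (psi_hb_vein * dchi_hb)
    """
    y_ss = (
        1.0
        - (1.0 - consts.alpha) * consts.Ya
        - (consts.alpha * chi_ss - consts.chi_ba) / (consts.psi_hb_vein * consts.dchi_hb)
    )
    if not 0.0 <= y_ss <= consts.Ya + 1e-12:
        raise ValueError(
            f"implausible sinus susceptibility {chi_ss} ppb: "
            f"implied Y_ss = {y_ss:.4f} outside [0, Ya = {consts.Ya}]"
        )
    return min(y_ss, consts.Ya)


def oef_wb_target(chi_ss: float, consts: PhysioConstants = DEFAULT_CONSTANTS) -> float:
    """Whole-brain OEF target from the straight-sinus susceptibility.

    OEF_wb = Hct_vt * OEF_ss with OEF_ss = 1 - Y_ss/Ya.
    """
    y_ss = yss_from_chi_ss(chi_ss, consts)
    return consts.hct_vt * (1.0 - y_ss / consts.Ya)
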