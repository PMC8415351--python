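"""Forward models against independent oracles and closed-form limits."""

import numpy as np
import pytest
from scipy import special
from scipy.integrate import quad

from qqoef.constants import DEFAULT_CONSTANTS
from qqoef.forward import (EchoSeries, MacroFieldModel, VoxelParams,
                           default_echo_times, delta_omega, f_bold, f_qsm,
                           fs_sdr, fs_sdr_fast, g_macro, s_qbold)


# ----------------------------------------------------------------------
# independent brute-force oracle for the SDR kernel (no shared code with
# the implementation: trapezoid panels + explicit series near u = 0)
# ----------------------------------------------------------------------

def fs_bruteforce(x: float, panels: int = 1_000_000, u0: float = 1e-6) -> float:
    if x == 0.0:
        return 0.0
    u = np.linspace(u0, 1.0, panels + 1)
    z = 1.5 * x * u
    integrand = (2.0 + u) * np.sqrt(1.0 - u) * (1.0 - special.j0(z)) / u ** 2
    body = np.trapezoid(integrand, u)
    # u -> 0: (2+u)sqrt(1-u) -> 2, 1-J0(z) ~ z^2/4 - z^4/64
    head = 2.0 * ((1.5 * x) ** 2 / 4.0 * u0 - (1.5 * x) ** 4 / 64.0 * u0 ** 3 / 3.0)
    return (body + head) / 3.0


def test_fs_sdr_matches_bruteforce_quadrature():
    xs = np.concatenate([np.linspace(0.0, 2.0, 9), np.linspace(3.0, 50.0, 12)])
    for x in xs:
        assert fs_sdr(float(x)) == pytest.approx(fs_bruteforce(float(x)), abs=1e-8)


def test_fs_sdr_limits():
    assert fs_sdr(0.0) == 0.0
    # small-argument quadratic limit fs ~ 0.3 x^2
    assert fs_sdr(0.1) == pytest.approx(0.3 * 0.1 ** 2, rel=0.05)
    # asymptotically linear with unit slope
    for x in (20.0, 40.0, 80.0):
        assert fs_sdr(x) / x == pytest.approx(1.0, rel=0.06)
    slope = (fs_sdr(80.0) - fs_sdr(40.0)) / 40.0
    assert slope == pytest.approx(1.0, rel=0.02)
    with pytest.raises(ValueError):
        fs_sdr(-1.0)


def test_fs_sdr_monotone_and_table_consistent():
    xs = np.linspace(0.0, 60.0, 301)
    vals = fs_sdr(xs)
    assert np.all(np.diff(vals) >= 0)
    assert np.max(np.abs(fs_sdr_fast(xs) - vals)) < 1e-7


def test_f_qsm_examples():
    c = DEFAULT_CONSTANTS
    # nu = 0: pure non-blood term
    assert f_qsm(0.6, 0.0, 12.5) == pytest.approx(12.5, abs=1e-12)
    # arithmetic oracle
    expect = (c.chi_ba / c.alpha
              + c.psi_hb_tissue * c.dchi_hb * (-0.6 + 1 - 0.23 * 0.98) / c.alpha) * 0.03
    assert f_qsm(0.6, 0.03, 0.0) == pytest.approx(expect, abs=1e-12)
    assert expect == pytest.approx(3.52, abs=0.01)
    # linear in nu at chi_nb = 0
    assert f_qsm(0.6, 0.06, 0.0) == pytest.approx(2 * f_qsm(0.6, 0.03, 0.0), abs=1e-12)


def test_f_qsm_monotone_in_deoxygenation():
    ys = np.linspace(0.2, 0.97, 30)
    chis = f_qsm(ys, 0.03, 5.0)
    assert np.all(np.diff(chis) < 0)  # lower Y (more deoxy) -> higher chi


def test_delta_omega():
    c = DEFAULT_CONSTANTS
    # bracket engineered to zero
    chi_nb0 = c.psi_hb_tissue * c.dchi_hb * (1 - 0.6) + c.chi_ba
    assert delta_omega(0.6, chi_nb0) == 0.0
    # arithmetic oracle at 3 T
    bracket = c.psi_hb_tissue * c.dchi_hb * 0.4 + c.chi_ba
    expect = c.gamma * 3.0 * bracket * 1e-9 / 3.0
    assert delta_omega(0.6, 0.0) == pytest.approx(expect, rel=1e-12)
    assert expect == pytest.approx(92.8, abs=0.2)
    # strictly decreasing in Y
    ys = np.linspace(0.1, 0.9, 17)
    assert np.all(np.diff(delta_omega(ys, 0.0)) < 0)
    with pytest.warns(UserWarning):
        assert delta_omega(0.98, 500.0) == 0.0


def test_f_bold_limits_and_oracle():
    p0 = VoxelParams(Y=0.6, nu=0.0, R2=15.0, S0=1000.0, chi_nb=0.0)
    assert f_bold(p0, 0.02) == 1.0
    p = VoxelParams(Y=0.6, nu=0.03, R2=15.0, S0=1000.0, chi_nb=0.0)
    assert f_bold(p, 0.0) == 1.0
    t = 0.0388
    dw = delta_omega(0.6, 0.0)
    assert f_bold(p, t) == pytest.approx(np.exp(-0.03 * fs_sdr(dw * t)), abs=1e-6)


def test_g_macro():
    unity = MacroFieldModel()
    assert g_macro(unity, 0.123) == 1.0
    c = DEFAULT_CONSTANTS
    grad = MacroFieldModel(mode="linear-gradient", gradient=(1e-6, 0.0, 0.0),
                           voxel_size=(2e-3, 2e-3, 2e-3), gamma=c.gamma)
    assert g_macro(grad, 0.0) == 1.0
    # first sinc null at gamma*g*dx*t = 2*pi
    t_null = 2 * np.pi / (c.gamma * 1e-6 * 2e-3)
    assert g_macro(grad, t_null) == pytest.approx(0.0, abs=1e-12)
    assert 0.0 <= g_macro(grad, t_null / 2) <= 1.0
    with pytest.raises(ValueError):
        MacroFieldModel(mode="bogus")


def test_s_qbold_limits_and_quadrature_oracle():
    p = VoxelParams(Y=0.6, nu=0.03, R2=15.0, S0=1000.0, chi_nb=0.0)
    assert s_qbold(p, 0.0) == pytest.approx(1000.0)
    # nu = 0: pure mono-exponential, log-linear
    p0 = VoxelParams(Y=0.6, nu=0.0, R2=15.0, S0=1000.0, chi_nb=0.0)
    te = default_echo_times()
    logs = np.log(s_qbold(p0, te))
    slopes = np.diff(logs) / np.diff(te)
    assert np.allclose(slopes, -15.0, atol=1e-9)
    # full model vs from-scratch quadrature at the 8 protocol TEs
    c = DEFAULT_CONSTANTS
    dw = c.gamma * c.B0 * (c.psi_hb_tissue * c.dchi_hb * 0.4 + c.chi_ba) * 1e-9 / 3.0
    for t in te:
        fs_val, _ = quad(lambda u: (2 + u) * np.sqrt(1 - u)
                         * (1 - special.j0(1.5 * dw * t * u)) / u ** 2,
                         1e-9, 1.0, limit=200)
        expect = 1000.0 * np.exp(-15.0 * t) * np.exp(-0.03 * fs_val / 3.0)
        assert s_qbold(p, float(t)) == pytest.approx(expect, rel=1e-6)


def test_s_qbold_monotone_properties():
    te = np.linspace(0.0, 0.05, 40)
    p = VoxelParams(Y=0.6, nu=0.05, R2=12.0, S0=500.0, chi_nb=0.0)
    sig = s_qbold(p, te)
    assert np.all(np.diff(sig) < 0)  # strictly decreasing in t
    # lower Y never increases the signal at any TE
    for y_hi, y_lo in ((0.8, 0.6), (0.6, 0.4)):
        s_hi = s_qbold(VoxelParams(y_hi, 0.05, 12.0, 500.0, 0.0), te[1:])
        s_lo = s_qbold(VoxelParams(y_lo, 0.05, 12.0, 500.0, 0.0), te[1:])
        assert np.all(s_lo <= s_hi + 1e-12)


def test_echo_series_validation():
    te = default_echo_times()
    assert te[0] == pytest.approx(4.5e-3) and te[-1] == pytest.approx(38.8e-3)
    with pytest.raises(ValueError):
        EchoSeries(echo_times=te[::-1], magnitudes=np.ones((4, 8)))
    with pytest.raises(ValueError):
        EchoSeries(echo_times=te, magnitudes=np.ones((4, 7)))
    with pytest.raises(ValueError):
        EchoSeries(echo_times=te, magnitudes=-np.ones((4, 8)))
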