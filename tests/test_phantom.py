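"""Phantom generator: geometry, forward consistency, noise, cohort roster."""

from dataclasses import replace

import numpy as np
import pytest

from qqoef.constants import DEFAULT_CONSTANTS
from qqoef.forward import f_qsm
from qqoef.phantom import (LONGITUDINAL_CASE_TYPES, PhantomConfig,
                           assign_params, build_geometry, case_masks,
                           make_cohort_roster, make_longitudinal_case,
                           make_phantom, simulate_cbf, simulate_chi,
                           simulate_mgre)
from qqoef.roi import apply_exclusions, classify_case, mirror_mask, relative_metric


@pytest.fixture(scope="module")
def small_cfg():
    return replace(PhantomConfig(seed=11).small(), snr=None)


@pytest.fixture(scope="module")
def small_truth(small_cfg):
    labels, masks, midline = build_geometry(small_cfg)
    return assign_params(labels, small_cfg, masks, midline)


def test_geometry_masks(small_cfg):
    labels, masks, midline = build_geometry(small_cfg)
    assert masks["brain"].any() and masks["ventricle"].any()
    assert masks["sinus"].any() and masks["lesion"].any()
    # sinus lies within the brain
    assert (masks["sinus"] & masks["brain"]).sum() == masks["sinus"].sum()
    # ventricle and lesion are disjoint
    assert not (masks["ventricle"] & masks["lesion"]).any()


def test_geometry_mirror_symmetric_without_lesion(small_cfg):
    cfg = replace(small_cfg, lesion_axes_mm=(0.0, 0.0, 0.0))
    labels, masks, midline = build_geometry(cfg)
    assert not masks["lesion"].any()
    assert np.array_equal(labels, np.flip(labels, axis=0))


def test_spherical_lesion_volume(small_cfg):
    r = 6.0  # mm
    cfg = replace(small_cfg, lesion_axes_mm=(r, r, r))
    _, masks, _ = build_geometry(cfg)
    expect = 4.0 / 3.0 * np.pi * r ** 3 / small_cfg.voxel_size_mm ** 3
    assert masks["lesion"].sum() == pytest.approx(expect, rel=0.15)


def test_lesion_must_stay_in_one_hemisphere(small_cfg):
    cfg = replace(small_cfg, lesion_center_frac=(0.48, 0.5, 0.5))
    with pytest.raises(ValueError, match="midsagittal"):
        build_geometry(cfg)


def test_assign_params_piecewise_constant_and_phase(small_truth, small_cfg):
    t = small_truth
    lesion = t.masks["lesion"]
    assert np.all(t.oef[lesion] == 0.26)     # acute profile
    brain = t.masks["brain"]
    # mirror symmetry outside the lesion support
    flipped = np.flip(t.oef, axis=0)
    outside = brain & ~lesion & ~mirror_mask(lesion, t.midline)
    assert np.allclose(t.oef[outside], flipped[outside])
    # piecewise constant: few distinct values
    assert len(np.unique(t.oef[brain])) <= 5


def test_simulate_chi_consistency(small_truth):
    c = DEFAULT_CONSTANTS
    chi = simulate_chi(small_truth)
    vent = small_truth.masks["ventricle"]
    assert abs(chi[vent].mean()) < 1e-9
    # sinus voxels invert back to the generating Y_ss
    sinus = small_truth.masks["sinus"]
    expect = f_qsm(small_truth.Y[sinus], 1.0, 0.0, psi_hb=c.psi_hb_vein)
    assert np.allclose(chi[sinus], expect, atol=1e-9)
    # lesion (higher deoxygenation? no: lower OEF) vs mirror contrast sign
    lesion = small_truth.masks["lesion"]
    mirror = mirror_mask(lesion, small_truth.midline)
    d_oef = small_truth.oef[lesion].mean() - small_truth.oef[mirror].mean()
    # f_qsm rises with deoxygenation, so the blood-compartment chi contrast
    # tracks the OEF contrast (the chi_nb class offset is excluded)
    chi_blood_les = f_qsm(small_truth.Y[lesion], small_truth.nu[lesion], 0.0)
    chi_blood_mir = f_qsm(small_truth.Y[mirror], small_truth.nu[mirror], 0.0)
    assert np.sign(chi_blood_les.mean() - chi_blood_mir.mean()) == np.sign(d_oef)


def test_simulate_mgre_noiseless_and_deterministic(small_truth):
    e0 = simulate_mgre(small_truth, snr=None)
    brain = small_truth.masks["brain"]
    assert np.all(e0.magnitudes[brain][:, 0] > 0)
    assert np.all(e0.magnitudes[~brain] == 0)
    e1 = simulate_mgre(small_truth, snr=80.0, seed=5)
    e2 = simulate_mgre(small_truth, snr=80.0, seed=5)
    assert np.array_equal(e1.magnitudes, e2.magnitudes)
    assert not np.array_equal(e0.magnitudes, e1.magnitudes)


def test_simulate_mgre_empirical_snr(small_truth):
    """Realized first-echo SNR tracks the request within 5%."""
    clean = simulate_mgre(small_truth, snr=None).magnitudes
    brain = small_truth.masks["brain"]
    req = 100.0
    sigmas = []
    for rep in range(10):
        noisy = simulate_mgre(small_truth, snr=req, seed=100 + rep).magnitudes
        resid = (noisy - clean)[brain][:, 1:4]   # early echoes, Rician ~ Gaussian
        sigmas.append(resid.std())
    snr_emp = clean[brain][:, 0].mean() / np.mean(sigmas)
    assert snr_emp == pytest.approx(req, rel=0.05)


def test_simulate_cbf_profiles(small_truth):
    brain = small_truth.masks["brain"]
    lesion = small_truth.masks["lesion"]
    cbf_flat = simulate_cbf(small_truth, rcbf_lesion=1.0, jitter_sd=0.0)
    mirror = mirror_mask(lesion, small_truth.midline)
    assert cbf_flat[lesion].mean() == pytest.approx(cbf_flat[mirror].mean(), rel=0.02)
    cbf_dr = simulate_cbf(small_truth, rcbf_lesion=1.45, jitter_sd=1.0, seed=3)
    rcbf = relative_metric(cbf_dr, lesion, small_truth.midline, brain)
    assert rcbf == pytest.approx(1.45, abs=0.05)
    assert np.array_equal(cbf_dr, simulate_cbf(small_truth, rcbf_lesion=1.45,
                                               jitter_sd=1.0, seed=3))


def test_longitudinal_case_invariants(small_cfg):
    dr = make_longitudinal_case("DR", cfg=small_cfg, seed=1)
    assert (dr.fi & dr.idl).sum() == dr.fi.sum() < dr.idl.sum()
    assert (dr.idl & ~dr.fi).any()          # reversal region nonempty
    eq = make_longitudinal_case("NDR-equal", cfg=small_cfg, seed=1)
    assert np.array_equal(eq.idl, eq.fi)
    en = make_longitudinal_case("NDR-enlarged", cfg=small_cfg, seed=1)
    assert (en.idl & ~en.fi).sum() == 0 and (en.fi & ~en.idl).any()
    with pytest.raises(ValueError):
        make_longitudinal_case("bogus", cfg=small_cfg)
    with pytest.raises(ValueError):
        make_longitudinal_case("DR", times_days=(5.0, 2.0), cfg=small_cfg)


def test_longitudinal_designed_trajectories():
    """Ground-truth rOEF of the reversal region rises between scans."""
    cfg = replace(PhantomConfig(seed=1), snr=None)   # default grid and lesion
    dr = make_longitudinal_case("DR", cfg=cfg, seed=1)
    rr = dr.idl & ~dr.fi
    brain = dr.masks["brain"]
    r1 = relative_metric(dr.truths[0].oef, rr, dr.midline, brain)
    r2 = relative_metric(dr.truths[1].oef, rr, dr.midline, brain)
    assert r1 == pytest.approx(0.73, abs=0.02)
    assert r2 == pytest.approx(0.90, abs=0.02)
    rcbf1 = relative_metric(dr.cbfs[0], dr.idl, dr.midline, brain)
    assert rcbf1 == pytest.approx(1.45, abs=0.05)


def test_eleven_case_reversal_proportion(small_cfg):
    kinds = [LONGITUDINAL_CASE_TYPES[i] for i in range(1, 12)]
    assert len(kinds) == 11
    n_dr = 0
    for kind in kinds:
        _, idl, fi, _, _ = case_masks(kind, small_cfg)
        vx = small_cfg.voxel_size_mm ** 3
        n_dr += classify_case(idl.sum() * vx, fi.sum() * vx) == "DR"
    assert n_dr == 5
    assert 100.0 * n_dr / 11 == pytest.approx(45.5, abs=0.1)


def test_cohort_roster_screening_counts():
    roster = make_cohort_roster(seed=0)
    assert len(roster) == 137
    included, tally = apply_exclusions(roster)
    assert len(included) == 115
    assert tally == {"brainstem_cerebellum": 8, "small_lesion": 2,
                     "hemorrhagic_transformation": 4,
                     "pre_mri_reperfusion_therapy": 8}
    counts = included["phase"].value_counts()
    assert counts["acute"] == 14 and counts["early_subacute"] == 54
    assert counts["late_subacute"] == 22 and counts["chronic"] == 25
    # derived phases agree with the designed ones
    assert (included["phase"] == included["phase_designed"]).all()
    # deterministic under seed
    assert roster.equals(make_cohort_roster(seed=0))
    assert not roster.equals(make_cohort_roster(seed=1))


def test_cohort_roster_moment_matched_group_stats():
    roster = make_cohort_roster(seed=3)
    included, _ = apply_exclusions(roster)
    acute = included[included["phase"] == "acute"]
    assert acute["lesion_oef"].mean() == pytest.approx(0.2604, abs=1e-9)
    assert acute["lesion_oef"].std(ddof=1) == pytest.approx(0.0724, abs=1e-9)
    chronic = included[included["phase"] == "chronic"]
    assert chronic["roef"].mean() == pytest.approx(0.75, abs=1e-9)
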