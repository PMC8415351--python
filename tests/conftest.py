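"""Shared fixtures: small noiseless/noisy phantoms and their CAT fits.

The phantom fits are session-scoped because several test modules assert
different properties of the same estimation run.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from qqoef.clustering import decay_features, xmeans
from qqoef.fitting import FitConfig, estimate_whole_brain_oef, fit_voxelwise
from qqoef.phantom import PhantomConfig, make_phantom


@pytest.fixture(scope="session")
def consts():
    from qqoef.constants import DEFAULT_CONSTANTS
    return DEFAULT_CONSTANTS


@pytest.fixture(scope="session")
def small_phantom_noiseless():
    cfg = replace(PhantomConfig(seed=1).small(), snr=None)
    truth, chi, echoes = make_phantom(cfg)
    return truth, chi, echoes


@pytest.fixture(scope="session")
def small_phantom_snr100():
    cfg = replace(PhantomConfig(seed=1).small(), snr=100.0)
    truth, chi, echoes = make_phantom(cfg)
    return truth, chi, echoes


def _cat_fit(truth, chi, echoes, lam):
    tissue = truth.masks["brain"] & ~truth.masks["sinus"]
    oef_wb = estimate_whole_brain_oef(chi, truth.masks["sinus"])
    feats = decay_features(echoes, brain_mask=tissue)
    clusters = xmeans(feats.features, seed=3)
    clusters.voxel_index = feats.voxel_index
    maps = fit_voxelwise(echoes, chi, clusters, tissue,
                         FitConfig(lam=lam, seed=3), oef_wb)
    return clusters, maps


@pytest.fixture(scope="session")
def noiseless_fit(small_phantom_noiseless):
    """CAT + QQ fit of the noiseless phantom with the constraint off."""
    truth, chi, echoes = small_phantom_noiseless
    clusters, maps = _cat_fit(truth, chi, echoes, lam=0.0)
    return truth, chi, echoes, clusters, maps


@pytest.fixture(scope="session")
def snr100_fit(small_phantom_snr100):
    """CAT + QQ fit at SNR 100 with the default whole-brain constraint."""
    truth, chi, echoes = small_phantom_snr100
    clusters, maps = _cat_fit(truth, chi, echoes, lam=1.0e3)
    return truth, chi, echoes, clusters, maps
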