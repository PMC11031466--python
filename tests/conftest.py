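"""Shared fixtures: small, fast phantoms with known ground truth.

Unit tests run on a reduced 4 x 40 x 40 grid (4 mm in-plane) to stay fast;
the acceptance tests use the full default geometry.
"""

import dataclasses

import numpy as np
import pytest

from ctperf import (DeconvConfig, LesionSpec, PhantomSpec, build_phantom,
                    compute_maps, gamma_variate)

SMALL_SPEC = PhantomSpec(shape=(4, 40, 40), voxel_size_mm=(5.0, 4.0, 4.0))
SMALL_LESION = LesionSpec(center_mm=(10.0, 80.0, 40.0),
                          penumbra_radii_mm=(8.0, 26.0, 22.0),
                          core_radii_mm=(6.0, 16.0, 13.0))


def small_spec(**overrides) -> PhantomSpec:
    return dataclasses.replace(SMALL_SPEC, **overrides)


@pytest.fixture(scope="session")
def lesion_case():
    """Noisy clean-scenario case with a mid-size lesion."""
    return build_phantom(small_spec(lesion=SMALL_LESION), seed=7)


@pytest.fixture(scope="session")
def noiseless_case():
    """Same lesion without noise: the forward model should invert cleanly."""
    return build_phantom(small_spec(lesion=SMALL_LESION, noise_sigma=0.0), seed=7)


@pytest.fixture(scope="session")
def noiseless_maps(noiseless_case):
    return compute_maps(noiseless_case.series,
                        brain_mask=noiseless_case.masks["brain"])


@pytest.fixture(scope="session")
def dense_forward():
    """Dense-grid (0.1 s) forward-model oracle for deconvolution tests.

    Returns (time grid, dense AIF) for the default bolus over the default
    39 s acquisition window.
    """
    spec = PhantomSpec()
    t = np.arange(0.0, (spec.n_frames - 1) * spec.dt + spec.dt_sim, spec.dt_sim)
    return t, gamma_variate(t, spec.aif)
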