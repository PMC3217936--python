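"""Shared fixtures: phantoms and full segmentation runs reused across tests.

The heavy objects (96^3 suite phantoms and their segmentations) are
session-scoped so each is computed exactly once.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from gwseg.deformation import segment_white_matter
from gwseg.phantom import PhantomSpec, make_phantom, phantom_suite


@pytest.fixture(scope="session")
def dev_spec() -> PhantomSpec:
    """Small folded phantom for fast unit-level pipeline tests."""
    return PhantomSpec(shape=(48, 48, 48), fold_amplitude=4.0, fold_wavelength=16.0,
                       seed=1, name="dev")


@pytest.fixture(scope="session")
def dev_truth(dev_spec):
    return make_phantom(dev_spec)


@pytest.fixture(scope="session")
def dev_result(dev_truth):
    return segment_white_matter(dev_truth.volume, dev_truth.brain_mask)


@pytest.fixture(scope="session")
def slab_truth():
    """Noise-free, bias-free flat-slab phantom (degenerate fold geometry)."""
    spec = PhantomSpec(shape=(48, 48, 48), fold_amplitude=0.0, noise_sd=0.0,
                       bias_strength=0.0, seed=0, name="slab")
    return make_phantom(spec)


@pytest.fixture(scope="session")
def noisy_slab_truth():
    """High-contrast flat slab with realistic noise (for round-1 coverage)."""
    spec = PhantomSpec(shape=(48, 48, 48), fold_amplitude=0.0, noise_sd=8.0,
                       bias_strength=0.15, seed=5, name="noisy-slab")
    return make_phantom(spec)


@pytest.fixture(scope="session")
def young_truth():
    return make_phantom(phantom_suite()[0])


@pytest.fixture(scope="session")
def old_truth():
    return make_phantom(phantom_suite()[1])


@pytest.fixture(scope="session")
def young_run(young_truth):
    """Full segmentation of the high-contrast preset, with the Euler
    characteristic of the outer complement recorded after every sweep."""
    chis: list[int] = []
    counts: list[tuple[int, int]] = []

    def on_sweep(st):
        chis.append(st.outer_complement_euler())
        claimed = int((st.state != 0).sum())
        counts.append((st.sweeps, claimed))

    result = segment_white_matter(young_truth.volume, young_truth.brain_mask,
                                  on_sweep=on_sweep)
    return result, chis, counts


@pytest.fixture(scope="session")
def old_run(old_truth):
    return segment_white_matter(old_truth.volume, old_truth.brain_mask)
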