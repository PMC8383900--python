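"""Shared fixtures: synthetic images (with preprocessing cached) and cohorts."""

from __future__ import annotations

import numpy as np
import pytest

import fundtess as ft


@pytest.fixture(scope="session")
def synth_case():
    """Factory for (rendered scene, preprocess result), cached per params."""
    cache: dict = {}

    def make(rho: float = 0.20, seed: int = 7, size: int = 128, **kw):
        key = (rho, seed, size, tuple(sorted(kw.items())))
        if key not in cache:
            p = ft.SynthImageParams(size=size, rho_target=rho, seed=seed, **kw)
            scene = ft.generate_image(p)
            cache[key] = (scene, ft.preprocess(scene.image))
        return cache[key]

    return make


@pytest.fixture(scope="session")
def calibration() -> ft.GeneratorCalibration:
    return ft.GeneratorCalibration()


@pytest.fixture(scope="session")
def cohort_3074(calibration):
    """The reference calibrated cohort (n matching the study population)."""
    return ft.generate_cohort(3074, calibration, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(20210923)


def random_mask(rng, shape, p=0.5, kind="choroid"):
    return ft.BinaryMask(rng.uniform(size=shape) < p, kind=kind)
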