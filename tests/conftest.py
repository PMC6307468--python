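"""Shared fixtures: small filament models and pre-rendered synthetic images.

Rendering is the slow part, so renders used by several tests are
session-scoped; tests must not mutate them.
"""

import numpy as np
import pytest

from cablemorph.envelope import FilamentGeometryParams, build_filament
from cablemorph.synthetic import (
    CLASS_SPECS,
    DeflationParams,
    render_afm_heightmap,
    render_section_image,
)


@pytest.fixture(scope="session")
def sf1_model():
    """Thin-filament reference model: 15 ridges of 231 nm."""
    return build_filament(FilamentGeometryParams(n_cells=3))


@pytest.fixture(scope="session")
def bf1_model():
    """Thick-filament reference model: 61 ridges of 205 nm."""
    return build_filament(FilamentGeometryParams(
        N_R=61, delta_R=205.0, delta_B=124.0, delta_C=57.0, delta_S=82.0,
        cell_length=4930.0, n_cells=3, ridge_area=11e3))


@pytest.fixture(scope="session")
def sf_deflation_clean():
    return DeflationParams(noise_sd=0.0, seed=101,
                           **CLASS_SPECS["SF"]["deflation"])


@pytest.fixture(scope="session")
def sf_deflation_noisy():
    return DeflationParams(noise_sd=5.0, seed=101,
                           **CLASS_SPECS["SF"]["deflation"])


@pytest.fixture(scope="session")
def sf1_heightmap_clean(sf1_model, sf_deflation_clean):
    return render_afm_heightmap(sf1_model, sf_deflation_clean, pixel_size=10.0)


@pytest.fixture(scope="session")
def sf1_heightmap_noisy(sf1_model, sf_deflation_noisy):
    return render_afm_heightmap(sf1_model, sf_deflation_noisy, pixel_size=10.0)


@pytest.fixture(scope="session")
def sf1_mid_section(sf1_model):
    z_mid = 0.5 * sf1_model.params.cell_length
    return render_section_image(sf1_model, z_mid, pixel_size=12.0, seed=3)


@pytest.fixture(scope="session")
def sf1_junction_section(sf1_model):
    return render_section_image(sf1_model, sf1_model.params.cell_length,
                                pixel_size=12.0, seed=3)


@pytest.fixture(scope="session")
def bf1_mid_section(bf1_model):
    z_mid = 0.5 * bf1_model.params.cell_length
    return render_section_image(bf1_model, z_mid, pixel_size=12.0, seed=3)


@pytest.fixture(scope="session")
def bf1_junction_section(bf1_model):
    return render_section_image(bf1_model, bf1_model.params.cell_length,
                                pixel_size=12.0, seed=3)
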