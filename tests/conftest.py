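"""Shared fixtures: a small sensor for fast optics tests and a cached
closed-loop measurement run reused by several fidelity tests."""

from __future__ import annotations

import numpy as np
import pytest

from holoplankton import OpticalConfig
from holoplankton.classify import classify
from holoplankton.extraction import measure_particle
from holoplankton.scenes import TAXON_CELLS, make_silhouette

PITCH_UM = 3.45


@pytest.fixture(scope="session")
def small_config() -> OpticalConfig:
    """256x256 sensor: fast FFTs, same physics."""
    return OpticalConfig(sensor_shape=(256, 256))


@pytest.fixture(scope="session")
def full_config() -> OpticalConfig:
    return OpticalConfig()


@pytest.fixture(scope="session")
def closed_loop_run():
    """500 random particles: generate mask -> measure -> classify.

    Returns a list of dicts with the true and measured (taxon, H, M,
    antennas).  Session-scoped because mask synthesis dominates runtime.
    """
    rng = np.random.default_rng(42)
    taxa = list(TAXON_CELLS)
    rows = []
    for i in range(500):
        taxon = taxa[i % len(taxa)]
        cell = TAXON_CELLS[taxon]
        h = float(rng.uniform(*cell["h"]))
        m = float(rng.uniform(*cell["m"]))
        mask = make_silhouette(taxon, h, m, cell["antennas"], PITCH_UM, rng=rng)
        pm = measure_particle(mask, PITCH_UM)
        rows.append(
            dict(
                taxon=taxon,
                H_true=h,
                M_true=m,
                antennas_true=cell["antennas"],
                H_meas=pm.H_um,
                M_meas=min(pm.M, 1.0),
                antennas_meas=pm.antennas,
                label=classify(pm.H_um, min(pm.M, 1.0), pm.antennas),
            )
        )
    return rows
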