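from __future__ import annotations

import numpy as np
import pytest

from fishmorph import FishParams, generate_fish
from fishmorph.shapes import OutlineShape
from fishmorph.synthetic import AssemblageDesign, generate_assemblage


def circle_outline(radius: float = 1.0, n: int = 256,
                   center=(0.0, 0.0)) -> OutlineShape:
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return OutlineShape(
        np.column_stack([center[0] + radius * np.cos(theta),
                         center[1] + radius * np.sin(theta)])
    )


def ellipse_outline(a: float, b: float, n: int = 256) -> OutlineShape:
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return OutlineShape(np.column_stack([a * np.cos(theta), b * np.sin(theta)]))


@pytest.fixture(scope="session")
def small_dataset():
    """20 species x 2 individuals with strong group structure (seed 5)."""
    return generate_assemblage(
        AssemblageDesign(n_species=20, n_individuals=40, seed=5)
    )


@pytest.fixture(scope="session")
def quiet_fish():
    """A single noise-free fish with all products."""
    return generate_fish(FishParams(noise_sd=0.0, seed=0), id="f0", species="sp0")
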