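"""Shared fixtures: small, fast synthetic scenes with exact ground truth."""

import numpy as np
import pytest

from voxsample.phantoms import CellSpec, PhantomSpec, render_phantom

INTENSITIES = {
    "nuclear": {"background": 5.0, "cytoplasm": 40.0, "membrane": 40.0,
                "nucleus": 200.0},
    "membrane": {"background": 5.0, "cytoplasm": 40.0, "membrane": 180.0,
                 "nucleus": 30.0},
    "signal": {"background": 5.0, "cytoplasm": 50.0, "membrane": 30.0,
               "nucleus": 100.0},
}


def make_separated_spec(noise_sigma_frac=0.0, seed=0):
    """Five well-separated spherical cells (nucleus diameter 6 µm,
    separations > 1.5 diameters), isotropic 1 µm spacing."""
    centres = [(15, 15, 15), (15, 15, 50), (15, 50, 15), (15, 50, 50),
               (15, 32.5, 32.5)]
    cells = [CellSpec(c, cell_radius_um=9.0, nucleus_radius_um=3.0)
             for c in centres]
    return PhantomSpec(cells=cells, intensities=INTENSITIES,
                       noise_sigma_frac=noise_sigma_frac,
                       spacing=(1.0, 1.0, 1.0), seed=seed)


@pytest.fixture(scope="session")
def separated_phantom():
    """(channels, truth, spec) of the noise-free separated-cell scene."""
    spec = make_separated_spec()
    channels, truth = render_phantom(spec)
    return channels, truth, spec


@pytest.fixture(scope="session")
def noisy_separated_phantom():
    spec = make_separated_spec(noise_sigma_frac=0.1, seed=11)
    channels, truth = render_phantom(spec)
    return channels, truth, spec
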