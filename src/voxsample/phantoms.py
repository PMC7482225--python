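"""Synthetic phantoms: mock tissues of spherical cells with known intensities.

Each phantom is a cluster of spherical cells, every cell carrying a
concentric spherical nucleus, a cytoplasmic interior, and a membrane shell of
fixed thickness at its boundary; where two cells' shells meet, the overlap is
the contacting membrane. Voxels take the intensity of their compartment
(deepest-containing rule: nucleus > membrane > cytoplasm > background), plus
seeded additive Gaussian noise and optional Poisson shot noise, so the ground
truth of every compartment mean is known exactly.

The default scale mirrors pre-implantation embryos: 15 µm cell radius, 5 µm
nucleus radius, (1, 0.5, 0.5) µm anisotropic confocal spacing, 1 µm membrane.
``validation_suite`` builds four clustered phantoms of four to six cells each
with intensity tables spanning a >= 4-fold dynamic range, the configuration
used throughout the accuracy tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import Volume, write_stack

_SIX = ndimage.generate_binary_structure(3, 1)

BACKGROUND, CYTOPLASM, MEMBRANE, NUCLEUS = 0, 1, 2, 3
COMPARTMENT_NAMES = {BACKGROUND: "background", CYTOPLASM: "cytoplasm",
                     MEMBRANE: "membrane", NUCLEUS: "nucleus"}


@dataclass
class CellSpec:
    centre_um: tuple  # (z, y, x)
    cell_radius_um: float
    nucleus_radius_um: float


@dataclass
class PhantomSpec:
    """Full description of one synthetic scene.

    ``intensities`` maps channel name -> {compartment name: value}, with
    compartments "background", "cytoplasm", "membrane", "nucleus".
    ``noise_sigma_frac`` scales the per-channel Gaussian noise sigma as a
    fraction of that channel's cytoplasm intensity (0.1 ~ SNR 10).
    """

    cells: list
    intensities: dict
    membrane_thickness_um: float = 1.0
    noise_sigma_frac: float = 0.1
    poisson: bool = False
    spacing: tuple = (1.0, 0.5, 0.5)
    shape: tuple | None = None  # derived from the cells when None
    seed: int = 0

    def __post_init__(self):
        for c in self.cells:
            if c.nucleus_radius_um >= c.cell_radius_um:
                raise ValueError("nucleus radius must be < cell radius")
        centres = np.array([c.centre_um for c in self.cells], dtype=float)
        for i in range(len(self.cells)):
            for j in range(i + 1, len(self.cells)):
                d = np.linalg.norm(centres[i] - centres[j])
                if d < self.cells[i].nucleus_radius_um + self.cells[j].nucleus_radius_um:
                    raise ValueError(f"nuclei of cells {i} and {j} overlap")
        for table in self.intensities.values():
            if any(v < 0 for v in table.values()):
                raise ValueError("compartment intensities must be >= 0")


@dataclass
class GroundTruth:
    """Exact noise-free truth accompanying a rendered phantom."""

    class_map: np.ndarray  # compartment code per voxel
    cell_owner: np.ndarray  # nearest-cell id over foreground, -1 background
    centres_um: np.ndarray  # (n_cells, 3), cell (= nucleus) centres
    cell_radii_um: np.ndarray
    nucleus_radii_um: np.ndarray
    intensities: dict  # channel -> {compartment: value}
    exposed_mask: np.ndarray
    contact_mask: np.ndarray
    exposed_fraction: np.ndarray  # per cell
    spacing: tuple

    def compartment_mean(self, channel: str, compartment: str) -> float:
        return float(self.intensities[channel][compartment])


def _distance_grids(spec: PhantomSpec):
    shape = spec.shape
    sz, sy, sx = spec.spacing
    zc = np.arange(shape[0]) * sz
    yc = np.arange(shape[1]) * sy
    xc = np.arange(shape[2]) * sx
    for cell in spec.cells:
        cz, cy, cx = cell.centre_um
        d2 = ((zc - cz) ** 2)[:, None, None] + ((yc - cy) ** 2)[None, :, None] \
            + ((xc - cx) ** 2)[None, None, :]
        yield np.sqrt(d2)


def _derive_shape(spec: PhantomSpec, margin_um: float = 5.0):
    centres = np.array([c.centre_um for c in spec.cells], dtype=float)
    radii = np.array([c.cell_radius_um for c in spec.cells])
    hi = (centres + radii[:, None]).max(axis=0) + margin_um
    return tuple(int(np.ceil(h / s)) + 1 for h, s in zip(hi, spec.spacing))


def render_phantom(spec: PhantomSpec):
    """Render the multi-channel volume and its exact ground truth.

    Voxels are classified at their centre point (no anti-aliasing), so the
    noise-free compartment masks are exact oracles. Same spec + same seed is
    bit-identical.
    """
    if spec.shape is None:
        spec.shape = _derive_shape(spec)
    shape = spec.shape
    t = spec.membrane_thickness_um

    nucleus = np.zeros(shape, bool)
    membrane = np.zeros(shape, bool)
    interior = np.zeros(shape, bool)
    shell_count = np.zeros(shape, np.int8)
    best_d = np.full(shape, np.inf)
    cell_owner = np.full(shape, -1, np.int32)
    for k, (cell, d) in enumerate(zip(spec.cells, _distance_grids(spec))):
        nucleus |= d < cell.nucleus_radius_um
        shell = (d >= cell.cell_radius_um - t) & (d < cell.cell_radius_um)
        membrane |= shell
        shell_count += shell
        interior |= d < cell.cell_radius_um - t
        closer = d < best_d
        cell_owner[closer] = k
        best_d[closer] = d[closer]

    class_map = np.zeros(shape, np.uint8)
    class_map[interior] = CYTOPLASM
    class_map[membrane & ~nucleus] = MEMBRANE
    class_map[nucleus] = NUCLEUS
    fg = class_map > 0
    cell_owner[~fg] = -1

    padded_out = np.pad(_exterior_bg(fg), 1, constant_values=True)
    exposed = fg & ndimage.binary_dilation(padded_out, _SIX)[1:-1, 1:-1, 1:-1]
    contact = (shell_count >= 2) & (class_map == MEMBRANE)

    n_cells = len(spec.cells)
    exposed_fraction = np.zeros(n_cells)
    for k in range(n_cells):
        ne = int(np.sum(exposed & (cell_owner == k)))
        nc = int(np.sum(contact & (cell_owner == k)))
        exposed_fraction[k] = ne / (ne + nc) if ne + nc else np.nan

    rng = np.random.default_rng(spec.seed)
    channels = {}
    for name in sorted(spec.intensities):
        table = spec.intensities[name]
        lut = np.array([table["background"], table["cytoplasm"],
                        table["membrane"], table["nucleus"]])
        data = lut[class_map].astype(np.float64)
        if spec.poisson:
            data = rng.poisson(data).astype(np.float64)
        sigma = spec.noise_sigma_frac * table["cytoplasm"]
        if sigma > 0:
            data = data + rng.normal(0.0, sigma, size=shape)
        channels[name] = Volume(np.clip(data, 0.0, None), spec.spacing,
                                channel_name=name)

    truth = GroundTruth(
        class_map=class_map,
        cell_owner=cell_owner,
        centres_um=np.array([c.centre_um for c in spec.cells], dtype=float),
        cell_radii_um=np.array([c.cell_radius_um for c in spec.cells]),
        nucleus_radii_um=np.array([c.nucleus_radius_um for c in spec.cells]),
        intensities={ch: dict(tbl) for ch, tbl in spec.intensities.items()},
        exposed_mask=exposed,
        contact_mask=contact,
        exposed_fraction=exposed_fraction,
        spacing=spec.spacing,
    )
    return channels, truth


def _exterior_bg(fg: np.ndarray) -> np.ndarray:
    padded = np.pad(fg, 1, constant_values=False)
    lab, _ = ndimage.label(~padded, structure=_SIX)
    return (lab == lab[0, 0, 0])[1:-1, 1:-1, 1:-1]


# Clustered layouts with unit nearest-neighbour distance: tetrahedron,
# square pyramid, octahedron. Scaled by 1.8 x cell radius, every cell
# touches its neighbours (slight overlap, as in a compacting tissue)
# without the deep interpenetration that no real tissue shows.
_S2 = 1.0 / np.sqrt(2.0)
_Q = 1.0 / np.sqrt(8.0)
_LAYOUTS = {
    4: np.array([(_Q, _Q, _Q), (_Q, -_Q, -_Q), (-_Q, _Q, -_Q), (-_Q, -_Q, _Q)]),
    5: np.array([(_S2, 0, 0),
                 (0, 0.5, 0.5), (0, 0.5, -0.5), (0, -0.5, 0.5), (0, -0.5, -0.5)]),
    6: np.array([(_S2, 0, 0), (-_S2, 0, 0), (0, _S2, 0),
                 (0, -_S2, 0), (0, 0, _S2), (0, 0, -_S2)]),
}


def validation_suite(seed: int, cell_radius_um: float = 15.0,
                     nucleus_radius_um: float = 5.0,
                     noise_sigma_frac: float = 0.1,
                     nc_ratios=(0.5, 1.0, 2.0, 4.0)) -> list[PhantomSpec]:
    """Four clustered phantom specs of 4–6 spherical cells each.

    Cell counts are drawn from {4, 5, 6} (seeded), layouts keep every cell
    touching its nearest neighbours (centre distance 1.8 × cell radius), and
    each model's "signal" channel carries a
    different true nuclear-to-cytoplasmic ratio, covering ``nc_ratios``
    across the suite. Intensity tables span a >= 4-fold dynamic range. Two
    calls with the same seed return identical specs.
    """
    rng = np.random.default_rng(seed)
    counts = rng.choice([4, 5, 6], size=4)
    ratios = rng.permutation(np.asarray(nc_ratios, dtype=float))
    specs = []
    for m in range(4):
        n = int(counts[m])
        centres = _LAYOUTS[n] * (1.8 * cell_radius_um)
        centres = centres + rng.normal(0.0, 0.5, size=centres.shape)
        origin = centres.min(axis=0) - (cell_radius_um + 5.0)
        centres = centres - origin
        cells = [CellSpec(tuple(c), cell_radius_um, nucleus_radius_um)
                 for c in centres]
        cyt_sig = 50.0 * float(rng.uniform(0.9, 1.1))
        ratio = float(ratios[m])
        intensities = {
            "nuclear": {"background": 5.0, "cytoplasm": 40.0,
                        "membrane": 40.0,
                        "nucleus": 200.0 * float(rng.uniform(0.9, 1.1))},
            "membrane": {"background": 5.0, "cytoplasm": 40.0,
                         "membrane": 180.0 * float(rng.uniform(0.9, 1.1)),
                         "nucleus": 30.0},
            "signal": {"background": 5.0, "cytoplasm": cyt_sig,
                       "membrane": 30.0, "nucleus": ratio * cyt_sig},
        }
        specs.append(PhantomSpec(cells=cells, intensities=intensities,
                                 noise_sigma_frac=noise_sigma_frac,
                                 seed=int(rng.integers(2 ** 31 - 1))))
    return specs


def save_phantom(spec: PhantomSpec, outdir) -> dict:
    """Render a phantom and write channel TIFF stacks plus the ground truth
    (cells + intensities as JSON, class map as a TIFF). Returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    channels, truth = render_phantom(spec)
    paths = {}
    for name, vol in channels.items():
        p = outdir / f"{name}.tif"
        write_stack(vol.data.astype(np.float32), p)
        paths[name] = p
    write_stack(truth.class_map, outdir / "truth_classes.tif")
    paths["classes"] = outdir / "truth_classes.tif"
    meta = {
        "spacing_um": list(spec.spacing),
        "cells": [{"centre_um_zyx": list(map(float, c.centre_um)),
                   "cell_radius_um": c.cell_radius_um,
                   "nucleus_radius_um": c.nucleus_radius_um}
                  for c in spec.cells],
        "intensities": truth.intensities,
        "exposed_fraction": [float(f) for f in truth.exposed_fraction],
        "seed": spec.seed,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    paths["truth"] = outdir / "truth.json"
    return paths
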