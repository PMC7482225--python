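"""Probabilistic subcellular sampling around detected nuclei.

Voxels near each nucleus are claimed by their nearest nuclear centre
(physical distance, anisotropy-aware), classified as nuclear or cytoplasmic
by the nuclear-stain intensity, and averaged per channel — cytoplasmic voxels
with a Gaussian distance weight, reflecting the falling probability that a
voxel far from the nucleus still belongs to the same cell. A membrane stain,
when present, adds two further readings per nucleus: the exposed (outward
facing) membrane surface and the contacting membrane located on the segment
between neighbouring nuclei.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import Volume

log = logging.getLogger(__name__)

_SIX = ndimage.generate_binary_structure(3, 1)


@dataclass
class CompartmentSample:
    nucleus_id: int
    channel: str
    nuclear_mean: float | None
    cytoplasm_weighted_mean: float | None
    n_nuclear_voxels: int
    n_cyto_voxels: int


@dataclass
class MembraneSample:
    nucleus_id: int
    channel: str
    exposed_mean: float | None = None
    contacting_mean: float | None = None
    partner_ids: list = field(default_factory=list)


@dataclass
class SampleRecord:
    """One detected object's full measurement row.

    ``values`` holds flattened per-channel measurements keyed by column name
    (``nuclear_<ch>``, ``cytoplasm_<ch>``, ``membrane_exposed_<ch>``,
    ``membrane_contacting_<ch>``, ``nc_ratio_<ch>``, ``log_nc_<ch>`` ...);
    missing measurements are simply absent and become empty CSV cells.
    """

    object_type: str
    object_id: int
    centre_um: np.ndarray  # (z, y, x)
    radius_um: float | None = None
    values: dict = field(default_factory=dict)
    distance_to_surface_um: float | None = None
    distance_to_roi_um: list = field(default_factory=list)

    def to_row(self) -> dict:
        z, y, x = (float(v) for v in self.centre_um)
        row = {"object_type": self.object_type, "object_id": self.object_id,
               "x_um": x, "y_um": y, "z_um": z}
        if self.radius_um is not None:
            row["radius_um"] = float(self.radius_um)
        row.update(self.values)
        if self.distance_to_surface_um is not None:
            row["distance_to_surface_um"] = float(self.distance_to_surface_um)
        for k, d in enumerate(self.distance_to_roi_um):
            row[f"distance_to_roi_{k}_um"] = float(d)
        return row


def assign_voxels(nuclei, volume_shape, spacing, crop_radius_um) -> np.ndarray:
    """Nearest-nucleus voxel ownership within a physical crop radius.

    Returns an int array of nucleus ids, −1 where unassigned (farther than
    ``crop_radius_um`` from every nucleus). Exact: a running minimum over
    nuclei in ascending-id order with a strict ``<`` update, so equidistant
    voxels deterministically go to the lowest nucleus id.
    """
    if not nuclei:
        raise ValueError("assign_voxels requires at least one nucleus")
    sz, sy, sx = spacing
    zc = np.arange(volume_shape[0]) * sz
    yc = np.arange(volume_shape[1]) * sy
    xc = np.arange(volume_shape[2]) * sx
    best_d2 = np.full(volume_shape, np.inf)
    owner = np.full(volume_shape, -1, dtype=np.int32)
    for nuc in sorted(nuclei, key=lambda n: n.id):
        cz, cy, cx = nuc.centre_um
        d2 = ((zc - cz) ** 2)[:, None, None] + ((yc - cy) ** 2)[None, :, None] \
            + ((xc - cx) ** 2)[None, None, :]
        closer = d2 < best_d2
        owner[closer] = nuc.id
        best_d2[closer] = d2[closer]
    owner[best_d2 > crop_radius_um ** 2] = -1
    return owner


NUCLEAR, CYTOPLASMIC = 1, 2


def classify_voxels(ownership: np.ndarray, nuclear_channel: Volume,
                    threshold: float) -> np.ndarray:
    """Classify assigned voxels by nuclear-stain intensity.

    Returns int8 classes: 0 unclassified (unassigned), 1 nuclear
    (intensity >= threshold), 2 cytoplasmic.
    """
    if ownership.shape != nuclear_channel.shape:
        raise ValueError("ownership and channel shapes differ")
    assigned = ownership >= 0
    classes = np.zeros(ownership.shape, dtype=np.int8)
    bright = nuclear_channel.data >= threshold
    classes[assigned & bright] = NUCLEAR
    classes[assigned & ~bright] = CYTOPLASMIC
    return classes


def sample_compartments(ownership, classes, channels, nuclei,
                        weight_sigma_um) -> list[CompartmentSample]:
    """Per-nucleus, per-channel nuclear and cytoplasmic fluorescence.

    nuclear_mean is the unweighted mean over the nucleus's nuclear voxels;
    the cytoplasmic mean weights each voxel by exp(−d²/(2σ²)) with d the
    physical distance to the nucleus centre and σ = ``weight_sigma_um``.
    Empty compartments yield missing (None) means.
    """
    channels = dict(channels)
    spacing = next(iter(channels.values())).spacing
    samples = []
    for nuc in sorted(nuclei, key=lambda n: n.id):
        idx = np.nonzero(ownership == nuc.id)
        if idx[0].size == 0:
            for name in channels:
                samples.append(CompartmentSample(nuc.id, name, None, None, 0, 0))
            continue
        pos = np.stack([idx[a] * spacing[a] for a in range(3)], axis=1)
        d2 = np.sum((pos - nuc.centre_um) ** 2, axis=1)
        cls = classes[idx]
        nuc_sel = cls == NUCLEAR
        cyt_sel = cls == CYTOPLASMIC
        w = np.exp(-d2[cyt_sel] / (2.0 * weight_sigma_um ** 2))
        wsum = w.sum()
        for name, vol in channels.items():
            vals = vol.data[idx]
            nuclear_mean = float(vals[nuc_sel].mean()) if nuc_sel.any() else None
            cyto = float(np.sum(w * vals[cyt_sel]) / wsum) if wsum > 0 else None
            samples.append(CompartmentSample(nuc.id, name, nuclear_mean, cyto,
                                             int(nuc_sel.sum()), int(cyt_sel.sum())))
    return samples


@dataclass
class ExposedSurface:
    """Outer boundary of the thresholded membrane foreground."""

    mask: np.ndarray  # boolean, full volume
    voxel_indices: np.ndarray  # (N, 3) int
    owner_ids: np.ndarray  # (N,) nucleus id per surface voxel
    spacing: tuple

    @property
    def coords_um(self) -> np.ndarray:
        return self.voxel_indices * np.asarray(self.spacing)


def _border_connected_background(foreground: np.ndarray) -> np.ndarray:
    """Background voxels connected (6-conn) to outside the volume."""
    padded = np.pad(foreground, 1, constant_values=False)
    lab, _ = ndimage.label(~padded, structure=_SIX)
    outside_label = lab[0, 0, 0]  # the padding is one outside component
    return (lab == outside_label)[1:-1, 1:-1, 1:-1]


def detect_exposed_membrane(membrane_channel: Volume, nuclei,
                            membrane_threshold: float) -> ExposedSurface:
    """Exposed-surface voxels of the thresholded membrane stain.

    The foreground is hole-filled; its outer boundary (foreground voxels with
    a 6-connected background neighbour reachable from the volume border) is
    the exposed surface. Each surface voxel is assigned to the nearest
    nucleus. Voxels on interfaces between touching cells have no
    border-reachable background neighbour and are therefore not exposed.
    """
    spacing = membrane_channel.spacing
    fg = membrane_channel.data >= membrane_threshold
    fg = ndimage.binary_fill_holes(fg)
    empty = ExposedSurface(np.zeros(fg.shape, bool),
                           np.empty((0, 3), int), np.empty(0, int), spacing)
    if not fg.any():
        log.warning("empty membrane foreground: no exposed surface")
        return empty
    outside = _border_connected_background(fg)
    # pad so foreground on the volume face counts as exposed
    outside_pad = np.pad(outside, 1, constant_values=True)
    touching = ndimage.binary_dilation(outside_pad, structure=_SIX)[1:-1, 1:-1, 1:-1]
    surface = fg & touching
    idx = np.argwhere(surface)
    if idx.size == 0:
        return empty
    centres = np.stack([n.centre_um for n in sorted(nuclei, key=lambda n: n.id)])
    ids = np.array([n.id for n in sorted(nuclei, key=lambda n: n.id)])
    coords = idx * np.asarray(spacing)
    d2 = np.sum((coords[:, None, :] - centres[None]) ** 2, axis=2)
    owners = ids[np.argmin(d2, axis=1)]
    return ExposedSurface(surface, idx, owners, spacing)


def sample_exposed_membrane(surface: ExposedSurface, channels, nuclei) -> dict:
    """Mean channel intensity over each nucleus's exposed-surface voxels.

    Returns {nucleus_id: {channel: mean or None}}.
    """
    out = {}
    idx = tuple(surface.voxel_indices.T) if surface.voxel_indices.size else None
    for nuc in nuclei:
        sel = surface.owner_ids == nuc.id if idx else np.empty(0, bool)
        out[nuc.id] = {}
        for name, vol in dict(channels).items():
            if idx is not None and sel.any():
                out[nuc.id][name] = float(vol.data[idx][sel].mean())
            else:
                out[nuc.id][name] = None
    return out


def sample_contacting_membrane(nuclei, neighbour_graph, channels,
                               membrane_channel_name: str,
                               probe_half_width_um: float = 0.5) -> dict:
    """Contacting-membrane samples on segments between neighbouring nuclei.

    For each neighbour pair the membrane channel is sampled along the segment
    between the two centres at sub-voxel steps (0.25 × min spacing, trilinear
    interpolation); the arg-max locates the shared membrane, and each channel
    is averaged within ``probe_half_width_um`` of that point along the line.
    The sample belongs to both nuclei. Returns
    {(id_lo, id_hi): {channel: mean}}.
    """
    channels = dict(channels)
    membrane = channels[membrane_channel_name]
    spacing = np.asarray(membrane.spacing)
    step = 0.25 * float(spacing.min())
    by_id = {n.id: n for n in nuclei}
    out = {}
    for i, j in neighbour_graph.edges:
        a, b = by_id[i].centre_um, by_id[j].centre_um
        length = float(np.linalg.norm(np.asarray(b) - np.asarray(a)))
        if length == 0:
            continue
        n_steps = max(2, int(math.ceil(length / step)) + 1)
        t = np.linspace(0.0, 1.0, n_steps)
        pts = np.asarray(a)[None] + t[:, None] * (np.asarray(b) - np.asarray(a))[None]
        vox = (pts / spacing).T
        profile = ndimage.map_coordinates(membrane.data, vox, order=1)
        k = int(np.argmax(profile))
        # centre on the arg-max plateau (interpolated profiles plateau on
        # thick membranes; the first-index bias would skew the window)
        lo = hi = k
        while lo > 0 and profile[lo - 1] == profile[k]:
            lo -= 1
        while hi < len(profile) - 1 and profile[hi + 1] == profile[k]:
            hi += 1
        k = (lo + hi) // 2
        arclen = t * length
        window = np.abs(arclen - arclen[k]) <= probe_half_width_um
        out[(min(i, j), max(i, j))] = {
            name: float(ndimage.map_coordinates(vol.data, vox, order=1)[window].mean())
            for name, vol in channels.items()
        }
    return out


def compute_ratios(nuclear_mean, cytoplasm_weighted_mean):
    """N/C ratio and its natural log; missing (None) on a zero or missing
    cytoplasmic mean rather than an exception."""
    if nuclear_mean is None or cytoplasm_weighted_mean is None:
        return None, None
    if cytoplasm_weighted_mean <= 0:
        log.warning("cytoplasmic mean <= 0: N/C ratio undefined")
        return None, None
    ratio = nuclear_mean / cytoplasm_weighted_mean
    return ratio, (math.log(ratio) if ratio > 0 else None)
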