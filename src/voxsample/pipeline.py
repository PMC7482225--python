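"""End-to-end pipelines tying detection, sampling and geometry together.

Three modes mirror the three reference types:

* ``nucleus`` — Hough nuclear detection, compartment sampling, optional
  exposed/contacting membrane readings, geometry distances;
* ``membrane_fragment`` — CLAHE + 3D Canny + RANSAC sphere fragments with
  membrane/cytoplasm disc sampling;
* ``surface_partition`` — exposed/junctional/basolateral split of supplied
  per-cell surface masks.

Every derived default scales from the user's two parameters (nuclear
diameter and brightness threshold): cytoplasm weighting sigma = one nuclear
radius, crop radius = two nuclear diameters, neighbour cutoff = 2.5
diameters. All remaining settings are derived, logged, and overridable.
"""

from __future__ import annotations

import logging

import numpy as np
from skimage.filters import threshold_otsu

from . import fragments as frag
from . import geometry, partition, sampling
from .detect import DetectionParams, derive_parameters, detect_nuclei
from .io import LabeledMask, ROISet, Volume
from .sampling import SampleRecord

log = logging.getLogger(__name__)


def _roi_distances(centre_um, roi):
    return geometry.distance_to_roi(centre_um, roi) if roi is not None else []


def run_nucleus_pipeline(channels: dict, nuclear_channel: str,
                         params: DetectionParams,
                         membrane_channel: str | None = None,
                         membrane_threshold: float | None = None,
                         roi: ROISet | None = None,
                         weight_sigma_um: float | None = None,
                         crop_radius_um: float | None = None,
                         max_edge_um: float | None = None,
                         probe_half_width_um: float = 0.5,
                         restrict_to_tissue: bool = False):
    """Nucleus-reference pipeline. Returns (records, info dict).

    ``restrict_to_tissue`` masks cytoplasm sampling to the filled membrane
    foreground; it is off by default, so sampling may reach outside the
    tissue exactly as the two-parameter interface implies (no bounding
    surface is computed).
    """
    channels = dict(channels)
    nuc_vol = channels[nuclear_channel]
    D = params.nuclear_diameter_um
    weight_sigma_um = weight_sigma_um if weight_sigma_um is not None else 0.5 * D
    crop_radius_um = crop_radius_um if crop_radius_um is not None else 2.0 * D
    max_edge_um = max_edge_um if max_edge_um is not None else 2.5 * D

    settings = derive_parameters(params, nuc_vol.spacing)
    log.info("derived detection settings: %s", settings)
    nuclei = detect_nuclei(nuc_vol, params, settings)
    info = {"n_nuclei": len(nuclei), "settings": settings}
    if not nuclei:
        log.warning("no nuclei detected")
        return [], info

    ownership = sampling.assign_voxels(nuclei, nuc_vol.shape, nuc_vol.spacing,
                                       crop_radius_um)
    classes = sampling.classify_voxels(ownership, nuc_vol,
                                       params.brightness_threshold)

    surface = None
    contacts = {}
    exposed_means = {}
    if membrane_channel is not None:
        mem_vol = channels[membrane_channel]
        if membrane_threshold is None:
            membrane_threshold = float(threshold_otsu(mem_vol.data))
            log.info("derived membrane threshold (Otsu): %.3f", membrane_threshold)
        if restrict_to_tissue:
            from scipy import ndimage as ndi
            tissue = ndi.binary_fill_holes(mem_vol.data >= membrane_threshold)
            classes = classes.copy()
            classes[~tissue] = 0
        surface = sampling.detect_exposed_membrane(mem_vol, nuclei,
                                                   membrane_threshold)
        exposed_means = sampling.sample_exposed_membrane(surface, channels, nuclei)
        graph = geometry.build_neighbour_graph(nuclei, max_edge_um)
        contacts = sampling.sample_contacting_membrane(
            nuclei, graph, channels, membrane_channel, probe_half_width_um)
        info["n_exposed_voxels"] = len(surface.voxel_indices)
        info["n_contact_pairs"] = len(contacts)

    comps = sampling.sample_compartments(ownership, classes, channels, nuclei,
                                         weight_sigma_um)
    by_nucleus = {}
    for cs in comps:
        by_nucleus.setdefault(cs.nucleus_id, {})[cs.channel] = cs

    records = []
    for nuc in sorted(nuclei, key=lambda n: n.id):
        values = {}
        for name in sorted(channels):
            cs = by_nucleus[nuc.id][name]
            if cs.nuclear_mean is not None:
                values[f"nuclear_{name}"] = cs.nuclear_mean
            if cs.cytoplasm_weighted_mean is not None:
                values[f"cytoplasm_{name}"] = cs.cytoplasm_weighted_mean
            ratio, log_nc = sampling.compute_ratios(cs.nuclear_mean,
                                                    cs.cytoplasm_weighted_mean)
            if ratio is not None:
                values[f"nc_ratio_{name}"] = ratio
            if log_nc is not None:
                values[f"log_nc_{name}"] = log_nc
            if exposed_means.get(nuc.id, {}).get(name) is not None:
                values[f"membrane_exposed_{name}"] = exposed_means[nuc.id][name]
        values["n_nuclear_voxels"] = by_nucleus[nuc.id][sorted(channels)[0]].n_nuclear_voxels
        values["n_cyto_voxels"] = by_nucleus[nuc.id][sorted(channels)[0]].n_cyto_voxels
        partner_means = {name: [] for name in channels}
        partners = []
        for (i, j), chan_means in contacts.items():
            if nuc.id in (i, j):
                partners.append(j if nuc.id == i else i)
                for name, m in chan_means.items():
                    partner_means[name].append(m)
        for name in sorted(channels):
            if partner_means[name]:
                values[f"membrane_contacting_{name}"] = float(np.mean(partner_means[name]))
        if partners:
            values["partner_ids"] = ";".join(str(p) for p in sorted(partners))
        dist = None
        if surface is not None and len(surface.voxel_indices):
            dist = geometry.distance_to_surface(nuc.centre_um, surface)
        records.append(SampleRecord(
            object_type="nucleus", object_id=nuc.id,
            centre_um=np.asarray(nuc.centre_um), radius_um=nuc.radius_um,
            values=values, distance_to_surface_um=dist,
            distance_to_roi_um=_roi_distances(nuc.centre_um, roi)))
    return records, info


def run_fragment_pipeline(channels: dict, membrane_channel: str,
                          cell_diameter_um: float, seed: int = 0,
                          clahe_clip: float = 0.01,
                          blur_sigma_um: float = 0.5,
                          low_frac: float = 0.2, high_frac: float = 0.5,
                          inlier_tol_um: float = 0.75, min_inliers: int = 30,
                          max_iter: int = 2000,
                          mask_geom: frag.FragmentMaskGeometry | None = None,
                          max_edge_points: int = 40000,
                          roi: ROISet | None = None,
                          refine: bool = True):
    """Membrane-fragment pipeline. Returns (records, info dict).

    Sphere radius bounds scale from the single cell-size estimate:
    [0.5, 3] × the cell radius. Edge clouds larger than
    ``max_edge_points`` are subsampled (seeded) before RANSAC.
    """
    channels = dict(channels)
    mem = channels[membrane_channel]
    pre = frag.preprocess_membrane(mem, clahe_clip, blur_sigma_um)
    points = frag.canny_edges_3d(pre, low_frac, high_frac)
    rng = np.random.default_rng(seed)
    if len(points) > max_edge_points:
        points = points[rng.choice(len(points), max_edge_points, replace=False)]
    radius_bounds = (0.25 * cell_diameter_um, 1.5 * cell_diameter_um)
    frags = frag.ransac_sphere_fit(points, radius_bounds, inlier_tol_um,
                                   min_inliers, max_iter,
                                   seed=int(rng.integers(2 ** 31 - 1)))
    if refine:
        frags = frag.refine_fragments(frags, mem)
    info = {"n_edge_points": len(points), "n_fragments": len(frags)}
    records = []
    for f in frags:
        values = {"fitted_radius_um": f.fitted_radius_um,
                  "inlier_count": f.inlier_count}
        partial = False
        for fs in [s for name in sorted(channels)
                   for s in frag.sample_fragment(f, {name: channels[name]}, mask_geom)]:
            name = fs.channel
            if fs.membrane_mean is not None:
                values[f"membrane_{name}"] = fs.membrane_mean
            if fs.cytoplasm_side_a_mean is not None:
                values[f"cytoplasm_side_a_{name}"] = fs.cytoplasm_side_a_mean
            if fs.cytoplasm_side_b_mean is not None:
                values[f"cytoplasm_side_b_{name}"] = fs.cytoplasm_side_b_mean
            partial |= fs.partial
        values["partial"] = int(partial)
        records.append(SampleRecord(
            object_type="membrane_fragment", object_id=f.id,
            centre_um=f.surface_point_um, radius_um=None, values=values,
            distance_to_roi_um=_roi_distances(f.surface_point_um, roi)))
    return records, info


def run_partition_pipeline(mask: LabeledMask, channels: dict,
                           junction_band_um: float = 1.0,
                           lumen_exposed: bool = True,
                           roi: ROISet | None = None):
    """Surface-partition pipeline over supplied per-cell masks."""
    channels = dict(channels)
    surfaces = partition.extract_surfaces(mask)
    parts = partition.partition_domains(surfaces, mask, junction_band_um,
                                        lumen_exposed=lumen_exposed)
    partition.quantify_domains(parts, channels)
    spacing = np.asarray(mask.spacing)
    records = []
    for part in parts:
        vox = np.concatenate([part.voxels[d] for d in partition.DOMAINS])
        centre = vox.mean(axis=0) * spacing
        values = {"exposed_fraction": part.exposed_fraction}
        for dom in partition.DOMAINS:
            values[f"n_{dom}_voxels"] = part.counts[dom]
            for name in sorted(channels):
                m = part.means[dom][name]
                if m is not None:
                    values[f"{dom}_{name}"] = m
        records.append(SampleRecord(
            object_type="cell_surface", object_id=part.cell_id,
            centre_um=centre, values=values,
            distance_to_roi_um=_roi_distances(centre, roi)))
    return records, {"n_cells": len(parts)}
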