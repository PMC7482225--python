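"""Nucleus-free membrane reference detection.

When no nuclear stain is available, membrane patches themselves serve as the
points of reference. The membrane channel is contrast-normalized (per-slice
CLAHE) and blurred, a 3D Canny detector extracts a thin edge point cloud, and
spheres are fitted to that cloud with a sequential, outlier-tolerant RANSAC.
Each accepted sphere is broken into local fragments — (surface point, inward
normal) pairs — which act as sampling masks: a thin tangent disc reads the
membrane fluorescence, and matching discs displaced along the normal read the
cytoplasm on either side.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import exposure

from .io import Volume

log = logging.getLogger(__name__)


def preprocess_membrane(volume: Volume, clahe_clip: float = 0.01,
                        blur_sigma_um: float = 0.5) -> Volume:
    """Per-slice CLAHE then anisotropy-corrected 3D Gaussian blur.

    Constant slices are left untouched (CLAHE of a flat image is flat).
    The output intensity scale is [0, 1]; it feeds the edge detector only.
    """
    data = volume.data
    peak = float(data.max())
    out = np.empty_like(data, dtype=np.float64)
    for z in range(data.shape[0]):
        sl = data[z]
        if sl.max() == sl.min():
            out[z] = 0.0 if peak == 0 else sl / peak
        else:
            out[z] = exposure.equalize_adapthist(sl / peak, clip_limit=clahe_clip)
    sigma_vox = [blur_sigma_um / s for s in volume.spacing]
    out = ndimage.gaussian_filter(out, sigma_vox)
    return Volume(out, volume.spacing, channel_name=volume.channel_name)


def canny_edges_3d(volume: Volume, low_frac: float = 0.2,
                   high_frac: float = 0.5, sigma_vox: float = 1.0) -> np.ndarray:
    """3D Canny edge detection; returns edge-voxel centres in µm (z, y, x).

    Gradients come from Gaussian-derivative filters per axis (scaled to
    physical units), non-maximum suppression runs along the quantized 3D
    gradient direction, and double hysteresis keeps weak edges only when
    26-connected to a strong one. Thresholds are fractions of the maximum
    gradient magnitude.
    """
    data = volume.data.astype(np.float64)
    spacing = np.asarray(volume.spacing)
    grads = []
    for axis in range(3):
        order = [0, 0, 0]
        order[axis] = 1
        grads.append(ndimage.gaussian_filter(data, sigma_vox, order=order)
                     / spacing[axis])
    mag = np.sqrt(sum(g * g for g in grads))
    peak = float(mag.max())
    if peak == 0:
        return np.empty((0, 3))
    # direction of steepest ascent, expressed in index space
    steps = [g / spacing[a] for a, g in enumerate(grads)]
    norm = np.maximum(np.max(np.abs(steps), axis=0), 1e-300)
    offsets = [np.rint(s / norm).astype(np.int8) for s in steps]

    padded = np.pad(mag, 1, constant_values=0.0)
    idx = np.indices(mag.shape)
    fwd = padded[tuple(idx[a] + 1 + offsets[a] for a in range(3))]
    bwd = padded[tuple(idx[a] + 1 - offsets[a] for a in range(3))]
    nms = (mag >= fwd) & (mag > bwd) & (mag > 0)

    weak = nms & (mag >= low_frac * peak)
    strong = nms & (mag >= high_frac * peak)
    if not strong.any():
        return np.empty((0, 3))
    lab, _ = ndimage.label(weak, structure=np.ones((3, 3, 3), bool))
    keep = np.unique(lab[strong])
    edges = weak & np.isin(lab, keep[keep > 0])
    return np.argwhere(edges) * spacing


@dataclass
class MembraneFragment:
    """A locally fitted sphere patch.

    The normal is a unit vector pointing from the surface point toward the
    fitted sphere's centre (the membrane curvature direction).
    """

    id: int
    surface_point_um: np.ndarray  # (z, y, x)
    normal: np.ndarray  # unit, (z, y, x), toward sphere centre
    fitted_radius_um: float
    inlier_count: int
    sphere_centre_um: np.ndarray


def _sphere_through_4(pts: np.ndarray):
    """Exact sphere through 4 non-coplanar points, or None if degenerate."""
    A = np.column_stack([pts, np.ones(4)])
    b = -np.sum(pts * pts, axis=1)
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(sol)):
        return None
    centre = -sol[:3] / 2.0
    r2 = float(centre @ centre - sol[3])
    if r2 <= 0:
        return None
    return centre, math.sqrt(r2)


def _sphere_lsq(pts: np.ndarray):
    """Algebraic least-squares sphere through >= 4 points."""
    A = np.column_stack([pts, np.ones(len(pts))])
    b = -np.sum(pts * pts, axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    centre = -sol[:3] / 2.0
    r2 = float(centre @ centre - sol[3])
    if r2 <= 0:
        return None
    return centre, math.sqrt(r2)


def _bin_fragments(inlier_pts, centre, radius, inlier_count, start_id,
                   min_bin_points):
    """One fragment per non-empty ~45° angular bin of a sphere's inliers.

    Bin centroids are projected onto the fitted sphere (a chord centroid lies
    inside it), and the normal points inward toward the centre.
    """
    rel = inlier_pts - centre
    d = np.linalg.norm(rel, axis=1)
    ok = d > 0
    rel, d = rel[ok], d[ok]
    theta = np.arccos(np.clip(rel[:, 0] / d, -1.0, 1.0))  # polar from +z
    phi = np.arctan2(rel[:, 1], rel[:, 2])  # azimuth in (y, x) plane
    tbin = np.minimum((theta / (math.pi / 4)).astype(int), 3)
    pbin = np.minimum(((phi + math.pi) / (math.pi / 4)).astype(int), 7)
    frags = []
    for code in np.unique(tbin * 8 + pbin):
        sel = (tbin * 8 + pbin) == code
        if sel.sum() < min_bin_points:
            continue
        centroid = inlier_pts[ok][sel].mean(axis=0)
        u = centroid - centre
        nu = np.linalg.norm(u)
        if nu == 0:
            continue
        u /= nu
        surface = centre + radius * u
        frags.append(MembraneFragment(start_id + len(frags), surface, -u,
                                      float(radius), int(inlier_count),
                                      centre.copy()))
    return frags


def ransac_sphere_fit(points_um: np.ndarray, radius_bounds_um,
                      inlier_tol_um: float = 0.75, min_inliers: int = 30,
                      max_iter: int = 2000, seed: int = 0,
                      min_bin_points: int = 5) -> list[MembraneFragment]:
    """Sequential multi-sphere RANSAC over an edge point cloud.

    Repeatedly: draw a seed point and three spatial neighbours, solve the
    exact sphere through the four (degenerate samples are rejected and
    redrawn), and count points within ``inlier_tol_um`` of the surface. The
    best model is accepted when it has >= ``min_inliers`` inliers and a
    radius within bounds; its centre/radius are refined by least squares on
    the inliers, the inliers are removed, and the search repeats until no
    acceptable model remains. Each accepted sphere is emitted as angular-bin
    fragments. Reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    pts = np.asarray(points_um, dtype=float)
    r_lo, r_hi = radius_bounds_um
    fragments: list[MembraneFragment] = []
    while len(pts) >= max(4, min_inliers):
        tree = cKDTree(pts)
        neigh_r = 1.5 * r_hi
        best_count, best_model = 0, None
        needed = max_iter
        it = 0
        while it < min(needed, max_iter):
            it += 1
            i = int(rng.integers(len(pts)))
            nb = tree.query_ball_point(pts[i], neigh_r)
            if len(nb) < 4:
                continue
            nb = np.asarray(nb)
            sel = rng.choice(nb, size=4, replace=False)
            model = _sphere_through_4(pts[sel])
            if model is None:
                continue
            centre, radius = model
            if not (r_lo <= radius <= r_hi):
                continue
            resid = np.abs(np.linalg.norm(pts - centre, axis=1) - radius)
            count = int((resid <= inlier_tol_um).sum())
            if count > best_count:
                best_count, best_model = count, (centre, radius)
                w = best_count / len(pts)
                if 0 < w < 1:
                    needed = math.log(1e-3) / math.log(1 - w ** 4)
                else:
                    needed = it
        if best_model is None or best_count < min_inliers:
            break
        centre, radius = best_model
        inl = np.abs(np.linalg.norm(pts - centre, axis=1) - radius) <= inlier_tol_um
        refined = _sphere_lsq(pts[inl])
        if refined is not None and r_lo <= refined[1] <= r_hi:
            centre, radius = refined
            inl = np.abs(np.linalg.norm(pts - centre, axis=1) - radius) <= inlier_tol_um
        if int(inl.sum()) < min_inliers:
            break
        fragments.extend(_bin_fragments(pts[inl], centre, radius, int(inl.sum()),
                                        len(fragments), min_bin_points))
        pts = pts[~inl]
    return fragments


def refine_fragments(fragments, membrane_channel: Volume,
                     search_um: float = 2.0) -> list[MembraneFragment]:
    """Snap each fragment to the membrane-intensity ridge along its normal.

    Canny edges flank the membrane ridge (both faces of the stained shell)
    rather than tracking its midline, so the fitted sphere sits off-centre by
    up to the shell half-width plus blur. Each surface point is moved along
    its normal to the arg-max of the raw membrane channel within
    ±``search_um``, keeping the fitted normal.
    """
    spacing = np.asarray(membrane_channel.spacing)
    step = 0.25 * float(spacing.min())
    offsets = np.arange(-search_um, search_um + step / 2, step)
    out = []
    for f in fragments:
        pts = f.surface_point_um[None] + offsets[:, None] * f.normal[None]
        vox = (pts / spacing).T
        profile = ndimage.map_coordinates(membrane_channel.data, vox, order=1,
                                          mode="constant", cval=0.0)
        k = int(np.argmax(profile))
        out.append(MembraneFragment(f.id, pts[k], f.normal, f.fitted_radius_um,
                                    f.inlier_count, f.sphere_centre_um))
    return out


@dataclass
class FragmentMaskGeometry:
    """Sampling-mask dimensions around a fragment, micrometres."""

    tangent_radius_um: float = 1.0
    thickness_um: float = 0.5
    offset_um: float = 1.5


@dataclass
class FragmentSample:
    fragment_id: int
    channel: str
    membrane_mean: float | None
    cytoplasm_side_a_mean: float | None  # toward the sphere centre
    cytoplasm_side_b_mean: float | None
    partial: bool = False


def _tangent_basis(normal: np.ndarray):
    e = np.zeros(3)
    e[np.argmin(np.abs(normal))] = 1.0
    t1 = np.cross(normal, e)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(normal, t1)
    return t1, t2


def sample_fragment(fragment: MembraneFragment, channels,
                    mask_geom: FragmentMaskGeometry | None = None) -> list[FragmentSample]:
    """Sample membrane and flanking cytoplasm around one fragment.

    The membrane reading averages a thin disc tangent to the fitted sphere at
    the surface point; the two cytoplasm readings average matching discs
    displaced ±``offset_um`` along the normal (side a toward the sphere
    centre). Discs partially outside the volume flag the sample partial.
    """
    if mask_geom is None:
        mask_geom = FragmentMaskGeometry()
    channels = dict(channels)
    spacing = np.asarray(next(iter(channels.values())).spacing)
    step = 0.5 * float(spacing.min())
    r = mask_geom.tangent_radius_um
    g = np.arange(-r, r + step / 2, step)
    uu, vv = np.meshgrid(g, g, indexing="ij")
    disc = np.stack([uu[uu ** 2 + vv ** 2 <= r ** 2],
                     vv[uu ** 2 + vv ** 2 <= r ** 2]], axis=1)
    n_th = max(1, int(round(mask_geom.thickness_um / step)) + 1)
    ws = np.linspace(-mask_geom.thickness_um / 2, mask_geom.thickness_um / 2, n_th)
    t1, t2 = _tangent_basis(fragment.normal)

    samples = []
    base = fragment.surface_point_um
    offs = {"membrane": 0.0, "side_a": mask_geom.offset_um,
            "side_b": -mask_geom.offset_um}
    pts_by_region = {}
    for region, off in offs.items():
        centres = base + off * fragment.normal
        pts = (centres[None, None]
               + disc[:, 0][:, None, None] * t1[None, None]
               + disc[:, 1][:, None, None] * t2[None, None]
               + (ws[None, :, None] * fragment.normal[None, None]))
        pts_by_region[region] = pts.reshape(-1, 3)

    for name, vol in channels.items():
        means, partial = {}, False
        for region, pts in pts_by_region.items():
            vox = (pts / spacing).T
            vals = ndimage.map_coordinates(vol.data, vox, order=1,
                                           mode="constant", cval=np.nan)
            inside = np.isfinite(vals)
            if not inside.all():
                partial = True
            means[region] = float(vals[inside].mean()) if inside.any() else None
        samples.append(FragmentSample(fragment.id, name, means["membrane"],
                                      means["side_a"], means["side_b"], partial))
    return samples
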