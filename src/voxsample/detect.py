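"""Nuclear centre-of-mass detection in 3D.

The nuclear stain is analysed slice by slice: each z-section is blurred,
thresholded, and its binary boundary fed to a circular Hough transform, so
circular nuclear cross-sections appear as accumulator peaks. Peaks are then
linked across consecutive slices into chains; each sufficiently long chain
yields one nucleus at the vote-weighted mean of its members. The whole path
is driven by two user parameters — an estimate of the nuclear diameter and a
brightness threshold for the nuclear channel — with every internal setting
derived from those two plus the voxel spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.transform import hough_circle

from .io import Volume


class ResolutionError(ValueError):
    """Nuclear diameter too small for the in-plane voxel size."""


@dataclass
class DetectionParams:
    """The two user-supplied parameters."""

    nuclear_diameter_um: float
    brightness_threshold: float

    def __post_init__(self):
        if self.nuclear_diameter_um <= 0:
            raise ValueError("nuclear diameter must be > 0")
        if self.brightness_threshold < 0:
            raise ValueError("brightness threshold must be >= 0")


@dataclass
class DetectionSettings:
    """Internal settings, all pure functions of DetectionParams and spacing.

    radius_band_vox : (r_min, r_max) Hough search radii, in-plane voxels —
        0.3–0.7 of the nuclear diameter, tolerating off-equator sections.
    blur_sigma_vox : Gaussian sigma before thresholding (diameter / 8).
    peak_threshold : accumulator fraction of a full circle's vote (0.4).
    link_radius_vox : max in-plane drift when chaining detections across
        slices (half a nuclear radius).
    min_slices : minimum chain length — a true sphere must span about half
        its diameter in z.
    """

    radius_band_vox: tuple
    blur_sigma_vox: float
    peak_threshold: float
    link_radius_vox: float
    min_slices: int
    xy_spacing_um: float
    z_spacing_um: float


@dataclass
class CircleDetection:
    slice_index: int
    centre_xy: tuple  # (x, y), voxels
    radius: float  # voxels
    vote_score: float


@dataclass
class Nucleus:
    """A detected nuclear centre of mass."""

    id: int
    centre_um: np.ndarray  # (z, y, x), micrometres
    radius_um: float
    supporting_slices: list = field(default_factory=list)


def derive_parameters(params: DetectionParams, spacing) -> DetectionSettings:
    """Derive every internal detection setting from the two user inputs."""
    sz, sy, sx = spacing
    xy = 0.5 * (sy + sx)
    d_vox = params.nuclear_diameter_um / xy
    if d_vox < 2.0:
        raise ResolutionError(
            f"nuclear diameter {params.nuclear_diameter_um} µm spans fewer than "
            f"2 in-plane voxels at spacing {xy} µm"
        )
    r_min = max(1, int(round(0.3 * d_vox)))
    r_max = max(r_min + 1, int(round(0.7 * d_vox)))
    return DetectionSettings(
        radius_band_vox=(r_min, r_max),
        blur_sigma_vox=d_vox / 8.0,
        peak_threshold=0.4,
        link_radius_vox=0.25 * d_vox,
        min_slices=max(2, math.ceil(0.5 * params.nuclear_diameter_um / sz)),
        xy_spacing_um=xy,
        z_spacing_um=sz,
    )


def _slice_edges(slice2d: np.ndarray, settings: DetectionSettings, threshold: float):
    blurred = ndimage.gaussian_filter(np.asarray(slice2d, dtype=float),
                                      settings.blur_sigma_vox)
    binary = blurred >= threshold
    if not binary.any():
        return None
    return binary & ~ndimage.binary_erosion(binary)


def hough_circles_2d(slice2d: np.ndarray, settings: DetectionSettings,
                     threshold: float, slice_index: int = 0):
    """Detect circular cross-sections on one slice.

    Returns accumulator maxima above ``peak_threshold`` (fraction of a full
    circle's perimeter vote), greedily non-maximum-suppressed so no two
    detections lie closer than the lower search-band radius.
    """
    r_min, r_max = settings.radius_band_vox
    edges = _slice_edges(slice2d, settings, threshold)
    if edges is None or not edges.any():
        return []
    radii = np.arange(r_min, r_max + 1)
    accum = hough_circle(edges, radii, normalize=True)
    candidates = []
    for a, r in zip(accum, radii):
        for (y, x) in peak_local_max(a, min_distance=r_min,
                                     threshold_abs=settings.peak_threshold):
            candidates.append((float(a[y, x]), float(x), float(y), float(r)))
    # greedy NMS across radii, deterministic ordering
    candidates.sort(key=lambda c: (-c[0], c[2], c[1], c[3]))
    kept = []
    for vote, x, y, r in candidates:
        if all((x - k.centre_xy[0]) ** 2 + (y - k.centre_xy[1]) ** 2 >= r_min ** 2
               for k in kept):
            kept.append(CircleDetection(slice_index, (x, y), r, vote))
    return kept


class _Chain:
    __slots__ = ("members", "w", "wx", "wy", "last_slice")

    def __init__(self, det: CircleDetection):
        self.members = [det]
        self.w = det.vote_score
        self.wx = det.vote_score * det.centre_xy[0]
        self.wy = det.vote_score * det.centre_xy[1]
        self.last_slice = det.slice_index

    @property
    def mean_xy(self):
        return self.wx / self.w, self.wy / self.w

    def add(self, det: CircleDetection):
        self.members.append(det)
        self.w += det.vote_score
        self.wx += det.vote_score * det.centre_xy[0]
        self.wy += det.vote_score * det.centre_xy[1]
        self.last_slice = det.slice_index


def link_circles_3d(per_slice, settings: DetectionSettings, spacing):
    """Greedy chain-building across consecutive slices.

    A detection joins the open chain whose running (vote-weighted) mean centre
    is nearest and within ``link_radius_vox``; ties go to the chain with more
    members. Chains shorter than ``min_slices`` are discarded; survivors yield
    one nucleus each at the vote-weighted mean position, in micrometres.
    """
    sz, sy, sx = spacing
    xy = settings.xy_spacing_um
    open_chains: list[_Chain] = []
    closed: list[_Chain] = []
    for z, dets in enumerate(per_slice):
        still_open = []
        for c in open_chains:
            (closed if c.last_slice < z - 1 else still_open).append(c)
        open_chains = still_open
        # strongest detections claim chains first (deterministic)
        for det in sorted(dets, key=lambda d: (-d.vote_score,
                                               d.centre_xy[1], d.centre_xy[0])):
            best = None
            for c in open_chains:
                if c.last_slice != z - 1:
                    continue  # one detection per chain per slice
                mx, my = c.mean_xy
                d2 = (det.centre_xy[0] - mx) ** 2 + (det.centre_xy[1] - my) ** 2
                if d2 > settings.link_radius_vox ** 2:
                    continue
                key = (d2, -len(c.members))
                if best is None or key < best[0]:
                    best = (key, c)
            if best is not None:
                best[1].add(det)
            else:
                open_chains.append(_Chain(det))
    closed.extend(open_chains)

    nuclei = []
    for chain in closed:
        if len(chain.members) < settings.min_slices:
            continue
        w = np.array([m.vote_score for m in chain.members])
        zs = np.array([m.slice_index for m in chain.members], dtype=float)
        xs = np.array([m.centre_xy[0] for m in chain.members])
        ys = np.array([m.centre_xy[1] for m in chain.members])
        zbar = float(np.sum(w * zs) / w.sum())
        xbar = float(np.sum(w * xs) / w.sum())
        ybar = float(np.sum(w * ys) / w.sum())
        radius_um = max(m.radius for m in chain.members) * xy
        centre_um = np.array([zbar * sz, ybar * sy, xbar * sx])
        nuclei.append(Nucleus(-1, centre_um, radius_um,
                              sorted(m.slice_index for m in chain.members)))
    # deterministic ids by position
    nuclei.sort(key=lambda n: tuple(n.centre_um))
    for i, n in enumerate(nuclei):
        n.id = i
    return nuclei


def detect_nuclei(volume: Volume, params: DetectionParams,
                  settings: DetectionSettings | None = None):
    """Full 3D detection: per-slice Hough voting, then cross-slice linking.

    Deterministic given its inputs. Returns an empty list (not an error) when
    nothing is detected.
    """
    if settings is None:
        settings = derive_parameters(params, volume.spacing)
    per_slice = [
        hough_circles_2d(volume.data[z], settings, params.brightness_threshold,
                         slice_index=z)
        for z in range(volume.shape[0])
    ]
    return link_circles_3d(per_slice, settings, volume.spacing)
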