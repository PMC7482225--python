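"""Voxel ownership, compartment classification and fluorescence sampling."""

import numpy as np
import pytest

from voxsample.detect import Nucleus
from voxsample.geometry import NeighbourGraph
from voxsample.io import Volume
from voxsample.phantoms import NUCLEUS as NUC_CODE
from voxsample.sampling import (CYTOPLASMIC, NUCLEAR, assign_voxels,
                                classify_voxels, compute_ratios,
                                detect_exposed_membrane, sample_compartments,
                                sample_contacting_membrane)


def _nuclei(centres_um):
    return [Nucleus(i, np.asarray(c, dtype=float), 4.0)
            for i, c in enumerate(centres_um)]


def brute_force_ownership(centres_um, shape, spacing, crop_um):
    """Independent all-pairs nearest-centre scan (argmin = lowest id wins)."""
    sz, sy, sx = spacing
    zz, yy, xx = np.meshgrid(np.arange(shape[0]) * sz,
                             np.arange(shape[1]) * sy,
                             np.arange(shape[2]) * sx, indexing="ij")
    stacks = []
    for cz, cy, cx in centres_um:
        stacks.append((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2)
    d2 = np.stack(stacks)
    owner = np.argmin(d2, axis=0).astype(np.int32)
    owner[np.min(d2, axis=0) > crop_um ** 2] = -1
    return owner


class TestAssignVoxels:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_including_tie_breaks(self, seed):
        rng = np.random.default_rng(seed)
        shape = (32, 32, 32)
        spacing = (1.0, 0.7, 0.7)
        n = int(rng.integers(2, 21))
        centres = rng.uniform(2, 28, size=(n, 3)) * np.array(spacing)
        # include integer centres so exact ties occur
        centres[: n // 2] = np.round(centres[: n // 2])
        owner = assign_voxels(_nuclei(centres), shape, spacing, crop_um := 12.0)
        oracle = brute_force_ownership(centres, shape, spacing, crop_um)
        np.testing.assert_array_equal(owner, oracle)

    def test_equidistant_voxel_goes_to_lower_id(self):
        owner = assign_voxels(_nuclei([(0, 0, 0), (0, 0, 4)]),
                              (1, 1, 5), (1, 1, 1), 10.0)
        assert owner[0, 0, 2] == 0  # exactly between the two nuclei

    def test_single_nucleus_crop_is_a_ball(self):
        owner = assign_voxels(_nuclei([(10, 10, 10)]), (21, 21, 21),
                              (1, 1, 1), 5.0)
        zz, yy, xx = np.meshgrid(*[np.arange(21)] * 3, indexing="ij")
        inside = (zz - 10) ** 2 + (yy - 10) ** 2 + (xx - 10) ** 2 <= 25
        np.testing.assert_array_equal(owner >= 0, inside)

    def test_zero_nuclei_rejected(self):
        with pytest.raises(ValueError):
            assign_voxels([], (4, 4, 4), (1, 1, 1), 5.0)


class TestClassifyVoxels:
    def test_threshold_zero_makes_every_assigned_voxel_nuclear(self):
        vol = Volume(np.random.default_rng(0).uniform(0, 10, (8, 8, 8)),
                     (1, 1, 1))
        owner = assign_voxels(_nuclei([(4, 4, 4)]), vol.shape, (1, 1, 1), 20.0)
        classes = classify_voxels(owner, vol, 0.0)
        assert np.all(classes[owner >= 0] == NUCLEAR)

    def test_threshold_above_max_makes_every_assigned_voxel_cytoplasmic(self):
        vol = Volume(np.random.default_rng(0).uniform(0, 10, (8, 8, 8)),
                     (1, 1, 1))
        owner = assign_voxels(_nuclei([(4, 4, 4)]), vol.shape, (1, 1, 1), 20.0)
        classes = classify_voxels(owner, vol, 11.0)
        assert np.all(classes[owner >= 0] == CYTOPLASMIC)

    def test_phantom_classes_match_ground_truth(self, separated_phantom):
        channels, truth, spec = separated_phantom
        vol = channels["nuclear"]
        owner = assign_voxels(_nuclei(truth.centres_um), vol.shape,
                              vol.spacing, 12.0)
        classes = classify_voxels(owner, vol, 120.0)
        sel = owner >= 0
        np.testing.assert_array_equal(classes[sel] == NUCLEAR,
                                      truth.class_map[sel] == NUC_CODE)


class TestSampleCompartments:
    def test_uniform_cytoplasm_mean_is_exact_for_any_sigma(self):
        data = np.full((9, 9, 9), 37.0)
        data[4, 4, 4] = 200.0
        vol = Volume(data, (1, 1, 1))
        nuclei = _nuclei([(4, 4, 4)])
        owner = assign_voxels(nuclei, vol.shape, (1, 1, 1), 20.0)
        classes = classify_voxels(owner, vol, 100.0)
        for sigma in (0.5, 2.0, 10.0):
            cs = sample_compartments(owner, classes, {"c": vol}, nuclei, sigma)[0]
            assert cs.cytoplasm_weighted_mean == pytest.approx(37.0)
            assert cs.nuclear_mean == pytest.approx(200.0)

    def test_two_voxel_cytoplasm_matches_hand_computed_weights(self):
        # nucleus at origin voxel; cytoplasm voxels at distances 2 and 4 µm
        data = np.zeros((1, 1, 5))
        data[0, 0, 0] = 300.0  # nuclear
        a, b = 80.0, 20.0
        data[0, 0, 2] = a
        data[0, 0, 4] = b
        vol = Volume(data, (1.0, 1.0, 1.0))
        nuclei = _nuclei([(0, 0, 0)])
        owner = np.zeros(vol.shape, np.int32)
        classes = np.full(vol.shape, CYTOPLASMIC, np.int8)
        classes[0, 0, 0] = NUCLEAR
        classes[0, 0, 1] = classes[0, 0, 3] = 0  # unclassified spacers
        sigma = 3.0
        w1, w2 = np.exp(-4 / (2 * sigma**2)), np.exp(-16 / (2 * sigma**2))
        expected = (w1 * a + w2 * b) / (w1 + w2)
        cs = sample_compartments(owner, classes, {"c": vol}, nuclei, sigma)[0]
        assert cs.cytoplasm_weighted_mean == pytest.approx(expected, rel=1e-12)

    def test_empty_compartment_yields_missing_mean(self):
        vol = Volume(np.full((3, 3, 3), 9.0), (1, 1, 1))
        nuclei = _nuclei([(1, 1, 1)])
        owner = np.zeros(vol.shape, np.int32)
        classes = np.full(vol.shape, NUCLEAR, np.int8)
        cs = sample_compartments(owner, classes, {"c": vol}, nuclei, 2.0)[0]
        assert cs.cytoplasm_weighted_mean is None
        assert cs.n_cyto_voxels == 0

    def test_means_invariant_under_id_permutation(self, separated_phantom):
        channels, truth, spec = separated_phantom
        vol = channels["nuclear"]
        fwd = _nuclei(truth.centres_um)
        rev = [Nucleus(len(fwd) - 1 - i, np.asarray(c, float), 4.0)
               for i, c in enumerate(truth.centres_um)]
        out = {}
        for tag, nuclei in (("fwd", fwd), ("rev", rev)):
            owner = assign_voxels(nuclei, vol.shape, vol.spacing, 12.0)
            classes = classify_voxels(owner, vol, 120.0)
            comps = sample_compartments(owner, classes, {"s": channels["signal"]},
                                        nuclei, 3.0)
            centre_of = {n.id: tuple(n.centre_um) for n in nuclei}
            out[tag] = {centre_of[c.nucleus_id]:
                        (c.nuclear_mean, c.cytoplasm_weighted_mean)
                        for c in comps}
        assert out["fwd"] == out["rev"]

    def test_snr10_noise_shifts_means_less_than_3_percent(
            self, separated_phantom, noisy_separated_phantom):
        clean_ch, truth, spec = separated_phantom
        noisy_ch, _, _ = noisy_separated_phantom
        nuclei = _nuclei(truth.centres_um)
        res = []
        for channels in (clean_ch, noisy_ch):
            vol = channels["nuclear"]
            owner = assign_voxels(nuclei, vol.shape, vol.spacing, 12.0)
            classes = classify_voxels(owner, vol, 120.0)
            res.append(sample_compartments(owner, classes,
                                           {"s": channels["signal"]},
                                           nuclei, 3.0))
        for c0, c1 in zip(*res):
            assert abs(c1.nuclear_mean - c0.nuclear_mean) / c0.nuclear_mean < 0.03
            assert abs(c1.cytoplasm_weighted_mean - c0.cytoplasm_weighted_mean) \
                / c0.cytoplasm_weighted_mean < 0.03


class TestExposedMembrane:
    def test_single_sphere_surface_all_assigned_to_its_nucleus(self):
        zz, yy, xx = np.meshgrid(*[np.arange(31)] * 3, indexing="ij")
        d = np.sqrt((zz - 15.0) ** 2 + (yy - 15.0) ** 2 + (xx - 15.0) ** 2)
        vol = Volume(np.where(d <= 10, 200.0, 0.0), (1, 1, 1))
        nuclei = _nuclei([(15, 15, 15)])
        surf = detect_exposed_membrane(vol, nuclei, 100.0)
        assert len(surf.voxel_indices) > 0
        assert np.all(surf.owner_ids == 0)
        radii = np.linalg.norm(surf.voxel_indices - 15.0, axis=1)
        assert radii.min() > 8.5 and radii.max() <= 10.0

    def test_interface_between_touching_cells_is_not_exposed(self):
        zz, yy, xx = np.meshgrid(np.arange(25), np.arange(25), np.arange(41),
                                 indexing="ij")
        d1 = np.sqrt((zz - 12.0) ** 2 + (yy - 12.0) ** 2 + (xx - 12.0) ** 2)
        d2 = np.sqrt((zz - 12.0) ** 2 + (yy - 12.0) ** 2 + (xx - 28.0) ** 2)
        fg = (d1 <= 10) | (d2 <= 10)
        vol = Volume(np.where(fg, 200.0, 0.0), (1, 1, 1))
        surf = detect_exposed_membrane(vol, _nuclei([(12, 12, 12),
                                                     (12, 12, 28)]), 100.0)
        # on the bisector plane only the outer waist rim (radius ~6) is
        # exposed; interface voxels nearer the axis are interior
        interface = surf.voxel_indices[surf.voxel_indices[:, 2] == 20]
        assert len(interface) > 0
        assert all(np.hypot(v[0] - 12, v[1] - 12) > 4.5 for v in interface)
        # poles along x are exposed
        mask = surf.mask
        assert mask[12, 12, 2] and mask[12, 12, 38]

    def test_empty_foreground_gives_empty_surface(self):
        vol = Volume(np.zeros((5, 5, 5)), (1, 1, 1))
        surf = detect_exposed_membrane(vol, _nuclei([(2, 2, 2)]), 10.0)
        assert len(surf.voxel_indices) == 0


class TestContactingMembrane:
    def _graph(self, edges):
        g = NeighbourGraph()
        g.edges = list(edges)
        return g

    def test_bright_midplane_is_found_at_segment_midpoint(self):
        data = np.full((9, 21, 21), 20.0)
        data[:, :, 9:12] = 180.0  # 3-voxel plane so interpolation plateaus
        vol = Volume(data, (1, 1, 1))
        nuclei = _nuclei([(4, 10, 3), (4, 10, 17)])
        out = sample_contacting_membrane(nuclei, self._graph([(0, 1)]),
                                         {"m": vol}, "m", 0.5)
        assert out[(0, 1)]["m"] == pytest.approx(180.0, rel=0.05)

    def test_isolated_nucleus_has_no_contact_sample(self):
        vol = Volume(np.full((5, 5, 5), 10.0), (1, 1, 1))
        out = sample_contacting_membrane(_nuclei([(2, 2, 2)]),
                                         self._graph([]), {"m": vol}, "m")
        assert out == {}

    def test_collinear_middle_nucleus_samples_both_flanks(self):
        data = np.full((9, 9, 41), 20.0)
        data[:, :, 9:12] = 150.0
        data[:, :, 29:32] = 170.0
        vol = Volume(data, (1, 1, 1))
        nuclei = _nuclei([(4, 4, 3), (4, 4, 20), (4, 4, 37)])
        out = sample_contacting_membrane(nuclei, self._graph([(0, 1), (1, 2)]),
                                         {"m": vol}, "m", 0.5)
        assert out[(0, 1)]["m"] == pytest.approx(150.0, rel=0.05)
        assert out[(1, 2)]["m"] == pytest.approx(170.0, rel=0.05)


class TestComputeRatios:
    @pytest.mark.parametrize("nuc,cyt,ratio,log_nc", [
        (100.0, 100.0, 1.0, 0.0),
        (200.0, 100.0, 2.0, np.log(2.0)),
    ])
    def test_ratio_and_natural_log(self, nuc, cyt, ratio, log_nc):
        r, l = compute_ratios(nuc, cyt)
        assert r == pytest.approx(ratio)
        assert l == pytest.approx(log_nc)

    def test_zero_or_missing_cytoplasm_gives_missing_not_error(self):
        assert compute_ratios(100.0, 0.0) == (None, None)
        assert compute_ratios(None, 50.0) == (None, None)


class TestPhantomAccuracy:
    def test_nuclear_and_cytoplasm_error_below_10_percent(
            self, noisy_separated_phantom):
        channels, truth, spec = noisy_separated_phantom
        vol = channels["nuclear"]
        nuclei = _nuclei(truth.centres_um)
        owner = assign_voxels(nuclei, vol.shape, vol.spacing, 12.0)
        classes = classify_voxels(owner, vol, 120.0)
        errs = []
        for name, ch in channels.items():
            tbl = truth.intensities[name]
            for cs in sample_compartments(owner, classes, {name: ch}, nuclei, 3.0):
                errs.append(abs(cs.nuclear_mean - tbl["nucleus"]) / tbl["nucleus"])
                errs.append(abs(cs.cytoplasm_weighted_mean - tbl["cytoplasm"])
                            / tbl["cytoplasm"])
        assert float(np.mean(errs)) < 0.10
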