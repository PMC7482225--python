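# voxsample

Sampling-based quantification of nuclear, cytoplasmic and membrane
fluorescence in crowded, noisy 3D tissue volumes.

Full 3D cell segmentation fails exactly where developmental biologists need
quantification most: dense tissues, mediocre signal-to-noise, features that
blur into each other deep in the stack. voxsample sidesteps segmentation.
It detects the features that *are* robustly resolvable — nuclei, via
per-slice circular Hough voting linked across slices, or membrane patches,
via 3D Canny edges with RANSAC sphere fitting — and then samples the
fluorescence of each subcellular compartment around those reference points:

* **nuclear mean** — unweighted over the voxels above the nuclear-stain
  threshold owned by each nucleus;
* **cytoplasmic mean** — distance-weighted (w = exp(−d²/2σ²), σ = one
  nuclear radius), reflecting the probability that a voxel at distance d
  still belongs to the same cell;
* **membrane readings** — the exposed (outward-facing) surface per nucleus,
  and the contacting membrane located at the intensity peak on the segment
  between neighbouring nuclei (Delaunay neighbourhood).

From these it reports, per detected object and channel, the
nuclear-to-cytoplasmic ratio N/C = Ī_nuc / Ī_cyt and ln(N/C) — the standard
normalization for shuttling proteins such as YAP — plus each object's 3D
position, distance to the exposed tissue surface, and distances to
user-marked regions of interest. Supplied per-cell surface masks can
additionally be partitioned into exposed (apical), junctional and
basolateral (contacting) membrane domains. The user supplies exactly two
parameters: an estimate of the nuclear diameter and a brightness threshold
for the nuclear channel; everything else is derived. See
`docs/methods.md` for the model, defaults and limitations.

## Worked example

Generate a synthetic four-cell phantom (spherical cells, radius 15 µm,
nuclei 5 µm, known compartment intensities, SNR ≈ 10) and analyse it:

```sh
voxsample phantom-generate --n-cells 4 --seed 3 --outdir ph
voxsample run --mode nucleus \
    --channel nuclear=ph/nuclear.tif --channel membrane=ph/membrane.tif \
    --channel signal=ph/signal.tif \
    --nuclear-channel nuclear --membrane-channel membrane \
    --diameter 10 --threshold 120 --spacing 1,0.5,0.5 --out samples.csv
```

The run log shows the settings derived from the two user parameters
(Hough radius band 6–14 voxels, blur sigma 2.5, link radius 5, minimum
chain 5 slices) and reports 4 detected nuclei. `samples.csv` holds one row
per nucleus; the first row reads (abridged):

| column | value | meaning |
|---|---|---|
| x_um, y_um, z_um | 39.0, 20.0, 20.0 | nuclear centre of mass (µm) |
| nuclear_signal | 192.0 | nuclear mean, signal channel |
| cytoplasm_signal | 46.4 | distance-weighted cytoplasmic mean |
| nc_ratio_signal | 4.14 | N/C ratio (rendered truth: 4.0) |
| log_nc_signal | 1.42 | ln N/C |
| membrane_exposed_membrane | 194.1 | exposed-surface mean, membrane channel |
| distance_to_surface_um | 14.0 | centre-to-exposed-surface distance |

The detected centre sits on the true centre to sub-voxel accuracy, and the
measured N/C of 4.14 recovers the phantom's true ratio of 4 within 4%.

The same pipelines are callable as a library
(`voxsample.run_nucleus_pipeline`, `run_fragment_pipeline`,
`run_partition_pipeline`), which is how the test suite drives them.

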