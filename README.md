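# mitonetquant

Quantitative morphometry of mitochondrial networks in fluorescence
micrographs.

Mitochondria shift between fused, interconnected networks and fragmented
collections of short tubules in response to age, stress and signalling; the
balance is a standard readout in *C. elegans* aging studies, where an
outer-membrane reporter (TOMM-20::GFP) labels the network in muscle and
neurons. `mitonetquant` turns a single-channel micrograph plus per-cell
ROIs into one CSV row per cell of the attributes used to phenotype that
balance:

* **coverage** — % of the cell area occupied by thresholded mitochondrial
  signal,
* **object count and density** — connected particles, normalized per
  100 µm² (fragmentation increases density),
* **object size** — mean skeleton length (µm) and mask area (µm²) per
  particle (fragmentation decreases both),
* **network complexity** — number of *networks* (objects whose skeleton has
  ≥ 1 junction) and junction points per network (fusion increases both).

The measurement chain is: local-contrast enhancement (CLAHE → median →
unsharp), per-ROI Otsu binarization with mask regularization, unit-width
skeletonization, per-pixel tagging (endpoint / slab / junction), object
labelling, and dissection of the skeleton into a branch graph whose merged
junction nodes and √2-metric branch lengths (orthogonal step = 1 px,
diagonal = √2 px, measured to junction-cluster centroids) feed the
attributes above. A ground-truthed synthetic generator of tubular networks
(random-walk centerlines, controllable branching and fragmentation, PSF +
Poisson–Gaussian noise) makes every stage testable without microscope data.
See `docs/methods.md` for the full model and its assumptions.

## Worked example

Generate a matched fused/fragmented pair of synthetic cells and quantify
both (pixel size 0.1 µm/px):

```python
from mitonetquant import (RunConfig, SimParams, quantify_image,
                          simulate_condition_pair, write_metrics_csv)

cfg = RunConfig(pixel_size_um=0.1)
fused, frag = simulate_condition_pair(SimParams(seed=42))
rows = [quantify_image(fused.image, "fused_cell", cfg),
        quantify_image(frag.image, "fragmented_cell", cfg)]
write_metrics_csv(rows, "metrics.csv")
```

`metrics.csv` then contains (abridged):

```
roi_id,...,mito_coverage_pct,object_count,objects_per_100um2,mean_object_length_um,...,network_count,...,mean_junctions_per_network,...
fused_cell,...,7.12891,10,1.52588,13.0322,...,9,...,3.22222,...
fragmented_cell,...,7.35168,50,7.62939,2.43839,...,1,...,1,...
```

Both cells carry near-identical mitochondrial content (7.1% vs 7.4%
coverage), but the fragmented cell splits it into 50 objects at 7.6 per
100 µm² with a mean length of 2.4 µm, while the fused cell holds 10 long
(13.0 µm) objects, 9 of them branched networks with 3.2 junctions each —
exactly the attribute pattern that separates fusion- from
fragmentation-shifted cells. The shared `params_fingerprint` column proves
both rows came from one constant parameter set.

The same pipeline runs from the shell:

```sh
mitonetquant simulate --preset pair --seed 42 --out frames/
mitonetquant batch --cropped-dir frames/ --out metrics.csv --pixel-size 0.1
mitonetquant crop --manifest rois.json --out-dir crops/ --pixel-size 0.065
mitonetquant quantify crops/frame__cell0.tif --out row.csv --pixel-size 0.065
```

`crop` batch-extracts per-cell TIFFs from large acquisitions using a JSON
ROI manifest (rectangles or polygons; a reader for ImageJ `.roi`/RoiSet.zip
rectangles eases migration), and `batch` quantifies a whole directory into
one CSV with constant, fingerprinted parameters.

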