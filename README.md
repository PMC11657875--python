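# spinemorph

Skeleton-based dendritic spine morphometry: width-profile extraction along
3D spine skeletons, ten quantitative shape descriptors, profile-based Ward
clustering with Davies–Bouldin class-number selection, and per-dendrite
heterogeneity statistics — plus a synthetic spine generator with known
class ground truth and a plane-wise Wiener deconvolution front end.

## What it does

- **I/O** (`spinemorph.io`): minimal webKnossos-style NML skeletons
  (voxel → nm via the `<scale>` element, `neck`/`head` node comments), an
  annotation JSON schema bundling skeletons with per-plane polygon
  outlines, and deterministic CSV result tables.
- **Synthetic data** (`spinemorph.synth`): four archetype diameter
  templates (stubby-like, mushroom-like, thin, filopodia-like); sampled
  spines get bent multi-plane 3D skeletons and ribbon outlines whose local
  width equals the (noise-perturbed) template, so the measurement stage can
  be validated against exact ground truth. Optional rendering to blurred,
  Poisson-noised image stacks.
- **Deconvolution** (`spinemorph.deconv`): 2D Lorentzian PSF (default
  50 nm FWHM, 20 nm pixels) and single-constant Wiener filtering applied
  plane-by-plane.
- **Morphometry** (`spinemorph.morphometry`): in-plane width every ~20 nm
  of 3D arc length, measured as the outline chord perpendicular to the
  local in-plane skeleton direction (linear interpolation across axial
  stretches), and the ten descriptors: head/neck diameter, their ratio,
  3D length, spine/neck/head areas, and spine/neck/head width CVs.
- **Clustering** (`spinemorph.cluster`): 175-dim feature vectors
  (100 resampled diameters + 75 length repeats, mean-balanced), Ward /
  Euclidean linkage, Davies–Bouldin class-number selection, per-class mean
  profiles.
- **Statistics** (`spinemorph.stats`): Pearson chi-square on
  dendrite × class tables (omnibus, per-neuron, pairwise with Bonferroni),
  Kruskal–Wallis with Dunn's post hoc on the descriptors, and a
  count-preserving spine-shuffle null control.

## CLI

```sh
spinemorph simulate --out ann.json --seed 1 --dendrites 4 --spines 100
spinemorph deconvolve --in stack.tif --out deconv.tif --fwhm 50 --pixel 20
spinemorph measure --in ann.json --out-dir out/
spinemorph cluster --profiles out/profiles.csv --out-dir out/
spinemorph compare --annotations ann.json --labels out/labels.csv \
    --descriptors out/descriptors.csv --out-dir out/ --shuffles 1000 --seed 0
spinemorph run --config config.yaml          # full pipeline + manifest
```

`run` writes annotations, profiles, descriptors, labels, the
Davies–Bouldin curve, class mean profiles, test tables, a shuffle summary
and a `manifest.json` into the run directory; a fixed seed reproduces
byte-identical outputs.

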