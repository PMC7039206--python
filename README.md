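# invquant

Quantification pipeline for intracellular nanovesicle (INV) experiments:
secretory-transport kinetics, mitochondrial-rerouting and FRAP kinetics,
EM vesicle-capture morphometry, localization-image spot sizing, flicker
variance, Golgi-dispersal measurement, and vesicle-capture screen
statistics — together with a synthetic-data generator so every stage is
verifiable without raw microscopy.

## Modules

| module                  | what it does |
|-------------------------|--------------|
| `invquant.synthetic`    | generators for every input class, with stored ground truth |
| `invquant.io`           | trace CSV, `model2point` contour text, TIFF stacks, JSON sidecars and manifests |
| `invquant.rush`         | Golgi-fraction traces, logistic + tail-line fits, the three transport half-times |
| `invquant.kinetics`     | ROI traces, simple-ratio bleach correction, FRAP normalization, single/double exponential fits |
| `invquant.morphometry`  | vesicle diameters, perimeter abundance, decorated-perimeter fraction (15 nm dilation) |
| `invquant.storm`        | prominence-based spot detection, 2-D Gaussian fits, FWHM summaries and densities |
| `invquant.imagestats`   | flicker variance of normalized excerpts; convex-hull dispersal |
| `invquant.screen`       | post/pre intensity ratios, BCa bootstrap effect sizes, max-t permutation (Dunnett-style) tests, co-rerouting correlations |

## Command line

All stages are exposed as `invquant` subcommands; every run writes a
reproducibility manifest (config, seed, input hashes, version) next to its
output.

```sh
# generate synthetic inputs (ground truth saved as a .truth.json sidecar)
invquant simulate rush --seed 1 --n-traces 5 --out traces.csv
invquant simulate em --seed 1 --n-vesicles 50 --out scene.txt
invquant simulate localization --seed 1 --n-spots 100 --out locs.tif
invquant simulate flicker --seed 1 --mode vesicles --out patch.tif
invquant simulate screen --seed 1 --construct Rab30=2.5 --out screen.csv

# analyze
invquant rush --traces traces.csv --out rush_fits.csv
invquant em --model scene.txt --scale-nm-per-px 1.0 --labels labels.json --out em.csv
invquant storm --image locs.tif --pixel-size-nm 16 --cell-area 100 --out spots.csv
invquant flicker --stack patch.tif --out flicker.csv
invquant screen --table screen.csv --control GFP --nboot 100000 --seed 1 --out effects.csv
invquant frap --traces frap.csv --bleach-index 10 --out frap_fits.csv
invquant reroute --stack video.tif --rois rois.json --out reroute.csv
invquant dispersal --signal tgn.tif --mask cell.tif --out dispersal.csv
```

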