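# drspipe

A tested pipeline for diffuse reflectance spectroscopy (DRS) tissue-
classification analysis:

- **`drspipe.synth`** — synthetic two-class (normal mucosa vs tumor) DRS
  datasets: chromophore-driven absorption (hemoglobins, water, lipid,
  collagen), power-law scattering, a diffusion-theory forward model evaluated
  at the probe source-detector distance (SDD), smooth lamp×detector response,
  per-patient/per-site variability and multiplicative noise. Raw
  three-channel bundles (tissue / reference / background, VIS + NIR) round-trip
  exactly through the preprocessing stage.
- **`drspipe.preprocess`** — raw-spectrum calibration
  `(tissue − background) / (reference − background)`, VIS/NIR merging via a
  101-point cross-fade over the 1095–1130 nm overlap, per-feature [−1, +1]
  min-max scaling (fit on training rows only), and wavelength-range /
  discrete-wavelength subsetting.
- **`drspipe.classify`** — soft-margin kernel SVMs (linear / quadratic /
  cubic polynomial, fine / medium / coarse Gaussian; C = 1), repeated
  stratified twofold cross-validation with pooled per-iteration predictions,
  sensitivity / specificity / accuracy / AUC (exact pair-counting AUC), and
  the kernel-comparison and wavelength-range experiment drivers.
- **`drspipe.mcdepth`** — numba-accelerated Monte Carlo photon transport in a
  semi-infinite homogeneous medium (MCML-style packet walk, Henyey–Greenstein
  scattering, unpolarised Fresnel boundary, Russian roulette), cylindrical
  fluence maps (50 µm bins, 5 × 5 mm), Cartesian photon-hitting-density maps
  (3.75 × 5 mm), and probed-depth profiles per wavelength and probe geometry.
- **`drspipe.io` / `drspipe.pipeline` / `drspipe.cli`** — plain-text CSV/JSON
  readers and writers, deterministic stage seeding from one master seed, a
  run manifest with content hashes, and the `drs` command-line interface.

## CLI

```sh
# full demo pipeline (datasets, kernel tables, range tables, depth profiles)
drs run-all --config cfg.yaml --out out/ --seed 1

# individual stages
drs synth --out out/ --seed 1
drs preprocess merge --bundle-dir out/bundles_sdd630 --stem site0000 --out m.csv
drs preprocess subset --data m.csv --ranges "400-440,540-580" --out sub.csv
drs classify eval --data out/dataset_sdd630.csv --kernel quadratic --seed 1
drs classify table2 --data out/dataset_sdd630.csv --out kernels.csv
drs classify table4 --data out/dataset_sdd630.csv --out ranges.csv
drs mcdepth simulate --mua 0.01 --mus 10 --photons 1e6 --seed 1 --out fluence.csv
drs mcdepth depth --sdd 2500 --props props.csv --out depth.csv
```

Exit codes: 0 success, 2 configuration error, 3 data-format error,
4 numerical failure. The YAML config keys mirror
`drspipe.pipeline.PipelineConfig` (seed, grid_step, sdds, n_patients,
sites_per_patient, noise_sd, contrast, cv_iterations, mc_photons, ...).

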