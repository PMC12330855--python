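# vasculomap

Mapping white-matter vasculature from contrast-enhanced multi-echo MRI:
R2*/ΔR2* relaxometry, equivolumetric laminar sampling, B0 orientation-bias
modelling, multi-scale Frangi vesselness filtering, along-tract (20-node)
profiling, exponential depth models with AICc/BIC comparison, forward
stepwise nonlinear prediction with leave-one-bundle-out cross-validation,
and parcel-level bootstrap statistics.

Every pipeline input can be generated synthetically — a folded-sheet digital
phantom with embedded tubular vessels of controlled orientation (radial in
gray matter, tangential in superficial white matter), commissural-style
streamline bundles whose node metrics follow exponential depth models, and
parcel tables with prescribed correlation structure — so the full chain is
testable without any scan data.

## Test

```bash
python -m pytest -q tests/
```

The suite (≈ 200 tests, ~2 min single-core) includes `tests/test_acceptance.py`
with one test per quantitative acceptance criterion (depth-model parameter
recovery, model-selection power, stepwise consistency, relaxometry round-trip,
orientation-bias correction, Frangi oracles, bundle cleaning, bootstrap
calibration, equivolume layering).

## CLI

Single entry point `vasculomap` with subcommands:

```bash
vasculomap run --out run_dir --seed 7          # full phantom→stats pipeline
vasculomap simulate --out phantom_dir          # phantom + bundles + parcels
vasculomap r2star --echoes e0.nii ... --te 3.4,5.8,... --method loglinear --out r2s.nii
vasculomap delta --post post.nii --pre pre.nii --out delta.nii
vasculomap layers --white white.surf.gii --pial pial.surf.gii --out-dir layers/
vasculomap sample --volume delta.nii --inner swm.surf.gii --outer white.surf.gii --out metric.func.gii
vasculomap b0correct --metric m.func.gii --surface white.surf.gii --b0 0,0,1 --out corrected.func.gii
vasculomap frangi --volume post_mean.nii --sigmas 0.25,0.5 --threshold 0.05 --out vesselness.nii
vasculomap profile --tck bundle.tck --volumes delta.nii ndi.nii odi.nii --out profile.csv
vasculomap depthfit --profiles profiles.csv --metric delta_r2star --compare --out fits.json
vasculomap predict --table predictors.csv --out model.json
vasculomap stats --table parcels.csv --x delta_r2star --y receptor --out stats.json
```

`vasculomap run` takes an optional YAML config (stage toggles, per-module
parameter blocks, global seed) and writes a JSON manifest with parameters
and output hashes; reruns with the same config and seed are bit-identical.

## Package layout

| module | role |
| --- | --- |
| `synthetic` | digital phantom, bundle, parcel-table and predictor-set generators with ground truth |
| `relaxometry` | multi-echo mono-exponential R2* fitting (log-linear / NLS) and ΔR2* maps |
| `laminar` | equivolumetric layers (EL1a…EL6b), SWM offset surface, ribbon sampling, surface gradients |
| `orientation` | cos²θ orientation-bias estimation and per-layer correction |
| `vesselness` | multi-scale Hessian/Frangi filter and vessel-mask statistics |
| `tracts` | bundle cleaning, equidistant resampling, 20-node median profiles, relative distance |
| `depth_models` | exponential/linear/quadratic/logistic depth fits, AICc/BIC comparison |
| `vascular_model` | forward stepwise BIC selection (NDI, ODI, exp-distance) and leave-one-bundle-out CV |
| `parcel_stats` | parcel medians, bootstrap correlation tests, paired t / variance ratio, Bonferroni |
| `pipeline`, `cli` | stage orchestration, manifest, `vasculomap` subcommands |

Units: echo times in ms at interfaces (converted to s internally), R2* and
ΔR2* in 1/s, distances in mm, relative tract distance in percent
(0 = white-matter surface, 100 = midline).
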