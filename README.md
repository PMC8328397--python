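# dtialps

Glymphatic function — the brain's perivascular fluid-clearance system —
cannot be measured directly in vivo without contrast injection. The
**DTI-ALPS index** (Diffusion Tensor Image Analysis ALong the Perivascular
Space) is a non-invasive surrogate: at the level of the lateral-ventricle
body, deep medullary veins and their perivascular spaces run left–right
(the x axis of standard space), perpendicular to both the projection fibers
(inferior–superior, z) and association fibers (anterior–posterior, y). Water
mobility along x in those two fiber bundles therefore isolates the
perivascular compartment:

```
ALPS = mean(Dx_proj, Dx_assoc) / mean(Dy_proj, Dz_assoc)
```

where each `D` is the corresponding diagonal element of the diffusion tensor
averaged over a 7-voxel (56 mm³ at 2 mm isotropic) crosshair ROI. ALPS ≈ 1
means no preferential perivascular diffusion; healthy white matter sits
around 1.4–1.6.

This package is for neuroimaging researchers who want to

* compute the ALPS index from tensor volumes with the standardized
  four-ROI protocol (left/right × projection/association, centers
  `[25 52 50]`, `[31 52 50]`, `[64 52 50]`, `[58 52 50]` on the 2 mm MNI152
  grid), including an automated orientation QC that replaces the manual
  "nudge the ROI onto the tract" step;
* validate the pipeline against **synthetic DWI phantoms** with an
  analytically known ALPS (planted perivascular diffusivity, Rician noise,
  log-linear tensor refit);
* study the statistical behavior of ALPS association analyses on
  **synthetic cohorts** with planted standardized effects of age, sex,
  hypertension and deep-medullary-vein (DMV) disruption, calibrated to a
  target model R²;
* run the cohort analysis itself: univariate screens, forward/backward
  selection, standardized betas, VIF, residual diagnostics, Cohen's kappa.

The regression machinery (`StandardizedOLS`, `StepwiseSelector`) follows the
scikit-learn estimator API and composes with sklearn pipelines.

## Worked example

Simulate a 142-subject cohort and analyze it:

```sh
$ dtialps simulate cohort --seed 5 --out-dir sim
n=142 achieved_r2=0.3190
$ dtialps analyze sim/cohort.csv --outcome alps_mean --out-dir analysis
alps_mean: selected=['age', 'sex', 'dmv_score'] adj_r2=0.3239
```

The first line reports the population R² the calibrated generator plants
(0.319, reached by linking hypertension and DMV score to age). The analysis
selects a model by forward selection (α_enter = 0.05); on this seed it finds
age, sex and DMV score — hypertension, the weakest planted effect
(β = −0.189), does not reach the entry threshold here, which is exactly the
kind of finite-sample behavior the simulator exists to quantify.
`analysis/analysis.json` holds the full model:

```
std_beta: age -0.347, sex -0.300, dmv_score -0.172
p:        age <0.001, sex <0.001, dmv_score 0.0253
adjusted R² 0.324;  VIF: age 1.22, sex 1.04, dmv_score 1.20
```

On the phantom side, the whole simulate → fit → measure chain is checked
against the closed form:

```python
>>> from dtialps import default_phantom_spec, phantom_to_alps
>>> result, expected = phantom_to_alps(default_phantom_spec(), snr=40, seed=7)
>>> print(f"measured={result.alps_mean:.4f} expected={expected}")
measured=1.4728 expected=1.5
```

Noiseless (`snr=float('inf')`) the two agree to 1e-6; at SNR 40 a single
run scatters around the truth with SD ≈ 0.018.

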