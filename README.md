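# hybridose

Image-based absorbed-dose estimation for [¹⁷⁷Lu]Lu-PSMA radioligand therapy,
for medical physicists and dosimetry researchers who need to compare what the
three standard post-therapy workflows would report on the same patient:

- **2D** — conjugate-view planar dosimetry: serial anterior/posterior
  whole-body scintigrams, A = √(C_A·C_P/T̄)·f/cf with transmission-based
  attenuation correction, dual-energy-window scatter correction, background
  subtraction and partial-organ extrapolation;
- **3D** — SPECT/CT VOI dosimetry: calibrated voxel activities (Bq/cps),
  adaptive-threshold delineation inside boundary VOIs, volume-dependent
  recovery-coefficient (RC) correction for partial-volume losses;
- **hybrid** — planar kinetics rescaled by a single quantitative SPECT:
  the planar time-activity curve is multiplied by
  s = A_SPECT/A_planar(t_anchor), keeping the curve shape and fixing its
  absolute scale.

Each chain produces time-activity curves at ~24/48/96 h, integrates them
piecewise (constant to the first point, trapezoids between points, a
physical-decay tail after the last), normalises to the administered activity
(TIAC) and converts to absorbed dose with mass-adjusted dose factors
(reference-organ factors for kidneys/liver, a sphere model for salivary
glands and bone lesions). Methods are compared with median paired
differences, an exact signed-rank test, and Bland-Altman limits of agreement
(mean difference ± 1.96 SD of relative differences).

Because clinical scans cannot be redistributed, the package includes a
digital-phantom simulator (`hybridose.phantom`) that generates the full set
of inputs — planar photopeak/scatter grids, blank/transmission/vial scans,
post-reconstruction SPECT volumes with calibration cylinder, CT-surrogate
label maps — with analytic ground truth for parameter-recovery tests, plus a
cohort generator at the clinical study scale (24 patients, 65 cycles).
See `docs/methods.md` for models, assumptions and limitations.

## Worked example

Run all three methods on one randomised abdominal therapy cycle:

```
hybridose run --seed 7 --out out/
```

prints (abridged):

```
instance  region_class method    tia_mbq_h   tiac_h  dose_gy_per_gbq   mass_g
kidneys   kidneys      2D      21789.86     3.066      0.929            281.4
liver     liver        2D      10330.28     1.453      0.077           1617.4
kidneys   kidneys      3D      22738.14     3.199      0.970            281.4
liver     liver        3D      12737.42     1.792      0.095           1617.4
kidneys   kidneys      hybrid  22353.16     3.145      0.954            281.4
liver     liver        hybrid  11962.36     1.683      0.089           1617.4
...
```

Reading it: the kidney pair accumulated a time-integrated activity of
~22 GBq·h, i.e. a TIAC of ~3.1 h of the administered activity, giving
~0.95 Gy per administered GBq by the 3D reference chain. The 2D estimate
sits a few percent lower (threshold and attenuation-geometry losses of
planar quantification); the hybrid estimate, anchored to the day-1 SPECT,
lands close to 3D while using only one SPECT instead of three.

Cohort-scale comparison (24 patients / 65 cycles, ~20 s):

```
hybridose cohort --seed 1 --out cohort_out/
```

writes the pooled dose table, the per-region comparison
(median difference, p-value, Bland-Altman LoA for 2D-vs-3D and
hybrid-vs-3D) and the Bland-Altman point data as CSV. With the default bias
model, 2D underestimates the kidney dose by ~15% (median) with LoA ≈ ±18%,
while hybrid stays within ~1% with LoA ≈ ±3% — hybrid agrees with the 3D
reference more closely and more consistently in every region class.

Library use mirrors the CLI:

```python
from hybridose.workbench import RunConfig, generate_fixture_cohort, run_cohort

cohort = generate_fixture_cohort(n_patients=24, total_cycles=65, seed=1)
res = run_cohort(cohort, RunConfig(seed=1))
print(res["comparison"])          # median diffs, p-values, LoA per region
```

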