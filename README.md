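# crvtoffset

Morphometry of the central retinal vascular trunk (CRVT) relative to
Bruch's membrane opening (BMO), and the paired-eye statistical
toolchain built around it.

## The problem

The lamina cribrosa — the sieve through which retinal ganglion cell
axons leave the eye — can end up offset from the BMO as the eyeball
grows, and that offset is suspected to mark loco-regional
susceptibility to glaucomatous damage, in particular in unilateral
normal-tension glaucoma (NTG), where one eye is affected and the
fellow eye is a built-in control. The CRVT is embedded in the lamina,
so its position inside the BMO is a measurable proxy for the offset.

From a delineated BMO margin (an ordered polygon in the OCT image
plane, in mm) and the CRVT landmark point, the package computes, per
eye:

* the **offset index** `a/b` — distance from the BMO centre to the
  CRVT (`a`) over the distance from the centre to the BMO margin along
  the same ray (`b`); dimensionless in `[0, 1]`, fixed at exactly 1.0
  when the trunk lies outside the BMO;
* the **angular deviation** α — direction of the centre→CRVT vector
  in right-eye orientation (nasal midline 0°, superior positive; left
  eyes are mirrored on ingest);
* RNFL-defect midpoint angles (temporal midline 0°) and β-/γ-zone
  parapapillary atrophy areas.

On eye-level cohort tables (one glaucoma and one fellow control eye
per patient) it then runs the matched inference chain: paired t /
Wilcoxon comparisons, matched-pair **conditional logistic regression**
with a p < 0.20 univariable screen, a linear **GEE**
`offset ~ diagnosis + AL + AL² + AL³` with exchangeable within-pair
correlation and sandwich CIs (AL = axial length, mm), the closed-form
minimum of the fitted cubic, LOESS curves, and Pearson correlations
between trunk angle and RNFL-defect angle. A calibrated synthetic
cohort generator emulates the study conditions (group moments, cubic
axial-length structure, within-pair correlation, angle correlation,
exclusion cascade) so everything runs without patient data; see
`docs/methods.md` for the model and calibration details.

## Worked example

```python
import crvtoffset as cx

# measure one synthetic left eye: 48-point BMO margin, trunk at 42% of
# the centre-to-margin distance, 65 degrees superior-nasal
eye = cx.synthesize_eye_geometry(0.42, 65.0, "OS", bmo_area=2.4, seed=7)
m = cx.measure_crvt(eye)
print(f"offset index = {m.offset_index:.3f}, "
      f"angular deviation = {m.angular_deviation_deg:+.1f} deg")

# recover the generative cubic from a simulated paired cohort
cal = cx.load_calibration()
sim = cx.simulate_cubic_cohort(cal, n_pairs=5000, seed=1, sigma_resid=0.1)
print(cx.OffsetIndexGEE(sim).fit().summary())
```

prints

```
offset index = 0.420, angular deviation = +65.0 deg
GEE: offset index ~ diagnosis + AL + AL^2 + AL^3
n eyes = 10000; exchangeable working correlation = 0.501; scale = 0.01876
           coefficient   ci_low  ci_high      p
intercept      82.3119  77.1715  87.4523 0.0000
diagnosis       0.1560   0.1522   0.1598 0.0000
al             -9.5632 -10.1723  -8.9541 0.0000
al2             0.3674   0.3435   0.3914 0.0000
al3            -0.0046  -0.0050  -0.0043 0.0000
fitted curve minimum at AL = 23.33 mm
```

The diagnosis coefficient (0.156, CI 0.152–0.160) recovers the
generating effect of 0.158 — glaucoma eyes have a higher offset index
than fellow eyes at every axial length — and the fitted J-shaped curve
bottoms out near 23.3 mm, close to the generative minimum at 23.4 mm
(an emmetropic-length eye); the working correlation (0.50) matches the
generator's within-pair noise correlation.

The same chain is available from the shell:

```bash
crvtoffset simulate --seed 42 --out run/     # 112 patients -> 93 after exclusions
crvtoffset measure eyes.json --out measurements.csv
crvtoffset analyse cohort.csv --out tables/
crvtoffset show-config
```

`simulate` generates a cohort, synthesises per-eye delineations and
routes them through the geometric measurement (not the generator's
targets), applies the exclusion cascade, and writes `table1.csv`
(paired comparisons), `table2.csv` (matched odds ratios),
`table3.csv` (GEE coefficients), `fig2_loess.csv`,
`angle_correlations.csv` and a JSON run report with the exclusion
tally, seed and calibration checksum.

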