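# ituri

Line-transect dung-survey analysis for forest-elephant monitoring: distance
sampling density estimation, before/after change inference, kriged density
surfaces with Getis–Ord Gi\* hotspots, landscape covariates, and
quasipoisson density-surface GAMs — together with a synthetic survey
generator so every stage can be validated end to end without field data.

## The problem

Forest elephants are censused indirectly: field teams walk straight
transects and record the perpendicular distance `x` of every dung pile from
the line. Detection falls off with distance according to a detection
function `g(x)` (with `g(0) = 1`), so raw counts must be corrected by the
**effective strip width** `μ = ∫₀ʷ g(x) dx` before they become densities:

```
D = n / (2 μ L)          dung piles per unit area,
```

with `n` the number of detections and `L` the total transect length. The
package fits uniform, half-normal and hazard-rate detection functions by
maximum likelihood and picks the best by AIC. Density uncertainty combines
the between-location encounter-rate CV with the ESW CV,
`CV(D)² = CV(n/L)² + CV(μ)²`, and confidence intervals are log-normal.

Change between two survey epochs is tested with a z-test on the density
difference; per-location changes are classified (declined / same /
increased) and compared with a chi-square test against uniform expectation.
Standing-crop dung densities convert to elephant densities through the mean
dung survival time `T` (days) and the defecation rate `r` (piles per
elephant per day): `E = D / (T·r)`.

Spatial structure is examined two ways: ordinary kriging of per-location
densities (spherical/exponential variogram fitted by weighted least
squares) with Gi\* hotspot z-scores, and density-surface GAMs

```
log E[n_i] = log(2 μ l_i) + β₀ + Σ_k s_k(z_ik)
```

where the offset is the effective area surveyed on transect `i`, the `s_k`
are penalized cubic-spline smooths of landscape covariates (distances to
roads, towns, boundary, headquarters; slope; habitat; a composite
deforestation index `I = Σ_j a_j / d_j`), counts are quasipoisson
(variance `φ·mean`), smoothing parameters minimize GCV, and backward
deletion yields the minimal adequate model.

## Worked example

```python
from ituri import (DensityEstimate, ConversionParams, ztest_change,
                   dung_to_elephants, extrapolate_population)

d1 = DensityEstimate.from_components("1995", n=460, L=280.0, k=51,
                                     esw=2.01, cv_encounter=18.63, cv_esw=4.07)
d2 = DensityEstimate.from_components("2006", n=286, L=280.0, k=51,
                                     esw=2.40, cv_encounter=28.08, cv_esw=5.93)
z, p, pct = ztest_change(d1, d2)
print(f"D1={d1.density:.2f}/ha  D2={d2.density:.2f}/ha  "
      f"z={z:.3f}  p={p:.3f}  decline={pct:.0f}%")

conv = ConversionParams()          # 19.77 piles/day, 44-day survival, 13700 km^2
e1 = dung_to_elephants(round(d1.density, 2), conv)
e2 = dung_to_elephants(round(d2.density, 2), conv)
print(f"elephants/km^2: {e1:.2f} -> {e2:.2f};  population "
      f"{extrapolate_population(e1, conv.area)} -> {extrapolate_population(e2, conv.area)}")
```

prints

```
D1=4.09/ha  D2=2.13/ha  z=1.978  p=0.024  decline=48%
elephants/km^2: 0.47 -> 0.24;  population 6439 -> 3288
```

— a 48% dung-density decline between the surveys, significant at the 5%
level one-sided, corresponding to a loss of 3151 elephants over the
13,700 km² reserve.

The full pipeline (synthetic survey → detection → density → change →
hotspots/kriging → covariates → GAMs → report) runs from the command line:

```
ituri all --seed 7 --out pipeline_out     # or: python -m ituri.cli
```

and writes per-stage artifacts (detection JSON, density/change reports,
hotspot and kriged-surface tables, GAM comparison tables, partial-effect
curves, a manifest) under `pipeline_out/`. Individual stages (`simulate`,
`detect`, `density`, `change`, `hotspots`, `krige`, `covariates`, `dsm`,
`report`) re-run in isolation from the cached artifacts.

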