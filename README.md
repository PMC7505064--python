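# bearcondition

Noninvasive, photograph-based body-condition evaluation for brown bears
(*Ursus arctos*), implemented as a tested Python package. The toolchain was
developed for the Shiretoko Peninsula (Hokkaido, Japan) population but the
machinery is population-agnostic: fit your own capture data, score your own
photographs.

## The problem and the method

Body condition — the relative size of an animal's energy reserves — predicts
health, reproductive success and survivorship, but weighing a wild bear
requires capture and anesthesia. This package implements a capture-free
alternative built on three linked analyses:

1. **Body condition index (BCI).** For killed or captured bears, body mass
   *W* (kg) scales allometrically with straight-line body length *L* (cm):
   ln *W* = *b* ln *L* + *a* + ε. The BCI of a bear is its standardized
   residual, BCI = (ln *W* − *b* ln *L* − *a*)/σ, with σ the residual SD.
   For the Shiretoko reference sample of 476 bears this is
   BCI = (ln *W* − 3.04 ln *L* + 10.41)/0.19.
2. **Growth curves.** Body length at age follows the von Bertalanffy model
   *A(t)* = *A*∞(1 − e^(−*K*(*t* − *T*))). The closed-form inverse
   *t(p)* = *T* − ln(1 − *p*)/*K* gives the age at which each sex reaches
   95 % of asymptotic length, which sets the adult age thresholds
   (females ≥ 5 y, males ≥ 8 y). Sexes are compared with an
   extra-sum-of-squares F test.
3. **Photo morphometrics.** Lateral photographs are scored 1–3 on nine
   quality/posture attributes, filtered (any 3 rejects), categorized
   (Good / BS / NF / NB), ground-aligned, and measured from named landmark
   pixels. The adopted condition indicator is **TH:HTL** — torso height over
   horizontal torso length — because it tolerates the widest range of
   postures at a between-photo CV below 5 %. Replicate tracings (≥ 3, so the
   measurement SE stays under 0.0025) are averaged before the ratio is
   formed. TH:HTL is calibrated against BCI using bears photographed within
   ±3 days of a physical capture, and seasonal condition is tracked as the
   median TH:HTL of the best ≥ 2 photographs per half-month.

A synthetic-data module (`bearcondition.simulate`) generates capture
records, replicate photo measurements, landmark sets, seasonal photo series
and calibration studies whose defaults are the published study conditions,
so the entire pipeline is testable offline.

## Worked example

```python
import numpy as np
import bearcondition as bc

# a synthetic capture population at the study conditions
records = bc.simulate.generate_population(seed=1)

res = bc.AllometricScaling.from_records(records).fit()
print(res.summary())

females = [(r.age_years, r.body_length) for r in records
           if r.sex is bc.Sex.FEMALE]
growth = bc.VonBertalanffyGrowth([a for a, _ in females],
                                 [l for _, l in females]).fit()
print(growth.summary())

# calibrate the photographic ratio against capture BCI (7-bear study)
caps, photos = bc.simulate.generate_calibration_study(seed=1)
pairs = []
for rec in caps:
    sel = bc.select_calibration_photos(photos, rec.bear_id, rec.date)
    pairs.append((float(np.median([p.ratio for p in sel])),
                  bc.compute_bci(rec.body_mass, rec.body_length,
                                 bc.SHIRETOKO_REFERENCE_MODEL)))
print(bc.RatioCalibration.from_pairs(pairs).fit().summary())
```

prints

```
Allometric mass-length scaling (OLS on natural logs)
  n                    476
  slope b                  3.1408  (SE 0.0404)
  intercept a            -10.8996  (SE 0.1983)
  residual SD sigma        0.1977
  R-squared                0.9272
  BCI = (ln W - 3.14 ln L + 10.90) / 0.20

von Bertalanffy growth curve: A(t) = A_inf (1 - exp(-K (t - T)))
  n            205
  A_inf (cm)      144.84  (SE 0.91)
  K (1/year)       0.512  (SE 0.028)
  T (years)       -1.271  (SE 0.117)
  RSS            13154.0
  age at 95% of A_inf: 4.6 years

TH:HTL -> BCI calibration (OLS)
  n pairs        7
  slope             19.546
  intercept        -13.971
  Pearson r          0.914  (p = 0.004)
  R-squared          0.835
  ratio range    [0.657, 0.754]
```

The fitted slope (3.14) and residual SD (0.20) recover the generating
allometry (3.04, 0.19) within one draw's sampling error; the female growth
curve lands on the reference parameters (A∞ ≈ 145 cm, K ≈ 0.51/y) and
reproduces maturity at 4.6 years; and the seven photographic TH:HTL ratios
correlate strongly and positively with capture BCI, so the fitted line
converts future photograph-only ratios into condition estimates
(`CalibrationResults.predict`, which flags extrapolation).

A thin CLI mirrors these steps:

```sh
bearcondition simulate-population --seed 1 --out records.csv
bearcondition fit-allometry --records records.csv --out model.json
bearcondition score-bci --model model.json --records records.csv --out scored.csv
bearcondition cv-test --cv 2.47,2.19,3.18,3.93 --n 15,15,25,34
```

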