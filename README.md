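# sicolor

Seasonal dorsal-colour analysis for wall lizards (*Podarcis siculus* and
similar lacertids): a reusable, tested pipeline from calibrated RGB pixels
to Bayesian circannual rhythm estimates.

## The problem

Wall lizards change dorsal colour over the activity season (March–October)
and between sexes: males tend to be greener and brighter, with a stronger
spring peak, while females stay closer to a cryptic baseline. Quantifying
this requires turning many thousands of photograph pixels per animal into
one colour score, and then modelling that score as a smooth annual cycle
while accounting for sex, body size and the sampling site.

`sicolor` implements that analysis as three composable stages plus a
synthetic-data generator with known ground truth:

1. **Colour spectra** (`sicolor.spectra`) — 8-bit RGB pixels of each
   animal's dorsal region of interest are converted to HSV; specular
   highlights (bright, desaturated pixels from reflected light) are
   removed; each channel (hue, saturation, value) is binned into a
   normalized per-individual frequency distribution, the *colour spectrum*.
2. **PCA scores** (`sicolor.pca`) — one covariance PCA per channel over
   the spectra; the sign-aligned first component (PC1) is the colour
   response. For hue, positive scores mean more mass in the green interval
   (90–150°) versus the orange-yellow interval; for saturation and value,
   scores increase with the mean channel level.
3. **Cosinor mixed model** (`sicolor.cosinor`, `sicolor.summaries`) — PC1
   scores are fitted with a Bayesian random-intercept linear mixed model
   containing a single-component cosinor:

   ```
   Y(t) = M + A·cos(2πt/τ + φ) + e(t)
        = M + β·x + γ·z + e(t),   x = cos(2πt/τ),  z = sin(2πt/τ),
          β = A·cos φ,  γ = −A·sin φ
   ```

   with τ = 365 days, t the capture day-of-year, plus sex, standardized
   snout-to-vent length (SVL), their interactions with the cosinor terms,
   and a population random intercept. Posterior draws (seeded Gibbs
   sampler, split R-hat monitoring) are summarised as the half-sample mode
   (HSM) with 95%/50% highest-density intervals (HDI) for each sex's MESOR
   (rhythm-adjusted mean), amplitude, acrophase and calendar peak date,
   male−female contrast probabilities P(m>f), and the share of residual
   variance carried by the population intercept.

The generator (`sicolor.simulate`) emulates the study design — three
populations, monthly sampling March–October, adults only (SVL ≥ 50 mm),
right-skewed pixel counts — at both the score level (directly from the
mixed model's generative process) and the pixel level (a two-mode
green/orange hue mixture with a seasonal logistic green weight), so every
stage is testable without field photographs.

## Worked example

```python
import warnings; warnings.simplefilter("ignore")
from sicolor import (StudyConfig, TruthSpec, simulate_individuals, simulate_scores,
                     build_design, fit_cosinor_lmm, MCMCSettings, PriorSpec,
                     summarize_posterior)

cfg = StudyConfig(n_individuals=300, seed=7)
records = simulate_individuals(cfg)
scored, truth = simulate_scores(records, TruthSpec(), seed=8)

design = build_design(scored, tau=365.0)
draws = fit_cosinor_lmm(design, PriorSpec(), MCMCSettings(seed=9))
summary = summarize_posterior(draws, channel="H")

m = summary["sexes"]["male"]
print(f"male amplitude  (HSM): {m['amplitude']['hsm']:.2f}   "
      f"HDI95: [{m['amplitude']['hdi95'][0]:.2f}, {m['amplitude']['hdi95'][1]:.2f}]")
print(f"male peak date:        {m['peak_date']}  (day {m['peak_day']['hsm']:.0f})")
print(f"P(amplitude m > f):    {summary['contrasts']['p_amplitude_m_gt_f']:.3f}")
print(f"P(MESOR m > f):        {summary['contrasts']['p_mesor_m_gt_f']:.3f}")
```

prints

```
male amplitude  (HSM): 1.36   HDI95: [1.11, 1.61]
male peak date:        11 March  (day 70)
P(amplitude m > f):    1.000
P(MESOR m > f):        0.893
```

The generator's truth here is a male amplitude of 1.5 peaking on day 75
(16 March) against a female amplitude of 0.75, so the fit recovers the
amplitude within its credible interval, places the peak four days early,
and is certain the male seasonal swing exceeds the female one — exactly
the kind of statement the model is built to make.

## Command line

Each stage is independently invokable; `run` chains them from a config
file:

```bash
sicolor simulate --n 300 --seed 1 --pixel-level --outdir study/
sicolor spectra  --pixels study/pixels.csv --channel H --out spectra_H.csv
sicolor pca      --spectra spectra_H.csv --scores-out scores_H.csv
sicolor fit      --metadata study/metadata.csv --draws-out draws.csv
sicolor summarize --draws draws.csv --channel H --out summary.json
sicolor recover  --n 300 --replicates 20 --seed 1 --out recovery.json
sicolor run      --config config.yaml
```

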