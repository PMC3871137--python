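# nirshelf

Chemometrics pipeline for quantifying vitamin C in stored fruit from
near-infrared (NIR) spectra and predicting shelf life from degradation
kinetics.

Vitamin C (ascorbic acid) is a key quality index of fresh fruit such as
jujube and declines steadily during room-temperature storage. Measuring
it chemically (2,6-dichloroindophenol titration) destroys the fruit, so
a longitudinal storage study can only titrate each fruit once. NIR
spectroscopy offers a non-destructive alternative: absorbances at a few
informative wavenumbers, calibrated against titration values by
multiple linear regression (MLR), predict the vitamin C content of any
intact fruit; combined with a kinetic model of the decline, they
predict how long a fruit has been stored and how long it can still be
stored. `nirshelf` implements that entire chain for analysts working on
NIR-based quality monitoring, and ships a synthetic storage-study
generator so the pipeline can be validated end to end without
instrument data.

## The model

1. **Pretreatment.** Savitzky–Golay smoothing (window 21 points,
   quadratic), first/second S–G derivatives with respect to wavenumber,
   and multiplicative scatter correction (MSC): each spectrum `x` is
   regressed on the calibration-set mean `x̄`, `x ≈ a + b·x̄`, and
   corrected to `(x − a)/b`, removing particle-size scatter.
2. **Wavelength selection (RC method).** A full-spectrum regression
   coefficient vector is computed by ridge-stabilised least squares;
   the N largest local maxima of |RC| pick the effective wavenumbers.
3. **Calibration.** Ordinary least squares of titrated vitamin C
   (`VCC`, mg/100 g) on the selected absorbances `X₁…X_N`:
   `VCC = b₀ + b₁X₁ + … + b_N X_N`, evaluated by the Pearson
   correlation and RMSE on a held-out prediction set (Rc/RMSEC,
   Rp/RMSEP) after a random 50/17 split of the non-decayed fruits.
4. **Kinetics.** Zero-order `C = C₀ − Kt` and first-order
   `C = C₀·e^(−Kt)` degradation models; because sampling is
   destructive, the zero-order model is fitted in regression form
   `VCC = a + b·VCC₀ − K·t`, with each fruit's initial content `VCC₀`
   predicted by the MLR calibration from its intake (day-1) spectrum.
5. **Shelf life.** Inverting the zero-order model gives the elapsed
   storage time `t = (a + b·VCC₀ − VCC)/K` from two spectra (day 0 and
   day t), and the safe storage time
   `t* = (a + b·VCC₀ − threshold)/K` at which the modelled content
   crosses a quality threshold (default 0 mg/100 g).

Everything is exposed as scikit-learn-style estimators
(`SavitzkyGolay`, `MultiplicativeScatterCorrection`, `MLRCalibration`,
`ZeroOrderKinetics`, `FirstOrderKinetics`), so the pieces compose with
sklearn pipelines and model selection; plain functions wrap them for
script use.

## Worked example

Generate the default synthetic study — 72 fruits in 18 groups of 4,
spectra on 12,000–4,000 cm⁻¹ at 8 cm⁻¹ steps at 3 probe positions per
fruit per day, one group titrated per day, 5 fruits decaying late in
storage — and run the full analysis:

```python
from nirshelf.calibrate import SplitSpec, compare_pretreatments
from nirshelf.pipeline import RunConfig, run_pipeline
from nirshelf.synth import SyntheticStudyConfig, generate_study

ds = generate_study(SyntheticStudyConfig(seed=42))
print(compare_pretreatments(ds, region="LWNIR", split=SplitSpec(seed=42)).round(4))
run_pipeline(RunConfig(output_dir="out", simulate=SyntheticStudyConfig(seed=42),
                       split=SplitSpec(seed=42)))
```

The comparison table (one MLR model per pretreatment on a shared
50/17 split, long-wavelength region 9,091–4,000 cm⁻¹):

```
         N      Rc   RMSEC      Rp    RMSEP
method
raw      6  0.9991  4.2859  0.9987   6.6816
sg       6  0.9981  6.1861  0.9943  11.7173
msc      6  0.9965  8.4741  0.9962  11.9297
d1      12  0.9994  3.4871  0.9974   8.0083
d2      10  0.9992  4.0712  0.9985   6.0614
```

N is the number of selected wavenumbers; Rc/RMSEC and Rp/RMSEP are the
correlation and root-mean-square error (mg/100 g) in the calibration
and prediction sets. `run_pipeline` then writes the fitted models and
reports; on this study the zero-order kinetic fit recovers the
generating decline of 20.677 mg/100 g per day as

```
rate_per_day = 19.86  (se 0.30)        # attenuated slightly by the
                                       # floor at zero in late storage
R = 0.993 (zero-order)  vs  0.931 (first-order)  ->  zero-order chosen
mean safe storage time = 17.4 days (range 13.9-20.9)
```

i.e. the linear model describes the decline better than the
exponential one, and a typical fruit's vitamin C reaches zero after
roughly two and a half weeks at 20 °C.

The same pipeline is scriptable from the shell:

```sh
nirshelf simulate --out study/
nirshelf run-all --out results/
nirshelf shelflife --mlr-model results/mlr_model.json \
    --kinetic-model results/zero_order_model.json \
    --day0 day0.csv --dayt dayt.csv --method algebraic
```

## Layout

- `nirshelf.synth` — synthetic study generator + titration arithmetic
- `nirshelf.io` — spectra CSV I/O, replicate averaging, region slicing
- `nirshelf.pretreat` — S–G smoothing/derivatives, MSC
- `nirshelf.calibrate` — split, RC selection, MLR fit, metrics
- `nirshelf.kinetics` — zero-/first-order fits and comparison
- `nirshelf.shelflife` — combined prediction, inversion, safe storage time
- `nirshelf.pipeline` / `nirshelf.cli` — orchestration and CLI

See `docs/methods.md` for the modelling assumptions, generator design
and numerical choices.
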