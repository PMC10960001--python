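# serstax

Forward-predictive SERS chemical taxonomy for epimeric cerebrosides.

Glucocerebrosides (GlcCerX:Y) and galactocerebrosides (GalCerX:Y) differ
only in the orientation of one hydroxyl on their hexose — an epimeric
distinction that matters clinically (GlcCer24:1 and GalCer24:1 are
biomarkers of different diseases) but is hard to resolve quickly by mass
spectrometry. Captured on a 4-mercaptophenylboronic-acid (4-MPBA) SERS
reporter, each epimer–reporter adduct produces a distinct vibrational
fingerprint. `serstax` implements the analysis side of that strategy:

- **Preprocessing** — airPLS baseline correction (order-2 Whittaker
  smoother with adaptive asymmetric weights), min–max normalization and
  resampling to a canonical 1200-point grid over 400–1800 cm⁻¹.
- **Featurization** — bounded least-squares fitting of 19 skewed
  pseudo-Voigt peaks; 5 attributes per peak (position, intensity, FWHM,
  skew, η) give a 95-dimensional feature vector per spectrum.
- **Chemical taxonomy** — a five-level hierarchical cascade: four random
  forests answer blank↔epimer, monosaccharide↔cerebroside,
  saturated↔unsaturated and glucosyl↔galactosyl in sequence, and two
  support-vector regressors estimate the ceramide chain length X. Because
  each level answers a structural question rather than naming a class, a
  cerebroside never seen in training is still identified by composing the
  answers (*forward prediction*), with majority voting across replicates.
- **Quantification** — per-analyte log₁₀-concentration regressions over
  1e-4…1e-10 M, and multiplex quantification of binary
  GlcCer24:1/GalCer24:1 mixtures at a fixed 100 µM total.
- **Synthetic generator** — labelled spectra encoding the
  structure→spectrum rules (capture drop of the B-OH bend at 1330 cm⁻¹,
  saturation-dependent redshift of the a₁ νCC mode, hexose-dependent
  blueshift of the 414 cm⁻¹ band, chain-length-proportional intensity
  ratios), the 14-class × 60-replicate design, log-linear concentration
  response and binary mixtures — so the whole pipeline is testable
  without measured data. See `docs/methods.md` for the model, the noise
  calibration and its limits.

## Worked example

```python
import serstax as sx

cfg = sx.SyntheticConfig()

# the study design: 14 classes x 60 replicates at 1e-4 M
dataset = sx.generate_dataset(cfg, seed=11)          # 840 spectra
features = sx.featurize_dataset(dataset)             # 840 x (95 + labels)

# forward prediction: remove every GalCer16 spectrum, train on the rest,
# route the held-out spectra through the cascade
report = sx.forward_prediction(features, "GalCer16",
                               sx.Protocol.mini(), seed=5)
print(report.stage_accuracy, report.overall_accuracy)
print(report.chain_mean, report.chain_sd)
```

prints (about a minute of compute):

```
{'stage1': 1.0, 'stage2': 1.0, 'stage3': 1.0, 'stage4': 1.0} 1.0
15.98 0.98
```

— every held-out GalCer16 spectrum is routed epimer → cerebroside →
saturated → galactosyl (100% at each stage, so 100% overall), and the
chain-length regressor, which never saw a 16-carbon galactocerebroside,
estimates 16.0 ± 1.0 carbons: the unseen class is fully identified as
GalCer16.

Quantification works the same way from the feature table:

```python
lab = sx.AnalyteLabel.from_nomenclature("GalCer24:1")
series = sx.generate_dataset(cfg, conc_list=[10.0**-k for k in range(4, 11)],
                             seed=21, labels=[lab], replicates=60)
model = sx.train_quant(sx.featurize_dataset(series), seed=13)
print(model.r2, model.rmsep)      # 0.9994  0.048 (log10-M units)
```

## Command line

A thin CLI wraps the same functions; every run writes its resolved
configuration next to its outputs:

```bash
serstax simulate --design full --seed 11 out/sim
serstax featurize out/sim/manifest.csv out/features.csv
serstax train-taxonomy --seed 0 out/features.csv out/model.joblib
serstax forward-predict --hold-out GalCer16 --mini out/features.csv out/fp
serstax conc-transfer --probe GalCer16 out/train.csv out/probe.csv out/ct.csv
serstax train-quant / quantify / train-multiplex / quantify-mix ...
```

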