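# sleepfusion

EEG-only three-class sleep staging (Wake / NREM / REM) for REM sleep
behavior disorder (RBD), with the downstream statistics needed to judge
whether automated staging is clinically usable: night-level REM%/NREM%
agreement against manual scoring, and associations between automated REM%
and symptom scales.

RBD is the regime where automated staging usually breaks: loss of REM
atonia leaks EMG-band activity into REM epochs, nights are fragmented,
and REM–wake boundaries blur.  `sleepfusion` targets this setting with a
multi-stream model over an 8-channel clinical EEG montage
(Fp1, Fp2, C3, C4, O1, O2, A1, A2), and ships a synthetic
polysomnography generator so the entire pipeline is testable end to end
without any clinical data.

## The model

Each 30-s epoch x (8 channels, 100 Hz, 3000 samples) is encoded three
ways and fused:

```
e1 = CNN1d(x)            ∈ R^64      raw-waveform embedding
e2 = CNN2d(S(x))         ∈ R^64      S(x): 8×32×32 log-STFT tensor
h  = features(x)         ∈ R^65      band powers, time stats, SEF90
z  = [e1; e2; h]         ∈ R^193
g  = σ(MLP(z))           ∈ (0,1)^193 feature-wise gate
ŷ  = softmax(W3 ρ(W2 ρ(W1 (g ⊙ z)))) over {Wake, NREM, REM}
```

Training uses class-weighted cross-entropy (w_c = N/(3 N_c)), Adam, and
patient-wise five-fold cross-validation: all epochs of a participant stay
in one fold, and evaluation pools out-of-fold predictions.  A frozen
model applied to a whole night yields a hypnogram, from which
TST = 0.5 min × #(non-wake) and REM% = 100 × #REM/(#NREM + #REM) are
derived.  Agreement is quantified by Bland–Altman bias and limits
(bias ± 1.96 SD), MAE, and ICC(A,1); associations by Spearman rho with
Benjamini–Hochberg FDR and covariate-adjusted standardized regression.

The network runs on a small in-repo numpy layer library (convolutions,
batch norm, pooling, dropout, Adam) whose gradients are verified against
finite differences in the test suite.  See `docs/methods.md` for the full
account.

## Worked example

Simulate a small cohort, cross-validate, apply the frozen model and
compute agreement:

```bash
sleepfusion simulate --seed 21 --out data/        # EDFs + hypnograms + scales
sleepfusion train-cv --data data/ --folds 5 --out cv/
sleepfusion apply --checkpoint cv/checkpoint.npz --data data/ --out applied/
```

The same workflow through the library, on a 6-subject cohort:

```python
import numpy as np
from sleepfusion import (
    SimConfig, ModelConfig, PreprocessConfig,
    simulate_cohort, preprocess_recording, build_inputs,
    patientwise_cv, epoch_metrics,
)

cohort = simulate_cohort(SimConfig(n_subjects=6, epochs_per_night=60, seed=21))
dataset = {}
for rec, hyp in zip(cohort.recordings, cohort.hypnograms):
    epochs, qc = preprocess_recording(rec, PreprocessConfig())
    dataset[rec.subject_id] = (build_inputs(epochs), hyp.labels[: epochs.n_epochs])

pooled, folds = patientwise_cv(dataset, k=3, cfg=ModelConfig(), seed=21)
m = epoch_metrics(pooled["reference"], pooled["predicted"])
print(m.to_frame().round(3))
print(f"macro-F1 {m.macro_f1:.3f}")
```

prints

```
  stage  precision  recall     f1  support
0  Wake      1.000   0.994  0.997      163
1  NREM      0.994   1.000  0.997      155
2   REM      1.000   1.000  1.000       42
macro-F1 0.998
```

Near-perfect scores are expected here: the synthetic stages are separable by
construction, so this verifies the pipeline and its cross-validation
hygiene, not clinical accuracy (see `docs/methods.md` for what the
generator does and does not emulate).

## Layout

| Module | Role |
| --- | --- |
| `sleepfusion.io` | EDF/CSV containers, montage selection, 30-s epoching |
| `sleepfusion.preprocess` | band-pass, wavelet denoising, resampling, artifact QC |
| `sleepfusion.features` | the 65-d handcrafted vector (Welch bands, SEF90) |
| `sleepfusion.spectrogram` | 8×32×32 log-STFT tensors |
| `sleepfusion.nn` / `sleepfusion.model` | numpy NN core; the fusion stager, training, patient-wise CV |
| `sleepfusion.evaluate` | epoch metrics, night summaries, Bland–Altman, ICC |
| `sleepfusion.assoc` | Spearman + FDR, standardized regression |
| `sleepfusion.synthgen` | synthetic PSG cohorts with planted effects |
| `sleepfusion.cli` | `sleepfusion simulate / preprocess / train-cv / apply / agree / associate` |
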