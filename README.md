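# qappg — quality-aware PPG processing

Energy-aware heart-rate monitoring from wrist photoplethysmography (PPG).
Each 10 s segment is scored with 14 signal-quality indices (SQIs); an
energy-ordered cascade of boosted binary classifiers then selects a
processing algorithm from a small, energy-budgeted, diversity-maximized
portfolio (or discards the segment), and heart rate is estimated from the
in-band spectral peak (0.83–2.16 Hz). The package also ships the comparison
baselines — one-for-all processing (OFA) and quality-gated discarding (SQA)
— plus a seeded synthetic wrist-PPG generator so the whole pipeline is
testable end to end without any recorded data.

## Layout

| module | contents |
|---|---|
| `qappg.core_io` | record/segment data model, CSV + JSON-sidecar I/O, run config |
| `qappg.algorithms` | the 9-algorithm pool: bypass, Butterworth band/low/high-pass, cubic-spline baseline removal, db8 wavelet filtering, rank-2 STFT-SVD, EMD, SSA |
| `qappg.hr_estimation` | spectral HR from PPG, Pan-Tompkins-style ECG reference, usability labels, accuracy/MAE/RMSE |
| `qappg.sqi_features` | the 14 SQIs (6 amplitude statistics + 8 periodogram quantities) |
| `qappg.portfolio` | outcome vectors, normalized hamming distance, energy-budget filtering, greedy portfolio formation |
| `qappg.cascade` | per-algorithm quality classifiers, energy-ascending cascade, reject-rate calibration |
| `qappg.synthetic_data` | protocol-faithful session generator (2 min static / 1 min typing × 5) with graded artifacts and exact ground truth |
| `qappg.frameworks` | OFA / SQA / QAP runners, energy accounting, group analysis, comparison reports |

## CLI

```sh
qappg simulate --seed 1 --subjects 12 --out data/           # synthetic corpus
qappg features --data data/ --out features.csv              # 14-SQI matrix
qappg portfolio --data data/ --budget 100 --out pf/         # budgeted portfolio
qappg train --data data/ --out model/                       # cascade training
qappg run --data data/ --framework ofa --algorithm WVL --out ofa.json
qappg run --data data/ --framework sqa --out sqa.json
qappg run --data data/ --framework qap --out qap.json
qappg compare ofa.json sqa.json qap.json --out comparison.json
```

All commands accept `--config cfg.yaml` (window length, HR band, usability
threshold, reject rate, energy overrides) and `--seed`; runs log the resolved
configuration to stderr and a manifest JSON.

## Notes

- Energies per algorithm are declarative configuration (mJ per 10 s segment
  on the reference platform), not re-measured.
- The cascade learner is scikit-learn gradient boosting with logistic loss;
  wavelet/EMD/SSA primitives are implemented in-package (`_wavelet`, `_emd`)
  so the package has no dependencies beyond the scientific Python stack.
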