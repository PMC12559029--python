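# eegunfold

Deep-unfolded low-rank + sparse decomposition for single-channel EEG
artifact removal, together with the classical iterative solver it unfolds,
an SNR-controlled synthetic contamination protocol, and the standard
four-metric evaluation suite.

## The problem

Scalp EEG is routinely contaminated by ocular (EOG: slow, high-amplitude,
nonperiodic) and myogenic (EMG: fast, short-burst) artifacts that overlap
the brain signal in time and frequency. For a noisy segment `R`, the
additive model `R = D + N` separates a clean component `D` — approximately
**low rank** once the signal is windowed into a matrix, because brain
rhythms repeat across time windows — from a **sparse** artifact `N`.
With convex relaxations and a quadratic penalty this becomes

```
min_{D,N}  ||D||_*  +  mu ||N||_1  +  (beta/2) ||R - D - N||_F^2
```

solved classically by alternating singular-value thresholding (D-step) and
soft thresholding (N-step). The package's core is a **deep unfolding
network** that maps K iterations of this solver onto K learned stages:
a 1-D U-Net replaces the low-rank proximal step (Net-D), a small CNN with a
learnable step size `rho_k` replaces the sparsity-gradient step (Net-N),
and a near-identity CNN re-synthesizes the next raw estimate (Net-R), with
`R_0 = y`, `N_0 = 0` and the clean estimate `D_K` as output.

The network and its training loop run on a self-contained NumPy
reverse-mode autodiff engine (`eegunfold.nn`) — no deep-learning framework
required; gradients are finite-difference checked in the tests.

## Worked example

```python
import eegunfold as eu

# synthetic data: clean EEG-like rhythms + EMG-like bursts, mixed at -7..2 dB
bundle = eu.make_synthetic_bundle(500, 500, artifact_kind="emg", seed=0)

config = eu.UnfoldConfig(K=3,
    netd=eu.NetDConfig(depth=3, channels=(4, 8, 16)),
    netn=eu.NetNConfig(n_layers=2, channels=8),
    netr=eu.NetRConfig(n_layers=2, channels=8))
model = eu.build_model(config, seed=0)

train_set = eu.build_training_set(bundle, n_repeats=5, seed=0)   # 2000 mixtures
val_set = eu.build_eval_set(bundle, "val")
eu.train(model, train_set, val_set,
         eu.TrainConfig(lr=1e-3, batch_size=64, max_epochs=6, patience=6))

table = eu.run_benchmark(model, eu.build_eval_set(bundle, "test"))
print(table.table.to_string(index=False))
```

prints (abridged; `python examples/04_train_unfolded.py` runs it end to end)

```
  method snr_level  rrmse_t  rrmse_s       cc   snr_db
unfolded      -7.0 0.661358 0.287266 0.801676 3.638432
unfolded      -2.0 0.464498 0.190765 0.889114 6.698136
unfolded       2.0 0.403543 0.195616 0.914579 7.919345
unfolded      mean 0.502381 0.222714 0.872469 6.127971
```

Each row is the mean over the test segments mixed at one input SNR level:
`rrmse_t`/`rrmse_s` are the time- and spectral-domain relative errors
against the clean signal, `cc` the Pearson correlation, and `snr_db` the
**output** SNR — a segment contaminated at −7 dB comes out at ≈ +3.6 dB, a
lift of more than 10 dB, after a couple of minutes of CPU training.

Other capabilities, one script each, under `examples/`: synthetic
generation and SNR-exact mixing (`01`), the four metrics (`02`), the
classical solver separating spikes from a sinusoid (`03`), PSD reports
(`04`, `05`). A thin CLI wraps the same functions:

```
eegunfold simulate --n-segments 100 --artifact emg --snr -3 --out sim
eegunfold train --artifact emg --k 3 --out model.npz
eegunfold denoise --checkpoint model.npz --in sim_mixture.csv --out denoised.csv
eegunfold score --denoised denoised.csv --clean sim_clean.csv --out report.csv
```

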