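# roughfmri

Rough stochastic volatility analysis of multi-echo fMRI noise.

The variance of fMRI noise is commonly assumed constant over a scan.
This package implements an analysis that tests that assumption and
quantifies *how* non-constant the noise volatility is: multi-echo
acquisitions read the signal at several echo times within every
repetition time, and the dispersion of those echoes — after T2*-weighted
combination — gives a per-volume **realised volatility** proxy `vhat_t`,
the imaging analogue of building daily realised volatility from intraday
returns.  The roughness of the resulting log-volatility path is then
summarised by the Hurst parameter `H` of a **rough Bergomi (rBergomi)**
model,

    y_t    = sqrt(v_t) * eps_t
    v_t    = xi0 * exp( eta * int_0^t (t-s)^(H-1/2) dW_s - 0.5 eta^2 t^(2H) ),

with `H in (0,1)` (`H < 0.5` is rougher than Brownian motion) and
volatility-of-volatility `eta > 0` (`eta = 0` means constant volatility).
`(H, eta)` are calibrated pathwise by a 1-D convolutional neural network
trained on exactly-simulated log-volatility paths (Cholesky factorisation
of the analytic covariance — no discretisation error), and cross-checked
against ARFIMA(0, d, 0) long-memory estimates via Spearman rank
agreement.

Intended users: neuroimaging methods researchers studying
heteroscedasticity of scanner/physiological noise, and anyone needing an
exact rBergomi log-volatility simulator with a CPU-only CNN calibrator.

Everything is testable without scanner data: a synthetic phantom
generator produces multi-echo 4-D volumes whose noise has known
`(H, eta, xi0)` ground truth.

## Worked example

```python
from roughfmri import synthetic, model

# phantom with three known roughness strata and 8 echoes at 12-124 ms
spec = synthetic.PhantomSpec.stratified_h(
    (5, 5, 3), h_values=(0.05, 0.2, 0.4), n_volumes=200, seed=7)
ds = synthetic.simulate_phantom(spec)

m = model.RoughVolatilityModel.from_synthetic(ds)
res = m.fit(n_training_paths=4_000, seed=7)   # trains the CNN calibrator
print(res)
print(res.strata_medians())
```

prints (about four minutes on one CPU, training included):

```
Rough volatility calibration results
  voxels: 75
  weighted combination: True

           H     eta
Mean  0.3182  1.4096
SD    0.1403  0.4671
Max   0.7451  2.7339
Min   0.0839  0.6492

Spearman(H_hat, d_hat): rho=0.246, p=0.0337, n=75

Calibrator test RMSE: 0.1731 (H: 0.1695, tanh eta: 0.1766)

H_true
0.05    0.215432
0.20    0.240806
0.40    0.451775
```

Reading the output: per-voxel `H_hat` estimates are summarised
Table-style (Mean/SD/Max/Min); all `eta_hat > 0` (no voxel looks
constant-volatility); the positive, significant Spearman correlation
between `H_hat` and the ARFIMA `d_hat` is the independent memory
cross-check; median `H_hat` rises monotonically with the true `H` of
each stratum.  The calibrator here is *noise-matched* — trained on paths
carrying the echo-sampling noise of an 8-echo realised variance — which
is why its test RMSE is larger than the clean-path benchmark below and
why recovery stays monotone on measured data (see `docs/methods.md`).

The same pipeline runs on real data from one 4-D NIfTI file per echo:

```python
m = model.RoughVolatilityModel.from_nifti(
    ["echo-1.nii", "echo-2.nii", "echo-3.nii"],
    echo_times=[13.7, 30.0, 47.0], mask="ventricles.nii")
```

A staged CLI (`roughfmri simulate-training / train / simulate-phantom /
estimate-vol / calibrate / memory / report`) exposes the same steps with
YAML configs and seeded reproducibility; see `roughfmri --help`.

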