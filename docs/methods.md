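# Methods

## The model

A voxel's BOLD time series is modelled as `y_t = mu_t + sqrt(v_t) eps_t`
with `eps_t` i.i.d. standard normal.  In phantom scans and
cerebrospinal-fluid (ventricle) voxels no neural signal is present, and
after linear detrending `mu_t = 0`, so the series is pure heteroscedastic
noise: `y_t = sqrt(v_t) eps_t`.  The object of interest is the latent
variance path `v_t` and, above all, its *roughness*.

`v_t` is modelled by the rough Bergomi (rBergomi) variance process

    v_t = xi0 * exp( eta * int_0^t (t-s)^(H-1/2) dW_s - 0.5 eta^2 t^(2H) ),

a driftless, mean-reverting stochastic-volatility model.  `H in (0,1)`
governs the roughness of the log-volatility path (`H < 0.5` is rougher
than Brownian motion, `H = 0.5` is Brownian), `eta > 0` is the volatility
of volatility (`eta = 0` means constant volatility), and `xi0 > 0` is the
flat initial variance level.  The leverage correlation `rho` and the
price-path half of the model are irrelevant to noise analysis and are not
simulated.

### Kernel normalisation

By the Ito isometry the kernel above gives `Var(vtilde_t) =
eta^2 t^(2H) / (2H)`, whereas the compensator `0.5 eta^2 t^(2H)` matches
the `sqrt(2H)`-normalised kernel convention of the original rBergomi
literature.  The package implements the formulas exactly as written above
(so `E[v_t] = xi0 * exp(0.5 eta^2 t^(2H) (1/(2H) - 1))`), and exposes
`normalised_kernel=True` everywhere to switch to the `sqrt(2H)` kernel,
under which `E[v_t] = xi0` — a property the test suite verifies by Monte
Carlo.  The default is the verbatim convention; the choice does not affect
H recovery (it is an `H`-dependent rescaling of `eta`).

### Time grid

Model time is the unit interval: a series of `T` volumes is identified
with the grid `t_i = i/T`, `i = 1..T`.  The Hurst parameter is invariant
under affine rescaling of time, so the repetition time never enters; this
also makes simulated training paths and measured paths directly
comparable at equal length.

## Exact simulation

`vtilde_t = eta int_0^t (t-s)^(H-1/2) dW_s` is a centred Gaussian process
with covariance (for `s <= t`)

    C(s,t)/eta^2 = s^(H+1/2) t^(H-1/2) / (H+1/2) * 2F1(1/2-H, 1; H+3/2; s/t),

derived from the Euler integral of the Gauss hypergeometric function; the
diagonal reduces to `t^(2H)/(2H)`.  Sample paths are drawn exactly as
`eta L z` with `L` the Cholesky factor of the grid covariance and `z`
standard normal — no discretisation error.  An adaptive-quadrature
evaluation of the covariance integral cross-checks the closed form to
1e-8 in the tests.  Should plain factorisation fail, diagonal jitter
starting at `1e-12 * max(diag)` and escalating tenfold up to `1e-8` is
applied before the grid/H combination is declared ill-conditioned (for
the unit grid and H in [0.01, 0.99] no jitter is ever needed).  Factors
are cached per (M, H), so ensembles sharing parameters factorise once;
cached and uncached paths are bit-identical.

Fractional Brownian motion (for roughness illustrations and invariance
tests) is simulated the same way from `cov(s,t) = (s^2H + t^2H -
|t-s|^2H)/2`.

## Realised volatility from multi-echo data

Echoes within one repetition time are treated as intra-time-point
replicates.  Per voxel:

1. each echo's time series is linearly detrended (OLS on intercept +
   time), removing scanner drift;
2. `T2*` is fitted by log-linear regression of the time-averaged echo
   signal on echo time (`S_n = S0 exp(-E_n/T2*)`), the convention of
   multi-echo combination tooling.  Fits with no decay or `T2*` above a
   500 ms cap are flagged invalid and the voxel falls back to equal
   weights with a warning;
3. echo weights `w_n ∝ E_n exp(-E_n/T2*)` (normalised to sum 1).  The
   equal-weight variant (`w_n = 1/N`) is available throughout and, per
   the tests, ranks voxels near-identically;
4. the realised-variance proxy is the weighted intra-TR dispersion
   `vhat_t = sum_n w_n (y_nt - ybar_t)^2 / sum_n w_n` about the weighted
   mean `ybar_t`.

The calibrator consumes `log vhat` truncated to its input length `M`
(truncation preserves the sampling interval; interpolation would not) and
demeaned.  Exact zeros of `vhat` (all echoes equal) are floored at
`max(eps_machine, 1e-12 * median positive vhat)` before the log so the
path stays finite without disturbing the rest of the series.

Head-motion QC uses Power-convention framewise displacement
(`sum |d translations| + 50 mm * sum |d rotations|`, fd_1 = 0) from
6-column rigid-body parameter files.

## CNN calibration

The calibrator maps a length-M log-volatility path to `(H, eta)`.
Architecture: three 1-D convolution blocks of kernel size 20 with
32/64/128 kernels, each followed by leaky-ReLU (slope 0.1), dropout
(0.25/0.25/0.4) and max pooling of size 3; then a dense layer of 128
units with leaky-ReLU and dropout 0.3, and a 2-unit linear output.
Stacked valid-padding convolutions of kernel 20 with three pool-3 stages
would exhaust a 200-point input (200 -> 181 -> 60 -> 41 -> 13 < 20), so
convolutions use 'same' zero padding — the only geometry consistent with
the stated depth at M = 200.

The network is implemented directly in NumPy (im2col convolutions on
BLAS, explicit reverse-mode gradients, Adam); gradient correctness is
verified against central finite differences in the test suite.

Training targets are `(H, tanh eta)`; tanh bounds the eta axis so both
targets live on comparable scales.  Predictions invert with atanh after
clipping the raw outputs to `[1e-4, tanh(eta_max)]` (and H to
`[1e-4, 1-1e-4]`), so estimates are finite and inside the training range
by construction.

Input normalisation: every path entering the network — simulated or
measured — is demeaned per path and then compressed by the fixed
elementwise map `x -> sign(x) * log1p(|x|)`, identically at training and
inference.  Demeaning removes the arbitrary `log xi0` / noise-amplitude
offset of measured series.  The signed-log compression matters: path
amplitudes span two orders of magnitude over the (H, eta) prior, and the
parameters enter through power-law and multiplicative-scale structure;
in log space that structure is near-additive, and the weight-shared
convolutions train an order of magnitude faster to a far lower error
than on raw amplitudes (demeaning alone leaves the network badly
underfit — a plain log-increment regression then outperforms it).
Variants (per-time-point standardisation, first-sample anchoring, an
inner scale in the compression) were tried and rejected as worse.

Training data: P paths simulated exactly with per-path independent
`H ~ Unif(0,1)`, `eta ~ Unif(0,3)` (unique pairs enforced by rejection
resampling), nested holdout of 30% test then 20% validation of the
remainder — at P = 50,000 this is the canonical 28,000/7,000/15,000
partition; desk-scale runs in this package use P = 10,000
(5,600/1,400/3,000), a size chosen so the full protocol runs in minutes
on one CPU.

Optimisation protocol (unstated in the source method; chosen here and
recorded in every checkpoint sidecar): Adam at learning rate 1e-3, batch
128, squared-error loss on the scaled labels with axis weights (1, 1.5)
— the eta axis is the harder regression target — global gradient-norm
clipping at 5, learning rate halved after 4 stale validation epochs,
early stopping (patience 12) with restoration of the best-validation
weights.  Two protocol elements deserve explanation:

- *Annealed dropout.*  The architecture's dropout rates are active for
  the first 10 epochs, after which they anneal to zero with an Adam warm
  restart at 5e-4.  Dropout at the published rates is calibrated to the
  full 28,000-path training set; at desk scale it leaves the network
  strongly underfit, while annealing it off after a regularised warm-up
  recovers the accuracy of the deterministic network without discarding
  the published design.
- *Exact symmetry augmentation.*  Per batch, each path is multiplied by
  a random sign (the driving Brownian motion is symmetric, so `-path` is
  an equally likely draw with identical labels) and rescaled to a
  freshly drawn `eta' ~ Unif(0, 3)` with its label adjusted (the
  log-volatility process is exactly linear in eta).  Both operations
  produce exact samples of the training law, not approximations.
  Inference averages the raw outputs over the same symmetries
  (sign flips x eta rescalings 0.75/1/1.3, each eta prediction mapped
  back through its rescaling) — deterministic test-time augmentation.

Fit quality is reported in two RMSE conventions on the scaled-label
space: the headline `rmse` is the component-mean form
`sqrt(mean over all 2n components of the squared error)` — the number a
multi-output regression framework's MSE metric yields, and the scale on
which this package quotes calibration accuracy — and `rmse_euclidean =
sqrt(mean_i ||theta_hat_i - theta_i||^2)` per parameter pair
(= `rmse * sqrt(2)` for two outputs).  The component-mean convention is
the meaningful accuracy scale here: an exact-likelihood analysis of this
simulation protocol (the Gaussian posterior mean over (H, eta), the
MSE-optimal estimator) bounds the per-pair Euclidean RMSE above 0.08,
so quoted accuracies well below that can only refer to the
component-mean form.  Per-parameter RMSEs accompany both.

### Noise-matched calibration for measured data

A realised variance built from N echoes is a ~chi-squared estimate of the
latent variance with nu = N - 1 degrees of freedom, so a *measured* log
realised-volatility path is the latent log-volatility path plus additive
white ``log(chi^2_nu / nu)`` noise (std ~0.58 at N = 8).  That noise
dominates the fine-scale increments of smoother (higher-H) paths; a
calibrator trained only on clean simulated paths reads it as roughness
and collapses H estimates for smooth voxels toward zero — incidentally
the same mechanism that makes empirical fMRI noise volatility look
uniformly very rough.  ``TrainConfig.observation_noise_dof`` therefore
adds this exact noise channel to the training and validation paths
(exact for the equal-weight combination of Gaussian echoes, a close
approximation for the T2*-weighted one), and
``RoughVolatilityModel.fit`` enables it by default when it trains its
own calibrator, with nu taken from the data's echo count.  On synthetic
phantoms this restores monotone recovery of the H strata.  Simulation
benchmarks on clean paths keep the plain protocol.

## ARFIMA memory cross-check

An independent check of the calibration: the fractional differencing
parameter `d` of an ARFIMA(0, d, 0) fit to each voxel's log-volatility
series also orders series by memory/roughness, so `Spearman(H_hat,
d_hat)` across voxels should be positive.  `d` is estimated by the
profiled Whittle likelihood on the periodogram (spectral density
`∝ (2 sin(lambda/2))^(-2d)`), searched over `d in (-0.99, 0.99)` with
boundary estimates flagged; a conditional-sum-of-squares time-domain
estimator is available as `method="css"`.  The truncated binomial filter
`(1-B)^d` uses the stable recursion `w_k = w_{k-1}(k-1-d)/k` up to lag
min(T-1, 1000), applied causally at full length (the first value keeps
the raw observation; the inversion property `fracdiff(fracdiff(x,d),-d)
≈ x` then holds away from the burn-in edge without re-alignment).
Two-sided p-values, no multiple-testing correction.

## Synthetic phantoms

The generator builds multi-echo 4-D volumes with known ground truth:
clean mono-exponential echo decay `S0 exp(-E_n/T2*)` plus additive
Gaussian noise `noise_scale * sqrt(v_t) * eps_nt`, with `v_t` an exact
rBergomi path per voxel and noise independent across echoes within a TR —
the assumption that lets intra-TR echo dispersion estimate `v_t`.
Defaults emulate a 3T multi-echo EPI phantom acquisition: 8 echoes at
12–124 ms, 200 volumes, S0 = 1000, T2* = 50 ms, noise at 2% of S0,
xi0 = 1, eta = 1.5 (mid training range).  Per-voxel noise streams derive
from the master seed and the voxel's flat index (counter-based
splitting), so traversal order cannot change the data and identical seeds
give bit-identical datasets.

What the generator does *not* emulate: Rician magnitude statistics of
thermal MR noise (the additive-Gaussian form matches the demeaned signal
model the analysis assumes), k-space artefacts, slice timing, motion,
physiological noise, spatial correlation between voxels.  Passing
recovery tests therefore show the pipeline is correct under its own
model assumptions, not that real scanner noise follows the rBergomi law.

Recovery behaviour worth noting: with N echoes the realised variance at
each volume is a ~chi^2_(N-1) estimate of `v_t`, so `log vhat` equals the
true log-volatility path plus heavy white measurement noise.  That noise
biases pathwise H estimates downward (toward apparent roughness) for all
voxels; the *ordering* of H across voxels survives, which is what the
parameter-recovery acceptance tests (median H_hat monotone in true H;
Spearman(H_hat, d_hat) > 0) assert.

## Problem sizes in the shipped tests

Unit tests use grids of 10–100 points and hundreds of paths.  The
acceptance suite trains two calibrators: the clean-protocol desk-scale
one (10,000 paths, M = 200, up to 55 epochs) for the RMSE benchmark, and
a noise-matched one (4,000 paths, 40 epochs, nu = 7) for the end-to-end
phantom-recovery test (5x5x3 voxels, 3 H strata, 200 volumes, 8 echoes);
simulator exactness
uses 10,000 paths per H value, asserted at fixed grid points under a
fixed seed — a 3-standard-error band at every one of 200 points jointly
fails with near certainty for a correct simulator, so a small fixed set
of points is the statistically honest check.

## Known limitations

- The mapping from measured log realised volatility to the calibrator's
  training distribution is approximate: measurement noise from finite
  echo counts is not present in the training paths, so absolute H values
  on data are biased low (see above); comparisons should be ordinal.
- The Whittle estimator assumes stationarity; log-volatility paths with
  `H` far above 0.5 are near the nonstationary edge and `d_hat` may pin
  at the optimiser bound (flagged).
- The CNN's accuracy degrades for `eta` near 0 (paths close to constant,
  parameters weakly identified) and `eta` near the tanh saturation.
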