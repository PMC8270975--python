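# Methods

This document describes the models implemented in `nvckit`, the parameter
conventions, the scope of the synthetic-data generator, the numerical choices
made in the estimators, and their known limitations.

## 1. Signals and conventions

All traces are uniformly sampled 1-D time series with an attached stimulus
protocol (`stim_onset`, `stim_duration`, seconds) and a half-open baseline
window `[start, end)` that must end at or before stimulus onset. Modalities:

- **calcium** — somatic or neuropil fluorescence, arbitrary units (ΔF/F after
  normalization);
- **diameter** — vessel lumen diameter, µm;
- **velocity** — red-blood-cell (RBC) axial velocity, mm/s (signed).

Trial normalizations (`nvckit.trials`):

- ΔF: `x − mean(baseline)`;
- percent change: `100 · (x − mean(baseline)) / mean(baseline)` (undefined for
  a zero baseline mean — an error);
- z-score: `(x − mean(baseline)) / sd(baseline)` with the sample SD
  (`ddof=1`); a zero baseline SD is an error, not a silent infinity.

Baseline statistics are NaN-aware. Trial averaging requires a shared time
base (relative tolerance 1e-6) and returns the point-wise mean with a
standard-error band `sd/√n`.

## 2. Kymograph extraction (`nvckit.kymo`)

A kymograph is a line-scan image: rows are successive scans (period
`dt_line`, s), columns are positions along the scan (pitch `dx`, µm).

**Diameter.** Each line is averaged with a causal moving mean over the
preceding 200 ms of lines (output at line *i* depends only on lines ≤ *i*),
then the lumen width is the distance between the two half-maximum crossings
of the background-subtracted intensity profile, located to subpixel precision
by linear interpolation. Quality is the profile contrast relative to the
image contrast; zero-contrast lines return NaN with quality 0.

**Velocity.** Moving RBCs produce dark streaks whose slope in the
(time, space) plane is the inverse velocity. In overlapping windows
(50 ms, 75 % overlap) the streak angle is found by shear-projection: for a
candidate slope, each line is shifted by the corresponding per-line
displacement and the between-column variance of the sheared window (an
ANOVA-style alignment score, between-SS / total-SS) is maximized. The search
is seeded by an FFT cross-correlation of adjacent line pairs and refined by
staged bracketing. Velocity is `slope · dx / dt_line / 1000` mm/s (signed);
windows whose best score falls below 0.2 (default) are returned as NaN with
their score as quality. Windows shorter than 8 lines are rejected.

**Activation map.** For frame stacks, a pixel is active when its
stimulus-window mean exceeds baseline by more than `threshold_frac` times the
maximum baseline-subtracted response; the map is invariant to intensity
scaling.

## 3. Sigmoid onset model (`nvckit.onset`)

Rising responses are fitted with

```
s(x) = A + B / (1 + exp((x + C) · D))
```

The fit is multi-start nonlinear least squares (Levenberg–Marquardt): a grid
of 40 starts crossing |D| ∈ {0.5, 1, 2, 5}, both signs of D, and five
quantiles of the fit window for the midpoint −C. Parameters are canonicalized
to B ≥ 0 after fitting, so a rising response has D < 0. Fits with
|B| below max(1e-8, 1e-3·sd(data)) are flagged unidentifiable.

Onset times at 10/25/50 % of the fitted span B are closed-form inversions of
the sigmoid, reported relative to stimulus onset when one is supplied, and
are therefore exactly self-consistent with the fitted curve (residual below
1e-9 by construction). Levels unreachable within the asymptotes are flagged
rather than extrapolated. The rising-slope statistic is the rate parameter D
(1/s); time dilation by a factor k scales it by 1/k.

The model follows a statsmodels-style shape: `SigmoidOnsetModel(...).fit()`
returns a `SigmoidOnsetResults` object carrying parameters, closed-form
onset queries, and a text summary.

## 4. Gamma-variate transfer function (`nvckit.tf`)

The vascular response is modeled as the convolution of the neural (calcium)
trace with a delayed gamma-variate kernel

```
TF(t) = H(t − p3) · p4 · (t − p3)^(p1−1) · p2^p1 · exp(−p2 (t − p3)) / Γ(p1)
```

with shape `p1 > 1`, rate `p2` (1/s), delay `p3` (s), and gain `p4`. The
kernel integrates exactly to `p4`, is exactly zero for `t ≤ p3`, and peaks at
the mode `p3 + (p1 − 1)/p2`. Evaluation uses `gammaln` in log space for
numerical stability. Default initial parameters are
`(1.3, 0.5, 0.27, 0.19)` (mode 0.87 s, gain 0.19). Discrete prediction is
`conv(input, kernel) · dt` truncated to the input length; the kernel is
tabulated out to a 1e-8 mass tail.

**Fitting.** `TransferFunctionModel.fit(seed)` minimizes the residual sum of
squares by two rounds of seeded simulated annealing (Metropolis acceptance,
geometric cooling at 0.95, reflection at the box bounds
p1 ∈ (1, 10], p2 ∈ (0, 20], p3 ∈ [0, 5], p4 ∈ (0, 100]), each round
finished with an L-BFGS-B polish; the better round wins. The default
protocol runs 200 restarts per round at 200 iterations; `FitConfig.small()`
(20/20/80) is the documented reduced protocol used in tests and simulation
studies to meet runtime budgets — a package choice, not a statement about
the method's asymptotic protocol. All randomness derives from a user
`seed` via `numpy.random.SeedSequence` spawning, so fits are bit-identical
for a fixed seed.

**Cross-state prediction.** `cross_predict` convolves a calcium trace with a
kernel, applies the closed-form least-squares scale
`⟨observed, predicted⟩ / ⟨predicted, predicted⟩`, and reports Pearson r
(scale/offset invariant) and R². `compare_states` fits a sigmoid to each
prediction's rising phase (window from trace start to the prediction argmax)
and reports per-network r and rising-slope magnitude for two candidate
kernels, for testing whether a state-matched (fast) kernel out-predicts a
mismatched (slow) one.

## 5. Vasomotion (`nvckit.vaso`)

**Bandpower** is computed from a boxcar periodogram (constant detrend) by
summing ordinates in 0.02–1 Hz times the frequency step; a sinusoid of
amplitude A contributes A²/2. The band's upper edge must lie below Nyquist.

**Phase classification** low-passes the trace at 0.2 Hz (4th-order
Butterworth, zero-phase `sosfiltfilt`) and inspects the last 2.5 s of the
baseline: above/below the whole filtered-baseline mean crossed with the
endpoint trend (rising/falling) yields four classes — 1: rising-high,
2: falling-high, 3: falling-low, 4: rising-low. Ties (flat or exactly at the
mean) resolve to the lower class and are flagged. For an ideal sinusoid the
class boundaries sit at phase offsets π/4 + kπ/2; the zero-phase filter's
finite-record edge response shifts the empirical boundaries by up to
≈0.03π, which is why exactness of the quarter partition is asserted on an
offset grid whose points sit at cell midpoints, away from boundaries.

## 6. Synthetic-data generator (`nvckit.synthdata`)

The generator is a first-class component, not a test fixture. A frozen
`GroundTruth` holds the true kernel parameters, calcium kinetics (double
exponential, peak-normalized), vasomotion (single sinusoid, default 0.1 Hz,
amplitude in the units of the trace), and white observation noise; its
invariants (p1 > 1, vasomotion frequency inside 0.02–1 Hz, nonnegative
noise/amplitude, positive time constants) are enforced at construction.

Default magnitudes are anchored to typical awake-rodent line-scan reports:
kernel gain 8 (≈6 % evoked dilation for the default calcium transient),
vasomotion amplitude 2 % of baseline, observation noise 0.3 %. Trial sets
draw per-trial noise and (optionally) vasomotion phase from per-trial
children of a `SeedSequence`, with optional amplitude jitter, adaptation
decay, and baseline offset. Kymographs are rendered from diameter traces
(error-function edge profile, 0.3 µm blur, dark background) or velocity
traces (advected periodic shadow pattern, spacing 8 µm, advancing by
`v · dt_line` per line), with per-pixel noise.

All generator randomness is reproducible from `(truth.seed, stream)` pairs;
distinct streams decouple calcium noise, vascular noise, and rendering.

## 7. Pipeline (`nvckit.pipeline`)

`run(RunConfig)` simulates per-arbor trial sets for both modalities, z-scores
trials, averages them, fits the sigmoid onset (window from baseline start to
the mean-z argmax), fits the transfer function between the z-scored means,
profiles vasomotion on percent-change trials, and writes CSV artifacts plus
a `report.json` with the seed and a config hash for provenance. Runs are
byte-identical for identical configs. `reproduce_state_contrast` builds
matched fast/slow-kernel regimes and scores cross-predictions per network.

## 8. Numerical choices and limitations

- **Fit-on-means design.** Transfer functions are fitted between trial
  means, not single trials; replicate-level tolerances in the test suite are
  medians over seeded replicates, matching how the estimator is meant to be
  used.
- **Kernel identifiability.** With few trials, residual vasomotion that
  survives trial averaging is structured (not white) and shifts the global
  least-squares optimum of the kernel parameters. At 2 % vasomotion and 8
  trials, single-realization mode errors of ±10 % are an information limit
  of the data, not an optimizer failure (verified: the biased optimum has
  lower RSS than the best-scaled true kernel, and polishing from the truth
  converges to the same biased optimum). Near-degenerate parameterizations
  (p1 → 1 with compensating delay p3) can occur on unlucky realizations.
- **Phase boundaries.** The filter edge response bounds the accuracy of the
  phase-class boundaries to ≈0.03π in offset; classifications of points near
  a boundary can differ from the ideal-sinusoid assignment by one class.
- **Velocity extremes.** Very slow flow (streaks steeper than the window
  height) and very fast flow (less than one pixel of shadow advance per
  window) degrade the alignment score; affected windows are quality-flagged
  rather than silently reported.
- **Reduced annealing protocol.** The shipped default (200/200/200) is
  expensive; studies and tests use `FitConfig.small()`. Both are exposed and
  seeded; results state which protocol produced them.
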