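# Methods

This note documents the models, the numerical choices, and what the
synthetic benchmark can and cannot show.

## Measurement model and simulator

The generator emulates a scanning capacitance probe in a mammalian
fed-batch. Its purpose is statistical fidelity to the situations the soft
sensor must survive — not electromagnetic accuracy.

**Culture dynamics.** Three states are integrated with fixed-step RK4
(5 sub-steps per online interval): viable cells V, dead cells D, and
debris B (in lysed-cell equivalents, all in 10⁵/mL):

    dV/dt = μ_max·s(t)·(1 − (V+D)/K)·V − δ·(1−s(t))·V
    dD/dt = δ·(1−s(t))·V − λ·D
    dB/dt = λ·D

with a sigmoid switch s(t) of width 6 h centred on the death-onset time, so
growth hands over smoothly to first-order death; dead cells lyse to debris
at rate λ. Total cells are TCC = V + D, and the bookkeeping conserves
material: d(V+D+B)/dt equals the growth term alone. Bolus feeds dilute all
three states instantaneously. This is the simplest ODE set that produces
the canonical fed-batch phenomenology: rise, peak, decline, with debris
accumulating only late.

Defaults (chosen once from CHO fed-batch practice): μ_max = 0.04 h⁻¹
(≈17 h doubling), K = 150 (1.5·10⁷ cells/mL peak), death onset 192 h,
δ = λ = 0.02 h⁻¹, duration 336 h (14 d), inoculum 5·10⁵/mL (valid range
3–10). Online sampling every 0.5 h (673 spectra), offline counts every 12 h
(29 samples) — dense spectra, sparse counts, as in practice.

**Dielectric response.** The per-channel capacitance is

    C(t, f) = c_cell·V(t)·g(f; fc_cell, α) + c_deb·B(t)·g(f; fc_deb, α) + artifacts

where g is the real part of the Cole-Cole relaxation
1/(1 + (i·f/fc)^(1−α)), which reduces to the Debye form 1/(1+(f/fc)²) at
α = 0; it is monotone decreasing, 1 at low f and 0 far above fc. Viable
cells use fc = 1.2 MHz (β-dispersion midpoint of a ~15 µm cell), debris
fc = 8 MHz (smaller particles relax higher), α = 0.1. The per-cell
amplitude 0.8 pF/cm per 10⁵ cells/mL puts the peak low-frequency signal
near 100 pF/cm, the magnitude a probe reports in a dense culture. The
debris amplitude default (1.0 pF/cm per unit) makes the declining phase
*debris-heavy*: by the end of a run the low-frequency channels carry more
debris signal than cell signal, which is exactly the regime in which
single-frequency calibrations fail by +100%.

**Disturbances.**

* multiplicative channel noise, CV 2% (instrument-level repeatability);
* offline counting noise, CV 5% (typical trypan-blue counter
  repeatability), applied independently to VCC and TCC with TCC ≥ VCC
  enforced so viability stays in (0, 100];
* bubble bursts: Gaussian dips (depth 5%, width 0.7 h) multiplying the
  dielectric signal;
* bolus feeds: 4% dilution steps;
* baseline drift: each channel drifts linearly with slope
  drift_rate·(f/f_max)·z_f, z_f a run-specific standard normal draw,
  default 0.03 pF/cm/h at 10 MHz. Drift is frequency-weighted and
  run-specific because electrode polarization, fouling and grounding
  artifacts hit the numerically small high-frequency channels hardest and
  differ between reactors and sites. This is the feature that makes the
  high channels non-transferable and lets the frequency-window ablation
  (1:10 versus 1:17) emerge from the physics rather than by construction.

**Fleets.** `generate_clone_pair` builds two fleets whose only systematic
difference is the per-cell amplitude (the clone phenotype that κ must
recover — deliberately *not* jittered). Per-run seeded variation: lognormal
jitter of the culture kinetics (5%) and of the debris critical frequency
(15%, debris size distributions differ run to run), inoculum clipped to the
3–10 seeding range.

**What the generator does not emulate:** electrode polarization physics,
conductivity channels, temperature effects, morphology changes (cell size
drift), perfusion formats, and gross events such as detergent treatment.
Passing the benchmark therefore shows that the pipeline is correct and
robust to the modeled disturbance classes; it does not certify performance
on real spectra, where slope errors from cell-size changes are a known
additional failure mode.

## Alignment

Offline VCC is interpolated onto the online grid with a cubic interpolating
spline, not-a-knot end conditions (the default of the standard numerical
tool for this task), which preserves the curvature of VCC between samples.
Two offline points degrade to linear interpolation. No extrapolation: online
timestamps outside the offline hull are dropped, because extrapolated cubics
oscillate. Alignment is per run; rows are pooled afterwards for fitting.

## Scaling and frequency selection

Columns are mean-centered (default) or standardized; the response is
centered only, never standardized — coefficients then keep interpretable
units. Scaling constants are stored in the model and re-used verbatim on
new data; coefficients are mapped back to raw pF/cm units so a serialized
model is a plain linear equation.

Windows are contiguous prefixes 1:k of the grid. The published window is
1:10 (0.3–2.16 MHz); on a 17-point log grid from 0.3 to 10 MHz the 10th
frequency is exactly 0.3·(10/0.3)^(9/16) = 2.16 MHz, which is why that grid
is adopted as the instrument's. The `data_driven` mode automates the visual
capacitance-map procedure: keep the longest prefix in which every channel's
whole-run Pearson correlation with splined VCC, averaged over runs, is
≥ 0.8. The threshold is a package choice (the visual procedure has no
formula); 0.8 separates cleanly because cell-dominated channels correlate
near 1 and debris-dominated channels fall well below it once a decline
phase exists. Selection is global across runs, not per clone.

## PLS estimator

SIMPLS (univariate response) computes weight vectors directly from the
deflated cross-covariance X'y; scores are orthonormalized, and the
basis V of loading space is used for deflation. Numerics: extraction stops
early, without error, when the residual cross-covariance norm falls below
1e-12 of its initial value (the response is exhausted — e.g. exactly linear
data); requesting more components than the numerical rank of the scaled
predictor matrix raises a rank error. At full rank the estimator equals
ordinary least squares; with truncation it equals NIPALS PLS — both are
enforced as test oracles (OLS to 1e-8, scikit-learn's NIPALS to 1e-6).

Component convention: three latent components whenever the window holds at
least three frequencies (they capture > 99% of the spectral variance; the
remainder is noise), else as many components as frequencies. Explained
X-variance is accumulated per component as ‖p_a‖²/‖X₀‖²_F.

Negative VCC estimates are reported, never clipped — evaluation must see
the raw estimator; the CLI offers clipping for display only.

The dual-mode baseline regresses VCC on (a_work − a_ref) by OLS, working
channel = grid frequency nearest 1 MHz (index 6, 0.90 MHz), reference =
channel 17; calibration on the exponential phase (rows up to the aligned
VCC maximum) or the whole run.

## Kappa transfer

x̂ is evaluated spline-free at offline timestamps via the nearest online
spectrum (required within one sampling interval). Default lag 6 h, minimum
3 qualifying samples — "a few hours" made concrete and config-exposed.
`regression` mode fits (κ, d) jointly by least squares and is the default;
`offset_anchored` pins d with the inoculation count and fits κ through that
anchor (the one-measurement workflow). Online updating re-fits from all
qualifying samples at each new count (no forgetting factor — the simplest
scheme that is exactly equivalent to the batch estimate) and appends to an
immutable κ trace. κ ≤ 0 raises a transfer failure: the base model does not
track the run at all. Whether d should be re-fit per run or fixed at
inoculation is genuinely open; both modes are provided rather than guessing
a single intent.

## Evaluation

RMSE uses the n−1 denominator. CVRMSE divides by the mean *estimated* VCC
(the convention adopted throughout; a flag switches to the mean of the
measurements, which typically changes values by a few percent). Errors are
computed at offline timestamps only, where measured VCC exists without
interpolation error. Verdicts: accepted iff whole-process ≤ 33% and
exponential ≤ 25%; rejected iff whole-process > 50%; questionable
otherwise. The exponential phase ends at the offline sample of maximum
measured VCC; a run declining from its first sample degenerates to a
single-point exponential phase and warns.

## Benchmark sizing

The default benchmark uses 5 training + 6 validation runs per clone
(22 runs of 673 spectra × 17 channels each), amplitude ratio 1/0.69, and
both transfer directions; it completes in a few seconds on one CPU, so no
scaling down was needed. The single-frequency R² check runs on a dedicated
disturbance-free, noise-free run: that claim concerns standard, highly
viable short-term cultivations, not the stressed debris-heavy fleet used
for everything else.

## Known limitations

* The simulator's debris channel is a single lumped state; real broths have
  particle-size spectra that evolve.
* κ is a pure gain correction; slope drift *within* a run (e.g. progressive
  cell swelling) is not representable and would appear as CVRMSE.
* The data-driven window rule assumes at least one run with a decline
  phase; without one it warns and effectively returns the full grid.
* Cole-Cole parameters are generator inputs, not fitted quantities; the
  package deliberately contains no mechanistic spectrum-fitting.
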