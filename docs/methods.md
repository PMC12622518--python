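# Methods

This note documents the models, the numerical choices behind them, and what
the synthetic-data generators do and do not emulate.

## Dose–response model

The ratiometric readout R = F405/F488 follows a Hill-type binding isotherm

    R([G]) = Rmax + (Rmin − Rmax) / (1 + ([G]/Kd)^p)

with R(0) = Rmin exactly (the zero concentration is evaluated as the
model's limit, never log-transformed), R(Kd) = (Rmin+Rmax)/2 for every
Hill slope p, and ΔRmax = (Rmax − Rmin)/Rmin. Quantification inverts the
curve in closed form, [G] = Kd·((R − Rmin)/(Rmax − R))^(1/p), and censors
readings at or outside (Rmin, Rmax) rather than raising.

**Fitting.** Nonlinear least squares with initialization Rmin ← min ratio,
Rmax ← max ratio, Kd ← concentration nearest half-response, and multi-start
over p ∈ {1, 0.5, 2}; p is free within [0.3, 4] by default
(`fix_hill_slope` pins it). Kd is bounded to [min positive conc/10,
max conc·10] so the fit never extrapolates the binding constant outside the
sampled range; hitting a bound raises a QC flag. The default error model is
*relative*: residuals are iteratively reweighted by the fitted curve
(σᵢ ∝ R̂ᵢ), the correct likelihood when plate fluorescence errors are
multiplicative. This matters for inference, not just efficiency — with
3 % multiplicative ratio noise the unweighted Wald CI on Kd covers ~89 %
instead of 95 %; the reweighted fit covers ~94 %. `error_model="absolute"`
restores plain least squares.

**Working range.** `valid_range_uM` is the 10–90 % response band,
[Kd·(1/9)^(1/p), Kd·9^(1/p)]. Outside it the curve's slope is too shallow
for useful inversion; agreement statistics and recovery claims are scoped
to this band.

**Detection limit.** The assay-convention 3σ criterion: LOD is the inverse
image of (blank mean + 3·blank sd). Noiseless blanks give LOD = 0; a blank
criterion beyond Rmax means the matrix saturates the sensor and the LOD is
undefined (flagged). LOD is monotone in blank noise and shrinks as ΔRmax
grows.

**Quantification.** Samples are mixed 3:1 with sensor, so the default
dilution factor is 4/3. Replicate ratios are averaged before inversion; the
95 % CI combines the delta-method variance from the calibration covariance
with the replicate scatter propagated through the inverse-curve slope, in
quadrature. A bootstrap alternative was considered and dropped: the delta
method is exact enough within the working range and keeps quantification
deterministic.

**Method agreement.** Estimate-vs-reference slope, intercept and R² by
least squares, plus mean relative error and per-level CVs. Because
inversion noise grows steeply toward the top of the range, the regression
optionally takes per-estimate standard deviations and switches to
inverse-variance weighting (with weighted R²); the spike-recovery pipeline
uses this, feeding in the quantification CIs.

## pH correction and normalization

The sensor and the unfused reporter fluorophore share their pH response, so
dividing the sensor ratio by the reference ratio cancels pH to first order;
`normalize_to_control` divides by the control-group mean. Both are explicit
steps so every derived number states its denominator.

## Melt-curve analysis

Dye-based thermal shift curves rise sigmoidally through unfolding and often
quench afterwards. Tm is the *derivative-curve* convention: the maximum of
the smoothed dF/dT. Numerical pipeline:

1. Savitzky–Golay smoothing of fluorescence (order 2). The window is
   specified as a temperature span (default 2 °C) and converted to an odd
   point count per curve, because a fixed point count under-smooths fine
   acquisition grids: at a 0.1 °C grid with 1 % amplitude noise an 11-point
   window leaves ~0.5 °C of Tm jitter, an order of magnitude worse than the
   span-based default (±0.04 °C).
2. `np.gradient` of the smoothed trace.
3. Peak search restricted to the configured range (default [30, 90] °C) and
   to temperatures at or below the global smoothed-fluorescence maximum —
   this tolerates post-transition quenching without mistaking the falling
   edge for a transition.
4. Refinement by a quadratic fit over the contiguous derivative region
   above half the peak height. A 3-point vertex is noise-dominated on fine
   grids; the half-height region spans the transition's real curvature and
   its correlated smoothed noise averages out.

A nowhere-positive derivative in range yields a no-transition result (NaN
Tm, flagged), which propagates through ΔTm. Binder calls use strict
ΔTm > 2 °C; a supplied concentration series additionally reports whether
ΔTm is non-decreasing with dose. Replicates are averaged at the Tm level
(mean ± sd, n = 3 in the emulated design).

## Transport kinetics

Reference-corrected ratio traces are inverted pointwise through the in-cell
calibration. Below-range points are genuine "empty cell" readings and enter
rate fits as 0; above-range points are censored to NaN; a trace more than
half censored is rejected.

The initial uptake rate is the slope of a line over the initial window
(default 300 s — six samples at the 1-min kinetic interval; a 60 s window
at that interval would hold only two points). Because inversion noise is
heteroscedastic (σ_C ∝ 1/(dR/dC), exploding toward saturation), the fit is
weighted by (dR/dC)² when the trace carries its calibration — the
inverse-variance weights under constant ratio noise. The weights are
re-evaluated on the fitted line in two passes so weight noise does not
correlate with residuals; one-pass weighting biases the downstream Km low
by ~8 %. `weighting="uniform"` gives ordinary least squares. An adaptive
window mode shrinks the window until the quadratic curvature term loses
significance (t-test, α = 0.05), guarding against saturation bias on
strongly curved traces.

Michaelis–Menten fits (v = Vmax·S/(Km+S)) use nonlinear least squares
seeded by a Lineweaver–Burk estimate; the double-reciprocal estimate itself
is only a diagnostic, attached to the error on non-convergence, never
reported as the primary fit. A post-hoc warning flags substrate designs
that fail to span [Km/3, 3·Km] of the estimate. Rates are per assay well at
OD600 = 5.0; no per-cell conversion is attempted.

Transport-type classification is threshold-based: percent inhibition
100·(1 − treated/baseline) per treatment; a protonophore-class treatment at
or above 90 % while all other classes stay below 50 % ⇒ proton-coupled
(analogously for thiol and metabolic classes). Thresholds are configuration
with logged defaults; without a protonophore treatment the call is
indeterminate. Competitor substrates are reported as percent rate reduction
and never drive the label.

## Isotopologue correction and flux partitioning

Elemental isotope vectors are CIAAW/IUPAC 2021 representative compositions
indexed by nominal mass shift (H, C, N, O, Si, S). Formula distributions
are convolution powers with tail truncation at 1e−12 cumulative mass.

The correction matrix for a fragment with n tracer-carbon positions has
column j = (natural ¹³C binomial over n−j unlabeled positions) ∗ (purity
binomial over j labeled positions) ∗ (natural distribution of all non-tracer
atoms). With zero natural abundance and unit purity it is the identity.
Raw areas are deconvolved by non-negative least squares (`scipy nnls`) and
renormalized — unlike a direct matrix inverse this guarantees physical
(non-negative, sum-1) distributions under noise. Condition numbers above
1e8 raise a flag. Derivatized fragments (e.g. TBDMS) are handled through
whatever elemental formula the input supplies; nothing is hard-coded.

The flux split solves obs ≈ f·H + (1−f)·D with boundary MDVs H (pure
hydroxylation, from the ΔgcdH strain) and D (pure dehydrogenation, ΔcsiD).
`full_mdv` mode projects onto the H−D segment in closed form and clips to
[0, 1]; `m5_ratio` solves the same mixture on the m+5 channel alone. The
two agree exactly whenever H and D differ only in the m+0/m+5 channels;
both are always reported because either convention is defensible, with
`full_mdv` the default (it uses all channels). Boundaries closer than 1e−6
in Euclidean norm are rejected as unidentifiable. Uncertainty comes from a
percentile bootstrap over replicates (seeded, deterministic); with three
replicates the percentile CI is coarse and undercovers — near-nominal
coverage needs ~8 or more replicates, which the test suite demonstrates.

## Synthetic data

Generators are pure functions of (config, seed); each file role draws from
its own stream keyed by (seed, role), so adding one dataset never perturbs
another, and every dataset ships a truth record embedding the scenario
digest.

Emulated conditions (defaults = the study conditions the analyses assume):

* **Dose–response**: Rmin 1, Rmax 7.46 (ΔRmax 646 %), Kd 60.68 µM, p 1;
  12 concentrations 0–2000 µM in triplicate; 3 % multiplicative ratio
  noise. Channels are split as F488 fixed, F405 = R·F488, so the tabular
  invariant R = F405/F488 holds exactly.
* **Melt curves**: 25–95 °C at 0.1 °C steps, logistic transition (Tm
  52.3 °C, width 1.5 °C), linear quench beyond Tm + 3 widths, Gaussian
  noise at 1 % of amplitude.
* **Uptake**: dC/dt = Vmax·S/(Km+S) with Km 23.34 µM, Vmax 10 µM·min⁻¹,
  8 substrate levels (5–200 µM), 1-min sampling for 10 min, 5 % ratio
  noise, mapped through the in-cell calibration (Kd 10.22 µM); inhibitor
  panel programmed at 95/10/10 % (protonophore/thiol/metabolic).
* **Labeling**: 50 % feed label fraction (the 2.5+2.5 g/L feed, mole ≈ mass
  fraction for a pure compound), tracer purity 0.99, f_hydroxylation
  0.9338; three strains (WT and both single-pathway knockouts) ×
  triplicate; true MDVs forward-convolved through the correction matrix,
  additive channel noise at 1 % of total area, clipped non-negative. The
  default boundary MDVs are *illustrative* shapes (hydroxylation route
  concentrated at m+4/m+5, acetyl-CoA route at m+2/m+3), not a TCA
  atom-map.
* **Spike recovery**: 20 levels 0–2000 µM, 3:1 mixing, triplicate, 1 %
  sensor ratio noise and 1 % reference noise — the precision of a
  purified-sensor in vitro plate assay, where ratiometric readout cancels
  common-mode (volume/concentration) errors; the noisier 3 % default
  belongs to the calibration scenario.

What the generators do **not** emulate: instrument drift, well-position
effects, spectral bleed-through, chromatographic peak integration, matrix
quenchers, or cell-to-cell expression variability. Passing recovery tests
therefore demonstrate the estimators' correctness and statistical behavior
under the stated noise models, not robustness to every artifact of real
instruments.

## Degenerate inputs and tie-breaks

Flat dose–response plates fit with Rmax ≈ Rmin and are flagged rather than
rejected; non-monotone calibrations (|Spearman ρ| < 0.5) are flagged.
Quadratic peak refinement falls back to the grid maximum when the local fit
is not concave, and clips the vertex into the fitted region. All-zero
isotopologue vectors and empty control sets are errors. Concentration-unit
columns are canonicalized to µM (nM/mM/M accepted).

## Known limitations

* The flux model is a two-source mixture, not a full ¹³C-MFA network; it is
  identifiable only insofar as the boundary MDVs differ.
* The bootstrap CI for the flux fraction undercovers at triplicate scale
  (see above).
* Kd values from in-cell endpoint fits inherit whatever normalization the
  ratios carry; Kd and p are invariant to global rescaling (asserted in the
  tests), but Rmin/Rmax are reported on the input scale.
* Transport classification is deliberately threshold-based; no membrane
  flux ODEs or symport stoichiometry are modeled.
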