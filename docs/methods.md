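# Methods

`maldicrs` analyses whole-cell MALDI-TOF MS dose-response bioassays: one
spectrum per target-plate spot, several technical replicates per compound
concentration, hundreds of metabolite m/z features monitored simultaneously.
The pipeline turns raw spectra into per-feature concentration-response
curves and ranks the features by a composite Curve Response Score (CRS).

## Preprocessing

Stages run per spectrum in a fixed order, each individually switchable and
each stamping a metadata flag so no stage can run twice:

1. **Savitzky–Golay smoothing** (half-window 10 points, order 3). Wide
   windows relative to the peak width produce small ringing lobes next to
   tall peaks; these are dose-proportional to their parent peak but carry no
   independent information, and the scoring stage leaves them well below
   true responders.
2. **TopHat baseline removal**: subtract the morphological opening
   (half-window 75 points). The output is bounded by 0 and the input.
   Because the opening is the *lower* envelope, the corrected background
   retains a positive pedestal of roughly the noise amplitude.
3. **Square-root transform** to stabilize intensity variance (for
   counting-type noise, Var[√X] ≈ 1/4 independent of the mean). Applied
   exactly once; the guard raises on a second application.
4. **Peak detection**: local maxima within ±10 points whose elevation above
   the spectrum median exceeds 3 × the MAD noise
   (1.4826 · median |y − median y|). The criterion measures elevation above
   the background pedestal rather than absolute intensity, so it is
   unaffected by residual baseline offsets; apex m/z is refined by the
   parabola through the three samples around the maximum, giving
   sub-grid-step precision.
5. **Monoisotopic filtering**: peaks spaced ≈ 1.00235/charge Th are chained
   into isotope envelopes; a satellite is absorbed when its intensity ratio
   to the envelope head lies within [0.25, 4] × the Poisson-expected ratio
   λ^k/k!, with λ(m) = 0.000594·m − 0.03091 (averagine approximation; at
   m/z 760 the expected A+1/A is ≈ 0.42). One missing satellite is
   tolerated so that an A+1 peak lost below the detection threshold does
   not orphan the A+2 peak as a fake feature.
6. **Optional single-point recalibration** to a reference peak (e.g. an
   internal standard): a constant axis shift, recorded in metadata; a
   missing reference leaves the spectrum unshifted and flagged for QC.
7. **Normalization**: TIC (default), median, or internal-standard. The sqrt
   transform precedes normalization.
8. **Alignment**: reference peaks are pooled-peak clusters present in ≥ 25 %
   of spots; the reference m/z is the cluster *median*, so a minority of
   shifted spots cannot drag it. Per spot a linear warp m/z′ = a·m/z + b is
   least-squares fitted to the matched pairs; spots with fewer than two
   matches stay unwarped and are flagged.
9. **Binning**: greedy single-linkage clustering of pooled peaks at 100 ppm,
   wide clusters split at their largest internal gap, bin center =
   intensity-weighted mean m/z. Features detected in fewer than 25 % of
   spots are dropped (sporadic noise detections). For the surviving
   features, spots without a detected peak receive the processed-spectrum
   intensity interpolated at the bin center rather than 0 — threshold-level
   detections otherwise drop in and out across replicates and inject
   spurious dose structure.

## Dose-response model

Each feature's per-concentration replicate means are fitted with the
four-parameter log-logistic model

    f(x) = c + (d − c) / (1 + exp(b · (ln x − ln e)))

with lower/upper asymptotes c ≤ d (canonical orientation; (b, c, d) and
(−b, d, c) describe the same curve), slope b and inflection e > 0 (fitted as
ln e, the only constraint). Zero-dose controls are mapped to a
pseudo-concentration one dilution step below the lowest nonzero dose.
Fitting uses `scipy.optimize.least_squares` (`trf`) with an analytic
Jacobian and a two-start initialization b₀ ∈ {−1, +1},
c₀ = min / d₀ = max of the responses, e₀ = geometric mean of the dose range;
exact SSE ties between orientations are broken toward the sign of the
Spearman correlation of dose vs response. The exponent argument is clipped
at ±50 (the sigmoid saturates at ~2·10⁻²² — far below measurement
precision) to keep every intermediate in the normal floating-point range.
The `trf` solver is used rather than the MINPACK `lm` path because the
latter proved irreproducible in exactly-flat SSE valleys of degenerate
(noise-only) fits. Optimizer failure yields a flat fallback
(b = 0, c = d = mean, `converged = False`).

Derived quantities: potency pEC50 = −log₁₀ e (conventional pEC50 when
concentrations are molar; units are otherwise taken as given), and the
signed effect size log₂FC = ±|log₂(d/c)| with the sign taken from the
fitted curve's direction of change over the tested dose range
(parameterization-invariant).

## Scoring

With H and L the replicate values at the highest and lowest tested
concentration (means μ, sample SDs σ) and the window W = |μ_H − μ_L|:

* **FZ** = 1 − 3(σ_H + σ_L)/W — the Z′ screening-window statistic applied
  to the curve endpoints. W = 0 gives −∞ (clipped to 0 below).
* **FV** = 1 − 6·RMSE/W — V-factor analogue; RMSE is the deviation of all
  replicate-level responses from the fitted curve, so FV penalizes lack of
  fit anywhere along the curve, not only endpoint scatter.
* **CRS** = 100 · (clip₀₁ FZ + clip₀₁ FV + clip₀₁(|log₂FC|/s)) / 3, the
  equal-weight composite, reported in percent to one decimal. The
  fold-change scale s defaults to the largest |log₂FC| among *regulated
  candidates* (features with FZ > 0 or FV > 0), making the fold-change
  component a within-dataset relative rank; it can be fixed for
  cross-dataset comparability. A feature whose FZ and FV components are
  both zero is nonregulated by definition and scores CRS = 0 regardless of
  its fitted fold change — without this gate, every pure-noise feature
  would score through its (meaningless) fitted fold change alone.
* **Direction**: `none` if CRS = 0, else `up`/`down` by the sign of log₂FC.
* Non-converged fits contribute FV = clip₀₁(−∞) = 0 but stay in the
  fingerprint, keeping feature axes complete.

The per-compound vector of (m/z, CRS, direction) is the **CRS fingerprint**;
fingerprints are compared across compounds by an m/z tolerance join.

## Quality control

Chauvenet's criterion flags a value when n · P(|Z| ≥ z) < 1/2, with z the
distance from the group mean in sample-SD units and P the two-sided normal
tail (erfc(z/√2)); single pass, no iterative re-flagging, and the flag set
is invariant under affine transformations. The spot-level test runs on the
pre-normalization TIC across **all spots of one compound**: within a
4-replicate group the criterion is mathematically inert, since the largest
attainable z-score (n−1)/√n = 1.5 never reaches the rejection region, while
the TIC is dose-insensitive enough for plate-wide comparison. Flagging is
informational by default; exclusion from averaging and fitting is opt-in
(`qc.outlier_mode: exclude`), and exclusion that empties a concentration
group is an error.

## Multivariate views

* **PCA** of the feature-standardized spot × feature matrix (zero-variance
  features dropped) visualizes the global dose response.
* **Sparse PCA** (L1-penalized loadings, scikit-learn, LARS solver) yields
  loadings with exact zeros; the selected set — features with any nonzero
  loading — shrinks as the penalty grows and can surface coordinated weak
  responses.
* **Curve-shape clustering**: converged fits are evaluated on a common
  50-point log-dose grid, min–max scaled to [0, 1] (scale- and offset-free,
  so mirrored curves are maximally distant), and k-means clustered
  (10 restarts, fixed seed); k = "auto" picks k ∈ [2, 6] by silhouette.
  All-flat inputs give a single cluster with a warning.

## Synthetic plates

The simulator generates profile-mode spectra on a uniform 0.02 Th axis
(default 300–900 Th) with Gaussian peaks (σ = 0.05 Th) and averagine-ratio
isotope satellites, a smooth positive baseline, lognormal spot-to-spot
intensity scatter (default SD 5 %), additive Gaussian detector noise, and
optional gross-outlier spots (scaled ×30). Default design: 8 concentrations
in a 10-fold dilution series from 10⁻¹⁰ to 10⁻³ (molar), 4 technical
replicates, 200 features of which 3 follow programmed LL.4 responses —
typical whole-cell screening conditions. Everything is a deterministic
function of the seed, and the written mzML is byte-identical across runs.

What the simulator does **not** emulate: physically realistic TOF peak
shapes and resolution-dependent widths, detector saturation, matrix-cluster
chemistry, mass-dependent calibration drift, or correlated biological
variation between features. Passing tests therefore certify the
statistical machinery (detection, fitting, scoring, ranking, QC) under
controlled artefact classes, not performance on any particular instrument's
data.

## Problem sizes and test design

Statistical guarantees are checked at desk scale: curve-level pEC50
recovery uses 200 simulations of 8 doses × 4 replicates at 5 %-of-window
noise (≥ 95 % within 0.15 log units); the null-control check runs 60
responder-free plates (10 features, 420–560 Th) and requires every feature
at CRS = 0 on ≥ 95 % of them; responder ranking runs 10 plates with 2–3
programmed responders and requires the programmed features to occupy the
top CRS ranks. `scripts/acceptance.py` recomputes the same quantities from
scratch (40 null plates, 8 responder plates) under a caller-supplied seed.

## Known limitations

* The fold-change normalizer makes CRS values relative within one dataset;
  cross-dataset CRS comparison requires fixing `scoring.fc_scale`.
* Linear warping only; no lowess/spline alignment, no resampling onto a
  common axis, and no deconvolution of overlapping isobars.
* Bruker Flex (.fid) raw data is not read — convert to mzML (msconvert).
* pEC50 from sqrt-transformed responses is the inflection of the
  transformed curve; for steep slopes the difference from the raw-scale
  EC50 is small (≈ 0.1 log unit at |b| = 2 for a 8-fold window) but it is
  not zero. Disable `transform.sqrt` when exact raw-scale potency matters
  more than variance stabilization.
* Confidence intervals on pEC50 and 5-parameter (asymmetric) logistic fits
  are out of scope.
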