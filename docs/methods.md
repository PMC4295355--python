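# Methods

## Physical model

Water in excised breast tissue is treated as two pools in slow exchange: a
fast diffusion phase (FDP, apparent diffusivity D_FDP ≈ 0.6–1.4 × 10⁻⁹
m²/s) and a slow diffusion phase (SDP, D_SDP ≈ 0.4–4 × 10⁻¹¹ m²/s), with
spin populations P₁ + P₂ = 1. On the b-value axis (b = γ²δ²g²t_d) the
normalized stimulated-echo amplitude is the two-term exponential mixture

    A(b)/A(0) = P₁ e^(−b·D_FDP) + P₂ e^(−b·D_SDP).

All fitted quantities are *apparent* values at the acquisition's diffusion
time: exchange and restriction make them differ from intrinsic
diffusivities, and the package never extrapolates them to zero echo time.
No relaxation (T₁/T₂) weighting of the populations, no inter-phase exchange
model, and no restricted-geometry or tortuosity corrections are included;
consequently the drift of the apparent P₁ with increasing diffusion time
seen in relaxation-weighted experiments is outside the model.

### Acquisition fixtures

The default acquisition mirrors the reference geometry: γ = 2.675 × 10⁸
rad s⁻¹ T⁻¹, δ = 0.2 ms, t_d = 20 ms, gradient ramp 0 → 4 T/m. The ramp
schedule is not documented in the source; 25 evenly spaced amplitudes are a
fixture choice. At t_d = 20 ms, max(b) ≈ 9.2 × 10⁸ s/m² gives
max(b)·D_SDP ≈ 0.015 — the slow phase is essentially flat, so a
biexponential fit is ill-posed there. The *extended* fixture therefore
merges ramps at t_d ∈ {11, 50, 200, 800} ms (≈ 97 unique b-values up to
3.7 × 10¹⁰ s/m², max(b)·D_SDP ≈ 0.6); the slow phase becomes identifiable
once max(b)·D_SDP ≳ 0.3.

### Noise

Synthetic curves carry additive zero-mean Gaussian noise on the amplitude
(default σ = 0.005 of A(0)). At the amplitudes retained for fitting the
signal stays far above the noise floor, so the Gaussian (rather than
Rician) approximation is adequate; non-positive amplitudes are dropped
before any log-domain fit.

## Peel-off decomposition

`PeelOffBiexponential` implements slow-first stripping:

1. **Slow phase.** Ordinary least squares on ln A vs b over the largest-b
   `tail_fraction` (default 0.4) of points, further restricted to
   b ≥ 3/ADC_rough so the fast phase has decayed to ≤ e⁻³ there. ADC_rough
   is taken from the b at which the curve first attenuates by 20% — a
   noise-robust lower bound on D_FDP; if the restriction leaves fewer than
   3 points, the plain count-based tail is used. A warning is emitted when
   max(b)·ADC_rough < 3 (slow-phase estimates are then unreliable, as on
   the default 20 ms fixture).
2. **Fast phase.** The fitted slow component is subtracted; residuals below
   max(10⁻⁶·A(0), 5% of the largest residual) are dropped — beyond that
   point the residual is subtraction error or noise, not fast-phase signal
   — and a second log-domain line gives D_FDP and its population.
3. **Closure.** Populations are renormalized to sum to exactly 1 (the raw
   sum is preserved as a diagnostic).
4. **Refinement** (default on). Trust-region nonlinear least squares on the
   full two-term model in the amplitude domain, seeded by the stripped
   estimates, with the analytic Jacobian — finite-difference steps at
   parameter magnitudes of 10⁻⁹–10⁻¹¹ underflow into rounding noise — and
   per-parameter scaling. Weighting is uniform in both domains; the source
   does not specify weights, so this is exposed as configuration only
   through the choice of domain.

The mixture model is symmetric under swapping the two components, so a
"swapped" optimum is relabeled to the canonical D_fast > D_slow ordering;
only an exact tie raises an order-violation error. A mono-exponential input
leaves no usable residuals after stripping and raises a stripping-failure
error, letting callers fall back to the mono fit.

The initial-slope ADC uses the `n_initial` (default 3) smallest-b points of
ln A vs b. For a positive mixture of exponentials ln A is convex in b, so
widening the window can only lower the estimate; the 3-point default keeps
the small-b bias negligible on the shipped grids. On noisy curves with very
finely spaced small-b points this estimator is noise-limited — it is
reported as measured and is deliberately not forced to agree with the
population-weighted ADC of the fitted components.

On the extended fixture, stripping + refinement recovers noise-free
parameters to machine precision across P₁ ∈ [0.2, 0.9] and
D_FDP/D_SDP ∈ [20, 200], and at amplitude noise 0.005 the median relative
parameter error is ≈ 1–2%.

## Response-surface regression

Diffusion parameters are regressed on five morphological constituents
(parenchyma, stroma, adipose tissue, pericellular edema, vessels; raw
percentages). Perivascular edema is excluded from every design because it
is determined by the other constituents. Two designs are exposed:
*pure quadratic* (intercept + linears + squares; 11 terms for 5
predictors — the layout of the published morphology equations) and
*full second order* (adds pairwise products; 6 or 10 terms for the 2- and
3-predictor diffusion equations). The general formula is typographically
missing in the source; the designs are inferred from the printed equations
themselves.

Fitting is ordinary least squares (via statsmodels) on raw scales — the
published coefficients apply to raw percentages and scaled diffusivities
(D_FDP in 10⁻⁹, D_SDP in 10⁻¹¹ m²/s), so no standardization is performed.
R² = 1 − SS_res/SS_tot, defined as 0 for a constant response.
Per-coefficient t-test p-values are reported for information; no term
pruning is done because the published equations retain all terms.
Rank-deficient designs raise an error naming the offending columns (QR with
column pivoting); underdetermined systems are rejected outright.

The published coefficient sets ship as a plain-text fixture
(`data/printed_coefficients.tsv`). Two transcription judgments are recorded
there: a squared-exponent mark missing from one fast-diffusivity term
(read as P²), and mixed decimal separators in the morphology malignancy
equation (both read as plain decimals).

## Malignancy scoring

CanP is the second-order surface evaluated on one of three predictor sets
(morphology; D_FDP, D_SDP; D_FDP, D_SDP, P₁), interpreted on a 0 → 1
probability scale. The raw polynomial is clamped to [0, 1] — the clamp is
what produces the flat saturation regions of the published response
surfaces, which the source describes but never states as an operation — and
thresholded at 0.5 by default (no threshold is published; it is
configurable). Training new scorers uses linear-probability OLS of the 0/1
label on the variant's design, mirroring the original procedure; logistic
regression is deliberately not offered, to avoid misrepresenting the
method. R² of a label fit and classification accuracy are different
quantities and are reported separately (confusion counts vs model R²).

## Cohort statistics

Group summaries report mean, sample SD (n − 1 denominator; undefined for a
singleton), range and max/min ratio (undefined when min ≤ 0). Wilcoxon
rank-sum comparisons use mid-ranks for ties; the two-sided p-value is exact
— the full permutation distribution of the rank sum, built by the shift
algorithm on doubled mid-ranks — when both groups have ≤ 10 observations,
and a tie-corrected normal approximation otherwise. Spearman correlations
use the t-approximation by default, with a permutation p (exhaustive for
n ≤ 7, 10⁴ resamples otherwise) available for the small subgroups where the
approximation is least trustworthy. Correlation tables are computed per
subgroup — control, stroma < 50%, stroma ≥ 50% (cut at ≥ 50 for the high
class, spanning control + cancer) — and skip subgroups with n < 3 with a
warning. All p-values are two-sided and uncorrected for multiple testing.

## Synthetic cohort

The generator emulates the study design: control n = 6 (mastopathy /
peritumoral tissue) and cancer n = 11 (T2 tumors, 6 T2N0M0 : 5 T2N1M0; the
TNM label affects only labeling, with the published sub-group diffusion
parameters available as optional overrides). Only per-variable mean/SD/range
summaries are published, so the joint distribution is a modeling choice:

* **Compositions.** The six constituents of a section are exhaustive (group
  means sum to ~100), so independent truncated normals are infeasible —
  one-sided truncation inflates every mean and pushes the expected sum to
  ≈ 107–115%. Instead each specimen is the group mean vector plus a
  zero-sum deviation: per-variable normals of the printed SD truncated
  *symmetrically* to ± min(mean − min, max − mean) (zero mean by
  construction), projected to zero sum with variance-proportional weights,
  and rejected if any constituent leaves its printed range. This preserves
  the printed means (to ≲ 0.6 percentage points), the printed ranges and
  the ≤ 100% closure exactly; the price is a narrower spread than the
  printed SD for strongly skewed variables (adipose tissue, perivascular
  edema) and an induced negative inter-constituent correlation. Mean and
  range fidelity were preferred over SD fidelity because the downstream
  analyses key on group locations and admissible ranges. Lower bounds
  printed as "0.01" are honored as 0.01%.
* **Diffusion, group-parameter mode.** Independent truncated normals with
  the printed group mean/SD/range; the physical ordering
  D_FDP > D_SDP (in SI units) is enforced by redrawing. The published
  whole-cancer-group D_SDP (0.86 ± 0.68 × 10⁻¹¹ m²/s) sits below both
  printed TNM sub-group means — the transcription keeps the printed numbers
  verbatim rather than reconciling them.
* **Diffusion, equation-driven mode.** Responses are computed from the
  transcribed morphology surfaces at the sampled composition plus Gaussian
  residuals calibrated once per cohort to a target R²:
  σ² = Var(predicted)·(1 − R²)/R², with the population variance of the
  predicted response taken over the cohort before noise is added. Default
  targets are the published determination coefficients (0.92, 0.81, 0.93).
  P₁ is clipped to [0.01, 0.99]; predicted diffusivities are floored at
  0.05 scaled units because the unconstrained polynomials dip below zero at
  composition extremes.

Per-specimen RNG streams are keyed by (seed, group, index, stage), so draws
are reproducible and independent of group ordering. Decay curves are
synthesized on the extended fixture from each specimen's true compartments.

What passing tests show — and do not show — about real data: the generator
reproduces printed group marginals and the forward model, not the real
cohort's inter-variable correlations, non-Gaussian shapes, relaxation
weighting or measurement systematics; recovery results on synthetic cohorts
therefore validate the algorithmic pipeline, not in-vitro accuracy.

## Problem sizes and numerical choices

Recovery and calibration checks use cohorts of 200 specimens (a size at
which group means are estimated to ~±0.01–0.02 in scaled units) and, for
the R² calibration, averages over 10 seeds; both complete in seconds.
Degenerate inputs are handled explicitly: flat curves are degenerate mono
fits, mono-exponential curves are stripping failures, constant responses
have R² ≡ 0, single-class label vectors are rejected, and zero rank
variance makes a correlation undefined rather than zero.

## Known limitations

* The two printed worked anchors that cannot be reconciled are reported,
  not forced: the population-weighted ADC of the printed control
  parameters (≈ 0.61 × 10⁻⁹ m²/s) differs from the printed control ADC
  (0.78 ± 0.28 × 10⁻⁹ m²/s), which was measured independently from initial
  slopes of real curves.
* Published per-specimen raw data do not exist, so the original n = 17
  regressions, correlation tables and p-values cannot be recomputed; the
  package validates against printed equations and synthetic cohorts
  instead.
* Whether the original peel-off fitted slow-first or fast-first is not
  documented; slow-first is implemented as the standard for stripping.
* No more-than-two-component stripping, no regularized/NNLS decay-spectrum
  inversion, no T₂-corrected populations, no ROC machinery beyond confusion
  counts.
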