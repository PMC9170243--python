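# Methods

`v4popcode` studies how attention reshapes shared ("correlated")
variability in visual cortical populations and what that implies for two
families of linear readout: a *specific* decoder optimized for one fine
discrimination, and a *general* decoder that reads out the whole stimulus
ring with a single set of weights.  This note records the models, the
estimators, the synthetic-data conditions, and the numerical and design
choices, so that every quantity the package reports can be traced to an
explicit assumption.

Orientation is always the normalized circular variable θ ∈ [0, 1); the
complex embedding is z = e^{i2πθ} (a normalized angle cannot cover the
circle without the 2π factor; the convention is isolated in
`decoders.ring_phase`).

## Decoders and information estimators

**Specific decoder.** For a fine discrimination between θ± = θ0 ± dθ with
mean responses f(θ±) and noise covariance Σ, the optimal local linear
estimator is θ̂ = θ0 + wᵀ(r − (f(θ+)+f(θ−))/2) with
w = Σ⁻¹f′ / (f′ᵀΣ⁻¹f′) and f′ ≈ (f(θ+)−f(θ−))/(2dθ).  Its inverse variance
is the linear Fisher information I = f′ᵀΣ⁻¹f′.  From finite data the
package uses the bias-corrected quadratic-form estimator

    Î = (Δf̂/dθ)ᵀ Σ̂⁻¹ (Δf̂/dθ) · (2Ntr−N−3)/(2Ntr−2) − 2N/(Ntr dθ²)

with Δf̂ the empirical mean difference, Σ̂ the average of the two condition
covariances (ddof = 1), N units and Ntr trials per condition (equal counts
required; `decoders.trim_equal_trials` trims protocol data
deterministically).  The mean difference is divided by dθ exactly as in the
estimator's printed form even though the conditions sit at θ0 ± dθ; the
convention is stated here prominently because it scales absolute
information values by 4 — it cancels in every attended/unattended ratio the
package reports, and the Monte-Carlo unit tests construct their conditions
so that Δf/dθ equals the target derivative.  Negative values are legitimate
near zero information and are reported as-is.  The correction requires
2Ntr > N + 3 and the estimator refuses to run otherwise.

**General decoder.**  A single complex weight vector w maps population
activity to ẑ = wᵀr for *all* orientations; the optimum for the squared
error ⟨|ẑ − z|²⟩ is

    w = ⟨Σ(θ) + f(θ)f(θ)ᵀ⟩θ⁻¹ ⟨f(θ)e^{i2πθ}⟩θ ,

estimated with per-orientation empirical moments.  The second moment uses
ddof = 0, making the closed form the exact minimizer of the empirical MSE
(verified against unconstrained least squares in the tests).  A singular
moment matrix triggers a ridge fallback (smallest power of ten bringing the
condition number below 1e12, recorded on the result).  Decoded angle
θ̂ = arg(ẑ)/2π; residuals are wrapped to (−0.5, 0.5] and the *linear*
variance of the wrapped residuals is used (circular variance was the
alternative; wrapped-linear keeps the value in 1/θ-units², directly
comparable with the specific decoder).  The information estimate is

    Îᵍ = [1/Var(θ̂ − θ)] · (Ntr−N−2)/(Ntr−1)

with Ntr the total trial count; zero residual variance yields an explicit
"unbounded" sentinel rather than a number.  The estimator is accurate to a
few percent against a tenfold holdout when the shared gain SD is ≲ 0.2;
larger gain noise produces rare near-zero-gain trials whose angular errors
dominate the variance, and no variance-based information summary is
reliable there.

**Classifier-based analyses.**  Pairwise orientation discrimination uses a
linear SVM with stratified two-fold cross-validation, either on the full
N-dimensional response or (general mode) on the 2-D plane (Re ẑ, Im ẑ)
with weights computed from all orientations.  Session-style decoders use
leave-one-out cross-validation with a regularized linear discriminant
(pooled covariance with Ledoit–Wolf shrinkage; logistic regression and the
linear SVM are selectable).  The in-house discriminant agrees with
scikit-learn's shrinkage LDA on ~98% of predictions while being fast enough
for the leave-one-out ladders.  Folds whose training set degenerates to one
class score the trial by that class, and are counted, not dropped.

## Shared-variability statistics

Noise correlation r_SC is the Pearson correlation of two units' spike
counts over repeated identical stimuli; signal correlation is the
correlation of their mean tuning across stimuli; pairs touching a
zero-variance or flat-tuned unit are dropped listwise from both vectors.

Factor analysis models counts as x ~ N(μ, LLᵀ + Ψ) with m = 5 factors by
default and reports the descending eigenvalues λ1..λm of LLᵀ.  The fit is
closed-form EM on the sample covariance, started from a principal-component
solution, with up to 10 jittered restarts and a relative log-likelihood
tolerance of 1e−8.  EM (rather than a direct SVD-style solution) matters:
the model is not identified between a single-unit factor column and private
variance, and the EM path from the PCA start selects the Ψ-side solution,
so independent-noise data correctly yields λ1 ≈ 0.  Per-iteration
log-likelihoods are retained and are non-decreasing (asserted in tests).

Williams' procedure for comparing two dependent correlations that share a
variable is implemented as the Williams t2 statistic with df = n − 3 and a
two-sided t p-value; it is antisymmetric in the two compared correlations
and its type-I error at α = 0.05 calibrates to 0.04–0.06 on a
trivariate-normal null with n = 86 (the across-days sample size of the
session analyses).

## The ring surrogate (synthetic_data)

The fast surrogate for the circuit model is a rank-1 multiplicative-gain
population: wrapped-Gaussian tuning curves f_i(θ) (amplitude 10,
width 0.12, baseline 4 counts per window by default), one shared gain
g ~ N(0, σ_r²) per trial multiplying every unit's mean, independent
Gaussian private noise (SD 2), truncation at zero.  The shared fluctuation
therefore points along the "radial" direction f(θ) of the population ring,
reproducing the geometry in which shared variability is largest along the
radius.  Attention scales σ_r by (1 − c·level) with c = 0.5, so the
attended (level 1) state has half the shared SD.  Truncation is a
deliberate departure from exact Gaussianity; at the default operating point
fewer than ~2% of samples touch zero, and the analytic rank-1 correlation
matrix (`expected_rank1_correlation`) still matches the empirical mean
pairwise correlation to within 15%.

Why the general decoder benefits more from attention here: the gain
direction f(θ) is locally orthogonal to f′(θ), so the specific decoder's
Fisher information is nearly unaffected by σ_r; the general decoder's
angular error is amplified multiplicatively by low-gain trials (the error
scales like 1/(1+g)), so shrinking σ_r improves Îᵍ substantially.  This is
the mechanism behind the information-ratio ordering test.  Trial shuffling
within condition destroys the shared gain, after which the bias-corrected
information grows approximately linearly with population size, as expected
without information-limiting correlations.

## The spiking circuit model

Three stages on the periodic unit square Γ = [−0.5, 0.5]²: a Poisson L4
front end, and two recurrent excitatory/inhibitory EIF layers (V1 L2/3 and
V4).  Printed model constants: orientation-map column spacing Λ = 0.2
(plane-wave superposition; the bundled map uses 30 randomly phased waves on
the integer lattice closest to |k| = 1/Λ so the map is exactly periodic and
its spectrum peaks at 1/Λ); 25×25-pixel Gabor stimulus with envelope
σ = 0.2, wavelength λ = 0.6, phase 0; OU pixel noise τ_n = 40 ms,
σ_n = 3.5 (exact-discretization updates, so the stationary SD
σ_n/√(2τ_n) holds for any step); L4 rates are rectified Gabor-filter
responses normalized to a 10 Hz grand mean; OFF-interval rate r_X = 5 Hz;
protocol 300 ms OFF / 200 ms ON, 20 s per simulation, first ON count
discarded; attention interpolates γ: 20→23 mV (feedforward strengths
γ·[1, 0.4]) and μ_i: 0→0.5 mV/ms into V4 inhibitory cells; V1→V4
projection width 0.05.  These values are recorded in
`v4popcode/configs/paper.json`.

Everything the published description defers to its companion network
(single-neuron constants, recurrent coupling, in-degrees) is an adopted
default here, overridable via `NetworkConfig`: EIF with τ_m = 15/10 ms
(E/I), E_L = −60 mV, V_T = −50 mV, ΔT = 2/0.5 mV, spike cut −10 mV, reset
−65 mV, refractory 1.5/0.5 ms; exponential synapses (τ_e = 5 ms,
τ_i = 8 ms); weights specified in mV and divided by √(layer size);
connection probabilities decay as wrapped Gaussians on Γ.

**Scale-down choices.**  Default layers are 900 L4, 400 E + 100 I per
recurrent layer (~100× below the published runs), integrated by forward
Euler at dt = 0.05 ms (the published step, 0.01 ms, is reachable via
config).  Two consequences of the small size require explicit modeling
decisions rather than silent hope:

1. *Feedforward dominance.*  At full size the feedforward current is
   O(√N)-large and the γ modulation dominates the mean-rate balance, while
   μ_i = 0.5 mV/ms is a subleading perturbation.  The scaled V4 keeps this
   ordering through `ffwd3_scale` (default 2.2), which restores a dominant
   feedforward current; without it the fixed printed μ_i overwhelms the γ
   boost and attended rates *fall*, inverting the physiology.
2. *Internally generated shared variability.*  The full-size model's
   low-dimensional correlated variability is an emergent spatiotemporal
   state that does not form with a few hundred neurons.  The scaled V4
   therefore receives an explicit shared slow modulatory current into its
   excitatory cells (OU, SD 0.6 mV/ms, τ = 150 ms), standing in for that
   internal variability; its amplitude is attention-independent, and
   attention acts on it only through the inhibitory operating point, as in
   the full model.

With the printed attention endpoints the scaled model robustly reproduces
the attended increase of excitatory rates and the attended decrease of mean
r_SC (paired comparisons sharing all stimulus-noise realizations between
attention levels).  The attended *decrease of the leading factor-analysis
eigenvalue does not reproduce robustly at this scale*: because attention
scales the feedforward weights by γ, every V1-inherited shared-variance
component arrives amplified by γ² ≈ +32% before any inhibitory damping,
and at N ≈ 500 per layer the μ_i-driven gain increase of the inhibitory
loop recoups only a fraction of that.  The corresponding acceptance test
asserts all three signs and is expected to fail on the λ1 component; this
is a documented limitation of desk-scale simulation, not of the analysis
code (the λ1 statistic itself is validated on planted-factor data).

Rate sanity is monitored, not enforced: neurons exceeding a configurable
200 Hz ceiling during ON intervals trigger a warning.  Voltage blow-up
aborts with the step index.  Connectivity (and the quenched per-neuron
background jitter, if enabled) is drawn once per configuration and reused
across simulations; membrane potentials and all noise are redrawn per
simulation from the seed, so identical (config, map, seeds) give identical
rasters.

## Synthetic sessions and the pipeline

A synthetic "day" emulates the cued change-detection experiment: blocks of
125 orientation-change trials (four blocks per day by default — two
cue-block pairs), cue alternating between the recorded location and the
opposite one; 80% of changes occur at the cued location; when the recorded
location is uncued its changes are restricted to the median and largest of
the five change amounts in the real 20:5 proportion (scaled with block
size).  Five change amounts (0.03–0.21 on the ring, wide relative to the
0.10 tuning width so that single-amount discriminant directions genuinely
differ), a geometric number of pre-change flashes (first flash flagged for
exclusion everywhere), and per-trial 100 ms baseline counts for the
inclusion test and evoked-response ranking.

Choices come from a planted linear readout: saccade iff a·r + ε exceeds a
threshold placed halfway to the median-change signal, with
ε ~ N(0, (0.5·s_med)²) by default.  The planted axis mixes the
median-change discriminant direction (weight 0.65) with the radial/gain
direction (weight 0.35): enough radial loading that shared variability
degrades the subject's decoder (the r_SC correlation analyses), while
keeping the choice axis recoverable (median cosine ≈ 0.85 across default
days).  The axis-recovery diagnostic fits the choice readout on the full
counting window — the window the generative choice model actually uses —
while all performance analyses use the abbreviated decoder window.

Counting-window bookkeeping follows the electrophysiological convention:
rates and correlations from a 60–260 ms window, decoders from 60–130 ms.
Synthetic sessions carry one count per flash (standing for the 200 ms
response); the decoder window is emulated by binomial thinning with
p = 70/200, preserving Poisson-like statistics while guaranteeing decoders
never see counts outside their window.

The generality ladder trains, for every k-subset of the non-median change
amounts {1, 2, 4, 5}, a linear classifier of changed-vs-starting
orientation, and evaluates it (i) by LOOCV against each non-median amount
and (ii) by its accuracy predicting the subject's choice on median-change
presentations (which never enter training, avoiding the inherent
relationship with the choice-trained decoder).  Across synthetic days, the
ladder statistics rise with k because day-to-day variation in noise level
(radial SD ~ U(0.05, 0.30) and private SD ~ U(1.0, 5.0) across days) is a
common difficulty factor that better-constrained (higher-k) decoders track
more faithfully, and because higher-k training sets average toward the
median discriminant that anchors the planted axis.

Across days, each ladder statistic is aggregated per generality level k and
the k-trend is the Spearman correlation of those per-level aggregates with
k; the pooled row-level trend (every subset × evaluation-amount decoder as
its own point) is reported alongside, but is dominated by within-level
dispersion — each row is itself an across-days correlation estimated with
substantial error — and is therefore not the headline trend statistic.

Day-level correlation analyses use two points per day (one per attention
condition); mean-r_SC outliers beyond the Tukey fences (Q1 − 1.5 IQR,
Q3 + 1.5 IQR) are excluded with both variants reported; Williams' t
compares the subject's-decoder and specific-decoder correlations with mean
r_SC across day-conditions.

## What the synthetic conditions do and do not establish

The generators reproduce the *structure* the analyses assume —
low-dimensional shared variability aligned with the population ring,
attention scaling of that variability, choice generated from a fixed linear
readout — but not the full richness of cortical data: no adaptation or
temporal nonstationarity beyond the first-flash exclusion, no
eye-movement artifacts, no unit-count attrition, Gaussian rather than
genuinely Poisson spiking in the ring surrogate, and day-to-day variation
driven by two scalar noise amplitudes.  Green pipeline tests therefore
demonstrate that the estimators and the session machinery recover planted
structure under the stated model, not that the model captures every
property of the recordings.  The headline monkey-data correlations require
the deposited recordings, which the package deliberately does not ship; an
adapter can map any trial-by-unit CSV with the session schema into the same
pipeline.

## Problem sizes used by the shipped checks

The automated checks run at desk scale on one CPU: 50-orientation front-end
calibration (900 filters); 1,000 Monte-Carlo repetitions of the Fisher
oracle at N = 2, Ntr = 200; 10 ring settings with 7,500 training and
75,000 holdout trials for the general-information oracle; four 20 s network
simulations per attention level with 30 samplings of 50 of the 400 V4
excitatory units; ring-surrogate information curves at N ∈ {50, 100, 200}
with 2,000 trials per fine-discrimination condition and 100 trials per
orientation on a 50-point grid; 50 synthetic days at the full default
session size; and 10,000 draws for the Williams calibration.
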