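# Methods

## Contact mechanics

### Hertz model with bottom-effect correction

The apparent Young's modulus is fitted on the approach phase as

    F = 4√R / (3(1−ν²)) · f_BEC(δ) · E_Hertz · δ^{3/2}

with the Poisson ratio fixed at ν = 0.5 (cells are treated as incompressible
on indentation timescales) and a spherical/paraboloidal tip of radius R
(default 70 nm, the nominal apex radius of the pre-calibrated live-cell
probes this pipeline targets; spring constant 0.1 N/m). Because the model is
linear in `E_Hertz`, the fit is a single projection.

`f_BEC` corrects for the finite thickness h of a sample bonded to rigid
glass: a quartic polynomial in χ = √(Rδ)/h with coefficients
(1.133, 1.497, 1.469, 0.755), exposed in `BEC_COEFFICIENTS` so an alternative
set can be substituted. The correction is ≥ 1, monotone in δ/h, → 1 as
h → ∞, and is clamped at χ = 2 (with a warning) where the series stops being
a controlled expansion. Per-pixel thickness is taken from the corrected
topography height, consistent with cells resting on rigid glass.

### Ting's viscoelastic model

For an arbitrary load–unload history δ(t) on a power-law-rheology (PLR)
half-space with relaxation modulus

    E(t) = E₀ · t^(−α) + η · δ_D(t)       (E₀ at t = 1 s; 0 ≤ α < 1; η ≥ 0)

the force is the hereditary integral

    F(t) = 4√R/(3(1−ν²)) ∫₀^{t₁(t)} f_BEC(δ) E(t−ξ) d(δ^{3/2})/dξ dξ,

with t₁(t) = t during approach, and t₁ on retract defined by the vanishing of
the kernel-weighted indentation-rate integral over [t₁, t]. The Dirac
dashpot term contributes η·d(δ^{3/2})/dt during approach only (on retract the
integration limit t₁ < t excludes it); with a velocity-discontinuous
triangular ramp this makes the model force discontinuous at the turnaround
for η > 0 — an inherent property of the springpot-plus-dashpot kernel, not a
numerical artifact. After t₁ reaches 0 the tip has separated and F ≡ 0.

**Numerics.** The history is piecewise linear in time, so all kernel
integrals are evaluated analytically per segment — the singular factor
t^(−α) is never evaluated at zero lag. The integrand factor d(δ^{3/2})/dξ is
taken piecewise constant from the exact node values of δ^{3/2}; because
δ^{3/2} has unbounded curvature at contact, segments with δ below 12% of the
peak are subdivided 8-fold and the contact region is refined to at least 96
sub-segments (δ interpolates exactly). This keeps the forward model within
0.05% of peak force of an adaptive-quadrature oracle across
α ∈ [0, 0.5] × η ∈ [0, 2] Pa·s at the native 512 samples/phase.

For t₁, the condition integral is *exactly* analytic for a piecewise-constant
indentation rate, so after locating the bracketing approach segment at the
node level, t₁ is obtained by closed-form inversion inside that segment —
accuracy is limited by float round-off rather than an iteration tolerance.
t₁ is monotone non-increasing during monotone unloading; queries at zero
indentation return the detachment sentinel 0.

### Contact point and fitting

The contact point z₀ is found by a grid search over approach samples
minimising the total squared residual of a linear Hertz fit past the
candidate plus the pre-contact force residual, with the baseline estimated
from the first 30% of the approach and the indentation built as
δ = (z − z₀) − F/k (cantilever deflection removed). When the local thickness
is known it can be included in the search model, which removes the bias the
uncorrected δ^{3/2} shape acquires on thin samples.

This elastic search is biased by a few samples on strongly viscoelastic
curves, whose early-contact force grows as t^{3/2−α} rather than t^{3/2}.
The viscoelastic fit therefore refines the contact position as a bounded
nuisance parameter (±150 nm) jointly with (E₀, α, η), using trust-region
least squares on the joint approach+retract residual with uniform weights,
initialised at (E_Hertz, 0.2, 1.0) — the Hertz estimate and the centre of
the ranges typical for adherent cells — and bounded to
[1 Pa, 1 MPa] × [0, 0.99] × [0, 100 Pa·s]. Noiseless round trips recover
generated parameters exactly; fits constrained to α = 0, η = 0 reproduce the
Hertz fit (model nesting).

**Per-curve precision.** Under additive Gaussian force noise with SD equal
to 5% of the trigger force, the Cramér–Rao bound of a single triangular-ramp
curve gives a relative standard deviation of ~13–15% for E₀ (the t = 1 s
modulus is an extrapolation from a millisecond contact window, so
d ln E₀ ≈ 5.8·dα), ~0.02 absolute for α and ~14% for η. Least squares is the
maximum-likelihood estimator for this noise, so no fitting choice can beat
that floor; single-curve E₀ values should be read with this spread in mind,
and study conclusions rest on per-map and per-line averaging (hundreds of
pixels, ≥20 maps per line), which reduces the uncertainty by an order of
magnitude.

### Map processing

Topography is the negative of the per-pixel contact height. A substrate
plane is fitted iteratively (pixels within 200 nm of the running substrate
median are inliers; at least 10 substrate pixels are required, otherwise the
tilt correction is skipped with a warning), subtracted, and the substrate
median set to zero. Pixels below 200 nm are background. Connected cell
components are labelled and, per component, pixels at or above 50% of the
component's maximum height form the central mask — the periphery, dominated
by peripheral F-actin, is excluded. Per-map arithmetic means are computed
over the central mask from pixels whose fits succeeded; rejected and
non-converged pixels are counted in the QC output, and maps with fewer than
20 valid central pixels (configurable) are excluded from group statistics.

## FLIM microviscosity

TCSPC histograms are fitted by Poisson maximum likelihood with a
discretized monoexponential (exact bin integrals) plus an optional uniform
background, tail-fitted from the histogram peak by default; a Gaussian IRF
convolution (exponentially-modified-Gaussian bin contents) is available
instead. Curves need ≥ 5000 photons.

The reduced χ² reported for gating uses model-expected (Pearson) weights:
with ~5000 photons over 256 bins the decay tail holds ~1 count per bin, and
observed-count (Neyman) weights — even clipped at 1 — bias the statistic to
a median of ~1.2, which would reject half of all well-specified fits at the
[0.8, 1.2] gate. Pearson weights centre the statistic at 1 (99% gate
acceptance for a correct model); Neyman weighting remains selectable for
comparability with software that reports it. A free background parameter
absorbs part of any short-lifetime contamination and roughly halves the χ²
power against it; misspecification screening is therefore best done with the
background fixed at the known value.

Lifetimes convert to microviscosity through the Förster–Hoffmann power law
τ = z·η_v^x, fitted by least squares of ln η on ln τ (viscosity is the
predicted quantity). The six bundled reference pairs, (2.95 ns, 427 cP)
through (3.45 ns, 579 cP), give d ln η/d ln τ ≈ 1.96, i.e. x ≈ 0.51,
with sub-percent leave-in residuals; leave-one-out predictions reproduce
every pair within 2%, and a leave-one-out residual scan flags distorted
pairs. The two published viscosity readings at 3.06 ns (456/457 cP) differ
only by rounding of the source calibration. A monotone PCHIP interpolant in
log–log space is available as an alternative conversion. The power-law
mapping is strictly monotone and exactly invertible; conversions outside the
calibrated lifetime range warn about extrapolation.

Per-line summaries average accepted fits only (χ² gate), report cell and
field-of-view counts, and flag lines with fewer than 10 accepted cells.

## ToF-SIMS lipid arithmetic

The module consumes peak-intensity tables (vendor spectra processing is out
of scope): ion yield = peak intensity / total ion count of the same
measurement (pixel-averaged upstream), in [0, 1] and scale-invariant;
fatty-acid classes are expressed relative to the same sample's saturated-FA
signal, and mismatched denominators are a validation error. Per-component
Pearson correlations against per-line microviscosity require ≥ 3 lines and
attach no p-value below 4 lines; components constant across lines report an
undefined r rather than a number.

## Group statistics and integration

Microviscosity and lipid data use one-way ANOVA with a Bonferroni post hoc
(pairwise pooled-MSE t statistics with N−k degrees of freedom,
p_adj = min(1, m·p)); AFM map means use Kruskal–Wallis with Dunn's pairwise
z-tests (tie-corrected rank variance, Bonferroni adjustment). Stars follow
the printed convention (* p ≤ 0.05, ** p ≤ 0.01, *** p ≤ 0.001,
**** p < 0.0001 — note the strict inequality on the last level).

Cross-modality correlations are Pearson coefficients over per-line mean
values (the headline stiffness–microviscosity r is a line-level quantity);
pooled per-cell correlation exists behind an explicit function because it
mixes within- and between-line variance. With five lines no parametric
p-value is attached by default; a permutation p (bounded below by 1/5! per
pair) is optional. The study report assembles per-line summaries, test
tables with stars, the correlation matrix and QC counts, omits absent
modalities with a note, and is byte-deterministic given its inputs.

## Synthetic data: what it emulates and what it does not

The generator drives a symmetric triangular indentation history at the piezo
speed, terminates the approach at the first sample whose noiseless model
force reaches the trigger (force-triggered fast force–volume operation), and
records z = z₀ + δ + F/k so the analysis-side δ reconstruction is exact.
Defaults follow the instrument protocol the pipeline targets: 3 µm ramp,
183 µm/s, 0.8 nN trigger (within the 0.5–1 nN operating range),
512 samples/phase; maps default to 128 samples/phase. Noise is additive
Gaussian on force plus optional Gaussian contact-point jitter; decays are
Poisson draws of exact bin expectations; the base seed (20231106) is
recorded in every output's metadata and re-runs are byte-identical.

Map phantoms are spherical caps on a tilted rigid plane; cell pixels carry
the local cap height as BEC thickness, substrate pixels an effectively rigid
(50 kPa) elastic response — stiff enough to read as substrate, soft enough
that contact detection still sees a resolvable curve.

The five-line study design uses measured line-level microviscosities
(427 ± 30 … 491 ± 45 cP; 60 cells in 10 fields of view per line) and plants
stiffness line means carrying an exact sample correlation (default 0.93)
with the viscosity means inside the 1–4 kPa band, via a deterministic
orthogonal-vector construction; E₀ scales with stiffness, η spans
0.9–1.4 Pa·s with stiffness, and α runs opposite across 0.15–0.25. Between-map
stiffness scatter (20% CV over 20 maps/line) and per-line cell heights are
not constrained by measurements and were chosen once as realistic for
adherent carcinoma lines. Lipid tables plant per-component correlations with
viscosity (PC/SM −0.72, cholesterol −0.62, monounsaturated −0.59,
polyunsaturated −0.42); the polyunsaturated between-line variation is set
below replicate noise, so ANOVA finds no difference on that component while
a weak ordering correlation remains.

Two fidelity levels exist: `detail="summary"` draws per-cell lifetimes and
per-map parameters directly from the design distributions (used for
many-replicate statistical checks); `detail="full"` generates the raw decay
histograms and small force-volume maps so the complete raw-data path runs.

What passing tests do **not** show about real data: the generator contains
no adhesion, no cantilever hydrodynamic drag, no piezo creep or drift, no
spatial heterogeneity within a cell, no optical IRF asymmetry, no rotor
photobleaching, and no ToF-SIMS matrix effects. Agreement on synthetic data
validates the estimators against their own forward models, not the forward
models against cells.

## Known limitations

* Single-curve E₀ has an irreducible ~13% relative spread at 5%-of-trigger
  force noise (Fisher-information floor of the millisecond window); compare
  lines through map- and line-level means.
* α = 1 (purely fluid) is excluded; fits bound α at 0.99.
* The Ting solver assumes a single contact event per curve and monotone
  unloading after the peak; hold segments after unloading are outside the
  t₁ monotonicity guarantee.
* ROI selection for FLIM is an input; no image segmentation is performed.
* Vendor raw formats (Bruker, Becker & Hickl, ION-TOF) are not parsed; the
  open text containers in `mechanoflim.io` define the interchange formats.
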