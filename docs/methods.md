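# Methods

This note documents the models behind each rodfold pipeline, the
defaults and why they were chosen, what the synthetic-data generators
do and do not emulate, and the numerical choices that affect results.

## Units and constants

All internal lengths are nm, forces pN, energies kcal/mol, denaturant
concentrations M (urea). kBT = 4.114 pN·nm and RT = 0.592 kcal/mol at
298 K (25 °C), the temperature of all experiments the package models.
Contour-length increments are converted to Å only in reports and event
CSVs, matching the convention of the force-spectroscopy literature.

## SHRImP localization

**Model.** A surface-immobilized molecule carries two fluorophores at
fixed separation, far below both the pixel size (157 nm) and the PSF
width. Each fluorophore photobleaches in a single irreversible step.
The trace of a 10×10-pixel region therefore has three plateaus
I₁ > I₂ > I₃. The mean image of the seven frames after the first step
contains only the survivor; the difference between the seven-frame
means before and after the step isolates the first-bleached
fluorophore. Both are localized by least squares with a 2D elliptical
Gaussian (amplitude, centre, widths, rotation, background), with each
model pixel value integrated over the pixel area (5-point
Gauss–Legendre quadrature per axis; the simulator's isotropic render
uses the exact error-function integral).

**Chung–Kennedy filter.** Each output sample is the inverse-variance-
weighted (exponent 2) combination of the means of a trailing and a
leading 5-frame window, both including the current sample. A noiseless
step is preserved exactly because the window on one side of the step
has zero variance. Window 5 and exponent 2 are package defaults; the
filter is standard but its parameters are rarely reported, so both are
configurable.

**Step detection.** Candidate change points are samples where the
discrete derivative of the filtered trace exceeds 4× the normalized
MAD of the *raw* derivative (the nonlinear filter deflates its own
derivative MAD; a relative floor of 1e-8 of the trace range guards the
noiseless limit where the MAD collapses to zero). Each detected step is
then refined within ±2 frames by exact two-plateau least squares on the
raw trace, which recovers the true bleach frame at photobleaching
signal-to-noise — important because a one-frame-early step contaminates
the I₂ window with a two-fluorophore frame and biases distances low.
Traces are accepted only with exactly two downward steps, I₁ > I₂ > I₃,
and both the I₁ and I₂ plateaus ≥ 7 frames (so the level images are
always computable); everything else is rejected with a reason. This
automates what is usually a manual trace-selection step.

**Eccentricity QC.** e = √(1 − (σmin/σmax)²). The default acceptance
threshold is 0.35, chosen as roughly the 99th percentile of
single-emitter eccentricity at the default photon budget (≈10⁴ photons
per level image): at finite photon counts the fitted widths fluctuate
by ~1–2 %, putting typical eccentricities of perfectly round spots at
0.1–0.3. Much stricter thresholds (e.g. 0.04, which demands width
agreement to 0.08 %) reject essentially all fits in this regime and
are only meaningful at very high photon counts; the threshold is a
config/CLI parameter.

**Distance histograms.** Default bin width 25 nm (appropriate for the
broad distributions of real, conformationally flexible molecules on a
surface). Automatic binning uses the Freedman–Diaconis rule rounded to
the nearest 5 nm; if that leaves fewer than five occupied bins — the
narrow-distribution regime of fixed-separation synthetic data — the
unrounded FD width and then range/8 are used so the Gaussian histogram
fit stays well-posed. Histogram counts always sum to the number of
accepted pairs.

**Known limitation.** The difference-image fit inherits the shot noise
of both level images, and that noise is heteroscedastic (largest under
the surviving fluorophore). With unweighted least squares this pulls
the bleached-fluorophore position very slightly toward the survivor:
about −1 nm on the recovered distance at the default photon budget,
an order of magnitude below the pair-to-pair scatter. Noiseless movies
are recovered exactly (≤1e-2 nm over 20–100 nm separations).

## TIRF movie generator

Single-step bleaching with geometrically distributed lifetimes (mean
40 frames), no blinking: traces with blinking would fail the two-step
QC in any case, so simulating it would only thin the accepted sample.
Defaults: 157 nm pixels, PSF σ = 110 nm (diffraction limit for ~525 nm
emission at NA 1.4; not a measured value), 1500 photons per fluorophore
per frame, background 10 photons/pixel, 150 frames at 2 fps, camera
gain 1 and read noise 2 counts. Poisson shot noise can be disabled
(`shot_noise=False`) for exactness tests. The generator does not model
drift, dye orientation effects, or the focusing-aid channel of the real
instrument — so passing recovery tests validate the analysis chain, not
robustness to instrument imperfections.

## AFM unfolding

**Forward model.** The cantilever base retracts at constant speed; at
every sample the quasi-static force balance
k_c(z − x) = F_WLC(x; Lc, p) is solved for the protein extension x by
vectorized bisection on (0, min(z, Lc)) (55 iterations; the balance
always brackets a root because F_WLC diverges at Lc). Each folded
domain carries a Bell hazard k(F) = k₀·exp(F·xu/kBT); unfolding times
are drawn by exact inhomogeneous-Poisson time-transform sampling of the
total hazard along the deterministic ramp, which is equivalent to
per-timestep Bernoulli thinning as dt → 0 but independent of the
sample grid. An unfolding adds the domain's ΔLc (with per-event scatter
drawn from the observed ΔLc spread) and the force relaxes along the new
WLC. The trace ends when the force reaches the detachment threshold
(650 pN, above all unfolding forces at the calibrated parameters), then
a short zero-force tail is appended.

**Generator truth.** The 13-domain construct (7 G5 + 6 E) starts at
Lc = 71 nm, the length of the maximally extended structure. Per-class
ΔLc truths come from the published speed-series table (800 nm/s row:
14.5 nm E, 21.6 nm G5, scatter 1.2/0.6 nm). xu per class is the
Bell–Evans estimate kBT/slope from the published mode-force-vs-ln(speed)
regression (≈0.28 nm E, ≈0.30 nm G5). k₀ per class is then fixed
analytically by inverting the most-probable-rupture-force condition
n·k₀·exp(F*xu/kBT) = r(F*)·xu/kBT at the published modal force, with
the loading rate r = v·k_eff evaluated from the series stiffness of
cantilever (30 pN/nm) and WLC at a representative mid-phase contour
length, and n the geometric mean of the folded-domain counts over the
class's unfolding sequence (first-of-n events rupture at lower force).
This calibration is closed-form from the published numbers; nothing in
it is fitted to simulation output. Defaults: 10 kHz sampling, 10 pN
Gaussian force noise (the Bell spread itself contributes ~20 pN, so the
pooled force histograms have widths comparable to the published ~35 pN).

**Analysis.** Peaks are found on a 5-sample median-filtered force
channel (scipy `find_peaks`, prominence ≥ 30 pN, height ≥ 50 pN), then
each peak is refined to the rupture edge — the steepest single-sample
raw-force drop within ±15 samples — and the event force is the raw
force at that sample (the median filter straddles the drop and would
bias the peak force low; the raw sample is unbiased at the cost of one
noise s.d. of extra scatter, which the modal fit absorbs). The rising
edge from the preceding valley to each peak is fitted with the one-
parameter WLC (p fixed at 0.4 nm, never varied; segments under 15
samples are dropped). ΔLc_i = Lc(i+1) − Lc(i) attributes each increment
to the event between the two segments. Classification windows:
E ∈ [12.0, 18.5) nm, G5 ∈ [18.5, 26.0] nm, chosen to bracket the
published per-speed ranges (145–154 Å and 216–227 Å) with the boundary
at the midpoint gap; misclassification between the two classes at the
observed scatter is < 0.1 %. Traces are accepted with ≥ 3 classified
events, a final detachment peak, and class counts within the construct
composition (≤ 6 E, ≤ 7 G5). Events are pooled across traces within a
speed before modal fitting (as triplicate experiments were pooled);
modes are Gaussian-fit means over histograms with 5 Å ΔLc bins and
Freedman–Diaconis force bins.

**Not modelled:** cantilever calibration, tip–sample adhesion,
refolding during retraction, instrument drift, constant-force modes.

## Folding thermodynamics

Two-state equilibrium fits use the six-parameter linear-baseline model;
ΔG = m·D₅₀ is an identity of the fit object, never an independently
fitted number, and its standard error uses the full m–D₅₀ covariance.
Initial guesses come from the curve ends (baselines) and the
mid-signal crossing (D₅₀). Fits are refused when the signal range is
below 3× the point-to-point noise or when a straight line already
explains the data (no transition in window).

Chevrons are fitted on log rates. The sequential transition-state
variant replaces the unfolding limb with the harmonic combination
1/ku = 1/(ku₁·e^{m₁D}) + 1/(ku₂·e^{m₂D}) — the rate-limiting barrier
switches with denaturant, curving the limb. This functional form is one
standard choice among several (the literature often cites the model
without equations); it is isolated in two small functions and easily
swapped. Model selection in `auto` mode prefers two-state unless the
sequential fit improves the reduced χ² by > 20 %. Single-limb data are
fitted limb-only and flagged partial. On matched noiseless synthetics
the detailed-balance identity RT·ln(kf₀/ku₀) = m·D₅₀ and the
kinetic/equilibrium m-value identity hold to 1e-6.

**Interface ledger.** Sign conventions are explicit: equilibrium
tables report unfolding ΔG (positive = stable); the ledger works in
folding convention (negative = stable) and every input carries bound
semantics ('exact', '≥', '≤') represented as intervals. Rule A
(partition additivity): ΔG_int(X–Y) = ΔG(XY) − ΔG(X) − ΔG(Y) for a
construct partitioned into independently measured parts, propagated by
interval arithmetic. Rule B (midpoint-shift bound): a domain folding
inside a larger construct at midpoint D₅₀(c) > D₅₀(d) must be
stabilized by at least m_d·(D₅₀(c) − D₅₀(d)); always a bound. Any
bounded input yields a bounded output — the ledger never upgrades a
bound to an equality. For the G5¹-E-G5² system with domain stabilities
(−3.2, ≥ +2.5, −2.8 kcal/mol) these rules give E–G5² ≥ 6.0 and
G5¹–E ≥ 1.7 kcal/mol. The rules are this package's reconstruction of
the bound derivation, stated as such; they are not claimed to be the
original algebra.

## Shape models

Domains are rigid cylinder segments of beads: axial stations every
1/beads_per_nm, each carrying a golden-angle sunflower disk so the
circular cross-section is sampled with uniform area density (giving the
solid-cylinder Rc = a/√2). Default per-domain lengths 6.2 nm (G5) and
4.6 nm (E) are solved from the two published rigid-model anchors
(three domains ≈ 17 nm, thirteen ≈ 71 nm); default radius 1.0 nm.
Flexed ensembles tilt each inter-domain junction by a normal polar
angle (s.d. `bend_sd`) at uniform azimuth, domains staying rigid; mean
end-to-end distance and Dmax are non-increasing in `bend_sd`, and the
measured solution Dmax of the 13-domain construct (~63 nm vs 71 rigid)
corresponds to bends of roughly 15–20°.

P(r) is the normalized histogram of all pairwise bead distances
(chunked to bound memory); Dmax is the exact maximum pairwise distance,
a geometric quantity — experimental Dmax from indirect-transform
support selection is a different estimator and is not reproduced here.
The cross-sectional distribution projects beads onto the plane normal
to the dominant gyration-tensor eigenvector. Debye intensities use the
standard fine-histogram approximation of I(s) = ΣΣ sinc(s·r_ij) with
uniform weights, so I(0) = n² exactly. Guinier (ln I vs s², slope
−Rg²/3), cross-sectional Guinier (ln(I·s) vs s², slope −Rc²/2) and
Porod (log–log slope) fits are plain linear regressions over a
caller-chosen s-range; accuracy claims in the tests use s·Rg ≤ 0.8.
No experimental scattering curves are fitted and no absolute-scale
molecular-mass estimation is attempted.

## Recovery experiments and problem sizes

`rodfold.reproduce` fixes the ensemble sizes of the closure
experiments: 100 denaturation curves per construct (30 points, 0–8 M,
2 % amplitude noise), 200 AFM traces at 800 nm/s, 500 one-molecule
movies at 59 nm separation. These sizes put the Monte-Carlo error of
each recovered mean comfortably below the published uncertainty it is
compared against while keeping a full run under a minute. Per-replicate
seeds derive deterministically from one base seed. What these closures
demonstrate is that the analysis chain is unbiased and correctly
calibrated *under the generative model described above*; they cannot
certify behaviour on artefacts the generators omit (drift, adhesion,
blinking, baseline curvature).
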