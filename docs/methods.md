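# Methods

This note documents the models implemented in `cvmbarrier`, the
defaults and why they were chosen, the numerical decisions, and the
limits of what the synthetic-data tests demonstrate.

## Trajectory and video simulation

Probe motion is simulated per particle in 2-D with ensemble
MSD(τ) = 4·D·τ^α (µm², s). α = 1 gives ordinary Brownian motion with
independent Gaussian increments of per-axis variance 2·D·dt. For α < 1
increments are fractional Gaussian noise synthesized from the exact
increment covariance by Cholesky factorization (the factor is cached
per (α, n, dt), and D scales out, so repeated draws are cheap). Tracks
are short (≤ a few hundred frames), so O(n³) factorization is
negligible and exactness is preferred over spectral approximations.

The mucus context maps onto two populations per sample: *mobile*
particles diffusing at the rate the obstruction model (below) predicts
for the sample's pore size, and *trapped* particles. The real dynamics
of trapped particles in CVM are not characterized — adhesive trapping
may look like confinement or like very slow transport — so the
generator supports both stand-ins: slow Brownian motion (default,
D = 1e-4 µm²/s, putting log₁₀ MSD(1 s) ≈ −3.4, well below the −1.3
cutoff) and subdiffusive fBm with small α. Tests exercise each.

Population assignment uses a deterministic quota, round(fraction·n)
with the remainder to the largest-fraction population, so ground-truth
label counts are exact in recovery tests rather than binomially noisy.

Video rendering emulates EM-CCD acquisition at the study's optics
defaults — 25 nm/px, 15 Hz, 20 s, 512×512 px: each frame is a constant
background plus a symmetric Gaussian spot (σ = 1.5 px) per particle,
with Poisson shot noise, written as uint16 multi-page TIFF. Particles
leaving the field raise an error by default (`out_of_field="reject"`);
`"clip"` renders the in-field part. What the renderer does *not*
emulate: EM gain register statistics, vignetting, focal drift, axial
defocus, photobleaching. Tracking results on these videos therefore
bound algorithmic error, not instrument error.

## Detection and linking

Localization is a Crocker–Grier-style pipeline: band-pass (Gaussian
σ = 1 px minus σ = 8 px rolling background), local maxima above the
99.5th intensity percentile, then intensity-weighted centroid
refinement in an 11 px window. Candidates fainter than 10% of the
brightest spot in the frame are discarded — with a percentile
threshold alone, sparse fields pass shot-noise peaks. Maxima closer
than the refinement window cannot be refined independently; they are
reported once, flagged ambiguous, and excluded from linking, trading
coverage for protection of the MSD against identity swaps. Note that
spots closer than ~2 PSF widths fuse into a single maximum and are
indistinguishable from one bright particle; the ambiguity flag only
covers resolvable-but-overlapping pairs.

Linking solves, per frame pair, the bipartite assignment minimizing
total squared displacement (Hungarian algorithm), gated at
`max_displacement` (default 0.5 µm/frame — generous for D ≤ 1 µm²/s at
15 Hz) times the gap length; a track may vanish for up to `memory = 2`
frames. Tracks shorter than 30 frames (2 s) are discarded so that
τ = 1 s is estimable from ≥ 15 displacement pairs. The thresholds are
declared defaults of this implementation, chosen from standard MPT
practice, not inferred from any particular instrument.

Drift correction is deliberately absent (sealed-well room-temperature
acquisition is assumed drift-free); the hook exists in config but is
off.

## MSD

Per-particle time-averaged MSD uses overlapping windows (every valid
start frame), the standard maximum-pairs estimator in MPT; a
non-overlapping variant is available behind a flag for variance
studies. Gaps contribute no pairs. A particle is eligible at τ = 1 s
with ≥ 15 valid pairs. Exactly zero MSD (possible for synthetic
stationary particles) is floored at 1e-6 µm² before taking log₁₀ so
mixture fitting never sees −∞; the floor is config.

## Trapped/mobile mixture

`LogMSDMixture` fits a two-component univariate Gaussian mixture to a
sample's log₁₀ MSD values by EM with deterministic initialization
(means at the 25th/75th percentiles, pooled SD, equal weights), a
variance floor of 1e-4 (log₁₀ units)², tol 1e-8 on the log-likelihood,
max 500 iterations. Components are reported mean-ascending. The
"single peak" condition that triggers the cutoff fallback is made
explicit: the fit counts as bimodal only if it converged, the means are
≥ 1 pooled SD apart, and both weights are ≥ 0.02. Otherwise the mobile
fraction is the proportion of particles above the −1.3 cutoff
(log₁₀ MSD in µm²; config-overridable).

The mobile fraction from a bimodal fit is the mixing *weight* of the
higher-mean component, matching the "estimated percentage of mobile
particles" reading of component fractions; a posterior-count mode is
implemented and selectable (`fraction_mode="posterior"`). Particles are
pooled across all videos of a sample before fitting; groups with fewer
than 10 particles are marked insufficient.

## Pore size

Free diffusivity from Stokes–Einstein, D₀ = k_B·T/(3πηd), at
T = 298.15 K and η = 8.9e-4 Pa·s (room-temperature water). Effective
diffusivity from the sample's ensemble-average MSD over all tracked
particles of a probe, D_eff = MSD/(4τ) for 2-D tracking. The forward
obstruction-scaling model

    D_eff/D₀ = exp[−(π/4)·((d + d_f)/(ξ + d_f))²]

with fiber diameter d_f = 7 nm inverts in closed form. The literature
on mesh-hindered diffusion offers several closed forms; this
exponential obstruction form is the tested default and the model is
pluggable behind the same interface. Hindrance ≥ 1 (free or
super-free diffusion) yields "unbounded" and is excluded from the
per-sample mean; a negative root (extreme hindrance) is clamped to 0
and flagged. The per-sample estimate is the arithmetic mean of the
defined per-probe ξ values across the 100/200/500 nm MPPs.

Because the ensemble average includes trapped particles, per-sample ξ
is an *effective* value biased low relative to the pore size the mobile
population experiences; CST contrasts (I vs IV) are preserved, and the
round-trip identity is exact when the input MSDs come from a single
hindered population.

## Community state typing

Bray–Curtis dissimilarities (scipy's implementation; identical to
1 − 2Σmin/(Σa+Σb) for compositional rows) feed classic PAM: greedy
BUILD initialization, then best-improvement SWAP to a local optimum of
the total within-cluster distance to medoid. BUILD is deterministic, so
the clustering is reproducible without a seed. k is fixed at 5 — the
five canonical CSTs — with no model selection. Clusters are named by
the medoid's dominant taxon (threshold 0.5 for Lactobacillus
dominance); a cluster whose medoid has no dominant archetype
Lactobacillus is CST IV, and if two clusters claim the same
Lactobacillus the lower-dominance one falls through to IV with a
warning. All samples are clustered jointly (no external reference
classifier).

Attrition bookkeeping: each visit's CST persists until the next visit;
after the last sampled visit it persists to delivery (rows flagged
unobserved). Per-participant mobility within a CST is the unweighted
mean over that participant's samples.

## Cohort statistics

Point RR and OR come from the raw 2×2 counts: zero numerators give 0
(matching how all-zero exposure rows print), zero denominators an
infinite marker, no continuity correction. Confidence intervals use
the Katz log method (RR) and Woolf log method (OR); when any cell is
zero, the Haldane–Anscombe 0.5 correction is applied *inside the CI
computation only* and flagged. Commercial packages differ in their CI
conventions, so the CI columns are documented implementation choices;
the point estimates are not. The exact test is the two-sided Fisher
test with the point-probability criterion (scipy). Welch's t uses
Satterthwaite df, with the (0, p = 1) convention for two degenerate
equal-mean groups. ANOVA is the standard one-way F; pairwise
comparisons use Tukey's HSD on the studentized range with Tukey–Kramer
standard errors for unequal n. Trend tests are OLS slope t-tests
reporting slope, R² and p.

## Synthetic cohort

Participants enroll at 8–16 weeks and are sampled every 4 weeks until
delivery (grid capped at 37 weeks). The CST path is first-order Markov
over visits with a diagonal-heavy transition matrix whose largest
off-diagonal moves are III→I and III→IV, the transitions most often
observed in pregnancy cohorts; initial state probabilities follow
typical cohort sample shares (29/4/32/28/7% for I/II/III/IV/V). Per-CST
mean mobile fractions for the MPP probes use observed per-CST values
where such values are established (e.g. CST I ≈ 72.5/62.8/52.6% and
CST II ≈ 93.7/97.4/87.7% for 100/200/500 nm MPPs) and plausible
interpolations for the rest; per-visit draws add Gaussian noise
(SD 0.06, clipped to [0,1]). Generating pore sizes are normal per CST
around {I: 240, II: 380, III: 330, IV: 420, V: 300} nm (SD 25), i.e.
tightest mesh under *L. crispatus* dominance, loosest in polymicrobial
samples, cohort average near ~310 nm.

Delivery outcome is Bernoulli with probability equal to the highest
per-CST preterm risk among CSTs occupied *before 27 weeks* — the
earliest possible delivery — so exposure precedes outcome and is always
observed; this makes configured risk ratios recoverable by construction
and avoids immortal-time artifacts when late visits are truncated at
delivery. Default risks are {I: 0.05, II: 0.05, III: 0.12, IV: 0.25,
V: 0.08}, reproducing the qualitative risk gradient (polymicrobial >
*L. iners* > *Lactobacillus*-dominated). Exclusion flags (blood,
recent intercourse) are Bernoulli at 5% each; 12% of participants stop
sampling early to exercise carry-forward.

What the cohort generator does **not** emulate: real 16S read-level
noise (sequencing error, chimeras, variable depth), sub-CST structure
(IV-A/IV-B), demographic confounding between attributes, gestational
trends in mucus properties (mobility is stationary within a CST by
construction), and postpartum samples. Passing recovery tests
therefore demonstrates the correctness of the estimators under the
stated generative model, not their robustness to real-world artifacts.

## Problem sizes

The default demo cohort is 20–25 participants (≈ 100–140 samples),
40–60 particles per (sample, probe) and 8–20 s recordings; the
acceptance script uses 80 participants for steadier group contrasts.
These sizes give Monte-Carlo error comfortably inside every asserted
tolerance while keeping a full pipeline run in seconds on one CPU;
larger cohorts change nothing structurally.

## Known limitations

- The pore-size equation is one member of a family of obstruction
  models; absolute ξ values shift by tens of nm across forms, though
  orderings are stable. The model is pluggable for this reason.
- The mixture mobile fraction is a component weight; for strongly
  overlapping components the weight and the posterior count can differ
  by more than the test tolerances — the bimodality rule is designed to
  route such cases to the cutoff method instead.
- PAM is run jointly on the analysis table; assignments are not stable
  under adding samples (no out-of-sample prediction), matching the
  joint-clustering protocol rather than a reference classifier.
- The tracker has no drift correction and assumes symmetric PSFs;
  anisotropic or defocused spots bias the centroid.
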