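# Methods

## Scope and model

The package implements a desk-scale version of the inference chain
relating carbon-ion LET, γH2AX focus volume and clonogenic killing at
1 Gy. It starts from measured-quantity tables (focus volumes, occupancy
areas, colony counts, depth profiles); microscopy, image segmentation and
Monte Carlo particle transport are upstream and out of scope.

Per LET *L*, the chain is:

1. **Max-volume law.** Foci below 0.01 μm³ are excluded as segmentation
   noise; the per-nucleus maximum volume of the remaining foci is modelled
   as Normal(μ_L, σ_L). The fit is a nonlinear least squares of the unit
   normal density against a histogram with 0.1 μm³ bins anchored at zero
   and normalised to density (bin fraction ÷ bin width). Density
   normalisation fixes the amplitude, so only (μ, σ) float. The fit is
   initialised at the sample mean/sd, constrained to σ > 0, with parameter
   tolerance 1e−10; non-convergence and degenerate samples (n < 5, or all
   values equal) are errors, never silent fallbacks. μ and σ are then
   regressed on LET by ordinary least squares (≥ 3 distinct LETs
   required).
2. **Clustering probability.** p_L(v_th) is the upper tail of the fitted
   normal, evaluated through the complementary error function. The tail is
   untruncated at v = 0 (sub-zero mass is < 0.5% at the lowest LET in the
   validity range 13–100 keV/μm) and the boundary is inclusive (≥ v_th),
   matching the empirical count. The empirical variant uses hit nuclei
   (those contributing a max-volume sample) as its denominator.
3. **Unhit law.** A cell is unhit when γH2AX occupancy is strictly below
   1% of the nucleus area. The unhit fraction versus LET is fitted with the
   one-parameter quadratic R(L) = (c·L)²/100, which is linear in c² and so
   has the closed-form unweighted least-squares solution
   c² = 100·ΣR_kL_k²/ΣL_k⁴. A quadratic is used rather than a Poisson
   zero class because one traversal does not demonstrably produce one
   detectable focus. The law's domain ends at L = 10/c (≈ 161.8 keV/μm at
   c = 0.0618), where R_unhit reaches 1; evaluation beyond is an error.
4. **Survival.** Plating efficiency pools control wells (total colonies /
   total seeded — variance-minimising and robust to unequal wells). SF and
   normalised killing above 1 warn rather than error, since both occur in
   noisy replicates. Replicate dispersion is the sample standard
   deviation. No dose-response fitting: everything is at the single dose
   of 1 Gy.
5. **Mixed beams.** Each ridge-filter leg contributes one (LET, dose) pair
   looked up on the monoenergetic depth profile at the SOBP-center depth
   plus its shift; component LET is capped at 100 keV/μm *before* dose
   averaging (overkill saturation). Depth lookups interpolate linearly on
   the 0.1 mm grid and error (never extrapolate) outside it. Full
   LET-histogram mixing with fragment spectra is out of scope; the
   spectrum is carbon-only by construction.
6. **Concordance.** For a v_th grid of 0.1–2.0 μm³ in 0.1 steps, the
   statistic is the mean ± sample sd over conditions of
   |p(v_th) − killing/R_hit|, computed on fractions; the optimal threshold
   is the grid argmin with ties broken toward the smaller v_th.
   Monoenergetic conditions (keyed by LET) and SOBP conditions (keyed by
   width, with p evaluated at L_mix) share this code path.

## Synthetic data generator

Defaults encode the study conditions: LET panel {13, 20, 40, 60, 80,
100} keV/μm, 30 nuclei per LET for volumetry, 200 occupancy-scored cells
per LET, triplicate clonogenic wells, 1 Gy, generating laws
μ = 0.0158·L + 0.126, σ = 0.00724·L + 0.0312, unhit coefficient 0.0618
and lethal threshold 0.7 μm³. Quantities the source tables do not pin
down were chosen once as field-plausible values: plating efficiency 0.8
(typical for A549), 2000 seeded cells per well, hit-nucleus focus counts
Poisson with mean 40·(13/L) — chosen so the whole panel yields roughly
3×10³ foci over 180 nuclei, with the observed 1/L decline of focus counts
at fixed dose — and nucleus areas Normal(120, 12) μm² emulating a
G0/G1-synchronised monolayer.

Structural choices:

* **Unhit sampling is Bernoulli** with probability R_unhit(L), mirroring
  the quadratic (not Poisson) law the analysis fits.
* **Max volumes below the exclusion floor are resampled** (truncation)
  so nuclei counts stay fixed and the fitting stage never sees sub-floor
  values. Consequently the generated sample mean converges to the
  floor-truncated normal mean, about +0.014 μm³ above μ at LET 60; tests
  use the truncated-normal expectation as their oracle.
* **Non-maximum focus volumes** are a plausibility-only log-normal
  (median ≈ max/3, log-sd 0.7) bounded to [floor, max]: only the maximum
  feeds the downstream model, so no generative law is claimed for the
  rest of the distribution.
* **Colony counts** are Binomial(n_seeded, PE·SF) with
  SF = 1 − R_hit·p(v_th*): traversed cells die exactly when their maximum
  focus reaches the lethal threshold. Control wells draw with success
  probability PE.
* **Depth profiles** are parametric Bragg-curve stand-ins on an exact
  0.1 mm grid: dose rises gently (≈ z²), peaks as a gaussian of width
  3 mm at the range (150 mm, peak-to-entrance ratio ≈ 4.3) and falls off
  over 1.5 mm distally; LET follows an inverse-residual-range power law
  (exponent 0.63, stopping-power-like) pinned exactly to 13 keV/μm at the
  entrance and 200 keV/μm at the peak. These reproduce the features the
  mixing stage relies on (monotone LET rise, single dose peak, plateau
  composability) but not nuclear fragmentation, straggling tails or
  field-size effects.
* **Ridge-filter weights** are non-negative least squares of the shifted
  mono dose curves against a flat unit target over the plateau (edges
  trimmed by 2 mm), normalised to sum 1; shifts span exactly the
  requested width in 2 mm steps. The composed plateau is flat to within
  about ±0.6%, and the resulting dose-averaged LET falls from ≈ 78 keV/μm
  at 30 mm width to ≈ 34 keV/μm at 120 mm, a clinically sensible trend.
* **Reproducibility.** One global integer seed; each generator draws from
  an independent named substream (`numpy` SeedSequence spawn keys), so
  outputs are bit-identical under a fixed seed and adding one generator
  never perturbs another.

Because the generator shares the analysis' own structural assumptions
(normal max volumes, quadratic unhit law, binomial colonies), passing
recovery tests demonstrates the correctness and calibration of the
fitting chain — not that real microscopy data obey these laws.

## Verification

* Closed-form tail probabilities agree with adaptive quadrature of the
  density to 1e−8 across LET ∈ [13, 100] and v_th ∈ [0, 3].
* The dose-averaged LET matches an explicit loop-and-sum oracle on random
  spectra to machine precision, including the cap rule.
* Parameter recovery at the study's own sizes: 500 replicates of
  30-nuclei-per-LET fits recover the four linear-law coefficients to a
  few percent in the mean (the σ intercept is noisiest, ≈ +15% at n = 30,
  an absolute error of ~0.005 μm³); 10⁴ occupancy cells per LET recover
  the unhit coefficient within 1%; and the full pipeline recovers the
  0.7 μm³ threshold within one 0.1 μm³ grid step in ≥ 95% of 100
  independently seeded runs.
* Conservation properties (R_hit + R_unhit = 1, ΣLd/D bounded by
  component range, p monotone in v_th) are property-tested over
  randomised inputs.

Problem sizes in the test suite (replicate counts, cells per LET, seeded
cells) are the package's calibration-experiment design and keep the whole
suite under a minute of compute.

## Known limitations

* The linear σ law goes negative below ≈ −4 keV/μm and the laws are only
  trusted on 13–100 keV/μm; nothing guards against mild extrapolation
  inside [0, 13).
* The empirical clustering probability's denominator (hit nuclei) is a
  convention; analyses that count unhit nuclei in the denominator will
  differ at high LET.
* SOBP spectra ignore nuclear fragments and straggling; the dose-averaged
  LET of the parametric stand-in beams should not be compared numerically
  against treatment-planning values.
* The concordance dispersion (± across conditions) is a sample sd over a
  six-point panel and is itself noisy.
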