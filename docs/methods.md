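# Methods

This note documents the models, estimators and synthetic-data generators in
`foxptools`, the choices that were genuinely open, and what the synthetic
benchmarks do and do not demonstrate about real instrument data.

## Scientific setting

Human FoxP1 carries two dimerization-competent domains — a leucine-zipper
(ZIP) coiled coil and a Forkhead (FKH) DNA-binding domain — tethered by a
~90-residue disordered linker.  The package quantifies how that tethering
shapes (i) dimerization and DNA-binding equilibria measured by fluorescence
anisotropy titration, (ii) conformational stability measured by GdmCl
unfolding, (iii) local domain mobility measured by single-molecule
fluorescence anisotropy, lifetimes and FCS, and (iv) the monomer's
conformational landscape over (Rg, α-helicity) from simulation trajectories.

## Equilibrium binding (`thermo`)

The default isotherm is the hyperbolic two-state model

    r_obs = offset + r_max · [P] / (Kd + [P]),

with [P] the *total* titrant concentration, matching the standard analysis
of anisotropy titrations.  Because self-dimerization is strictly quadratic
in free monomer, an exact mass-action monomer–dimer isotherm is available
(`fit_binding(model="quadratic")`) and labeled in the output; for the Kd
range here (tens to hundreds of nM against 0–5000 nM titrant) the two differ
by less than the titration noise.  Fits are trust-region least squares with
five jittered starts; standard errors come from the linearized covariance.
A fit whose Kd standard error exceeds the estimate is flagged
`non_informative` (negative control: shuffled responses).

## Chemical unfolding (`thermo`)

The linear extrapolation model is used with a *signed* m-value,

    ΔG_U(D) = ΔG_H2O + m·D,     m < 0 for destabilization,

and reports also include |m|.  Four mechanisms are supported; dimer
equilibrium constants are expressed in total-monomer units (P_t), giving
closed-form positive roots for the conservation quadratics:

* mono2 (N⇌U):           f_N = 1/(1+K)
* mono3 (N⇌I⇌U):         f_N = 1/(1+K₁+K₁K₂)
* dimer2 (N₂⇌2U):        2P_t f_U² + K f_U − K = 0
* dimer3 (N₂⇌2I⇌U):      (2P_t/K₁) f_I² + (1+K₂) f_I − 1 = 0

Roots are evaluated in cancellation-free form (e.g. f_N = x/(1+√(1+x))² for
the two-state dimer) so the mass-action identity K = 2P_t f_U²/f_N holds to
better than 1e−7 relative even at f_N → 0; the solvers are verified against
a brute-force `brentq` root scan (1000 random parameter draws, ≤ 1e−8).
R = 1.987×10⁻³ kcal/(mol·K); binding defaults to 310.15 K (titrations are
incubated at 37 °C), unfolding to 298.15 K, both configurable.

`fit_unfolding` uses multi-start least squares.  Three-state fits add
structured starts obtained by splitting an effective two-state pre-fit, and
candidate optima whose residuals are statistically tied (F-ratio within the
95% band for the data's degrees of freedom) are resolved in favor of
interior solutions over bound-pinned ones — a parameter pinned at its bound
marks a flat likelihood direction, not information.  `fix_baselines` pins
the native/unfolded signals to the curve endpoints, appropriate for curves
normalized to folded fraction.

### Summed stability of overlapping three-state transitions

When the two transitions of a three-state monomer overlap (midpoints ~1.1
and ~1.6 M here), the free 7-parameter fit is not identifiable at realistic
noise: the likelihood has an interior optimum near the true total plus a
nearly flat ridge toward arbitrarily large totals, reached either by hiding
a transition behind a baseline or by co-scaling ΔG and |m| at fixed midpoint
until the transition sharpens below the denaturant spacing.
`total_stability_profile` therefore estimates the summed stability by
profile likelihood: residuals are minimized at each fixed total, and the
estimate is the smallest-total local optimum statistically tied (within
`tie_ratio`, default 1.10) with the global one.  Two physically motivated
constraints close the ridge: the intermediate signal must lie between the
pinned baselines, and the *summed* |m| is bounded (default 4 kcal/(mol·M))
because m-values scale with buried surface area of the whole molecule and
the transitions partition it — for these small, partly disordered helical
constructs a larger total m would imply more surface exposure than the
folded regions can provide.  The 1σ uncertainty is read off the
χ²_min + s² profile crossing.  Over 100 simulated replicates at the study
conditions (total ΔG = 4 kcal/mol split 40/60 sequentially, |m| = 1.5 per
transition, 3% noise, 20 points over 0–5 M) the estimator's median is ≈ 4.1
with interquartile range ≈ [2.9, 5.8].

## Time-resolved fluorescence (`fluortime`)

Decays are multi-exponential, F(t) = Σ xᵢ exp(−t/τᵢ) (the decaying-exponent
form), convolved with the instrument response.  A Gaussian IRF uses the
closed-form exponentially-modified-Gaussian reconvolution, evaluated in log
space to avoid overflow; measured IRF histograms use discrete linear
convolution on the shared grid.  Fits maximize the Poisson likelihood
(L-BFGS-B; covariance from a finite-difference Hessian of the NLL), and the
reduced χ² is computed with Neyman weights so nested models can be compared
with the F-test

    F = ((χ²₁ − χ²₂)/Δdf) / (χ²₂/df₂),

keeping the richer model only at p < 0.05.  The fluorescence-weighted mean
lifetime is ⟨τ⟩_F = Σxᵢτᵢ²/Σxᵢτᵢ.

Steady-state anisotropy supports two dialects of the intensity formula:
`as-printed` r = (F_p − F_s)/(F_p + 2G·F_s) (the package default, for
continuity with common lab usage) and `conventional`
r = (F_p − G·F_s)/(F_p + 2G·F_s), which is recommended when G ≠ 1; they
coincide at G = 1.

Polarized decays are fitted jointly as F_p ∝ F(t)(1+2r(t))/3 and
F_s ∝ F(t)(1−r(t))/(3G) with r(t) = r₀ Σ b_j exp(−t/ρ_j).  Every product
term is again a pure exponential, so the Gaussian-IRF reconvolution stays
analytic.  r₀ is fixed at 0.38 by default (configurable or fittable); with
the pooled sub-ensemble of a mixture of rotational states sharing one
lifetime, the fitted b_j are the state population fractions, and the
per-state steady-state anisotropies follow from the Perrin relation
r_j = r₀/(1 + ⟨τ⟩_F/ρ_j).  A ρ exceeding 50·⟨τ⟩ is reported as a lower
bound (`rho_lower_bound` flag).

## Burst analysis and FCS (`smburst`)

Burst search is the all-photon sliding window: a photon is in-burst when at
least m photons (default 10) fall within a centered 500 µs window; runs
also break across gaps wider than the window; runs of ≥ L photons (default
50) become bursts.  All thresholds are exposed.  Per-burst observables:
r_G from background-corrected polarized counts, a fast mean-microtime
lifetime estimate, and E/S with γ, α, δ corrections (defaults 1, 0, 0).
Acceptor-excitation photons are encoded PIE-style in the second half of the
excitation period, which keeps the four-channel (Dp/Ds/Ap/As) layout while
making F_A^Aex — and hence stoichiometry — well defined; in streams without
acceptor excitation S is reported as NaN rather than 1.

The correlator is multi-tau (16 linear base lags, 8 points per octave,
coarsening by 2), with the symmetric segment normalization
G(k) = ⟨I_t I_{t+k}⟩/(mean_left·mean_right) − 1.  It is verified against a
naive per-lag reference to 1e−10.  FCS curves are fitted with the
3D-Gaussian confocal model

    G(t) = (1/N)(1+t/t_d)⁻¹(1+(ω/z)² t/t_d)^(−1/2)(1−d+d e^(−t/t_pho)) + B,

with d constrained to [0,1); ω/z can be fixed per curve or shared across
curves by a profiled global analysis.

## Landscape analysis (`landscape`)

Rg is the (optionally mass-weighted) RMS distance from the weighted
centroid.  α-helicity is assigned from backbone dihedrals: a residue is
helical when φ ∈ [−100°, −30°] and ψ ∈ [−67°, −7°], and only runs of ≥ 3
consecutive helical residues count; residues lacking either dihedral are
excluded from the denominator.  (A dihedral-window criterion was chosen
because simulation snapshots may lack the amide hydrogens that H-bond-based
assignment needs.)  The PMF is −k_B·T ln(n/n_max) on a 50×50 grid padded 5%
(k_B·T = 0.596 kcal/mol at 300 K, the analysis temperature), zero at the
most occupied bin and +∞ where unvisited — so it is invariant to
duplicating the sampling.  Basins grow from grid local minima below a depth
threshold by steepest-descent assignment; basins separated by barriers
below 0.5 k_B·T are merged.  Representative frames must lie within ±5 Å of
the basin mean Rg and ±0.02 of its mean helicity, are thinned to ≥ 0.5 ns
separation, and require a configurable minimum sampling history (default
10 000 frames).

## Synthetic-data generators (`synthgen`)

The generators define the study conditions used throughout the tests:

* **Titrations** — 12 points, zero plus a log ladder to 5000 nM (ZIP-lin),
  200 nM (ZIP-lin-FKH, with or without DNA preincubation) or 500 nM (DNA
  binding); 5 nM labeled species; homoscedastic Gaussian noise with
  σ = 1% of the anisotropy amplitude (the source reports duplicate means
  ± SD without an error model, so a simple homoscedastic choice is used).
* **Unfolding** — 20 points over 0–3 M (two-state dimers) or 0–5 M
  (three-state and monomer curves); 200 nM total protein for dimers, 5 nM
  for monomers; noise 2% (dimers) or 3% (monomers) of amplitude; generating
  stabilities are the published values (10, 12, 12+6, 4, 6 kcal/mol) with
  |m| = 4 (dimer) and 1.5 (monomer) kcal/(mol·M), which place the
  transitions in the reported 0.5–1.5 M and 2.5–4.5 M windows.  The
  three-state monomer total is split 40/60 with the smaller ΔG first —
  the only ordering that makes the transitions sequential (midpoint order
  1.07 M then 1.6 M) so that an intermediate actually populates.  The
  noiseless signal is produced by the same fraction solvers the fitters
  use; independence of the recovery tests rests on the noise, the oracle
  tests of the solvers, and the closed-form anchors, not on a separate
  forward model.
* **Photon streams** — bursts arrive as a Poisson process; each burst is a
  top-hat transit whose duration is drawn by inverse-survival sampling from
  the distribution whose E[(T−τ)₊] is proportional to the 3D-Gaussian FCS
  curve, so the ensemble intensity ACF matches the model it will be fitted
  with (a plain exponential transit distorts the fitted t_diff).  Photon
  microtimes follow the species' lifetime mixture plus Gaussian IRF jitter
  and are floor-quantized to the TCSPC resolution (floor, not round — bins
  are left-edge aligned).  Polarization channels are drawn with weights
  (1+2r(t))/3 and (1−r(t))/(3G) at the true emission delay, and the
  emission-time draw is thinned by the time-varying summed detection
  probability so the joint (time, channel) law is exact; thinning preserves
  Poisson statistics.  Background photons are uniform in macro- and
  microtime on all four channels.  Defaults (background 1 kHz/channel,
  brightness 50–100 kHz, t_diff 1 ms, 20 MHz excitation) are chosen for
  statistical adequacy; the source reports no acquisition parameters.
* **Reaction coordinates** — Gaussian-mixture basins over (Rg, f_α) with
  helicity clipped to [0,1]; an 18-replica ladder helper spans 280–370 K
  equally spaced; an ideal-geometry backbone builder (NeRF placement,
  standard bond lengths/angles) produces structural fixtures with exact
  (φ, ψ) round trip.

Identical (spec, seed) ⇒ byte-identical output, including photon ordering.

### What the synthetic benchmarks do not show

The generators reproduce the statistical structure the analysis assumes —
not detector dead time or afterpulsing, dye photophysics (triplet blinking,
PIFE, quenching), spectral crosstalk beyond the α/δ corrections, true 3D
Brownian transits, or correlated/heteroscedastic titration noise.  Passing
recovery tests therefore demonstrates correctness and calibration of the
estimators under the stated model, not robustness to every instrument
artifact.

## Problem sizes

The test suite and the acceptance script use 12-point titrations (20
seeds), 20-point unfolding curves (20 seeds; 40 for the profile-likelihood
total), 10⁶-photon streams (10 seeds) for sub-ensemble anisotropy, ~10⁵–10⁶
photon streams for FCS, and 6 000–40 000-frame coordinate series for the
landscape properties.  These sizes were chosen so each benchmark's Monte
Carlo error is several times smaller than the tolerance it is checked
against.
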