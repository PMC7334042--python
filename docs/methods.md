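# Methods

This note records the modelling assumptions, parameter choices and
numerical decisions behind `qbold`, in the spirit of a model-description
appendix. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted that the code
does not measure.

## Signal model

**Tissue (extravascular).** Vessels are randomly oriented infinite
cylinders in the static dephasing regime: tissue water is taken as
stationary relative to the vessel geometry, so reversible dephasing is not
motionally averaged. The free-dephasing signal fraction is
`exp(−R2t·t)·exp(−DBV·I(δω·t))` with the cylinder-averaged integral
`I(x) = ∫₀¹ (2+u)√(1−u)/(3u²)(1−J₀(1.5xu)) du` and
`δω = (4/3)π·γB₀·Δχ₀·Hct·OEF`. `I` is evaluated by adaptive quadrature
(`scipy.integrate.quad`, relative tolerance 1e−10) with a series guard for
the `1−J₀` cancellation at small argument, and cached per argument; it
satisfies `I(x) → 0.3x²` (small x) and `I(x) → x−1` (large x), which the
tests verify.

**ASE mapping.** With the refocusing pulse displaced by τ/2 at fixed TE,
irreversible decay acts over TE while the net reversible dephasing time is
τ. Because the fields are static and the cylinder-average is symmetric,
the signal depends on |τ| only; the analytic ASE tissue signal is
`S0·exp(−R2t·TE)·exp(−DBV·I(δω|τ|))`. The asymptotic fitting model keeps
this evenness: `exp(−(3/10)·DBV·(δω·τ)²)` for |τ| < tc and
`exp(DBV − R2′·|τ|)` for |τ| ≥ tc, with `R2′ = DBV·δω`, and equality at
the boundary assigned to the long-τ branch so the fitted long-τ regime is
contiguous. The equivalent (R2′, DBV) parameterisation replaces
`δω = R2′/DBV`; both forms agree to machine precision and the package
fits in (R2′, DBV) by default because that posterior is closer to
Gaussian (see the separability analysis below).

**Blood (intravascular).** The venous compartment enters as a convex
combination `S = S0·(ζ′·Sb + (1−ζ′)·St)` with apparent blood volume
`ζ′ = m_b·n_b·DBV`. Three blood models are provided:

- *Motional narrowing* (default): plasma spins diffuse far past a red
  blood cell within TE, so intravascular dephasing is Gaussian-phase
  averaged. The attenuation exponent is
  `−(γ²G₀t_D²/2)·[TE/t_D + √(¼+TE/t_D) + 3/2 − 2√(¼+(TE+τ)/(2t_D)) −
  2√(¼+(TE−τ)/(2t_D))]` with
  `G₀ = (4/45)·Hct(1−Hct)·(4π·B₀·OEF·Δχ₀)²`. This form follows from the
  Gaussian-phase identity for one refocusing pulse,
  `⟨φ²⟩ = γ²[2F((TE−τ)/2) + 2F((TE+τ)/2) − F(TE)]`, with field
  autocorrelation `K(s) = G₀(1+4s/t_D)^{−3/2}`; it is even in τ, bounded
  by 1, and collapses to `exp(−R2b,true·TE)` at OEF = 0. It requires
  |τ| ≤ TE and rejects inputs outside that range.
- *Monoexponential*: `exp(−R2b·TE)·exp(−R2b*·|τ|)` with empirical
  quadratic-in-OEF relations `R2b = 4.5 + 16.4·Hct + (165.2·Hct² +
  55.7)·OEF²` and `R2b* = 10.2 − 1.5·Hct + (136.9·Hct² − 13.9)·OEF²`
  (3 T literature coefficients; configurable).
- *Powder (Fresnel)*: magnitude of `(C(η) − iS(η))/η` with
  `η = √(3δω|τ|/π)`, scaled by `exp(−R2b·TE)`; the global phase factor is
  discarded because magnitude MR data carry no phase. η → 0 is handled by
  its analytic limit 1.

**Constants.** TE 74 ms, TR 3 s, B₀ 3 T, Hct 0.40, Δχ₀ 0.264 ppm
(dimensionless, used exactly as printed with the (4/3)π convention — no
cgs conversion), R2t 11.5 s⁻¹, R2b,true 5.29 s⁻¹, t_D 4.51 ms, γ fixed at
2.675×10⁸ rad s⁻¹ T⁻¹. t_D is taken as the tabulated value rather than
recomputed from cell radius and diffusivity. The blood magnetisation m_b
defaults to the saturation steady state `1 − exp(−TR/T1b)` (T1b = 1.58 s)
because the simulated protocol carries no inversion pulse; with a FLAIR
inversion time set it becomes `1 − 2exp(−TI/T1b) + exp(−TR/T1b)`. The
relative blood spin density n_b defaults to 0.775. All constants live in
one YAML-overridable configuration.

## Simulation design

The generator reproduces the reference synthetic study: 50 linearly spaced
OEF values on [20, 70]% × 50 DBV values on [0.3, 15]% (2500 signals), the
analytic tissue model plus motional-narrowing blood as ground truth, the
24-point τ schedule (−28…+64 ms, 4 ms steps; reduced 11-point alternative
−16…+64 ms, 8 ms steps), and i.i.d. real Gaussian noise with
σ = S(τ=0)/SNR at 7 SNR levels {5, 10, 20, 50, 100, 200, 500} — the
stated endpoints plus log-spaced interior values. One noise realisation
per cell is the default, with a replicate option. Noise is seeded and
regeneration is bit-identical.

What the simulator does **not** emulate: Rician magnitude bias (noise is
signed Gaussian by construction), vessel-size distributions and
diffusion-sensitive extravascular dephasing, partial-volume mixtures with
white matter or CSF, macroscopic field gradients, and the τ = 0 signal
transient seen in vivo. Passing tests therefore demonstrate correct
behaviour of the estimators *under the stated generative model*, not
robustness to those real-data effects.

## Transition-constant calibration

The asymptotic model is phenomenological, so κ = tc·δω is chosen to make
it match the analytic model over the noise-free grid. The default
objective is the mean squared difference of the two *signal* curves
across the τ schedule, averaged over grid cells with equal weights and
minimised by a coarse 0.01-step scan followed by bounded golden-section
refinement (tolerance 1e−4); the scan is needed because the objective is
piecewise smooth with small shelves wherever κ crosses a scheduled
δω·|τ|. A log-signal variant (whose per-cell mismatch factorises as
DBV²×an OEF-only term) and a per-cell-optimise-then-average mode are kept
for comparison; the aggregation and scale are recorded in the result
object. On the default grid the signal-scale objective gives
κ* ≈ 1.710 and the log-scale ≈ 1.703; the per-cell average is markedly
lower (≈1.5). The package default κ = 1.76 is the reference value, and
the calibration lands within 0.05 of it.

## Estimation engines

**Log-linear (L).** OLS of ln S on τ over the scheduled points above the
long-τ threshold; R2′ is the negative slope and DBV the intercept minus
ln S(τ=0). The default threshold is the smallest scheduled τ strictly
above tc evaluated at reference physiology (OEF 40%, Hct 0.40:
tc ≈ 12.4 ms → 16 ms), giving 13 regression points plus the spin echo —
14 data points. Voxels with non-positive selected amplitudes are flagged
and returned as missing. R2′ is invariant to global rescaling of the
signal.

**Non-linear least squares.** Bounded trust-region fits of the 1C/2C
asymptotic models over the full schedule (R2′ ∈ [0, 50] s⁻¹,
DBV ∈ [0, 1], S0 > 0), initialised from the log-linear estimates. Inside
all fitting forward models DBV is clamped to (0, 1] so optimiser
excursions cannot leave the model domain; converged estimates sit
interior in all tests.

**Grid search.** The posterior of (OEF, DBV) or (R2′, DBV) given the 2C
model is evaluated on a uniform grid with known noise σ, flat prior over
the searched region, S0 fixed at its simulation value, and log-space
normalisation. Both searches cover the same physiological box
(OEF ∈ [20, 70]%, DBV ∈ [0.3, 15]%): the R2′ axis spans the image of that
box under R2′ = δω·DBV and nodes whose implied OEF falls outside the
interval carry zero prior mass. The derived OEF estimate is summarised by
first-order propagation of the DBV-marginal uncertainty through the
inverse relation — `sd(OEF) = (mean OEF/mean DBV)·sd(DBV)` — because the
raw node-mapped OEF distribution is heavy-tailed in 1/DBV at the low-DBV
edge and its SD is dominated by physically implausible corner nodes (the
node-mapped version remains available). Under a flat prior the node
ordering by posterior equals the ordering by −SSE, which is tested.

**Variational Bayes.** Observation noise is Gaussian with conjugate Gamma
precision prior (shape 1e−6, scale 1e6 — near-uninformative); the
parameter prior is an independent Gaussian per parameter with the broad
literature values R2′ ~ N(2.6, 10^{3/2}), DBV ~ N(3.6%, 10^{3/2}%), and
the amplitude S0 ~ N(500, 10³) — effectively flat on the simulated scale.
Each iteration linearises the forward model at the current posterior mean
(central differences), updates the Gaussian factor and then the noise
factor in closed form, and evaluates the free energy
`E[ln p(y|θ,φ)] − KL(q(θ)‖p(θ)) − KL(q(φ)‖p(φ))`. A step that would
lower the free energy by more than the tolerance is halved (up to 9
times) before being accepted or the fit stops; on affine models the
update is exact, the free energy is monotone, and the converged posterior
equals the conjugate linear-Gaussian closed form to 1e−6, which is the
engine's oracle test. S0 is initialised from the spin-echo amplitude (the
model is exactly linear in S0, so this affects speed only). Covariance
inverses go through Cholesky with jitter repair.

**Spatial priors.** Voxelwise VB alternates with prior rebuilding over a
fixed number of sweeps (default 10): each voxel's prior mean becomes the
precision-weighted mean of its 6-connected in-mask neighbours' posterior
means, and its prior precision the mean of the neighbour precisions,
per parameter. Isolated voxels keep the global prior; zero sweeps
reproduces the non-spatial fit exactly. This aggregation rule is one
defensible choice among several (the reference implementation's exact
form is not published); it is symmetric, stable, and in tests it shrinks
the across-voxel SD on a homogeneous phantom without moving region means
by more than 5% — provided regions are larger than a few voxels, since
boundary voxels are genuinely smoothed across edges.

## Separability and parameterisation choice

For one signal at OEF 40%, DBV 3%, SNR 50, the (OEF, DBV) posterior is a
collinear ridge (OEF·DBV ≈ const): its OEF marginal is nearly flat over
the box while the DBV marginal has SD ≈ 1%. The (R2′, DBV) posterior is
far better separated and closer to Gaussian, which is why VB fits run in
(R2′, DBV) by default with OEF derived afterwards. The acceptance script
reports the four SD summaries (medians over 50 noise seeds).

## Problem sizes and defaults in the scripted experiments

The experiment drivers default to reduced 10×10 grids (10×16 for the
high-DBV comparison, 3 noise seeds), which preserve the grid-averaged
error structure at a few percent while keeping a full run in the
seconds-to-minutes range; the full 50×50 design is available everywhere
by passing it explicitly (`--full` on the CLI). Error tables use
absolute-then-average aggregation per (engine, model, SNR), skipping
voxels flagged as missing.

## Known limitations

- The high-DBV two-compartment comparison in this implementation shows a
  bias-dominated 2C advantage that emerges only at high SNR (up to ~60%
  error reduction at SNR 500) and is offset by extra estimator variance
  at SNR 20–100, so the SNR-averaged reduction is ≈5% rather than the
  reference ~14–24%; the acceptance script reports the computed values.
- Grid-search summaries depend on the node measure: uniform-in-R2′
  sampling weights the physiological box proportionally to DBV, which
  lowers the node-mean OEF relative to the uniform-in-OEF search.
- The VB free energy is exact only up to the local linearisation; it is
  monotone across accepted steps by construction, not by theorem.
- Noise is treated as voxel-independent and Gaussian; no Rician floor,
  no spatial noise correlation, no R2-weighting differences across τ.
- White-matter signal models, CSF/FLAIR and macroscopic-gradient effects
  are out of scope; masks are consumed, never computed.
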