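# Methods

This note documents the models, parameter choices and numerical
decisions behind `mrst2`, and what the synthetic experiments do and do
not establish.

## Spin physics

Each metabolite moiety is a small spin-½ system (≤ 7 spins; larger
systems must be declared as split moieties, keeping matrices ≤ 128²)
with chemical shifts δᵢ (ppm) and scalar couplings Jᵢⱼ (Hz) from the
standard literature compilation of brain-metabolite NMR parameters
(Govindaraju et al., NMR Biomed 2000); the registry records the source
per entry. Five compounds with distinct singlet/multiplet relaxation
behaviour (NAA, Cr, PCr, PCho, GPC) are split into constituent
moieties; the choline channel (tCho) and creatine channel (tCr) are
re-combined after fitting.

The stimulated-echo sequence is idealised: instantaneous on-resonance
90° pulses, no relaxation inside the sequence (T2 enters downstream as
`exp(−TE/T2)` per compound), no spatial localisation. Crusher-gradient
coherence selection is modelled as hard order masks in the Zeeman
basis: order +1 during the first TE/2, order 0 (populations **and**
zero-quantum coherence) during TM, order −1 afterwards; acquisition
starts at the echo top. Free evolution uses the eigen-decomposition of
the isotropic-J Hamiltonian; the FID is synthesised from the
transition amplitudes, which is exact and fast. Consequences that the
tests pin down:

- an uncoupled spin yields exactly ½ of the one-pulse amplitude at any
  TE and TM;
- a weak-coupling AX doublet has echo-top in-phase amplitude
  `cos²(πJ·TE/2) − ½·sin²(πJ·TE/2)·cos(δ·TM)·(1 − cos(δ·TE/2))`
  (product-operator closed form; δ the shift difference in rad/s), the
  familiar `cos(πJ·TE)` modulation once the zero-quantum term drops;
- a `weak_coupling` flag truncates the J Hamiltonian to IzIz for exact
  comparison against that closed form; production runs use the full
  isotropic coupling (strong-coupling effects matter at 4 T for Glu,
  Gln, mIns).

Spectra are produced by Lorentzian apodisation to the target full
width at half maximum (default 12 Hz, the reported in vivo linewidth)
followed by FFT; the ppm axis is referenced to the water carrier at
4.65 ppm. Internal arrays are ascending in Hz; display order is a
presentation concern left to the caller.

The macromolecule (MM) background is synthesised, not measured: nine
Gaussian humps at the conventional M0.92…M3.75 positions with a single
fast T2 of 25 ms, attached to the basis at every TE except 180 ms,
where its decay (e^−180/25 ≈ 7·10⁻⁴) makes it unobservable. Only its
presence and fast decay matter for fit realism; no claim is made that
it reproduces a measured MM spectrum.

## Synthetic cohorts

Per-subject ground truth is drawn from normals truncated at ±3 SD (and
at 1 ms for T2s, [0, 1] for the CSF fraction), with group parameters
equal to the study conditions listed in the README. Truncation keeps
every generated subject physical while changing group means by well
under 1 %. Compounds that fail quality control in vivo (Glu, Gln,
mIns) still need decay constants to be synthesised realistically;
plausible occipital-lobe values at this field strength are used
(young/elderly Glu 135/122, Gln 125/115, mIns 110/100 ms, SD 12–15 ms)
— these are package choices, not reported results. Concentrations are
typical occipital ratios in arbitrary units (NAA 12, Cr 5, PCr 4.5,
GPC 1.0, PCho 0.6, Glu 9, Gln 3, mIns 6); absolute scale never enters
the T2 analysis (no water scaling).

Noise is i.i.d. complex Gaussian per frequency bin — equivalent to
white time-domain noise under the unitary FFT and easier to calibrate.
The default `noise_sd = 120` (spectral units, for the default
concentration scale) was calibrated once so that the CRLB gate
reproduces the in vivo behaviour: NAA/tCr/tCho pass the 30 % threshold
at all seven TEs for every subject (worst-case CRLBs ≈ 6/11/21 %),
while Glu, Gln and mIns fail for every subject (best-case maxima ≈
33–63 %). The in vivo SNR itself is not reported; this calibration is a
package choice documented here, not a measured value. The four
averages per TE of the original acquisition are emulated only through
this noise level, not by generating shots.

Water is generated directly as a twelve-TE integral series from the
two-compartment model with additive noise of 0.2 % of S0; the
unsuppressed water fit in vivo is far better conditioned than the
metabolite problem, and nothing downstream consumes a water *spectrum*.

Known departures from real data: no frequency drift, phase errors,
eddy currents, lipid contamination or lineshape distortions; noise is
exactly Gaussian and the forward model of the generator is exactly the
model class of the fitters (up to the spline baseline and NNLS
constraints). Passing recovery tests therefore demonstrates
self-consistency and correct implementation of the estimators at a
realistic SNR — not robustness to real-world artefacts.

## Linear-combination fitting

The real part of each spectrum over 0.5–4.2 ppm is fitted as a
non-negative combination of the basis spectra at that TE plus an
unconstrained cubic B-spline baseline. The baseline-stiffness knob
maps to an interior knot spacing of `0.15/stiffness` ppm (default
stiffness 0.25 → 0.6 ppm ≈ 6 interior knots); this is an analog of the
usual spline-flatness parameter, not a replica of any particular
package, and equivalence with LCModel outputs is explicitly not
claimed. Zero-order phase is known by construction (synthetic data),
so no phase/lineshape adaptation is fitted; an optional ±2 Hz grid
search for a global frequency shift exists but is off by default since
the generator introduces no shift errors.

CRLBs use the standard linear-model expression
`100·σ̂·sqrt([(DᵀD)⁻¹]ₘₘ)/aₘ` with σ̂ from the median absolute
deviation of the fit residual; `(DᵀD)⁻¹` is a pseudo-inverse because
the Cr/PCr (Δδ = 0.002 ppm) and PCho/GPC (0.004 ppm) singlet pairs are
nearly collinear at a 12 Hz linewidth. Exactly as with real LCModel
output, the individual members are ill-determined while the combined
tCr/tCho channels — amplitude sums whose variance includes the
(negative) covariance — are tight. Zero amplitudes report CRLB = ∞.

## Relaxometry

Metabolite T2s: unweighted trust-region least squares of
`S0·exp(−TE/T2)`, initialised from the closed-form two-point T2 of the
first and last TE with a restart grid (T2 ∈ {50, 100, 200, 400} ms) on
failure; two points solve the closed form exactly and are flagged.
Failures raise and the subject is excluded from that compound's group
statistics (exclusions are rare and logged). Water: S0, tissue T2 and
CSF fraction are fitted with the CSF T2 *fixed* (default 1500 ms);
fixing it is the minimal model consistent with two free physiological
parameters plus an overall scale, and the 5000 ms TE anchors the CSF
term. Whether S0 is counted as free is a modelling convention; it is
floated here.

At the calibrated noise the per-subject estimator is effectively
unbiased (|bias| ≤ 1.6 %, largest for tCho) with per-subject SDs of
about 4 % (NAA), 6 % (tCr) and 12 % (tCho) — reproducing the in vivo
pattern that tCho is the least precise channel.

## Monte Carlo TE assessment

The bounded-noise recovery simulation adds uniform noise on
`[−b, +b]·S0` (the stated constraint is a *bound*, not a variance, so
the bounded-uniform is the least-assumption reading; a clipped-normal
alternative is config-exposed) to `exp(−TE/T2)` at each scheme's TEs
and refits, 500 iterations per T2. In pipeline use, b is the maximum
fractional T2-fit residual measured per compound and group (≈
0.04–0.10). Scheme comparisons share one noise draw over the union of
TEs per iteration (common random numbers): each scheme's marginal
distribution is untouched, but SD differences between schemes are not
drowned in independent sampling noise at 500 iterations.

## Statistics

Rank-sum p-values come from the Mann-Whitney formulation: exact when
the pooled sample has ≤ 20 observations without ties, otherwise the
normal approximation with midranks, tie correction and continuity
correction. The one-sided alternative is "young stochastically
greater" (shorter T2 in elderly). The ratio is rounded to 2 decimals
and the percent shortening to integer percent, half away from zero —
so generative means 208/161 give 0.77 and 23 %. No multiple-testing
correction is applied (three metabolites plus water at p < 0.05), and
no age or cognition covariates exist in the synthetic world.

## Problem sizes and determinism

The default run is 32 subjects × 7 TEs (6144-point spectra), one
12-point water series each, and 6 × 5 × 500 Monte Carlo fits — about
half a minute on one core; the basis simulation (11 moieties × 7 TEs)
adds ~5 s and is bit-reproducible, so it can be cached and passed into
`run_pipeline`. All randomness flows from one master seed through
`numpy` `SeedSequence` spawning (per-subject, per-stage streams), so
any subject can be regenerated in isolation and a repeated run is
byte-identical, as the pipeline tests assert.

## Limitations

- Single-voxel, single-field-strength idealisation; no T1/TR
  saturation, diffusion or exchange effects.
- The spline baseline and NNLS make the fitted model only *almost* the
  generative model; residual-based σ̂ absorbs the difference.
- Group-mean recovery at n = 18/14 inherits sampling noise of order
  SD/√n (≈ 2–5 % depending on channel); single-seed comparisons
  against the generative means scatter accordingly, which is a
  property of the study size, not of the estimators.
- The in vivo p-values (down to 10⁻⁷) depend on the actual subjects'
  realisations and are not reproduced numerically; the package instead
  demonstrates the detection power of the NAA effect size at these
  group sizes.
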