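# Methods

`cytofccs` quantifies the integrity of fluorescently tagged ligand–receptor
complexes from two complementary optical readouts: two-colour fluorescence
cross-correlation spectroscopy (FCCS), which yields complex concentrations
and equilibrium dissociation constants, and FLIM–FRET, which yields donor
lifetimes, transfer efficiencies and donor–acceptor distances. Because raw
photon data from the original in-vivo experiments are not publicly
deposited, the package ships a first-class synthetic-data generator with
known ground truth, and every estimator is validated end to end against it.
This note records the models, the defaults and the reasoning behind the
numerical choices.

## FCCS model

Each spectral channel observes molecules through an effectively 3D-Gaussian
detection profile W(ρ, z) = exp(−2ρ²/ω² − 2z²/z₀²) with lateral waist ω,
axial extent z₀ and structure parameter S = z₀/ω. Its effective volume is
V_ef = π^{3/2} ω² z₀ (fl, for µm inputs), and the two-channel
cross-correlation probes

    V_cc = π^{3/2} · (ω_g² + ω_r²)/2 · sqrt((z_g² + z_r²)/2),

which reduces to V_ef for identical channels and lies between the two V_ef
when the channels share S. (The corresponding printed equation in the
instrument-workflow literature sometimes shows the geometric factor in a
denominator, which is dimensionally impossible; the product form above
reproduces the canonical worked example — 0.56 fl and 0.75 fl combining to
0.65 fl — exactly, and is the form implemented.)

Autocorrelations are fitted with the standard triplet–diffusion model

    G(τ) = (1/N) (1 + T/(1−T) e^{−τ/τ_tr}) (1+τ/τ_D)^{−1} (1+τ/(S²τ_D))^{−1/2}

and cross-correlations with its diffusion-only form (independent blinking
of the two fluorophores cancels in the cross-correlation). N is the mean
(co-)diffusing molecule number in the effective volume; τ_D = ω²/4D.

From the three fitted amplitudes the concentrations and the dissociation
constant follow the amplitude-reciprocal reading of N_cc (= 1/G_cc(0)):

    C_green = N1/(V_ef,g N_A)        C_red = N2/(V_ef,r N_A)
    C_cc    = (N1·N2/N_cc) / (V_cc N_A)
    K_d     = (C_green − C_cc)(C_red − C_cc) / C_cc

Only under the amplitude-reciprocal reading is N1·N2/N_cc the bound-complex
count, making C_cc a concentration; this is the reading implemented.
Measurements with either channel above 2,000 nM (strict inequality;
configurable to require both channels) are excluded as over-expressing, but
retained with an audit flag. When the fitted cross-amplitude 1/N_cc falls
below 3× the per-lag standard error of the cross-correlation over its first
octave of lags (or the cross fit fails), the noise floor itself is converted
to a concentration and K_d is reported as a lower bound — reproducing the
"K_d > value" convention for non-interacting pairs — and such records are
never averaged together with point estimates.

## Correlator

The software correlator implements the multi-tau scheme: 16 linearly spaced
lags per octave, pairwise rebinning per further octave, symmetric
normalization with per-level, per-lag mean re-estimation (suppresses drift
bias). Lag zero is excluded (shot-noise dominated); the shortest lag is one
bin. Cross-correlations average the two lag directions,
G ← (G_gr + G_rg)/2 — neither channel is distinguished in a
cross-correlation, so the symmetrized form is the natural estimator, is
exactly invariant under relabelling the channels, and has slightly lower
variance. Per-lag standard errors come from splitting the trace into 10
segments and taking the standard error of the per-segment curves —
model-free, at the cost of neglecting correlations between lags. The level-0 estimator is
algebraically identical to the direct (brute-force) estimator, which the
tests exploit as an oracle.

## Fitting

Correlation curves are fitted by weighted least squares (weights 1/σ²,
falling back to unweighted), multi-start (a data-driven initial guess plus
deterministic log-normal perturbations, lowest χ² kept, ties broken by the
smaller τ_D). The triplet relaxation time is bounded to [1, 50] µs and
required to stay below τ_D/5 whenever the fitted triplet fraction is
material, preventing the triplet and diffusion terms from swapping roles;
if no start satisfies the constraint the triplet term is dropped and the
fit repeated — the legitimate resolution when blinking is unidentifiable at
the trace's binning. Sample-measurement fits are restricted to lags up to
30 ms by default: the amplitudes that carry the concentration information
live in the early curve, while the slow tail contributes correlated noise
that the segment-based per-lag errors understate and would otherwise pull
the fitted cross-amplitude down by a few percent. Decay histograms are fitted by Poisson maximum
likelihood (correct at low counts per bin, where least squares is biased)
of an exponential mixture convolved with a Gaussian instrument response,
over log-amplitudes, log-lifetimes and a zero-time shift.

## Calibration

Reference dyes of known diffusion coefficient (400 µm²/s) at two known
dilutions per channel (3/6 nM green, 4/8 nM red) pin the geometry down in
two complementary ways, and the calibration uses each where it is robust:
the waist from the fitted early-lag diffusion time (ω = sqrt(4Dτ_D), fitted
over lags ≤ 300 µs), and the effective volume from the fitted amplitude at
the known concentration (V_ef = N/(C·N_A), averaged over dilutions). The
axial extent and S follow as z₀ = V_ef/(π^{3/2}ω²), S = z₀/ω, and τ_D is
re-fitted once with S held at the derived value. The alternative — fitting
S from the shallow axial tail of the curve — is statistically fragile and,
in the simulated validation data, additionally corrupted by the finite
periodic box (below). Dilutions whose fitted diffusion times disagree by
more than 20% (relative spread; configurable, and wider in toy-scale demo
configurations whose short recordings scatter more) reject the
calibration; the per-dilution N/(C·V_ef·N_A) consistency ratios are
recorded for audit. The fitted S is
then held fixed in all sample fits, matching the convention that sample
measurements share the calibration settings.

Two practicalities of reference-dye work are built in: the dye's triplet
relaxation time is treated as known (datasheet photophysics) and held
fixed in the calibration fits, decoupling it from τ_D; and when the
dilution-consistency gate rejects a calibration, the pipeline re-acquires
a fresh dilution series (up to three attempts) before giving up — exactly
what one does at the instrument.

## Synthetic-data generator

The generator produces every input with known truth:

* **Equilibrium mixtures.** Free green, free red and bound complex at
  mass-action equilibrium; the complex is the physical root of
  C² − (G_t+R_t+K_d)C + G_tR_t = 0. K_d = 0 and K_d = ∞ give the
  infinite-affinity and no-binding limits.
* **Photon traces.** Brownian dynamics in a periodic cubic box (side 10×
  the largest waist by default): per species, particles are placed at
  concentration × box volume (Poisson-drawn by default, emulating
  cell-to-cell expression variability; exactly rounded for reference-dye
  reservoirs), moved by isotropic Gaussian steps with r.m.s. displacement
  per axis kept at or below ω/10 by automatic sub-stepping, and detected
  through the two channel profiles with peak molecular brightness ε
  (counts/molecule/s). The mean count rate per channel is therefore
  C·N_A·ε·∫W = C·N_A·ε·V_ef/2^{3/2}, reduced by the bright-state fraction
  and by the erf-truncation of W at the box boundary. Triplet blinking is
  an exact two-state telegraph propagator per fluorophore (stationary dark
  fraction T, relaxation time τ_tr); complexes carry one fluorophore of
  each colour, blinking independently, and emit the summed brightness.
  Per-bin photon counts are Poisson draws around the accumulated
  expectation. All randomness derives from one seed via a counter-based
  fan-out (`spawn_seed`), so every trace is bit-reproducible in isolation.
* **TCSPC decays.** Exponential-mixture arrival times plus Gaussian IRF
  jitter, histogrammed on [0, 25) ns at 0.05 ns by default.
* **Cell grids.** Clone cells plus neighbours at breadth-first (4-adjacent)
  graph distance, with per-row activation probabilities realised as
  nuclear/cytoplasmic reporter ratios on the appropriate side of the call
  threshold.

### Defaults and what they represent

| parameter | default | rationale |
|---|---|---|
| recording time | 10 s | standard per-measurement acquisition |
| detection waists ω_g, ω_r | 0.20, 0.22 µm | high-NA confocal |
| structure parameter S | 3 | tight pinhole; keeps the axial profile well inside the box |
| box side | 10 × max ω (16 × for dye calibration) | open-reservoir approximation |
| sample bin width | 250 µs | resolves τ_D (≈ 12–20 ms) with sub-stepping at the ω/10 bound |
| dye bin width / duration | 1 µs / 3 s | resolves the 25–30 µs dye diffusion time; ample statistics |
| free-species diffusion | 0.8 µm²/s | membrane-tethered ligand/receptor |
| complex diffusion | 0.5 µm²/s | bound complex, slower than either partner |
| brightness ε | 30 kHz (samples), 60 kHz (dyes) | typical confocal count yields |
| triplet T, τ_tr | 0.15, 5 µs (samples); 0.10, 3 µs (dyes) | common fluorophore photophysics |
| totals per channel | 300 nM | within the expression range used for affinity measurements |

The defaults are study conditions, not tuning knobs: recovery accuracy is
assessed under them.

### What the generator does and does not emulate

It emulates dilute 3D diffusion with blinking, two-colour co-diffusion of
complexes, photon shot noise, expression variability between measurements,
and the quenched/unquenched donor populations of lifetime imaging. It does
**not** emulate spectral cross-talk, background, afterpulsing (each is off
by default and the analysis applies no such corrections, matching the
uncorrected K_d convention), photobleaching, membrane (2D) geometry,
cytoneme geometry, vesicular transport, or optical details beyond the 3D
Gaussian profile (polarization, pinhole diffraction). Passing recovery
tests therefore demonstrates the correctness of the estimator chain under
these idealised conditions, not robustness to every instrumental artefact
of real recordings.

### Finite-box effects

A periodic box is an imperfect reservoir: correlation decays at lags beyond
roughly (L/2π)²/D follow the box's slowest diffusion mode rather than the
infinite-space algebraic tail, and the detection integrals are
erf-truncated at the boundary. Three design choices keep this harmless:
S = 3 keeps the axial profile well inside the box; the dye calibration
avoids tail-fitting entirely (amplitude-based V_ef, early-lag τ_D, and a
16× box for its fast dye); sample fits fix S and draw their information
from amplitudes and the early decay, with segment-based σ down-weighting
the distorted tail. Residual truncation effects largely cancel between
calibration and sample measurements because both share one optical
geometry.

## FLIM–FRET

The unquenched donor lifetime τ_D is the mean of the donor-only fitted
lifetimes. Per region of interest, the fitted (amplitude-weighted, by
default; intensity-weighted available) lifetime τ_DA gives

    E = 1 − τ_DA/τ_D      r = R0 · ((1−E)/E)^{1/6},  R0 = 52.4 Å

with E clipped to [0, 1] (flagged when clipping occurs) and r marked "not
detectable" (NaN) at E ∈ {0, 1}. E = 0.5 returns exactly R0. Fits below
1,000 photons are flagged low-signal rather than dropped. Published
efficiency/distance pairs from vendor FLIM software are not always mutually
consistent with the bare Förster relation (per-pixel weighting schemes are
proprietary); this package implements the bare relation and treats it as
the definition.

## Morphometrics

Protrusions count as filopodia at length ≥ 1 µm and width ≥ 1 µm (boundary
inclusive; a "long-and-thin" alternative reading, length ≥ 1 µm and width
≤ 1 µm, is selectable). Circularity is 4π·area/perimeter², validated
against the isoperimetric inequality. KTR activity is nuclear/cytoplasmic
ratio < 1 (nuclear exclusion = active; threshold configurable, since the
original call is a binary visual one). Paracrine profiles count cell rows
(graph distance), not micrometres, and analyse five rows by default. Length
and K_d histogram bin edges are configuration with documented, arbitrary
defaults.

## Problem sizes

Validation workloads are sized so the full suite runs on one CPU in tens of
minutes while retaining statistical power: headline K_d recovery uses ≥ 20
ten-second recordings per condition against a 3-s-per-dilution dye
calibration; the K_d sweep across {100, 500, 2000} nM uses 20 seeds of 3-s
recordings (8 s for the 2000 nM condition, which otherwise sits at the
cross-correlation detection floor where the lower-bound rule censors the
sample); unit-level recovery tests use sub-second recordings of fast
(D = 50–400 µm²/s) species. Tolerances on scaled-down checks are widened in
proportion to the per-trace statistical scatter at the reduced length, and
say so where they are.

## Known limitations

* K_d point estimates carry a small positive bias (≈ +5% at the defaults)
  because K_d is convex in the noisy fitted amplitudes; it shrinks with
  recording length and repeat count.
* Near and above ~2,000 nM true K_d at a few hundred nM expression, the
  cross-amplitude approaches its noise floor; the lower-bound rule then
  censors weak-binding measurements and the surviving point estimates are
  selection-biased low. This mirrors the real detection limit of the
  technique.
* Segment-based σ ignores inter-lag correlations, so χ² values are
  indicative, not calibrated p-values.
* The simulation volume is 3D; membrane-confined (2D) diffusion alters
  correlation shapes and is out of scope.
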