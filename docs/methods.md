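# Methods

This note documents the models behind each `parabind` module, the defaults
and why they were chosen, what the synthetic generators do and do not
emulate, and the numerical decisions that matter when interpreting output.

## Study system and synthetic conditions

The package targets the promoter-autoregulation chemistry of type Ia
plasmid partition systems: a ParA ATPase whose N-terminal winged-HTH (wHTH)
binds hexamer motifs in the *parAB* promoter. The synthetic defaults
encode the F-plasmid configuration:

- **Promoter** (`default_f_architecture`): three exact CTTTGC hexamers in
  direct orientation separated by 13-bp gaps (#1, #2, #3), a degenerate
  inverted half-site #2′ (read tcTTGC on the minus strand, two mismatches)
  spaced 27 bp downstream of #2, and a perfect inverted #4 spaced 28 bp
  downstream of #3. Motifs #3/#4 therefore form a perfect inverted repeat
  (IR) with centers 34 bp apart; #2/#2′ form a degenerate IR overlapping
  it. Flanks are sized so the fragment is 136 bp, the length of the SPR
  probe. The background is i.i.d. with 73% AT (the promoter's measured
  composition); it deliberately has **no** dinucleotide structure, so
  A-tract bending exists only as a geometry-module parameter, not in the
  sequence model.
- **SPR scenario**: three dimers bound at saturation on the 136-bp probe at
  300 RU immobilized, giving a true saturation response
  `Rmax = 3·2·(44000/89760)·300 ≈ 882.4 RU` via the mass proportionality of
  the SPR signal. True rates are k_a = 1×10⁴ M⁻¹s⁻¹, k_d = 1×10⁻³ s⁻¹
  (K_D = 100 nM, the order of magnitude the titrations indicate; no
  reference rate constants exist for this interaction, so only
  self-consistency — generator vs fitter — is testable). The injection
  series spans 0.05–4.5 µM with 180 s association and dissociation phases.
  Noise is 2 RU i.i.d. Gaussian, a typical Biacore-scale residual; the
  true noise level of the original measurements is unknown, so it is an
  explicit free parameter.
- **Mass conventions**: duplex DNA at 660 Da/bp and a 44 kDa ParA monomer.
  Both are configurable; the stoichiometry analysis is self-consistent
  under any value because generator and estimator share the convention.
- **Titration scenarios**: the gel-shift (EMSA) default is a Hill isotherm
  with K_D = 85 nM and h = 3 on a 15 nM probe — the Hill coefficient is an
  assumption standing in for a qualitatively "sharp" cooperative
  transition, as no measured h exists. The thermophoresis (MST) default is
  a non-cooperative (h = 1) isotherm with K_D = 140 nM on a 25 nM probe
  over 3.6 nM–60 µM. The ParB-stimulated scenario uses the quadratic
  ligand-depletion law with K_D = 10 nM against the 15 nM probe, where the
  non-depleting approximation breaks down. Fraction-bound noise is 0.02,
  clipped into [0, 1].
- **Melt scenarios**: two-state van't Hoff unfolding with ΔH = 300 kJ/mol
  (a typical small-domain enthalpy) at condition-specific midpoints
  (apo 44.5 °C, +DNA 45.1 °C, +ADP 46.1 °C, +DNA+ADP 45.8 °C), linear
  folded/unfolded ratio baselines, and a 25–65 °C grid at 0.1 °C.
- **Trajectory scenario**: 120 CA pseudo-residues on a deterministic coarse
  helix, isotropic per-residue Gaussian fluctuation with σ = 0.5 Å/axis in
  the core and 2.0 Å/axis inside the loop interval (residues 40–100,
  emulating a flexible wHTH insertion), optionally a marker residue (75)
  drifting linearly by 30 Å between first and last frame — a constructed
  stand-in for a large wing-tip excursion.

All generators draw from `numpy.random.default_rng(seed)` with explicit
integer seeds; equal scenario + seed is bit-reproducible. The promoter
builder additionally resamples its background (bounded, seeded attempts)
until no exact consensus match exists outside the truth table, so
exact-hit counts reflect the designed architecture for every seed;
near-matches (1–2 mismatches) in the background are allowed and expected.

What the generators do **not** emulate: instrument drift and bulk
refractive-index jumps in SPR, mass-transport limitation, aggregation at
high protein concentration, sequence-dependent DNA mechanics, and actual
force-field dynamics. Passing tests therefore demonstrate correctness of
the estimators under the stated statistical model, not robustness to every
artifact of real data.

## Motif and IR analysis

Coordinates are 0-based, half-open, on the plus strand. A minus-strand hit
at `start` means the reverse complement of the window `[start, start+6)`
matches the consensus when read 5′→3′ on the minus strand. Matching is
case-insensitive; ambiguity codes never match. The scanner is exhaustive
(every window × strand within the Hamming tolerance) — no log-odds
scoring, by design.

IR pairing takes every (plus hit, downstream minus hit) combination with
spacer `right.start − left.end` inside the window, default [26, 29] bp
(the observed spacer range across related partition promoters; [25, 30] is
a supported widening). Degenerate pairs are accepted only with ≤2 total
mismatches and at least one perfect half-site, the configuration of the
degenerate IR in the F promoter. The motif "center" distance is defined as
`spacer + motif_length`, i.e. the start-coordinate difference — integer bp
arithmetic, consistent with the 28-bp spacer ↔ 34-bp center distance of
the perfect IR.

The architecture report flags promoters whose first paired motif sits
closer than 40 bp to the 5′ end: an IR nucleates a three-dimer assembly
only when enough upstream DNA is available, and 40 bp is a heuristic
derived from the ~85-bp minimal footprint minus the IR's own extent.

Information content is IC_j = 2 + Σ_b p log₂ p bits with 0·log 0 ≡ 0 and
no small-sample correction by default (motif sets as small as n = 3 are
logo-analyzed; the uncorrected IC is what stacked logos display). The
Schneider e_n correction is available behind a flag.

## Binding inference

The 1:1 Langmuir sensorgram model is solved in closed form per phase
(association saturating to R_eq = Rmax·k_aC/(k_aC + k_d) at rate
k_obs = k_aC + k_d; pure exponential dissociation), continuous at the
phase boundary — no ODE integration, hence no solver tolerance. Mass
transport and refractive-index artifacts are intentionally outside the
model.

`fit_kinetics` defaults to **local** analysis: each concentration is fit
independently (log-parameterized least squares, a fixed-order 3×3×3
log-spaced multi-start grid screened by SSE with the best three starts
refined), and the per-curve parameters are aggregated by the median. This
mirrors per-curve SPR analysis and is robust to curves that individually
constrain parameters poorly; a global shared-parameter refinement is
available (`mode="global"`). K_D ≡ k_d/k_a is a derived identity, exact by
construction. All-zero input raises instead of returning junk.

The stoichiometry statistic S = Rmax/[(MW_A/MW_L)·R_L] counts analyte
monomers per immobilized DNA; S/2 is the dimer count. It is linear in
Rmax and invariant to common rescaling of the two molecular weights.

`fit_hill` reports the EC50 of the Hill curve as the apparent K_D — a
titration midpoint, not a microscopic constant — with bounds h ∈ [0.5, 6]
and K_D ∈ (0, 10·max P]. `fit_depletion` fits the single K_D of the
quadratic tight-binding law at known probe concentration. Both use fixed
multi-start grids, so fits are deterministic. Parameter uncertainties are
asymptotic standard errors from the Jacobian at the optimum.

## DNA geometry

The curved-DNA layer is an analytic planar circular arc: rise 0.34 nm/bp,
contour L = Δbp·rise, total turn θ = Δbp·bend, chord 2(L/θ)sin(θ/2)
(computed via `sinc` for numerical stability near zero bend). The
curvature convention counts one bend step per base pair — 3°/bp over
40 bp gives 120° — matching how per-nucleotide bends are specified in DNA
model building; the strict N−1 steps convention is available
(`convention="per-step"`, 117° for the same input). A per-bp polyline
construction is provided as an independent cross-check of the closed form
(they agree to <0.01 nm at physiological bends).

Helical-face offset is the center separation modulo 10.5 bp/turn mapped to
[0, 180]°, with a qualitative "same face" threshold of 90°: 34 bp ≈ 3.24
turns ≈ 86° offset, i.e. nearly the same face. The bend scan evaluates the
chord over a 0–5°/bp grid (0.25° steps) against the 10–11 nm wHTH span
window and reports all feasible bends plus the one closest to the span
midpoint; an empty feasible set is a result, not an error. All bend is in
a single plane — helically phased roll, all-atom model building and
docking are out of scope.

## Flexibility analytics

Superposition is weighted Kabsch with the proper-rotation constraint
(det = +1); mirror solutions are never returned, and coincident or
collinear point sets raise. The RMSD time series superposes every frame
onto the first (deviation from the starting structure). Fluctuations use
the standard B-factor construction: frames are superposed onto an
iteratively refined mean structure (two mass-weighted passes), then the
superposition weights are refined once to mass/⟨Δr²⟩ — a
variance-weighted, maximum-likelihood-flavored fit. Without that
refinement a mobile region covering half the chain drags the rigid-body
fit and inflates the apparent core fluctuation by ~8%; with it, per-region
σ² is recovered within 5% at 2000 frames. Per-residue values are
mass-weighted averages over the residue's atoms (identity for CA-only
input), and B = (8π²/3)⟨Δr²⟩ exactly.

Flexible-region calling defaults to `rule="auto"`: residues with
B > mean + 2·SD are flagged and merged across gaps of ≤2 residues. The
outlier rule assumes flexible residues are a minority; when roughly half
the chain is mobile the global SD is inflated and nothing is flagged, so
`auto` falls back to an exact two-class (Otsu) threshold when the profile
is strongly bimodal (90th percentile > 4× the 10th). Both rules are also
selectable explicitly. Marker displacement superposes the final frame
onto the first using a caller-supplied stable core and reports the
Euclidean marker shift; note that on single frames the measurement
carries the frame noise (σ = 2 Å/axis in the loop gives ~3 Å scatter on a
30 Å excursion).

Running dynamics is out of scope: trajectories come from the generator or
from multi-model CA PDB / long CSV files. Only the CSV format round-trips
per-residue masses; the PDB reader assigns element masses.

## Thermal stability

The forward model is two-state van't Hoff unfolding,
f_u(T) = 1/(1 + exp[(ΔH/R)(1/T − 1/Tm)]) in kelvin, mixed between linear
folded/unfolded baselines of the 350/330 nm fluorescence ratio (the
standard label-free DSF interpretation; the ratio rises as tryptophans
become solvent-exposed).

`extract_tm` smooths the ratio with a quadratic Savitzky–Golay filter
(default window 1.5 °C), differentiates, and locates the extremum of the
Jacobian-corrected score T_K²·|dρ/dT| ≡ |dρ/d(1/T)|, refined by parabolic
interpolation. The correction matters: the raw dT-derivative peak of a
van't Hoff transition sits **below** Tm by ≈ 4/(a²·Tm) with
a = (ΔH/R)/Tm² — in practice ~0.1 °C at 300 kJ/mol and ~0.9 °C at
100 kJ/mol; the corrected score peaks exactly at Tm for constant
baselines. Residual bias from
*sloping* baselines remains for very broad transitions (≤0.3 °C at
100 kJ/mol with the default slopes; <0.05 °C at 300 kJ/mol) — an
estimator limitation of any derivative-peak method, documented rather
than hidden. The peak search always uses the 350/330 orientation
internally because the reciprocal ratio carries an extra 1/ρ² Jacobian
that would displace its derivative peak by ~0.7 °C; the convention flag
only flips the reported derivative curve and extremum sign.

A transition is accepted only when the score extremum is interior to the
grid and the derivative's range exceeds a noise floor estimated from the
smoothing residuals and propagated through the differentiation filter
coefficients; flat or purely sloping curves raise a "no transition"
error. ΔTm is the plain arithmetic difference b − a (reported as, e.g.,
+1.6 °C for the ADP condition against apo).

## Pipeline

`run_pipeline` executes motifs → SPR → isotherms → geometry → flexibility
→ thermal, deriving one independent substream seed per stage from the
global seed keyed by stage name (CRC32 XOR multiplicative hash, <2³¹), so
adding or removing a stage never reshuffles the others. The geometry
stage consumes the perfect-IR center distance detected by the motif stage
when available. Reports are deterministic JSON (config SHA-256 prefix,
seed, package version); every written file is re-readable by the
corresponding module reader. Config files are JSON with strict schema
checking (unknown keys are named in the error) and unit-suffixed strings
("85 nM") normalized on load. Exit codes: 0 success, 2 config error, 3
stage error.

## Problem sizes used in the test suite

The default suite exercises: 2000-frame trajectories for the 5% Gaussian
recovery properties (120 residues), 400 frames for region calling, 100
seeded replicates for the Hill-K_D recovery distribution and 10 for the
SPR stoichiometry replicates, 200 random sequences (≤200 bp) against the
brute-force scanner oracle, and 50 random 10-atom pairs against the
quaternion-search superposition oracle. These sizes make the statistical
assertions stable at the stated tolerances while keeping the suite fast.

## Known limitations

- The Hill coefficient of the cooperative titration is an assumed 3; only
  K_D recovery, not h, is checked against external values.
- No reference kinetic constants exist for the SPR layer, so k_a/k_d are
  validated by self-consistency (noiseless round trips recover the
  generator truth to <0.1%).
- The planar-arc geometry reduces DNA bending to a single uniform
  curvature parameter; it answers a feasibility question (can a dimer
  span both half-sites?), not a structure-prediction one.
- Derivative-peak Tm extraction inherits an O(width²) sensitivity to
  multiplicative baseline tilt (see above).
- The i.i.d. promoter background has the correct AT content but no
  A-tract or dinucleotide statistics; motif-architecture conclusions on
  real promoters should use real sequences via the FASTA readers.
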