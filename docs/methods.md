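# Methods

`foldsense` packages the computational workflow used to study how a point
mutation in the calmodulin-binding helix of a potassium channel's calcium
responsive domain (CRD) disrupts folding during translation: spectral FRET
quantification in cells, arrest-peptide force-profile analysis in bacteria,
and a conformational two-state free-energy analysis of the mutated side
chain.  Every stage can be exercised end-to-end on synthetic data with known
ground truth, generated in-package.

## Spectral FRET

**Forward model.** A spectral confocal detector records 32 contiguous 5-nm
emission bands covering 450–610 nm.  For a sample with donor abundance *d*,
acceptor abundance *a* and FRET efficiency *E*, the expected signal in band
*b* is

    S_b = d·X_D(λ_L)·Q_D·(1−E)·B_D(b) + [d·X_D(λ_L)·Q_A·E + a·X_A(λ_L)·Q_A]·B_A(b)

where X are excitation shapes at the laser line λ_L, Q quantum yields, and
B(b) the band-integrated emission shapes.  The second bracket contains the
sensitized acceptor emission plus the direct (cross-excitation) acceptor
term, which is configurable and on by default — whether the original
instrument corrected for it is not documented, and with the blue lasers and
red-shifted acceptors used here the term is numerically negligible anyway.

**Unmixing.** Measured stacks are decomposed per sample into non-negative
contributions of donor and acceptor reference emission shapes (as recorded
from cells expressing one fluorophore alone) by non-negative least squares —
the standard open equivalent of the vendor unmixing software.  References
are normalized to unit sum over the detection bands; a condition-number
guard (limit 1e6) rejects near-collinear reference pairs.

**FRET index and efficiency.** The integral FRET index is the ratio of
unmixed acceptor to donor emission integrals (with unit-sum references, the
coefficient ratio).  The peak-ratio variant divides mean intensities over
two half-open wavelength bands [lo, hi) — half-open so band membership on a
5-nm grid is unambiguous.  Efficiency follows from a transfer function

    E(x) = a + b·x/(x + c),   c > 0,

which is strictly increasing for b > 0 and analytically invertible,
x = c(E−a)/(a+b−E).  Two calibrated presets are built in: the living-cell
mCFP/mCitrine function (a, b, c) = (0.001, 1.0022, 2.11) and the bacterial
mTFP1/mcpVenus function (−0.9279, 1.9335, 0.6821).  Clamping of E to [0, 1]
is off by default so the bacterial preset's negative intercept stays
visible; a flag records clamping when requested.  Samples are gated on an
expression window (both the FRET-laser and acceptor-laser summaries within
20–170 a.u.); the window boundaries are taken as inclusive, a convention
this package fixes explicitly because "between" is ambiguous.

**Calibration.** `forster.derive_transfer_function` regenerates such a
transfer function for any pair: noiseless stacks are forward-simulated on a
grid of true efficiencies (default 0 to 0.95 in steps of 0.05, 1:1
donor:acceptor stoichiometry), unmixed, indexed, and fitted by unweighted
least squares initialized at (0, 1, median x).  In the no-cross-excitation
limit the exact relation is E = x/(x + c*) with
c* = Q_A·B_A/(Q_D·B_D), which the fit recovers to ~1e-3; fits report R² and
warn below 0.99.  The printed preset parameters are kept as presets rather
than fit targets because the exact detection-band weighting and background
treatment behind them are not documented; the fitted functions are validated
by functional form and by round-trip recovery (|E_est − E_true| < 0.02 over
E ∈ {0, …, 0.9} at zero noise).

**Förster theory.** The overlap integral J = ∫ f_D(λ) ε_A(λ) λ⁴ dλ uses the
unit-area donor emission and the acceptor excitation shape scaled to its
peak extinction, by trapezoidal quadrature after linear resampling to the
finer grid; units are M⁻¹cm⁻¹nm⁴ with the matching Förster-radius prefactor
R₀(Å) = 0.211·(κ² n⁻⁴ Q_D J)^(1/6).  Defaults κ² = 2/3 and n = 1.4 follow
the most common convention of public R₀ calculators.  E(r) = 1/(1+(r/R₀)⁶).

## Synthetic data

Fluorophore spectra are Gaussians in wavelength — simple, and sufficient for
every property the pipeline tests; real spectra can be supplied as CSV.
The built-in stand-ins carry the literature quantum yields (mCFP 0.41,
mCitrine 0.74, mTFP1 0.85, mcpVenus 0.64).  The wavelength grid is the
450–610 nm detection lattice at 5 nm, extended on-lattice when an excitation
peak falls outside it.  What the generator does **not** emulate: real
fluorophore spectra are asymmetric with vibronic shoulders, detectors have
wavelength-dependent sensitivity, and cellular backgrounds are structured —
so passing tests demonstrate correctness of the estimators under the stated
model, not instrument-grade calibration.  Detector noise statistics are not
documented for the original instrument; both Gaussian and Poisson options
are provided without asserting either is faithful.

## Side-chain conformation analysis

**Angle observable.** The analysis needs an inclination angle θ between the
helix axis and the side chain; no operational definition exists in the
literature this emulates, so one is fixed here: the helix axis is the
leading principal component of the Cα cloud (sign toward the C-terminus),
and the side-chain tip is the centroid of terminal heavy atoms — the
six-membered-ring centroid for tryptophan, the guanidinium carbon for
arginine, a configurable atom list otherwise.  θ ∈ [0°, 180°] is an
inclination, not a dihedral, so the Langevin sampler uses reflecting
boundaries at 0° and 180°.

**Two-state landscape.** The native-like (N) and tilted (T) orientations are
modelled as a quartic double well parameterized directly by the two minima
(defaults 100° and 40°), the well-depth difference, and the barrier height
above the shallower well; this reproduces the two-minima picture without
claiming the true landscape's shape.  The quartic is solved in a shifted
coordinate where the barrier heights have closed forms, avoiding
cancellation.  Presets: the WT-like landscape has a deep N well (barrier out
of N ≈ 6.5 kcal/mol ≈ 11 kT at 298 K, so no N→T transitions occur on
accessible trajectory lengths) and the mutant-like landscape favors T by
0.7 kcal/mol with a ~2 kT barrier, so both states are visited with T
dominating.

**Sampling.** Overdamped Langevin dynamics,
θ ← θ − U′(θ)·Δt/γ + √(2·kT·Δt/γ)·ξ, with kT = 0.5925 kcal/mol (298 K) and
mandatory explicit seeds (no global RNG state).  A precondition rejects Δt
whose deterministic drift at the barrier exceeds 5°/step, and a runtime
check aborts on steps above 30°.  This 1-D sampler is a deliberate stand-in
for all-atom molecular dynamics: it reproduces equilibrium populations of
the input landscape, not kinetics or coupling to other degrees of freedom.

**PMFs.** Direct Boltzmann inversion F(θ) = −kT·ln p(θ), min-shifted, with
never-visited bins reported as undefined (NaN) rather than zero — the
corresponding free energy is effectively infinite.  Umbrella windows add a
harmonic bias ½k(θ−c)²; the weighted histogram analysis method (WHAM)
iterates the window free energies to self-consistency (tolerance 1e-7
kcal/mol, max 1e5 iterations) and warns when adjacent windows share <1%
histogram mass.  A single unbiased window degenerates exactly to Boltzmann
inversion, which the tests assert to 1e-10.  Choosing umbrella spring
constants matters: springs much softer than the landscape's curvature let
windows slide into the wells and leave the barrier unsampled (k ≈ 0.05
kcal/mol/deg² with ~7.5° spacing works for the preset landscapes).

**State classification.** Auto mode smooths the angle histogram, takes the
two highest modes and splits at the intervening minimum; explicit boundaries
are supported, and populations are computed from integer frame counts so
relabeling swaps them exactly.  No numeric N/T windows are fixed a priori
because the orientation angles shift with the binding partner present.

**Interaction energies.** Pairwise Lennard-Jones plus Coulomb
(332.0636·q_iq_j/(D·r)) between two disjoint selections, Lorentz–Berthelot
style combining (geometric-mean ε, r_min as the sum of half-radii), plain
distance cutoff at 12 Å.  Particle-mesh Ewald is intentionally replaced by
the cutoff: the toy systems are small and non-periodic.  Atoms closer than
0.1 Å are rejected as overlapping input.

**Ensemble Metropolis ΔΔG.** The binding analysis follows an ensemble
protocol: 50 independent runs per variant, each a chain of 50,000
single-coordinate perturbation moves accepted by the Metropolis criterion at
a dimensionless score temperature kT_mc = 1.2 (a Rosetta-style setting
applied to the toy score, not 1.2× thermal kT); snapshots every n_moves/10
(10 per run); per-run ΔG is the snapshot mean of E_complex − E_separated;
ΔΔG = mean(ΔG_mutant) − mean(ΔG_WT), so positive values mean the wild type
binds more strongly.  True backrub moves rigidly rotate backbone segments;
here they are approximated by independent harmonic perturbation coordinates,
which preserves the accept/reject protocol under test without an
internal-coordinate engine.  The toy energy is the intrinsic double well
plus a state-dependent interaction term; the default interaction magnitudes
(−20/−10 for WT N/T, −76/−16 for the mutant) are configuration constants
chosen to reproduce the qualitative ordering — N more binding-compatible
than T, and the mutant's bound N state more favorable than the WT's — not
reproducible physical values.  Both variants consume identical per-run
random streams derived from the seed, so identical models give ΔΔG = 0
exactly.

## Force-profile analysis

A stalled construct yields a truncated product carrying only the N-terminal
donor (mTFP1); full-length product carries the C-terminal acceptor
(mcpVenus) too, so the acceptor/donor peak-emission ratio reads out the
full-length fraction.  Profiles aggregate replicates per tether length
(mean ± sample sd; a single replicate's sd is reported as unavailable, never
zero — sd, not SEM, because the sd feeds the peak rule).  Tether lengths
count residues from the arrest peptide's C-terminal conserved proline with
the 17 AP residues included; the construct table stores this post-proline
count directly to avoid bookkeeping ambiguity.  The default library is
{18, 22, 24, 27, 34, 40, 50}.

**Peak rule.** Published force profiles report "peak" vs "no resolvable
peak" qualitatively; this package fixes an explicit rule: the unique maximum
(interior or boundary) is a peak when it exceeds each neighbor by at least
k times the quadrature-pooled replicate sd of the two points (default k = 2);
tied maxima or failed comparisons return "no peak".  The pooled sd is used
because it is the standard deviation of the difference being tested.  Under
the default WT scenario (onset 20, peak 22, decay 0.4/residue, amplitude
0.8, baseline 0.1, noise sd 0.05, 3 replicates) the rule recovers the true
peak in ≥95% of noisy realizations and returns "no peak" for the
partner-free scenario in ≥95%.  The mutant-like scenario is a low-amplitude
plateau (no decay beyond its shoulder), which the rule correctly declines to
call even noiselessly.

Solubility is quantified as SN/(SN+P) from supernatant and pellet gel-band
intensities; band segmentation is out of scope (intensities are inputs).

## Pipeline and reproducibility

One global seed fans out to per-stage seeds via
SeedSequence([seed, crc32(stage_name)]) mod 2³¹, so stages are independent
yet fully reproducible; the demo's JSON summary is byte-identical across
runs with one seed.  Default demo sizes — 50 cells × 10 efficiencies,
5×10⁵-step trajectories, 22 umbrella windows × 2×10⁴ steps, 10 ΔΔG runs ×
5×10³ moves — were chosen so the complete demo finishes in a few seconds on
one CPU while keeping every reported statistic stable at the precision
printed.

## Known limitations

- The spectral model is linear and noise-additive; no detector saturation,
  bleed-through beyond the two references, photobleaching, or lifetime
  effects.
- The 1-D angle landscape cannot capture coupling between the side chain and
  backbone or partner degrees of freedom; WHAM here operates on that single
  coordinate.
- The ΔΔG protocol tests the ensemble/acceptance machinery and sign
  conventions on a toy score; it does not approximate an all-atom energy
  function, and its magnitudes are not comparable to published kcal/mol
  values.
- Real reference spectra, structures and construct tables can be supplied
  through the documented CSV/TIFF/PDB interfaces, but all validation in the
  test suite uses the synthetic generators.
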