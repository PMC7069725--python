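# Methods

This note documents the models, numerical choices and limitations behind
vsdkit. It is written from the package's point of view: what each stage
computes, which knobs matter, and what the synthetic generators do and
do not emulate.

## Restraint derivation

**NOE calibration.** Cross-peak intensities follow I = A·r⁻⁶ up to a
per-group amplitude. Because transmembrane-core resonances are broadened
relative to the periphery, peaks are calibrated in two groups (a peak is
"core" when both of its residues are core) and binned by log-intensity at
configurable quantiles (quartiles by default, the highest bin being
"strong"). Class bounds are fixed at 1.8–2.8, 1.8–3.5, 1.8–4.5 and
1.8–5.5 Å. Quantile calibration is scale-invariant within each group —
multiplying a whole group's intensities by any constant leaves the class
assignment unchanged — but it does not guarantee that an individual
peak's true distance lies inside its class bounds; that is the nature of
intensity-binned calibration, not an implementation artifact.

**PRE inversion.** The paramagnetic rate for a nitroxide–amide-proton
pair is Γ₂ = (K/r⁶)(4τ_c + 3τ_c/(1+ω_H²τ_c²)) with
K = 1.23×10⁻³² cm⁶ s⁻², and the observable intensity ratio is
I_para/I_dia = R₂·exp(−Γ₂ t)/(R₂+Γ₂) with R₂ = π·FWHM_dia (Lorentzian
lineshape assumption) and t the INEPT evolution time. Ratios below 0.2
map to bounds (2, 18) Å; ratios above 0.8 map to (19, 100) Å; ratios in
the closed interval [0.2, 0.8] are inverted explicitly — Γ₂ by bisection
on [0, 10⁶] s⁻¹ (the forward ratio is strictly decreasing in Γ₂;
residual < 10⁻¹²) and then r through the r⁻⁶ law — and widened by ±6 Å,
clipped to [2, 100] Å. Boundary ratios of exactly 0.2 or 0.8 fall in the
explicit regime. τ_c, t and the field are not derivable from the ratio
table and must be supplied; the documented working point is τ_c = 20 ns,
t = 10 ms, 900 MHz. An optional residue-range exclusion drops targets on
mobile elements (the S0 helix in the study system). The spin label is
represented by the CB of the labeled residue; no linker-rotamer ensemble
averaging is attempted.

**Torsions and hydrogen bonds.** Chemical-shift torsion predictions are
used only when classified "strong" with confidence ≥ 7, as φ/ψ flat
wells of half-width 20°. Helical ranges contribute O(i)–H(i+4)
(1.8–2.3 Å) and O(i)–N(i+4) (2.8–3.3 Å) pairs; ranges shorter than five
residues are skipped.

## RDC analysis

Couplings come from ¹⁵N-dimension HSQC/TROSY peak pairs: the pair is
split by half the coupling, so J = 2|Δν_iso| and J+D = 2|Δν_aligned|,
D = (J+D) − J. Splittings are processed as magnitudes — the physical
one-bond J_NH is negative (≈ −93 Hz), but only frequency differences are
observable, so the sign convention is "D positive when alignment
increases the apparent splitting"; it is documented here rather than
configurable per call. Initial tensor estimates use the extrema
(D_zz = 2Da; D_min = −Da(1+1.5R)); they are reliable only when bond
orientations sample the sphere densely. The definitive fit is linear
least squares on the five independent Saupe elements (SVD-based, exact
on noise-free data); unweighted, since no per-coupling errors are
modeled. Ensemble RDC r.m.s.d. fits one tensor per model by default (a
shared-tensor mode exists) — the choice matters when models differ
substantially. Missing amide protons are rebuilt at 1.02 Å along the
bisector-opposed direction of the idealized amide geometry.

## The embedder

The embedder reconstructs backbone-level structures (N, H, CA, C, O and
a CB pseudo-atom per non-glycine residue) from flat-well distance and
dihedral restraints. The energy is a sum of harmonic ideal-geometry
pair terms (bonds and angle-equivalent 1–3 distances measured on an
ideally built peptide template), flat-well distance terms with
r⁻⁶-summed effective distances over ambiguous selections, wrapped
quadratic dihedral wells, a CA-centered chirality term (L-amino acids
only), and a soft steric floor (2.7 Å heavy–heavy, 1.7 Å with
hydrogens; covalently adjacent residues excluded). Side-chain selections
that name atoms absent from the reduced representation fall back to the
residue's CB with a +1 Å upper-bound correction.

Each run starts from a randomized distance-geometry embedding: pair
bounds are assembled from geometry and restraints, upper bounds are
triangle-smoothed (min-plus transitive closure), a random metric is
sampled within the bounds, classical MDS embeds it in 3D, and the
mirror image with the lower chirality-aware energy is kept. Refinement
is basin-hopping down the annealing temperature ladder (default
3500 → 100 K in 25 K steps, subsampled to 10 visited levels): at each
level the current structure is thermally perturbed (σ ∝ √T), pushed by
a few normalized noisy gradient steps, locally minimized (L-BFGS with
analytic gradients), and accepted by a Metropolis criterion; restraint
weights ramp from their starting to final values (NOE 20 → 30,
PRE 2 → 3, dihedral 200) halfway down the ladder. A final minimization
at the end-point weights closes each run. This gradient-guided scheme
replaces plain Cartesian Metropolis from extended chains, which does not
reach useful accuracy at desk scale; it is the classical
distance-geometry/anneal strategy rather than a molecular-dynamics
protocol, and there is no torsion-angle-dynamics stage — restraint
satisfaction is therefore somewhat looser than a full structure-
calculation engine would achieve, which shows up as a nonzero residual
energy rather than as biased geometry.

Runs are ranked by energy; energy separates failed topologies from
correct ones clearly on the test fixture, so "best of N" selection (and
the top-10 % helper mirroring a keep-the-best refinement workflow) is
meaningful. The jackknife excludes a disjoint-as-possible random 10 % of
long-range (|i−j| ≥ 5) NOE restraints per repeat, ten times, so that
every long-range restraint is excluded at least once whenever coverage
allows, and reports each repeat's best-model backbone r.m.s.d. to the
all-data best model.

## Validation statistics

Restraints are tallied by class and by sequence separation (intra 0,
sequential 1, medium-range 2–4, long-range ≥ 5). The violation statistic
is the r.m.s.d. of zero-floored flat-well violations per model, reported
as mean ± sd over models — chosen so that a fully satisfied ensemble
scores exactly zero; a deviation-based alternative would not. Ensemble
precision superposes every model onto the evolving mean structure
(Kabsch least squares on the selection) until the mean shifts by
< 10⁻⁶ Å and averages the r.m.s.d. to the mean; a pairwise mode is also
provided. "Backbone heavy atoms" means N, CA, C, O; "all heavy atoms"
means every non-hydrogen atom. Block clustering runs DBSCAN on the
pairwise aligned-r.m.s.d. matrix of each block of frames and returns the
summed-r.m.s.d.-minimizing member of the most populated cluster; blocks
with no core points fall back to the block medoid and are flagged.

## Conformation comparison

Helix axes are first principal components of the CA trace, oriented
toward increasing residue number. The membrane normal is the normalized
mean of the consistently oriented S1–S3 axes (S4 is excluded because it
moves); its extracellular sign is fixed by requiring a positive
projection of the S3 C-terminus → N-terminus vector, a convention that
must be stated because the measurement frame determines the sign of the
S4 translation. The S4 displacement superposes the second model on the
first over the S1–S3 core CA atoms (default ranges 120–142, 160–179,
198–215) and projects the difference of S4 CA centroids (default
219–239) on the normal; it is antisymmetric under model exchange and
invariant to rigid motion of either input. Ortholog numbering is handled
by a fixed offset (human − 10 = Xenopus, anchored at G229/G219). Salt
bridges use the standard 4.0 Å minimum N–O side-chain criterion (Arg
NE/NH1/NH2, Lys NZ, His ND1+NE2 regardless of protonation; Asp OD1/OD2,
Glu OE1/OE2). Helical span reports the longest run (≥ 4 residues) with
φ ∈ [−100, −30] and ψ ∈ [−80, −5], truncated at chain breaks
(C–N > 2.5 Å).

## Electrophysiology and VCF

Temperature defaults to 295.15 K (room-temperature oocyte recordings);
F = 96485 C·mol⁻¹, R = 8.314 J·mol⁻¹·K⁻¹. The G-V relation uses
instantaneous tail currents: the mean over a window (default 100 ms,
20 ms in round-trip tests) starting after a configurable
capacitive-settling gap (default 5 ms), normalized to the largest tail.
Fluorescence baselines are fitted as exponential-plus-constant on the
first 2 s at holding (linear fallback when degenerate), extrapolated and
subtracted; ΔF/F is read at the end of the 4 s test pulse and normalized
to the global maximum across voltages. Boltzmann fits use nonlinear
least squares with a multi-start grid over V₁/₂ (−150 to +50 mV, 20 mV
steps); the double form orders V₁ < V₂ and bounds the first amplitude to
[0.05, 0.95] to prevent component collapse. Steady-state current is the
mean of the final 100 ms of the test pulse (window configurable). The
inhibition fraction is Eq.-1-style chromanol subtraction,
f = (I_control − I_XE991)/(I_control − I_chromanol); values outside
[0, 1] are returned but flagged. Time-dependent inhibition is the
pointwise drug/control current ratio from test-pulse onset, with
zero-crossing points masked and any smoothing window recorded in the
output metadata.

## Synthetic generators — what they emulate, and what they do not

The bundle generator produces ideal-helix geometry (radius 2.3 Å, rise
1.5 Å, twist 100°/residue — chosen over φ/ψ propagation for analytic
testability) with circular-arc loop connectors at 3.8 Å CA spacing;
backbone decoration transfers local-frame offsets measured on an ideally
built α-helix, with helix-end frames taken from the helix
parametrization itself so terminal hydrogen bonds stay ideal. Loop
junction peptides are slightly non-ideal; only helix-derived restraints
are exactly satisfied by construction. The NOE generator optionally
emits a pseudo side-chain proton ("HB") at each CB: backbone amide
protons alone carry almost no inter-helix contact information (they
point along the helix axes), whereas real spectra are dominated by
side-chain NOEs; the HB sites stand in for that network and deliberately
exercise the CB-fallback mapping in the embedder and validator. The
gating generator uses equilibrium Boltzmann occupancies of a sequential
three-state scheme with mono-exponential relaxation per transition
(occupancies always sum to one) — sufficient to exercise every analysis
operation, but not a kinetic model of any real channel; there is no
Markov single-channel noise, no leak beyond a zero default, and
photobleaching is a single exponential. Consequently, passing tests
demonstrate the correctness of the analysis chain under its own model
assumptions, not the accuracy of those assumptions for real membranes,
micelles or oocytes.

Generator defaults for the gating model (valences 2.0/1.2, half-voltages
−50/+10 mV, 10 µS conductances, E_rev −80 mV, bleach τ 50 s, block
0.8/0.2) are plausible oocyte-scale values chosen once; the 0.8/0.2
IO/AO block asymmetry is the condition the drug-block analyses are
tested against.

## Problem sizes and tolerances

The standard recovery fixture is a 60-residue, four-helix bundle
(~360 atoms, ~700 restraints); the embedder reaches < 3.5 Å backbone
r.m.s.d. best-of-20 with the default-derived light schedule
(t_step 100 K, 10 steps/level), and the 10 × 10 % jackknife stays within
4 Å of the all-data model. PRE inversion is exact to < 10⁻³ Å on
noise-free mid-regime ratios; the SVD tensor fit is exact to < 10⁻⁶
relative Da on noise-free couplings. Boltzmann round trips recover
parameters to < 10⁻⁶ noise-free and V₁/₂ to ~2 mV at 2 % amplitude
noise. Degenerate inputs are handled explicitly: all-zero couplings,
all-zero observed RDCs, all-noise clustering blocks, equal
control/chromanol currents, and baseline-fit failures all raise or flag
rather than silently returning numbers.

## Known limitations

- The embedder's reduced representation cannot express side-chain
  packing; side-chain restraints are CB-mapped with a fixed +1 Å
  correction.
- Quantile NOE calibration guarantees class-bound coverage only in
  distribution, not per peak.
- The accession-dependent comparisons (deposited ensembles, source-data
  spreadsheets) require those files locally; the package ships only the
  operations, exercised on synthetic constructions.
- Mirror-image topologies are penalized through chirality and dihedral
  terms but not provably excluded; energy ranking across multiple runs
  is the practical safeguard.
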