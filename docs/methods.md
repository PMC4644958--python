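# Methods

This note records the models the package implements, the conventions and
defaults it commits to, and the numerical choices a maintainer would want
to know. Units throughout: kcal/mol for energies, Å for lengths, e for
charges, amu for masses, ps for times, K for temperature.

## Single-trajectory MM-GBSA

The binding enthalpy of one snapshot is assembled as

    ΔH = ΔE_ele + ΔE_vdw + ΔG_pol + ΔG_nonpol.

**Gas phase.** ΔE_ele and ΔE_vdw are full receptor × ligand pairwise sums
(Coulomb constant K = 332.0637 kcal·Å/mol/e²; LJ combining rules
Rmin_ij = rmin½_i + rmin½_j, ε_ij = √(ε_i ε_j)). No distance cutoff and no
periodicity: end-state post-processing conventionally uses complete sums
even when the generating dynamics used a cutoff. In the single-trajectory
scheme complex, receptor and ligand share coordinates, so intramolecular
terms cancel in the complex − receptor − ligand difference and only cross
terms remain.

**Polar solvation.** The Still generalized-Born energy

    ΔG_pol-species = −(K/2)(1/ε_in − 1/ε_out) Σ_ij q_i q_j / f_GB(r_ij, R_i, R_j),
    f_GB = sqrt(r² + R_i R_j exp(−r²/(4 R_i R_j))),  f_GB(i=i) = R_i,

evaluated separately for complex, receptor and ligand on the same frame
(the same-molecule pairs do not cancel — effective radii change upon
binding). Effective radii follow the Hawkins–Cramer–Truhlar pairwise
descreening model with the conventional 0.09 Å offset; the closed-form
descreening integral is verified in the tests against direct numerical
integration of ∫ dV/r⁴ over the descreening sphere. Dielectrics default to
ε_in = 1, ε_out = 80 (config-overridable); a non-positive inverse radius
(pathological burial) is clamped to R = 30 Å with a warning. Which GB
flavour a given legacy workflow used is generally not recoverable, so
absolute polar energies are treated as model-dependent; everything checked
quantitatively here is either a closed form (Born ion) or an internal
consistency property.

**Nonpolar solvation.** γ·SASA + β with γ = 0.005 kcal/mol/Å², β = 0,
probe 1.4 Å. SASA is Shrake–Rupley quadrature on a deterministic
golden-spiral (Fibonacci) point set, 960 points/atom by default, with the
LJ rmin/2 as the atomic radius proxy (the packaged toy parameters make
this a reasonable van der Waals envelope). Isolated-sphere closed form is
reproduced to <0.5 %; doubling the point count moves a 10-atom toy total
by <0.3 %.

*Quadrature dithering.* A fixed point-set orientation gives each pose a
deterministic quadrature error that does not shrink with snapshot count;
at n = 500 snapshots the standard error of the mean nonpolar term
(~2×10⁻⁴ kcal/mol on the toy complex) is far below that grid error
(~10⁻³). Because a uniformly random orientation makes Shrake–Rupley
exactly unbiased in expectation, `BindingFreeEnergyModel` rotates the
point set by a deterministic per-snapshot random orientation (fixed
internal seed — fits are bit-reproducible). The `sasa` primitive itself
stays deterministic for a given point count; dithering is an ensemble
feature.

**Decomposition.** Every pairwise term (Coulomb, LJ, GB pair term —
including the complex-minus-isolated difference of same-molecule GB pairs)
is split half/half between the two atoms' residues; GB self terms and
per-atom SASA differences go wholly to the owning residue. Residue totals
therefore reconcile with the system totals exactly (tested at 1e-6,
observed at round-off). The half/half split is a convention, not physics;
alternatives redistribute between partners but preserve the totals.

**Snapshot protocol.** The default protocol mirrors common practice for a
20 ns trajectory saved every 1 ps: 500 snapshots taken evenly from the
last 5 ns at 10 ps intervals (window (start, end] in ns; a window/interval
mismatch is a configuration error, never silently rounded), with the
normal-mode entropy evaluated on every 4th snapshot (125 of 500) since it
is by far the most expensive term. Aggregates report per-component means
and standard errors σ = sd(n−1)/√n; ΔG_bind = mean ΔH + mean(−TΔS), and
its sem combines the two in quadrature. Cross-compound summary statistics
use the sample (n−1) standard deviation — this convention reproduces the
packaged table's published spread values, an n denominator does not.
Correlations are Pearson; an `absolute` mode exists because the weak
vdW+nonpolar correlation is conventionally quoted as |r| (its signed value
on the packaged table is negative).

## Normal-mode entropy

−TΔS = −T(S_complex − S_receptor − S_ligand), each species entropy the sum
of ideal-gas translational (Sackur–Tetrode, 1 atm), rigid-rotor rotational
(principal moments from the minimized geometry; σ = 1 by default) and
harmonic-oscillator vibrational terms. Vibrational frequencies come from
the mass-weighted Hessian, built by central finite differences (step
1e-4 Å) of the analytic toy-force-field gradient and symmetrized. Modes
with |ν| < 1 cm⁻¹ are treated as rigid-body modes and removed; more than
six removals, or surviving imaginary modes, warn that the structure is not
at a minimum. The 1 cm⁻¹ threshold separates rigid-body from soft
vibrational modes on the packaged toys; note that a mode drifting across
the threshold changes T·S_vib by several kcal/mol (S_vib ~ −ln ν at small
ν), which is an intrinsic sensitivity of harmonic entropies, not an
implementation artifact.

Each species is minimized before the Hessian (tolerance 1e-6 kcal/mol/Å on
the projected gradient). The minimizer is L-BFGS with analytic gradients:
on the charged toys, plain steepest descent needs orders of magnitude more
iterations to reach the same gradient norm, and the pipeline runs 3 × 125
minimizations per fit.

The toy force field is harmonic bonds k_b(r−r0)² and angles k_a(θ−θ0)²
plus intramolecular Coulomb/LJ with 1-2 and 1-3 exclusions and no
dihedrals — the minimal model with a well-defined vibrational spectrum.

## Structural analyses

RMSD series superpose each frame onto a reference frame (Kabsch SVD,
proper rotation enforced) on a fit selection — protein backbone by
convention — and measure RMSD on a possibly different selection without
refitting. Pocket-style selections (`within R of …`) are residue-granular
and use minimum heavy-atom distances, evaluated once on a designated
reference frame: pocket membership is frozen, making the time series
well-defined. Window statistics use sd(n−1).

Hydrogen bonds use the strict geometric criterion donor–acceptor
distance < 3.5 Å AND donor–H–acceptor angle > 120° (both inequalities
strict; boundary values fail). The angle is measured at the hydrogen —
the most common convention — and is config-overridable. Hydrogens attach
to donors through the topology bond table only; donors without bonded
hydrogens are skipped with a debug log. Occupancy is the percentage of
frames where a donor/acceptor pair passes with any of its hydrogens
(counted once per frame); mean distances are over passing frames only, and
pairs never observed are omitted from the report. A companion profile bins
per-frame bond counts along a pulling displacement (0.5 Å bins) to track
bond breaking/forming during unbinding.

## Bidirectional-work PMF

Work samples are cumulative works on a displacement grid inside contiguous
segments (the packaged default emulates a 16 × 1 Å protocol). Forward
samples start at the segment entry A; reverse samples are recorded from
their own pulling start at the far end B, and the estimator re-indexes
them so the work from an intermediate point r back to A is
W_R(L) − W_R(L−r). Within a segment, BD-FDT is applied at every grid
point; segments are stitched by cumulative offsetting (segment ids must be
consecutive — a gap or duplicate is an error) and the profile is anchored
at zero displacement. All exponential averages use log-sum-exp.

Estimator properties enforced by tests: exact antisymmetry under
forward/reverse exchange; adding a constant c to all forward (reverse)
works shifts the estimate by +c/2 (−c/2); and on Crooks-consistent
Gaussian work with equal forward/reverse variance — the regime the
synthetic sampler generates — the estimator is exact in expectation, which
is what makes planted free energies recoverable. Jarzynski and BAR are
provided as independent references; BAR solves the implicit equation by
bracketing + Brent to 1e-8 and agrees with BD-FDT within mutual bootstrap
uncertainties on Crooks-consistent data.

Uncertainties come from a path-level bootstrap (default 200 resamples,
seeded): paths are resampled with replacement per direction within each
segment, the profile is re-stitched, and per-point standard errors and an
endpoint percentile CI are reported. The sampler's within-segment
cumulative ramp is linear, under which interior grid points of a planted
linear profile are also recovered exactly in expectation.

## Synthetic data

`make_host_guest` builds a 14-atom bound pose: three host residues — two
arginine-like (+1 N–H side chains) and one serine-like (O–H) — whose
donors each face one oxygen of a phosphate-like PO₃⁻² + C guest at 2.9 Å,
collinear D–H···A geometry. The three CA atoms are bonded into a soft
triangular scaffold so the isolated host has a bound minimum (the two +1
side chains would otherwise repel to infinity during pre-NMA
minimization); all bond/angle equilibria are set to the constructed
geometry, so the pose is the bonded-term minimum by construction. The
system is net-neutral (+2 host, −2 guest). Parameters are conventional
force-field magnitudes per element class. What the toy does *not* emulate:
explicit water, real protein geometry, dihedral physics, polarization.

`jitter_trajectory` adds i.i.d. Gaussian coordinate noise (frames 1 ps
apart, seed-deterministic). The default σ = 0.01 Å is deliberately in the
linear-response regime: ensemble means of the nonlinear energy terms then
estimate the static-pose values, since the convexity bias grows as σ²
(dominated by the r⁻¹² LJ wall) while the n-snapshot sem grows only as
σ/√n — at σ = 0.1 the vdW bias is already ~10 sems at n = 500. Structural
analyses that want visible motion (RMSD statistics, occupancy fixtures)
pass larger σ explicitly. Passing pipeline tests on this generator
therefore demonstrates estimator correctness, not force-field realism or
conformational-sampling adequacy on real data.

`crooks_work_sampler` draws per-segment endpoint works
W_F ~ N(ΔG_s + σ_W²/2k_BT, σ_W²), W_R ~ N(−ΔG_s + σ_W²/2k_BT, σ_W²)
(equal dissipation both directions — the Crooks-consistent equal-variance
regime) and ramps them linearly inside the segment. Defaults: 16 segments
of 1 Å whose ΔG_s sum to −13.0 kcal/mol in a steep-rise-then-plateau
shape, σ_W = 1 kcal/mol, 4 paths per direction (the realistic pulling
protocol; parameter-recovery checks use 10⁴), T = 300 K, 11 grid
points/segment.

The packaged nine-compound table carries printed means, standard errors
and experimental ΔG values; composite rows are rebuilt from the component
means so every identity (ele+pol, vdw+nonpol, ΔH, ΔG_bind) holds exactly.
It is fixture data for the statistics machinery — the absolute component
values are not recomputation targets at desk scale.

## Numerical/degenerate-input policy

- Pair energies at r < 1e-6 Å raise a singularity error naming the pair.
- Kabsch superposition requires ≥3 non-collinear fit atoms (checked via
  the second singular value); mirror-image fits are forced to proper
  rotations.
- Snapshot selection never rounds: windows not covered by the trajectory,
  or spans not divisible by the interval, are configuration errors.
- Aggregation needs ≥2 snapshots (sem undefined otherwise); correlation
  needs n ≥ 3 and non-zero variance.
- Work grids inconsistent across paths are linearly resampled onto a
  common grid (logged); work/displacement must start at zero at segment
  entry.
- Numeric report cells render at two decimals (round-half-even);
  compounds without experimental values render `null`.

## Known limitations

- No Poisson–Boltzmann polar term, no explicit-solvent energetics, no PME.
- GB flavour fixed to HCT/Still; other igb-style variants would change
  absolute polar energies.
- Normal-mode entropy assumes harmonic wells; no quasi-harmonic or
  conformational-ensemble entropy.
- The PMF machinery consumes cumulative works; it does not integrate raw
  force traces and does not implement WHAM or replica protocols.
- The toy generator is a correctness testbed, not a physical model of any
  real receptor.
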