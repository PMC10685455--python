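# Methods

This note documents the models, numerical choices and limitations
behind `macrorew`. Units throughout: coordinates Å, energies kcal/mol,
time ns, temperature K, charges elementary charge (e);
k_B = 0.0019872 kcal/(mol·K).

## Boost model and reweighting

Accelerated MD modifies the potential below a threshold E:

    ΔV(x) = (E − V(x))² / (α + E − V(x))   for V(x) < E, else 0,

with α > 0 controlling how aggressively basins are flattened. ΔV is
continuous and non-increasing in V. In dual-boost runs a dihedral-only
boost and a total-potential boost act simultaneously; the per-frame
boost entering reweighting is their **sum** by default
(`WeightParams.use_boost`), with either component selectable alone —
dual boost deposits both energies, and the choice is exposed because
log conventions vary.

Canonical (unbiased) expectations are recovered with per-frame weights

    w_i ∝ exp(β ΔV_i),  β = 1/(k_B T),

normalized to Σ w_i = 1. The exponential estimator is dominated by the
few largest boosts; the default estimator therefore truncates the
exponential's Maclaurin series at order 20:

    w_i ∝ Σ_{n=0..20} (β ΔV_i)ⁿ / n!

The truncated series converges to the exponential monotonically from
below for positive arguments. Its relative truncation error at order 20
is < 1e-4 up to β ΔV ≈ 8 and grows to ~1.6e-3 by β ΔV = 10; for the
boost magnitudes of the synthetic oracles here (β ΔV ≲ 2.5) the two
estimators agree to ~1e-14. Exponential mode is retained as the exact
oracle. Temperature defaults to 300 K and is configuration, not a
derived quantity.

Dual-boost parameter rules (`dual_boost_params`): the dihedral
threshold sits 3.5 kcal/mol per freely movable backbone dihedral above
the average dihedral energy with α = 3.5/5 per dihedral (the
Pierce-style convention; coefficients overridable); the total-potential
threshold sits 0.2 kcal/mol per atom above the average potential in
aqueous-like solvents and **0.56 kcal/mol per atom in DMSO**, which has
more internal degrees of freedom. With zero movable dihedrals the
dihedral window is empty; α is floored at 1e-6 to keep the functional
defined.

Free-energy surfaces use F = −k_B T ln(p / p_max) on a 2D grid of
reweighted bin probabilities: the most probable bin is pinned to
F = 0 and bins with zero sampled weight are flagged *unoccupied*
(NaN), never assigned an arbitrary cap — unsampled is not
zero-energy. Histogram bins are half-open [lo, hi) with the last bin
closed; out-of-range values go to a reported overflow bucket.

## Dihedral PCA

Torsions are circular, so each angle is encoded as a (sin θ, cos θ)
pair (feature order sin-before-cos per torsion — any fixed order works;
this one is pinned for reproducibility). PCA is an eigendecomposition
of the covariance of the encoded features, using the total-weight
(population) denominator so the eigenvalue sum equals the total feature
variance. Determinism conventions: eigenvalues sorted descending; each
component's largest-magnitude entry is made positive.

The PCA fit is **unweighted** over all frames by default and the
density on the PC plane is reweighted afterwards; this keeps the axes
fixed while populations shift, which is what cross-solvent and
split-half comparisons require. Weighted fitting is available
(`fit_pca(..., weights=)`) but off by default. Ensembles that must
share axes (solvents, repeat runs) should be concatenated before
fitting and projected separately.

State assignment is K-means (k-means++ initialization, Lloyd
iterations, tolerance 1e-6, max 500 iterations, seeded and
deterministic) on the first two PCs, k = 6 by default. Clusters are
relabeled by descending population so "cluster 0" is always the
dominant state. The representative frame of a cluster is its member
nearest the centroid (Euclidean; ties to the lowest frame index).
Matching a reference conformation from another ensemble returns the
cluster whose representative lies nearest the reference; when no
centroid falls within a configurable radius (default 1.0 in PC units)
there is no adequate cluster and the single nearest frame is returned
instead, flagged as a frame fallback.

## Intramolecular hydrogen bonds

A donor is one N–H or O–H pair (one donor entry per hydrogen);
acceptors are all oxygens plus nitrogens that are neither amide-N
(bonded to a carbonyl carbon, i.e. a carbon with a terminal oxygen)
nor H-bearing. This keeps carbonyl oxygens always in and amide
nitrogens always out; an H-bearing amine nitrogen counts as a donor
but not as an acceptor.

A contact in a frame requires all of (cutoffs inclusive):

* donor-heavy to acceptor-heavy distance ≤ 3.5 Å — the heavy-atom
  convention; the alternative H···acceptor distance is configurable;
* donor–H···acceptor angle ≥ 90°, deliberately permissive to capture
  unconventional short-range IMHBs;
* bond-graph separation of the heavy atoms ≥ 3 bonds (default), so
  covalently adjacent polar atoms are not self-counted.

Occupancy is the weight-weighted contact count, occ(d,a) =
Σ_f w_f · 1[contact], an exact linear functional of the weights:
splitting a trajectory and recombining halves with weight-proportional
mixing reproduces the full map identically. Donor contributions are
row-share percentages of total occupancy (undefined/NaN for an all-zero
map). Polar-vs-apolar comparison reports the apolar − polar difference
map; a pair is *short-range* when donor and acceptor residues are
adjacent on the macrocycle ring (ring-sequence separation ≤ 1 taking
the shorter direction), otherwise *long-range* (transannular).

## Convergence diagnostics

2D-RMSD: frames sampled at a fixed stride (default 1 ns) are compared
pairwise after optimal superposition (centering + Kabsch rotation via
SVD, with the determinant correction that excludes reflections),
hydrogens excluded by default.

Split-half test: the trajectory is cut at the midpoint (first half
takes the extra frame when odd, noted in the report), each half's
weights are renormalized, and the halves are compared on shared axes —
PCA fitted once on the full trajectory, a common 2D histogram grid
spanning the full projection range. Reported: the maximum absolute
contact-occupancy difference (∈ [0,1]) and the Jensen–Shannon
divergence between the reweighted PC densities in bits (∈ [0,1],
computed as the square of `scipy.spatial.distance.jensenshannon` with
base 2). The default grid is 24 × 24: the JSD noise floor between
statistically identical halves grows roughly linearly with the number
of occupied bins over the half size, and at ~10⁴ frames per half this
resolution keeps the floor near 0.006 bits (30-seed calibration,
max 0.009), comfortably below the 0.02-bit level used to judge
identical-by-construction halves; a 40 × 40 grid roughly doubles the
floor.

Cross-run reproducibility: histogram intersection Σ min(p_a, p_b) of
two reweighted PC densities on a shared grid, in [0, 1]; the test
passes at ≥ 0.7 by default. The original visual "resembles" judgement
has no printed numeric criterion, so both thresholds are documented
implementation policy, not literature values.

## Conformer-averaged charges

Charges fitted to one conformer inherit its conformational bias, and a
high-free-energy conformer can yield misleading charges; plain per-atom
averaging over independently generated conformers (default 10, fewer
accepted with a warning) neutralizes single-conformer error. Averaging
is exactly linear in the total charge. Validation checks
|Σq − formal charge| ≤ tol (default 1e-4 e) and lists per-atom
outliers; the spread diagnostic is the per-atom sample standard
deviation (ddof = 1) across conformers. QM/RESP fitting itself is out
of scope — the module consumes externally produced tables. No
symmetry-equivalence re-averaging is applied (equivalent atoms are
normally symmetrized upstream by the fitting procedure).

## Synthetic generators and what they do (not) show

All generators are pure functions of their arguments including the
seed.

* `toy_macrocycle(n_residues, linker_len)`: simplified amide units
  (N, H, Cα, C, O) closed through a secondary amine and a CH₂ linker,
  ring backbone on a circle (1.5 Å spacing), carbonyl O and polar H
  radially outward, CH₂ hydrogens out of plane. It reproduces the
  donor/acceptor census of a semipeptidic macrocycle (n amide N–H, one
  amine N–H, n carbonyl O) but its geometry is idealized — it carries
  no force-field energetics and no realistic ring pucker.
* `sample_boosted_potential`: 1D Metropolis on the boosted surface
  V + ΔV(V) with exact per-step ΔV. Metropolis has an exact stationary
  distribution, so reweighted observables have analytic targets
  (harmonic well: ⟨x²⟩ = k_B T/k) — something MD cannot provide at this
  cost. Default conditions for the oracle runs: k = 1 kcal/mol/Ų,
  T = 300 K, 10⁵ steps, step size 0.5 Å (acceptance ≈ 0.9).
* `plant_torus_clusters`: k von-Mises clusters on the T-torus with
  chosen populations and concentration κ (default oracle: 3 clusters,
  populations 0.5/0.3/0.2, κ = 50, 11 torsions, 10⁴ frames). A
  `center_seed` pins the cluster layout independently of the frame
  noise for repeat-run scenarios.
* `plant_hbond_trajectory`: frames copy two fixed templates per planned
  pair — contact-formed (heavy distance 2.9 Å, D–H···A angle 165°) and
  broken (5.5 Å) — scheduled greedily over descending weights (seeded
  tie-break) so the weighted occupancy matches the target as closely as
  the weights allow; the achieved value is returned as ground truth
  (reported as a frame-order weighted count so recovery is exact in
  floating point). Occupancy statistics, not mechanics, are modeled;
  infeasible targets warn with the nearest achievable value.

Passing tests on these generators demonstrates that the estimators are
implemented correctly (reweighting mathematics, geometric criteria,
eigenstructure, divergences), not that real macrocycle ensembles
converge: real trajectories have correlated frames, anharmonic
potentials and solvent effects none of the generators emulate.

## Problem sizes and numerical policy

The test-suite and acceptance-script problem sizes — 10⁵ Metropolis
steps, 10⁴-frame cluster recoveries, 2 × 10⁴-frame split-half runs —
were chosen so every statistical bound holds with a comfortable margin
under repeated-seed calibration while the whole suite runs in seconds;
they are desk-scale stand-ins for the microsecond production ensembles
the workflow targets.

Degenerate inputs are errors, not silent results: zero-variance PCA
features, fewer than two frames for RMSD, all-zero contact maps
(shares reported NaN), non-finite or negative boost energies. Exact
ties break deterministically (lowest index); dihedrals use the
(−180, 180] wrap with −180 mapped to +180; exponential weights are
computed max-shifted to avoid overflow.

## Known limitations

* No dynamical (time-dependent) reweighting, Gaussian-approximation or
  cumulant-expansion variants.
* No solvent-bridged or C–H hydrogen bonds; geometric, not energetic,
  H-bond scoring.
* Solute-only trajectories are assumed (imaging/stripping happens
  upstream); no periodic-box handling.
* Ring-residue adjacency uses residue ids modulo the ring length and
  assumes contiguous ids around the macrocycle, as produced by
  `toy_macrocycle`.
* The boost-log reader implements a configurable whitespace-column
  dialect (AMBER-style defaults); exotic log schemas need a custom
  column map.
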