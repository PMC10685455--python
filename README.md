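# macrorew

Reweighted conformational-ensemble analysis for macrocycle
accelerated-MD (aMD) trajectories.

Semipeptidic macrocycles can be *chameleonic*: they expose polar groups
in water but fold them away into intramolecular hydrogen bonds (IMHBs)
in apolar media, which helps them cross membranes. Quantifying that
behaviour from simulation requires enhanced sampling — dual-boost aMD —
whose ensembles are biased and must be statistically reweighted before
any population, free-energy surface, or hydrogen-bond occupancy is
trustworthy. `macrorew` implements that analysis chain as a tested
library plus a `macrorew` command-line tool:

* **Reweighting.** aMD adds a boost ΔV(x) wherever the potential falls
  below a threshold E: ΔV = (E − V)² / (α + E − V). Canonical averages
  are recovered with per-frame weights w ∝ exp(β ΔV); because the
  exponential estimator is noisy, the default replaces it with the
  Maclaurin series of the exponential truncated at order 20,
  w ∝ Σₙ₌₀²⁰ (β ΔV)ⁿ / n!. Dual-boost parameter rules are included
  (e.g. the DMSO total-potential threshold E = ⟨V⟩ + 0.56 kcal/mol ×
  N_atoms).
* **Dihedral PCA (dPCA).** Ring torsions θ₁..θ_T are encoded as
  (sin θ, cos θ) pairs to respect angular periodicity, PCA is fitted on
  the encoded features, and conformational states are assigned by
  K-means (default six centroids) on the first two PCs, with
  per-cluster representative frames and reweighted free-energy surfaces
  F = −k_B T ln(p / p_max).
* **IMHB contact maps.** Geometric detection (donor-heavy to
  acceptor-heavy distance ≤ 3.5 Å, donor–H···acceptor angle ≥ 90°,
  both inclusive), reweighted occupancy per donor/acceptor pair,
  per-donor contribution percentages, and polar-vs-apolar difference
  maps split into short-range (adjacent ring residues) and long-range
  (transannular) classes.
* **Convergence diagnostics.** Pairwise heavy-atom 2D-RMSD (Kabsch
  superposition, default 1 ns stride), split-half comparison of contact
  maps and reweighted PC densities (max occupancy difference +
  Jensen–Shannon divergence in bits), and a cross-run histogram-
  intersection overlap score for reproducibility tests.
* **Conformer-averaged charges.** Plain per-atom averaging of partial
  charges over independently generated conformers (default 10), with
  total-charge validation and per-atom spread diagnostics.
* **Synthetic generators.** Every input can be generated with planted
  ground truth: a toy macrocycle topology, Metropolis samples from a
  boosted 1D potential with exact ΔV bookkeeping, von-Mises torsion
  clusters on the torus, and trajectories with scheduled H-bond
  occupancies — so the whole chain is verifiable end to end.

## Worked example

Generate a synthetic run (toy macrocycle, 500 noisy frames, a random
boost log, four ring torsions) and execute the full chain:

```bash
macrorew run --config config.yaml --out-dir demo_run
```

with `config.yaml`:

```yaml
topology: topo.pdb
trajectory: traj.xyz
boost_log: amd.log
torsions: torsions.txt
kmeans_k: 3
seed: 7
```

The run directory contains `weights.txt`, `pc_projection.tsv`,
`fes.tsv`, `contact_map.tsv`, `donor_contributions.tsv`,
`convergence.json` and a machine-readable `summary.json`, which for the
inputs above prints:

```json
{
 "config_hash": "d38b09e0b72b79dc",
 "stages": {
  "convergence": {
   "contact_divergence": 0.01694547468770818,
   "density_divergence_bits": 0.7164250703755392,
   "n_first_half": 250,
   "n_second_half": 250
  },
  "dpca": {
   "cluster_populations": [0.374, 0.385, 0.241],
   "explained_variance_pc1_pc2": [0.216, 0.154]
  },
  "hbonds": {
   "donor_shares_percent": [38.1, 28.4, 33.5, 0.0],
   "total_occupancy": 0.0495
  }
 }
}
```

Reading the numbers: the three reweighted cluster populations and the
PC1/PC2 explained-variance fractions describe the conformational
distribution; the donor shares say which N–H drives the (here sparse,
total occupancy ≈ 0.05) IMHB network; the split-half contact
divergence of 0.017 is small, while the density divergence of 0.72 bits
correctly flags that 250 frames per half is far too little data for a
converged PC-density comparison — the noise floor falls below 0.02 bits
only around 10⁴ frames per half.

Individual stages are also available as subcommands
(`macrorew reweight|dpca|hbonds|convergence|charges|synth`), and the
library API mirrors them (`macrorew.reweight.compute_weights`,
`macrorew.dpca.fit_pca`, `macrorew.hbond.contact_occupancy`, ...).

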