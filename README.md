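# allonet

Network-centric allostery analysis of protein conformational ensembles.

Allosteric proteins — Hsp70-family chaperones are the motivating case —
transmit binding signals between distant sites through networks of residue
interactions and correlated motions. `allonet` turns a conformational
ensemble (multi-model PDB, MD snapshots, or a bundled synthetic generator)
into the quantities used to map that communication:

- **Dynamics maps** — iterative Kabsch superposition, B-factors
  B_i = (8π²/3)⟨|Δr_i|²⟩, dynamic cross-correlation matrices (DCCM), PCA
  with low-frequency-mode mobility profiles, rigid-body subdomain
  RMSD/rotation, and density-of-states population analysis on the
  (energy, RMSD) plane.
- **Force-constant rigidity profiles** — k_i = 3k_BT / Var(d_i), with d_i
  the mean distance from residue *i* to the rest of the protein; sharp
  peaks mark hinge residues.
- **Residue interaction networks** — edges from normalized side-chain
  contact counts I_ij = n_ij/(N_i·N_j)·100 (side-chain heavy atoms within
  4.5 Å; sqrt-denominator variant available), thresholded at I_min
  (default 2.5%), with a largest-connected-cluster transition scan.
- **Dynamics-weighted betweenness centrality** — edge weights
  w_ij = −log|C_ij|, Floyd–Warshall shortest paths with multiplicity
  counting, normalization by (N−1)(N−2)/2 within each connected component,
  ensemble averaging, distributions and mutation-cluster means.
- **Clique-percolation communities** — k ∈ {3, 4} cliques chained by the
  relaxed adjacency rule (sharing k−1 *or* k−2 nodes), filtered for
  dynamic stability (intact in > 75% of snapshots).
- **Residue depth / protection** — ensemble-averaged distance below the
  solvent-accessible surface, differential ΔRD maps between states, and
  sign agreement with hydrogen–deuterium-exchange peak-ratio tables.
- **MM-GBSA-style energetics** — ΔG_bind = ⟨ΔG_MM⟩ + ⟨ΔG_solv⟩ − ⟨TΔS⟩
  over per-snapshot term tables, σ·SASA nonpolar solvation
  (σ = 0.0072 kcal·mol⁻¹·Å⁻²), and computational alanine scanning by
  Cβ truncation (ΔΔG = ΔG_mut − ΔG_WT).

A synthetic-ensemble module generates elastic-network (ANM) Gaussian
ensembles with analytically known covariance, two-state population
mixtures, planted community graphs and Gaussian energy tables, so every
estimator in the package is tested against a closed-form or brute-force
oracle without any external data.

## Worked example

Run the pipeline on a synthetic 20-residue helical ensemble (100 ANM
frames, 3 pseudo side-chain atoms per residue):

```python
from allonet import pipeline as pl

config = pl.PipelineConfig.from_dict({
    "synthetic": {"n_residues": 20, "n_frames": 100, "seed": 1,
                  "sidechain_atoms": 3},
    "stages": ["bfactors", "forceconst", "network", "centrality",
               "communities"],
    "output_dir": "out",
    "params": {"denominator": "sqrt_product", "c_min": 0.0},
})
manifest = pl.run_pipeline(config)
print(pl.generate_report(manifest))
```

which prints:

```
# allonet run report

stage bfactors: ok
stage forceconst: ok
stage network: ok (LCC transition at I_min=8.5)
stage centrality: ok
stage communities: ok

top centrality residues:
  ('A', 8, ''): 0.2963
  ('A', 12, ''): 0.2538
  ('A', 10, ''): 0.2456
  ('A', 11, ''): 0.2366
  ('A', 9, ''): 0.1936
hubs: ('A', 6, ''); ('A', 8, ''); ('A', 9, ''); ('A', 12, '')
communities:
  none detected
force-constant peaks:
('A', 11, '') 73.3303
```

The reading: the mid-helix residues (8–12) carry the most shortest-path
traffic (betweenness up to 0.30 of all residue pairs), are the most
connected (hubs, degree ≥ 4), and residue 11 is the rigidity peak
(k ≈ 73 kcal·mol⁻¹·Å⁻²) — the toy's "hinge". The sparse helix contact
graph supports no 3-clique communities, which the report states
explicitly. The same analyses are exposed as CLI subcommands
(`allonet simulate | bfactors | pca | dccm | dos | forceconst | network |
centrality | communities | depth | mmgbsa | alascan | run | report`).

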