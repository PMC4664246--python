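# Methods

This note records the models, conventions and numerical choices behind
`allonet`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Indexing contract

Residues are identified everywhere by the tuple `(chain, resnum, icode)`,
never by bare sequence position, so insertion codes survive; a dense
0-based index is derived once per topology and reused by every module.
Covalent sequence neighbours are defined as residues on the same chain
whose numbers differ by exactly 1. Hydrogens are parsed but excluded from
all contact, depth and SASA computations; waters are stripped on load and
other hetero records dropped unless requested. Alternate locations keep
the highest-occupancy conformer (ties broken alphabetically), giving
deterministic parsing.

## Synthetic ensembles (what they emulate, what they do not)

The anisotropic network model (ANM) places harmonic springs
(γ = 1 kcal·mol⁻¹·Å⁻², cutoff 13 Å — conventional elastic-network
settings) between Cα-like nodes. The Hessian's six rigid-body modes are
removed by an eigenvalue threshold of 1e-8 relative to the largest
eigenvalue, and the fluctuation covariance is k_B·T·H⁺
(k_B = 0.0019872041 kcal·mol⁻¹·K⁻¹, T = 300 K). Ensembles are exact
Gaussian draws through the eigenbasis, so every second-moment statistic
(covariance, DCCM, B-factors, PCA spectrum) has a closed form to converge
to. The generator reproduces the *statistics* of an equilibrium harmonic
ensemble — it does not emulate force-field anharmonicity, solvent
friction, conformational transitions or time correlation, so passing
Monte-Carlo convergence tests demonstrates estimator correctness, not
fidelity to real chaperone dynamics.

Toy proteins carry an ideal helical (rise 1.5 Å, twist 100°, radius
2.3 Å) or extended (3.8 Å step) Cα trace, four backbone satellites and a
deterministic tetrahedral fan of pseudo side-chain carbons off the Cβ
direction, with a rotating residue-type assignment — enough geometric and
compositional structure for contact counting and normalization tables to
be nontrivial. Two-state mixtures draw each frame from conformer A with
probability p (default study condition p = 0.7) plus isotropic Gaussian
noise (0.3 Å in the population-shift tests — small against the
conformer separation, as for well-separated free-energy basins). Random
streams are named per operation and seeded from `(seed, operation name)`
via CRC32, so pipeline stages are independently reproducible across
processes.

## Superposition and dynamics maps

Superposition uses the Kabsch algorithm restricted to proper rotations
(det = +1). The mean-structure reference is found by fixed-point
iteration (fit → mean → refit, tolerance 1e-10 Å on the mean, up to 30
iterations), with the iteration *anchored at the current mean* so that a
converged ensemble is an exact fixed point — this makes repeated
superposition idempotent to < 1e-8 Å, which a frame-0 anchor does not
achieve (it re-rotates the converged gauge by the first frame's
fluctuation).

B-factors use the population mean square fluctuation; DCCM entries are
C_ij = ⟨Δr_i·Δr_j⟩/√(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) on one Cα per residue.
Zero-variance residues get C = 0 off-diagonal with a warning rather than
NaN propagation. "Lowest-frequency modes" are the largest-variance
principal components (amplitude and frequency are inversely related in a
harmonic system); PCA is offered on Cα (default) or backbone atoms, since
both conventions are in use. The density-of-states analysis histograms
(per-frame scalar, rigid-body RMSD) on a 50×50 grid by default, takes
8-neighbour local maxima above 10% of the global maximum as peaks (one
per plateau), and assigns every occupied bin to its nearest peak in
bin-index space to estimate basin populations. The per-frame scalar is
deliberately unconstrained — any energy-like series can be supplied.

## Force constants

k_i = 3k_BT/Var(d_i) with the population variance over frames. In CA
mode, d_i is the per-frame mean Cα–Cα distance to all residues except i
and its sequence neighbours i±1 (whose distances are nearly constant). In
all-atom mode (the default elsewhere documented), an atom-level k is
computed from each heavy atom's mean distance to heavy atoms of *other*
residues — atoms-to-atoms, the alternative residue-centroid reading is
not used — and averaged over the residue. Zero-variance units are capped
at k = 1e6 kcal·mol⁻¹·Å⁻² so downstream peak detection stays finite.
Peaks are interior local maxima within a ±3-residue window at ≥ 50% of
the profile maximum; endpoints are never peaks, so monotone profiles
yield none.

A note on the rigidity–flexibility relation: k_i measures the energetic
cost of changing a residue's *mean distance* to the protein, which
confounds stiffness with geometry (a central residue's isotropic motion
barely changes its mean distance). On free-free elastic bodies the rank
anticorrelation between positional variance and k is therefore moderate;
it becomes strong (ρ < −0.7 in the test suite) on cantilever-like
fixtures — a rigid base with a flexible arm — where variance is monotone
in position, which is the regime the measure is meant for.

## Interaction networks

n_ij counts heavy side-chain atom pairs within 4.5 Å (inclusive);
glycine's "side chain" is its Cα, otherwise glycine could never join the
network. Both printed normalizations are implemented:
I_ij = n_ij/(N_i·N_j)·100 (default, the equation as printed) and
n_ij/√(N_i·N_j)·100 (the form used in the underlying network
methodology). The N_i table is not published, so the default is
data-derived — the maximum (100th percentile, configurable) over residues
of each type of its total heavy-atom pair count with non-adjacent
residues, floored at 1 — and the table actually used is logged; a
user-supplied 2-column TSV overrides it. Note that with max-capacity
tables the product form yields small percentages, so sparse toys may have
no edges at I_min = 2.5%; the LCC transition scan (steepest backward
difference of the largest-component size over I_min = 1–15%, ties to the
smaller threshold) is the tool for locating a sensible threshold, and the
sqrt variant is the practical escape hatch.

Ensemble graph sets take every `stride`-th frame up to 1000 snapshots;
edge persistence is the exact containment fraction.

## Centrality

Edges are weighted w = −log|C| (floor 1e-8 caps the weight of near-zero
correlations). The correlated-intermediate filter removes edges with
|C| < 0.5 *before* pathfinding — equivalent to requiring every
consecutive pair along a path to be correlated; by default the magnitude
is used, so strong anticorrelations pass (a `signed` switch restricts to
C ≥ 0.5). All-pairs distances come from Floyd–Warshall
(`scipy.sparse.csgraph`); multiplicities σ(s,v) are accumulated per
source over nodes in order of increasing distance, and pass-through
counts are g_jk(i) = σ(j,i)·σ(i,k) wherever d(j,i)+d(i,k) = d(j,k)
within a relative tie tolerance of 1e-9 (an explicit tie rule is
unavoidable with floating-point weights; exactly-zero-weight edges, i.e.
|C| = 1 pairs, can in principle create tied cycles and are not given a
special rule). Betweenness is normalized by (N−1)(N−2)/2 over unordered
pairs with N the node's *component* size, so values live in [0, 1],
leaves score 0 and components smaller than 3 score 0. Ensemble centrality
is the arithmetic mean of per-snapshot profiles. The pass-through tensor
is O(n³) memory, sized for residue graphs up to a few hundred nodes.

## Communities

k-cliques (k = 3 and 4 both reported) are enumerated exactly; two cliques
are adjacent when they share ≥ k−1 nodes (classical clique percolation,
the `strict` rule) or ≥ k−2 nodes (`relaxed`, the default here). The
relaxation is applied literally at k = 3, where sharing a single node
suffices. "Intact in a snapshot" is not defined by the source protocol;
the conservative edge-level definition is used — every edge of every
member clique must be present — and a community is retained when intact
in strictly more than 75% of snapshots (751/1000 passes, 750/1000 does
not). Output ordering is size-descending then lexicographic, for
deterministic diffs.

## Residue depth and SASA

Both stand on the same deterministic surface machinery: a Fibonacci
lattice (no RNG) of 256 points per atom (64 in the faster energetics
default) on each heavy atom's solvent-accessible sphere (r_vdw + 1.4 Å
probe; built-in per-element radius table, carbon 1.70 Å). A point is
exposed iff outside every other atom's accessible sphere. Atom depth is
the distance to the nearest exposed point minus the atom's own accessible
radius, clamped at zero — surface atoms score ≈ 0, and the value is a
deterministic, parameter-light proxy for solvation-based residue-depth
methods rather than a reimplementation of them. Residue depth averages
over heavy atoms, then over snapshots. Angular sampling limits accuracy
to roughly 0.3 Å at 256 points/atom, which is also the oracle tolerance.
ΔRD = RD_A − RD_B is compared sign-wise with HDX peak-intensity ratios
using two one-sided thresholds (> 1.1 protected-in-A, < 1.0
protected-in-B); the band [1.0, 1.1] and ΔRD = 0 are excluded from the
agreement denominator.

## Energetics

The MM-GBSA bookkeeping is exact by construction:
ΔG_bind = ⟨ΔG_MM⟩ + ⟨ΔG_solv⟩ − ⟨TΔS⟩ with all Δ terms taken
complex − receptor − ligand per snapshot. The single-trajectory protocol
evaluates receptor and ligand on the *same* frame coordinates with no
re-minimization, so intramolecular terms cancel exactly — a deliberate
simplification (no minimizer is in scope) that should be kept in mind
when reading absolute values. The built-in pairwise backend uses
Lennard-Jones 12-6 with generic per-element parameters, Coulomb with a
distance-dependent dielectric ε(r) = 4r and constant
332.06 kcal·Å·mol⁻¹·e⁻², zero bonded energy on rigid snapshots, σ·SASA
nonpolar solvation (σ = 0.0072 kcal·mol⁻¹·Å⁻²) and a pluggable
electrostatic-solvation hook defaulting to 0 — reproducibility over
realism; absolute energies are **not** comparable to a full
force-field/GB treatment. Pair exclusions are crude on purpose: atoms
within one residue and across adjacent residues do not interact.
Entropy enters only as a user-supplied TΔS scalar (normal-mode entropy
is out of scope). Alanine scanning removes heavy side-chain atoms beyond
Cβ (Cβ keeps its coordinates; no mutant minimization) on every wild-type
snapshot and re-aggregates with the same backend; glycine and alanine
report ΔΔG = 0 with a note.

## Pipeline

One YAML config drives the stages; defaults pin the protocol parameters
(4.5 Å, I_min 2.5%, hub degree ≥ 4, k ∈ {3,4}, 75%, ≤ 1000 snapshots,
T = 300 K, σ = 0.0072, probe 1.4 Å), and every defaulted-but-unstated
parameter (probe radius, N_i table, peak thresholds, surface sampling) is
logged at WARN once per run. A manifest records the resolved config,
input checksums and output registry; deterministic stages are
bit-reproducible under a fixed seed. Exit codes: 0 ok, 2 config error,
3 data error, 4 numerical error.

## Problem sizes

The bundled analyses and checks run on deliberately small systems chosen
to make the statistics sharp rather than the structures realistic:
20-residue toys (140 heavy atoms) for network and estimator work, 50,000
Gaussian frames for DCCM/PCA convergence, 10,000 frames for B-factor and
rigidity statistics, 2,000 frames for two-state population recovery,
≤ 27-atom lattices for the depth oracle, and ~100 random graphs of ≤ 12
nodes for exhaustive betweenness enumeration.

## Known limitations

- The ANM generator cannot produce anharmonic or multi-basin dynamics;
  two-state mixtures fake the latter distributionally, not kinetically.
- Data-derived normalization tables depend on the input ensemble; results
  across datasets are only comparable under a shared override table.
- Residue depth is a surface-distance proxy, not an explicit-solvent
  depth; SASA-based depths differ near crevices narrower than the probe.
- The energetics backend is a generic surrogate; only differences and
  decompositions computed under the same backend are meaningful.
- Betweenness memory grows as O(n³) with component size; the intended
  regime is single-protein residue graphs, not large assemblies.
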