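# Methods

This note documents the models, conventions, and numerical choices behind
`gnmcompare`, and what the synthetic test bed does and does not establish.

## Elastic network model

The Gaussian Network Model treats a structure as beads joined by identical
harmonic springs.  Nodes are Cα atoms inside an inclusive residue window
(default [15, 135], matching the well-ordered core of streptavidin as
deposited) plus, for a holo structure, named ligand heavy atoms (default
the selenobiotin atoms N1, C2, C9, O12) that participate in the network
exactly like Cα nodes.  Two nodes interact iff their distance is at most
r_c; the Kirchhoff matrix Γ is the Laplacian of that contact graph.

Parameters:

- **r_c = 7.3 Å** — contact cutoff. The conventional Cα-GNM value; at
  ~3.8 Å Cα spacing it links sequence neighbours i±1 (and usually i±2)
  plus spatial neighbours.
- **γ = 1.0 (dimensionless)** — uniform spring constant. Every reported
  quantity (Pearson r, normalized correlations, profile ratios) is
  invariant under γ → cγ, so the absolute 3kT/γ prefactor of the
  fluctuations is never applied; fluctuation values are in arbitrary kT/γ
  units.
- **zero-mode tolerance 1e-8 × λ_max** — eigenvalues below it count as
  zero modes; for a valid Laplacian this equals the number of connected
  components.  Eigenvalues in [−tol, 0) are clipped to 0; anything more
  negative raises an invariant error.
- **n_slowest = 10** — slow-mode profile depth for the report. Modes are
  ranked by ascending eigenvalue (variance ∝ 1/λ); ties keep eigensolver
  order.  Eigenvector signs are fixed (largest-magnitude component
  positive) so serialized output is reproducible.

Cross-correlations are computed over **all** non-zero modes; the
fluctuation matrix then equals the Moore–Penrose pseudoinverse of Γ (tested
against `np.linalg.pinv` at a matched rcond).  B-factor validation
correlates the diagonal ⟨ΔR_i²⟩ with deposited B-factors over Cα nodes
only: ligand atoms have no unambiguous theoretical/experimental pairing and
are excluded from the correlation (and from difference sections).

## Apo/holo comparison

Chains are paired by geometry, not label: the assemblies are superposed,
chains assigned one-to-one by minimum mean inter-Cα distance
(`scipy.optimize.linear_sum_assignment`), and the fit refined on the
assignment.  Because homotetramers are nearly point-group symmetric, a
single greedy start can lock onto a symmetry-related assignment; the
implementation therefore tries every "first chain of A ↔ chain X of B"
hypothesis and keeps the lowest-total-cost assignment.  The mapping is
recorded in the report rather than hard-coding chain letters.

Difference sections (intrachain per mapped pair, interchain per pair of
mapped pairs) subtract holo-minus-apo cross-correlations over the common
residue grid; residues present in only one structure are dropped pairwise
and listed.  Positive entries mean the correlation increased in holo.

## Superposition

`kabsch_superpose` is the closed-form least-squares rigid fit (SVD of the
weighted covariance; a reflection, if optimal, is corrected to the nearest
proper rotation).  `iterative_superpose` repeats the fit, discarding pairs
whose deviation exceeds **2.0 × current RMSD**, for at most **5 cycles** —
the convention common to molecular-graphics aligners, whose exact published
protocols vary; reproduced literature RMSDs should therefore be read with
a ±0.05 Å margin.  Atom pairing uses Cα with equal residue numbers
(side-chain atoms excluded); an "overall" RMSD across several chain fits is
the RMSD over the union of retained pairs.

## Polar contacts and pocket census

A polar interaction is any N/O–N/O heavy-atom pair within **3.6 Å**.  No
donor/acceptor chemistry, angle term, or hydrogens (structures are X-ray;
sulfur excluded).  Intra-residue pairs never count; sequential backbone
N(i+1)–O(i) pairs count by default (`include_adjacent_backbone=False` to
exclude).  A pocket census for one chain pairs the pocket-residue atoms
against: themselves, every water oxygen, and polar atoms of all other
residues.  `n_waters` counts distinct waters with ≥ 1 contact to a pocket
atom; `n_polar_interactions` counts contacts.  Water–water contacts among
coordinated waters are excluded by default (`include_water_water=True`
adds them) — the published per-chain counts do not state their counting
protocol, so these flags make the conventions explicit and reproduction
approximate rather than exact.

Two pocket presets ship because two slightly different residue lists
circulate for the same biotin pocket: `canonical8` (Asn23, Ser42, Tyr43,
Ser45, Asn49, Ser88, Thr90, Asp128 — the classic hydrogen-bond set) and
`compact7` (Asn23, Ser27, Tyr43, Ser45, Asn49, Ser88, Asp128).  Which list
a given published figure used is not always stated; the census takes the
list (or preset name) as input.

## Structure input conventions

Parsing goes through gemmi.  Hydrogens are dropped.  Altloc resolution
keeps, per atom name, the conformer with the highest occupancy (tie →
lexicographically first altloc), matching common single-conformer
analysis practice.  Waters are residues named HOH/WAT, reduced to their
oxygen.  Residue numbering is taken from the file as deposited;
insertion-coded residues are excluded from the integer residue window.  A
ligand with its own chain id is assigned to the nearest protein chain by
minimum atom distance.  The PDB writer emits deterministic fixed-width
records so that generated fixtures are byte-identical across runs.

## Synthetic test bed

The generators produce the geometric/statistical features the analyses
assume, chosen once as study conditions:

- Monomer: ideal α-helical Cα trace (1.5 Å rise, 100°/residue, radius
  solved for 3.8 Å spacing), 40 residues (numbered 15–54), with 0.15 Å
  Gaussian jitter applied to the monomer **before** replication — chains
  stay exactly congruent.
- Tetramer: four rigid copies under 222 (D2) rotations, offset scanned so
  the A–B dimer interface has ≥ 8 contacts at 7.3 Å with no steric
  collapse (< 2.5 Å) and a connected graph.  A small per-chain rigid
  rotation (0.02 rad) breaks exact point-group symmetry, as in real
  crystal structures; without it the apo↔holo chain correspondence would
  be mathematically ambiguous.  Draws that leave no clash-free window are
  redrawn deterministically.
- B-factors: B = a·⟨ΔR_i²⟩ + b + N(0, σ) from the assembly's **own** GNM,
  truncated at 0.01; a = 30 Å², b = 2 Å², σ defaulting to 5 % of the mean
  signal (noiseless real B-factors have no declared noise model — this is
  purely a test-harness choice).  Stored at PDB 2-decimal precision.
- Holo: the apo assembly plus a rigid planar 4-atom pseudo-ligand (names
  N1/C2/C9/O12, residue BTN, 1.4–2.5 Å internal spacing) placed at the
  most buried clash-free distance from the designated pocket residues —
  emulating a ligand enclosed by its pocket — plus a < 1 Å displacement of
  the pocket residues toward the ligand, recomputed B-factors, and an
  optional chain relabelling recorded as ground truth.
- Pocket scenes: polar pocket atoms with n_near waters at exactly d_near
  and n_far decoys at d_far, rejection-sampled so no accidental contact
  exists (verified by a final brute-force scan).

What passing these tests shows: the algebra (spectra, pseudoinverse,
correlation bounds), the selection/ordering contracts, the mapping and
rejection logic, and the census counting are correct on inputs whose
ground truth is known exactly.  What they do not show: agreement with real
crystallographic data — real structures have side chains, alternate
conformations, anisotropic packing, correlated B-factor errors, and
crystal contacts that the generator deliberately omits.  The
deposited-structure acceptance test covers that gap when the coordinate
files for 7EK8/7EK9/5JD2 are available locally.

On ligand-induced stiffening: adding the ligand pseudo-nodes lowers the
pocket residues' mean-square fluctuations computed over the full non-zero
spectrum (the property asserted in the tests).  Restricted to the 10
slowest modes of this synthetic geometry the sign is not stable — ligand
attachment also reshuffles which collective modes load the pocket — so the
slow-mode report emits both raw and per-chain-normalized profiles and the
stiffening claim is made at the full-spectrum limit.

## Known limitations

- Isotropic GNM only: no anisotropic (3N×3N) network, no mode animation.
- The holo node bookkeeping of the original streptavidin study is
  internally inconsistent (486 nodes cannot yield 488 non-zero modes); the
  package reports N and the zero-mode count and leaves the discrepancy to
  the reader.
- Exact reproduction of published per-chain census counts depends on an
  unstated counting protocol; the flags above bound, but cannot remove,
  that ambiguity.
- The iterative-rejection protocol is a convention, not a published
  algorithm; printed RMSDs from graphics programs are matched only
  approximately.
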