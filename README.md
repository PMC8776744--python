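# gnmcompare

Comparative structural-dynamics analysis of ligand-free (apo) and
ligand-bound (holo) multimeric protein assemblies with the Gaussian Network
Model (GNM), written for the streptavidin–biotin system but applicable to
any multi-chain Cα structure.

Streptavidin is a homotetramer whose four biotin-binding pockets are capped
by a flexible loop (L3/4, residues 45–52) that closes over the ligand.
Understanding how ligand binding redistributes the tetramer's collective
motions — and how the pocket's water/polar-contact network differs between
chains — requires comparing apo and holo structures with one consistent
coarse-grained model.  This package provides that comparison as a tested
library: GNM construction with ligand pseudo-nodes, B-factor validation,
cross-correlation difference maps, slow-mode fluctuation profiles,
outlier-rejected superposition, and a binding-pocket polar-contact/water
census.

## Model

Each Cα (residues 15–135 by default) and, in the holo structure, each of
the ligand atoms N1, C2, C9 and O12 becomes a node of an elastic network.
Nodes closer than r_c = 7.3 Å are joined by identical springs (γ = 1), giving
the Kirchhoff (contact-graph Laplacian) matrix

    Γ_ij = −γ              if i ≠ j and d_ij ≤ r_c
    Γ_ij = 0               if i ≠ j and d_ij > r_c
    Γ_ii = −Σ_{j≠i} Γ_ij

With eigenpairs Γ u_k = λ_k u_k (λ ascending, one zero mode per connected
component), residue fluctuations and cross-correlations follow from the
pseudoinverse:

    ⟨ΔR_i · ΔR_j⟩ ∝ Σ_{λ_k>0} λ_k⁻¹ u_ki u_kj
    C_ij = ⟨ΔR_i·ΔR_j⟩ / √(⟨ΔR_i²⟩⟨ΔR_j²⟩)

The diagonal ⟨ΔR_i²⟩ is proportional to the crystallographic B-factor
(B_i = 8π²⟨ΔR_i²⟩/3) and is validated by Pearson correlation against the
deposited B-factors.  Slow-mode profiles restrict the sum to the k slowest
non-zero modes (variance ∝ 1/λ).  Apo/holo difference maps subtract
cross-correlation sections over chains paired by geometry (minimum mean
inter-Cα distance under a one-to-one assignment), not by label.  Polar
interactions are N/O–N/O heavy-atom pairs within 3.6 Å; a pocket water is
"coordinated" when it has at least one such contact to a pocket residue.

## Worked example

`examples/02_apo_holo_comparison.py` generates a matched synthetic
apo/holo tetramer pair (the holo copy carries a 4-atom ligand pseudo-group
and relabelled chains) and runs the full pipeline:

```
apo:  160 nodes, 159 non-zero modes, B-factor r = 0.991
holo: 164 nodes (4 ligand), B-factor r = 0.991
chain mapping (apo -> holo): {'A': 'B', 'B': 'C', 'C': 'D', 'D': 'A'}
ground truth mapping:        {'A': 'B', 'B': 'C', 'C': 'D', 'D': 'A'}
intrachain A difference section: (40, 40), range [-0.042, +0.111]
apo vs holo RMSD over mapped chains: 0.000 A
```

160 = 4 chains × 40 residues; a single zero mode confirms the contact
graph is connected; r = 0.991 says the network reproduces the generated
B-factors up to their injected noise; the mapping is recovered purely from
geometry despite the relabelling; positive difference entries mark residue
pairs whose motions became more correlated with the ligand wired in.  The
other examples cover single-structure mode analysis, the pocket water
census, and superposition/chain mapping.

A thin CLI wraps the same calls: `gnmcompare gnm|compare|contacts|
superpose|simulate|fetch` (see `gnmcompare --help`).

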