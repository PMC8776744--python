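"""Full apo-vs-holo comparison on a matched synthetic pair.

The holo assembly carries a 4-atom ligand pseudo-group (atoms N1, C2, C9,
O12) wired into the elastic network, with relabelled chains.  The pipeline
maps chains by geometry, subtracts cross-correlation sections over the
mapped chains, and reports B-factor validation, RMSDs, and pocket censuses.
"""

from gnmcompare import AnalysisConfig, run_comparison
from gnmcompare.synthetic import LigandSpec, SyntheticSpec, make_apo_holo_pair

spec = SyntheticSpec(seed=1, ligand=LigandSpec(),
                     chain_relabel={"A": "B", "B": "C", "C": "D", "D": "A"})
apo, holo, truth = make_apo_holo_pair(spec)

report = run_comparison(apo, holo, AnalysisConfig())
d = report.to_dict()

print(f"apo:  {d['apo']['node_count']} nodes, "
      f"{d['apo']['nonzero_mode_count']} non-zero modes, "
      f"B-factor r = {d['apo']['bfactor_pearson_r']:.3f}")
print(f"holo: {d['holo']['node_count']} nodes "
      f"({d['holo']['ligand_node_count']} ligand), "
      f"B-factor r = {d['holo']['bfactor_pearson_r']:.3f}")
print("chain mapping (apo -> holo):",
      {p["apo"]: p["holo"] for p in d["chain_mapping"]})
print("ground truth mapping:       ", truth.chain_map)
lm = report.differences["intrachain_A"]
print(f"intrachain A difference section: {lm.values.shape}, "
      f"range [{lm.values.min():+.3f}, {lm.values.max():+.3f}]")
print(f"apo vs holo RMSD over mapped chains: "
      f"{d['superposition']['apo_vs_holo']['overall_rmsd']:.3f} A")

# Positive entries in the difference section mark residue pairs whose
# motions became more correlated once the ligand joined the network; the
# RMSD is small because the holo assembly differs only by the sub-Angstrom
# pocket-loop shift (large deviations are outlier-rejected).
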