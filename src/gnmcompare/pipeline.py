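"""Orchestration of the full apo-vs-holo comparative analysis.

``run_comparison`` composes the stages: structure parsing, GNM node
selection (ligand pseudo-nodes on the holo side), Kirchhoff build and
eigendecomposition, B-factor validation, chain mapping by spatial
correspondence, difference cross-correlation sections over the mapped
chains, slow-mode fluctuation profiles (raw and per-chain normalized),
superposition RMSDs, and per-chain pocket censuses.  The report is fully
deterministic: identical inputs and config give byte-identical JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import contacts as _contacts
from . import gnm as _gnm
from .errors import PipelineError, SelectionError
from .gnm import (
    bfactor_correlation,
    build_kirchhoff,
    cross_correlation,
    decompose,
    fluctuations,
    slow_mode_profile,
    theoretical_bfactors,
)
from .structures import NodeSet, Structure, parse_structure, select_gnm_nodes
from .superpose import ChainMapping, map_chains, superpose_chains, superpose_structures


@dataclass
class AnalysisConfig:
    """Defaults reproduce the study settings for streptavidin."""

    residue_range: tuple[int, int] = (15, 135)
    cutoff: float = 7.3                  # GNM contact cutoff, Å
    gamma: float = 1.0                   # spring constant (scale-free)
    ligand_resname: str = "BTN"
    ligand_atom_names: tuple[str, ...] = ("N1", "C2", "C9", "O12")
    n_slowest: int = 10
    polar_cutoff: float = 3.6            # polar-contact cutoff, Å
    pocket_preset: str = "canonical8"
    pocket_residues: tuple | None = None  # overrides the preset when given
    max_cycles: int = 5                  # superposition rejection cycles
    reject_sigma: float = 2.0
    zero_tol: float = 1e-8
    include_water_water: bool = False
    include_adjacent_backbone: bool = True
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.residue_range
        if lo > hi:
            raise ValueError("residue_range must be (lo, hi) with lo <= hi")
        for name in ("cutoff", "gamma", "n_slowest", "polar_cutoff",
                     "max_cycles", "reject_sigma", "zero_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def pocket(self):
        return (self.pocket_residues if self.pocket_residues is not None
                else self.pocket_preset)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("residue_range", "ligand_atom_names", "pocket_residues"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(
                    tuple(v) if isinstance(v, list) else v for v in raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["residue_range"] = list(self.residue_range)
        d["ligand_atom_names"] = list(self.ligand_atom_names)
        if self.pocket_residues is not None:
            d["pocket_residues"] = [list(r) if isinstance(r, tuple) else r
                                    for r in self.pocket_residues]
        return d


@dataclass
class LabeledMatrix:
    """A matrix with residue-number row/column labels and a drop report."""

    values: np.ndarray
    row_labels: list
    col_labels: list
    dropped: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_labels,
                            columns=self.col_labels)


def difference_cross_correlation(
    cc_holo: _gnm.CrossCorrelationMap,
    cc_apo: _gnm.CrossCorrelationMap,
    mapping: ChainMapping,
    kind: str,
    chains: tuple[str, ...],
) -> LabeledMatrix:
    """Element-wise holo − apo cross-correlation over a common residue grid.

    ``kind`` is ``"intrachain"`` (chains = one apo chain id) or
    ``"interchain"`` (chains = two apo chain ids).  Apo chain ids are
    translated to holo ids through the mapping; ligand nodes are excluded
    and residues present in only one structure are dropped pairwise (listed
    in ``dropped``).  Positive entries mean the correlation increased in
    the holo structure.
    """
    if kind == "intrachain":
        (ca,) = chains
        cb = ca
    elif kind == "interchain":
        ca, cb = chains
    else:
        raise ValueError(f"kind must be intrachain|interchain, got {kind!r}")
    ha, hb = mapping.b_for(ca), mapping.b_for(cb)

    def common(cc, chain):
        return {int(n.resnum): i for i, n in enumerate(cc.nodes.nodes)
                if n.chain_id == chain and n.kind == "calpha"}

    rows_a, rows_h = common(cc_apo, ca), common(cc_holo, ha)
    cols_a, cols_h = common(cc_apo, cb), common(cc_holo, hb)
    row_common = sorted(set(rows_a) & set(rows_h))
    col_common = sorted(set(cols_a) & set(cols_h))
    if not row_common or not col_common:
        raise SelectionError(
            f"empty residue intersection for section {kind} {chains}")
    dropped = sorted((set(rows_a) ^ set(rows_h)) | (set(cols_a) ^ set(cols_h)))
    ia = np.array([rows_a[r] for r in row_common])
    ja = np.array([cols_a[r] for r in col_common])
    ih = np.array([rows_h[r] for r in row_common])
    jh = np.array([cols_h[r] for r in col_common])
    diff = cc_holo.values[np.ix_(ih, jh)] - cc_apo.values[np.ix_(ia, ja)]
    return LabeledMatrix(diff, row_common, col_common, dropped)


@dataclass
class StructureAnalysis:
    """Single-structure GNM results bundled for the report."""

    structure: Structure
    nodes: NodeSet
    modes: _gnm.ModeSet
    cc: _gnm.CrossCorrelationMap
    bfactor_r: float
    slow_profile: np.ndarray
    n_slowest_used: int

    def summary(self) -> dict:
        return {
            "structure_id": self.structure.id,
            "node_count": len(self.nodes),
            "calpha_count": int(len(self.nodes.indices(kind="calpha"))),
            "ligand_node_count": int(len(self.nodes.indices(kind="ligand"))),
            "zero_mode_count": int(self.modes.zero_mode_count),
            "nonzero_mode_count": int(self.modes.n_nonzero),
            "bfactor_pearson_r": round(self.bfactor_r, 6),
            "n_slowest_used": self.n_slowest_used,
        }


def analyse_structure(
    structure: Structure,
    config: AnalysisConfig,
    with_ligand: bool,
) -> StructureAnalysis:
    """GNM analysis of one structure under the configured settings."""
    lo, hi = config.residue_range
    nodes = select_gnm_nodes(
        structure, lo, hi,
        config.ligand_resname if with_ligand else None,
        config.ligand_atom_names if with_ligand else ())
    modes = decompose(build_kirchhoff(nodes, config.cutoff, config.gamma),
                      config.zero_tol)
    fl = fluctuations(modes)
    cc = cross_correlation(fl)
    theo = theoretical_bfactors(fl)
    # B-factor validation over Cα nodes only (ligand atoms have no
    # unambiguous experimental pairing)
    ca = nodes.indices(kind="calpha")
    r = bfactor_correlation(theo[ca], nodes.bfactors[ca])
    k = min(config.n_slowest, modes.n_nonzero)
    profile = slow_mode_profile(modes, k)
    return StructureAnalysis(structure, nodes, modes, cc, r, profile, k)


@dataclass
class ComparisonReport:
    config: AnalysisConfig
    apo: StructureAnalysis
    holo: StructureAnalysis
    mapping: ChainMapping
    differences: dict[str, LabeledMatrix]
    superposition: dict
    pocket_censuses: dict[str, list]

    def _profiles(self, ana: StructureAnalysis) -> dict:
        out = {}
        for cid in ana.nodes.chain_ids:
            idx = ana.nodes.indices(chain=cid, kind="calpha")
            raw = ana.slow_profile[idx]
            out[cid] = {
                "resnums": [int(r) for r in ana.nodes.resnums(cid)],
                "raw": [round(float(v), 8) for v in raw],
                "normalized": [round(float(v), 8) for v in raw / raw.sum()],
            }
        return out

    def to_dict(self, include_matrices: bool = False) -> dict:
        d = {
            "config": self.config.to_dict(),
            "apo": self.apo.summary(),
            "holo": self.holo.summary(),
            "chain_mapping": [
                {"apo": a, "holo": b, "rmsd": round(r, 6)}
                for a, b, r in self.mapping.pairs],
            "slow_mode_profiles": {
                "apo": self._profiles(self.apo),
                "holo": self._profiles(self.holo),
            },
            "superposition": self.superposition,
            "pocket_censuses": {
                which: [c.to_dict() for c in censuses]
                for which, censuses in self.pocket_censuses.items()},
            "difference_sections": {},
        }
        for name, lm in self.differences.items():
            entry = {
                "rows": list(lm.row_labels),
                "cols": list(lm.col_labels),
                "dropped_residues": list(lm.dropped),
                "min": round(float(lm.values.min()), 6),
                "max": round(float(lm.values.max()), 6),
                "mean": round(float(lm.values.mean()), 6),
            }
            if include_matrices:
                entry["values"] = [[round(float(v), 6) for v in row]
                                   for row in lm.values]
            d["difference_sections"][name] = entry
        return d

    def to_json(self, include_matrices: bool = False) -> str:
        return json.dumps(self.to_dict(include_matrices), indent=2,
                          sort_keys=True)

    def save(self, out_dir: str | Path) -> None:
        """Write report.json plus TSV matrices (differences, correlations)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json() + "\n")
        for name, lm in self.differences.items():
            lm.to_frame().to_csv(out / f"diff_{name}.tsv", sep="\t")
        for which, ana in (("apo", self.apo), ("holo", self.holo)):
            pd.DataFrame(ana.cc.values, index=ana.nodes.labels,
                         columns=ana.nodes.labels).to_csv(
                out / f"cc_{which}.tsv", sep="\t")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(name, e) from e
        return wrapped
    return deco


def run_comparison(
    apo_source: str | Path | Structure,
    holo_source: str | Path | Structure,
    config: AnalysisConfig | None = None,
) -> ComparisonReport:
    """Full apo-vs-holo comparative analysis; see module docstring."""
    config = config or AnalysisConfig()

    @_stage("parse")
    def _load(src) -> Structure:
        return src if isinstance(src, Structure) else parse_structure(src)

    apo_st = _load(apo_source)
    holo_st = _load(holo_source)

    apo = _stage("gnm-apo")(analyse_structure)(apo_st, config, with_ligand=False)
    holo = _stage("gnm-holo")(analyse_structure)(holo_st, config, with_ligand=True)

    mapping = _stage("chain-mapping")(map_chains)(apo_st, holo_st)

    @_stage("difference-sections")
    def _diffs() -> dict[str, LabeledMatrix]:
        out = {}
        apo_chains = [a for a, _, _ in mapping.pairs]
        for ca in apo_chains:
            out[f"intrachain_{ca}"] = difference_cross_correlation(
                holo.cc, apo.cc, mapping, "intrachain", (ca,))
        for i, ca in enumerate(apo_chains):
            for cb in apo_chains[i + 1:]:
                out[f"interchain_{ca}{cb}"] = difference_cross_correlation(
                    holo.cc, apo.cc, mapping, "interchain", (ca, cb))
        return out

    differences = _diffs()

    @_stage("superposition")
    def _superpositions() -> dict:
        out: dict = {}
        for which, st in (("apo", apo_st), ("holo", holo_st)):
            if len(st.chains) > 1:
                res = superpose_chains(
                    st, residue_range=config.residue_range,
                    max_cycles=config.max_cycles,
                    reject_sigma=config.reject_sigma)
                out[f"{which}_intra_chain"] = {
                    "reference_chain": res["reference_chain"],
                    "overall_rmsd": round(res["overall_rmsd"], 6),
                    "paired_count": res["paired_count"],
                    "per_chain_rmsd": {
                        cid: round(r.rmsd, 6)
                        for cid, r in res["per_chain"].items()},
                }
        cross = superpose_structures(
            apo_st, holo_st, mapping,
            max_cycles=config.max_cycles, reject_sigma=config.reject_sigma)
        out["apo_vs_holo"] = {
            "overall_rmsd": round(cross.rmsd, 6),
            "paired_count": cross.paired_count,
            "rejected_count": len(cross.rejected_pairs),
            "cycles_run": cross.cycles_run,
        }
        return out

    superposition = _superpositions()

    @_stage("pocket-census")
    def _censuses() -> dict:
        return {
            which: _contacts.census_all_chains(
                st, config.pocket, config.polar_cutoff,
                config.include_water_water, config.include_adjacent_backbone)
            for which, st in (("apo", apo_st), ("holo", holo_st))}

    censuses = _censuses()

    return ComparisonReport(config, apo, holo, mapping, differences,
                            superposition, censuses)
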