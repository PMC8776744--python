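"""Macromolecular structure model, PDB/mmCIF reading, and GNM node selection.

The in-memory model is deliberately small: protein chains hold residues of
heavy atoms (hydrogens are dropped on input — the analyses are heavy-atom
based), water oxygens are kept in a flat list, and every non-water hetero
residue (e.g. a bound ligand) is kept as a :class:`HeteroGroup`.  Parsing is
delegated to :mod:`gemmi`; altloc resolution keeps, per atom name, the
conformer with the highest occupancy (ties broken by the lexicographically
first altloc identifier).

A :class:`NodeSet` is the ordered list of coarse-grained network nodes used
to build a Kirchhoff matrix: one node per Cα in a residue-number window,
plus (optionally) named ligand atoms appended after all Cα nodes.
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    EmptySelectionError,
    EmptyStructureError,
    InputError,
    InvariantError,
    ParseError,
    SelectionError,
)

WATER_RESNAMES = {"HOH", "WAT"}

#: three-letter codes treated as polymer residues when a file carries no
#: explicit ATOM/HETATM distinction (e.g. minimal mmCIF).
AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}

POLAR_ELEMENTS = {"N", "O"}


@dataclass(frozen=True)
class Atom:
    """A single heavy atom with crystallographic annotations."""

    name: str
    element: str
    coords: tuple[float, float, float]
    bfactor: float
    occupancy: float
    altloc: str
    resname: str
    resnum: int
    icode: str
    chain_id: str
    het: bool = False

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)

    @property
    def residue_key(self) -> tuple[str, str, int, str]:
        return (self.chain_id, self.resname, self.resnum, self.icode)

    @property
    def key(self) -> tuple[str, str, int, str, str]:
        return (self.chain_id, self.resname, self.resnum, self.icode, self.name)

    @property
    def is_water(self) -> bool:
        return self.resname in WATER_RESNAMES

    @property
    def is_polar(self) -> bool:
        return self.element in POLAR_ELEMENTS

    def moved(self, xyz: np.ndarray) -> "Atom":
        return replace(self, coords=(float(xyz[0]), float(xyz[1]), float(xyz[2])))


@dataclass
class Residue:
    name: str
    number: int
    icode: str
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)

    @property
    def atoms(self) -> list[Atom]:
        return [a for r in self.residues for a in r.atoms]

    def residue(self, number: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.number == number and r.icode == icode:
                return r
        return None

    def calpha(self, lo: int | None = None, hi: int | None = None) -> list[Atom]:
        """Cα atoms in residue-number order, optionally within [lo, hi].

        Insertion-coded residues are excluded (the selection contract is an
        integer residue window).
        """
        out = []
        for r in sorted(self.residues, key=lambda r: r.number):
            if r.icode:
                continue
            if lo is not None and r.number < lo:
                continue
            if hi is not None and r.number > hi:
                continue
            ca = r.atom("CA")
            if ca is not None and ca.element != "CA":  # guard against calcium
                out.append(ca)
        return out


@dataclass
class HeteroGroup:
    resname: str
    chain_id: str
    resnum: int
    icode: str
    atoms: list[Atom] = field(default_factory=list)


@dataclass
class Structure:
    """Parsed macromolecular model: chains / waters / hetero groups."""

    id: str
    chains: list[Chain] = field(default_factory=list)
    waters: list[Atom] = field(default_factory=list)
    hetero_groups: list[HeteroGroup] = field(default_factory=list)

    @property
    def chain_ids(self) -> list[str]:
        return [c.id for c in self.chains]

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise SelectionError(
            f"unknown chain {chain_id!r}; available chains: {self.chain_ids}"
        )

    @property
    def protein_atoms(self) -> list[Atom]:
        return [a for c in self.chains for a in c.atoms]

    @property
    def n_atoms(self) -> int:
        n = len(self.protein_atoms) + len(self.waters)
        n += sum(len(g.atoms) for g in self.hetero_groups)
        return n

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigidly transformed copy (x -> R x + t)."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)

        def mv(a: Atom) -> Atom:
            return a.moved(R @ a.xyz + t)

        chains = [
            Chain(c.id, [Residue(r.name, r.number, r.icode, [mv(a) for a in r.atoms])
                         for r in c.residues])
            for c in self.chains
        ]
        waters = [mv(a) for a in self.waters]
        het = [HeteroGroup(g.resname, g.chain_id, g.resnum, g.icode,
                           [mv(a) for a in g.atoms])
               for g in self.hetero_groups]
        return Structure(self.id, chains, waters, het)


# ---------------------------------------------------------------------------
# parsing

def _looks_like_cif(text: str) -> bool:
    head = text[:4000]
    return "_atom_site." in head or head.lstrip().startswith("data_")


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Per atom name keep the highest-occupancy conformer (tie: first altloc)."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            by_name[a.name] = []
            order.append(a.name)
        by_name[a.name].append(a)
    out = []
    for name in order:
        group = by_name[name]
        best = min(group, key=lambda a: (-a.occupancy, a.altloc))
        out.append(best)
    return out


def parse_structure(source: str | Path, fmt: str = "auto") -> Structure:
    """Read a PDB or mmCIF file (or literal text) into a :class:`Structure`.

    Parameters
    ----------
    source:
        Path to a file, or the file content itself (detected by the presence
        of a newline).
    fmt:
        ``"pdb"``, ``"mmcif"`` or ``"auto"`` (dispatch on extension/content).
    """
    import gemmi

    text: str
    sid = "structure"
    src = str(source)
    if "\n" not in src:
        path = Path(src)
        if not path.is_file():
            raise InputError(f"cannot read structure file: {path}")
        try:
            text = path.read_text()
        except OSError as e:
            raise InputError(f"cannot read structure file: {path}: {e}") from e
        sid = path.stem
        if fmt == "auto":
            suffix = path.suffix.lower()
            if suffix in {".cif", ".mmcif"}:
                fmt = "mmcif"
            elif suffix in {".pdb", ".ent"}:
                fmt = "pdb"
    else:
        text = src
    if fmt == "auto":
        fmt = "mmcif" if _looks_like_cif(text) else "pdb"

    try:
        if fmt == "pdb":
            st = gemmi.read_pdb_string(text)
        elif fmt == "mmcif":
            doc = gemmi.cif.read_string(text)
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            raise ValueError(f"unknown format {fmt!r}")
        if st.name:
            sid = st.name.strip().lower() or sid
    except ParseError:
        raise
    except Exception as e:  # gemmi raises RuntimeError/ValueError
        raise ParseError(f"failed to parse {fmt} input ({sid}): {e}") from e

    if len(st) == 0:
        raise EmptyStructureError(f"{sid}: no models in file")
    model = st[0]

    chains: list[Chain] = []
    waters: list[Atom] = []
    het_index: dict[tuple, HeteroGroup] = {}

    for gchain in model:
        chain = Chain(gchain.name)
        for gres in gchain:
            resname = gres.name.strip().upper()
            icode = (gres.seqid.icode or "").strip()
            atoms: list[Atom] = []
            for ga in gres:
                element = ga.element.name.upper()
                if element in {"H", "D"}:
                    continue
                xyz = (ga.pos.x, ga.pos.y, ga.pos.z)
                if not all(math.isfinite(v) for v in xyz):
                    raise ParseError(
                        f"non-finite coordinates at {gchain.name}/{resname}"
                        f"{gres.seqid.num}/{ga.name}"
                    )
                atoms.append(Atom(
                    name=ga.name.strip(),
                    element=element,
                    coords=xyz,
                    bfactor=float(ga.b_iso),
                    occupancy=float(ga.occ),
                    altloc=(ga.altloc or "").strip(),
                    resname=resname,
                    resnum=int(gres.seqid.num),
                    icode=icode,
                    chain_id=gchain.name,
                    het=(gres.het_flag == "H"),
                ))
            atoms = _resolve_altlocs(atoms)
            if not atoms:
                continue
            if resname in WATER_RESNAMES:
                # keep only the oxygen of each water molecule
                waters.extend(a for a in atoms if a.element == "O")
            elif gres.het_flag == "H" or (gres.het_flag != "A"
                                          and resname not in AMINO_ACIDS):
                key = (resname, gchain.name, int(gres.seqid.num), icode)
                grp = het_index.setdefault(key, HeteroGroup(*key))
                grp.atoms.extend(atoms)
            else:
                chain.residues.append(
                    Residue(resname, int(gres.seqid.num), icode, atoms))
        if chain.residues:
            chains.append(chain)

    structure = Structure(sid, chains, waters, list(het_index.values()))
    if structure.n_atoms == 0:
        raise EmptyStructureError(f"{sid}: no ATOM/HETATM records")
    return structure


# ---------------------------------------------------------------------------
# minimal PDB writing (fixed-width, deterministic)

def write_pdb(structure: Structure, path: str | Path | None = None) -> str:
    """Serialize to minimal fixed-width PDB text (deterministic byte output)."""

    def fmt_name(name: str) -> str:
        # Standard convention: 1-2 letter elements start at column 14 when
        # the name is <= 3 characters.
        if len(name) >= 4:
            return name[:4]
        return f" {name:<3s}"

    lines: list[str] = []
    serial = 1

    def atom_line(record: str, a: Atom) -> str:
        nonlocal serial
        line = (
            f"{record:<6s}{serial:>5d} {fmt_name(a.name)}{a.altloc or ' ':1s}"
            f"{a.resname:>3s} {a.chain_id[:1]:1s}{a.resnum:>4d}{a.icode or ' ':1s}"
            f"   {a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}"
            f"{a.occupancy:6.2f}{a.bfactor:6.2f}          {a.element:>2s}"
        )
        serial += 1
        return line

    for chain in structure.chains:
        for res in chain.residues:
            for a in res.atoms:
                lines.append(atom_line("ATOM", a))
        lines.append(f"TER   {serial:>5d}")
        serial += 1
    for grp in structure.hetero_groups:
        for a in grp.atoms:
            lines.append(atom_line("HETATM", a))
    for a in structure.waters:
        lines.append(atom_line("HETATM", a))
    lines.append("END")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# GNM node selection

@dataclass(frozen=True)
class GNMNode:
    chain_id: str
    resnum: int
    atom_name: str
    kind: str  # "calpha" | "ligand"
    coords: tuple[float, float, float]
    bfactor: float

    @property
    def label(self) -> str:
        return f"{self.chain_id}:{self.resnum}:{self.atom_name}"


@dataclass
class NodeSet:
    """Ordered coarse-grained node list feeding the Kirchhoff matrix.

    Order is deterministic: chains in file order, Cα nodes by ascending
    residue number within each chain; ligand nodes appended after all Cα
    nodes, grouped by assigned chain, in file atom order.
    """

    nodes: list[GNMNode]
    structure_id: str

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def coords(self) -> np.ndarray:
        return np.array([n.coords for n in self.nodes], dtype=float)

    @property
    def bfactors(self) -> np.ndarray:
        return np.array([n.bfactor for n in self.nodes], dtype=float)

    @property
    def labels(self) -> list[str]:
        return [n.label for n in self.nodes]

    @property
    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for n in self.nodes:
            if n.kind == "calpha" and n.chain_id not in seen:
                seen.append(n.chain_id)
        return seen

    def indices(self, chain: str | None = None, kind: str | None = None) -> np.ndarray:
        idx = [
            i for i, n in enumerate(self.nodes)
            if (chain is None or n.chain_id == chain)
            and (kind is None or n.kind == kind)
        ]
        return np.asarray(idx, dtype=int)

    def resnums(self, chain: str) -> np.ndarray:
        return np.array(
            [n.resnum for n in self.nodes
             if n.chain_id == chain and n.kind == "calpha"], dtype=int)


def _nearest_protein_chain(structure: Structure, group: HeteroGroup) -> str:
    gx = np.array([a.coords for a in group.atoms], float)
    best, best_d = structure.chains[0].id, np.inf
    for chain in structure.chains:
        cx = np.array([a.coords for a in chain.atoms], float)
        d = np.min(np.linalg.norm(cx[:, None, :] - gx[None, :, :], axis=2))
        if d < best_d:
            best, best_d = chain.id, d
    return best


def select_gnm_nodes(
    structure: Structure,
    residue_lo: int = 15,
    residue_hi: int = 135,
    ligand_resname: str | None = None,
    ligand_atom_names: Iterable[str] = (),
) -> NodeSet:
    """Select Cα nodes in [residue_lo, residue_hi] plus named ligand atoms.

    Every protein chain contributes its in-window Cα atoms; when
    ``ligand_resname`` is given, each matching hetero group contributes one
    node per atom whose name is in ``ligand_atom_names`` (appended after all
    Cα nodes, grouped by the chain the ligand is assigned to).
    """
    if residue_lo > residue_hi:
        raise ValueError(f"residue_lo {residue_lo} > residue_hi {residue_hi}")
    ligand_atom_names = set(ligand_atom_names)
    if ligand_resname and not ligand_atom_names:
        raise ValueError("ligand_atom_names must be nonempty when "
                         "ligand_resname is given")

    nodes: list[GNMNode] = []
    for chain in structure.chains:
        for ca in chain.calpha(residue_lo, residue_hi):
            nodes.append(GNMNode(chain.id, ca.resnum, "CA", "calpha",
                                 ca.coords, ca.bfactor))
    if not nodes:
        raise EmptySelectionError(
            f"{structure.id}: no Cα atoms in residue range "
            f"[{residue_lo}, {residue_hi}]")

    if ligand_resname:
        groups = [g for g in structure.hetero_groups
                  if g.resname == ligand_resname.upper()]
        if not groups:
            warnings.warn(
                f"{structure.id}: ligand {ligand_resname!r} not present; "
                "selecting zero ligand nodes", stacklevel=2)
        protein_ids = set(structure.chain_ids)
        assigned: list[tuple[str, HeteroGroup]] = []
        for g in groups:
            cid = g.chain_id if g.chain_id in protein_ids \
                else _nearest_protein_chain(structure, g)
            assigned.append((cid, g))
        chain_order = {cid: i for i, cid in enumerate(structure.chain_ids)}
        assigned.sort(key=lambda cg: chain_order.get(cg[0], len(chain_order)))
        for cid, g in assigned:
            for a in g.atoms:
                if a.name in ligand_atom_names:
                    nodes.append(GNMNode(cid, a.resnum, a.name, "ligand",
                                         a.coords, a.bfactor))

    keys = [(n.chain_id, n.resnum, n.atom_name) for n in nodes]
    if len(set(keys)) != len(keys):
        dup = sorted({k for k in keys if keys.count(k) > 1})
        raise InvariantError(f"duplicate GNM node entries: {dup[:5]}")
    return NodeSet(nodes, structure.id)


# ---------------------------------------------------------------------------
# pocket extraction

@dataclass
class PocketSelection:
    chain_id: str
    atoms: list[Atom]
    residues_used: list[tuple[str, int]]
    skipped: list[tuple[str | None, int]]


def _normalize_pocket_list(
    pocket_residues: Sequence,
) -> list[tuple[str | None, int]]:
    out: list[tuple[str | None, int]] = []
    for item in pocket_residues:
        if isinstance(item, int):
            out.append((None, item))
        else:
            name, num = item
            out.append((None if name is None else str(name).upper(), int(num)))
    return out


def extract_pocket(
    structure: Structure,
    chain: str,
    pocket_residues: Sequence,
) -> PocketSelection:
    """All heavy atoms of the named residues in one chain.

    Residues absent from the model (or whose name does not match the
    requested one) are skipped and reported in ``skipped``.
    """
    ch = structure.chain(chain)  # raises SelectionError listing chains
    wanted = _normalize_pocket_list(pocket_residues)
    atoms: list[Atom] = []
    used: list[tuple[str, int]] = []
    skipped: list[tuple[str | None, int]] = []
    for name, num in wanted:
        res = ch.residue(num)
        if res is None or (name is not None and res.name != name):
            skipped.append((name, num))
            continue
        atoms.extend(res.atoms)
        used.append((res.name, num))
    return PocketSelection(chain, atoms, used, skipped)
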