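"""Polar-contact enumeration and binding-pocket water/interaction census.

A "polar interaction" is operationalized purely geometrically: any pair of
nitrogen/oxygen heavy atoms within a distance cutoff (default 3.6 Å),
excluding pairs within the same residue.  No donor/acceptor chemistry or
angle term is applied, and sulfur is excluded.  A "coordinated water" is a
water oxygen with at least one such contact to a pocket-residue atom.

Counting behaviour that is genuinely convention-dependent is exposed as
flags: sequential backbone N(i+1)–O(i) pairs are included by default, and
water–water contacts among coordinated waters are excluded by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import SelectionError
from .structures import Atom, PocketSelection, Structure, extract_pocket

DEFAULT_POLAR_CUTOFF = 3.6  # Å

#: Named binding-pocket presets for the streptavidin biotin pocket.  Two
#: slightly different residue lists circulate for the same pocket; both are
#: shipped so the census can be run under either.
POCKET_PRESETS: dict[str, tuple[tuple[str, int], ...]] = {
    "canonical8": (("ASN", 23), ("SER", 42), ("TYR", 43), ("SER", 45),
                   ("ASN", 49), ("SER", 88), ("THR", 90), ("ASP", 128)),
    "compact7": (("ASN", 23), ("SER", 27), ("TYR", 43), ("SER", 45),
                 ("ASN", 49), ("SER", 88), ("ASP", 128)),
}


def resolve_pocket_preset(pocket_residues) -> Sequence:
    if isinstance(pocket_residues, str):
        try:
            return POCKET_PRESETS[pocket_residues]
        except KeyError:
            raise SelectionError(
                f"unknown pocket preset {pocket_residues!r}; "
                f"available: {sorted(POCKET_PRESETS)}") from None
    return pocket_residues


@dataclass(frozen=True)
class PolarContact:
    """An unordered N/O–N/O heavy-atom pair within the cutoff."""

    atom_a: tuple[str, str, int, str]   # (chain, resname, resnum, atom name)
    atom_b: tuple[str, str, int, str]
    distance: float
    kind: str  # protein-protein | protein-water | water-water

    def to_dict(self) -> dict:
        return {
            "atom_a": list(self.atom_a),
            "atom_b": list(self.atom_b),
            "distance": round(self.distance, 3),
            "kind": self.kind,
        }


def _contact_key(a: Atom) -> tuple[str, str, int, str]:
    return (a.chain_id, a.resname, a.resnum, a.name)


def _res_key(a: Atom) -> tuple[str, str, int, str]:
    return (a.chain_id, a.resname, a.resnum, a.icode)


def _kind(a: Atom, b: Atom) -> str:
    nw = int(a.is_water) + int(b.is_water)
    return ("protein-protein", "protein-water", "water-water")[nw]


def find_polar_contacts(
    selection_a: Iterable[Atom],
    selection_b: Iterable[Atom],
    cutoff: float = DEFAULT_POLAR_CUTOFF,
    include_adjacent_backbone: bool = True,
) -> list[PolarContact]:
    """All unordered polar (N/O) heavy-atom pairs across two selections.

    Overlapping selections are deduplicated (each unordered pair appears
    once); pairs within the same residue are excluded.  With
    ``include_adjacent_backbone=False``, backbone N/O pairs of sequence
    neighbours in the same chain are excluded as well.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pa = [a for a in selection_a if a.is_polar]
    pb = [b for b in selection_b if b.is_polar]
    if not pa or not pb:
        return []
    xa = np.array([a.coords for a in pa], float)
    xb = np.array([b.coords for b in pb], float)
    tree = cKDTree(xb)
    seen: set[frozenset] = set()
    contacts: list[PolarContact] = []
    for i, hits in enumerate(tree.query_ball_point(xa, cutoff)):
        a = pa[i]
        for j in hits:
            b = pb[j]
            if _res_key(a) == _res_key(b):
                continue
            pair_id = frozenset((_contact_key(a), _contact_key(b)))
            if len(pair_id) == 1 or pair_id in seen:
                continue
            if not include_adjacent_backbone and _is_adjacent_backbone(a, b):
                continue
            d = float(np.linalg.norm(a.xyz - b.xyz))
            if d > cutoff:
                continue
            seen.add(pair_id)
            contacts.append(PolarContact(_contact_key(a), _contact_key(b),
                                         d, _kind(a, b)))
    contacts.sort(key=lambda c: (c.atom_a, c.atom_b))
    return contacts


def _is_adjacent_backbone(a: Atom, b: Atom) -> bool:
    if a.is_water or b.is_water or a.chain_id != b.chain_id:
        return False
    pair = {(a.name, b.name, a.resnum - b.resnum),
            (b.name, a.name, b.resnum - a.resnum)}
    return ("N", "O", 1) in pair


@dataclass
class PocketCensus:
    """Waters and polar interactions coordinated by one chain's pocket."""

    chain: str
    n_waters: int
    n_polar_interactions: int
    contacts: list[PolarContact]
    pocket_residues_used: list[tuple[str, int]]
    skipped_residues: list = field(default_factory=list)
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "chain": self.chain,
            "n_waters": self.n_waters,
            "n_polar_interactions": self.n_polar_interactions,
            "pocket_residues_used": [list(r) for r in self.pocket_residues_used],
            "skipped_residues": [list(r) for r in self.skipped_residues],
            "contacts": [c.to_dict() for c in self.contacts],
            "error": self.error,
        }


def pocket_census(
    structure: Structure,
    chain: str,
    pocket_residues,
    cutoff: float = DEFAULT_POLAR_CUTOFF,
    include_water_water: bool = False,
    include_adjacent_backbone: bool = True,
) -> PocketCensus:
    """Census the polar environment of one chain's binding pocket.

    Contact partners of the pocket atoms are: the pocket atoms themselves,
    every water oxygen in the structure, and polar atoms of all non-pocket
    residues (any chain, including hetero groups).  ``n_waters`` counts
    distinct waters with ≥ 1 contact to a pocket-residue atom;
    ``n_polar_interactions`` is the total number of contacts.
    """
    pocket_residues = resolve_pocket_preset(pocket_residues)
    sel: PocketSelection = extract_pocket(structure, chain, pocket_residues)
    pocket_res_keys = {(chain, name, num) for name, num in sel.residues_used}

    def in_pocket(a: Atom) -> bool:
        return (a.chain_id, a.resname, a.resnum) in pocket_res_keys

    neighbors = [a for a in structure.protein_atoms
                 if a.is_polar and not in_pocket(a)]
    neighbors += [a for g in structure.hetero_groups for a in g.atoms
                  if a.is_polar]
    partners = sel.atoms + list(structure.waters) + neighbors
    contacts = find_polar_contacts(sel.atoms, partners, cutoff,
                                   include_adjacent_backbone)
    water_keys = set()
    for c in contacts:
        for atom in (c.atom_a, c.atom_b):
            if atom[1] in {"HOH", "WAT"}:
                water_keys.add(atom[:3])
    if include_water_water and water_keys:
        coord_waters = [w for w in structure.waters
                        if (w.chain_id, w.resname, w.resnum) in water_keys]
        contacts = sorted(
            set(contacts)
            | set(find_polar_contacts(coord_waters, coord_waters, cutoff)),
            key=lambda c: (c.atom_a, c.atom_b))
    return PocketCensus(
        chain=chain,
        n_waters=len(water_keys),
        n_polar_interactions=len(contacts),
        contacts=contacts,
        pocket_residues_used=sel.residues_used,
        skipped_residues=sel.skipped,
    )


def census_all_chains(
    structure: Structure,
    pocket_residues,
    cutoff: float = DEFAULT_POLAR_CUTOFF,
    include_water_water: bool = False,
    include_adjacent_backbone: bool = True,
) -> list[PocketCensus]:
    """One census per chain (same pocket residue numbers), ordered by chain id.

    Per-chain failures are collected on the census object rather than
    aborting the sweep.
    """
    out: list[PocketCensus] = []
    for cid in sorted(structure.chain_ids):
        try:
            out.append(pocket_census(structure, cid, pocket_residues, cutoff,
                                     include_water_water,
                                     include_adjacent_backbone))
        except Exception as e:  # pragma: no cover - defensive
            out.append(PocketCensus(cid, 0, 0, [], [], [], error=str(e)))
    return out
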