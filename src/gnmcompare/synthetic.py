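"""Seed-deterministic synthetic structures for testing every analysis stage.

The generators emulate the geometric and statistical features the analyses
assume, without any physical realism beyond them: Cα traces at ~3.8 Å
spacing, a D2 (222-point-group) tetramer whose chains are rigid copies of
one jittered monomer, per-node B-factors drawn as a·MSF + b + N(0, σ) from
the assembly's own GNM, a rigid planar 4-atom ligand pseudo-group placed
within the GNM cutoff of designated pocket residues, and small water scenes
with controlled near/far placement around polar pocket atoms.

Every generator is fully determined by its seed: the same spec yields
byte-identical PDB output.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, PlacementError
from .gnm import build_kirchhoff, decompose, fluctuations, theoretical_bfactors
from .structures import (
    Atom,
    Chain,
    HeteroGroup,
    Residue,
    Structure,
    select_gnm_nodes,
)

START_RESNUM = 15

_D2_ROTATIONS = {
    "A": np.diag([1.0, 1.0, 1.0]),
    "B": np.diag([-1.0, -1.0, 1.0]),   # 2-fold about z: dimer partner of A
    "C": np.diag([1.0, -1.0, -1.0]),   # 2-fold about x
    "D": np.diag([-1.0, 1.0, -1.0]),   # 2-fold about y
}

#: rigid planar ligand pseudo-group (atom name -> local coordinates, Å)
_LIGAND_TEMPLATE = {
    "N1": np.array([0.0, 0.0, 0.0]),
    "C2": np.array([1.45, 0.0, 0.0]),
    "C9": np.array([2.15, 1.25, 0.0]),
    "O12": np.array([0.70, 1.90, 0.0]),
}
_LIGAND_ELEMENTS = {"N1": "N", "C2": "C", "C9": "C", "O12": "O"}


@dataclass
class LigandSpec:
    resname: str = "BTN"
    chains: tuple[str, ...] = ("A",)
    pocket_residues: tuple[int, ...] = ()   # empty -> mid-chain default
    displacement: float = 0.45              # pocket-loop shift toward ligand, Å


@dataclass
class SyntheticSpec:
    """Study conditions for the synthetic tetramer generator."""

    topology: str = "helix"          # monomer topology: path | ring | helix
    nodes_per_chain: int = 40
    spacing: float = 3.8             # consecutive Cα distance, Å
    interchain_contacts: int = 8     # minimum dimer-interface contacts at cutoff
    cutoff: float = 7.3              # GNM cutoff used for contact/B-factor model
    bfactor_scale: float = 30.0      # a, Å²
    bfactor_offset: float = 2.0      # b, Å²
    bfactor_noise: float | None = None  # σ, Å²; None -> 5% of a·mean(MSF)
    jitter: float = 0.15             # monomer coordinate jitter, Å
    asymmetry: float = 0.02          # per-chain rigid rotation, rad (breaks
                                     # exact 222 symmetry, as in real data)
    ligand: LigandSpec | None = None
    chain_relabel: dict | None = None  # holo chain relabelling (apo id -> holo id)
    seed: int = 0


def _chain_coords(topology: str, n: int, spacing: float) -> np.ndarray:
    if topology == "path":
        return np.column_stack([np.arange(n) * spacing,
                                np.zeros(n), np.zeros(n)])
    if topology == "ring":
        radius = spacing / (2.0 * np.sin(np.pi / n))
        ang = 2.0 * np.pi * np.arange(n) / n
        return np.column_stack([radius * np.cos(ang),
                                radius * np.sin(ang),
                                np.zeros(n)])
    if topology == "helix":
        rise, turn = 1.5, np.deg2rad(100.0)
        radius = np.sqrt(spacing ** 2 - rise ** 2) / (2.0 * np.sin(turn / 2.0))
        ang = turn * np.arange(n)
        return np.column_stack([radius * np.cos(ang),
                                radius * np.sin(ang),
                                rise * np.arange(n)])
    raise ValueError(f"unknown topology {topology!r}")


def _coords_to_chain(coords: np.ndarray, chain_id: str,
                     bfactors: np.ndarray | None = None) -> Chain:
    n = len(coords)
    if bfactors is None:
        bfactors = 10.0 + 4.0 * np.sin(np.arange(n) * 0.7)
    residues = []
    for i, xyz in enumerate(coords):
        num = START_RESNUM + i
        atom = Atom("CA", "C", (float(xyz[0]), float(xyz[1]), float(xyz[2])),
                    float(round(bfactors[i], 2)), 1.0, "", "ALA", num, "",
                    chain_id)
        residues.append(Residue("ALA", num, "", [atom]))
    return Chain(chain_id, residues)


def make_chain(topology: str, n: int, spacing: float = 3.8,
               seed: int = 0, chain_id: str = "A") -> Structure:
    """Single-chain Cα-only structure (residue numbers start at 15).

    ``path``: collinear points at the given spacing; ``ring``: regular
    polygon with the given edge length; ``helix``: ideal α-helical trace
    (1.5 Å rise, 100°/residue, radius solved for the requested Cα spacing).
    """
    if n < 4:
        raise ValueError(f"need n >= 4 residues, got {n}")
    coords = _chain_coords(topology, n, spacing)
    return Structure(f"synthetic-{topology}-{n}", [
        _coords_to_chain(coords, chain_id)])


def _tetramer_coords(
    monomer: np.ndarray, spec: SyntheticSpec, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Place D2 copies of a centred monomer; tune the offset for contacts.

    The offset magnitude is scanned from large to small; the first placement
    reaching the requested dimer-interface contact count without steric
    collapse (min inter-chain distance >= 2.5 Å) and with a connected
    contact graph wins.  A small per-chain rigid rotation (spec.asymmetry,
    applied about each chain's centroid) breaks exact point-group symmetry
    while keeping the chains congruent.
    """
    from scipy.spatial.transform import Rotation

    mono = monomer - monomer.mean(axis=0)
    # offset in the xy-plane: the z two-fold then yields an antiparallel
    # side-by-side dimer (A,B) while the x/y two-folds keep the other
    # chains clear of the helix axis
    direction = np.array([0.8, 0.75, 0.0])
    direction /= np.linalg.norm(direction)
    span = float(np.linalg.norm(mono, axis=1).max())
    # the asymmetry *magnitude* is the study condition; a particular random
    # rotation draw that leaves no clash-free placement window is redrawn
    for _ in range(25):
        perturb = [Rotation.from_rotvec(rng.normal(0.0, spec.asymmetry, 3))
                   if spec.asymmetry > 0 else None for _ in range(4)]
        for scale in np.arange(span + 10.0, 2.0, -0.05):
            placed = mono + scale * direction
            coords = {cid: placed @ rot.T for cid, rot in _D2_ROTATIONS.items()}
            for k, cid in enumerate("ABCD"):
                if perturb[k] is not None:
                    center = coords[cid].mean(axis=0)
                    coords[cid] = perturb[k].apply(coords[cid] - center) + center
            # dimer partner of A under the z rotation is B
            dab = np.linalg.norm(
                coords["A"][:, None, :] - coords["B"][None, :, :], axis=2)
            mins = [np.linalg.norm(
                        coords[a][:, None, :] - coords[b][None, :, :],
                        axis=2).min()
                    for a, b in (("A", "B"), ("A", "C"), ("A", "D"),
                                 ("B", "C"), ("B", "D"), ("C", "D"))]
            if min(mins) < 2.5:
                continue
            if (dab <= spec.cutoff).sum() < spec.interchain_contacts:
                continue
            if not _connected(np.concatenate(list(coords.values())),
                              spec.cutoff):
                continue
            return coords
        if spec.asymmetry == 0:
            break  # deterministic placement; retrying cannot help
    raise GeometryError(
        f"cannot reach {spec.interchain_contacts} inter-chain contacts for "
        f"this monomer geometry")


def _connected(coords: np.ndarray, cutoff: float) -> bool:
    from scipy.sparse.csgraph import connected_components
    from scipy.spatial.distance import pdist, squareform
    adj = squareform(pdist(coords)) <= cutoff
    np.fill_diagonal(adj, False)
    n, _ = connected_components(adj, directed=False)
    return n == 1


@dataclass
class GroundTruth:
    """Generator-side record sufficient to verify every pipeline stage."""

    chain_map: dict          # apo chain id -> holo chain id (spatial identity)
    pocket_residues: tuple   # residue numbers adjacent to the ligand
    ligand_chains: tuple
    msf: np.ndarray | None = None        # noiseless per-node MSF (apo order)
    bfactor_sigma: float = 0.0
    ligand_contacts: int = 0
    extra: dict = field(default_factory=dict)


def _assign_bfactors(structure: Structure, spec: SyntheticSpec,
                     rng: np.random.Generator,
                     ligand_resname: str | None = None,
                     ligand_atoms: tuple[str, ...] = ()) -> tuple[np.ndarray, float]:
    """B = a·MSF + b + N(0, σ) (clipped at 0.01) from the assembly's own GNM."""
    nodes = select_gnm_nodes(structure, START_RESNUM, START_RESNUM + 5000,
                             ligand_resname, ligand_atoms)
    modes = decompose(build_kirchhoff(nodes, spec.cutoff, 1.0))
    msf = theoretical_bfactors(fluctuations(modes))
    a, b = spec.bfactor_scale, spec.bfactor_offset
    sigma = spec.bfactor_noise
    if sigma is None:
        sigma = 0.05 * a * float(msf.mean())
    noise = rng.normal(0.0, sigma, size=len(msf)) if sigma > 0 else np.zeros(len(msf))
    bvals = np.clip(a * msf + b + noise, 0.01, None)
    by_key = {(n.chain_id, n.resnum, n.atom_name): float(round(v, 2))
              for n, v in zip(nodes.nodes, bvals)}
    for chain in structure.chains:
        for res in chain.residues:
            res.atoms = [
                a_.__class__(**{**a_.__dict__,
                                "bfactor": by_key.get(
                                    (chain.id, res.number, a_.name),
                                    a_.bfactor)})
                for a_ in res.atoms]
    for grp in structure.hetero_groups:
        grp.atoms = [
            a_.__class__(**{**a_.__dict__,
                            "bfactor": by_key.get(
                                (grp.chain_id, a_.resnum, a_.name),
                                a_.bfactor)})
            for a_ in grp.atoms]
    return msf, float(sigma)


def make_tetramer(spec: SyntheticSpec | None = None) -> tuple[Structure, GroundTruth]:
    """D2-symmetric four-chain assembly with GNM-consistent B-factors.

    Chains are rigid copies of one jittered monomer (hence exactly
    congruent); the dimer interface carries at least the requested contact
    count at the GNM cutoff and the whole assembly is connected.
    """
    spec = spec or SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    mono = _chain_coords(spec.topology, spec.nodes_per_chain, spec.spacing)
    if spec.jitter > 0:
        mono = mono + rng.normal(0.0, spec.jitter, size=mono.shape)
    coords = _tetramer_coords(mono, spec, rng)
    structure = Structure(
        f"synthetic-tetramer-{spec.seed}",
        [_coords_to_chain(coords[cid], cid) for cid in "ABCD"])
    msf, sigma = _assign_bfactors(structure, spec, rng)
    pocket = spec.ligand.pocket_residues if spec.ligand else ()
    if spec.ligand and not pocket:
        mid = START_RESNUM + spec.nodes_per_chain // 2
        pocket = tuple(range(mid - 3, mid + 3))
    gt = GroundTruth(
        chain_map={c: c for c in "ABCD"},
        pocket_residues=tuple(pocket),
        ligand_chains=tuple(spec.ligand.chains) if spec.ligand else (),
        msf=msf,
        bfactor_sigma=sigma,
    )
    return structure, gt


def _place_ligand(structure: Structure, chain_id: str,
                  pocket_resnums: tuple[int, ...], cutoff: float,
                  resname: str, resnum: int) -> tuple[HeteroGroup, int]:
    chain = structure.chain(chain_id)
    pocket_ca = np.array([r.atom("CA").xyz for r in chain.residues
                          if r.number in pocket_resnums])
    if len(pocket_ca) == 0:
        raise GeometryError(f"no pocket residues {pocket_resnums} in chain "
                            f"{chain_id}")
    all_ca = np.array([a.xyz for a in structure.protein_atoms])
    centroid = pocket_ca.mean(axis=0)
    outward = centroid - all_ca.mean(axis=0)
    outward /= np.linalg.norm(outward)
    # local frame for the planar template
    ref = np.array([0.0, 0.0, 1.0])
    if abs(outward @ ref) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    e1 = np.cross(outward, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(outward, e1)
    frame = np.column_stack([e1, e2, outward])
    template = np.array([_LIGAND_TEMPLATE[n] for n in _LIGAND_TEMPLATE])
    template = template - template.mean(axis=0)
    # scan from buried outwards: the first clash-free placement maximizes
    # ligand coordination, emulating a ligand enclosed by its pocket
    for dist in np.arange(2.0, 6.6, 0.1):
        lig = (template @ frame.T) + centroid + dist * outward
        d_pocket = np.linalg.norm(lig[:, None, :] - pocket_ca[None, :, :], axis=2)
        d_all = np.linalg.norm(lig[:, None, :] - all_ca[None, :, :], axis=2)
        if d_all.min() < 3.0:
            continue
        if (d_pocket.min(axis=1) <= cutoff - 0.3).all():
            atoms = [Atom(name, _LIGAND_ELEMENTS[name],
                          (float(x), float(y), float(z)), 15.0, 1.0, "",
                          resname, resnum, "", chain_id, het=True)
                     for name, (x, y, z) in zip(_LIGAND_TEMPLATE, lig)]
            n_contacts = int((d_all <= cutoff).sum())
            return HeteroGroup(resname, chain_id, resnum, "", atoms), n_contacts
    raise GeometryError("cannot place ligand within cutoff of the pocket "
                        "without steric collision")


def make_apo_holo_pair(
    spec: SyntheticSpec | None = None,
) -> tuple[Structure, Structure, GroundTruth]:
    """Matched ligand-free / ligand-bound assemblies with ground truth.

    The holo structure is the apo assembly with (i) pocket residues of each
    ligand-bearing chain displaced < 1 Å toward the incoming ligand, (ii) a
    rigid 4-atom pseudo-ligand (atoms N1/C2/C9/O12, residue BTN) placed
    within the GNM cutoff of the pocket, (iii) B-factors re-drawn from the
    holo assembly's own GNM, and (iv) chains optionally relabelled.  The
    ground truth records the apo→holo chain correspondence, pocket residue
    numbers, and noiseless fluctuations.
    """
    spec = copy.deepcopy(spec) if spec else SyntheticSpec()
    if spec.ligand is None:
        spec.ligand = LigandSpec()
    apo, gt = make_tetramer(spec)
    rng = np.random.default_rng(spec.seed + 1)

    holo = copy.deepcopy(apo)
    holo.id = apo.id.replace("tetramer", "holo")
    pocket = gt.pocket_residues
    lig = spec.ligand
    n_contacts = 0
    for k, cid in enumerate(lig.chains):
        grp, nc = _place_ligand(holo, cid, pocket, spec.cutoff,
                                lig.resname, 201 + k)
        # displace the pocket loop toward the ligand (< 1 Å)
        lig_centroid = np.mean([a.xyz for a in grp.atoms], axis=0)
        chain = holo.chain(cid)
        for res in chain.residues:
            if res.number in pocket:
                ca = res.atom("CA")
                u = lig_centroid - ca.xyz
                u /= np.linalg.norm(u)
                res.atoms = [a.moved(a.xyz + lig.displacement * u)
                             for a in res.atoms]
        holo.hetero_groups.append(grp)
        n_contacts += nc
    holo_msf, _ = _assign_bfactors(
        holo, spec, rng, lig.resname,
        tuple(_LIGAND_TEMPLATE))
    chain_map = {c: c for c in "ABCD"}
    if spec.chain_relabel:
        chain_map = dict(spec.chain_relabel)
        for chain in holo.chains:
            chain.id = chain_map[chain.id]
            for res in chain.residues:
                res.atoms = [a.__class__(**{**a.__dict__, "chain_id": chain.id})
                             for a in res.atoms]
        for grp in holo.hetero_groups:
            new_id = chain_map[grp.chain_id]
            grp.chain_id = new_id
            grp.atoms = [a.__class__(**{**a.__dict__, "chain_id": new_id})
                         for a in grp.atoms]
    gt = GroundTruth(
        chain_map=chain_map,
        pocket_residues=pocket,
        ligand_chains=tuple(chain_map[c] for c in lig.chains),
        msf=gt.msf,
        bfactor_sigma=gt.bfactor_sigma,
        ligand_contacts=n_contacts,
        extra={"holo_msf": holo_msf},
    )
    return apo, holo, gt


# ---------------------------------------------------------------------------
# pocket water scenes

_SCENE_TEMPLATES = (
    ("ASN", 23, "ND2", "N"),
    ("SER", 42, "OG", "O"),
    ("TYR", 43, "OH", "O"),
    ("THR", 90, "OG1", "O"),
)


def make_pocket_scene(
    n_near: int,
    d_near: float = 3.0,
    n_far: int = 2,
    d_far: float = 4.5,
    seed: int = 0,
) -> Structure:
    """Protein fragment + waters at controlled distances from polar atoms.

    ``n_near`` waters sit exactly ``d_near`` Å from a pocket N/O atom
    (round-robin over the pocket atoms) and ``n_far`` waters exactly
    ``d_far`` Å away; placement is rejected-and-retried until no accidental
    extra polar contact exists (verified by a final brute-force scan).
    """
    if not (d_near <= 3.6 < d_far):
        raise ValueError(f"require d_near <= 3.6 < d_far, got {d_near}, {d_far}")
    rng = np.random.default_rng(seed)
    residues: list[Residue] = []
    polar_atoms: list[Atom] = []
    for i, (resname, resnum, polar_name, element) in enumerate(_SCENE_TEMPLATES):
        ca_pos = np.array([9.0 * i, 0.0, 0.0])
        polar_pos = ca_pos + np.array([1.4, 1.2, 0.9])
        ca = Atom("CA", "C", tuple(ca_pos), 10.0, 1.0, "", resname, resnum,
                  "", "A")
        pa = Atom(polar_name, element, tuple(polar_pos), 10.0, 1.0, "",
                  resname, resnum, "", "A")
        residues.append(Residue(resname, resnum, "", [ca, pa]))
        polar_atoms.append(pa)

    placed: list[np.ndarray] = []
    waters: list[Atom] = []

    def place(dist: float, idx: int, resnum: int) -> Atom:
        anchor = polar_atoms[idx % len(polar_atoms)].xyz
        others = [p.xyz for j, p in enumerate(polar_atoms)
                  if j != idx % len(polar_atoms)]
        protein = [a.xyz for r in residues for a in r.atoms]
        for _ in range(500):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            pos = anchor + dist * v
            if any(np.linalg.norm(pos - o) <= 3.8 for o in others):
                continue
            if any(np.linalg.norm(pos - p) < 2.6 for p in protein):
                continue
            if any(np.linalg.norm(pos - w) <= 3.8 for w in placed):
                continue
            placed.append(pos)
            return Atom("O", "O", (float(pos[0]), float(pos[1]), float(pos[2])),
                        20.0, 1.0, "", "HOH", resnum, "", "S")
        raise PlacementError("water placement collision after 500 retries")

    for i in range(n_near):
        waters.append(place(d_near, i, 301 + i))
    for i in range(n_far):
        waters.append(place(d_far, i + 1, 401 + i))

    scene = Structure(f"pocket-scene-{seed}", [Chain("A", residues)], waters)
    _verify_scene(scene, n_near)
    return scene


def _verify_scene(scene: Structure, n_near: int) -> None:
    """Brute-force check: exactly n_near polar contacts, all protein-water."""
    polar = [a for a in scene.protein_atoms if a.is_polar] + scene.waters
    hits = []
    for i in range(len(polar)):
        for j in range(i + 1, len(polar)):
            if polar[i].residue_key == polar[j].residue_key:
                continue
            d = np.linalg.norm(polar[i].xyz - polar[j].xyz)
            if d <= DEFAULT_POLAR_CUTOFF_SCENE:
                hits.append((polar[i].key, polar[j].key, d))
    if len(hits) != n_near:
        raise PlacementError(
            f"scene verification failed: {len(hits)} contacts, expected {n_near}")


DEFAULT_POLAR_CUTOFF_SCENE = 3.6
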