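"""Rigid-body superposition, iterative-rejection RMSD, and chain mapping.

`kabsch_superpose` is the closed-form least-squares fit (SVD of the
covariance matrix, reflection corrected to a proper rotation).
`iterative_superpose` wraps it in the outlier-rejection protocol common to
molecular-graphics aligners: after each fit, pairs deviating by more than
``reject_sigma`` times the current RMSD are discarded and the fit repeated,
up to ``max_cycles`` cycles.  `map_chains` pairs chains of two assemblies
by minimum mean inter-Cα distance under a one-to-one assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import DegenerateSuperpositionError, SelectionError
from .structures import Structure

DEFAULT_MAX_CYCLES = 5
DEFAULT_REJECT_SIGMA = 2.0


@dataclass
class SuperpositionResult:
    rotation: np.ndarray          # 3x3, proper (det = +1)
    translation: np.ndarray       # Å
    rmsd: float                   # over retained pairs
    paired_count: int
    rejected_pairs: list = field(default_factory=list)
    cycles_run: int = 1
    retained_mask: np.ndarray | None = None

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation

    def to_dict(self) -> dict:
        return {
            "rotation": [[round(float(x), 6) for x in row]
                         for row in self.rotation],
            "translation": [round(float(x), 6) for x in self.translation],
            "rmsd": round(float(self.rmsd), 6),
            "paired_count": int(self.paired_count),
            "rejected_pairs": [str(p) for p in self.rejected_pairs],
            "cycles_run": int(self.cycles_run),
        }


def _as_points(x) -> np.ndarray:
    p = np.asarray(x, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3:
        raise ValueError(f"expected (N, 3) coordinates, got shape {p.shape}")
    return p


def kabsch_superpose(
    moving, target, weights: np.ndarray | None = None
) -> SuperpositionResult:
    """Least-squares optimal proper rotation + translation (moving → target)."""
    m = _as_points(moving)
    t = _as_points(target)
    if m.shape != t.shape:
        raise ValueError(f"length mismatch: {m.shape[0]} vs {t.shape[0]} points")
    n = m.shape[0]
    if n < 3:
        raise DegenerateSuperpositionError(f"need >= 3 points, got {n}")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, float)
        w = w / w.sum()
    cm = w @ m
    ct = w @ t
    mc = m - cm
    tc = t - ct
    h = (mc * w[:, None]).T @ tc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = ct - r @ cm
    moved = m @ r.T + translation
    rmsd = float(np.sqrt(np.sum(w * np.sum((moved - t) ** 2, axis=1))))
    return SuperpositionResult(r, translation, rmsd, n)


def iterative_superpose(
    moving,
    target,
    labels: list | None = None,
    max_cycles: int = DEFAULT_MAX_CYCLES,
    reject_sigma: float = DEFAULT_REJECT_SIGMA,
) -> SuperpositionResult:
    """Kabsch fit with per-cycle rejection of pairs deviating > σ·RMSD.

    Stops at convergence (a cycle rejecting nothing) or ``max_cycles``.
    The reported RMSD covers retained pairs only; rejected pairs are listed
    by label (or index when no labels are given).
    """
    m = _as_points(moving)
    t = _as_points(target)
    if m.shape != t.shape:
        raise ValueError(f"length mismatch: {m.shape[0]} vs {t.shape[0]} points")
    n = m.shape[0]
    if labels is None:
        labels = list(range(n))
    keep = np.ones(n, dtype=bool)
    result = None
    cycles = 0
    for _ in range(max_cycles):
        if keep.sum() < 3:
            raise DegenerateSuperpositionError(
                "fewer than 3 pairs retained during iterative superposition")
        result = kabsch_superpose(m[keep], t[keep])
        cycles += 1
        dev = np.linalg.norm(result.transform(m) - t, axis=1)
        new_keep = keep & (dev <= reject_sigma * result.rmsd + 1e-12)
        if not new_keep.any():
            raise DegenerateSuperpositionError("all pairs rejected")
        if new_keep.sum() == keep.sum():
            break
        keep = new_keep
    assert result is not None
    result.paired_count = int(keep.sum())
    result.rejected_pairs = [labels[i] for i in np.flatnonzero(~keep)]
    result.cycles_run = cycles
    result.retained_mask = keep
    # recompute rmsd over the final retained set under the final transform
    dev = np.linalg.norm(result.transform(m[keep]) - t[keep], axis=1)
    result.rmsd = float(np.sqrt(np.mean(dev ** 2)))
    return result


# ---------------------------------------------------------------------------
# chain-level helpers

def paired_calpha(
    chain_a, chain_b, residue_range: tuple[int, int] | None = None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Match Cα atoms of two chains by equal residue number."""
    lo, hi = residue_range if residue_range else (None, None)
    ca_a = {a.resnum: a for a in chain_a.calpha(lo, hi)}
    ca_b = {a.resnum: a for a in chain_b.calpha(lo, hi)}
    shared = sorted(set(ca_a) & set(ca_b))
    xa = np.array([ca_a[r].coords for r in shared], float).reshape(-1, 3)
    xb = np.array([ca_b[r].coords for r in shared], float).reshape(-1, 3)
    labels = [f"{chain_a.id}:{r}:CA" for r in shared]
    return xa, xb, labels


def superpose_chains(
    structure: Structure,
    reference_chain: str | None = None,
    residue_range: tuple[int, int] | None = None,
    max_cycles: int = DEFAULT_MAX_CYCLES,
    reject_sigma: float = DEFAULT_REJECT_SIGMA,
) -> dict:
    """Superpose every chain onto a reference chain of the same structure.

    Returns per-chain results and the overall RMSD over the union of all
    retained pairs (the convention used for a single "overall" number when
    several chains are superposed).
    """
    ref_id = reference_chain or structure.chains[0].id
    ref = structure.chain(ref_id)
    per_chain: dict[str, SuperpositionResult] = {}
    sq_devs: list[np.ndarray] = []
    for chain in structure.chains:
        if chain.id == ref_id:
            continue
        xm, xt, labels = paired_calpha(chain, ref, residue_range)
        res = iterative_superpose(xm, xt, labels, max_cycles, reject_sigma)
        per_chain[chain.id] = res
        dev = np.linalg.norm(
            res.transform(xm[res.retained_mask]) - xt[res.retained_mask], axis=1)
        sq_devs.append(dev ** 2)
    if not sq_devs:
        raise DegenerateSuperpositionError("structure has a single chain")
    allsq = np.concatenate(sq_devs)
    return {
        "reference_chain": ref_id,
        "per_chain": per_chain,
        "overall_rmsd": float(np.sqrt(allsq.mean())),
        "paired_count": int(allsq.size),
    }


@dataclass
class ChainMapping:
    """One-to-one chain correspondence between two assemblies."""

    pairs: list[tuple[str, str, float]]  # (chain in A, chain in B, rmsd Å)

    def as_dict(self) -> dict[str, str]:
        return {a: b for a, b, _ in self.pairs}

    def b_for(self, chain_a: str) -> str:
        for a, b, _ in self.pairs:
            if a == chain_a:
                return b
        raise SelectionError(f"chain {chain_a!r} not in mapping")


def _assembly_fit(struct_a: Structure, struct_b: Structure,
                  pairing: list[tuple[str, str]]) -> SuperpositionResult:
    xa_parts, xb_parts = [], []
    for ca, cb in pairing:
        xa, xb, _ = paired_calpha(struct_a.chain(ca), struct_b.chain(cb))
        xa_parts.append(xa)
        xb_parts.append(xb)
    xa = np.concatenate(xa_parts) if xa_parts else np.empty((0, 3))
    xb = np.concatenate(xb_parts) if xb_parts else np.empty((0, 3))
    if len(xa) < 3:
        raise DegenerateSuperpositionError(
            "no shared residue numbers between structures")
    return kabsch_superpose(xb, xa)  # moving = B onto A


def map_chains(struct_a: Structure, struct_b: Structure) -> ChainMapping:
    """Pair chains of two assemblies by minimum mean inter-Cα distance.

    For each hypothesis "first chain of A corresponds to chain X of B" the
    two assemblies are superposed on that chain pair, all chains are then
    assigned one-to-one by solving the linear assignment problem on mean
    inter-Cα distance, and the fit is refined on the assignment.  The
    hypothesis with the lowest total assigned cost wins — this matters for
    near-symmetric homo-oligomers, where a single greedy start can lock
    onto a symmetry-related (wrong) correspondence.  Chain labels carry no
    geometric meaning: a relabelled copy maps by position, not by id.
    """
    if not struct_a.chains or not struct_b.chains:
        raise SelectionError("both structures need at least one protein chain")
    ids_a, ids_b = struct_a.chain_ids, struct_b.chain_ids

    def cost_matrix(fit: SuperpositionResult) -> np.ndarray:
        cost = np.full((len(ids_a), len(ids_b)), 1e9)
        for i, ca in enumerate(ids_a):
            for j, cb in enumerate(ids_b):
                xa, xb, _ = paired_calpha(struct_a.chain(ca), struct_b.chain(cb))
                if len(xa) == 0:
                    continue
                d = np.linalg.norm(fit.transform(xb) - xa, axis=1)
                cost[i, j] = float(d.mean())
        return cost

    def assign_and_refine(fit: SuperpositionResult):
        assigned = None
        for _ in range(2):
            cost = cost_matrix(fit)
            ri, ci = linear_sum_assignment(cost)
            assigned = [(ids_a[i], ids_b[j]) for i, j in zip(ri, ci)
                        if cost[i, j] < 1e9]
            if not assigned:
                return None
            fit = _assembly_fit(struct_a, struct_b, assigned)
        cost = cost_matrix(fit)
        total = sum(cost[ids_a.index(ca), ids_b.index(cb)]
                    for ca, cb in assigned)
        return total, assigned, fit

    candidates = []
    a0 = ids_a[0]
    for cb in ids_b:
        try:
            seed_fit = _assembly_fit(struct_a, struct_b, [(a0, cb)])
        except DegenerateSuperpositionError:
            continue
        result = assign_and_refine(seed_fit)
        if result is not None:
            candidates.append(result)
    if not candidates:
        raise DegenerateSuperpositionError(
            "no shared residue numbers between structures")
    _, assigned, fit = min(candidates, key=lambda c: c[0])

    pairs = []
    for ca, cb in assigned:
        xa, xb, _ = paired_calpha(struct_a.chain(ca), struct_b.chain(cb))
        d = np.linalg.norm(fit.transform(xb) - xa, axis=1)
        pairs.append((ca, cb, float(np.sqrt((d ** 2).mean()))))
    pairs.sort(key=lambda p: ids_a.index(p[0]))
    return ChainMapping(pairs)


def superpose_structures(
    struct_a: Structure,
    struct_b: Structure,
    mapping: ChainMapping | None = None,
    max_cycles: int = DEFAULT_MAX_CYCLES,
    reject_sigma: float = DEFAULT_REJECT_SIGMA,
) -> SuperpositionResult:
    """Overall iterative superposition of assembly B onto assembly A.

    Cα pairs are pooled over mapped chains (equal residue numbers within a
    pair); the returned RMSD is over the union of retained pairs.
    """
    mapping = mapping or map_chains(struct_a, struct_b)
    xa_parts, xb_parts, labels = [], [], []
    for ca, cb, _ in mapping.pairs:
        xa, xb, lab = paired_calpha(struct_a.chain(ca), struct_b.chain(cb))
        xa_parts.append(xa)
        xb_parts.append(xb)
        labels.extend(lab)
    xa = np.concatenate(xa_parts)
    xb = np.concatenate(xb_parts)
    return iterative_superpose(xb, xa, labels, max_cycles, reject_sigma)
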