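"""Gaussian network model: Kirchhoff matrix, modes, fluctuations, correlations.

The GNM treats each node (Cα or ligand pseudo-atom) as a bead joined by
identical springs (force constant γ) to every neighbour within a cutoff
r_c.  The connectivity (Kirchhoff) matrix Γ is the graph Laplacian of that
contact network; its eigendecomposition Γ = Σ_k λ_k u_k u_kᵀ gives the
normal modes.  Cross-correlations of residue displacements are

    ⟨ΔR_i · ΔR_j⟩ ∝ Σ_{λ_k > 0} λ_k⁻¹ u_ki u_kj,

i.e. the Moore–Penrose pseudoinverse of Γ when all non-zero modes are used.
The absolute (3kT/γ) prefactor is omitted throughout: every reported
quantity (Pearson correlation with experimental B-factors, normalized
cross-correlations, relative slow-mode profiles) is scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.linalg
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from .errors import InvariantError, UndefinedCorrelationError
from .structures import NodeSet

DEFAULT_CUTOFF = 7.3  # Å
DEFAULT_GAMMA = 1.0
DEFAULT_ZERO_TOL = 1e-8


@dataclass
class KirchhoffMatrix:
    """Contact-graph Laplacian with its construction parameters."""

    matrix: np.ndarray
    cutoff: float
    gamma: float
    nodes: NodeSet

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def validate(self, atol: float = 1e-10) -> None:
        m = self.matrix
        if not np.allclose(m, m.T, atol=atol):
            raise InvariantError("Kirchhoff matrix is not symmetric")
        if not np.allclose(m.sum(axis=1), 0.0, atol=atol):
            raise InvariantError("Kirchhoff row sums are not zero")
        off = m[~np.eye(self.n, dtype=bool)]
        ok = np.isclose(off, 0.0) | np.isclose(off, -self.gamma)
        if not ok.all():
            raise InvariantError("off-diagonal entries not in {0, -gamma}")
        if (np.diag(m) < -atol).any():
            raise InvariantError("negative diagonal entry")


def build_kirchhoff(
    nodes: NodeSet,
    cutoff: float = DEFAULT_CUTOFF,
    gamma: float = DEFAULT_GAMMA,
) -> KirchhoffMatrix:
    """Γ_ij = -γ for i≠j with d_ij ≤ cutoff, Γ_ii = node degree × γ.

    Ligand nodes participate identically to Cα nodes.
    """
    if len(nodes) < 2:
        raise ValueError(f"need at least 2 nodes, got {len(nodes)}")
    if cutoff <= 0 or gamma <= 0:
        raise ValueError("cutoff and gamma must be positive")
    xyz = nodes.coords
    bad = ~np.isfinite(xyz).all(axis=1)
    if bad.any():
        raise ValueError(
            f"non-finite coordinates at node {nodes.labels[int(np.argmax(bad))]}")
    d = squareform(pdist(xyz))
    adj = (d <= cutoff)
    np.fill_diagonal(adj, False)
    m = np.where(adj, -gamma, 0.0)
    np.fill_diagonal(m, gamma * adj.sum(axis=1))
    return KirchhoffMatrix(m, cutoff, gamma, nodes)


@dataclass
class ModeSet:
    """Eigenpairs of a Kirchhoff matrix with zero-mode bookkeeping.

    Eigenvalues ascend; eigenvectors are orthonormal columns with a fixed
    sign convention (largest-magnitude component positive) so serialized
    output is reproducible across eigensolvers.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    zero_mode_count: int
    zero_tol: float
    nodes: NodeSet

    @property
    def n(self) -> int:
        return len(self.eigenvalues)

    @property
    def n_nonzero(self) -> int:
        return self.n - self.zero_mode_count

    def nonzero_indices(self, n_slowest: int | None = None) -> np.ndarray:
        idx = np.arange(self.zero_mode_count, self.n)
        if n_slowest is not None:
            if not 1 <= n_slowest <= self.n_nonzero:
                raise ValueError(
                    f"n_slowest must be in [1, {self.n_nonzero}], got {n_slowest}")
            idx = idx[:n_slowest]
        return idx


def decompose(K: KirchhoffMatrix, zero_tol: float = DEFAULT_ZERO_TOL) -> ModeSet:
    """Full symmetric eigendecomposition with zero-mode classification.

    Eigenvalues below ``zero_tol × λ_max`` are classified as zero modes; for
    a valid Laplacian their count equals the number of connected components
    of the contact graph.
    """
    try:
        w, v = scipy.linalg.eigh(K.matrix)
    except scipy.linalg.LinAlgError as e:  # pragma: no cover - rare
        raise InvariantError(f"eigendecomposition failed: {e}") from e
    lam_max = float(w[-1])
    scale = lam_max if lam_max > 0 else 1.0
    if w[0] < -zero_tol * scale:
        raise InvariantError(
            f"negative eigenvalue {w[0]:.3e} beyond tolerance; "
            "input is not positive semidefinite")
    n_zero = int(np.sum(w < zero_tol * scale)) if lam_max > 0 else len(w)
    w = np.clip(w, 0.0, None)
    # sign convention: largest-|component| entry of each eigenvector positive
    piv = np.argmax(np.abs(v), axis=0)
    signs = np.sign(v[piv, np.arange(v.shape[1])])
    signs[signs == 0] = 1.0
    v = v * signs
    return ModeSet(w, v, n_zero, zero_tol, K.nodes)


@dataclass
class FluctuationMatrix:
    """⟨ΔR_i·ΔR_j⟩ over a mode subset, in kT/γ units (arbitrary scale)."""

    values: np.ndarray
    mode_indices: np.ndarray
    nodes: NodeSet

    @property
    def msf(self) -> np.ndarray:
        """Per-node mean-square fluctuation (the diagonal)."""
        return np.diag(self.values).copy()


def fluctuations(
    modes: ModeSet,
    n_slowest: int | None = None,
    mode_indices: Sequence[int] | None = None,
) -> FluctuationMatrix:
    """⟨ΔR_i·ΔR_j⟩ = Σ_{k∈subset} λ_k⁻¹ u_ki u_kj.

    Default subset is all non-zero modes (equals pinv(Γ)); ``n_slowest``
    restricts to the k slowest non-zero modes.  Zero modes are rejected.
    """
    if mode_indices is not None:
        idx = np.asarray(mode_indices, dtype=int)
        if (idx < modes.zero_mode_count).any() or (idx >= modes.n).any():
            raise ValueError("mode subset contains a zero mode or is out of range")
    else:
        idx = modes.nonzero_indices(n_slowest)
    lam = modes.eigenvalues[idx]
    u = modes.eigenvectors[:, idx]
    values = (u / lam) @ u.T
    return FluctuationMatrix(values, idx, modes.nodes)


@dataclass
class CrossCorrelationMap:
    """Normalized residue-motion correlation matrix with chain sections."""

    values: np.ndarray
    nodes: NodeSet

    def section(
        self, chain_row: str, chain_col: str | None = None, kind: str = "calpha"
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Submatrix for an intrachain (chain_col=None) or interchain block.

        Returns (matrix, row residue numbers, column residue numbers);
        ligand nodes are excluded unless ``kind`` is None.
        """
        rows = self.nodes.indices(chain=chain_row, kind=kind)
        cols = self.nodes.indices(chain=chain_col or chain_row, kind=kind)
        sub = self.values[np.ix_(rows, cols)]
        rnum = np.array([self.nodes.nodes[i].resnum for i in rows])
        cnum = np.array([self.nodes.nodes[i].resnum for i in cols])
        return sub, rnum, cnum


def cross_correlation(fluct: FluctuationMatrix) -> CrossCorrelationMap:
    """C_ij = ⟨ΔR_i·ΔR_j⟩ / √(⟨ΔR_i²⟩⟨ΔR_j²⟩)."""
    d = np.diag(fluct.values)
    if (d <= 0).any():
        i = int(np.argmax(d <= 0))
        raise InvariantError(
            f"zero/negative mean-square fluctuation at node "
            f"{fluct.nodes.labels[i]}")
    denom = np.sqrt(np.outer(d, d))
    c = fluct.values / denom
    c = np.clip(c, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return CrossCorrelationMap(c, fluct.nodes)


def theoretical_bfactors(fluct: FluctuationMatrix) -> np.ndarray:
    """Per-node ⟨ΔR_i²⟩ (∝ B_i = 8π²⟨ΔR_i²⟩/3; prefactor not applied)."""
    return fluct.msf


def bfactor_correlation(theoretical: np.ndarray, experimental: np.ndarray) -> float:
    """Pearson correlation between theoretical MSF and experimental B-factors."""
    t = np.asarray(theoretical, float)
    e = np.asarray(experimental, float)
    if t.shape != e.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {e.shape}")
    if t.size < 3:
        raise ValueError("need at least 3 values")
    if np.ptp(t) == 0 or np.ptp(e) == 0:
        raise UndefinedCorrelationError("zero variance in input vector")
    return float(pearsonr(t, e).statistic)


def slow_mode_profile(modes: ModeSet, n_slowest: int) -> np.ndarray:
    """Per-node mean-square fluctuation over the n slowest non-zero modes.

    Each mode is weighted by λ_k⁻¹ (variance weighting); slice per chain via
    ``modes.nodes.indices(chain=...)``.
    """
    return fluctuations(modes, n_slowest=n_slowest).msf
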