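"""C-alpha elastic network models (ANM) and normal-mode observables.

Nodes are C-alpha positions; every pair within a distance cutoff is
joined by a Hookean spring with its equilibrium length set to the
reference distance.  The Hessian at the reference is the standard ANM
form built from 3x3 blocks ``-gamma_ij r_hat r_hat^T``.  Beyond the
eigensystem itself, the module provides mean-square fluctuations,
normalized cross-correlations (covariance analysis), per-mode overlaps
with an observed conformational change, and harmonic deformation
energies -- the quantities used to dissect chaperonin T -> R'' dynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse
import scipy.sparse.csgraph
import scipy.sparse.linalg
from scipy.spatial import cKDTree

log = logging.getLogger(__name__)

DEFAULT_CUTOFF = 12.0
DEFAULT_GAMMA = 1.0
ZERO_MODE_RTOL = 1e-8
DENSE_LIMIT = 3000  # dense eigensolve up to this many degrees of freedom


@dataclass
class EnmModel:
    """Pairwise Hookean network on C-alpha nodes.

    ``spring`` is ``"uniform"`` (gamma for every contact) or
    ``"distance_weighted"`` (gamma * (r_ref / r0)^(-6), an inverse-sixth
    power law of the Hinsen C-alpha family with r_ref = 3.8 A, the
    consecutive C-alpha distance).
    """

    coords: np.ndarray
    cutoff: float = DEFAULT_CUTOFF
    spring: str = "uniform"
    gamma: float = DEFAULT_GAMMA
    pairs: np.ndarray = field(init=False)
    k: np.ndarray = field(init=False)
    r0: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3 or len(coords) < 2:
            raise ValueError("need an (N>=2, 3) coordinate array")
        if not np.all(np.isfinite(coords)):
            raise ValueError("non-finite coordinates")
        self.coords = coords
        tree = cKDTree(coords)
        pairs = np.array(sorted(tree.query_pairs(self.cutoff)), dtype=int)
        if pairs.size == 0:
            raise ValueError("no contacts at this cutoff")
        self.pairs = pairs
        d = coords[pairs[:, 0]] - coords[pairs[:, 1]]
        self.r0 = np.linalg.norm(d, axis=1)
        if self.spring == "uniform":
            self.k = np.full(len(pairs), self.gamma)
        elif self.spring == "distance_weighted":
            self.k = self.gamma * (self.r0 / 3.8) ** (-6.0)
        else:
            raise ValueError(f"unknown spring law {self.spring!r}")
        if self.n_components > 1:
            log.warning(
                "network disconnected at cutoff %.1f A (%d components); "
                "expect extra zero modes", self.cutoff, self.n_components
            )

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    @property
    def n_components(self) -> int:
        n = self.n_nodes
        adj = scipy.sparse.coo_matrix(
            (np.ones(len(self.pairs)), (self.pairs[:, 0], self.pairs[:, 1])),
            shape=(n, n),
        )
        ncomp, _ = scipy.sparse.csgraph.connected_components(
            adj, directed=False)
        return ncomp

    # ---- reference Hessian (ANM) ------------------------------------

    def hessian(self, sparse: bool = False):
        """3N x 3N reference Hessian from ANM blocks -k_ij r_hat r_hat^T."""
        n = self.n_nodes
        i, j = self.pairs[:, 0], self.pairs[:, 1]
        d = self.coords[i] - self.coords[j]
        rhat = d / self.r0[:, None]
        blocks = self.k[:, None, None] * rhat[:, :, None] * rhat[:, None, :]
        if sparse:
            rows, cols, vals = [], [], []
            for (a, b), blk in zip(self.pairs, blocks):
                for u in range(3):
                    for v in range(3):
                        rows += [3 * a + u, 3 * b + u, 3 * a + u, 3 * b + u]
                        cols += [3 * b + v, 3 * a + v, 3 * a + v, 3 * b + v]
                        vals += [-blk[u, v], -blk[u, v], blk[u, v], blk[u, v]]
            return scipy.sparse.csr_matrix(
                (vals, (rows, cols)), shape=(3 * n, 3 * n))
        h = np.zeros((3 * n, 3 * n))
        for (a, b), blk in zip(self.pairs, blocks):
            h[3 * a:3 * a + 3, 3 * b:3 * b + 3] -= blk
            h[3 * b:3 * b + 3, 3 * a:3 * a + 3] -= blk
            h[3 * a:3 * a + 3, 3 * a:3 * a + 3] += blk
            h[3 * b:3 * b + 3, 3 * b:3 * b + 3] += blk
        return h

    # ---- energy surface away from the reference ----------------------

    def energy(self, x: np.ndarray) -> float:
        """0.5 * sum k_ij (|d_ij| - r0_ij)^2 at arbitrary coordinates."""
        x = x.reshape(self.n_nodes, 3)
        d = x[self.pairs[:, 0]] - x[self.pairs[:, 1]]
        r = np.linalg.norm(d, axis=1)
        return float(0.5 * np.sum(self.k * (r - self.r0) ** 2))

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x = x.reshape(self.n_nodes, 3)
        d = x[self.pairs[:, 0]] - x[self.pairs[:, 1]]
        r = np.linalg.norm(d, axis=1)
        f = (self.k * (r - self.r0) / np.maximum(r, 1e-12))[:, None] * d
        g = np.zeros_like(x)
        np.add.at(g, self.pairs[:, 0], f)
        np.add.at(g, self.pairs[:, 1], -f)
        return g.ravel()

    def hessian_at(self, x: np.ndarray) -> np.ndarray:
        """Exact Hessian of the pair energy at arbitrary coordinates."""
        x = x.reshape(self.n_nodes, 3)
        n = self.n_nodes
        d = x[self.pairs[:, 0]] - x[self.pairs[:, 1]]
        r = np.maximum(np.linalg.norm(d, axis=1), 1e-12)
        rhat = d / r[:, None]
        rr = rhat[:, :, None] * rhat[:, None, :]
        tang = (1.0 - self.r0 / r)[:, None, None] * (np.eye(3) - rr)
        blocks = self.k[:, None, None] * (rr + tang)
        h4 = np.zeros((n, n, 3, 3))
        i, j = self.pairs[:, 0], self.pairs[:, 1]
        np.add.at(h4, (i, j), -blocks)
        np.add.at(h4, (j, i), -blocks)
        np.add.at(h4, (i, i), blocks)
        np.add.at(h4, (j, j), blocks)
        return h4.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n)


def build_enm(calphas: np.ndarray, cutoff: float = DEFAULT_CUTOFF,
              spring: str = "uniform", gamma: float = DEFAULT_GAMMA) -> EnmModel:
    return EnmModel(np.asarray(calphas, dtype=float), cutoff, spring, gamma)


@dataclass
class ModeSet:
    """Eigensystem of an ENM Hessian, eigenvalues ascending."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # (3N, n_modes), columns orthonormal
    n_zero: int
    tol: float

    @property
    def nonzero(self) -> np.ndarray:
        return np.arange(self.n_zero, len(self.eigenvalues))

    def nonzero_pairs(self):
        for k in self.nonzero:
            yield self.eigenvalues[k], self.eigenvectors[:, k]


class EigenConvergenceError(RuntimeError):
    pass


def normal_modes(model: EnmModel, n_modes: int | None = None,
                 force_sparse: bool | None = None) -> ModeSet:
    """Lowest eigenpairs of the reference Hessian.

    Dense solve for 3N <= 3000 degrees of freedom, shift-invert Lanczos
    otherwise; zero modes flagged by |lambda| < 1e-8 * lambda_max.
    """
    n3 = 3 * model.n_nodes
    use_sparse = (n3 > DENSE_LIMIT) if force_sparse is None else force_sparse
    if n_modes is None:
        n_modes = n3 if not use_sparse else min(n3 - 2, 56)
    if use_sparse:
        h = model.hessian(sparse=True)
        k = min(n_modes + 6, n3 - 1)
        try:
            vals, vecs = scipy.sparse.linalg.eigsh(
                h, k=k, sigma=-1e-5, which="LM")
        except Exception as exc:  # noqa: BLE001 - diagnostics wanted
            raise EigenConvergenceError(
                f"sparse eigensolver failed: {exc}") from exc
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
        lam_max = float(scipy.sparse.linalg.eigsh(
            h, k=1, which="LA", return_eigenvectors=False)[0])
    else:
        h = model.hessian()
        vals, vecs = np.linalg.eigh(h)
        lam_max = float(vals[-1])
    tol = ZERO_MODE_RTOL * max(lam_max, 1.0)
    n_zero = int(np.sum(np.abs(vals) < tol))
    keep = min(len(vals), n_zero + n_modes)
    return ModeSet(vals[:keep], vecs[:, :keep], n_zero, tol)


def mean_square_fluctuation(modes: ModeSet) -> np.ndarray:
    """Per-node MSF_i = sum_k (1/lambda_k) |v_k,i|^2 over nonzero modes
    (relative units of kT/gamma)."""
    if modes.n_zero >= len(modes.eigenvalues):
        raise ValueError("no nonzero modes available")
    n = modes.eigenvectors.shape[0] // 3
    msf = np.zeros(n)
    for lam, vec in modes.nonzero_pairs():
        msf += (vec.reshape(n, 3) ** 2).sum(axis=1) / lam
    return msf


def cross_correlation(modes: ModeSet) -> np.ndarray:
    """Normalized covariance C_ij = <dr_i . dr_j> / sqrt(<dr_i^2><dr_j^2>)."""
    if modes.n_zero >= len(modes.eigenvalues):
        raise ValueError("no nonzero modes available")
    n = modes.eigenvectors.shape[0] // 3
    cov = np.zeros((n, n))
    for lam, vec in modes.nonzero_pairs():
        v = vec.reshape(n, 3)
        cov += (v @ v.T) / lam
    diag = np.sqrt(np.diag(cov))
    return cov / np.outer(diag, diag)


def mode_overlap(modes: ModeSet, delta: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Per-mode overlap of a conformational change with each nonzero mode.

    The displacement is first orthogonalized against the rigid-body
    (zero-mode) space.  Returns (overlaps, cumulative squared overlap),
    both over nonzero modes in eigenvalue order.
    """
    delta = np.asarray(delta, dtype=float).ravel()
    if delta.shape[0] != modes.eigenvectors.shape[0]:
        raise ValueError("displacement length does not match mode dimension")
    for k in range(modes.n_zero):
        v = modes.eigenvectors[:, k]
        delta = delta - (delta @ v) * v
    norm = np.linalg.norm(delta)
    if norm < 1e-12:
        raise ValueError("zero-norm displacement after rigid-body removal")
    overlaps = np.array([
        abs(modes.eigenvectors[:, k] @ delta) / norm for k in modes.nonzero
    ])
    return overlaps, np.cumsum(overlaps ** 2)


def deformation_energy(modes: ModeSet, mode_index: int,
                       amplitude: float) -> float:
    """Harmonic energy 0.5 * lambda * a^2 of exciting one mode
    (``mode_index`` counts within this ModeSet, zero modes included)."""
    lam = modes.eigenvalues[mode_index]
    return float(0.5 * lam * amplitude ** 2)
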