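"""Spatial priors for latent factors: exact GP, predictive process, NNGP.

Each latent factor ``eta_.h`` carries a zero-mean Gaussian prior over the
sites with exponential covariance ``k(s1, s2) = exp(-||s1 - s2|| / alpha)``;
the range ``alpha`` sets the distance at which correlation drops to 1/e
and is learned on a discrete grid during fitting.  The kernel variance is
fixed at 1 (factor scale is carried by the loadings).

Three factorizations of the implied n_y x n_y covariance are supported:

* ``gp`` — the dense covariance and its Cholesky factor (O(n^3); small
  data only).
* ``gpp`` — a Gaussian predictive process: the field is summarized at m
  knot locations, giving the low-rank covariance ``U U^T`` with
  ``U = K_{S S*} chol(K_{S*S*})^{-T}``, plus the diagonal correction
  ``c_i = 1 - sum_t U_it^2`` that restores the exact unit marginal
  variance at every site (the modified predictive process).
* ``nngp`` — a nearest-neighbour Gaussian process: after ordering the
  sites, each site conditions only on its m nearest predecessors, giving
  the sparse factorization ``K^ = (I - A)^{-1} D (I - A)^{-T}`` whose
  precision has O(n m) structural nonzeros.

Both approximations are exact in their limits (knots = sites;
m >= n_y - 1), which the test-suite exploits as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.sparse.linalg import spsolve_triangular
from scipy.spatial.distance import cdist

JITTER = 1e-8  # added to every dense covariance diagonal before factorization
_LOG2PI = float(np.log(2.0 * np.pi))

__all__ = [
    "JITTER",
    "exp_cov",
    "exp_cov_matrix",
    "KnotSet",
    "build_knot_grid",
    "NeighborGraph",
    "build_neighbor_graph",
    "build_structure",
    "SpatialStructure",
    "IdentityStructure",
    "DenseGPStructure",
    "GPPStructure",
    "NNGPStructure",
]


class SpatialNumericalError(RuntimeError):
    """Raised when a covariance factorization fails despite jitter."""


def exp_cov(d, alpha: float):
    """Exponential covariance ``exp(-d / alpha)`` for distances ``d >= 0``.

    ``alpha`` must be strictly positive: a range of 0 denotes the
    nonspatial grid entry and is handled by :class:`IdentityStructure`,
    never passed here.
    """
    if alpha <= 0:
        raise ValueError(f"spatial range alpha must be > 0, got {alpha}")
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    return np.exp(-d / alpha)


def exp_cov_matrix(A: np.ndarray, B: np.ndarray | None = None, *, alpha: float):
    """Kernel matrix between coordinate sets ``A`` and ``B`` (default A)."""
    B = A if B is None else B
    return exp_cov(cdist(np.atleast_2d(A), np.atleast_2d(B)), alpha)


# ---------------------------------------------------------------------------
# knot grids and neighbour graphs
# ---------------------------------------------------------------------------


@dataclass
class KnotSet:
    """Hexagonal-lattice knot locations for the predictive process."""

    coords: np.ndarray  # (m_star, 2)
    spacing: float

    @property
    def m_star(self) -> int:
        return self.coords.shape[0]


def _padded_box(S: np.ndarray):
    x0, y0 = S.min(axis=0)
    x1, y1 = S.max(axis=0)
    w, h = x1 - x0, y1 - y0
    # degenerate boxes are padded so a planar lattice still exists
    if w <= 0:
        pad = 0.5 * max(h, 1.0)
        x0, x1 = x0 - pad, x1 + pad
    if h <= 0:
        pad = 0.5 * max(x1 - x0, 1.0)
        y0, y1 = y0 - pad, y1 + pad
    return x0, x1, y0, y1


def build_knot_grid(S: np.ndarray, m_target: int) -> KnotSet:
    """Uniform hexagonal knot lattice covering the site bounding box.

    Rows are pitched ``sqrt(3)/2 x spacing`` apart and every other row is
    offset by half a spacing.  The spacing is chosen (by a fine scan) as
    the largest value whose lattice holds at least ``m_target`` nodes, so
    the actual knot count ``m_star`` is the smallest achievable count
    >= ``m_target``.  Offset rows keep the full column count and may
    extend slightly past the box edge.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    if m_target < 1:
        raise ValueError("m_target must be >= 1")
    x0, x1, y0, y1 = _padded_box(S)
    w, h = x1 - x0, y1 - y0
    if m_target == 1:
        return KnotSet(
            coords=np.array([[0.5 * (x0 + x1), 0.5 * (y0 + y1)]]),
            spacing=max(w, h),
        )
    pitch = np.sqrt(3.0) / 2.0

    def lattice_shape(a: float):
        ncols = int(np.floor(w / a)) + 1
        nrows = int(np.floor(h / (pitch * a))) + 1
        return nrows, ncols

    a_hi = 2.0 * max(w, h)
    a_lo = 0.25 * np.sqrt(w * h / m_target)
    best = None
    for a in np.geomspace(a_hi, a_lo, 4096):
        nrows, ncols = lattice_shape(a)
        if nrows * ncols >= m_target:
            best = a
            break
    if best is None:  # pragma: no cover - a_lo always yields enough nodes
        best = a_lo
    nrows, ncols = lattice_shape(best)
    nodes = []
    for r in range(nrows):
        yr = y0 + r * pitch * best
        xoff = 0.5 * best if r % 2 else 0.0
        for cidx in range(ncols):
            nodes.append((x0 + xoff + cidx * best, yr))
    return KnotSet(coords=np.array(nodes), spacing=float(best))


@dataclass
class NeighborGraph:
    """Ordered-site neighbour sets for the NNGP factorization.

    ``order[k]`` is the original index of the k-th ordered site; sites are
    ordered by first coordinate, ties by second coordinate, then by input
    index (a deterministic coordinate ordering).  ``neighbors[k]`` lists
    the ordered indices of the min(m, k) nearest predecessors of ordered
    site k (Euclidean distance; ties prefer the smaller ordered index).
    """

    order: np.ndarray
    neighbors: list
    m: int

    @property
    def n(self) -> int:
        return self.order.size


def build_neighbor_graph(S: np.ndarray, m: int) -> NeighborGraph:
    S = np.atleast_2d(np.asarray(S, dtype=float))
    if m < 1:
        raise ValueError("neighbor count m must be >= 1")
    n = S.shape[0]
    order = np.lexsort((np.arange(n), S[:, 1], S[:, 0]))
    coords = S[order]
    neighbors = [np.empty(0, dtype=int)]
    for i in range(1, n):
        d = np.linalg.norm(coords[:i] - coords[i], axis=1)
        sel = np.lexsort((np.arange(i), d))[: min(m, i)]
        neighbors.append(sel)
    return NeighborGraph(order=order, neighbors=neighbors, m=m)


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------


class SpatialStructure:
    """One factorization of a factor's prior covariance at a given range.

    Concrete subclasses expose the primitives the Gibbs sampler needs:
    prior draws, log prior density (``log_marginal``), draws from
    ``N(0, K^{-1})`` for the block factor update, and the cached
    log-determinant of the implied covariance.
    """

    method: str
    alpha: float
    n: int

    def prior_sample(self, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def log_marginal(self, w: np.ndarray) -> float:
        raise NotImplementedError

    def sample_precision(self, rng: np.random.Generator) -> np.ndarray:
        """Draw from ``N(0, K^{-1})`` (used by the perturbation sampler)."""
        raise NotImplementedError

    def covariance(self) -> np.ndarray:
        """Dense implied covariance (small-n diagnostics and tests)."""
        raise NotImplementedError

    def _check_vector(self, w: np.ndarray) -> np.ndarray:
        w = np.asarray(w, dtype=float)
        if w.shape != (self.n,):
            raise ValueError(f"factor vector must have length {self.n}")
        if not np.isfinite(w).all():
            raise ValueError("factor vector contains non-finite values")
        return w


class IdentityStructure(SpatialStructure):
    """Nonspatial factor: iid standard-normal prior (the alpha = 0 entry)."""

    method = "none"

    def __init__(self, n: int):
        self.n = n
        self.alpha = 0.0
        self.log_det = 0.0

    def prior_sample(self, rng):
        return rng.standard_normal(self.n)

    def log_marginal(self, w):
        w = self._check_vector(w)
        return float(-0.5 * w @ w - 0.5 * self.n * _LOG2PI)

    def sample_precision(self, rng):
        return rng.standard_normal(self.n)

    def covariance(self):
        return np.eye(self.n)

    def sparse_sqrt_precision(self):
        return sp.identity(self.n, format="csr")


class DenseGPStructure(SpatialStructure):
    """Exact GP: dense covariance with Cholesky factor (small n only)."""

    method = "gp"

    def __init__(self, S: np.ndarray, alpha: float):
        S = np.atleast_2d(np.asarray(S, dtype=float))
        self.n = S.shape[0]
        self.alpha = float(alpha)
        K = exp_cov_matrix(S, alpha=alpha)
        K[np.diag_indices_from(K)] += JITTER
        try:
            self.L = cholesky(K, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise SpatialNumericalError(
                f"dense covariance not positive-definite at alpha={alpha}"
            ) from exc
        self.K = K
        self.log_det = float(2.0 * np.log(np.diag(self.L)).sum())
        self._sqrt_prec = None

    def prior_sample(self, rng):
        return self.L @ rng.standard_normal(self.n)

    def log_marginal(self, w):
        w = self._check_vector(w)
        u = solve_triangular(self.L, w, lower=True)
        return float(-0.5 * u @ u - 0.5 * self.log_det - 0.5 * self.n * _LOG2PI)

    def sample_precision(self, rng):
        # cov(L^{-T} z) = L^{-T} L^{-1} = K^{-1}
        return solve_triangular(self.L, rng.standard_normal(self.n),
                                lower=True, trans="T")

    def covariance(self):
        return self.K.copy()

    def sparse_sqrt_precision(self):
        if self._sqrt_prec is None:
            Linv = solve_triangular(self.L, np.eye(self.n), lower=True)
            self._sqrt_prec = sp.csr_matrix(Linv)
        return self._sqrt_prec


class GPPStructure(SpatialStructure):
    """Knot-based predictive process with the marginal-variance correction.

    The implied covariance is ``U U^T + diag(c)`` where ``U U^T`` is the
    low-rank predictive-process covariance and ``c_i = 1 - sum_t U_it^2``
    restores the exact unit prior variance at every site.  Solves and
    log-determinants use the Woodbury / matrix-determinant-lemma forms on
    the knot scale and never form the dense n x n covariance.

    The diagonal jitter is treated as a nugget of the kernel: the
    site-knot cross-covariance carries the same nugget at zero distance,
    so a site sitting exactly on a knot is interpolated together with its
    jitter and the knots = sites limit reproduces the jittered dense
    covariance identically.  In that limit ``c`` underflows to 0, the
    Woodbury form degenerates, and the structure transparently falls back
    to a dense factorization (which only ever happens when sites
    coincide with knots, i.e. outside the m << n production regime).
    """

    method = "gpp"

    _C_LOWRANK_MIN = 1e-6  # below this the Woodbury solve is ill-posed

    def __init__(self, S: np.ndarray, alpha: float, knots: KnotSet):
        S = np.atleast_2d(np.asarray(S, dtype=float))
        self.n = S.shape[0]
        self.alpha = float(alpha)
        self.knots = knots
        Kkk = exp_cov_matrix(knots.coords, alpha=alpha)
        Kkk[np.diag_indices_from(Kkk)] += JITTER
        try:
            Lk = cholesky(Kkk, lower=True)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise SpatialNumericalError(
                f"knot covariance not positive-definite at alpha={alpha}"
            ) from exc
        D = cdist(S, knots.coords)
        Ksk = exp_cov(D, alpha)
        Ksk[D == 0.0] += JITTER  # nugget-consistent cross-covariance
        # U = K_{S S*} chol(K_{S*S*})^{-T}, so U U^T = K_{S S*} K_{S*S*}^{-1} K_{S* S}
        self.U = solve_triangular(Lk, Ksk.T, lower=True).T
        self.c = np.maximum(1.0 - np.einsum("ij,ij->i", self.U, self.U), 0.0)
        self.c_eff = np.maximum(self.c, JITTER)
        self.low_rank = bool(self.c.min() > self._C_LOWRANK_MIN)
        if self.low_rank:
            m = self.U.shape[1]
            W = np.eye(m) + self.U.T @ (self.U / self.c[:, None])
            self._LW = cholesky(W, lower=True)
            self.log_det = float(
                np.log(self.c).sum() + 2.0 * np.log(np.diag(self._LW)).sum()
            )
            self._Ld = None
        else:
            Kd = self.U @ self.U.T + np.diag(self.c)
            try:
                self._Ld = cholesky(Kd, lower=True)
            except np.linalg.LinAlgError:
                Kd[np.diag_indices_from(Kd)] += JITTER
                self._Ld = cholesky(Kd, lower=True)
            self.log_det = float(2.0 * np.log(np.diag(self._Ld)).sum())

    @property
    def m_star(self) -> int:
        return self.U.shape[1]

    def marginal_variance(self) -> np.ndarray:
        """Prior variance at each site; equals 1 by the correction."""
        return np.einsum("ij,ij->i", self.U, self.U) + self.c

    def solve_K(self, v: np.ndarray) -> np.ndarray:
        """Solve ``(U U^T + diag(c)) x = v`` (Woodbury, or dense fallback)."""
        if not self.low_rank:
            return cho_solve((self._Ld, True), v)
        t = v / self.c
        y = cho_solve((self._LW, True), self.U.T @ t)
        return t - (self.U @ y) / self.c

    def prior_sample(self, rng):
        if not self.low_rank:
            return self._Ld @ rng.standard_normal(self.n)
        zm = rng.standard_normal(self.m_star)
        zn = rng.standard_normal(self.n)
        return self.U @ zm + np.sqrt(self.c) * zn

    def log_marginal(self, w):
        w = self._check_vector(w)
        quad = float(w @ self.solve_K(w))
        return -0.5 * quad - 0.5 * self.log_det - 0.5 * self.n * _LOG2PI

    def sample_precision(self, rng):
        # K^{-1} x with x ~ N(0, K) has covariance K^{-1}
        return self.solve_K(self.prior_sample(rng))

    def covariance(self):
        return self.U @ self.U.T + np.diag(self.c)

    def sparse_sqrt_precision(self):
        """Dense-fallback square root of the precision (csr).

        Only available outside the low-rank regime; low-rank solves go
        through the knot-scale Woodbury machinery instead.
        """
        if self.low_rank:
            raise RuntimeError(
                "low-rank predictive process has no sparse precision factor"
            )
        if getattr(self, "_sqrt_prec", None) is None:
            Linv = solve_triangular(self._Ld, np.eye(self.n), lower=True)
            self._sqrt_prec = sp.csr_matrix(Linv)
        return self._sqrt_prec


class NNGPStructure(SpatialStructure):
    """Nearest-neighbour GP: sparse triangular factorization of the prior.

    In the coordinate ordering, site k conditions on its neighbour set
    N(k) with weights ``a_k = K(s_k, N) K(N, N)^{-1}`` and conditional
    variance ``d_k = 1 + jitter - a_k K(N, s_k)``, giving
    ``K^ = B^{-1} D B^{-T}`` with the sparse unit-lower-triangular
    ``B = I - A``.  With m >= n-1 this reproduces the dense (jittered)
    covariance exactly.
    """

    method = "nngp"

    def __init__(self, S: np.ndarray, alpha: float, graph: NeighborGraph):
        S = np.atleast_2d(np.asarray(S, dtype=float))
        self.n = S.shape[0]
        if graph.n != self.n:
            raise ValueError("neighbor graph size does not match coordinates")
        self.alpha = float(alpha)
        self.graph = graph
        coords = S[graph.order]
        d = np.empty(self.n)
        rows, cols, vals = [], [], []
        for k in range(self.n):
            nb = graph.neighbors[k]
            if nb.size == 0:
                d[k] = 1.0 + JITTER
                continue
            Knn = exp_cov_matrix(coords[nb], alpha=alpha)
            Knn[np.diag_indices_from(Knn)] += JITTER
            kvec = exp_cov_matrix(coords[k][None, :], coords[nb], alpha=alpha)[0]
            try:
                a = np.linalg.solve(Knn, kvec)
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise SpatialNumericalError(
                    f"neighbor covariance singular at alpha={alpha}"
                ) from exc
            dk = 1.0 + JITTER - float(a @ kvec)
            if dk <= 0:
                raise SpatialNumericalError(
                    f"non-positive conditional variance at alpha={alpha}"
                )
            d[k] = dk
            rows.extend([k] * nb.size)
            cols.extend(nb.tolist())
            vals.extend((-a).tolist())
        self.d = d
        B = sp.coo_matrix(
            (np.concatenate([np.ones(self.n), np.array(vals)]),
             (np.concatenate([np.arange(self.n), np.array(rows, dtype=int)]),
              np.concatenate([np.arange(self.n), np.array(cols, dtype=int)]))),
            shape=(self.n, self.n),
        )
        self.B = B.tocsr()  # I - A, unit lower triangular, ordered space
        self.log_det = float(np.log(d).sum())
        self._inv_order = np.empty(self.n, dtype=int)
        self._inv_order[graph.order] = np.arange(self.n)

    def _to_ordered(self, w):
        return w[self.graph.order]

    def _from_ordered(self, w_ord):
        out = np.empty_like(w_ord)
        out[self.graph.order] = w_ord
        return out

    def prior_sample(self, rng):
        z = rng.standard_normal(self.n)
        w_ord = spsolve_triangular(
            self.B, np.sqrt(self.d) * z, lower=True, unit_diagonal=True
        )
        return self._from_ordered(w_ord)

    def log_marginal(self, w):
        w = self._check_vector(w)
        resid = self.B @ self._to_ordered(w)
        return float(
            -0.5 * np.sum(resid * resid / self.d)
            - 0.5 * self.log_det
            - 0.5 * self.n * _LOG2PI
        )

    def sample_precision(self, rng):
        z = rng.standard_normal(self.n)
        return self._from_ordered(self.B.T @ (z / np.sqrt(self.d)))

    def sparse_sqrt_precision(self):
        """G (csr) with ``G^T G = K^{-1}`` in the original site order."""
        if getattr(self, "_sqrt_prec", None) is None:
            P = sp.csr_matrix(
                (np.ones(self.n), (np.arange(self.n), self.graph.order)),
                shape=(self.n, self.n),
            )
            self._sqrt_prec = (sp.diags(1.0 / np.sqrt(self.d)) @ self.B @ P).tocsr()
        return self._sqrt_prec

    def covariance(self):
        Binv = solve_triangular(self.B.toarray(), np.eye(self.n),
                                lower=True, unit_diagonal=True)
        K_ord = (Binv * self.d) @ Binv.T
        out = np.empty_like(K_ord)
        out[np.ix_(self.graph.order, self.graph.order)] = K_ord
        return out


def build_structure(
    S: np.ndarray,
    method: str,
    alpha: float,
    *,
    knots: KnotSet | None = None,
    graph: NeighborGraph | None = None,
) -> SpatialStructure:
    """Build one factor-prior factorization for a given spatial range.

    ``alpha = 0`` (or ``method="none"``) yields the nonspatial identity
    structure; otherwise the method-specific auxiliary object (knots for
    gpp, neighbour graph for nngp) must be supplied.
    """
    S = np.atleast_2d(np.asarray(S, dtype=float))
    n = S.shape[0]
    if method == "none" or alpha == 0.0:
        return IdentityStructure(n)
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if method == "gp":
        return DenseGPStructure(S, alpha)
    if method == "gpp":
        if knots is None:
            raise ValueError("gpp requires a KnotSet")
        return GPPStructure(S, alpha, knots)
    if method == "nngp":
        if graph is None:
            raise ValueError("nngp requires a NeighborGraph")
        return NNGPStructure(S, alpha, graph)
    raise ValueError(f"unknown spatial method {method!r}")
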