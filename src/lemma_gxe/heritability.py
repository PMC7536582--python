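"""Randomized Haseman-Elston (RHE) variance components for additive and GxE effects.

Given a phenotype y, genotypes X and an environmental score eta, the
single-component model is

    y ~ N(0,  sigma_b^2 K + sigma_g^2 V + sigma_e^2 I),
    K = X X'/M,   V = Z Z'/M,   Z = diag(eta) X,

after projecting fixed effects (intercept, covariates, and eta itself) out of
y, X and Z. Method-of-moments estimation reduces to a small linear system in
traces of products of K and V; at scale those traces are estimated with
Hutchinson probe vectors so nothing N x N is ever formed. SNPs may be
stratified into MAF x LD-score bins (the LDMS scheme) with one additive and
one interaction component per bin, and standard errors come from a
delete-one-block jackknife over contiguous SNP blocks.

Heritabilities use the general transform that weights each component by its
trace over N, which is robust to interaction columns not having unit variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ComponentPartition",
    "VarianceComponents",
    "HeritabilityEstimate",
    "exact_rhe",
    "randomized_rhe",
    "ld_scores",
    "ldms_partition",
    "multi_component_rhe",
    "h2_estimates",
    "jackknife_se",
]

_MAF_EDGES = (0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass
class ComponentPartition:
    """Per-SNP bin assignment for MAF x LD stratified estimation."""

    assignment: np.ndarray
    maf_edges: tuple = _MAF_EDGES
    ld_quantiles: int = 4

    @property
    def n_bins(self) -> int:
        return len(self.maf_edges) * self.ld_quantiles

    def bin_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.n_bins)


@dataclass
class VarianceComponents:
    """Method-of-moments solution (negative estimates permitted but flagged)."""

    sigma_b2: np.ndarray  # per-bin additive variance
    sigma_g2: np.ndarray  # per-bin GxE variance
    sigma_e2: float
    trK_over_N: np.ndarray
    trV_over_N: np.ndarray
    n_eff: float
    bins: np.ndarray = None  # bin label of each component entry
    any_negative: bool = False

    def __post_init__(self) -> None:
        self.sigma_b2 = np.atleast_1d(np.asarray(self.sigma_b2, dtype=float))
        self.sigma_g2 = np.atleast_1d(np.asarray(self.sigma_g2, dtype=float))
        self.trK_over_N = np.atleast_1d(np.asarray(self.trK_over_N, dtype=float))
        self.trV_over_N = np.atleast_1d(np.asarray(self.trV_over_N, dtype=float))
        self.any_negative = bool(
            (self.sigma_b2 < 0).any() or (self.sigma_g2 < 0).any() or self.sigma_e2 < 0
        )


@dataclass
class HeritabilityEstimate:
    h2_g: float
    h2_gxe: float
    se_g: float = float("nan")
    se_gxe: float = float("nan")
    h2_g_bins: np.ndarray = None
    h2_gxe_bins: np.ndarray = None


# ---------------------------------------------------------------------------
# fixed-effect projection helpers
# ---------------------------------------------------------------------------


def _covariate_basis(n: int, es, C) -> np.ndarray:
    """Orthonormal basis Q of [1, C, es]; projection is v - Q (Q'v)."""
    cols = [np.ones(n)]
    if C is not None and np.size(C):
        C = np.asarray(C, dtype=float)
        cols.append(C if C.ndim == 2 else C[:, None])
    if es is not None:
        cols.append(np.asarray(es, dtype=float)[:, None])
    W = np.column_stack(cols)
    q, r = np.linalg.qr(W)
    keep = np.abs(np.diag(r)) > 1e-10 * max(np.abs(np.diag(r)).max(), 1.0)
    return q[:, keep]


def _project(v: np.ndarray, Q: np.ndarray) -> np.ndarray:
    return v - Q @ (Q.T @ v)


# ---------------------------------------------------------------------------
# exact (small-N) solver
# ---------------------------------------------------------------------------


def exact_rhe(y, X, es, C=None) -> VarianceComponents:
    """Solve the single-component moment system with explicit kinship matrices.

    Forms K = X X'/M and V = Z Z'/M after projecting the fixed effects
    (intercept, C, es) out of y, X and Z, so it is only usable at small N.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    es = np.asarray(es, dtype=float)
    n, m = X.shape
    if not np.any(es):
        raise ValueError("es is identically zero: the GxE component is void")
    Q = _covariate_basis(n, es, C)
    yp = _project(y, Q)
    Xp = _project(X, Q)
    Zp = _project(es[:, None] * X, Q)
    K = (Xp @ Xp.T) / m
    V = (Zp @ Zp.T) / m
    n_eff = n - Q.shape[1]
    T = np.array(
        [
            [np.sum(K * K), np.sum(K * V), np.trace(K)],
            [np.sum(K * V), np.sum(V * V), np.trace(V)],
            [np.trace(K), np.trace(V), n_eff],
        ]
    )
    rhs = np.array([yp @ K @ yp, yp @ V @ yp, yp @ yp])
    if np.linalg.cond(T) > 1e12:
        raise ValueError("singular moment system (is V proportional to K?)")
    sol = np.linalg.solve(T, rhs)
    return VarianceComponents(
        sigma_b2=[sol[0]],
        sigma_g2=[sol[1]],
        sigma_e2=float(sol[2]),
        trK_over_N=[np.trace(K) / n_eff],
        trV_over_N=[np.trace(V) / n_eff],
        n_eff=n_eff,
        bins=np.array([0]),
    )


# ---------------------------------------------------------------------------
# randomized core
# ---------------------------------------------------------------------------


class _RandomizedSystem:
    """Hutchinson-estimated moment system, decomposable over SNP blocks.

    Components are (kind, bin) pairs, kind 'K' (additive) or 'V' (interaction),
    plus the identity. All per-component quantities are sums over that
    component's SNPs, so deleting a contiguous SNP block only subtracts the
    block's contribution — which is what the jackknife exploits.
    """

    def __init__(self, y, X, es, C, assignment, B, seed):
        if B < 2:
            raise ValueError("need at least B = 2 probe vectors")
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        es = np.asarray(es, dtype=float)
        n, m = X.shape
        assignment = np.zeros(m, dtype=int) if assignment is None else np.asarray(assignment)
        self.n, self.m, self.B = n, m, B
        self.assignment = assignment

        Q = _covariate_basis(n, es, C)
        self.n_eff = n - Q.shape[1]
        yp = _project(y, Q)
        rng = np.random.default_rng(seed)
        probes = rng.standard_normal((n, B))
        probes = _project(probes, Q)

        # shared M x B / M-vector sketches
        QX = Q.T @ X
        QeX = (Q * es[:, None]).T @ X
        self.t1 = X.T @ probes  # X' P z
        self.t2 = X.T @ (es[:, None] * probes)  # Z' P z
        self.t1y = X.T @ yp
        self.t2y = X.T @ (es * yp)
        self.colsq_k = np.einsum("ij,ij->j", X, X) - np.einsum("ij,ij->j", QX, QX)
        es2_col = np.einsum("i,ij,ij->j", es * es, X, X)
        self.colsq_v = es2_col - np.einsum("ij,ij->j", QeX, QeX)
        self.yy = float(yp @ yp)

        bins = sorted(set(assignment.tolist()))
        empty = [b for b in range(assignment.max() + 1) if b not in bins]
        if empty:
            warnings.warn(f"empty bins {empty} excluded from the solver", stacklevel=3)
        self.bins = np.array(bins)
        self.comps = [("K", b) for b in bins] + [("V", b) for b in bins]
        self._X, self._es, self._Q = X, es, Q

        # unnormalized probe images U_u = P X_S X_S' P z   (N x B each)
        self.U = []
        self.sizes = []
        self.tr_sums = []  # sum of projected column norms over the component
        self.q_sums = []  # sum over component of (x_j' yp)^2
        for kind, b in self.comps:
            sel = np.flatnonzero(assignment == b)
            self.sizes.append(sel.size)
            if kind == "K":
                img = X[:, sel] @ self.t1[sel]
                self.tr_sums.append(float(self.colsq_k[sel].sum()))
                self.q_sums.append(float(np.sum(self.t1y[sel] ** 2)))
            else:
                img = es[:, None] * (X[:, sel] @ self.t2[sel])
                self.tr_sums.append(float(self.colsq_v[sel].sum()))
                self.q_sums.append(float(np.sum(self.t2y[sel] ** 2)))
            self.U.append(_project(img, Q))
        self.sizes = np.array(self.sizes, dtype=float)
        # full Gram of probe images
        nc = len(self.comps)
        self.gram = np.empty((nc, nc))
        for u in range(nc):
            for v in range(u, nc):
                self.gram[u, v] = self.gram[v, u] = float(np.sum(self.U[u] * self.U[v]))

    def _assemble(self, gram, sizes, tr_sums, q_sums):
        """Normal equations from (possibly block-deleted) raw sums."""
        nc = len(self.comps)
        T = np.empty((nc + 1, nc + 1))
        rhs = np.empty(nc + 1)
        traces = tr_sums / sizes
        for u in range(nc):
            for v in range(u, nc):
                T[u, v] = T[v, u] = gram[u, v] / (self.B * sizes[u] * sizes[v])
            T[u, nc] = T[nc, u] = traces[u]
            rhs[u] = q_sums[u] / sizes[u]
        T[nc, nc] = self.n_eff
        rhs[nc] = self.yy
        return T, rhs, traces

    def solve(self, gram=None, sizes=None, tr_sums=None, q_sums=None) -> VarianceComponents:
        T, rhs, traces = self._assemble(
            self.gram if gram is None else gram,
            self.sizes if sizes is None else sizes,
            np.asarray(self.tr_sums if tr_sums is None else tr_sums, dtype=float),
            np.asarray(self.q_sums if q_sums is None else q_sums, dtype=float),
        )
        # symmetric Jacobi scaling: the raw traces span orders of magnitude
        d = np.sqrt(np.abs(np.diag(T)))
        d[d == 0] = 1.0
        T_s = T / np.outer(d, d)
        cond = np.linalg.cond(T_s)
        if cond > 1e10:
            warnings.warn(
                f"ill-conditioned moment system (cond ~ {cond:.2g}); "
                "solving by pseudo-inverse",
                stacklevel=3,
            )
        sol, *_ = np.linalg.lstsq(T_s, rhs / d, rcond=None)
        sol = sol / d
        nb = len(self.bins)
        return VarianceComponents(
            sigma_b2=sol[:nb],
            sigma_g2=sol[nb : 2 * nb],
            sigma_e2=float(sol[-1]),
            trK_over_N=traces[:nb] / self.n_eff,
            trV_over_N=traces[nb:] / self.n_eff,
            n_eff=self.n_eff,
            bins=self.bins.copy(),
        )

    def block_corrections(self, block: np.ndarray):
        """Raw-sum corrections for deleting one contiguous SNP block.

        Returns (gram_d, sizes_d, tr_d, q_d) such that subtracting them from
        the full raw sums reproduces the system built without the block.
        """
        X, es, Q = self._X, self._es, self._Q
        nc = len(self.comps)
        sizes_d = np.zeros(nc)
        tr_d = np.zeros(nc)
        q_d = np.zeros(nc)
        imgs = {}
        for u, (kind, b) in enumerate(self.comps):
            sel = block[self.assignment[block] == b]
            if sel.size == 0:
                continue
            sizes_d[u] = sel.size
            if kind == "K":
                img = X[:, sel] @ self.t1[sel]
                tr_d[u] = float(self.colsq_k[sel].sum())
                q_d[u] = float(np.sum(self.t1y[sel] ** 2))
            else:
                img = es[:, None] * (X[:, sel] @ self.t2[sel])
                tr_d[u] = float(self.colsq_v[sel].sum())
                q_d[u] = float(np.sum(self.t2y[sel] ** 2))
            imgs[u] = _project(img, Q)
        gram_d = np.zeros((nc, nc))
        for u in imgs:
            for v in range(nc):
                cross = float(np.sum(imgs[u] * self.U[v]))
                gram_d[u, v] += cross
                gram_d[v, u] += cross
        for u in imgs:
            for v in imgs:
                gram_d[u, v] -= float(np.sum(imgs[u] * imgs[v]))
        return gram_d, sizes_d, tr_d, q_d


def randomized_rhe(y, X, es, C=None, B: int = 50, seed: int = 0) -> VarianceComponents:
    """Single-component RHE with Hutchinson trace estimates (B probe vectors).

    Deterministic for a fixed seed; agrees with :func:`exact_rhe` up to
    Monte-Carlo error of order 1/sqrt(B) in the estimated traces.
    """
    sys_ = _RandomizedSystem(y, X, es, C, None, B, seed)
    return sys_.solve()


def multi_component_rhe(
    y, X, es, C, partition: ComponentPartition, B: int = 50, seed: int = 0
) -> VarianceComponents:
    """One additive and one GxE variance component per partition bin."""
    sys_ = _RandomizedSystem(y, X, es, C, partition.assignment, B, seed)
    return sys_.solve()


# ---------------------------------------------------------------------------
# LD scores and LDMS partition
# ---------------------------------------------------------------------------


def ld_scores(X: np.ndarray, window: int, chrom_bounds=None) -> np.ndarray:
    """In-sample LD score: sum of r^2 with SNPs within ``window`` either side.

    ``X`` must be column-standardized; r uses the n-1 denominator so that
    r_jj = 1 is always included. ``chrom_bounds`` is an iterable of
    half-open column ranges; windows never cross a boundary.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if chrom_bounds is None:
        chrom_bounds = [(0, m)]
    scores = np.empty(m)
    chunk = 512
    for start, stop in chrom_bounds:
        for s in range(start, stop, chunk):
            e = min(s + chunk, stop)
            lo = max(start, s - window)
            hi = min(stop, e + window)
            G = (X[:, lo:hi].T @ X[:, s:e]) / (n - 1)
            G2 = G * G
            csum = np.vstack([np.zeros((1, e - s)), np.cumsum(G2, axis=0)])
            for j in range(s, e):
                a = max(lo, j - window) - lo
                b = min(hi, j + window + 1) - lo
                scores[j] = csum[b, j - s] - csum[a, j - s]
    return scores


def ldms_partition(variants, ld: np.ndarray, n_ld_quantiles: int = 4) -> ComponentPartition:
    """Assign each SNP to one of 5 MAF bins x ``n_ld_quantiles`` LD bins.

    MAF bins are (0, 0.1], (0.1, 0.2], ..., (0.4, 0.5] (right-inclusive); LD
    quantile edges come from the empirical in-sample LD-score distribution.
    """
    maf = np.array([v.maf for v in variants], dtype=float)
    ld = np.asarray(ld, dtype=float)
    if maf.shape != ld.shape:
        raise ValueError("ld scores and variants differ in length")
    edges = np.asarray(_MAF_EDGES)
    # right-inclusive bins: maf <= 0.1 -> 0, 0.1 < maf <= 0.2 -> 1, ...
    maf_bin = np.searchsorted(edges, maf, side="left")
    maf_bin = np.clip(maf_bin, 0, len(edges) - 1)
    qs = np.quantile(ld, np.linspace(0, 1, n_ld_quantiles + 1)[1:-1])
    ld_bin = np.searchsorted(qs, ld, side="right")
    assignment = maf_bin * n_ld_quantiles + ld_bin
    return ComponentPartition(
        assignment=assignment, maf_edges=_MAF_EDGES, ld_quantiles=n_ld_quantiles
    )


# ---------------------------------------------------------------------------
# heritability transform and jackknife
# ---------------------------------------------------------------------------


def h2_estimates(components: VarianceComponents) -> HeritabilityEstimate:
    """Trace-weighted heritability shares from a variance-component solution.

    h2_gxe = sum_b sigma_g2_b tr(V_b)/N over the total expected variance
    sum_b sigma_b2_b tr(K_b)/N + sum_b sigma_g2_b tr(V_b)/N + sigma_e2; the
    additive share is analogous. Reduces to the naive ratio when all traces
    over N are one (standardized genotype columns).
    """
    g_parts = components.sigma_b2 * components.trK_over_N
    gxe_parts = components.sigma_g2 * components.trV_over_N
    denom = float(g_parts.sum() + gxe_parts.sum() + components.sigma_e2)
    if denom <= 0:
        raise ValueError("non-positive total variance in heritability transform")
    return HeritabilityEstimate(
        h2_g=float(g_parts.sum() / denom),
        h2_gxe=float(gxe_parts.sum() / denom),
        h2_g_bins=g_parts / denom,
        h2_gxe_bins=gxe_parts / denom,
    )


def jackknife_se(
    y,
    X,
    es,
    C=None,
    partition: ComponentPartition | None = None,
    n_blocks: int = 100,
    B: int = 50,
    seed: int = 0,
) -> HeritabilityEstimate:
    """Point estimates with delete-one-block jackknife standard errors.

    Blocks are ``n_blocks`` contiguous SNP ranges. Each delete-one re-estimate
    reuses the full-data probe sketches, subtracting only the block's sums, so
    the whole jackknife costs about one extra pass over the genotypes.
    """
    X = np.asarray(X, dtype=float)
    m = X.shape[1]
    if n_blocks < 2:
        raise ValueError("need at least 2 jackknife blocks")
    if n_blocks > m:
        raise ValueError(f"n_blocks = {n_blocks} exceeds SNP count {m}")
    assignment = partition.assignment if partition is not None else None
    sys_ = _RandomizedSystem(y, X, es, C, assignment, B, seed)
    full = sys_.solve()
    point = h2_estimates(full)

    bounds = np.linspace(0, m, n_blocks + 1).astype(int)
    thetas = []
    for d in range(n_blocks):
        block = np.arange(bounds[d], bounds[d + 1])
        gram_d, sizes_d, tr_d, q_d = sys_.block_corrections(block)
        sizes = sys_.sizes - sizes_d
        if np.any(sizes <= 0):
            # a bin fully contained in the block: skip this replicate
            continue
        comp = sys_.solve(
            gram=sys_.gram - gram_d,
            sizes=sizes,
            tr_sums=np.asarray(sys_.tr_sums) - tr_d,
            q_sums=np.asarray(sys_.q_sums) - q_d,
        )
        est = h2_estimates(comp)
        thetas.append((est.h2_g, est.h2_gxe))
    thetas = np.asarray(thetas)
    nb = thetas.shape[0]
    mean = thetas.mean(axis=0)
    se = np.sqrt((nb - 1) / nb * np.sum((thetas - mean) ** 2, axis=0))
    point.se_g = float(se[0])
    point.se_gxe = float(se[1])
    return point
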