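"""Variational inference for the environmental-score whole-genome regression.

The model is

    y = C alpha + X beta + (eta (.) X) gamma + eps,     eta = E w,

with mixture-of-Gaussians (slab + spike) priors on the per-SNP main effects
beta and interaction effects gamma, a flat Gaussian prior on the covariate
effects alpha, and a standard Gaussian prior on the environment weights w.
The length-N vector eta — the environmental score (ES) — is a single linear
combination of environments that multiplies genotypes genome wide.

The posterior is approximated by a fully factorized (mean-field) distribution
optimized by coordinate ascent on the evidence lower bound (ELBO). The eight
model hyper-parameters (residual variance, two variance scales and a mixture
weight per effect type, and the fixed covariate prior variance) are updated by
closed-form variational-EM steps, accelerated with SQUAREM extrapolation on a
log/logit-transformed scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as _dataclass_fields, replace

import numpy as np

from . import _kernels
from .data_io import SampleAlignedDataset

__all__ = [
    "Hyperparameters",
    "VariationalState",
    "FitConfig",
    "FitResult",
    "initialize_state",
    "coordinate_ascent_pass",
    "compute_elbo",
    "maximize_hyperparameters",
    "squarem_step",
    "fit",
    "environmental_score",
]

_LAMBDA_CLAMP = 1e-6
_VAR_FLOOR = 1e-10


def _logit(p):
    return np.log(p) - np.log1p(-p)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class Hyperparameters:
    """The eight-parameter set governing the priors.

    ``sigma_b1``/``sigma_b2`` (and ``sigma_g1``/``sigma_g2``) are slab/spike
    variance *scales*: the prior variance of a slab main effect is
    ``sigma_e2 * sigma_b1``. ``lambda_b``/``lambda_g`` are slab mixture
    weights. ``sigma_a2`` is held at a large constant (flat covariate prior)
    and never updated.
    """

    sigma_e2: float
    sigma_b1: float
    sigma_b2: float
    sigma_g1: float
    sigma_g2: float
    lambda_b: float
    lambda_g: float
    sigma_a2: float = 100.0

    def __post_init__(self) -> None:
        for name in ("sigma_e2", "sigma_b1", "sigma_b2", "sigma_g1", "sigma_g2", "sigma_a2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.lambda_b = float(np.clip(self.lambda_b, _LAMBDA_CLAMP, 1 - _LAMBDA_CLAMP))
        self.lambda_g = float(np.clip(self.lambda_g, _LAMBDA_CLAMP, 1 - _LAMBDA_CLAMP))

    def to_vector(self) -> np.ndarray:
        """Unconstrained transform: log variances, logit mixture weights."""
        return np.array(
            [
                math.log(self.sigma_e2),
                math.log(self.sigma_b1),
                math.log(self.sigma_b2),
                math.log(self.sigma_g1),
                math.log(self.sigma_g2),
                _logit(self.lambda_b),
                _logit(self.lambda_g),
            ]
        )

    @classmethod
    def from_vector(cls, vec: np.ndarray, sigma_a2: float = 100.0) -> "Hyperparameters":
        if not np.all(np.isfinite(vec)) or np.any(np.abs(vec) > 50.0):
            raise ValueError("hyper-parameter vector outside the representable domain")
        return cls(
            sigma_e2=math.exp(vec[0]),
            sigma_b1=math.exp(vec[1]),
            sigma_b2=math.exp(vec[2]),
            sigma_g1=math.exp(vec[3]),
            sigma_g2=math.exp(vec[4]),
            lambda_b=float(_expit(vec[5])),
            lambda_g=float(_expit(vec[6])),
            sigma_a2=sigma_a2,
        )

    def label_ordered(self) -> "Hyperparameters":
        """Enforce slab >= spike variance by swapping component labels."""
        out = replace(self)
        if out.sigma_b1 < out.sigma_b2:
            out.sigma_b1, out.sigma_b2 = out.sigma_b2, out.sigma_b1
            out.lambda_b = 1.0 - out.lambda_b
        if out.sigma_g1 < out.sigma_g2:
            out.sigma_g1, out.sigma_g2 = out.sigma_g2, out.sigma_g1
            out.lambda_g = 1.0 - out.lambda_g
        return out


@dataclass
class VariationalState:
    """Factorized approximate posterior plus cached linear predictors.

    Each SNP effect has a two-component posterior: slab responsibility
    (``beta_resp``) and a Gaussian (mean, variance) under each component.
    Cache vectors: ``r_lin = y - C a - X beta_bar`` (gamma part excluded),
    ``g = X gamma_bar``, ``eta`` / ``eta2`` the first two moments of the ES.
    """

    alpha_mean: np.ndarray
    alpha_var: np.ndarray
    w_mean: np.ndarray
    w_var: np.ndarray
    beta_resp: np.ndarray
    beta_mean1: np.ndarray
    beta_var1: np.ndarray
    beta_mean2: np.ndarray
    beta_var2: np.ndarray
    gamma_resp: np.ndarray
    gamma_mean1: np.ndarray
    gamma_var1: np.ndarray
    gamma_mean2: np.ndarray
    gamma_var2: np.ndarray
    r_lin: np.ndarray
    g: np.ndarray
    eta: np.ndarray
    eta2: np.ndarray
    g2: np.ndarray = None  # end-of-pass E[(X gamma)_i^2]; rebuilt when absent

    def copy(self) -> "VariationalState":
        """Deep copy (used to roll back rejected accelerated steps)."""
        return VariationalState(
            **{
                f.name: (getattr(self, f.name).copy() if getattr(self, f.name) is not None else None)
                for f in _dataclass_fields(self)
            }
        )

    @property
    def beta_bar(self) -> np.ndarray:
        r = self.beta_resp
        return r * self.beta_mean1 + (1 - r) * self.beta_mean2

    @property
    def beta_sq(self) -> np.ndarray:
        """Posterior second moment E[beta_j^2]."""
        r = self.beta_resp
        return r * (self.beta_mean1**2 + self.beta_var1) + (1 - r) * (
            self.beta_mean2**2 + self.beta_var2
        )

    @property
    def gamma_bar(self) -> np.ndarray:
        r = self.gamma_resp
        return r * self.gamma_mean1 + (1 - r) * self.gamma_mean2

    @property
    def gamma_sq(self) -> np.ndarray:
        r = self.gamma_resp
        return r * (self.gamma_mean1**2 + self.gamma_var1) + (1 - r) * (
            self.gamma_mean2**2 + self.gamma_var2
        )

    def check_cache(self, dataset: SampleAlignedDataset, tol: float = 1e-6) -> None:
        """Verify cached predictors against from-scratch recomputation."""
        X, C, E = dataset.genotypes, dataset.covariates, dataset.environments
        y = dataset.phenotype
        ref_r = y - C @ self.alpha_mean - X @ self.beta_bar
        ref_g = X @ self.gamma_bar
        ref_eta = E @ self.w_mean
        ref_eta2 = ref_eta**2 + (E**2) @ self.w_var
        for name, got, ref in (
            ("r_lin", self.r_lin, ref_r),
            ("g", self.g, ref_g),
            ("eta", self.eta, ref_eta),
            ("eta2", self.eta2, ref_eta2),
        ):
            err = float(np.max(np.abs(got - ref))) if got.size else 0.0
            if err > tol:
                raise AssertionError(f"cache {name} drifted by {err:.3g}")


@dataclass
class FitConfig:
    """Controls for :func:`fit`."""

    covariate_mode: str = "variational"  # or "project-out"
    elbo_tol: float = 0.01
    max_passes: int = 200
    seed: int = 0
    sigma_a2: float = 100.0
    use_squarem: bool = True
    init: str = "default"

    def __post_init__(self) -> None:
        if self.elbo_tol <= 0:
            raise ValueError("elbo_tol must be positive")
        if self.covariate_mode not in ("variational", "project-out"):
            raise ValueError(f"unknown covariate_mode {self.covariate_mode!r}")


@dataclass
class FitResult:
    alpha_hat: np.ndarray
    beta_hat: np.ndarray
    gamma_hat: np.ndarray
    w_hat: np.ndarray
    w_sd: np.ndarray
    es: np.ndarray
    phi: Hyperparameters
    elbo_trace: list[float]
    n_passes: int
    converged: bool
    beta_resp: np.ndarray = None
    gamma_resp: np.ndarray = None
    state: VariationalState = None


# ---------------------------------------------------------------------------
# chunked helpers (avoid materializing X**2)
# ---------------------------------------------------------------------------

_CHUNK = 2048


def _weighted_sq_colsums(X: np.ndarray, w: np.ndarray) -> np.ndarray:
    """sum_i w_i * X_ij**2 for every column j."""
    m = X.shape[1]
    out = np.empty(m)
    for s in range(0, m, _CHUNK):
        blk = X[:, s : s + _CHUNK]
        out[s : s + _CHUNK] = w @ (blk * blk)
    return out


def _sq_matvec(X: np.ndarray, v: np.ndarray) -> np.ndarray:
    """sum_j X_ij**2 * v_j for every row i."""
    out = np.zeros(X.shape[0])
    for s in range(0, X.shape[1], _CHUNK):
        blk = X[:, s : s + _CHUNK]
        out += (blk * blk) @ v[s : s + _CHUNK]
    return out


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def initialize_state(
    dataset: SampleAlignedDataset, config: FitConfig
) -> tuple[VariationalState, Hyperparameters]:
    """Deterministic (per seed) starting point for the variational fit.

    SNP-effect posteriors start at zero mean with prior variances; the
    environment-weight means are drawn N(0, 1/L) to break the sign symmetry
    of the bilinear ES-times-gamma term. Initial hyper-parameters put 10% of
    expected phenotypic variance on main effects and 1% on interactions, with
    slab mixture weights of 0.1 and spike variances 100x smaller than slabs.
    """
    n, m = dataset.genotypes.shape
    n_env = dataset.environments.shape[1]
    if n_env == 0:
        raise ValueError(
            "no environmental variables: the model requires L >= 1 "
            "(a main-effects-only fit is unsupported)"
        )
    rng = np.random.default_rng(config.seed)
    lam = 0.1
    sb1 = 0.1 / (m * lam)
    sg1 = 0.01 / (m * lam)
    phi = Hyperparameters(
        sigma_e2=1.0,
        sigma_b1=sb1,
        sigma_b2=sb1 / 100.0,
        sigma_g1=sg1,
        sigma_g2=sg1 / 100.0,
        lambda_b=lam,
        lambda_g=lam,
        sigma_a2=config.sigma_a2,
    )
    n_cov = dataset.covariates.shape[1]
    w_mean = rng.normal(0.0, 1.0 / math.sqrt(n_env), size=n_env)
    w_var = np.full(n_env, 1.0 / n_env)
    eta = dataset.environments @ w_mean
    eta2 = eta**2 + (dataset.environments**2) @ w_var
    state = VariationalState(
        alpha_mean=np.zeros(n_cov),
        alpha_var=np.full(n_cov, config.sigma_a2),
        w_mean=w_mean,
        w_var=w_var,
        beta_resp=np.full(m, phi.lambda_b),
        beta_mean1=np.zeros(m),
        beta_var1=np.full(m, phi.sigma_e2 * phi.sigma_b1),
        beta_mean2=np.zeros(m),
        beta_var2=np.full(m, phi.sigma_e2 * phi.sigma_b2),
        gamma_resp=np.full(m, phi.lambda_g),
        gamma_mean1=np.zeros(m),
        gamma_var1=np.full(m, phi.sigma_e2 * phi.sigma_g1),
        gamma_mean2=np.zeros(m),
        gamma_var2=np.full(m, phi.sigma_e2 * phi.sigma_g2),
        r_lin=dataset.phenotype.astype(float).copy(),
        g=np.zeros(n),
        eta=eta,
        eta2=eta2,
    )
    return state, phi


def _mixture_update(lin, quad, se2, slab_scale, spike_scale, lam):
    """Optimal two-component posterior for one coefficient.

    ``lin`` is the coefficient of the linear term of the expected
    log-likelihood (x' residual), ``quad`` the coefficient of the quadratic
    term (expected squared design column). Returns (resp, m1, v1, m2, v2).
    """
    d1 = quad + 1.0 / slab_scale
    d2 = quad + 1.0 / spike_scale
    m1 = lin / d1
    m2 = lin / d2
    v1 = se2 / d1
    v2 = se2 / d2
    # log-odds of slab vs spike; the se2 factors cancel
    log_odds = (
        _logit(lam)
        - 0.5 * math.log1p(slab_scale * quad)
        + 0.5 * math.log1p(spike_scale * quad)
        + 0.5 * m1 * m1 / v1
        - 0.5 * m2 * m2 / v2
    )
    if not np.isfinite(log_odds):
        raise FloatingPointError("non-finite mixture update")
    resp = _expit(np.clip(log_odds, -700, 700))
    return resp, m1, v1, m2, v2


def coordinate_ascent_pass(
    state: VariationalState, phi: Hyperparameters, dataset: SampleAlignedDataset
) -> VariationalState:
    """One full sweep of closed-form coordinate updates at fixed phi.

    Order: covariate effects, then per SNP the (beta_j, gamma_j) pair in
    genome order, then the environment weights. Each factor is replaced by
    its optimal mean-field update; caches are maintained incrementally. The
    ELBO is non-decreasing over the sweep.
    """
    X, C, E, y = (
        dataset.genotypes,
        dataset.covariates,
        dataset.environments,
        dataset.phenotype,
    )
    n, m = X.shape
    se2 = phi.sigma_e2
    r_lin, g, eta, eta2 = state.r_lin, state.g, state.eta, state.eta2

    # --- covariate effects (Gaussian, prior N(0, sigma_a2))
    if C.shape[1]:
        eta_g = eta * g
        for c in range(C.shape[1]):
            cc = C[:, c]
            ctc = float(cc @ cc)
            lin = float(cc @ r_lin) + ctc * state.alpha_mean[c] - float(cc @ eta_g)
            prec = ctc / se2 + 1.0 / phi.sigma_a2
            new_mean = lin / se2 / prec
            if not np.isfinite(new_mean):
                raise FloatingPointError(f"non-finite update for covariate factor {c}")
            r_lin -= cc * (new_mean - state.alpha_mean[c])
            state.alpha_mean[c] = new_mean
            state.alpha_var[c] = 1.0 / prec

    # --- per-SNP effect pairs
    xtx = _get_xtx(dataset)
    z2 = _weighted_sq_colsums(X, eta2)  # expected squared interaction column
    eta_g = eta * g
    e2g = eta2 * g
    beta_bar = state.beta_bar
    gamma_bar = state.gamma_bar
    if _kernels.HAVE_NUMBA:
        status = _kernels.snp_sweep(
            X,
            xtx,
            z2,
            r_lin,
            g,
            eta,
            eta2,
            eta_g,
            e2g,
            state.beta_resp,
            state.beta_mean1,
            state.beta_var1,
            state.beta_mean2,
            state.beta_var2,
            beta_bar,
            state.gamma_resp,
            state.gamma_mean1,
            state.gamma_var1,
            state.gamma_mean2,
            state.gamma_var2,
            gamma_bar,
            se2,
            phi.sigma_b1,
            phi.sigma_b2,
            phi.sigma_g1,
            phi.sigma_g2,
            _logit(phi.lambda_b),
            _logit(phi.lambda_g),
        )
        if status:
            raise FloatingPointError(f"non-finite update for SNP factor {status - 1}")
    else:
        for j in range(m):
            xj = X[:, j]
            # main effect
            lin = float(xj @ r_lin) + xtx[j] * beta_bar[j] - float(xj @ eta_g)
            resp, m1, v1, m2, v2 = _mixture_update(
                lin, xtx[j], se2, phi.sigma_b1, phi.sigma_b2, phi.lambda_b
            )
            new_bar = resp * m1 + (1 - resp) * m2
            delta = new_bar - beta_bar[j]
            if delta != 0.0:
                r_lin -= xj * delta
            state.beta_resp[j] = resp
            state.beta_mean1[j] = m1
            state.beta_var1[j] = v1
            state.beta_mean2[j] = m2
            state.beta_var2[j] = v2
            beta_bar[j] = new_bar
            # interaction effect
            xe = xj * eta
            lin = float(xe @ r_lin) - float(xj @ e2g) + z2[j] * gamma_bar[j]
            resp, m1, v1, m2, v2 = _mixture_update(
                lin, z2[j], se2, phi.sigma_g1, phi.sigma_g2, phi.lambda_g
            )
            new_bar = resp * m1 + (1 - resp) * m2
            delta = new_bar - gamma_bar[j]
            if delta != 0.0:
                g += xj * delta
                eta_g += xe * delta
                e2g += (xj * eta2) * delta
            state.gamma_resp[j] = resp
            state.gamma_mean1[j] = m1
            state.gamma_var1[j] = v1
            state.gamma_mean2[j] = m2
            state.gamma_var2[j] = v2
            gamma_bar[j] = new_bar

    # --- environment weights (Gaussian, prior N(0, 1))
    gvar = _sq_matvec(X, state.gamma_sq - gamma_bar**2)
    g2 = g * g + gvar  # E[(X gamma)_i^2]
    state.g2 = g2
    n_env = E.shape[1]
    if n_env:
        a2 = _weighted_sq_colsums(E, g2)
        gr = g * r_lin
        g2eta = g2 * eta
        for l in range(n_env):
            el = E[:, l]
            lin = float(el @ gr) - float(el @ g2eta) + a2[l] * state.w_mean[l]
            prec = a2[l] / se2 + 1.0
            new_mean = lin / se2 / prec
            if not np.isfinite(new_mean):
                raise FloatingPointError(f"non-finite update for environment weight {l}")
            delta = new_mean - state.w_mean[l]
            if delta != 0.0:
                eta += el * delta
                g2eta += g2 * el * delta
            state.w_mean[l] = new_mean
            state.w_var[l] = 1.0 / prec
        state.eta2[:] = eta**2 + (E**2) @ state.w_var
    return state


def _get_xtx(dataset: SampleAlignedDataset) -> np.ndarray:
    """Column squared norms of X, memoized on the dataset instance."""
    cached = getattr(dataset, "_xtx_cache", None)
    if cached is not None and cached[0] == id(dataset.genotypes):
        return cached[1]
    xtx = np.einsum("ij,ij->j", dataset.genotypes, dataset.genotypes)
    dataset._xtx_cache = (id(dataset.genotypes), xtx)
    return xtx


def _expected_rss(state: VariationalState, dataset: SampleAlignedDataset) -> float:
    """E_q || y - C alpha - X beta - eta (.) X gamma ||^2."""
    X, C = dataset.genotypes, dataset.covariates
    mu = state.r_lin - state.eta * state.g
    total = float(mu @ mu)
    if C.shape[1]:
        ctc = np.einsum("ij,ij->j", C, C)
        total += float(ctc @ state.alpha_var)
    xtx = _get_xtx(dataset)
    total += float(xtx @ (state.beta_sq - state.beta_bar**2))
    if state.g2 is not None:
        g2 = state.g2
    else:
        g2 = state.g**2 + _sq_matvec(X, state.gamma_sq - state.gamma_bar**2)
    total += float(np.sum(state.eta2 * g2 - (state.eta * state.g) ** 2))
    return total


def _kl_gaussian(mean, var, prior_var):
    return 0.5 * ((mean**2 + var) / prior_var - 1.0 - np.log(var / prior_var))


def _kl_mixture(resp, m1, v1, m2, v2, lam, slab_var, spike_var):
    r = np.clip(resp, 1e-300, 1.0)
    q = np.clip(1.0 - resp, 1e-300, 1.0)
    kl = r * (np.log(r / lam) + _kl_gaussian(m1, v1, slab_var))
    kl += q * (np.log(q / (1.0 - lam)) + _kl_gaussian(m2, v2, spike_var))
    return float(np.sum(kl))


def compute_elbo(
    state: VariationalState, phi: Hyperparameters, dataset: SampleAlignedDataset
) -> float:
    """Evidence lower bound F(nu; phi) under the factorized posterior."""
    n = dataset.n_samples
    se2 = phi.sigma_e2
    ll = -0.5 * n * math.log(2 * math.pi * se2) - _expected_rss(state, dataset) / (
        2 * se2
    )
    kl = 0.0
    if state.alpha_mean.size:
        kl += float(np.sum(_kl_gaussian(state.alpha_mean, state.alpha_var, phi.sigma_a2)))
    if state.w_mean.size:
        kl += float(np.sum(_kl_gaussian(state.w_mean, state.w_var, 1.0)))
    kl += _kl_mixture(
        state.beta_resp,
        state.beta_mean1,
        state.beta_var1,
        state.beta_mean2,
        state.beta_var2,
        phi.lambda_b,
        se2 * phi.sigma_b1,
        se2 * phi.sigma_b2,
    )
    kl += _kl_mixture(
        state.gamma_resp,
        state.gamma_mean1,
        state.gamma_var1,
        state.gamma_mean2,
        state.gamma_var2,
        phi.lambda_g,
        se2 * phi.sigma_g1,
        se2 * phi.sigma_g2,
    )
    elbo = ll - kl
    if not np.isfinite(elbo):
        raise FloatingPointError("non-finite ELBO")
    return elbo


def maximize_hyperparameters(
    state: VariationalState,
    dataset: SampleAlignedDataset,
    phi: Hyperparameters | None = None,
) -> Hyperparameters:
    """Closed-form variational M-step (sigma_a2 untouched).

    The residual variance is the expected residual sum of squares over N;
    slab/spike variance scales are responsibility-weighted means of the
    posterior second moments divided by the new residual variance; mixture
    weights are mean slab responsibilities. Jointly these maximize the ELBO
    at fixed q, so the ELBO cannot decrease.
    """
    n, m = dataset.genotypes.shape
    sigma_a2 = phi.sigma_a2 if phi is not None else 100.0
    se2 = _expected_rss(state, dataset) / n
    se2 = max(se2, _VAR_FLOOR)

    def scales(resp, m1, v1, m2, v2):
        r1 = float(np.sum(resp))
        r2 = float(m - r1)
        a1 = float(np.sum(resp * (m1**2 + v1)))
        a2 = float(np.sum((1 - resp) * (m2**2 + v2)))
        s1 = a1 / (se2 * r1) if r1 > 0 else _VAR_FLOOR
        s2 = a2 / (se2 * r2) if r2 > 0 else _VAR_FLOOR
        return max(s1, _VAR_FLOOR), max(s2, _VAR_FLOOR), r1 / m

    sb1, sb2, lam_b = scales(
        state.beta_resp, state.beta_mean1, state.beta_var1, state.beta_mean2, state.beta_var2
    )
    sg1, sg2, lam_g = scales(
        state.gamma_resp,
        state.gamma_mean1,
        state.gamma_var1,
        state.gamma_mean2,
        state.gamma_var2,
    )
    # enforce slab >= spike by swapping component labels; the matching state
    # components must swap too (the ELBO is invariant only under a joint swap)
    if sb1 < sb2:
        sb1, sb2, lam_b = sb2, sb1, 1.0 - lam_b
        state.beta_resp = 1.0 - state.beta_resp
        state.beta_mean1, state.beta_mean2 = state.beta_mean2, state.beta_mean1
        state.beta_var1, state.beta_var2 = state.beta_var2, state.beta_var1
    if sg1 < sg2:
        sg1, sg2, lam_g = sg2, sg1, 1.0 - lam_g
        state.gamma_resp = 1.0 - state.gamma_resp
        state.gamma_mean1, state.gamma_mean2 = state.gamma_mean2, state.gamma_mean1
        state.gamma_var1, state.gamma_var2 = state.gamma_var2, state.gamma_var1
    return Hyperparameters(
        sigma_e2=se2,
        sigma_b1=sb1,
        sigma_b2=sb2,
        sigma_g1=sg1,
        sigma_g2=sg2,
        lambda_b=lam_b,
        lambda_g=lam_g,
        sigma_a2=sigma_a2,
    )


def squarem_step(phi_t2, phi_t1, phi_t, step: float | None = None):
    """Squared-extrapolation acceleration of a fixed-point iterate sequence.

    Operates on unconstrained (log/logit-transformed) parameter vectors or
    scalars. With first difference d1 = phi_t1 - phi_t2 and second difference
    d2 = phi_t - 2 phi_t1 + phi_t2, the step size is
    v = min(-1, -||d1||^2 / ||d2||^2) and the extrapolated point is
    phi_t2 - 2 v d1 + v^2 d2; v = -1 recovers phi_t unchanged. A vanishing
    second difference returns phi_t (no acceleration possible).
    """
    phi_t2 = np.asarray(phi_t2, dtype=float)
    phi_t1 = np.asarray(phi_t1, dtype=float)
    phi_t = np.asarray(phi_t, dtype=float)
    d1 = phi_t1 - phi_t2
    d2 = phi_t - 2 * phi_t1 + phi_t2
    denom = float(np.sum(d2 * d2))
    if denom == 0.0:
        return phi_t
    v = step if step is not None else min(-1.0, -float(np.sum(d1 * d1)) / denom)
    if v == -1.0:  # mathematically the identity: avoid round-off
        return phi_t
    return phi_t2 - 2 * v * d1 + v * v * d2


def fit(dataset: SampleAlignedDataset, config: FitConfig | None = None) -> FitResult:
    """Fit the whole-genome regression and extract the environmental score.

    Alternates a coordinate-ascent sweep, a hyper-parameter M-step and (when
    three iterates are available) a SQUAREM extrapolation that is accepted
    only if it does not lower the ELBO. Convergence is declared when a full
    pass changes the ELBO by less than ``config.elbo_tol`` in absolute value.
    """
    if config is None:
        config = FitConfig()
    ds = dataset
    if config.covariate_mode == "project-out" and dataset.covariates.shape[1]:
        C = np.column_stack([np.ones(dataset.n_samples), dataset.covariates])
        coef, *_ = np.linalg.lstsq(C, dataset.phenotype, rcond=None)
        ds = replace(
            dataset,
            phenotype=dataset.phenotype - C @ coef,
            covariates=np.empty((dataset.n_samples, 0)),
            covariate_names=[],
        )
    if _kernels.HAVE_NUMBA and not ds.genotypes.flags.f_contiguous:
        ds = replace(ds, genotypes=np.asfortranarray(ds.genotypes, dtype=float))
    state, phi = initialize_state(ds, config)
    trace: list[float] = []
    cycle: list[np.ndarray] = [phi.to_vector()]
    converged = False
    n_passes = 0

    def em_step(state, phi):
        state = coordinate_ascent_pass(state, phi, ds)
        phi = maximize_hyperparameters(state, ds, phi)
        return state, phi

    def record(elbo: float) -> bool:
        prev = trace[-1] if trace else -np.inf
        trace.append(elbo)
        return abs(elbo - prev) < config.elbo_tol

    while n_passes < config.max_passes and not converged:
        # two ordinary variational-EM steps open a SQUAREM cycle
        n_passes += 1
        state, phi = em_step(state, phi)
        cycle.append(phi.to_vector())
        converged = record(compute_elbo(state, phi, ds))
        if converged or not config.use_squarem or n_passes >= config.max_passes:
            if len(cycle) == 3:
                cycle = [phi.to_vector()]
            continue
        if len(cycle) < 3:
            continue
        # extrapolate, with backtracking toward v = -1 while out of domain
        cand = None
        v = None
        cand_vec = squarem_step(cycle[0], cycle[1], cycle[2])
        for _try in range(6):
            try:
                cand = Hyperparameters.from_vector(
                    cand_vec, sigma_a2=phi.sigma_a2
                ).label_ordered()
                break
            except (ValueError, FloatingPointError, OverflowError):
                d1 = cycle[1] - cycle[0]
                d2 = cycle[2] - 2 * cycle[1] + cycle[0]
                denom = float(np.sum(d2 * d2))
                if denom == 0.0:
                    break
                if v is None:
                    v = min(-1.0, -float(np.sum(d1 * d1)) / denom)
                v = 0.5 * (v - 1.0)
                cand_vec = squarem_step(cycle[0], cycle[1], cycle[2], step=v)
                cand = None
        if cand is not None and not np.allclose(cand_vec, cycle[2]):
            # stabilizing EM step from the extrapolated point; keep it only if
            # the ELBO does not fall below the last recorded value, halving
            # the step toward v = -1 on failure (v = -1 is the plain EM step)
            saved_state, saved_phi = state.copy(), phi
            d1 = cycle[1] - cycle[0]
            d2 = cycle[2] - 2 * cycle[1] + cycle[0]
            denom = float(np.sum(d2 * d2))
            if v is None:
                v = min(-1.0, -float(np.sum(d1 * d1)) / denom) if denom else -1.0
            for _try in range(4):
                if n_passes >= config.max_passes:
                    state, phi = saved_state, saved_phi
                    break
                n_passes += 1
                try:
                    state, phi = em_step(state, cand)
                    elbo = compute_elbo(state, phi, ds)
                except (ValueError, FloatingPointError, OverflowError):
                    elbo = -np.inf
                if elbo >= trace[-1] - 1e-8 * abs(trace[-1]):
                    converged = record(elbo)
                    break
                # fall back and retry with a shorter extrapolation
                state, phi = saved_state.copy(), saved_phi
                v = 0.5 * (v - 1.0)
                if v >= -1.0 or _try == 3:
                    state, phi = saved_state, saved_phi
                    break
                try:
                    cand = Hyperparameters.from_vector(
                        squarem_step(cycle[0], cycle[1], cycle[2], step=v),
                        sigma_a2=phi.sigma_a2,
                    ).label_ordered()
                except (ValueError, FloatingPointError, OverflowError):
                    state, phi = saved_state, saved_phi
                    break
        cycle = [phi.to_vector()]
    if not converged:
        import warnings

        warnings.warn(
            f"variational fit did not converge in {config.max_passes} passes",
            stacklevel=2,
        )
    es = environmental_score(ds.environments, state.w_mean)
    return FitResult(
        alpha_hat=state.alpha_mean.copy(),
        beta_hat=state.beta_bar,
        gamma_hat=state.gamma_bar,
        w_hat=state.w_mean.copy(),
        w_sd=np.sqrt(state.w_var),
        es=es,
        phi=phi,
        elbo_trace=trace,
        n_passes=n_passes,
        converged=converged,
        beta_resp=state.beta_resp.copy(),
        gamma_resp=state.gamma_resp.copy(),
        state=state,
    )


def environmental_score(environments: np.ndarray, w_hat: np.ndarray) -> np.ndarray:
    """The ES: eta = E w."""
    environments = np.asarray(environments, dtype=float)
    w_hat = np.asarray(w_hat, dtype=float)
    if environments.ndim != 2 or environments.shape[1] != w_hat.shape[0]:
        raise ValueError(
            f"environment matrix has {environments.shape[1] if environments.ndim == 2 else '?'} "
            f"columns but w_hat has length {w_hat.shape[0]}"
        )
    return environments @ w_hat
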