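"""Synthetic genotype / environment / phenotype generation with ground truth.

The generator emulates the study design used throughout the package's
evaluation: binomial hard-call genotypes (allele frequencies uniform on
[0.05, 0.5], optional first-order Markov LD) split across pseudo-chromosomes,
standard-Gaussian environments, and phenotypes built from

    y = X beta + (E w) (.) (X gamma) + c1 PC1 + eps,

where all causal SNPs sit in the first half of each chromosome (the second
half provides null SNPs for calibration), a small set of SNPs carries
standardized (equal-size) effects for power measurement, and every component
is rescaled empirically so realized variance fractions hit their targets
exactly. A misspecification design is included where the trait depends on the
square of a heritable environmental factor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.linalg import svds

from .data_io import VariantRecord

__all__ = [
    "SimConfig",
    "SimTruth",
    "MisspecConfig",
    "simulate_genotypes",
    "simulate_environments",
    "simulate_phenotype",
    "simulate_misspecified",
    "evaluate_power_fpr",
]


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic phenotype generator."""

    n_samples: int = 25000
    n_snps: int = 100000
    n_chrom: int = 22
    n_env: int = 30
    n_active_env: int = 6
    n_causal_main: int = 2500
    n_causal_gxe: int = 1250
    var_main: float = 0.20
    var_gxe: float = 0.05
    n_standardized_snps: int = 60
    var_std_main: float = 0.01
    var_std_gxe: float = 0.01
    var_pc1: float = 0.01
    ld_rho: float = 0.0
    causal_maf_max: float | None = None  # restrict causal SNPs to low MAF
    seed: int = 0

    def __post_init__(self) -> None:
        total = (
            self.var_main
            + self.var_gxe
            + self.var_std_main
            + self.var_std_gxe
            + self.var_pc1
        )
        if total >= 1.0:
            raise ValueError(f"variance fractions sum to {total} >= 1")
        eligible = self.n_snps // 2
        if self.n_causal_main + self.n_causal_gxe + self.n_standardized_snps > 2 * eligible:
            raise ValueError("causal counts exceed eligible (first-half) SNP count")


@dataclass
class SimTruth:
    """Full generative record for one simulated phenotype."""

    beta: np.ndarray  # main effects of the polygenic causal set (length M)
    gamma: np.ndarray  # interaction effects of the polygenic causal set
    beta_std: np.ndarray  # main effects of the standardized-effect SNPs
    gamma_std: np.ndarray  # interaction effects of the standardized-effect SNPs
    w: np.ndarray  # environment weights (nonzero on active environments)
    eta: np.ndarray  # true ES
    causal_main_idx: np.ndarray
    causal_gxe_idx: np.ndarray
    std_idx: np.ndarray
    null_idx: np.ndarray  # second half of each chromosome
    realized: dict = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "causal_main_idx": self.causal_main_idx.tolist(),
            "causal_gxe_idx": self.causal_gxe_idx.tolist(),
            "std_idx": self.std_idx.tolist(),
            "w": self.w.tolist(),
            "realized": self.realized,
            "beta_nonzero": self.beta[self.causal_main_idx].tolist(),
            "gamma_nonzero": self.gamma[self.causal_gxe_idx].tolist(),
        }
        return json.dumps(payload, indent=1)


@dataclass
class MisspecConfig:
    """Trait depending non-linearly on a heritable environmental factor S."""

    a: float = 0.2  # strength of the squared dependence
    h_tau2: float = 0.2  # heritability of S
    h_beta2: float = 0.2  # additive heritability of Y
    lambda_tau: float = 0.05  # causal fraction for S
    lambda_beta: float = 0.05  # causal fraction for Y
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("h_tau2", "h_beta2"):
            if not (0.0 <= getattr(self, name) < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        for name in ("lambda_tau", "lambda_beta"):
            if not (0.0 < getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")


def simulate_genotypes(config: SimConfig):
    """Binomial(2, f_j) dosages, f_j ~ U(0.05, 0.5), over pseudo-chromosomes.

    With ``ld_rho`` > 0, first-order LD is induced within each chromosome by a
    Gaussian-copula haplotype model: two latent AR(1) Gaussian processes (one
    per haplotype, autocorrelation ``ld_rho``) are thresholded at each SNP's
    allele frequency, so every marginal stays exactly Binomial(2, f_j) and the
    MAF spectrum is preserved at any LD level. Returns the integer dosage
    matrix and the variant list with chromosome labels.
    """
    if config.n_snps < 2 * config.n_chrom:
        raise ValueError("need at least 2 SNPs per pseudo-chromosome")
    rng = np.random.default_rng(config.seed)
    n, m = config.n_samples, config.n_snps
    freqs = rng.uniform(0.05, 0.5, size=m)
    bounds = np.linspace(0, m, config.n_chrom + 1).astype(int)
    if config.ld_rho == 0:
        X = rng.binomial(2, freqs[None, :], size=(n, m)).astype(np.int8)
    else:
        from scipy.stats import norm

        rho = config.ld_rho
        cut = norm.ppf(freqs)
        X = np.zeros((n, m), dtype=np.int8)
        innov_sd = np.sqrt(1.0 - rho * rho)
        for _hap in range(2):
            for start, stop in zip(bounds[:-1], bounds[1:]):
                z = rng.standard_normal(n)
                X[:, start] += z < cut[start]
                for j in range(start + 1, stop):
                    z = rho * z + innov_sd * rng.standard_normal(n)
                    X[:, j] += z < cut[j]
    variants = []
    for c, (start, stop) in enumerate(zip(bounds[:-1], bounds[1:]), start=1):
        for j in range(start, stop):
            variants.append(
                VariantRecord(
                    chrom=str(c),
                    pos=j - start + 1,
                    id=f"snp{j}",
                    a0="A",
                    a1="B",
                    maf=min(freqs[j], 1 - freqs[j]),
                )
            )
    return X, variants


def simulate_environments(n_samples: int, n_env: int, seed: int = 0) -> np.ndarray:
    """i.i.d. standard-Gaussian environments, column-standardized."""
    if n_env < 1:
        raise ValueError("need at least one environment")
    rng = np.random.default_rng(seed)
    E = rng.standard_normal((n_samples, n_env))
    return (E - E.mean(axis=0)) / E.std(axis=0, ddof=1)


def _first_half_mask(n_snps: int, n_chrom: int) -> np.ndarray:
    bounds = np.linspace(0, n_snps, n_chrom + 1).astype(int)
    mask = np.zeros(n_snps, dtype=bool)
    for start, stop in zip(bounds[:-1], bounds[1:]):
        mask[start : (start + stop) // 2] = True
    return mask


def _scale_to(component: np.ndarray, target: float) -> tuple[np.ndarray, float]:
    """Scale a component vector so its empirical variance equals ``target``."""
    if target == 0.0:
        return np.zeros_like(component), 0.0
    sd = component.std()
    if sd == 0:
        raise ValueError("degenerate zero-variance component")
    factor = np.sqrt(target) / sd
    return component * factor, factor


def simulate_phenotype(genotypes, environments, config: SimConfig, maf=None):
    """Build a unit-variance phenotype with the configured architecture.

    ``genotypes`` and ``environments`` must be column-standardized. Causal
    SNPs (polygenic and standardized-effect, all disjoint) are drawn from the
    first half of each chromosome; each variance component is rescaled so its
    realized fraction matches the target exactly. With
    ``config.causal_maf_max`` set, polygenic causal SNPs are further
    restricted to variants at or below that minor allele frequency (``maf``
    per SNP must then be supplied). Returns ``(y, SimTruth)``.
    """
    X = np.asarray(genotypes, dtype=float)
    E = np.asarray(environments, dtype=float)
    n, m = X.shape
    rng = np.random.default_rng(config.seed + 1)

    eligible_mask = _first_half_mask(m, config.n_chrom)
    if config.causal_maf_max is not None:
        if maf is None:
            raise ValueError("causal_maf_max requires per-SNP maf values")
        eligible_mask = eligible_mask & (np.asarray(maf) <= config.causal_maf_max)
    first_half = np.flatnonzero(eligible_mask)
    null_idx = np.flatnonzero(~_first_half_mask(m, config.n_chrom))
    needed = config.n_causal_main + config.n_standardized_snps
    if max(needed, config.n_causal_gxe + config.n_standardized_snps) > first_half.size:
        raise ValueError("not enough first-half SNPs for the requested causal counts")
    perm = rng.permutation(first_half)
    std_idx = np.sort(perm[: config.n_standardized_snps])
    rest = perm[config.n_standardized_snps :]
    causal_main = np.sort(rest[: config.n_causal_main])
    causal_gxe = np.sort(rng.permutation(rest)[: config.n_causal_gxe])

    # environment weights: equal on active environments
    w = np.zeros(config.n_env)
    active = rng.choice(config.n_env, size=config.n_active_env, replace=False)
    w[active] = 1.0 / np.sqrt(config.n_active_env)
    eta = E @ w

    beta = np.zeros(m)
    beta[causal_main] = rng.standard_normal(causal_main.size)
    main_comp, f = _scale_to(X @ beta, config.var_main)
    beta *= f

    gamma = np.zeros(m)
    gamma[causal_gxe] = rng.standard_normal(causal_gxe.size)
    gxe_comp, f = _scale_to(eta * (X @ gamma), config.var_gxe)
    gamma *= f

    # standardized-effect SNPs: equal magnitudes, random signs
    beta_std = np.zeros(m)
    gamma_std = np.zeros(m)
    std_main_comp = np.zeros(n)
    std_gxe_comp = np.zeros(n)
    if config.n_standardized_snps:
        beta_std[std_idx] = rng.choice([-1.0, 1.0], size=std_idx.size)
        std_main_comp, f = _scale_to(X @ beta_std, config.var_std_main)
        beta_std *= f
        gamma_std[std_idx] = rng.choice([-1.0, 1.0], size=std_idx.size)
        std_gxe_comp, f = _scale_to(eta * (X @ gamma_std), config.var_std_gxe)
        gamma_std *= f

    pc_comp = np.zeros(n)
    if config.var_pc1 > 0:
        u, s, vt = svds(X, k=1, random_state=np.random.RandomState(config.seed + 2))
        pc_comp, _ = _scale_to(u[:, 0] * s[0], config.var_pc1)

    var_e = 1.0 - (
        config.var_main
        + config.var_gxe
        + config.var_std_main
        + config.var_std_gxe
        + config.var_pc1
    )
    eps, _ = _scale_to(rng.standard_normal(n), var_e)

    y = main_comp + gxe_comp + std_main_comp + std_gxe_comp + pc_comp + eps
    vy = y.var()
    realized = {
        "var_main": float(main_comp.var() / vy),
        "var_gxe": float(gxe_comp.var() / vy),
        "var_std_main": float(std_main_comp.var() / vy),
        "var_std_gxe": float(std_gxe_comp.var() / vy),
        "var_pc1": float(pc_comp.var() / vy),
        "var_resid": float(eps.var() / vy),
    }
    # normalize to unit variance; effects rescale with y
    scale = 1.0 / np.sqrt(vy)
    truth = SimTruth(
        beta=beta * scale,
        gamma=gamma * scale,
        beta_std=beta_std * scale,
        gamma_std=gamma_std * scale,
        w=w,
        eta=eta,
        causal_main_idx=causal_main,
        causal_gxe_idx=causal_gxe,
        std_idx=std_idx,
        null_idx=null_idx,
        realized=realized,
    )
    return y * scale, truth


def simulate_misspecified(genotypes, config: MisspecConfig):
    """Trait with a squared dependence on a heritable environment S.

    S = X tau + eps_s with spike-and-slab tau (slab variance
    h_tau2 / (M lambda_tau)) and eps_s ~ N(0, (1 - h_tau2) I), so Var(S) is
    about 1 for standardized X. Y = a S^2 + X beta + eps with
    eps ~ N(0, 1 - h_beta2). Returns (Y, S, truth dict with the nonzero
    index sets of tau and beta).
    """
    X = np.asarray(genotypes, dtype=float)
    n, m = X.shape
    rng = np.random.default_rng(config.seed)
    v = rng.random(m) < config.lambda_tau
    tau = np.zeros(m)
    tau[v] = rng.normal(0.0, np.sqrt(config.h_tau2 / (m * config.lambda_tau)), v.sum())
    S = X @ tau + rng.normal(0.0, np.sqrt(1.0 - config.h_tau2), n)

    u = rng.random(m) < config.lambda_beta
    beta = np.zeros(m)
    beta[u] = rng.normal(0.0, np.sqrt(config.h_beta2 / (m * config.lambda_beta)), u.sum())
    Y = config.a * S**2 + X @ beta + rng.normal(0.0, np.sqrt(1.0 - config.h_beta2), n)
    truth = {
        "tau": tau,
        "beta": beta,
        "tau_nonzero": np.flatnonzero(v),
        "beta_nonzero": np.flatnonzero(u),
    }
    return Y, S, truth


def evaluate_power_fpr(results, truth: SimTruth, alpha: float):
    """Power on the standardized-effect SNPs and FPR on second-half null SNPs.

    ``results`` is a genome-ordered list of per-SNP association results (one
    per simulated SNP) or an array of GxE p-values of the same length.
    Returns a dict with power, fpr and their binomial standard errors.
    """
    if hasattr(results[0], "p_gxe"):
        p = np.array([r.p_gxe for r in results], dtype=float)
    else:
        p = np.asarray(results, dtype=float)
    n_expected = truth.beta.shape[0]
    if p.shape[0] != n_expected:
        raise ValueError(
            f"results cover {p.shape[0]} SNPs but the truth records {n_expected}"
        )
    hits_std = np.nan_to_num(p[truth.std_idx], nan=1.0) < alpha
    hits_null = np.nan_to_num(p[truth.null_idx], nan=1.0) < alpha
    power = float(hits_std.mean()) if truth.std_idx.size else float("nan")
    fpr = float(hits_null.mean())
    return {
        "power": power,
        "power_se": float(np.sqrt(power * (1 - power) / max(truth.std_idx.size, 1))),
        "fpr": fpr,
        "fpr_se": float(np.sqrt(fpr * (1 - fpr) / truth.null_idx.size)),
        "alpha": alpha,
    }
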