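"""Single-SNP association testing with the environmental score.

After the whole-genome fit, each variant is tested for a main effect and a
multiplicative interaction with the estimated ES against a leave-one-
chromosome-out (LOCO) residual phenotype. Because genome-wide GxE induces
conditional heteroskedasticity, the interaction test uses Huber-White
(sandwich) standard errors with the small-sample leverage adjustment that
divides squared residuals by (1 - h_ii)^2.

Also provided: the multi-environment F-test and robust F-test comparators,
screening for squared environmental dependence, SNP-specific interaction
profiles, and least-squares utilities for re-expressing ES weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .data_io import SampleAlignedDataset, VariantRecord
from .inference import FitResult

__all__ = [
    "LocoResidualSet",
    "AssociationResult",
    "SquaredEnvReport",
    "InteractionProfile",
    "loco_residuals",
    "gxe_single_snp_test",
    "gxe_scan",
    "f_test",
    "robust_f_test",
    "detect_squared_env",
    "snp_interaction_profile",
    "rescale_weights",
    "marginal_es",
]


@dataclass
class LocoResidualSet:
    """Per-chromosome residual phenotypes y - C a - X_loco b - es (.) X_loco g."""

    residuals: dict[str, np.ndarray]
    es: np.ndarray


@dataclass
class AssociationResult:
    variant: VariantRecord
    beta_test: float
    gamma_test: float
    se_beta: float
    se_gamma_robust: float
    p_main: float
    p_gxe: float
    n: int
    flagged: bool = False
    # diagnostic: the same interaction test without the sandwich correction
    se_gamma_homo: float = float("nan")
    p_gxe_homo: float = float("nan")


@dataclass
class SquaredEnvReport:
    """Per-environment squared-effect screen; ``included`` marks p < 0.01/L."""

    estimates: np.ndarray
    p_values: np.ndarray
    included: np.ndarray
    threshold: float
    augmented_covariates: np.ndarray = None


@dataclass
class InteractionProfile:
    variant_id: str
    w_ls: np.ndarray
    eta_ls: np.ndarray
    r2_with_es: float


def loco_residuals(dataset: SampleAlignedDataset, fit: FitResult) -> LocoResidualSet:
    """Residualize the phenotype leaving each chromosome's fitted effects out.

    For chromosome c the residual excludes main and interaction contributions
    of SNPs on c, so a test SNP is never conditioned on its own chromosome.
    """
    chroms = dataset.chromosomes
    if len(chroms) < 2:
        raise ValueError(
            "LOCO residuals need >= 2 chromosomes; split SNPs into "
            "pseudo-chromosomes if the data has only one"
        )
    X, C = dataset.genotypes, dataset.covariates
    es = fit.es
    base = dataset.phenotype - C @ fit.alpha_hat if C.shape[1] else dataset.phenotype.copy()
    full_pred = X @ fit.beta_hat + es * (X @ fit.gamma_hat)
    residuals = {}
    for chrom in chroms:
        start, stop = dataset.chrom_index[chrom]
        Xc = X[:, start:stop]
        contrib = Xc @ fit.beta_hat[start:stop] + es * (Xc @ fit.gamma_hat[start:stop])
        residuals[chrom] = base - (full_pred - contrib)
    return LocoResidualSet(residuals=residuals, es=es)


def gxe_single_snp_test(
    x_test: np.ndarray,
    es: np.ndarray,
    residual: np.ndarray,
    variant: VariantRecord | None = None,
) -> AssociationResult:
    """Joint main + GxE single-SNP test on a residualized phenotype.

    Regresses the residual on H = [x, es (.) x]. The main effect uses a plain
    t test (homoskedastic SE, N - 2 df); the interaction effect is referred
    to chi-square(1) with the leverage-adjusted sandwich variance
    (H'H)^-1 H' Sigma H (H'H)^-1, Sigma_ii = e_i^2 / (1 - h_ii)^2.
    """
    x = np.asarray(x_test, dtype=float)
    y = np.asarray(residual, dtype=float)
    n = x.shape[0]
    if variant is None:
        variant = VariantRecord(chrom="0", pos=1, id="snp", a0="A", a1="B")
    H = np.column_stack([x, es * x])
    hth = H.T @ H
    if np.linalg.matrix_rank(hth) < 2 or np.linalg.cond(hth) > 1e12:
        return AssociationResult(
            variant, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, n, flagged=True
        )
    hth_inv = np.linalg.inv(hth)
    tau = hth_inv @ (H.T @ y)
    resid = y - H @ tau
    rss = float(resid @ resid)
    # main effect: homoskedastic t test
    sigma2 = rss / (n - 2)
    var_homo = sigma2 * hth_inv
    se_beta = float(np.sqrt(var_homo[0, 0]))
    t_stat = tau[0] / se_beta
    p_main = 2.0 * stats.t.sf(abs(t_stat), df=n - 2)
    # interaction effect: leverage-adjusted sandwich
    leverage = np.einsum("ij,jk,ik->i", H, hth_inv, H)
    one_minus_h = 1.0 - leverage
    degenerate = rss <= 1e-24 * max(float(y @ y), 1.0)  # residual in span(H)
    if np.any(one_minus_h <= 0) or degenerate:
        return AssociationResult(
            variant,
            float(tau[0]),
            float(tau[1]),
            se_beta,
            np.nan,
            p_main,
            np.nan,
            n,
            flagged=True,
        )
    w = (resid / one_minus_h) ** 2
    meat = (H * w[:, None]).T @ H
    var_robust = hth_inv @ meat @ hth_inv
    se_gamma = float(np.sqrt(var_robust[1, 1]))
    chi2 = (tau[1] / se_gamma) ** 2
    p_gxe = float(stats.chi2.sf(chi2, df=1))
    se_gamma_homo = float(np.sqrt(var_homo[1, 1]))
    p_gxe_homo = float(stats.chi2.sf((tau[1] / se_gamma_homo) ** 2, df=1))
    tiny = np.finfo(float).tiny
    return AssociationResult(
        variant,
        float(tau[0]),
        float(tau[1]),
        se_beta,
        se_gamma,
        float(max(p_main, tiny)),
        float(max(p_gxe, tiny)),
        n,
        se_gamma_homo=se_gamma_homo,
        p_gxe_homo=float(max(p_gxe_homo, tiny)),
    )


def gxe_scan(
    dataset: SampleAlignedDataset,
    loco: LocoResidualSet,
    standardize: bool = True,
) -> list[AssociationResult]:
    """Run the single-SNP test at every variant against its LOCO residual."""
    from .data_io import standardize_columns

    results = []
    X = dataset.genotypes
    for chrom, (start, stop) in dataset.chrom_index.items():
        resid = loco.residuals[chrom]
        for j in range(start, stop):
            x = X[:, j]
            if standardize:
                sd = x.std(ddof=1)
                x = (x - x.mean()) / sd if sd > 0 else x - x.mean()
            results.append(
                gxe_single_snp_test(x, loco.es, resid, variant=dataset.variants[j])
            )
    return results


def _interaction_design(C, E, x_test):
    n = x_test.shape[0]
    cols = [np.ones(n)]
    if C is not None and C.size:
        cols.append(C)
    cols.append(E)
    cols.append(x_test[:, None])
    cols.append(x_test[:, None] * E)
    H = np.column_stack(cols)
    n_gxe = E.shape[1]
    if np.linalg.matrix_rank(H) < H.shape[1]:
        raise ValueError("rank-deficient design (collinear covariate/environment columns)")
    return H, n_gxe


def f_test(y, C, E, x_test) -> tuple[float, float]:
    """Homoskedastic F test of all L interaction coefficients being zero.

    Fits y ~ 1 + C + E + x + x(.)E by OLS; under the null the statistic
    follows F(L, N - d1) with d1 the column rank of the full design.
    """
    H, n_gxe = _interaction_design(C, E, np.asarray(x_test, dtype=float))
    model = sm.OLS(np.asarray(y, dtype=float), H).fit()
    R = np.zeros((n_gxe, H.shape[1]))
    R[:, H.shape[1] - n_gxe :] = np.eye(n_gxe)
    res = model.f_test(R)
    return float(res.fvalue), float(res.pvalue)


def robust_f_test(y, C, E, x_test) -> tuple[float, float]:
    """Wald test of the L interaction coefficients with HC3 sandwich variance.

    The statistic is referred to chi-square with L degrees of freedom; the
    (1 - h_ii)^-2 weighting matches the small-sample adjustment used by the
    single-SNP GxE test.
    """
    H, n_gxe = _interaction_design(C, E, np.asarray(x_test, dtype=float))
    model = sm.OLS(np.asarray(y, dtype=float), H).fit(cov_type="HC3")
    R = np.zeros((n_gxe, H.shape[1]))
    R[:, H.shape[1] - n_gxe :] = np.eye(n_gxe)
    res = model.wald_test(R, use_f=False, scalar=True)
    return float(res.statistic), float(res.pvalue)


def detect_squared_env(y, C, E, threshold: float = 0.01) -> SquaredEnvReport:
    """Screen each environment for a squared effect on the phenotype.

    Environment l is included when the t-test p-value of b_l in
    y = 1 a0 + C a + E_l^2 b_l + e falls below ``threshold / L`` (Bonferroni
    over the L environments). Included squared columns (centered) are
    appended to the covariates.
    """
    y = np.asarray(y, dtype=float)
    E = np.asarray(E, dtype=float)
    n, n_env = E.shape
    base = [np.ones(n)]
    if C is not None and np.size(C):
        base.append(np.asarray(C, dtype=float))
    base = np.column_stack(base)
    cutoff = threshold / n_env
    estimates = np.full(n_env, np.nan)
    pvals = np.full(n_env, np.nan)
    for l in range(n_env):
        sq = E[:, l] ** 2
        H = np.column_stack([base, sq])
        if np.linalg.matrix_rank(H) < H.shape[1]:
            warnings.warn(
                f"squared environment {l} collinear with covariates; skipped",
                stacklevel=2,
            )
            continue
        model = sm.OLS(y, H).fit()
        estimates[l] = model.params[-1]
        pvals[l] = model.pvalues[-1]
    included = pvals < cutoff
    aug = base[:, 1:]
    if included.any():
        sq_cols = E[:, included] ** 2
        aug = np.column_stack([aug, sq_cols - sq_cols.mean(axis=0)]) if aug.size else (
            sq_cols - sq_cols.mean(axis=0)
        )
    return SquaredEnvReport(
        estimates=estimates,
        p_values=pvals,
        included=included,
        threshold=cutoff,
        augmented_covariates=aug,
    )


def snp_interaction_profile(y, C, E, x_test, es) -> InteractionProfile:
    """Least-squares interaction weights at a single locus.

    Fits y ~ 1 + C + x + x(.)E by OLS; the locus-specific profile is
    eta_LS = E w_LS. Its squared correlation with the supplied genome-wide ES
    measures how well the shared score captures this locus's interactions.
    """
    y = np.asarray(y, dtype=float)
    E = np.asarray(E, dtype=float)
    x = np.asarray(x_test, dtype=float)
    n, n_env = E.shape
    cols = [np.ones(n)]
    if C is not None and np.size(C):
        cols.append(np.asarray(C, dtype=float))
    cols.append(x[:, None])
    cols.append(x[:, None] * E)
    H = np.column_stack(cols)
    if np.linalg.matrix_rank(H) < H.shape[1]:
        raise ValueError("rank-deficient design in interaction profile fit")
    coef, *_ = np.linalg.lstsq(H, y, rcond=None)
    w_ls = coef[-n_env:]
    eta_ls = E @ w_ls
    es = np.asarray(es, dtype=float)
    if eta_ls.std() == 0 or es.std() == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(eta_ls, es)[0, 1] ** 2)
    return InteractionProfile(variant_id="snp", w_ls=w_ls, eta_ls=eta_ls, r2_with_es=r2)


def rescale_weights(es: np.ndarray, E1: np.ndarray) -> tuple[np.ndarray, float]:
    """Express the ES in the basis of a re-coded environment matrix.

    Returns the least-squares weights (E1'E1)^-1 E1' es together with the
    norm of the projection residual (zero when E1 spans the ES exactly).
    """
    E1 = np.asarray(E1, dtype=float)
    es = np.asarray(es, dtype=float)
    if np.linalg.matrix_rank(E1) < E1.shape[1]:
        raise ValueError("rank-deficient recoded environment matrix")
    coef, *_ = np.linalg.lstsq(E1, es, rcond=None)
    resid = float(np.linalg.norm(es - E1 @ coef))
    return coef, resid


def marginal_es(y, C, E, env_cols: list[int] | None = None) -> np.ndarray:
    """ES built from marginal (least-squares) environmental main effects.

    Fits y on the covariates C (which must contain the environment columns)
    and combines the coefficients of the E columns: ES_marginal = E b_E.
    ``env_cols`` gives the indices of the E columns within C; by default the
    E block is matched by value against C's columns.
    """
    y = np.asarray(y, dtype=float)
    C = np.asarray(C, dtype=float)
    E = np.asarray(E, dtype=float)
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    if env_cols is None:
        env_cols = []
        for l in range(E.shape[1]):
            matches = np.flatnonzero(
                np.all(np.isclose(C, E[:, l][:, None]), axis=0)
            )
            if matches.size == 0:
                raise ValueError(f"environment column {l} not found among covariates")
            env_cols.append(int(matches[0]))
    coef, *_ = np.linalg.lstsq(C, y, rcond=None)
    return E @ coef[env_cols]
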