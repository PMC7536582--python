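"""Shared fixtures: small simulated datasets built at test time."""

from __future__ import annotations

import numpy as np
import pytest

from lemma_gxe import data_io, simulation


def make_dataset(
    n_samples=300,
    n_snps=120,
    n_chrom=4,
    n_env=5,
    n_active_env=2,
    n_causal_main=20,
    n_causal_gxe=10,
    n_standardized_snps=4,
    var_main=0.2,
    var_gxe=0.05,
    var_std_main=0.01,
    var_std_gxe=0.01,
    var_pc1=0.0,
    seed=1,
    env_seed=2,
):
    """Standardized SampleAlignedDataset plus ground truth."""
    cfg = simulation.SimConfig(
        n_samples=n_samples,
        n_snps=n_snps,
        n_chrom=n_chrom,
        n_env=n_env,
        n_active_env=n_active_env,
        n_causal_main=n_causal_main,
        n_causal_gxe=n_causal_gxe,
        n_standardized_snps=n_standardized_snps,
        var_main=var_main,
        var_gxe=var_gxe,
        var_std_main=var_std_main,
        var_std_gxe=var_std_gxe,
        var_pc1=var_pc1,
        seed=seed,
    )
    X, variants = simulation.simulate_genotypes(cfg)
    E = simulation.simulate_environments(cfg.n_samples, cfg.n_env, seed=env_seed)
    Xs = data_io.standardize_columns(X.astype(float))
    y, truth = simulation.simulate_phenotype(Xs, E, cfg)
    ds = data_io.SampleAlignedDataset(
        sample_ids=[f"S{i}" for i in range(cfg.n_samples)],
        genotypes=Xs,
        variants=variants,
        phenotype=y,
        covariates=np.empty((cfg.n_samples, 0)),
        environments=E,
        environment_names=[f"env{l}" for l in range(cfg.n_env)],
    )
    ds.rebuild_chrom_index()
    return ds, truth


def bare_dataset(X, y, E=None, C=None, n_chrom=1):
    """Wrap raw arrays into a dataset (variants on evenly split chromosomes)."""
    n, m = X.shape
    bounds = np.linspace(0, m, n_chrom + 1).astype(int)
    variants = []
    for c, (a, b) in enumerate(zip(bounds[:-1], bounds[1:]), start=1):
        variants.extend(
            data_io.VariantRecord(chrom=str(c), pos=j - a + 1, id=f"s{j}", a0="A", a1="B")
            for j in range(a, b)
        )
    ds = data_io.SampleAlignedDataset(
        sample_ids=[f"S{i}" for i in range(n)],
        genotypes=X,
        variants=variants,
        phenotype=y,
        covariates=C if C is not None else np.empty((n, 0)),
        environments=E if E is not None else np.empty((n, 0)),
    )
    ds.rebuild_chrom_index()
    return ds


@pytest.fixture(scope="session")
def small_sim():
    """Small standardized dataset with ground truth (N=300, M=120)."""
    return make_dataset()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
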