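"""Input handling for genotype / phenotype / covariate / environment data.

Genotypes come either from PLINK binary filesets (.bed/.bim/.fam,
variant-major) or from whitespace-delimited text matrices. Phenotype,
covariate and environment tables are whitespace-delimited text with a header
row, the sample ID in the first column and ``NA`` marking missing values.

All downstream modelling assumes a :class:`SampleAlignedDataset`: every input
restricted to a common, ordered sample set with complete data, genotype and
environment columns standardized to mean zero / unit variance, and every
environment column also present among the covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as _stats

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

__all__ = [
    "VariantRecord",
    "SampleAlignedDataset",
    "PreprocessConfig",
    "read_genotypes",
    "write_plink",
    "read_table",
    "align_and_complete_cases",
    "standardize_columns",
    "filter_variants",
    "preprocess_phenotype",
    "impute_missing_genotypes",
]


@dataclass
class VariantRecord:
    """Per-variant metadata for one column of the genotype matrix.

    The dosage counts the first allele listed in the .bim (``a1``, the
    alternative allele); ``maf`` is folded, ``min(f, 1 - f)``. ``info`` is an
    imputation info score in [0, 1], 1.0 for hard calls.
    """

    chrom: str
    pos: int
    id: str
    a0: str
    a1: str
    maf: float = float("nan")
    info: float = 1.0


@dataclass
class SampleAlignedDataset:
    """Phenotype, genotypes, covariates and environments on a shared sample set.

    Attributes mirror the regression y = C alpha + X beta + (Ew (.) X) gamma + eps:
    ``phenotype`` y (N,), ``genotypes`` X (N, M), ``covariates`` C (N, L'),
    ``environments`` E (N, L). ``chrom_index`` maps a chromosome label to the
    half-open column range [start, stop) of X it occupies.
    """

    sample_ids: list[str]
    genotypes: np.ndarray
    variants: list[VariantRecord]
    phenotype: np.ndarray
    covariates: np.ndarray
    environments: np.ndarray
    covariate_names: list[str] = field(default_factory=list)
    environment_names: list[str] = field(default_factory=list)
    chrom_index: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chrom_index)

    def rebuild_chrom_index(self) -> None:
        index: dict[str, tuple[int, int]] = {}
        for j, v in enumerate(self.variants):
            if v.chrom in index:
                start, stop = index[v.chrom]
                if j != stop:
                    raise ValueError(
                        f"variants of chromosome {v.chrom} are not contiguous"
                    )
                index[v.chrom] = (start, j + 1)
            else:
                index[v.chrom] = (j, j + 1)
        self.chrom_index = index


@dataclass
class PreprocessConfig:
    """Variant filters and phenotype transforms.

    ``maf_min`` / ``info_min`` are inclusive lower bounds (kept when >=).
    ``outlier_sd``, when set, masks phenotype values more than that many SDs
    from the mean before any transform. ``transform`` is one of ``none``,
    ``log``, ``group-INT`` (rank-based inverse-normal within each level of
    ``group_labels``).
    """

    maf_min: float = 0.01
    info_min: float = 0.3
    outlier_sd: float | None = None
    transform: str = "none"
    group_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must lie in [0, 0.5)")
        if not (0.0 <= self.info_min <= 1.0):
            raise ValueError("info_min must lie in [0, 1]")
        if self.transform not in ("none", "log", "group-INT"):
            raise ValueError(f"unknown transform {self.transform!r}")


# ---------------------------------------------------------------------------
# PLINK binary fileset
# ---------------------------------------------------------------------------

# 2-bit genotype codes in variant-major .bed, dosage of the first .bim allele.
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])  # 00, 01, 10, 11


def _read_bim(path: str) -> list[VariantRecord]:
    bim = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "a1", "a0"],
        dtype={"chrom": str, "id": str, "a1": str, "a0": str},
    )
    return [
        VariantRecord(chrom=r.chrom, pos=int(r.pos), id=r.id, a0=r.a0, a1=r.a1)
        for r in bim.itertuples()
    ]


def _read_fam(path: str) -> list[str]:
    fam = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    return list(fam.iloc[:, 1])  # IID column


def read_genotypes(path: str, format: str = "bed"):
    """Read a genotype matrix with missing markers (NaN).

    ``format='bed'`` expects ``path`` to be the fileset prefix with
    accompanying .bim/.fam; dosages are in {0, 1, 2, NaN} counting the first
    .bim allele. ``format='text'`` expects a whitespace-delimited matrix with
    a header of variant IDs and the sample ID in the first column.

    Returns ``(matrix, variants, sample_ids)``.
    """
    if format == "bed":
        variants = _read_bim(path + ".bim")
        sample_ids = _read_fam(path + ".fam")
        n, m = len(sample_ids), len(variants)
        with open(path + ".bed", "rb") as fh:
            raw = fh.read()
        if raw[:3] != _BED_MAGIC:
            raise ValueError(f"{path}.bed: bad magic bytes (not a PLINK .bed)")
        bytes_per_variant = (n + 3) // 4
        body = np.frombuffer(raw, dtype=np.uint8, offset=3)
        if body.size != bytes_per_variant * m:
            raise ValueError(
                f"{path}.bed sized for {body.size} payload bytes but "
                f".bim/.fam imply {bytes_per_variant * m}"
            )
        codes = body.reshape(m, bytes_per_variant)
        # unpack 2-bit fields, sample-minor within byte
        expanded = np.stack(
            [(codes >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=2
        ).reshape(m, -1)[:, :n]
        matrix = _BED_DECODE[expanded].T.copy()
        return matrix, variants, sample_ids
    if format == "text":
        df = pd.read_csv(path, sep=r"\s+", na_values="NA", dtype={0: str})
        sample_ids = list(df.iloc[:, 0])
        matrix = df.iloc[:, 1:].to_numpy(dtype=float)
        variants = [
            VariantRecord(chrom="0", pos=j + 1, id=name, a0="A", a1="B")
            for j, name in enumerate(df.columns[1:])
        ]
        return matrix, variants, sample_ids
    raise ValueError(f"unknown genotype format {format!r}")


def write_plink(prefix: str, matrix: np.ndarray, variants, sample_ids) -> None:
    """Write dosages in {0,1,2,NaN} as a PLINK .bed/.bim/.fam fileset."""
    n, m = matrix.shape
    if len(variants) != m or len(sample_ids) != n:
        raise ValueError("matrix shape inconsistent with variants/sample_ids")
    with open(prefix + ".fam", "w") as fh:
        for sid in sample_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    with open(prefix + ".bim", "w") as fh:
        for v in variants:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\t{v.a1}\t{v.a0}\n")
    bytes_per_variant = (n + 3) // 4
    # dosage -> 2-bit code: 2 -> 00, missing -> 01, 1 -> 10, 0 -> 11
    codes = np.full(matrix.T.shape, 0b01, dtype=np.uint8)
    vals = matrix.T
    codes[vals == 2.0] = 0b00
    codes[vals == 1.0] = 0b10
    codes[vals == 0.0] = 0b11
    padded = np.zeros((m, bytes_per_variant * 4), dtype=np.uint8)
    padded[:, :n] = codes
    out = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(out.tobytes())


def read_table(path: str) -> pd.DataFrame:
    """Whitespace-delimited table: header row, sample ID first column, NA=missing."""
    df = pd.read_csv(path, sep=r"\s+", na_values="NA", dtype={0: str})
    return df.set_index(df.columns[0])


# ---------------------------------------------------------------------------
# Alignment and preprocessing
# ---------------------------------------------------------------------------


def align_and_complete_cases(
    genotypes: tuple,
    phenotype: pd.DataFrame,
    covariates: pd.DataFrame | None,
    environments: pd.DataFrame,
) -> SampleAlignedDataset:
    """Intersect samples, drop incomplete cases, and assemble a dataset.

    ``genotypes`` is the ``(matrix, variants, sample_ids)`` triple from
    :func:`read_genotypes`. Retained samples are those present everywhere with
    no missing phenotype, covariate or environment entry, ordered as in the
    genotype file. Environment columns absent from the covariates are appended
    to them (with a warning): every column of E must also be a column of C.
    """
    matrix, variants, sample_ids = genotypes
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample IDs in genotype input")
    tables = {"phenotype": phenotype, "environment": environments}
    if covariates is not None:
        tables["covariate"] = covariates
    for name, tab in tables.items():
        if tab.index.has_duplicates:
            raise ValueError(f"duplicate sample IDs in {name} table")

    keep: list[int] = []
    for i, sid in enumerate(sample_ids):
        ok = all(sid in tab.index for tab in tables.values())
        if ok:
            ok = not any(tab.loc[sid].isna().any() for tab in tables.values())
        if ok:
            keep.append(i)
    if not keep:
        raise ValueError("no samples with complete data across all inputs")
    ids = [sample_ids[i] for i in keep]

    y = tables["phenotype"].loc[ids].iloc[:, 0].to_numpy(dtype=float)
    E = tables["environment"].loc[ids].to_numpy(dtype=float)
    env_names = list(tables["environment"].columns)
    if covariates is not None:
        C = tables["covariate"].loc[ids].to_numpy(dtype=float)
        cov_names = list(tables["covariate"].columns)
    else:
        C = np.empty((len(ids), 0))
        cov_names = []
    missing_env = [n for n in env_names if n not in cov_names]
    if missing_env:
        warnings.warn(
            f"environment column(s) {missing_env} absent from covariates; appending",
            stacklevel=2,
        )
        idx = [env_names.index(n) for n in missing_env]
        C = np.column_stack([C, E[:, idx]])
        cov_names = cov_names + missing_env

    ds = SampleAlignedDataset(
        sample_ids=ids,
        genotypes=matrix[keep],
        variants=list(variants),
        phenotype=y,
        covariates=C,
        environments=E,
        covariate_names=cov_names,
        environment_names=env_names,
    )
    ds.rebuild_chrom_index()
    return ds


def standardize_columns(matrix: np.ndarray) -> np.ndarray:
    """Center each column and scale it to unit sample variance (n-1 denominator)."""
    matrix = np.asarray(matrix, dtype=float)
    mean = matrix.mean(axis=0)
    sd = matrix.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(f"constant column(s) at index {bad.tolist()}: cannot standardize")
    return (matrix - mean) / sd


def filter_variants(
    dataset: SampleAlignedDataset, config: PreprocessConfig
) -> SampleAlignedDataset:
    """Drop variants failing MAF >= maf_min or info >= info_min (inclusive)."""
    X = dataset.genotypes
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        freq = np.nanmean(X, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep = []
    variants = []
    for j, v in enumerate(dataset.variants):
        v = replace(v, maf=float(maf[j]))
        if v.maf >= config.maf_min and v.info >= config.info_min:
            keep.append(j)
            variants.append(v)
    if not keep:
        raise ValueError("all variants removed by MAF/info filtering")
    ds = replace(
        dataset,
        genotypes=X[:, keep],
        variants=variants,
        chrom_index={},
    )
    ds.rebuild_chrom_index()
    return ds


def _inverse_normal(values: np.ndarray) -> np.ndarray:
    """Blom-offset rank-based inverse normal transform."""
    n = values.size
    ranks = _stats.rankdata(values)
    return _stats.norm.ppf((ranks - 0.375) / (n + 0.25))


def preprocess_phenotype(y: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Outlier-mask then transform a phenotype vector.

    Values more than ``outlier_sd`` SDs from the mean of observed values are
    set to NaN before any transform. ``log`` requires positive values;
    ``group-INT`` maps ranks to Gaussian quantiles via (rank - 3/8)/(n + 1/4)
    separately within each level of ``config.group_labels``.
    """
    y = np.asarray(y, dtype=float).copy()
    if config.outlier_sd is not None:
        obs = ~np.isnan(y)
        mu, sd = y[obs].mean(), y[obs].std(ddof=1)
        y[obs & (np.abs(y - mu) > config.outlier_sd * sd)] = np.nan
    obs = ~np.isnan(y)
    if config.transform == "log":
        if np.any(y[obs] <= 0):
            raise ValueError("log transform requires strictly positive phenotype values")
        y[obs] = np.log(y[obs])
    elif config.transform == "group-INT":
        if config.group_labels is None:
            raise ValueError("group-INT requires group_labels")
        labels = np.asarray(config.group_labels)
        for g in np.unique(labels):
            mask = obs & (labels == g)
            if mask.sum() > 0:
                y[mask] = _inverse_normal(y[mask])
    return y


def impute_missing_genotypes(matrix: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the column mean of observed entries."""
    matrix = np.asarray(matrix, dtype=float).copy()
    missing = np.isnan(matrix)
    if not missing.any():
        return matrix
    fully = np.flatnonzero(missing.all(axis=0))
    if fully.size:
        raise ValueError(f"fully-missing genotype column(s) {fully.tolist()}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(matrix, axis=0)
    idx = np.where(missing)
    matrix[idx] = means[idx[1]]
    return matrix
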