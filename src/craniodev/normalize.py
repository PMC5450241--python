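"""Gene exclusion, expression filtering, CPM, and TMM normalization.

The count matrix is a genes x samples pandas DataFrame of non-negative
integers. Filtering follows the two-pronged rule used for per-stage
analysis: keep a gene if it reaches 1 cpm in at least half the stage's
samples, or 2 cpm in at least a quarter — the second prong retains genes
expressed in only a single taxon (4 of 16 samples).

TMM (trimmed mean of M-values) effective-library-size factors follow the
canonical definition: per-sample weighted trimmed mean of gene-wise log2
count-ratios against a reference sample, the reference being the sample
whose 75th-percentile count fraction is closest to the across-sample mean;
factors are rescaled to geometric mean 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class NormalizationFactors:
    """Per-sample raw library sizes and TMM scaling factors."""

    lib_size: pd.Series
    factor: pd.Series

    def __post_init__(self) -> None:
        if not self.lib_size.index.equals(self.factor.index):
            raise ValueError("lib_size and factor indexed differently")
        if (self.factor <= 0).any():
            raise ValueError("TMM factors must be positive")

    @property
    def effective_lib_size(self) -> pd.Series:
        return self.lib_size * self.factor

    @classmethod
    def unit(cls, counts: pd.DataFrame) -> "NormalizationFactors":
        lib = counts.sum(axis=0).astype(float)
        return cls(lib_size=lib, factor=pd.Series(1.0, index=lib.index))


def validate_matrix(counts: pd.DataFrame) -> None:
    if counts.index.has_duplicates:
        raise ValueError("duplicate gene IDs in count matrix")
    if counts.columns.has_duplicates:
        raise ValueError("duplicate sample IDs in count matrix")
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative counts in matrix")


def remove_excluded_genes(
    counts: pd.DataFrame, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Drop genes flagged mitochondrial or pseudogene; keep row order.

    ``annotation`` is indexed by gene with boolean columns (any column
    counts as an exclusion flag; conventional columns are ``mito`` and
    ``pseudogene``). Flags for genes absent from the matrix warn rather
    than fail.
    """
    flagged = annotation.index[annotation.any(axis=1)]
    unknown = flagged.difference(counts.index)
    if len(unknown):
        warnings.warn(
            f"{len(unknown)} flagged gene(s) not present in matrix "
            f"(e.g. {list(unknown[:3])})",
            stacklevel=2,
        )
    return counts.drop(index=flagged.intersection(counts.index))


def compute_cpm(
    counts: pd.DataFrame, factors: NormalizationFactors | None = None
) -> pd.DataFrame:
    """Counts per million over (effective) library sizes."""
    if factors is None:
        lib = counts.sum(axis=0).astype(float)
    else:
        lib = factors.effective_lib_size.reindex(counts.columns)
        if lib.isna().any():
            missing = list(lib.index[lib.isna()][:3])
            raise ValueError(f"no normalization factors for samples {missing}")
    zero = lib.index[lib == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s) {list(zero[:3])}")
    return counts / lib * 1e6


def filter_low_expression(
    counts: pd.DataFrame,
    cpm1: float = 1.0,
    frac1: float = 0.5,
    cpm2: float = 2.0,
    frac2: float = 0.25,
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-pronged low-expression filter on raw-library cpm.

    Keep a gene iff it has cpm >= cpm1 in at least ceil(frac1 * n) samples,
    or cpm >= cpm2 in at least ceil(frac2 * n) samples. Returns the kept
    matrix and the boolean kept mask over all genes. Intended for the
    samples of a single developmental stage across all taxa.
    """
    n = counts.shape[1]
    cpm = compute_cpm(counts)
    need1 = math.ceil(frac1 * n)
    need2 = math.ceil(frac2 * n)
    kept = ((cpm >= cpm1).sum(axis=1) >= need1) | (
        (cpm >= cpm2).sum(axis=1) >= need2
    )
    return counts.loc[kept], kept


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Weighted trimmed mean of M-values for one sample vs the reference.

    Genes zero in either sample are excluded; trim_m / trim_a fractions are
    trimmed from EACH tail of the M and A rankings; weights are the
    delta-method inverse variances of M.
    """
    use = (obs > 0) & (ref > 0)
    if not use.any():
        return 1.0
    o, r = obs[use], ref[use]
    po, pr = o / lib_obs, r / lib_ref
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    if np.max(np.abs(m)) < 1e-6:  # already equivalent
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(
    counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05
) -> NormalizationFactors:
    """TMM scaling factors for every sample, geometric mean 1."""
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        empty = list(lib.index[lib == 0][:3])
        raise ValueError(f"sample(s) with zero total count: {empty}")
    x = counts.to_numpy(dtype=float)
    frac = x / lib.to_numpy()
    q75 = np.quantile(frac, 0.75, axis=0)
    ref_j = int(np.argmin(np.abs(q75 - q75.mean())))
    f = np.array(
        [
            1.0
            if j == ref_j
            else _tmm_pair(
                x[:, j], x[:, ref_j], lib.iloc[j], lib.iloc[ref_j], trim_m, trim_a
            )
            for j in range(x.shape[1])
        ]
    )
    f = f / np.exp(np.mean(np.log(f)))
    return NormalizationFactors(
        lib_size=lib, factor=pd.Series(f, index=counts.columns)
    )
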