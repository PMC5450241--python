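"""Sample ordination: log-CPM transform, PCA, and loading-based rankings.

PCA runs on the gene-centered log2(cpm + prior) matrix via SVD; samples
are observations, genes are variables. Variance fractions are singular
values squared over their total; each component's sign is fixed so its
largest-magnitude gene loading is positive, making loading ranks
reproducible. Expression enters as cpm (gene length cancels within gene
for between-sample ordination, so length-normalised units are not
needed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .enrichment import make_ranked


def log_transform(cpm: pd.DataFrame, prior: float = 1.0) -> pd.DataFrame:
    """Elementwise log2(cpm + prior)."""
    if (cpm.to_numpy() < 0).any():
        raise ValueError("negative cpm values")
    return np.log2(cpm + prior)


@dataclass
class PcaModel:
    scores: pd.DataFrame      # samples x components
    loadings: pd.DataFrame    # genes x components
    variance_fraction: pd.Series
    centering: pd.Series      # per-gene means removed

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca_samples(log_matrix: pd.DataFrame, n_components: int) -> PcaModel:
    """PCA of samples on a genes x samples log-expression matrix.

    Components beyond the matrix rank are truncated with a warning.
    """
    if log_matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    X = log_matrix.to_numpy(dtype=float).T  # samples x genes
    rank = int(np.linalg.matrix_rank(X - X.mean(axis=0)))
    k = min(n_components, rank)
    if k < n_components:
        warnings.warn(
            f"requested {n_components} components but rank is {rank}; "
            f"returning {k}",
            stacklevel=2,
        )
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # genes x k
    # deterministic orientation: largest-|loading| gene positive
    for j in range(k):
        lead = np.argmax(np.abs(loadings[:, j]))
        if loadings[lead, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    comp_names = [f"PC{j + 1}" for j in range(k)]
    sv_all = np.linalg.svd(X - X.mean(axis=0), compute_uv=False)
    var_frac = pca.singular_values_**2 / float(np.sum(sv_all**2))
    return PcaModel(
        scores=pd.DataFrame(
            scores, index=log_matrix.columns, columns=comp_names
        ),
        loadings=pd.DataFrame(
            loadings, index=log_matrix.index, columns=comp_names
        ),
        variance_fraction=pd.Series(var_frac, index=comp_names),
        centering=pd.Series(X.mean(axis=0), index=log_matrix.index),
    )


def loading_ranks(model: PcaModel, component: int) -> pd.DataFrame:
    """Ranked gene list by signed loading on one (1-based) component."""
    name = f"PC{component}"
    if name not in model.loadings.columns:
        raise ValueError(
            f"component {component} not retained "
            f"(model has {model.n_components})"
        )
    return make_ranked(model.loadings[name])
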