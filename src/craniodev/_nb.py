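"""Negative-binomial likelihood machinery shared by the DE module.

Counts are modelled as NB(mean mu, dispersion phi) with variance
mu + phi * mu**2; phi -> 0 recovers Poisson. Group means enter through a
log link with per-sample offsets log(effective library size), so the
fitted parameter is a per-million-style rate lambda with
mu_gj = lambda_g * S_j.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln

# Dispersions below this are treated as (numerically) Poisson-like but kept
# positive so the NB log-likelihood stays well defined.
MIN_PHI = 1e-8

_NEWTON_TOL = 1e-12
_NEWTON_MAXIT = 60


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Elementwise NB log-likelihood.

    Parameters broadcast; ``phi`` may be scalar or per-gene (same leading
    shape as ``y``). Entries with mu == 0 contribute 0 when y == 0 and -inf
    otherwise.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.maximum(np.asarray(phi, dtype=float), MIN_PHI)
    r = 1.0 / phi
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = (
            gammaln(y + r)
            - gammaln(r)
            - gammaln(y + 1.0)
            + r * np.log(r / (r + mu))
            + y * np.log(mu / (r + mu))
        )
    zero = mu == 0
    if np.any(zero):
        ll = np.where(zero, np.where(y == 0, 0.0, -np.inf), ll)
    return ll


def fit_group_rate(
    counts: np.ndarray, eff_libsize: np.ndarray, phi
) -> np.ndarray:
    """MLE of the per-gene rate lambda for one group, vectorised over genes.

    ``counts`` is genes x samples, ``eff_libsize`` per-sample effective
    library size, ``phi`` scalar or per-gene. Fisher-scoring on
    beta = log(lambda); the score of the NB GLM with log link is
    sum_j (y - mu) / (1 + phi * mu).
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    S = np.asarray(eff_libsize, dtype=float)
    phi = np.maximum(np.asarray(phi, dtype=float), MIN_PHI)
    if phi.ndim == 0:
        phi = np.full(counts.shape[0], float(phi))
    phi = phi[:, None]
    tot = counts.sum(axis=1)
    nonzero = tot > 0
    beta = np.full(counts.shape[0], -np.inf)
    if not np.any(nonzero):
        return np.exp(beta)
    b = np.log(tot[nonzero] / S.sum())
    y = counts[nonzero]
    p = phi[nonzero]
    for _ in range(_NEWTON_MAXIT):
        mu = np.exp(b)[:, None] * S[None, :]
        w = 1.0 + p * mu
        score = ((y - mu) / w).sum(axis=1)
        info = (mu / w).sum(axis=1)
        step = score / np.maximum(info, 1e-300)
        step = np.clip(step, -5.0, 5.0)
        b = b + step
        if np.max(np.abs(step)) < _NEWTON_TOL:
            break
    beta[nonzero] = b
    return np.exp(beta)


def group_profile_loglik(
    counts: np.ndarray,
    eff_libsize: np.ndarray,
    group_cols: list[np.ndarray],
    phi,
    adjust: bool = False,
) -> np.ndarray:
    """Per-gene log-likelihood with a separate rate fitted per group.

    ``group_cols`` holds integer column indices for each group. Returns the
    summed (over samples) log-likelihood per gene at the profiled-out group
    rates, for the given dispersion(s).

    With ``adjust`` the Cox-Reid adjusted profile likelihood is returned
    (subtracting half the log Fisher information of each fitted group
    mean), removing the downward bias of plain profiling when estimating
    dispersions with few replicates. The adjustment is for dispersion
    estimation only; likelihood-ratio statistics use the plain profile.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    S = np.asarray(eff_libsize, dtype=float)
    total = np.zeros(counts.shape[0])
    phi_arr = np.asarray(phi, dtype=float)
    for cols in group_cols:
        y = counts[:, cols]
        lam = fit_group_rate(y, S[cols], phi_arr)
        mu = lam[:, None] * S[cols][None, :]
        ph = phi_arr[:, None] if phi_arr.ndim == 1 else phi_arr
        total += nb_loglik(y, mu, ph).sum(axis=1)
        if adjust:
            info = (mu / (1.0 + np.maximum(ph, MIN_PHI) * mu)).sum(axis=1)
            # all-zero groups carry no information about the mean
            total -= np.where(info > 0, 0.5 * np.log(np.maximum(info, 1e-300)), 0.0)
    return total
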