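"""Gene-list overrepresentation and pre-ranked GSEA (classic scheme).

Two complementary enrichment procedures:

* a permutation test for curated-list overrepresentation — the observed
  overlap of a query list with a curated list is compared against the
  overlap of randomly drawn same-size sets from the universe (the null is
  exactly hypergeometric, so the closed-form upper tail is reported
  alongside);
* pre-ranked gene-set enrichment with the *classic* (unweighted) scoring
  scheme: walking the ranked list, a set member adds 1/G and a non-member
  subtracts 1/(N-G); the enrichment score (ES) is the running-sum value of
  maximum absolute deviation from zero. Significance and normalization
  come from random same-size gene draws (gene-label permutation), the
  standard null for a pre-ranked list.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)


# ----------------------------------------------------------- ranked lists ---

def make_ranked(scores: pd.Series) -> pd.DataFrame:
    """Build a ranked list: descending score, ties broken by gene ID."""
    if scores.index.has_duplicates:
        raise ValueError("duplicate genes in score table")
    df = scores.rename("score").rename_axis("gene_id").reset_index()
    df["gene_id"] = df["gene_id"].astype(str)
    df = df.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return df


def rank_by_mean_logfc(results: list[pd.DataFrame]) -> pd.DataFrame:
    """Rank genes by the mean signed log2FC across the focal comparisons."""
    universe = pd.Index(results[0]["gene_id"])
    stacked = []
    for t in results:
        s = t.set_index("gene_id")["logFC"]
        if not universe.sort_values().equals(s.index.sort_values()):
            diff = universe.symmetric_difference(s.index)
            raise ValueError(
                f"gene universes differ across tables ({len(diff)} genes)"
            )
        stacked.append(s.reindex(universe))
    mean = pd.concat(stacked, axis=1).mean(axis=1)
    return make_ranked(mean)


# ----------------------------------------------- curated-list permutation ---

@dataclass
class EnrichmentPermutationResult:
    observed: int
    null_counts: np.ndarray
    p_empirical: float
    p_hypergeom: float

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_counts))


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) drawing n from N with K marked."""
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def permutation_overlap_test(
    query: list[str],
    curated: list[str],
    universe: list[str],
    n_perm: int = 1000,
    seed: int = 0,
) -> EnrichmentPermutationResult:
    """Overlap of a query list with a curated list vs random same-size sets.

    Each permutation draws ``len(query)`` genes from the universe without
    replacement and counts curated members. The empirical p uses the
    (1 + exceedances) / (1 + n_perm) correction; the exact hypergeometric
    upper tail is reported alongside.
    """
    uni = pd.Index(universe)
    if uni.has_duplicates:
        raise ValueError("duplicate genes in universe")
    q = set(query)
    if len(q) != len(query):
        raise ValueError("duplicate genes in query")
    if len(query) > len(uni):
        raise ValueError("query larger than universe")
    outside = q - set(uni)
    if outside:
        raise ValueError(
            f"query gene(s) outside universe, e.g. {sorted(outside)[:3]}"
        )
    cur = set(curated) & set(uni)
    observed = len(q & cur)
    rng = np.random.default_rng(seed)
    is_cur = np.array([g in cur for g in uni])
    k = len(query)
    pos = _sample_null_positions(len(uni), k, n_perm, rng)
    null = is_cur[pos].sum(axis=1).astype(np.int64)
    p_emp = (1.0 + np.sum(null >= observed)) / (1.0 + n_perm)
    p_exact = hypergeometric_tail(observed, len(cur), k, len(uni))
    return EnrichmentPermutationResult(
        observed=observed,
        null_counts=null,
        p_empirical=float(p_emp),
        p_hypergeom=p_exact,
    )


# ------------------------------------------------------------------- GSEA ---

def gsea_es(
    ranked: pd.DataFrame, geneset: list[str]
) -> tuple[float, np.ndarray]:
    """Classic-scheme enrichment score and the full running sum.

    Hits add 1/G, misses subtract 1/(N-G); ES is the running-sum value of
    maximum |deviation| (first such position on ties along the walk). Set
    members absent from the ranked list are ignored.
    """
    genes = ranked["gene_id"].to_numpy()
    hit = np.isin(genes, list(set(geneset)))
    G = int(hit.sum())
    N = genes.size
    if G == 0:
        raise ValueError("gene set has no member in the ranked list")
    if G == N:
        raise ValueError("gene set covers the entire ranked list")
    inc = np.where(hit, 1.0 / G, -1.0 / (N - G))
    running = np.cumsum(inc)
    es = float(running[int(np.argmax(np.abs(running)))])
    return es, running


def _null_es_from_positions(pos: np.ndarray, N: int) -> np.ndarray:
    """Vectorised ES for random hit-position matrices (n_perm x G, sorted).

    Running-sum extremes occur just before a hit (trough candidate) or
    just after (peak candidate); interleaving the candidates preserves the
    walk order for first-maximum tie-breaking.
    """
    n_perm, G = pos.shape
    i = np.arange(G)
    miss_before = pos - i  # misses strictly before hit i
    before = i / G - miss_before / (N - G)
    after = (i + 1.0) / G - miss_before / (N - G)
    walk = np.empty((n_perm, 2 * G))
    walk[:, 0::2] = before
    walk[:, 1::2] = after
    idx = np.argmax(np.abs(walk), axis=1)
    return walk[np.arange(n_perm), idx]


def _sample_null_positions(
    N: int, G: int, n_perm: int, rng: np.random.Generator, chunk: int = 256
) -> np.ndarray:
    if G >= N:
        return np.tile(np.arange(N), (n_perm, 1))
    out = np.empty((n_perm, G), dtype=np.int64)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        r = rng.random((m, N))
        part = np.argpartition(r, G, axis=1)[:, :G]
        out[done: done + m] = np.sort(part, axis=1)
        done += m
    return out


def _exhaustive_positions(N: int, G: int) -> np.ndarray:
    return np.array(list(itertools.combinations(range(N), G)), dtype=np.int64)


def gsea_preranked(
    ranked: pd.DataFrame,
    collection: dict[str, list[str]],
    n_perm: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
) -> pd.DataFrame:
    """Pre-ranked GSEA over a gene-set collection, classic scheme.

    The null for each set is the ES of random same-size gene draws from
    the ranked list (``n_perm`` of them, or every possible draw when
    ``exhaustive``). NES divides ES by the mean |null ES| of matching
    sign; the nominal p is the matching-sign null tail (with the +1
    Monte-Carlo correction unless exhaustive); FDR q compares the pooled
    normalized null scores beyond each NES with the observed NES beyond
    it, per sign, clipped to 1. Sets with no gene in the list, or covering
    the whole list, are skipped with a warning.
    """
    if not collection:
        raise ValueError("empty gene-set collection")
    N = len(ranked)
    genes = ranked["gene_id"].to_numpy()
    rng = np.random.default_rng(seed)

    rows = []
    null_nes_pool: list[np.ndarray] = []
    for name, members in collection.items():
        present = set(members) & set(genes)
        dropped = len(set(members)) - len(present)
        if dropped:
            logger.info(
                "gene set %s: %d member(s) absent from ranked list", name, dropped
            )
        G = len(present)
        if G == 0 or G == N:
            warnings.warn(
                f"gene set {name!r} skipped (degenerate size {G} of {N})",
                stacklevel=2,
            )
            continue
        es, running = gsea_es(ranked, sorted(present))
        hit_idx = np.flatnonzero(np.isin(genes, sorted(present)))
        peak = int(np.argmax(np.abs(running)))
        if es >= 0:
            leading = int(np.sum(hit_idx <= peak))
        else:
            leading = int(np.sum(hit_idx >= peak))

        if exhaustive:
            if math.comb(N, G) > 200_000:
                raise ValueError(
                    f"exhaustive null infeasible for N={N}, G={G}"
                )
            # run the exact cumsum walk per subset so enumeration and the
            # observed score share one arithmetic path (tie-exact)
            pos = _exhaustive_positions(N, G)
            inc_miss = -1.0 / (N - G)
            null_es = np.empty(pos.shape[0])
            for i, p in enumerate(pos):
                inc = np.full(N, inc_miss)
                inc[p] = 1.0 / G
                run = np.cumsum(inc)
                null_es[i] = run[int(np.argmax(np.abs(run)))]
        else:
            pos = _sample_null_positions(N, G, n_perm, rng)
            null_es = _null_es_from_positions(pos, N)

        same = null_es >= 0 if es >= 0 else null_es < 0
        n_same = int(same.sum())
        if n_same == 0:
            nes = np.nan
            p = 1.0 / (1.0 + len(null_es))
        else:
            denom = float(np.mean(np.abs(null_es[same])))
            nes = es / denom if denom > 0 else np.nan
            extreme = int(np.sum(np.abs(null_es[same]) >= abs(es)))
            if exhaustive:
                p = extreme / n_same
            else:
                p = (1.0 + extreme) / (1.0 + n_same)
        pos_mean = (
            float(np.mean(null_es[null_es >= 0])) if (null_es >= 0).any() else np.nan
        )
        neg_mean = (
            float(np.mean(np.abs(null_es[null_es < 0])))
            if (null_es < 0).any()
            else np.nan
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            null_nes = np.where(
                null_es >= 0, null_es / pos_mean, null_es / neg_mean
            )
        null_nes_pool.append(null_nes[np.isfinite(null_nes)])
        rows.append(
            {
                "name": name,
                "size": G,
                "ES": es,
                "NES": float(nes),
                "p": float(p),
                "leading_edge": leading,
            }
        )
    if not rows:
        raise ValueError("no usable gene set in collection")
    table = pd.DataFrame(rows)
    table["q"] = _gsea_fdr(
        table["NES"].to_numpy(), np.concatenate(null_nes_pool)
    )
    return table


def _gsea_fdr(obs_nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """Pooled-null FDR q per observed NES, matching-sign pools."""
    q = np.full(obs_nes.shape, np.nan)
    for i, nes in enumerate(obs_nes):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            null_pool = null_nes[null_nes >= 0]
            obs_pool = obs_nes[np.isfinite(obs_nes) & (obs_nes >= 0)]
            f_null = (
                np.mean(null_pool >= nes) if null_pool.size else np.nan
            )
            f_obs = np.mean(obs_pool >= nes)
        else:
            null_pool = null_nes[null_nes < 0]
            obs_pool = obs_nes[np.isfinite(obs_nes) & (obs_nes < 0)]
            f_null = (
                np.mean(null_pool <= nes) if null_pool.size else np.nan
            )
            f_obs = np.mean(obs_pool <= nes)
        if f_obs > 0 and np.isfinite(f_null):
            q[i] = min(1.0, f_null / f_obs)
    return q
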