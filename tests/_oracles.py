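"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain loops from the defining formulas,
deliberately sharing no code with the package.
"""

import math

import numpy as np
import pandas as pd


def es_oracle(ranked: pd.DataFrame, geneset) -> float:
    """Classic-scheme enrichment score by naive running-sum walk."""
    genes = list(ranked["gene_id"])
    members = set(geneset) & set(genes)
    G = len(members)
    N = len(genes)
    running, best, best_abs = 0.0, 0.0, -1.0
    for g in genes:
        running += 1.0 / G if g in members else -1.0 / (N - G)
        if abs(running) > best_abs:
            best_abs, best = abs(running), running
    return best


def tmm_oracle(counts: pd.DataFrame, trim_m=0.30, trim_a=0.05) -> np.ndarray:
    """Literal-formula TMM reference: per-gene loops, rank trimming,
    delta-method weights, geometric-mean-1 rescale."""
    lib = counts.sum(axis=0).astype(float).to_numpy()
    x = counts.to_numpy(dtype=float)
    q = [np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])]
    ref = min(range(len(q)), key=lambda j: abs(q[j] - np.mean(q)))
    factors = []
    for j in range(x.shape[1]):
        if j == ref:
            factors.append(1.0)
            continue
        M, A, W = [], [], []
        for g in range(x.shape[0]):
            yo, yr = x[g, j], x[g, ref]
            if yo == 0 or yr == 0:
                continue
            po, pr = yo / lib[j], yr / lib[ref]
            M.append(math.log2(po / pr))
            A.append(0.5 * math.log2(po * pr))
            W.append((lib[j] - yo) / (lib[j] * yo)
                     + (lib[ref] - yr) / (lib[ref] * yr))
        if not M or max(abs(v) for v in M) < 1e-6:
            factors.append(1.0)
            continue
        n = len(M)
        rank_m = pd.Series(M).rank().to_list()
        rank_a = pd.Series(A).rank().to_list()
        lo_m, lo_a = math.floor(n * trim_m) + 1, math.floor(n * trim_a) + 1
        hi_m, hi_a = n + 1 - lo_m, n + 1 - lo_a
        num = den = 0.0
        for m_, a_, w_, rm, ra in zip(M, A, W, rank_m, rank_a):
            if lo_m <= rm <= hi_m and lo_a <= ra <= hi_a:
                num += m_ / w_
                den += 1.0 / w_
        factors.append(2.0 ** (num / den) if den > 0 else 1.0)
    f = np.array(factors)
    return f / np.exp(np.mean(np.log(f)))


def joint_coverage_oracle(tracks: dict, min_depth: int = 10) -> list:
    """Per-base boolean-AND run scan over all samples and scaffolds."""
    rows = []
    samples = list(tracks)
    for sc in tracks[samples[0]]:
        n = len(tracks[samples[0]][sc])
        run = None
        for pos in range(n):
            ok = all(tracks[s][sc][pos] >= min_depth for s in samples)
            if ok and run is None:
                run = pos
            if not ok and run is not None:
                rows.append((sc, run, pos))
                run = None
        if run is not None:
            rows.append((sc, run, n))
    return rows
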