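"""Coverage-based interval selection and supermatrix construction.

Implements the phylogenomic data-preparation procedure: find the maximal
genomic runs where every sample has read depth at or above a threshold,
keep runs within a length window, slice the per-sample consensus sequences
over those runs, and concatenate the slices into an equal-length alignment
(a supermatrix) with a coordinate map for downstream partitioning.

Coordinates are 0-based, half-open throughout, matching bedGraph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

#: per-sample coverage: mapping scaffold -> per-base depth array
CoverageTrack = Mapping[str, np.ndarray]
#: per-sample consensus: mapping scaffold -> sequence string (A/C/G/T/N)
ConsensusSet = Mapping[str, Mapping[str, str]]


@dataclass
class IntervalCatalog:
    """Sorted, non-overlapping (scaffold, start, end) intervals."""

    intervals: pd.DataFrame  # columns scaffold, start, end

    def __post_init__(self) -> None:
        df = self.intervals.reset_index(drop=True)
        expected = ["scaffold", "start", "end"]
        if list(df.columns) != expected:
            raise ValueError(f"interval table must have columns {expected}")
        if len(df) and (df["end"] <= df["start"]).any():
            raise ValueError("empty or inverted interval in catalog")
        self.intervals = df

    @property
    def lengths(self) -> pd.Series:
        return self.intervals["end"] - self.intervals["start"]

    @property
    def total_length(self) -> int:
        return int(self.lengths.sum())

    def __len__(self) -> int:
        return len(self.intervals)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalCatalog):
            return NotImplemented
        return self.intervals.equals(other.intervals)

    def summary(self) -> pd.DataFrame:
        """Count, total bp and a length histogram (decade bins)."""
        n = len(self)
        hist_edges = [0, 10, 50, 100, 250, 500, 1000, np.inf]
        counts, _ = np.histogram(self.lengths, bins=hist_edges) if n else (
            np.zeros(len(hist_edges) - 1, dtype=int), None)
        rows = [("n_intervals", n), ("total_bp", self.total_length)]
        rows += [
            (f"len_{int(lo)}_{'inf' if np.isinf(hi) else int(hi)}", int(c))
            for lo, hi, c in zip(hist_edges[:-1], hist_edges[1:], counts)
        ]
        return pd.DataFrame(rows, columns=["statistic", "value"])


def joint_covered_regions(
    tracks: Mapping[str, CoverageTrack], min_depth: int = 10
) -> IntervalCatalog:
    """Maximal runs where every sample reaches ``min_depth`` at every base.

    ``tracks`` maps sample -> scaffold -> per-base depth. All samples must
    cover the same scaffolds at the same lengths; the joint requirement
    leaves no missing data in the resulting catalog.
    """
    if not tracks:
        raise ValueError("no coverage tracks supplied")
    samples = list(tracks)
    scaffolds = list(tracks[samples[0]])
    for s in samples[1:]:
        if set(tracks[s]) != set(scaffolds):
            raise ValueError(f"sample {s!r} covers a different scaffold set")
    rows = []
    for sc in scaffolds:
        lengths = {len(tracks[s][sc]) for s in samples}
        if len(lengths) > 1:
            raise ValueError(
                f"scaffold {sc!r} length differs across samples: {sorted(lengths)}"
            )
        n = lengths.pop()
        if n == 0:
            continue
        ok = np.ones(n, dtype=bool)
        for s in samples:
            ok &= np.asarray(tracks[s][sc]) >= min_depth
        padded = np.concatenate(([False], ok, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        starts, ends = edges[::2], edges[1::2]
        rows.extend((sc, int(a), int(b)) for a, b in zip(starts, ends))
    df = pd.DataFrame(rows, columns=["scaffold", "start", "end"])
    df = df.sort_values(["scaffold", "start"], kind="mergesort").reset_index(
        drop=True
    )
    return IntervalCatalog(df)


def filter_by_length(
    catalog: IntervalCatalog, min_len: int = 51, max_len: int = 999
) -> IntervalCatalog:
    """Keep intervals with min_len <= length <= max_len, order preserved.

    Defaults encode the strict reading of the length window (strictly
    longer than 50 bp and strictly shorter than 1 kb); both bounds are
    configurable.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    df = catalog.intervals
    lengths = df["end"] - df["start"]
    kept = df[(lengths >= min_len) & (lengths <= max_len)]
    return IntervalCatalog(kept.reset_index(drop=True))


@dataclass
class Supermatrix:
    """Concatenated alignment with interval -> column coordinate map."""

    sequences: dict[str, str]
    #: columns scaffold, start, end, sm_start, sm_end (supermatrix columns)
    coordinate_map: pd.DataFrame
    dropped_intervals: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["scaffold", "start", "end"]
        )
    )

    @property
    def n_columns(self) -> int:
        if not self.sequences:
            return 0
        return len(next(iter(self.sequences.values())))


def build_supermatrix(
    consensus: ConsensusSet,
    catalog: IntervalCatalog,
    strict: bool = False,
) -> Supermatrix:
    """Slice each sample's consensus over the catalog and concatenate.

    Every sample must provide a consensus for every cataloged scaffold. In
    ``strict`` mode, intervals where any sample carries an N are dropped
    (and reported); otherwise they are kept and only reported.
    """
    samples = list(consensus)
    if not samples:
        raise ValueError("no consensus sequences supplied")
    needed = catalog.intervals["scaffold"].unique()
    for s in samples:
        missing = [sc for sc in needed if sc not in consensus[s]]
        if missing:
            raise ValueError(
                f"sample {s!r} lacks consensus for scaffold(s) {missing}"
            )
    has_n = np.zeros(len(catalog), dtype=bool)
    for i, (sc, a, b) in enumerate(
        catalog.intervals.itertuples(index=False)
    ):
        for s in samples:
            seq = consensus[s][sc]
            if b > len(seq):
                raise ValueError(
                    f"interval {sc}:{a}-{b} exceeds consensus length "
                    f"for sample {s!r}"
                )
            if "N" in seq[a:b]:
                has_n[i] = True
                break
    flagged = catalog.intervals[has_n].reset_index(drop=True)
    used = catalog.intervals[~has_n] if strict else catalog.intervals
    used = used.reset_index(drop=True)

    parts: dict[str, list[str]] = {s: [] for s in samples}
    coords = []
    col = 0
    for sc, a, b in used.itertuples(index=False):
        for s in samples:
            parts[s].append(consensus[s][sc][a:b])
        coords.append((sc, int(a), int(b), col, col + (b - a)))
        col += b - a
    cmap = pd.DataFrame(
        coords, columns=["scaffold", "start", "end", "sm_start", "sm_end"]
    )
    return Supermatrix(
        sequences={s: "".join(parts[s]) for s in samples},
        coordinate_map=cmap,
        dropped_intervals=flagged,
    )
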