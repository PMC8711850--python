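"""Spatial non-randomness testing and sliding-window hotspot detection.

CNVs are reduced to their midpoints both for the genome-wide KS test and
for window counting, so a multi-megabase CNV is counted once rather than
once per overlapping window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import special

from cnvscape.sv_io import CNVTable, GenomeIndex

logger = logging.getLogger(__name__)


@dataclass
class WindowTrack:
    """Sliding-window CNV counts, stored per scaffold as numpy arrays.

    ``windows[name] = (starts, ends, counts)``; windows never cross scaffold
    boundaries and the last window of a scaffold is truncated at its end.
    """

    scaffolds: tuple[str, ...]
    windows: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    window_size: int
    step: int

    def all_counts(self) -> np.ndarray:
        parts = [self.windows[s][2] for s in self.scaffolds]
        if not parts:
            return np.zeros(0, dtype=np.int64)
        return np.concatenate(parts)

    def iter_rows(self):
        """Yield (scaffold, start, end, count) rows in genome order."""
        for s in self.scaffolds:
            starts, ends, counts = self.windows[s]
            for ws, we, c in zip(starts, ends, counts):
                yield s, int(ws), int(we), int(c)


@dataclass(frozen=True)
class Hotspot:
    scaffold: str
    start: int
    end: int
    n_windows: int
    n_cnvs: int


@dataclass(frozen=True)
class KSResult:
    D: float
    p: float
    n_x: int
    n_y: int


def concatenated_positions(table: CNVTable, genome: GenomeIndex) -> np.ndarray:
    """Map each CNV to its midpoint in concatenated genome coordinates."""
    offsets = genome.offsets
    return np.array(
        [offsets[r.scaffold] + r.midpoint for r in table.records], dtype=float
    )


def ks_two_sample(x: np.ndarray, y: np.ndarray) -> KSResult:
    """Two-sample Kolmogorov-Smirnov test.

    D is the supremum of |F_x - F_y| over the pooled sample points; p comes
    from the asymptotic Kolmogorov distribution with effective sample size
    n_x * n_y / (n_x + n_y).
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    n_x, n_y = x.size, y.size
    if n_x == 0 or n_y == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / n_x
    cdf_y = np.searchsorted(y, pooled, side="right") / n_y
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    en = n_x * n_y / (n_x + n_y)
    p = float(special.kolmogorov(np.sqrt(en) * d))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return KSResult(D=d, p=p, n_x=n_x, n_y=n_y)


def _cnv_union_concatenated(
    table: CNVTable, genome: GenomeIndex
) -> list[tuple[int, int]]:
    """Merged CNV intervals mapped into concatenated coordinates."""
    offsets = genome.offsets
    ivs = sorted(
        (offsets[r.scaffold] + r.start, offsets[r.scaffold] + r.end)
        for r in table.records
    )
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def _sample_without_replacement(
    n_population: int, n_draws: int, rng: np.random.Generator
) -> np.ndarray:
    """Distinct integers in [0, n_population), deterministic given rng state.

    Rejection-based so memory stays O(n_draws) even for genome-sized
    populations; draw order is preserved (dict keeps insertion order).
    """
    if n_draws > n_population:
        raise ValueError("cannot draw more positions than available")
    chosen: dict[int, None] = {}
    while len(chosen) < n_draws:
        need = n_draws - len(chosen)
        batch = rng.integers(0, n_population, size=max(need * 2, 16))
        for v in batch:
            if len(chosen) >= n_draws:
                break
            chosen.setdefault(int(v), None)
    return np.fromiter(chosen.keys(), dtype=np.int64, count=n_draws)


def spatial_randomness_test(
    table: CNVTable,
    genome: GenomeIndex,
    n_draws: int | None = None,
    seed: int = 0,
) -> KSResult:
    """KS test of CNV midpoints against positions sampled uniformly (without
    replacement) from the non-CNV bases of the concatenated genome."""
    if not table.records:
        raise ValueError("empty CNV table")
    x = concatenated_positions(table, genome)
    if n_draws is None:
        n_draws = x.size

    union = _cnv_union_concatenated(table, genome)
    total = genome.total_length
    # complement of the CNV union over [0, total)
    free: list[tuple[int, int]] = []
    prev = 0
    for s, e in union:
        if s > prev:
            free.append((prev, s))
        prev = max(prev, e)
    if prev < total:
        free.append((prev, total))
    free_lengths = np.array([e - s for s, e in free], dtype=np.int64)
    n_free = int(free_lengths.sum())
    if n_free == 0:
        raise ValueError("CNV union covers the whole genome: no non-CNV bases")

    rng = np.random.default_rng(seed)
    idx = _sample_without_replacement(n_free, n_draws, rng)
    cum = np.concatenate([[0], np.cumsum(free_lengths)])
    which = np.searchsorted(cum, idx, side="right") - 1
    starts = np.array([s for s, _ in free], dtype=np.int64)
    y = (starts[which] + (idx - cum[which])).astype(float)
    return ks_two_sample(x, y)


def window_counts(
    table: CNVTable,
    genome: GenomeIndex,
    window: int = 2_000_000,
    step: int = 1_000,
) -> WindowTrack:
    """Count CNV midpoints in sliding windows tiling each scaffold.

    A CNV belongs to a window iff its midpoint lies in [start, end).
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be positive")
    mids: dict[str, list[float]] = {name: [] for name in genome.names}
    for r in table.records:
        mids[r.scaffold].append(r.midpoint)
    windows: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for name, length in zip(genome.names, genome.lengths):
        starts = np.arange(0, length, step, dtype=np.int64)
        ends = np.minimum(starts + window, length)
        m = np.sort(np.asarray(mids[name], dtype=float))
        counts = np.searchsorted(m, ends, side="left") - np.searchsorted(
            m, starts, side="left"
        )
        windows[name] = (starts, ends, counts.astype(np.int64))
    return WindowTrack(
        scaffolds=tuple(genome.names), windows=windows, window_size=window, step=step
    )


def detect_hotspots(
    track: WindowTrack,
    table: CNVTable | None = None,
    genome: GenomeIndex | None = None,
    quantile: float = 0.975,
) -> list[Hotspot]:
    """Merge windows whose count is strictly above the genome-wide empirical
    quantile of all window counts into hotspots.

    The threshold uses numpy's linear-interpolation quantile over every
    window genome-wide.  Overlapping-or-abutting supra-threshold windows on
    one scaffold merge into a single hotspot whose interval is their union;
    ``n_cnvs`` counts distinct CNV midpoints inside the merged interval
    (requires ``table``; 0 if omitted).
    """
    if not (0.0 < quantile < 1.0):
        raise ValueError("quantile must be in (0, 1)")
    all_counts = track.all_counts()
    if all_counts.size == 0:
        return []
    threshold = float(np.quantile(all_counts, quantile))

    mids: dict[str, np.ndarray] = {}
    if table is not None:
        tmp: dict[str, list[float]] = {}
        for r in table.records:
            tmp.setdefault(r.scaffold, []).append(r.midpoint)
        mids = {k: np.sort(np.asarray(v)) for k, v in tmp.items()}

    hotspots: list[Hotspot] = []
    for scaffold in track.scaffolds:
        starts, ends, counts = track.windows[scaffold]
        supra = counts > threshold
        if not supra.any():
            continue
        idx = np.flatnonzero(supra)
        cur_lo, cur_hi = int(starts[idx[0]]), int(ends[idx[0]])
        n_win = 1
        for i in idx[1:]:
            if int(starts[i]) <= cur_hi:  # overlap or abut
                cur_hi = max(cur_hi, int(ends[i]))
                n_win += 1
            else:
                hotspots.append(
                    _make_hotspot(scaffold, cur_lo, cur_hi, n_win, mids)
                )
                cur_lo, cur_hi = int(starts[i]), int(ends[i])
                n_win = 1
        hotspots.append(_make_hotspot(scaffold, cur_lo, cur_hi, n_win, mids))
    return hotspots


def _make_hotspot(
    scaffold: str, lo: int, hi: int, n_win: int, mids: dict[str, np.ndarray]
) -> Hotspot:
    m = mids.get(scaffold)
    if m is None:
        n_cnvs = 0
    else:
        n_cnvs = int(
            np.searchsorted(m, hi, side="left") - np.searchsorted(m, lo, side="left")
        )
    return Hotspot(scaffold=scaffold, start=lo, end=hi, n_windows=n_win, n_cnvs=n_cnvs)
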