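"""Genome-arithmetic primitives: fixed windows, coverage fractions,
interval subtraction/intersection.

All coordinates are 0-based half-open. Single-chromosome primitives take
lists of ``(start, end)`` tuples; the windowing helpers operate on
chromosome-keyed frames.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

Interval = tuple[int, int]


def _validate(intervals) -> list[Interval]:
    out = []
    for s, e in intervals:
        if s < 0 or e < 0:
            raise DataError(f"negative coordinate in interval ({s}, {e})")
        if e > s:
            out.append((int(s), int(e)))
    return sorted(out)


def flatten_intervals(intervals) -> list[Interval]:
    """Merge overlapping or abutting intervals into a disjoint sorted set."""
    ivs = _validate(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def total_bp(intervals) -> int:
    return sum(e - s for s, e in flatten_intervals(intervals))


def interval_intersect(a, b) -> list[Interval]:
    """Intervals covered by both a and b (each flattened first)."""
    fa, fb = flatten_intervals(a), flatten_intervals(b)
    out: list[Interval] = []
    i = j = 0
    while i < len(fa) and j < len(fb):
        s = max(fa[i][0], fb[j][0])
        e = min(fa[i][1], fb[j][1])
        if e > s:
            out.append((s, e))
        if fa[i][1] < fb[j][1]:
            i += 1
        else:
            j += 1
    return out


def interval_subtract(a, b) -> list[Interval]:
    """Parts of a not overlapped by b (clipped remainders)."""
    fa, fb = flatten_intervals(a), flatten_intervals(b)
    out: list[Interval] = []
    j = 0
    for s, e in fa:
        cur = s
        while j < len(fb) and fb[j][1] <= cur:
            j += 1
        k = j
        while k < len(fb) and fb[k][0] < e:
            bs, be = fb[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if cur >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def make_windows(chrom_sizes: dict[str, int], width: int = 50_000) -> pd.DataFrame:
    """Tile each chromosome with fixed windows; the last one is truncated.

    Returns a frame with columns chrom, start, end in genome order.
    """
    if width <= 0:
        raise ConfigError(f"window width must be positive, got {width}")
    rows = []
    for chrom, size in chrom_sizes.items():
        if size < 0:
            raise DataError(f"negative chromosome size for {chrom}")
        starts = np.arange(0, size, width, dtype=np.int64)
        ends = np.minimum(starts + width, size)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    if not rows:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(rows, ignore_index=True)


def _covered_bp(flat: list[Interval], s: int, e: int) -> int:
    if not flat:
        return 0
    starts = np.fromiter((iv[0] for iv in flat), dtype=np.int64)
    ends = np.fromiter((iv[1] for iv in flat), dtype=np.int64)
    lo = np.clip(starts, s, e)
    hi = np.clip(ends, s, e)
    return int(np.sum(hi - lo))


def interval_coverage_fraction(windows: pd.DataFrame, intervals: pd.DataFrame) -> np.ndarray:
    """Fraction of each window covered by the (flattened) intervals.

    ``windows`` and ``intervals`` both carry chrom/start/end columns;
    overlapping input intervals are flattened per chromosome first so the
    result is invariant to splitting an interval into abutting pieces.
    """
    flat_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom, sub in intervals.groupby("chrom", sort=False):
        flat = flatten_intervals(zip(sub["start"], sub["end"]))
        starts = np.array([s for s, _ in flat], dtype=np.int64)
        ends = np.array([e for _, e in flat], dtype=np.int64)
        cum = np.concatenate([[0], np.cumsum(ends - starts)])
        flat_by_chrom[str(chrom)] = (starts, ends, cum)

    fractions = np.zeros(len(windows), dtype=float)
    for i, (chrom, s, e) in enumerate(zip(windows["chrom"], windows["start"], windows["end"])):
        if s < 0:
            raise DataError("negative window coordinate")
        if e <= s or chrom not in flat_by_chrom:
            continue
        starts, ends, cum = flat_by_chrom[chrom]
        # intervals wholly inside [s, e) via prefix sums, plus clipped edges
        lo = int(np.searchsorted(ends, s, side="right"))
        hi = int(np.searchsorted(starts, e, side="left"))
        covered = 0
        for j in range(lo, hi):
            covered += min(ends[j], e) - max(starts[j], s)
        fractions[i] = covered / (e - s)
    return fractions
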