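"""Small helpers for genomic interval lists (BED-style tables)."""

from __future__ import annotations

import pandas as pd

COLS = ["chrom", "start", "end"]


def as_interval_frame(intervals) -> pd.DataFrame:
    """Coerce a list of (chrom, start, end[, ...]) tuples or a DataFrame to a
    sorted interval table."""
    if isinstance(intervals, pd.DataFrame):
        df = intervals.copy()
    else:
        df = pd.DataFrame(list(intervals), columns=COLS[: len(intervals[0])]
                          if len(intervals) else COLS)
    if df.empty:
        return pd.DataFrame(columns=COLS)
    df["chrom"] = df["chrom"].astype(str)
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def merge_intervals(intervals) -> pd.DataFrame:
    """Union of intervals: merged, sorted, non-overlapping (idempotent)."""
    df = as_interval_frame(intervals) if not isinstance(intervals, pd.DataFrame) \
        else as_interval_frame(intervals)
    if df.empty:
        return pd.DataFrame(columns=COLS)
    out = []
    for chrom, sub in df.groupby("chrom", sort=True):
        cur_s, cur_e = None, None
        for r in sub.sort_values("start").itertuples():
            if cur_s is None:
                cur_s, cur_e = int(r.start), int(r.end)
            elif int(r.start) <= cur_e:
                cur_e = max(cur_e, int(r.end))
            else:
                out.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(r.start), int(r.end)
        if cur_s is not None:
            out.append((chrom, cur_s, cur_e))
    return pd.DataFrame(out, columns=COLS)


def overlap_bp(chrom: str, start: int, end: int, intervals: pd.DataFrame) -> int:
    """Base pairs of [start, end) on chrom covered by the (merged) intervals."""
    if intervals.empty:
        return 0
    sub = intervals[intervals["chrom"].astype(str) == str(chrom)]
    total = 0
    for r in sub.itertuples():
        total += max(0, min(end, int(r.end)) - max(start, int(r.start)))
    return total


def read_bed(path, names=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    ncol = df.shape[1]
    base = ["chrom", "start", "end", "name", "score", "strand"]
    df.columns = (names or base[:ncol]) if ncol <= 6 else list(df.columns)
    return df


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, header=False)
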