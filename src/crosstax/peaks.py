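"""Fixed-width peak processing: summit extension, score-per-million and
iterative overlap merging.

All intervals are 0-based half-open.  The central operation is
:func:`iterative_overlap_merge`, a ranked greedy merge that keeps the
strongest peak in any overlapping set and discards everything it touches,
which prevents daisy-chaining (spurious fusion of non-overlapping peaks
through chains of pairwise overlaps).
"""

from __future__ import annotations

import bisect
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd

SUMMIT_COLUMNS = ["chrom", "summit", "score", "cluster"]
PEAK_COLUMNS = ["chrom", "start", "end", "score", "cluster"]

SPM_SCALE = 1_000_000.0


def _as_frame(obj, columns, name):
    df = pd.DataFrame(obj).reset_index(drop=True)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{name} is missing columns {missing}")
    return df


def extend_summits(
    summits: pd.DataFrame,
    chrom_sizes: Mapping[str, int],
    flank: int = 250,
) -> pd.DataFrame:
    """Extend summit positions to fixed-width intervals.

    Each summit becomes ``[summit - flank, summit + flank + 1)`` (width
    ``2 * flank + 1``).  Intervals running past a chromosome end are
    shifted inward so the fixed width is preserved; fixed width is what
    makes the downstream merge well-behaved.

    Parameters
    ----------
    summits
        Table with columns ``chrom``, ``summit`` (0-based bp), ``score``
        and ``cluster``.
    chrom_sizes
        Mapping chromosome name -> length in bp; must cover every
        chromosome referenced by `summits`.
    flank
        Bases added on each side of the summit.

    Returns
    -------
    pandas.DataFrame
        Peak table with columns ``chrom, start, end, score, cluster``.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    df = _as_frame(summits, SUMMIT_COLUMNS, "summits")
    unknown = set(df["chrom"]) - set(chrom_sizes)
    if unknown:
        raise ValueError(f"summits reference unknown chromosomes: {sorted(unknown)}")
    width = 2 * flank + 1
    sizes = df["chrom"].map(chrom_sizes).to_numpy()
    if (sizes < width).any():
        bad = df.loc[sizes < width, "chrom"].unique()
        raise ValueError(f"chromosomes shorter than peak width {width}: {list(bad)}")
    pos = df["summit"].to_numpy()
    if (pos < 0).any() or (pos >= sizes).any():
        raise ValueError("summit positions outside chromosome bounds")
    start = np.clip(pos - flank, 0, sizes - width)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"],
            "start": start.astype(np.int64),
            "end": (start + width).astype(np.int64),
            "score": df["score"].astype(float),
            "cluster": df["cluster"],
        }
    )
    return out


def score_per_million(peaks: pd.DataFrame) -> pd.DataFrame:
    """Normalize peak scores to score-per-million within each cluster.

    ``spm_i = score_i * 1e6 / sum(scores of the peak's cluster)``, so the
    per-cluster SPM sums to 1e6 and scores are comparable across
    clusters of different sequencing depth.
    """
    df = _as_frame(peaks, PEAK_COLUMNS, "peaks")
    if (df["score"] < 0).any():
        raise ValueError("scores must be nonnegative")
    totals = df.groupby("cluster")["score"].transform("sum")
    zero = totals <= 0
    if zero.any():
        bad = df.loc[zero, "cluster"].unique()
        raise ValueError(f"clusters with all-zero scores: {list(bad)}")
    out = df.copy()
    out["spm"] = df["score"].to_numpy() * SPM_SCALE / totals.to_numpy()
    return out


def _pooled(peaksets) -> pd.DataFrame:
    if isinstance(peaksets, pd.DataFrame):
        frames = [peaksets]
    else:
        frames = [pd.DataFrame(p) for p in peaksets]
    if not frames:
        raise ValueError("no peak sets supplied")
    pooled = pd.concat(frames, ignore_index=True)
    if "spm" not in pooled.columns:
        raise ValueError("peaks must carry an 'spm' column (run score_per_million)")
    return pooled


def iterative_overlap_merge(peaksets: pd.DataFrame | Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Merge pooled fixed-width peaks by ranked greedy selection.

    Peaks are ranked by SPM (descending; ties broken by chrom then
    start).  The top remaining peak is kept and every remaining peak
    overlapping it by >= 1 bp is discarded; this repeats until no peaks
    remain.  The kept set is pairwise non-overlapping and fixed width.
    Unlike a coordinate-span merge this never fuses two peaks that do
    not themselves overlap (no daisy-chaining).

    The result depends only on the multiset of (interval, spm) records,
    not on input order.
    """
    pooled = _pooled(peaksets)
    widths = (pooled["end"] - pooled["start"]).unique()
    if len(widths) > 1:
        raise ValueError(f"mixed peak widths {sorted(widths)}; merge requires fixed width")
    if len(pooled) == 0:
        return pooled.copy()
    width = int(widths[0])
    order = pooled.sort_values(
        ["spm", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    ).index
    kept_starts: dict[str, list[int]] = {}
    kept_idx = []
    chroms = pooled["chrom"].to_numpy()
    starts = pooled["start"].to_numpy()
    for i in order:
        chrom = chroms[i]
        s = int(starts[i])
        lst = kept_starts.setdefault(chrom, [])
        # fixed width: overlap with a kept peak iff |start difference| < width
        j = bisect.bisect_left(lst, s)
        if j > 0 and s - lst[j - 1] < width:
            continue
        if j < len(lst) and lst[j] - s < width:
            continue
        lst.insert(j, s)
        kept_idx.append(i)
    out = pooled.loc[sorted(kept_idx)].reset_index(drop=True)
    assert_non_overlapping(out)
    return out


def filter_spm(peaks: pd.DataFrame, cutoff: float = 5.0, inclusive: bool = True) -> pd.DataFrame:
    """Keep peaks with SPM >= cutoff (or > cutoff when ``inclusive=False``)."""
    df = _pooled(peaks)
    mask = df["spm"] >= cutoff if inclusive else df["spm"] > cutoff
    return df.loc[mask].reset_index(drop=True)


def assert_non_overlapping(peaks: pd.DataFrame) -> None:
    """Raise AssertionError if any two intervals in `peaks` overlap."""
    for _, grp in peaks.groupby("chrom"):
        srt = grp.sort_values("start")
        if (srt["start"].to_numpy()[1:] < srt["end"].to_numpy()[:-1]).any():
            raise AssertionError("overlapping peaks found")
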