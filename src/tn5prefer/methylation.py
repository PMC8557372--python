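"""Context-dependent 9-mer analysis of DNA methylation and insertion.

Comparing insertion frequency between two conditions (e.g. two cell types)
at matched sequence contexts: the genome is tiled into non-overlapping 9-bp
bins; each bin carries its 9-mer sequence, a per-condition mean percent
methylation over covered cytosines (absent, not zero, when no cytosine is
covered), and per-condition insertion counts.  Eligible bins are classified
into four groups by the two methylation levels (A-only: >0 in A and =0 in
B; B-only; Both; None).  Insertion frequency is then averaged per unique
9-mer within each (group, condition); only 9-mers occurring in all four
groups are kept, so sequence context is identical across groups, and the
retained means are Z-scaled within each condition to put the two conditions
on one scale.  A separate 11-level stratification bins 9-mers by their
methylation level (level 0 = exactly 0%, then ten equal-width levels of
(0, 100]).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from tn5prefer.core_io import GenomeSequence, InsertionSite, sites_to_arrays

BIN = 9
GROUPS = ("a_only", "both", "none", "b_only")

MethTrack = dict[str, tuple[np.ndarray, np.ndarray]]


def _bin_means(
    track: tuple[np.ndarray, np.ndarray] | None, n_bins: int
) -> np.ndarray:
    """Mean percent methylation per bin over covered cytosines; NaN where
    no cytosine is covered."""
    out = np.full(n_bins, np.nan)
    if track is None:
        return out
    pos, vals = track
    keep = pos < n_bins * BIN
    pos, vals = pos[keep], vals[keep]
    if pos.size == 0:
        return out
    bins = pos // BIN
    sums = np.bincount(bins, weights=vals, minlength=n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    covered = counts > 0
    out[covered] = sums[covered] / counts[covered]
    return out


def _bin_counts(sites: Sequence[InsertionSite], contig: str, n_bins: int) -> np.ndarray:
    arrays = sites_to_arrays(sites)
    out = np.zeros(n_bins, dtype=np.int64)
    if contig not in arrays:
        return out
    pos, counts = arrays[contig]
    keep = pos < n_bins * BIN
    np.add.at(out, pos[keep] // BIN, counts[keep])
    return out


def tile_and_annotate(
    genome: GenomeSequence,
    meth_a: MethTrack,
    meth_b: MethTrack,
    sites_a: Sequence[InsertionSite],
    sites_b: Sequence[InsertionSite],
) -> pd.DataFrame:
    """Tile the genome into 9-bp bins annotated with per-condition mean
    methylation and insertion counts; bins containing N are dropped."""
    for track, label in ((meth_a, "A"), (meth_b, "B")):
        for contig in track:
            if contig not in genome.sequences:
                raise ValueError(
                    f"methylation track {label} names unknown contig {contig!r}"
                )
    frames = []
    for contig, seq in genome.sequences.items():
        n_bins = len(seq) // BIN
        if n_bins == 0:
            continue
        ninemers = [seq[i * BIN : (i + 1) * BIN] for i in range(n_bins)]
        frame = pd.DataFrame(
            {
                "contig": contig,
                "start": np.arange(n_bins) * BIN,
                "ninemer": ninemers,
                "meth_a": _bin_means(meth_a.get(contig), n_bins),
                "meth_b": _bin_means(meth_b.get(contig), n_bins),
                "count_a": _bin_counts(sites_a, contig, n_bins),
                "count_b": _bin_counts(sites_b, contig, n_bins),
            }
        )
        frame = frame[~frame["ninemer"].str.contains("N")]
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def classify_groups(bins: pd.DataFrame) -> pd.DataFrame:
    """Assign each eligible bin (methylation present in both conditions)
    one of the four groups; ineligible bins are excluded."""
    eligible = bins.dropna(subset=["meth_a", "meth_b"]).copy()
    a = eligible["meth_a"] > 0
    b = eligible["meth_b"] > 0
    group = np.select(
        [a & ~b, a & b, ~a & ~b, ~a & b],
        ["a_only", "both", "none", "b_only"],
        default="none",
    )
    eligible["group"] = group
    return eligible


def ninemer_profile(bins: pd.DataFrame) -> pd.DataFrame:
    """Per-(9-mer, group) mean insertion frequency, shared-9-mer filtered
    and Z-scaled within each condition.

    Returns columns: ninemer, group, mean_a, mean_b, z_a, z_b.  The Z-score
    is computed across all retained (9-mer, group) means per condition.
    """
    if "group" not in bins.columns:
        raise ValueError("bins must be classified first (classify_groups)")
    agg = (
        bins.groupby(["ninemer", "group"], sort=True)[["count_a", "count_b"]]
        .mean()
        .rename(columns={"count_a": "mean_a", "count_b": "mean_b"})
        .reset_index()
    )
    n_groups = agg.groupby("ninemer")["group"].nunique()
    shared = set(n_groups[n_groups == len(GROUPS)].index)
    agg = agg[agg["ninemer"].isin(shared)].reset_index(drop=True)
    if agg.empty:
        warnings.warn("no 9-mer occurs in all four groups; empty profile")
        agg["z_a"] = agg["z_b"] = np.nan
        return agg
    for cond in ("a", "b"):
        x = agg[f"mean_{cond}"].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        agg[f"z_{cond}"] = (x - x.mean()) / sd if sd > 0 else 0.0
    return agg


def trim_outliers(values: np.ndarray, frac: float = 0.01) -> np.ndarray:
    """Drop the top and bottom ``frac`` of values (boxplot-ready export)."""
    lo, hi = np.quantile(values, [frac, 1.0 - frac])
    return values[(values >= lo) & (values <= hi)]


def methylation_level(meth: np.ndarray, n_levels: int = 11) -> np.ndarray:
    """Level 0 = exactly 0%; levels 1..n-1 = equal-width bins of (0, 100],
    left-open right-closed."""
    width = 100.0 / (n_levels - 1)
    levels = np.ceil(meth / width).astype(int)
    levels = np.clip(levels, 0, n_levels - 1)
    levels[meth == 0] = 0
    return levels


def stratify_levels(
    bins: pd.DataFrame, condition: str = "a", n_levels: int = 11
) -> pd.DataFrame:
    """Insertion-frequency distribution per methylation level.

    Returns per level: bin count, median, lower and upper quartile of the
    per-bin insertion counts of the chosen condition.  Empty levels are
    reported with NaN summaries.
    """
    if condition not in ("a", "b"):
        raise ValueError("condition must be 'a' or 'b'")
    sub = bins.dropna(subset=[f"meth_{condition}"])
    meth = sub[f"meth_{condition}"].to_numpy(dtype=float)
    counts = sub[f"count_{condition}"].to_numpy(dtype=float)
    levels = methylation_level(meth, n_levels)
    rows = []
    for level in range(n_levels):
        vals = counts[levels == level]
        if vals.size:
            q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
        else:
            q1 = med = q3 = np.nan
        rows.append(
            {"level": level, "n_bins": int(vals.size), "q1": q1, "median": med, "q3": q3}
        )
    return pd.DataFrame(rows)
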