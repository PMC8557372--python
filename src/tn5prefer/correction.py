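"""k-mer sequence-bias model and single-base insertion-signal correction.

Tn5's sequence preference spans roughly 19 bp around the insertion center,
so insertion counts are modelled per k-mer context (default k = 19, odd so
a center exists).  For each masked k-mer w the empirical insertion rate is

    rate(w) = (site-weighted count of centers with context w + pc)
              / (genome occurrences of w + pc)

and the correction scale is scale(w) = mean rate / rate(w): over-preferred
contexts are scaled down, avoided contexts up.  Corrected signal is
raw count x scale(context), rescaled so the genome-wide total equals the
raw total (threshold semantics downstream are preserved).  A mask string
over {X, .} of length k restricts which positions inform the context
('.' positions are ignored), which keeps large-k models tractable; contexts
are stored sparsely (only k-mers observed in the genome).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from tn5prefer.core_io import (
    GenomeSequence,
    InsertionSite,
    IntervalSet,
    sites_to_arrays,
)
from tn5prefer.motif import sequence_to_indices


@dataclass
class BiasModel:
    """Sparse masked-k-mer -> scale-factor table.

    ``codes`` are the sorted masked-context codes observed in the genome;
    ``scales`` align with them.  Scales are +inf where undefined (possible
    only at pseudocount 0 for contexts without site observations).
    """

    k: int
    mask: str
    pseudocount: float
    codes: np.ndarray
    scales: np.ndarray
    genome_counts: np.ndarray
    site_counts: np.ndarray
    mean_rate: float

    def scale_for(self, kmer: str) -> float:
        """Scale factor for an explicit k-mer string (test/inspection aid)."""
        if len(kmer) != self.k:
            raise ValueError(f"k-mer must be length {self.k}")
        code = _mask_code(sequence_to_indices(kmer)[None, :], self.mask)[0]
        idx = np.searchsorted(self.codes, code)
        if idx >= self.codes.size or self.codes[idx] != code:
            raise KeyError(f"context {kmer!r} not observed in the genome")
        s = float(self.scales[idx])
        if not np.isfinite(s):
            raise ValueError(
                f"scale undefined for {kmer!r}: no site observations and "
                "pseudocount 0"
            )
        return s


def _mask_code(windows: np.ndarray, mask: str) -> np.ndarray:
    """Base-4 code of each window row using only 'X' mask positions."""
    codes = np.zeros(windows.shape[0], dtype=np.int64)
    for j, m in enumerate(mask):
        if m == "X":
            codes = codes * 4 + windows[:, j]
    return codes


def _context_codes(
    idx: np.ndarray, k: int, mask: str
) -> tuple[np.ndarray, np.ndarray]:
    """(codes, valid) for the k-mer centered at every position.

    Positions whose window runs off the contig or contains N are invalid
    (excluded from both numerator and denominator).
    """
    L = idx.size
    half = k // 2
    codes = np.zeros(L, dtype=np.int64)
    valid = np.ones(L, dtype=bool)
    valid[:half] = False
    valid[L - half :] = False
    safe = np.maximum(idx, 0).astype(np.int64)
    n_windows = L - k + 1
    if n_windows <= 0:
        return codes, np.zeros(L, dtype=bool)
    win_codes = np.zeros(n_windows, dtype=np.int64)
    win_bad = np.zeros(n_windows, dtype=bool)
    for j, m in enumerate(mask):
        col = idx[j : j + n_windows]
        win_bad |= col < 0
        if m == "X":
            win_codes = win_codes * 4 + safe[j : j + n_windows]
    codes[half : half + n_windows] = win_codes
    valid[half : half + n_windows] &= ~win_bad
    return codes, valid


def build_bias_model(
    sites: Sequence[InsertionSite],
    genome: GenomeSequence,
    k: int = 19,
    mask: str | None = None,
    pseudocount: float = 0.5,
) -> BiasModel:
    """Tabulate per-context insertion rates and correction scales.

    Contexts are the '+'-strand k-mers centered at strand-merged positions.
    With an all-'.' mask every position collapses to one context and all
    scales are 1 (correction becomes the identity).
    """
    if k % 2 == 0:
        raise ValueError("k must be odd so a center position exists")
    if mask is None:
        mask = "X" * k
    if len(mask) != k or set(mask) - {"X", "."}:
        raise ValueError("mask must be a length-k string over {X, .}")

    arrays = sites_to_arrays(sites)
    all_codes: list[np.ndarray] = []
    site_code_list: list[np.ndarray] = []
    site_weight_list: list[np.ndarray] = []
    for contig, seq in genome.sequences.items():
        idx = sequence_to_indices(seq)
        codes, valid = _context_codes(idx, k, mask)
        all_codes.append(codes[valid])
        if contig in arrays:
            pos, counts = arrays[contig]
            ok = valid[pos]
            site_code_list.append(codes[pos[ok]])
            site_weight_list.append(counts[ok])

    genome_codes = np.concatenate(all_codes)
    uniq, gen_counts = np.unique(genome_codes, return_counts=True)
    site_counts = np.zeros_like(gen_counts, dtype=float)
    if site_code_list:
        scodes = np.concatenate(site_code_list)
        sweights = np.concatenate(site_weight_list).astype(float)
        loc = np.searchsorted(uniq, scodes)
        np.add.at(site_counts, loc, sweights)

    total_sites = float(site_counts.sum())
    total_positions = float(gen_counts.sum())
    mean_rate = total_sites / total_positions
    rate = (site_counts + pseudocount) / (gen_counts + pseudocount)
    with np.errstate(divide="ignore"):
        scales = np.where(rate > 0, mean_rate / rate, np.inf)
    return BiasModel(
        k=k,
        mask=mask,
        pseudocount=pseudocount,
        codes=uniq,
        scales=scales,
        genome_counts=gen_counts,
        site_counts=site_counts,
        mean_rate=mean_rate,
    )


def correct_signal(
    sites: Sequence[InsertionSite],
    model: BiasModel,
    genome: GenomeSequence,
) -> tuple[list[tuple[str, int, int, float]], int]:
    """Rescale strand-merged site counts by their context scale factor.

    Returns bedGraph-ready rows and the number of positions emitted
    uncorrected because their context is undefined (N or contig edge).
    The corrected track is globally rescaled so its total equals the raw
    total.
    """
    arrays = sites_to_arrays(sites)
    rows: list[tuple[str, int, int, float]] = []
    n_flagged = 0
    raw_total = 0.0
    for contig in sorted(arrays):
        if contig not in genome.sequences:
            raise ValueError(f"sites name contig {contig!r} absent from genome")
        idx = sequence_to_indices(genome.sequences[contig])
        codes, valid = _context_codes(idx, model.k, model.mask)
        pos, counts = arrays[contig]
        raw_total += float(counts.sum())
        loc = np.searchsorted(model.codes, codes[pos])
        loc_ok = (loc < model.codes.size) & valid[pos]
        in_table = loc_ok.copy()
        in_table[loc_ok] &= model.codes[loc[loc_ok]] == codes[pos[loc_ok]]
        for i in range(pos.size):
            if in_table[i] and np.isfinite(model.scales[loc[i]]):
                value = counts[i] * float(model.scales[loc[i]])
            else:
                value = float(counts[i])
                n_flagged += 1
            rows.append((contig, int(pos[i]), int(pos[i]) + 1, value))
    corrected_total = sum(r[3] for r in rows)
    if corrected_total > 0:
        factor = raw_total / corrected_total
        rows = [(c, s, e, v * factor) for c, s, e, v in rows]
    return rows, n_flagged


def per_context_cv(
    rows: Sequence[tuple[str, int, int, float]],
    model: BiasModel,
    genome: GenomeSequence,
    min_occurrences: int = 10,
) -> float:
    """Coefficient of variation of the per-context mean signal.

    For each masked context with at least ``min_occurrences`` genome
    occurrences, the mean signal per occurrence is (sum of track values at
    positions carrying the context) / (genome occurrences); the CV over
    contexts measures residual context-driven bias (0 = none).
    """
    sums = np.zeros(model.codes.size)
    for contig, seq in genome.sequences.items():
        idx = sequence_to_indices(seq)
        codes, valid = _context_codes(idx, model.k, model.mask)
        contig_rows = [(s, v) for c, s, _e, v in rows if c == contig]
        for pos, value in contig_rows:
            if not valid[pos]:
                continue
            loc = np.searchsorted(model.codes, codes[pos])
            if loc < model.codes.size and model.codes[loc] == codes[pos]:
                sums[loc] += value
    keep = model.genome_counts >= min_occurrences
    if not keep.any():
        raise ValueError("no context reaches min_occurrences")
    means = sums[keep] / model.genome_counts[keep]
    mu = means.mean()
    if mu == 0:
        return 0.0
    return float(means.std(ddof=0) / mu)


def compare_interval_sets(
    a: IntervalSet, b: IntervalSet
) -> dict[str, IntervalSet]:
    """Partition each set into shared (>= 1 bp overlap with the other set)
    and specific intervals."""

    def _split(src: IntervalSet, other: IntervalSet) -> tuple[IntervalSet, IntervalSet]:
        other_iv: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for contig, s, e in other.merged().intervals:
            other_iv.setdefault(contig, ([], []))  # type: ignore[arg-type]
            other_iv[contig][0].append(s)  # type: ignore[union-attr]
            other_iv[contig][1].append(e)  # type: ignore[union-attr]
        other_iv = {
            c: (np.array(ss), np.array(ee)) for c, (ss, ee) in other_iv.items()
        }
        shared, specific = [], []
        for contig, s, e in src.intervals:
            ivs = other_iv.get(contig)
            hit = False
            if ivs is not None:
                starts, ends = ivs
                j = np.searchsorted(starts, e, side="left") - 1
                hit = j >= 0 and ends[j] > s
            (shared if hit else specific).append((contig, s, e))
        return (
            IntervalSet(f"{src.name}_shared", shared),
            IntervalSet(f"{src.name}_specific", specific),
        )

    a_shared, a_specific = _split(a, b)
    b_shared, b_specific = _split(b, a)
    return {
        "a_shared": a_shared,
        "a_specific": a_specific,
        "b_shared": b_shared,
        "b_specific": b_specific,
    }
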