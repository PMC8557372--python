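"""Tn5 sequence-motif model: PWM building, exact-p-value scanning, usage.

High-confidence insertion sites are selected from *paired fragments* — two
adjacent fragments whose coordinates overlap by exactly the 9-bp target-site
duplication, evidencing one insertion event seen from both sides.  A PWM is
then built from center-aligned windows around sites (no discovery step is
needed because the windows are already aligned at the event center), and the
genome is scanned with the exact score-distribution dynamic programming used
by FIMO-class scanners: per-window p-values from the discretized null score
distribution under the background model, with Benjamini-Hochberg q-values
over all scanned windows.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from tn5prefer.core_io import (
    DUPLICATION_LENGTH,
    FORWARD_SHIFT,
    Fragment,
    GenomeSequence,
    InsertionSite,
    merge_strands,
    reverse_complement,
)

log = logging.getLogger(__name__)

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# practical bound for the exact-p dynamic programming at the default grain
MAX_SCAN_WIDTH = 30


def sequence_to_indices(seq: str) -> np.ndarray:
    """Map a DNA string to int8 indices (A=0,C=1,G=2,T=3, N=-1)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


@dataclass
class PWM:
    """Position weight matrix over A,C,G,T with background and pseudocount.

    ``probs`` is 4 x width and column-stochastic; ``log_odds`` is
    log2(prob / background), finite whenever the pseudocount is positive.
    """

    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 1.0
    n_sites: int = 0

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.shape[0] != 4:
            raise ValueError("PWM probs must be 4 x width")
        col_sums = self.probs.sum(axis=0)
        if not np.allclose(col_sums, 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.probs / self.background[:, None])

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))

    def reverse_complement(self) -> "PWM":
        # complement swaps A<->T and C<->G, i.e. reverses the base axis
        return PWM(
            self.probs[::-1, ::-1].copy(),
            self.background[::-1].copy(),
            self.pseudocount,
            self.n_sites,
        )

    def score(self, seq: str) -> float:
        """Total log-odds score of a sequence of exactly the PWM width."""
        if len(seq) != self.width:
            raise ValueError(f"sequence length {len(seq)} != PWM width {self.width}")
        idx = sequence_to_indices(seq)
        if (idx < 0).any():
            raise ValueError("sequence contains non-ACGT characters")
        return float(self.log_odds[idx, np.arange(self.width)].sum())

    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    def write_meme(self, path: str | Path, name: str = "Tn5") -> None:
        """Serialize in MEME minimal motif format."""
        bg = self.background
        with Path(path).open("w") as fh:
            fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
            fh.write(
                "Background letter frequencies\n"
                f"A {bg[0]:.6f} C {bg[1]:.6f} G {bg[2]:.6f} T {bg[3]:.6f}\n\n"
            )
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {self.width} "
                f"nsites= {max(self.n_sites, 1)} E= 0\n"
            )
            for col in self.probs.T:
                fh.write(" " + " ".join(f"{p:.6f}" for p in col) + "\n")

    @classmethod
    def read_meme(cls, path: str | Path) -> "PWM":
        background = np.full(4, 0.25)
        rows: list[list[float]] = []
        in_matrix = False
        lines = Path(path).read_text().splitlines()
        for i, line in enumerate(lines):
            stripped = line.strip()
            if stripped.startswith("Background letter frequencies"):
                toks = lines[i + 1].split()
                background = np.array([float(toks[j]) for j in (1, 3, 5, 7)])
            elif stripped.startswith("letter-probability matrix"):
                in_matrix = True
            elif in_matrix:
                toks = stripped.split()
                if len(toks) == 4:
                    rows.append([float(t) for t in toks])
                elif rows:
                    break
        if not rows:
            raise ValueError(f"no letter-probability matrix found in {path}")
        probs = np.array(rows).T
        # renormalize away printed-precision drift
        probs /= probs.sum(axis=0, keepdims=True)
        return cls(probs, background)


@dataclass(frozen=True)
class MotifHit:
    contig: str
    start: int
    end: int
    strand: str
    score: float
    p: float
    q: float


@dataclass
class UsageSummary:
    """The four-way taxonomy of sites vs predicted motif intervals."""

    frac_insert_inside: float
    frac_insert_outside: float
    frac_motif_used: float | None
    frac_motif_unused: float | None
    n_sites: int
    n_hits: int


def paired_fragment_sites(fragments: Sequence[Fragment]) -> list[InsertionSite]:
    """Insertion sites evidenced by two fragments sharing a 9-bp overlap.

    For every ordered pair (left, right) on one contig with
    ``left.end - right.start == 9`` — the exact target-site duplication —
    one event is emitted at ``right.start + 4`` (equivalently
    ``left.end - 5``).  Duplicate events are merged into counts.
    """
    by_start: dict[tuple[str, int], int] = Counter()
    for f in fragments:
        by_start[(f.contig, f.start)] += 1
    events: Counter[tuple[str, int]] = Counter()
    for f in fragments:
        right_start = f.end - DUPLICATION_LENGTH
        n_right = by_start.get((f.contig, right_start), 0)
        if n_right and right_start > f.start:
            events[(f.contig, right_start + FORWARD_SHIFT)] += n_right
    return [
        InsertionSite(contig, pos, "+", c) for (contig, pos), c in sorted(events.items())
    ]


def subsample_sites(
    sites: Sequence[InsertionSite], n: int, seed: int
) -> list[InsertionSite]:
    """Uniform without-replacement subsample of distinct sites (seeded)."""
    if n <= 0:
        raise ValueError("subsample size must be positive")
    if n >= len(sites):
        if n > len(sites):
            warnings.warn(
                f"requested {n} sites but only {len(sites)} available; taking all"
            )
        return list(sites)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(sites), size=n, replace=False)
    return [sites[i] for i in sorted(chosen)]


def build_pwm(
    sites: Sequence[InsertionSite],
    genome: GenomeSequence,
    window: int = 19,
    pseudocount: float = 1.0,
    min_windows: int = 100,
    strand_aware: bool = True,
) -> PWM:
    """Positional base frequencies in windows centered at insertion sites.

    Windows are already aligned at the event center, so the PWM is the
    direct per-offset base-frequency matrix (with pseudocount), no motif
    discovery required.  Minus-strand sites contribute the reverse
    complement of their window when ``strand_aware`` is set; strand-merged
    sites contribute the forward window.

    The background is the base composition of the used windows.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    counts = np.zeros((4, window), dtype=float)
    n_used = 0
    n_edge = n_withn = 0
    for site in sites:
        win = genome.window(site, window)
        if win is None:
            half = window // 2
            if site.pos - half < 0 or site.pos + half + 1 > genome.length(site.contig):
                n_edge += 1
            else:
                n_withn += 1
            continue
        if strand_aware and site.strand == "-":
            win = reverse_complement(win)
        idx = sequence_to_indices(win)
        # each insertion event contributes one window
        counts[idx, np.arange(window)] += site.count
        n_used += site.count
    if n_used < min_windows:
        raise ValueError(
            f"only {n_used} usable windows (need >= {min_windows}); "
            f"dropped {n_edge} at contig edges, {n_withn} containing N"
        )
    probs = (counts + pseudocount) / (n_used + 4 * pseudocount)
    # background = overall genome base composition (FIMO convention)
    base_counts = np.zeros(4)
    for seq in genome.sequences.values():
        for b, i in ((b, i) for i, b in enumerate(BASES)):
            base_counts[i] += seq.count(b)
    background = (base_counts + pseudocount) / (base_counts.sum() + 4 * pseudocount)
    return PWM(probs, background, pseudocount, n_sites=n_used)


def _discretized_matrix(log_odds: np.ndarray, delta: float) -> tuple[np.ndarray, np.ndarray]:
    """Integer score matrix per column plus column offsets, grain ``delta``."""
    col_min = log_odds.min(axis=0)
    disc = np.rint((log_odds - col_min[None, :]) / delta).astype(np.int64)
    return disc, col_min


def exact_score_distribution(
    log_odds: np.ndarray, background: np.ndarray, delta: float
) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of the discretized window score under background.

    Dynamic programming over positions: the distribution of the total
    integer score of a random sequence with i.i.d. letters drawn from the
    background.  Returns (disc_matrix, survival) where ``survival[t]`` is
    P(total discretized score >= t).
    """
    disc, _ = _discretized_matrix(log_odds, delta)
    max_total = int(disc.max(axis=0).sum())
    dist = np.zeros(max_total + 1)
    dist[0] = 1.0
    for j in range(disc.shape[1]):
        new = np.zeros_like(dist)
        for b in range(4):
            k = disc[b, j]
            new[k:] += background[b] * dist[: dist.size - k if k else None]
        dist = new
    survival = np.cumsum(dist[::-1])[::-1]
    return disc, survival


def _scan_strand(
    idx: np.ndarray, disc: np.ndarray, survival: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Discretized scores and validity mask for every window start."""
    w = disc.shape[1]
    n_win = idx.size - w + 1
    if n_win <= 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    scores = np.zeros(n_win, dtype=np.int64)
    valid = np.ones(n_win, dtype=bool)
    for j in range(w):
        col_idx = idx[j : j + n_win]
        bad = col_idx < 0
        valid &= ~bad
        scores += disc[np.where(bad, 0, col_idx), j]
    return scores, valid


def benjamini_hochberg(pvals: np.ndarray, m: int | None = None) -> np.ndarray:
    """BH step-up q-values; ``m`` overrides the number of tests."""
    p = np.asarray(pvals, dtype=float)
    if m is None:
        m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def scan_pwm(
    pwm: PWM,
    genome: GenomeSequence,
    q_threshold: float = 0.001,
    grain: float = 1e-4,
) -> list[MotifHit]:
    """Scan both strands with exact p-values and BH q-values.

    Scores are log-odds discretized to ``grain`` x (score range); p-values
    come from the exact DP null distribution under the PWM background, and
    q-values are BH across all scanned windows on both strands.  Hits with
    q below the threshold are returned; overlapping hits are all retained.
    """
    if pwm.width > MAX_SCAN_WIDTH:
        raise ValueError(
            f"PWM width {pwm.width} exceeds the exact-p bound {MAX_SCAN_WIDTH}; "
            "use a coarser grain or a narrower matrix"
        )
    lo_fwd = pwm.log_odds
    lo_rev = pwm.reverse_complement().log_odds
    span = max(lo_fwd.max() - lo_fwd.min(), 1e-12)
    delta = span * grain

    # the null draws forward-strand letters from the PWM background on
    # both strands; the minus strand scores the reverse-complement matrix
    strands = {}
    for strand, lo in (("+", lo_fwd), ("-", lo_rev)):
        disc, survival = exact_score_distribution(lo, pwm.background, delta)
        strands[strand] = (lo, disc, survival)

    chunks: list[tuple[str, str, np.ndarray, np.ndarray, np.ndarray]] = []
    m = 0
    for contig, seq in genome.sequences.items():
        idx = sequence_to_indices(seq)
        for strand, (lo, disc, survival) in strands.items():
            scores, valid = _scan_strand(idx, disc, survival)
            if scores.size == 0:
                continue
            m += scores.size
            pvals = survival[np.minimum(scores, survival.size - 1)]
            pvals = np.where(valid, pvals, 1.0)
            chunks.append((contig, strand, scores, valid, pvals))

    if not chunks:
        return []
    qvec = benjamini_hochberg(np.concatenate([c[4] for c in chunks]), m=m)
    hits: list[MotifHit] = []
    offset = 0
    for contig, strand, scores, valid, pvals in chunks:
        q = qvec[offset : offset + pvals.size]
        offset += pvals.size
        col_min_total = strands[strand][0].min(axis=0).sum()
        for start in np.nonzero(valid & (q < q_threshold))[0]:
            real = float(scores[start] * delta + col_min_total)
            hits.append(
                MotifHit(
                    contig, int(start), int(start) + pwm.width, strand,
                    real, float(pvals[start]), float(q[start]),
                )
            )
    hits.sort(key=lambda h: (h.contig, h.start, h.strand))
    return hits


def usage_summary(
    sites: Sequence[InsertionSite], hits: Sequence[MotifHit]
) -> UsageSummary:
    """Inside/outside fractions of sites and used/unused fractions of hits.

    A site is *inside* if its position falls within any hit interval
    (strand-agnostic, half-open); a hit is *used* if at least one site
    falls within it.  Fractions are over distinct sites and distinct hits.
    """
    merged_sites = merge_strands(sites)
    site_pos: dict[str, np.ndarray] = {}
    for s in merged_sites:
        site_pos.setdefault(s.contig, []).append(s.pos)  # type: ignore[arg-type]
    site_pos = {c: np.array(sorted(p)) for c, p in site_pos.items()}

    hit_iv: dict[str, list[tuple[int, int]]] = {}
    for h in hits:
        hit_iv.setdefault(h.contig, []).append((h.start, h.end))

    n_sites = len(merged_sites)
    n_hits = len(hits)
    n_inside = 0
    for contig, positions in site_pos.items():
        ivs = hit_iv.get(contig)
        if not ivs:
            continue
        # merge hit intervals for the inside test
        merged: list[tuple[int, int]] = []
        for s, e in sorted(set(ivs)):
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        starts = np.array([s for s, _ in merged])
        ends = np.array([e for _, e in merged])
        k = np.searchsorted(starts, positions, side="right") - 1
        inside = (k >= 0) & (positions < ends[np.maximum(k, 0)])
        n_inside += int(inside.sum())

    n_used = 0
    for h in hits:
        positions = site_pos.get(h.contig)
        if positions is None:
            continue
        lo = np.searchsorted(positions, h.start, side="left")
        if lo < positions.size and positions[lo] < h.end:
            n_used += 1

    frac_inside = n_inside / n_sites if n_sites else 0.0
    if n_hits:
        frac_used: float | None = n_used / n_hits
        frac_unused: float | None = 1.0 - frac_used
    else:
        frac_used = frac_unused = None
    return UsageSummary(
        frac_insert_inside=frac_inside,
        frac_insert_outside=1.0 - frac_inside,
        frac_motif_used=frac_used,
        frac_motif_unused=frac_unused,
        n_sites=n_sites,
        n_hits=n_hits,
    )


def write_hits_bed(hits: Iterable[MotifHit], path: str | Path) -> None:
    """BED6+2 with score, p and q columns."""
    with Path(path).open("w") as fh:
        for h in hits:
            fh.write(
                f"{h.contig}\t{h.start}\t{h.end}\tmotif\t{h.score:.4f}\t{h.strand}"
                f"\t{h.p:.6g}\t{h.q:.6g}\n"
            )
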