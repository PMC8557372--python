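"""Genomic formats, coordinate conventions and the Tn5 read shift.

All coordinates are 0-based half-open (BED convention) everywhere inside
the package; 1-based formats are converted at the boundary.  Tn5 insertion
generates a 9-bp target-site duplication, so the single-base center of an
insertion event is recovered by shifting the forward fragment end by +4 bp
and the reverse fragment end by -5 bp; under the half-open end convention
both shifted positions land on the duplication center.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from pyfaidx import Fasta

log = logging.getLogger(__name__)

# length of the Tn5 target-site duplication; fragments shorter than this
# cannot carry a full duplication and are rejected by the shift
DUPLICATION_LENGTH = 9
FORWARD_SHIFT = 4
REVERSE_SHIFT = 5

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Fragment:
    """A sequenced fragment as a half-open genomic interval."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid fragment interval {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class InsertionSite:
    """Single-base center of a Tn5 insertion event."""

    contig: str
    pos: int
    strand: str = "+"
    count: int = 1

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass
class IntervalSet:
    """A named set of half-open genomic intervals (one annotation feature)."""

    name: str
    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def merged(self) -> "IntervalSet":
        """Union of intervals with overlaps and bookended runs collapsed."""
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end in self.intervals:
            by_contig.setdefault(contig, []).append((start, end))
        out: list[tuple[str, int, int]] = []
        for contig in sorted(by_contig):
            ivs = sorted(by_contig[contig])
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s <= cur_e:
                    cur_e = max(cur_e, e)
                else:
                    out.append((contig, cur_s, cur_e))
                    cur_s, cur_e = s, e
            out.append((contig, cur_s, cur_e))
        return IntervalSet(self.name, out)

    @property
    def total_length(self) -> int:
        return sum(e - s for _, s, e in self.merged().intervals)

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class GenomeSequence:
    """In-memory genome: uppercased contig sequences plus mappable size.

    ``mappable_size`` counts non-N bases, minus any bases covered by the
    blacklist supplied at load time.
    """

    sequences: dict[str, str]
    mappable_size: int = -1

    def __post_init__(self) -> None:
        self.sequences = {name: seq.upper() for name, seq in self.sequences.items()}
        if self.mappable_size < 0:
            self.mappable_size = sum(
                len(s) - s.count("N") for s in self.sequences.values()
            )

    @property
    def contigs(self) -> list[str]:
        return list(self.sequences)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def length(self, contig: str) -> int:
        return len(self.sequences[contig])

    def fetch(self, contig: str, start: int, end: int) -> str:
        if start < 0 or end > len(self.sequences[contig]):
            raise IndexError(f"{contig}:{start}-{end} outside contig bounds")
        return self.sequences[contig][start:end]

    def window(self, site: InsertionSite, width: int) -> str | None:
        """Width-bp window centered at the site; None if it runs off the
        contig or contains N (shape and PWM tables are undefined on N)."""
        if width % 2 == 0:
            raise ValueError("window width must be odd")
        half = width // 2
        start, end = site.pos - half, site.pos + half + 1
        seq = self.sequences[site.contig]
        if start < 0 or end > len(seq):
            return None
        win = seq[start:end]
        return None if "N" in win else win


def _blacklist_mask_length(genome_seqs: dict[str, str], blacklist: IntervalSet) -> int:
    """Number of non-N bases covered by the (merged) blacklist."""
    covered = 0
    for contig, start, end in blacklist.merged().intervals:
        if contig not in genome_seqs:
            warnings.warn(f"blacklist contig {contig!r} absent from genome; skipped")
            continue
        seq = genome_seqs[contig]
        s, e = max(0, start), min(len(seq), end)
        if s < e:
            covered += (e - s) - seq.count("N", s, e)
    return covered


def load_genome(fasta_path: str | Path, blacklist: IntervalSet | None = None) -> GenomeSequence:
    """Load a FASTA genome, uppercasing sequences and computing mappable size.

    Parameters
    ----------
    fasta_path
        Path to the genome FASTA (indexed on the fly).
    blacklist
        Optional intervals excluded from the mappable size (e.g. ENCODE
        blacklist regions).  Intervals on unknown contigs are skipped with
        a warning.
    """
    fa = Fasta(str(fasta_path), sequence_always_upper=True)
    seqs = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    genome = GenomeSequence(seqs)
    if blacklist is not None:
        genome.mappable_size -= _blacklist_mask_length(seqs, blacklist)
    return genome


def shift_fragment(fragment: Fragment) -> tuple[InsertionSite, InsertionSite]:
    """Shift a fragment's ends onto the two insertion-event centers.

    The plus-strand site is ``start + 4``, the minus-strand site ``end - 5``
    (half-open end).  A fragment of length exactly 9 is a single duplication
    and both sites coincide.

    Raises
    ------
    ValueError
        If the fragment is shorter than the 9-bp duplication.
    """
    if fragment.length < DUPLICATION_LENGTH:
        raise ValueError(
            f"fragment length {fragment.length} < {DUPLICATION_LENGTH}; "
            "cannot carry a full target-site duplication"
        )
    plus = InsertionSite(fragment.contig, fragment.start + FORWARD_SHIFT, "+")
    minus = InsertionSite(fragment.contig, fragment.end - REVERSE_SHIFT, "-")
    return plus, minus


def fragments_to_sites(
    fragments: Iterable[Fragment],
) -> tuple[list[InsertionSite], int]:
    """Shift every eligible fragment and aggregate duplicate events.

    Returns the aggregated, sorted site list and the number of fragments
    rejected for being shorter than 9 bp (rejection is counted, not fatal).
    """
    counts: Counter[tuple[str, int, str]] = Counter()
    n_rejected = 0
    for frag in fragments:
        if frag.length < DUPLICATION_LENGTH:
            n_rejected += 1
            continue
        plus, minus = shift_fragment(frag)
        counts[(plus.contig, plus.pos, plus.strand)] += 1
        counts[(minus.contig, minus.pos, minus.strand)] += 1
    sites = [
        InsertionSite(contig, pos, strand, c)
        for (contig, pos, strand), c in sorted(counts.items())
    ]
    if n_rejected:
        log.info("rejected %d fragments shorter than %d bp", n_rejected, DUPLICATION_LENGTH)
    return sites, n_rejected


def merge_strands(sites: Iterable[InsertionSite]) -> list[InsertionSite]:
    """Collapse sites at the same position regardless of strand.

    Counting operations in the package are strand-merged unless stated
    otherwise; merged sites are reported on the '+' strand.
    """
    counts: Counter[tuple[str, int]] = Counter()
    for s in sites:
        counts[(s.contig, s.pos)] += s.count
    return [
        InsertionSite(contig, pos, "+", c) for (contig, pos), c in sorted(counts.items())
    ]


def fragment_size_distribution(fragments: Iterable[Fragment]) -> dict[int, int]:
    """Histogram of fragment lengths (length -> count)."""
    return dict(Counter(f.length for f in fragments))


def _check_sorted(sites: Sequence[InsertionSite]) -> list[InsertionSite]:
    keys = [(s.contig, s.pos) for s in sites]
    if keys != sorted(keys):
        warnings.warn("insertion sites not sorted; sorting internally")
        return sorted(sites, key=lambda s: (s.contig, s.pos, s.strand))
    return list(sites)


def write_insertion_track(
    sites: Sequence[InsertionSite], path: str | Path, fmt: str = "BED"
) -> None:
    """Write sites as BED6 (per-strand) or bedGraph (strand-merged sums)."""
    sites = _check_sorted(sites)
    path = Path(path)
    with path.open("w") as fh:
        if fmt.upper() == "BED":
            for s in sites:
                fh.write(f"{s.contig}\t{s.pos}\t{s.pos + 1}\t.\t{s.count}\t{s.strand}\n")
        elif fmt.lower() == "bedgraph":
            for s in merge_strands(sites):
                fh.write(f"{s.contig}\t{s.pos}\t{s.pos + 1}\t{s.count}\n")
        else:
            raise ValueError(f"unknown track format {fmt!r}")


def read_sites_bed(path: str | Path) -> list[InsertionSite]:
    sites = []
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            contig, start = fields[0], int(fields[1])
            count = int(fields[4]) if len(fields) > 4 and fields[4] != "." else 1
            strand = fields[5] if len(fields) > 5 else "+"
            sites.append(InsertionSite(contig, start, strand, count))
    return sites


def read_bedgraph(path: str | Path) -> list[tuple[str, int, int, float]]:
    rows = []
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            contig, start, end, value = line.rstrip("\n").split("\t")[:4]
            rows.append((contig, int(start), int(end), float(value)))
    return rows


def write_bedgraph(rows: Iterable[tuple[str, int, int, float]], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for contig, start, end, value in rows:
            v = f"{value:g}" if isinstance(value, float) else str(value)
            fh.write(f"{contig}\t{start}\t{end}\t{v}\n")


def read_fragments_bed(path: str | Path) -> list[Fragment]:
    frags = []
    with Path(path).open() as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            contig, start, end = line.rstrip("\n").split("\t")[:3]
            frags.append(Fragment(contig, int(start), int(end)))
    return frags


def write_fragments_bed(fragments: Iterable[Fragment], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for f in fragments:
            fh.write(f"{f.contig}\t{f.start}\t{f.end}\n")


def read_bed_intervals(path: str | Path, name: str | None = None) -> IntervalSet:
    """Read a BED3+ file as one feature IntervalSet named after the file."""
    path = Path(path)
    ivs = []
    with path.open() as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            contig, start, end = line.rstrip("\n").split("\t")[:3]
            ivs.append((contig, int(start), int(end)))
    return IntervalSet(name or path.stem, ivs)


def write_bed_intervals(ivset: IntervalSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for contig, start, end in ivset.intervals:
            fh.write(f"{contig}\t{start}\t{end}\n")


def write_fasta(genome: GenomeSequence, path: str | Path, line_width: int = 70) -> None:
    with Path(path).open("w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i : i + line_width] + "\n")


def sites_to_arrays(
    sites: Sequence[InsertionSite],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-contig (positions, counts) arrays for strand-merged sites,
    sorted by position.  The workhorse layout for vectorized counting."""
    merged = merge_strands(sites)
    out: dict[str, list[tuple[int, int]]] = {}
    for s in merged:
        out.setdefault(s.contig, []).append((s.pos, s.count))
    return {
        contig: (
            np.array([p for p, _ in rows], dtype=np.int64),
            np.array([c for _, c in rows], dtype=np.int64),
        )
        for contig, rows in out.items()
    }
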