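"""Feature encodings for 51-bp windows around insertion sites.

Three vector families feed the classifier:

* **DNA shape** — 14 structural descriptors (minor groove width, propeller
  twist, roll, helix twist, ...) obtained by sliding-pentamer table lookup.
  Intra-base-pair shapes give one value per pentamer center; inter-base-pair
  (step) shapes carry two step values per pentamer, averaged to one value at
  the center so every shape yields the same vector length (L-4 = 47 for a
  51-bp window; the two edge positions on each side have no pentamer and
  are dropped, not imputed).
* **Motif** — the per-position PWM log-odds of the observed base under a
  window-wide PWM.
* **k-mer one-hot** — mono/di/trinucleotide indicators per start position,
  encoding nucleotide dependence directly.

Shape tables are data assets in a simple TSV schema; the bundled default is
a synthetic table (seeded random values per pentamer) sufficient for
planted-signal recovery — users may drop in published pentamer tables.
Seeded table shuffling (permuting values across pentamers) provides the
negative control that destroys pentamer/shape relationships while keeping
the value multiset intact.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from tn5prefer.core_io import GenomeSequence, InsertionSite
from tn5prefer.motif import BASES, PWM, sequence_to_indices

log = logging.getLogger(__name__)

PENTAMER = 5
N_PENTAMERS = 4**PENTAMER

# canonical shape list: 6 inter-base-pair (step) + 8 intra-base-pair
SHAPE_CLASSES: dict[str, str] = {
    "Shift": "inter",
    "Slide": "inter",
    "Rise": "inter",
    "Tilt": "inter",
    "Roll": "inter",
    "HelT": "inter",
    "Shear": "intra",
    "Stretch": "intra",
    "Stagger": "intra",
    "Buckle": "intra",
    "ProT": "intra",
    "Opening": "intra",
    "MGW": "intra",
    "EP": "intra",
}
SHAPE_NAMES = list(SHAPE_CLASSES)


def pentamer_index(pentamer: str) -> int:
    idx = sequence_to_indices(pentamer)
    if idx.size != PENTAMER or (idx < 0).any():
        raise ValueError(f"invalid pentamer {pentamer!r}")
    return int(idx @ (4 ** np.arange(PENTAMER - 1, -1, -1)))


def index_to_pentamer(code: int) -> str:
    out = []
    for _ in range(PENTAMER):
        out.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def pentamer_codes(idx: np.ndarray) -> np.ndarray:
    """Base-4 code of the pentamer centered at each position 2..L-3.

    Returns an array of length L-4; entries touching an N are -1.
    """
    L = idx.size
    if L < PENTAMER:
        raise ValueError("sequence shorter than a pentamer")
    codes = np.zeros(L - 4, dtype=np.int64)
    bad = np.zeros(L - 4, dtype=bool)
    for k in range(PENTAMER):
        part = idx[k : L - 4 + k].astype(np.int64)
        bad |= part < 0
        codes = codes * 4 + np.maximum(part, 0)
    codes[bad] = -1
    return codes


@dataclass
class ShapeTable:
    """Pentamer -> shape-value lookup for one shape feature.

    ``values`` has shape (1024,) for intra-base-pair shapes and (1024, 2)
    for inter-base-pair shapes (the two central steps of the pentamer).
    """

    name: str
    klass: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.klass not in ("intra", "inter"):
            raise ValueError("class must be 'intra' or 'inter'")
        expected = (N_PENTAMERS,) if self.klass == "intra" else (N_PENTAMERS, 2)
        if self.values.shape != expected:
            raise ValueError(
                f"{self.name}: values shape {self.values.shape} != {expected}"
            )

    def center_values(self) -> np.ndarray:
        """One value per pentamer: the intra value, or the mean of the two
        central steps for inter-base-pair shapes."""
        return self.values if self.klass == "intra" else self.values.mean(axis=1)

    def lookup(self, pentamer: str) -> float:
        return float(self.center_values()[pentamer_index(pentamer)])

    def shuffled(self, seed: int) -> "ShapeTable":
        """Seeded permutation of values across pentamers.

        Destroys the pentamer->shape relationship while preserving the
        value multiset exactly (inter rows are permuted as pairs).
        """
        rng = np.random.default_rng(seed)
        perm = rng.permutation(N_PENTAMERS)
        return ShapeTable(self.name, self.klass, self.values[perm].copy())


def synthetic_shape_table(name: str, seed: int = 2024) -> ShapeTable:
    """A synthetic stand-in shape table: seeded Gaussian values per pentamer.

    Carries no biophysical meaning; it provides a deterministic, well-spread
    pentamer -> value mapping so planted-signal recovery and shuffled-table
    controls can be exercised without licensed shape data.
    """
    if name not in SHAPE_CLASSES:
        raise ValueError(f"unknown shape {name!r}")
    klass = SHAPE_CLASSES[name]
    rng = np.random.default_rng([seed, SHAPE_NAMES.index(name)])
    shape = (N_PENTAMERS,) if klass == "intra" else (N_PENTAMERS, 2)
    return ShapeTable(name, klass, rng.normal(size=shape))


def default_shape_tables(seed: int = 2024) -> dict[str, ShapeTable]:
    """The bundled synthetic table set, one per shape feature."""
    return {name: synthetic_shape_table(name, seed) for name in SHAPE_NAMES}


def write_shape_tables_tsv(tables: dict[str, ShapeTable], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("pentamer\tshape\tvalue1\tvalue2\n")
        for name, table in tables.items():
            vals = np.atleast_2d(table.values.T).T
            for code in range(N_PENTAMERS):
                v1 = f"{vals[code, 0]:.6g}"
                v2 = f"{vals[code, 1]:.6g}" if table.klass == "inter" else ""
                fh.write(f"{index_to_pentamer(code)}\t{name}\t{v1}\t{v2}\n")


def read_shape_tables_tsv(path: str | Path) -> dict[str, ShapeTable]:
    store: dict[str, np.ndarray] = {}
    with Path(path).open() as fh:
        header = fh.readline()
        if not header.startswith("pentamer"):
            raise ValueError("shape table TSV must start with a header row")
        for line in fh:
            pent, name, v1, v2 = (line.rstrip("\n").split("\t") + [""])[:4]
            if name not in SHAPE_CLASSES:
                raise ValueError(f"unknown shape {name!r}")
            klass = SHAPE_CLASSES[name]
            arr = store.setdefault(
                name,
                np.full((N_PENTAMERS,) if klass == "intra" else (N_PENTAMERS, 2), np.nan),
            )
            code = pentamer_index(pent)
            if klass == "intra":
                arr[code] = float(v1)
            else:
                arr[code] = (float(v1), float(v2))
    tables = {}
    for name, arr in store.items():
        if np.isnan(arr).any():
            raise ValueError(f"shape {name}: not all 1024 pentamers present")
        tables[name] = ShapeTable(name, SHAPE_CLASSES[name], arr)
    return tables


def encode_shape(seq: str, table: ShapeTable) -> np.ndarray:
    """Shape-value vector for a window: one value per pentamer center,
    5'->3', length len(seq) - 4."""
    if len(seq) < PENTAMER:
        raise ValueError("window shorter than a pentamer")
    idx = sequence_to_indices(seq)
    codes = pentamer_codes(idx)
    if (codes < 0).any():
        raise ValueError("window contains N; drop it upstream")
    return table.center_values()[codes]


def encode_pwm_vector(seq: str, pwm: PWM) -> np.ndarray:
    """Per-position log-odds of the observed base under a window-wide PWM.

    Summing the vector reproduces the full-window scan score.
    """
    if len(seq) != pwm.width:
        raise ValueError(f"window length {len(seq)} != PWM width {pwm.width}")
    idx = sequence_to_indices(seq)
    if (idx < 0).any():
        raise ValueError("window contains N")
    return pwm.log_odds[idx, np.arange(pwm.width)]


def encode_kmer(seq: str, k: int) -> np.ndarray:
    """One-hot k-mer encoding: per start position one 4^k indicator block."""
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    if len(seq) < k:
        raise ValueError("window shorter than k")
    idx = sequence_to_indices(seq)
    if (idx < 0).any():
        raise ValueError("window contains N")
    n_pos = len(seq) - k + 1
    codes = np.zeros(n_pos, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + idx[j : j + n_pos]
    out = np.zeros(n_pos * 4**k)
    out[np.arange(n_pos) * 4**k + codes] = 1.0
    return out


def decode_kmer(vector: np.ndarray, k: int) -> str:
    """Inverse of :func:`encode_kmer` (sanity utility)."""
    block = 4**k
    n_pos = vector.size // block
    codes = vector.reshape(n_pos, block).argmax(axis=1)
    seq = list(_code_to_kmer(int(codes[0]), k))
    for c in codes[1:]:
        seq.append(_code_to_kmer(int(c), k)[-1])
    return "".join(seq)


def _code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def sample_control_sites(
    genome: GenomeSequence,
    n: int,
    seed: int,
    window: int = 51,
    exclude: set[tuple[str, int]] | None = None,
) -> list[InsertionSite]:
    """Random genomic control positions with valid (N-free, in-bounds)
    windows, sampled uniformly over the mappable genome with a seed."""
    rng = np.random.default_rng(seed)
    half = window // 2
    contigs = genome.contigs
    lengths = np.array([genome.length(c) for c in contigs], dtype=float)
    p = lengths / lengths.sum()
    out: list[InsertionSite] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 200 * n + 1000:
            raise RuntimeError("cannot find enough N-free control windows")
        ci = rng.choice(len(contigs), p=p)
        contig = contigs[ci]
        pos = int(rng.integers(half, genome.length(contig) - half))
        if exclude and (contig, pos) in exclude:
            continue
        site = InsertionSite(contig, pos, "+")
        if genome.window(site, window) is not None:
            out.append(site)
    return out


@dataclass
class FeatureMatrix:
    """Site x feature matrix with binary labels and block structure.

    ``X`` holds raw (unstandardized) features; min-max standardization to
    [0, 1] happens at fit time so the training bounds can be reapplied to
    held-out data.  ``blocks`` maps block name -> column slice and
    ``positions`` gives each column's window position (for importance maps).
    """

    X: np.ndarray
    y: np.ndarray
    names: list[str]
    blocks: dict[str, slice] = field(default_factory=dict)
    positions: np.ndarray | None = None
    window: int = 51

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset_rows(self, rows: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(
            self.X[rows], self.y[rows], self.names, self.blocks, self.positions, self.window
        )


def standardize(
    X: np.ndarray, bounds: tuple[np.ndarray, np.ndarray] | None = None
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Min-max scale columns to [0, 1].

    With ``bounds`` given (training bounds), they are reapplied and the
    result clipped to [0, 1]; degenerate (zero-range) columns map to 0.
    """
    if bounds is None:
        lo, hi = X.min(axis=0), X.max(axis=0)
    else:
        lo, hi = bounds
    span = hi - lo
    degenerate = span <= 0
    if bounds is None and degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance features mapped to 0")
    safe = np.where(degenerate, 1.0, span)
    X01 = (X - lo) / safe
    X01[:, degenerate] = 0.0
    return np.clip(X01, 0.0, 1.0), (lo, hi)


def _shuffle_each(seqs: list[str], seed: int) -> list[str]:
    rng = np.random.default_rng(seed)
    out = []
    for s in seqs:
        chars = np.array(list(s))
        rng.shuffle(chars)
        out.append("".join(chars))
    return out


def assemble_matrix(
    sites: Sequence[InsertionSite],
    controls: Sequence[InsertionSite],
    genome: GenomeSequence,
    blocks: Sequence[str],
    pwm: PWM | None = None,
    tables: dict[str, ShapeTable] | None = None,
    meth_track: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    window: int = 51,
    shuffle_seed: int = 0,
) -> FeatureMatrix:
    """Build the standardizable feature matrix for sites (label 1) vs
    controls (label 0).

    Block names: ``motif``, ``motif_shuffled`` (sequence-shuffled negative
    control), ``shapes``, ``kmer1``/``kmer2``/``kmer3``, ``meth``
    (per-position percent methylation from a per-cytosine track).
    Windows running off a contig or containing N are dropped with a log
    message; rows are sites first, then controls.
    """
    seqs: list[str] = []
    labels: list[int] = []
    kept: list[InsertionSite] = []
    n_dropped = 0
    for label, group in ((1, sites), (0, controls)):
        for site in group:
            win = genome.window(site, window)
            if win is None:
                n_dropped += 1
                continue
            seqs.append(win)
            labels.append(label)
            kept.append(site)
    if n_dropped:
        log.info("dropped %d windows (N or contig edge)", n_dropped)
    if not seqs:
        raise ValueError("no usable windows")

    col_blocks: dict[str, slice] = {}
    mats: list[np.ndarray] = []
    names: list[str] = []
    positions: list[int] = []
    start_col = 0

    def add_block(name: str, mat: np.ndarray, colnames: list[str], pos: list[int]) -> None:
        nonlocal start_col
        col_blocks[name] = slice(start_col, start_col + mat.shape[1])
        mats.append(mat)
        names.extend(colnames)
        positions.extend(pos)
        start_col += mat.shape[1]

    for block in blocks:
        if block in ("motif", "motif_shuffled"):
            if pwm is None or pwm.width != window:
                raise ValueError("motif block needs a PWM of the window width")
            use = seqs if block == "motif" else _shuffle_each(seqs, shuffle_seed)
            mat = np.stack([encode_pwm_vector(s, pwm) for s in use])
            add_block(
                block,
                mat,
                [f"{block}_pos{j:02d}" for j in range(window)],
                list(range(window)),
            )
        elif block == "shapes":
            if tables is None:
                raise ValueError("shapes block needs shape tables")
            for shape_name in SHAPE_NAMES:
                if shape_name not in tables:
                    raise ValueError(f"missing shape table {shape_name!r}")
                table = tables[shape_name]
                mat = np.stack([encode_shape(s, table) for s in seqs])
                add_block(
                    f"shape_{shape_name}",
                    mat,
                    [f"{shape_name}_pos{j + 2:02d}" for j in range(window - 4)],
                    list(range(2, window - 2)),
                )
        elif block in ("kmer1", "kmer2", "kmer3"):
            k = int(block[-1])
            mat = np.stack([encode_kmer(s, k) for s in seqs])
            n_pos = window - k + 1
            colnames = [
                f"{k}mer_pos{j:02d}_{_code_to_kmer(c, k)}"
                for j in range(n_pos)
                for c in range(4**k)
            ]
            add_block(block, mat, colnames, [j for j in range(n_pos) for _ in range(4**k)])
        elif block == "meth":
            if meth_track is None:
                raise ValueError("meth block needs a methylation track")
            mat = np.zeros((len(kept), window))
            half = window // 2
            for i, site in enumerate(kept):
                track = meth_track.get(site.contig)
                if track is None:
                    continue
                pos_arr, val_arr = track
                lo = np.searchsorted(pos_arr, site.pos - half)
                hi = np.searchsorted(pos_arr, site.pos + half + 1)
                for j in range(lo, hi):
                    mat[i, pos_arr[j] - (site.pos - half)] = val_arr[j]
            add_block(
                "meth",
                mat,
                [f"meth_pos{j:02d}" for j in range(window)],
                list(range(window)),
            )
        else:
            raise ValueError(f"unknown block {block!r}")

    X = np.concatenate(mats, axis=1)
    return FeatureMatrix(
        X=X,
        y=np.array(labels, dtype=np.int8),
        names=names,
        blocks=col_blocks,
        positions=np.array(positions, dtype=np.int64),
        window=window,
    )
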