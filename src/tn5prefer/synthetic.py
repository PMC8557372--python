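"""Synthetic genomes and insertion events with planted preference structure.

The generator emulates a naked-DNA tagmentation experiment at desk scale:
an i.i.d. random genome, and insertion events sampled multinomially from a
per-position propensity

    propensity(i)  proportional to  exp( motif_weight * pwm_score(i)
                                        + sum of dinucleotide weights over
                                          the 19-bp context at i
                                        + shape_weight * mean shape value
                                          over the 19-bp context at i
                                        + methylation_effect * meth(i) )

where ``meth(i)`` is the fractional (0-1) methylation at position i.  The
19-bp context mirrors the empirical range over which sequence affects Tn5
insertion.  Every planted parameter is echoed in a SimulationTruth record,
so each analysis stage can be validated by parameter recovery.  Sampling is
with replacement (multinomial), so pileups with count > 1 arise naturally.

One global seed fans out to fixed per-stage child seeds, keeping stages
independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from tn5prefer.core_io import (
    Fragment,
    GenomeSequence,
    InsertionSite,
    IntervalSet,
    write_bedgraph,
    write_fasta,
    write_fragments_bed,
    write_insertion_track,
)
from tn5prefer.encoding import ShapeTable, pentamer_codes
from tn5prefer.motif import BASES, PWM, sequence_to_indices

CONTEXT_WINDOW = 19  # empirical span of sequence influence on insertion


def _child_seed(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % 2**31, stage])


@dataclass
class SimulationConfig:
    """Parameters of one synthetic experiment; defaults give a neutral
    (uniform-propensity) genome of realistic desk scale."""

    genome_length: int = 100_000
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    planted_pwm: PWM | None = None
    motif_weight: float = 0.0
    dinuc_weights: np.ndarray | None = None  # 16 reals, AA..TT row-major
    shape_table: ShapeTable | None = None
    shape_weight: float = 0.0
    methylation_effect: float = 0.0
    n_insertions: int = 10_000
    n_contigs: int = 1
    n_planted_motifs: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or abs(comp.sum() - 1.0) > 1e-9 or (comp < 0).any():
            raise ValueError("base_composition must be 4 probabilities summing to 1")
        if self.n_insertions < 1:
            raise ValueError("n_insertions must be >= 1")
        if self.genome_length < 200:
            raise ValueError("genome_length must be >= 200")
        if self.dinuc_weights is not None:
            self.dinuc_weights = np.asarray(self.dinuc_weights, dtype=float)
            if self.dinuc_weights.shape != (16,):
                raise ValueError("dinuc_weights must have 16 entries")
            if not np.isfinite(self.dinuc_weights).all():
                raise ValueError("dinuc_weights must be finite")


@dataclass
class SimulationTruth:
    """Ground truth of one simulation: exact normalized propensity per
    position, the planted parameters, and the sampled sites."""

    propensity: dict[str, np.ndarray]
    config: SimulationConfig
    sites: list[InsertionSite] = field(default_factory=list)

    def total_mass(self) -> float:
        return float(sum(v.sum() for v in self.propensity.values()))


def simulate_genome(config: SimulationConfig) -> GenomeSequence:
    """I.i.d. genome from the configured base composition (seeded).

    With ``n_planted_motifs`` > 0 and a planted PWM, that many motif
    instances (drawn column-wise from the PWM) are written into the
    sequence at seeded non-overlapping positions, emulating the fact that
    real genomes carry motif occurrences far above the i.i.d. background.
    """
    rng = _child_seed(config.seed, 1)
    per = config.genome_length // config.n_contigs
    seqs = {}
    for c in range(config.n_contigs):
        length = per if c < config.n_contigs - 1 else config.genome_length - per * (
            config.n_contigs - 1
        )
        draws = rng.choice(4, size=length, p=np.asarray(config.base_composition))
        if config.n_planted_motifs and config.planted_pwm is not None:
            n_here = config.n_planted_motifs // config.n_contigs
            w = config.planted_pwm.width
            # non-overlapping slots on a coarse grid, seeded subset
            slots = np.arange(2 * w, length - 2 * w, 2 * w)
            chosen = rng.choice(slots, size=min(n_here, slots.size), replace=False)
            for start in chosen:
                for j in range(w):
                    draws[start + j] = rng.choice(4, p=config.planted_pwm.probs[:, j])
        seqs[f"chr{c + 1}"] = "".join(BASES[i] for i in draws)
    return GenomeSequence(seqs)


def _contig_log_propensity(
    seq: str,
    config: SimulationConfig,
    meth: tuple[np.ndarray, np.ndarray] | None,
) -> np.ndarray:
    idx = sequence_to_indices(seq)
    L = idx.size
    logp = np.zeros(L)
    half = CONTEXT_WINDOW // 2

    valid = np.ones(L, dtype=bool)
    valid[:half] = False
    valid[L - half :] = False
    # any N inside the 19-bp context invalidates the position
    is_n = idx < 0
    if is_n.any():
        bad = np.convolve(is_n.astype(int), np.ones(CONTEXT_WINDOW, dtype=int), "same")
        valid &= bad == 0

    if config.planted_pwm is not None and config.motif_weight != 0.0:
        pwm = config.planted_pwm
        w = pwm.width
        if w > CONTEXT_WINDOW:
            raise ValueError("planted PWM wider than the 19-bp context")
        lo = pwm.log_odds
        phalf = w // 2
        score = np.zeros(L)
        safe_idx = np.maximum(idx, 0)
        for j in range(w):
            sl = safe_idx[j : L - w + 1 + j]
            score[phalf : L - (w - 1 - phalf)] += lo[sl, j]
        logp += config.motif_weight * score

    if config.dinuc_weights is not None:
        pair = np.maximum(idx[:-1], 0) * 4 + np.maximum(idx[1:], 0)
        pair_w = config.dinuc_weights[pair]
        # sum of the 18 adjacent-pair weights inside the centered 19-bp window
        csum = np.concatenate([[0.0], np.cumsum(pair_w)])
        win = np.zeros(L)
        lo_i, hi_i = half, L - half
        win[lo_i:hi_i] = csum[np.arange(lo_i, hi_i) + half] - csum[
            np.arange(lo_i, hi_i) - half
        ]
        logp += win

    if config.shape_table is not None and config.shape_weight != 0.0:
        center_vals = config.shape_table.center_values()
        codes = pentamer_codes(idx)
        v = np.zeros(L)
        ok = codes >= 0
        v[2 : L - 2][ok] = center_vals[codes[ok]]
        # mean shape value over the 19 pentamer centers in the context
        csum = np.concatenate([[0.0], np.cumsum(v)])
        win = np.zeros(L)
        lo_i, hi_i = half + 2, L - half - 2
        win[lo_i:hi_i] = (
            csum[np.arange(lo_i, hi_i) + half + 1] - csum[np.arange(lo_i, hi_i) - half]
        ) / CONTEXT_WINDOW
        valid[:lo_i] = False
        valid[hi_i:] = False
        logp += config.shape_weight * win

    if config.methylation_effect != 0.0 and meth is not None:
        pos, vals = meth
        m = np.zeros(L)
        m[pos] = vals / 100.0
        logp += config.methylation_effect * m

    logp[~valid] = -np.inf
    return logp


def simulate_insertions(
    genome: GenomeSequence,
    config: SimulationConfig,
    meth_track: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
) -> tuple[list[InsertionSite], SimulationTruth]:
    """Sample insertion events from the planted propensity (multinomial).

    Returns the aggregated site list (count >= 1 per position) and the
    SimulationTruth with the exact normalized propensity vector.
    """
    logps = {}
    for contig, seq in genome.sequences.items():
        meth = meth_track.get(contig) if meth_track else None
        logps[contig] = _contig_log_propensity(seq, config, meth)
    flat = np.concatenate(list(logps.values()))
    finite = np.isfinite(flat)
    if not finite.any():
        raise ValueError("all-zero propensity: no valid positions")
    mx = flat[finite].max()
    prop = np.where(finite, np.exp(flat - mx), 0.0)
    prop /= prop.sum()

    rng = _child_seed(config.seed, 2)
    counts = rng.multinomial(config.n_insertions, prop)

    sites: list[InsertionSite] = []
    offset = 0
    propensity: dict[str, np.ndarray] = {}
    for contig, lp in logps.items():
        L = lp.size
        propensity[contig] = prop[offset : offset + L]
        nz = np.nonzero(counts[offset : offset + L])[0]
        for i in nz:
            sites.append(
                InsertionSite(contig, int(i), "+", int(counts[offset + i]))
            )
        offset += L
    truth = SimulationTruth(propensity=propensity, config=config, sites=sites)
    return sites, truth


def simulate_methylation(
    genome: GenomeSequence,
    seed: int,
    regions: IntervalSet | None = None,
    mean_level: float = 75.0,
    sd: float = 15.0,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Percent-methylation track at every cytosine position.

    Inside ``regions`` cytosines draw a level around ``mean_level``; outside
    (or everywhere when regions is None) they are 0.  Values clipped to
    [0, 100].  Returns {contig: (positions, percent values)}.
    """
    rng = _child_seed(seed, 3)
    track: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    region_map: dict[str, list[tuple[int, int]]] = {}
    if regions is not None:
        for contig, s, e in regions.merged().intervals:
            region_map.setdefault(contig, []).append((s, e))
    any_c = False
    for contig, seq in genome.sequences.items():
        idx = sequence_to_indices(seq)
        cpos = np.nonzero(idx == 1)[0]
        if cpos.size == 0:
            track[contig] = (cpos, np.zeros(0))
            continue
        any_c = True
        vals = np.zeros(cpos.size)
        if regions is None:
            inside = np.ones(cpos.size, dtype=bool)
        else:
            inside = np.zeros(cpos.size, dtype=bool)
            for s, e in region_map.get(contig, []):
                inside |= (cpos >= s) & (cpos < e)
        vals[inside] = np.clip(
            rng.normal(mean_level, sd, size=int(inside.sum())), 0.0, 100.0
        )
        track[contig] = (cpos, vals)
    if not any_c:
        import warnings

        warnings.warn("genome contains no cytosine; methylation track is empty")
    return track


def two_condition_methylation(
    genome: GenomeSequence, seed: int, mean_level: float = 75.0
) -> tuple[
    dict[str, tuple[np.ndarray, np.ndarray]], dict[str, tuple[np.ndarray, np.ndarray]]
]:
    """Two methylation tracks whose regional layout populates all four
    two-condition groups (A-only, B-only, both, none): each contig is split
    into quarters methylated in A only, B only, both, and neither."""
    a_regions, b_regions = [], []
    for contig, seq in genome.sequences.items():
        L = len(seq)
        q = L // 4
        a_regions += [(contig, 0, q), (contig, 2 * q, 3 * q)]
        b_regions += [(contig, q, 2 * q), (contig, 2 * q, 3 * q)]
    track_a = simulate_methylation(
        genome, seed + 101, IntervalSet("cond_a", a_regions), mean_level
    )
    track_b = simulate_methylation(
        genome, seed + 202, IntervalSet("cond_b", b_regions), mean_level
    )
    return track_a, track_b


def sites_to_fragments(
    sites: Sequence[InsertionSite],
    seed: int,
    min_length: int = 60,
    max_length: int = 250,
    contig_lengths: dict[str, int] | None = None,
) -> list[Fragment]:
    """Expand each insertion event into the two fragments flanking its
    9-bp duplication (left fragment ends at pos+5, right starts at pos-4),
    with seeded random outer lengths, truncated at contig bounds when
    ``contig_lengths`` is given.  Paired-fragment site recovery on the
    output reproduces the input positions exactly."""
    rng = _child_seed(seed, 4)
    frags: list[Fragment] = []
    for site in sites:
        limit = contig_lengths.get(site.contig) if contig_lengths else None
        for _ in range(site.count):
            left_len = int(rng.integers(min_length, max_length + 1))
            right_len = int(rng.integers(min_length, max_length + 1))
            left_start = max(0, site.pos + 5 - left_len)
            right_end = site.pos - 4 + right_len
            if limit is not None:
                right_end = min(right_end, limit)
            frags.append(Fragment(site.contig, left_start, site.pos + 5))
            frags.append(Fragment(site.contig, site.pos - 4, right_end))
    frags.sort(key=lambda f: (f.contig, f.start, f.end))
    return frags


def methylation_to_bedgraph_rows(
    track: dict[str, tuple[np.ndarray, np.ndarray]],
) -> list[tuple[str, int, int, float]]:
    rows = []
    for contig in sorted(track):
        pos, vals = track[contig]
        rows.extend(
            (contig, int(p), int(p) + 1, float(v)) for p, v in zip(pos, vals)
        )
    return rows


def bedgraph_rows_to_track(
    rows: Sequence[tuple[str, int, int, float]],
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_contig: dict[str, list[tuple[int, float]]] = {}
    for contig, start, _end, value in rows:
        by_contig.setdefault(contig, []).append((start, value))
    return {
        contig: (
            np.array([p for p, _ in sorted(vals)], dtype=np.int64),
            np.array([v for _, v in sorted(vals)]),
        )
        for contig, vals in by_contig.items()
    }


def emit_dataset(
    config: SimulationConfig,
    outdir: str | Path,
    with_methylation: bool = False,
) -> dict[str, Path]:
    """Generate and write a full synthetic dataset: FASTA genome, BED6
    sites, fragment BED, optional methylation bedGraph, and a truth JSON
    with all planted parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(config)
    meth = None
    paths: dict[str, Path] = {}
    if with_methylation or config.methylation_effect != 0.0:
        meth = simulate_methylation(
            genome, config.seed, _default_methylation_regions(genome)
        )
        paths["methylation"] = outdir / "methylation.bedGraph"
        write_bedgraph(methylation_to_bedgraph_rows(meth), paths["methylation"])
    sites, truth = simulate_insertions(genome, config, meth)
    lengths = {c: len(s) for c, s in genome.sequences.items()}
    fragments = sites_to_fragments(sites, config.seed, contig_lengths=lengths)

    paths["genome"] = outdir / "genome.fa"
    write_fasta(genome, paths["genome"])
    paths["sites"] = outdir / "sites.bed"
    write_insertion_track(sites, paths["sites"], "BED")
    paths["fragments"] = outdir / "fragments.bed"
    write_fragments_bed(fragments, paths["fragments"])

    truth_record = {
        "genome_length": config.genome_length,
        "base_composition": list(config.base_composition),
        "motif_weight": config.motif_weight,
        "planted_pwm": (
            config.planted_pwm.probs.tolist() if config.planted_pwm else None
        ),
        "dinuc_weights": (
            config.dinuc_weights.tolist() if config.dinuc_weights is not None else None
        ),
        "shape_weight": config.shape_weight,
        "methylation_effect": config.methylation_effect,
        "n_insertions": config.n_insertions,
        "seed": config.seed,
        "n_distinct_sites": len(sites),
    }
    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(json.dumps(truth_record, indent=2, sort_keys=True))
    return paths


def _default_methylation_regions(genome: GenomeSequence) -> IntervalSet:
    ivs = [
        (contig, 0, len(seq) // 2) for contig, seq in genome.sequences.items()
    ]
    return IntervalSet("methylated", ivs)


def consensus_pwm(consensus: str, strength: float = 0.9) -> PWM:
    """Helper: a PWM concentrated on a consensus sequence (probability
    ``strength`` on the consensus base, rest spread evenly)."""
    idx = sequence_to_indices(consensus)
    if (idx < 0).any():
        raise ValueError("consensus must be ACGT only")
    probs = np.full((4, idx.size), (1.0 - strength) / 3.0)
    probs[idx, np.arange(idx.size)] = strength
    return PWM(probs, pseudocount=0.5)
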