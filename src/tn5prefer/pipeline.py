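"""End-to-end synthetic demonstration pipeline and run configuration.

Runs every stage in dependency order on one generated dataset: simulate ->
fragments-to-sites -> feature enrichment -> motif (build/scan/usage) ->
classification -> two-condition methylation -> bias correction.  All
randomness flows from the config seed, every output is a text table, and a
provenance record (config, seeds, package version) accompanies the run, so
reruns with the same seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

import tn5prefer
from tn5prefer import correction, enrichment, methylation, model, motif, synthetic
from tn5prefer.core_io import (
    IntervalSet,
    fragments_to_sites,
    merge_strands,
    read_fragments_bed,
    write_bedgraph,
    write_insertion_track,
)
from tn5prefer.encoding import assemble_matrix, default_shape_tables
from tn5prefer.enrichment import results_to_frame


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration; stage defaults follow the analysis protocol
    (51-bp feature window, 19-bp motif window, q < 0.001 motif threshold,
    FDR < 0.001 enrichment threshold, 10-fold CV, 70/30 split, k = 19)."""

    seed: int = 1
    genome_length: int = 400_000
    n_insertions: int = 40_000
    motif_consensus: str = "ACAGTGGTT"
    motif_strength: float = 0.9
    motif_weight: float = 0.7
    n_planted_motifs: int = 12_000
    methylation_effect: float = 1.0
    window: int = 51
    motif_window: int = 19
    subsample: int = 500_000
    n_train: int = 2_000
    folds: int = 10
    fdr: float = 0.001
    q_threshold: float = 0.001
    k: int = 7
    split: float = 0.7

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if not (0.0 < self.split < 1.0):
            raise ValueError("split must be in (0, 1)")


def _write_tsv(frame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict[str, Path]:
    """Execute all stages; returns the map of written artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    # --- simulate ---------------------------------------------------------
    sim = synthetic.SimulationConfig(
        genome_length=config.genome_length,
        planted_pwm=synthetic.consensus_pwm(
            config.motif_consensus, config.motif_strength
        ),
        motif_weight=config.motif_weight,
        n_planted_motifs=config.n_planted_motifs,
        methylation_effect=config.methylation_effect,
        n_insertions=config.n_insertions,
        seed=config.seed,
    )
    simdir = outdir / "simulate"
    paths.update(synthetic.emit_dataset(sim, simdir, with_methylation=True))
    genome = synthetic.simulate_genome(sim)
    meth = synthetic.simulate_methylation(
        genome, sim.seed, synthetic._default_methylation_regions(genome)
    )
    _sites, truth = synthetic.simulate_insertions(genome, sim, meth)

    # --- fragments -> sites ----------------------------------------------
    fragments = read_fragments_bed(paths["fragments"])
    shifted, n_rejected = fragments_to_sites(fragments)
    sites = merge_strands(shifted)
    paths["shifted_sites"] = outdir / "sites.shifted.bed"
    write_insertion_track(sites, paths["shifted_sites"], "BED")
    # high-confidence events: both sides of one 9-bp duplication sequenced
    paired = motif.paired_fragment_sites(fragments)
    paths["paired_sites"] = outdir / "sites.paired.bed"
    write_insertion_track(paired, paths["paired_sites"], "BED")

    # --- enrichment -------------------------------------------------------
    features = _propensity_features(truth, tile=1_000)
    enr = enrichment.feature_enrichment(features, sites, genome, fdr=config.fdr)
    paths["enrichment"] = outdir / "enrichment.tsv"
    _write_tsv(results_to_frame(enr), paths["enrichment"])

    # --- motif ------------------------------------------------------------
    sub = motif.subsample_sites(paired, config.subsample, config.seed)
    pwm = motif.build_pwm(sub, genome, window=config.motif_window)
    paths["pwm"] = outdir / "tn5_motif.meme"
    pwm.write_meme(paths["pwm"])
    core = motif.build_pwm(sub, genome, window=9)
    hits = motif.scan_pwm(core, genome, q_threshold=config.q_threshold)
    paths["hits"] = outdir / "motif_hits.bed"
    motif.write_hits_bed(hits, paths["hits"])
    usage = motif.usage_summary(sites, hits)
    paths["usage"] = outdir / "motif_usage.tsv"
    with paths["usage"].open("w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"frac_insert_inside\t{usage.frac_insert_inside:.6g}\n")
        fh.write(f"frac_insert_outside\t{usage.frac_insert_outside:.6g}\n")
        fh.write(f"frac_motif_used\t{_fmt(usage.frac_motif_used)}\n")
        fh.write(f"frac_motif_unused\t{_fmt(usage.frac_motif_unused)}\n")

    # --- classification ---------------------------------------------------
    from tn5prefer.encoding import sample_control_sites

    n_train = min(config.n_train, len(paired))
    train_sites = motif.subsample_sites(paired, n_train, config.seed + 7)
    controls = sample_control_sites(
        genome, len(train_sites), config.seed + 8, window=config.window
    )
    wide_pwm = motif.build_pwm(
        train_sites, genome, window=config.window, min_windows=50
    )
    tables = default_shape_tables()
    matrices = {
        "motif": assemble_matrix(
            train_sites, controls, genome, ["motif"], pwm=wide_pwm,
            window=config.window,
        ),
        "motif_shuffled_seqs": assemble_matrix(
            train_sites, controls, genome, ["motif_shuffled"], pwm=wide_pwm,
            window=config.window, shuffle_seed=config.seed + 9,
        ),
        "dinucleotide": assemble_matrix(
            train_sites, controls, genome, ["kmer2"], window=config.window
        ),
    }
    fits = model.compare_vector_sets(
        matrices, folds=config.folds, seed=config.seed, n_lambda=12
    )
    paths["model"] = outdir / "model_accuracy.tsv"
    with paths["model"].open("w") as fh:
        fh.write("vector_set\tcv_accuracy\tlambda\n")
        for name, fit in fits.items():
            fh.write(f"{name}\t{fit.cv_accuracy:.6g}\t{fit.lambda_:.6g}\n")

    # --- methylation ------------------------------------------------------
    track_a, track_b = synthetic.two_condition_methylation(genome, config.seed)
    sim_b = dataclasses.replace(sim, seed=config.seed + 50)
    sites_a, _ = synthetic.simulate_insertions(genome, sim, track_a)
    sites_b, _ = synthetic.simulate_insertions(genome, sim_b, track_b)
    bins = methylation.classify_groups(
        methylation.tile_and_annotate(genome, track_a, track_b, sites_a, sites_b)
    )
    profile = methylation.ninemer_profile(bins)
    paths["ninemers"] = outdir / "ninemer_profile.tsv"
    _write_tsv(profile, paths["ninemers"])
    levels = methylation.stratify_levels(bins, "a")
    paths["levels"] = outdir / "methylation_levels.tsv"
    _write_tsv(levels, paths["levels"])

    # --- correction -------------------------------------------------------
    bias = correction.build_bias_model(sites, genome, k=config.k)
    corrected, n_flagged = correction.correct_signal(sites, bias, genome)
    paths["corrected"] = outdir / "corrected.bedGraph"
    write_bedgraph(corrected, paths["corrected"])

    # --- provenance -------------------------------------------------------
    paths["provenance"] = outdir / "provenance.json"
    paths["provenance"].write_text(
        json.dumps(
            {
                "package": "tn5prefer",
                "version": tn5prefer.__version__,
                "config": dataclasses.asdict(config),
                "n_fragments": len(fragments),
                "n_rejected_fragments": n_rejected,
                "n_sites": len(sites),
                "n_motif_hits": len(hits),
                "n_flagged_positions": n_flagged,
            },
            indent=2,
            sort_keys=True,
        )
    )
    return paths


def _fmt(value: float | None) -> str:
    return "NA" if value is None else f"{value:.6g}"


def _propensity_features(
    truth: synthetic.SimulationTruth, tile: int = 1_000
) -> list[IntervalSet]:
    """Demo annotation: tiles in the top propensity decile vs the rest.

    Stands in for real feature annotations (promoters, repeats, ...) so the
    enrichment stage has a planted positive and a planted neutral set.
    """
    hot, cold = [], []
    for contig, prop in truth.propensity.items():
        n_tiles = prop.size // tile
        if n_tiles < 2:
            continue
        mass = prop[: n_tiles * tile].reshape(n_tiles, tile).sum(axis=1)
        cut = np.quantile(mass, 0.9)
        for t in range(n_tiles):
            (hot if mass[t] >= cut else cold).append((contig, t * tile, (t + 1) * tile))
    return [IntervalSet("high_propensity", hot), IntervalSet("background", cold)]
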