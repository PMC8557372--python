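"""Observed/expected insertion enrichment across genomic features.

For each annotation feature the expected insertion count is

    E = merged feature length * (total sites / mappable genome size)

and the observed count O is tallied directly inside the (merged) feature
intervals.  Preference is reported as log2(O/E), tested by the two-cell
(inside/outside) chi-square goodness of fit with one degree of freedom,
and controlled across the feature list by Benjamini-Hochberg FDR.
Per-sample log2(O/E) rows can be assembled into a matrix with
complete-linkage hierarchical clustering of samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import chi2 as chi2_dist

from tn5prefer.core_io import GenomeSequence, InsertionSite, IntervalSet, sites_to_arrays
from tn5prefer.motif import benjamini_hochberg


@dataclass
class EnrichmentResult:
    feature: str
    observed: int
    expected: float
    log2_oe: float
    chi2: float
    p: float
    q: float
    significant: bool
    testable: bool = True


def expected_insertions(
    feature: IntervalSet, total_sites: int, mappable_size: int
) -> float:
    """E = merged feature length x (total sites / mappable size)."""
    if mappable_size <= 0:
        raise ValueError("mappable_size must be positive")
    length = feature.total_length
    if length > mappable_size:
        raise ValueError("feature length exceeds mappable genome size")
    return length * total_sites / mappable_size


def observed_insertions(feature: IntervalSet, sites: Sequence[InsertionSite]) -> int:
    """Strand-merged site counts falling inside the merged feature
    intervals (half-open: start <= pos < end)."""
    arrays = sites_to_arrays(sites)
    total = 0
    for contig, start, end in feature.merged().intervals:
        if contig not in arrays:
            continue
        positions, counts = arrays[contig]
        lo = np.searchsorted(positions, start, side="left")
        hi = np.searchsorted(positions, end, side="left")
        total += int(counts[lo:hi].sum())
    return total


def _gof_chi2(o: float, e: float, total: float, yates: bool = False) -> float:
    """Two-cell goodness-of-fit statistic on (inside, outside) counts."""
    o_out, e_out = total - o, total - e
    if yates:
        return (abs(o - e) - 0.5) ** 2 / e + (abs(o_out - e_out) - 0.5) ** 2 / e_out
    return (o - e) ** 2 / e + (o_out - e_out) ** 2 / e_out


def feature_enrichment(
    features: Sequence[IntervalSet],
    sites: Sequence[InsertionSite],
    genome: GenomeSequence,
    fdr: float = 0.001,
    yates: bool = False,
) -> list[EnrichmentResult]:
    """Per-feature O, E, log2(O/E), chi-square GOF p and BH q.

    FDR control is applied within this feature list (one sample).  Features
    with E = 0 or E = total are reported untestable (p absent as NaN).
    """
    total = sum(s.count for s in sites)
    if total == 0:
        raise ValueError("no insertion sites supplied")
    results: list[EnrichmentResult] = []
    pvals: list[float] = []
    testable_idx: list[int] = []
    for i, feature in enumerate(features):
        e = expected_insertions(feature, total, genome.mappable_size)
        o = observed_insertions(feature, sites)
        if e <= 0 or e >= total:
            results.append(
                EnrichmentResult(feature.name, o, e, math.nan, math.nan, math.nan,
                                 math.nan, False, testable=False)
            )
            continue
        log2_oe = math.log2(o / e) if o > 0 else -math.inf
        stat = _gof_chi2(o, e, total, yates)
        p = float(chi2_dist.sf(stat, df=1)) if stat > 0 else 1.0
        results.append(
            EnrichmentResult(feature.name, o, e, log2_oe, stat, p, math.nan, False)
        )
        pvals.append(p)
        testable_idx.append(i)
    if pvals:
        qvals = benjamini_hochberg(np.array(pvals))
        for idx, q in zip(testable_idx, qvals):
            results[idx].q = float(q)
            results[idx].significant = bool(q < fdr)
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "observed": [r.observed for r in results],
            "expected": [r.expected for r in results],
            "log2_oe": [r.log2_oe for r in results],
            "chi2": [r.chi2 for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "significant": [r.significant for r in results],
        }
    )


def enrichment_matrix(
    per_sample: dict[str, Sequence[EnrichmentResult]],
    mask_nonsignificant: bool = True,
) -> tuple[pd.DataFrame, list[str], np.ndarray | None]:
    """Sample x feature log2(O/E) matrix plus a complete-linkage sample order.

    Nonsignificant cells are masked to NaN in the returned matrix (the
    clustering runs on the unmasked values).  With a single sample the
    matrix is returned without a dendrogram.
    """
    samples = list(per_sample)
    features = [r.feature for r in next(iter(per_sample.values()))]
    raw = np.full((len(samples), len(features)), np.nan)
    masked = raw.copy()
    for i, sample in enumerate(samples):
        for j, r in enumerate(per_sample[sample]):
            raw[i, j] = r.log2_oe
            masked[i, j] = r.log2_oe if (r.significant or not mask_nonsignificant) else np.nan
    frame = pd.DataFrame(masked, index=samples, columns=features)
    if len(samples) < 2:
        return frame, samples, None
    clean = np.nan_to_num(raw, neginf=-10.0, posinf=10.0)
    Z = linkage(clean, method="complete", metric="euclidean")
    order = [samples[i] for i in leaves_list(Z)]
    return frame, order, Z
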