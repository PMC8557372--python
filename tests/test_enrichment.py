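"""Observed/expected statistics, chi-square GOF, BH FDR, clustering."""

import math

import numpy as np
import pytest
from scipy.stats import chi2 as chi2_dist

from tn5prefer.core_io import GenomeSequence, InsertionSite, IntervalSet
from tn5prefer import enrichment, synthetic
from tn5prefer.motif import benjamini_hochberg


def _genome(length=1_000):
    return GenomeSequence({"c1": "A" * length})


class TestExpected:
    def test_formula(self):
        feature = IntervalSet("f", [("c1", 0, 100)])
        assert enrichment.expected_insertions(feature, 100, 1_000) == 10.0

    def test_whole_genome_conserves_total(self):
        feature = IntervalSet("f", [("c1", 0, 1_000)])
        assert enrichment.expected_insertions(feature, 250, 1_000) == 250.0

    def test_overlaps_merged_before_measuring(self):
        feature = IntervalSet("f", [("c1", 0, 50), ("c1", 25, 75)])
        assert enrichment.expected_insertions(feature, 100, 1_000) == 7.5


class TestObserved:
    def test_half_open_boundaries(self):
        feature = IntervalSet("f", [("c1", 10, 11)])
        assert enrichment.observed_insertions(feature, [InsertionSite("c1", 10)]) == 1
        assert enrichment.observed_insertions(feature, [InsertionSite("c1", 11)]) == 0

    def test_count_semantics(self):
        feature = IntervalSet("f", [("c1", 0, 20)])
        sites = [InsertionSite("c1", 5, "+", 3)]
        assert enrichment.observed_insertions(feature, sites) == 3


class TestChiSquare:
    def test_worked_example_against_sf_oracle(self):
        """O=20, E=10, T=100: chi2 = 100/10 + 100/90, p from the chi2(1)
        survival function."""
        genome = _genome()
        sites = [InsertionSite("c1", i, "+", 1) for i in range(100)]
        feature = IntervalSet("f", [("c1", 0, 100)])  # E = 10
        # place 20 of the 100 sites inside the feature
        sites = [InsertionSite("c1", i) for i in range(20)] + [
            InsertionSite("c1", 200 + i) for i in range(80)
        ]
        (res,) = enrichment.feature_enrichment([feature], sites, genome, fdr=0.001)
        expected_chi2 = (20 - 10) ** 2 / 10 + (80 - 90) ** 2 / 90
        assert res.chi2 == pytest.approx(expected_chi2, rel=1e-12)
        assert res.log2_oe == pytest.approx(1.0)
        assert res.p == pytest.approx(float(chi2_dist.sf(expected_chi2, 1)), rel=1e-12)
        assert res.p == pytest.approx(8.54e-4, rel=0.01)

    def test_null_identity(self):
        genome = _genome()
        sites = [InsertionSite("c1", i) for i in range(0, 1000, 10)]  # 100 sites
        feature = IntervalSet("f", [("c1", 0, 100)])  # E = 10, O = 10
        (res,) = enrichment.feature_enrichment([feature], sites, genome)
        assert res.chi2 == 0 and res.p == 1.0 and res.log2_oe == 0.0

    def test_doubling_counts_preserves_log2oe_increases_chi2(self):
        genome = _genome()
        feature = IntervalSet("f", [("c1", 0, 100)])
        sites1 = [InsertionSite("c1", i) for i in range(20)] + [
            InsertionSite("c1", 200 + i) for i in range(80)
        ]
        sites2 = [InsertionSite(s.contig, s.pos, s.strand, 2) for s in sites1]
        (r1,) = enrichment.feature_enrichment([feature], sites1, genome)
        (r2,) = enrichment.feature_enrichment([feature], sites2, genome)
        assert r2.log2_oe == pytest.approx(r1.log2_oe, abs=1e-12)
        assert r2.chi2 >= r1.chi2


class TestBenjaminiHochberg:
    def test_hand_worked_stepup(self):
        q = benjamini_hochberg(np.array([0.01, 0.02, 0.03]))
        assert q == pytest.approx([0.03, 0.03, 0.03])

    def test_monotone_in_p(self):
        p = np.array([0.001, 0.5, 0.04, 0.2])
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestPartitionAndNull:
    def test_partition_conserves_totals(self):
        genome = _genome(1_000)
        sites = [InsertionSite("c1", i, "+", 1 + i % 3) for i in range(0, 1000, 7)]
        total = sum(s.count for s in sites)
        parts = [
            IntervalSet("a", [("c1", 0, 300)]),
            IntervalSet("b", [("c1", 300, 700)]),
            IntervalSet("c", [("c1", 700, 1000)]),
        ]
        results = enrichment.feature_enrichment(parts, sites, genome)
        assert sum(r.observed for r in results) == total
        assert sum(r.expected for r in results) == pytest.approx(total)

    def test_uniform_simulation_rarely_significant(self):
        """Uniformly simulated insertions: >= 99% of feature tests are
        nonsignificant at FDR < 0.001 (10 seeds x 20 features)."""
        n_sig = n_tests = 0
        for seed in range(10):
            cfg = synthetic.SimulationConfig(
                genome_length=20_000, n_insertions=5_000, seed=seed
            )
            genome = synthetic.simulate_genome(cfg)
            sites, _ = synthetic.simulate_insertions(genome, cfg)
            features = [
                IntervalSet(f"f{i}", [("chr1", i * 1000, (i + 1) * 1000)])
                for i in range(20)
            ]
            for r in enrichment.feature_enrichment(features, sites, genome):
                n_tests += 1
                n_sig += r.significant
        assert n_sig / n_tests <= 0.01


class TestClustering:
    @staticmethod
    def _naive_complete_linkage(rows):
        """Brute-force complete linkage on Euclidean distances."""
        clusters = [[i] for i in range(len(rows))]
        heights = []
        while len(clusters) > 1:
            best = (None, None, math.inf)
            for i in range(len(clusters)):
                for j in range(i + 1, len(clusters)):
                    d = max(
                        np.linalg.norm(rows[a] - rows[b])
                        for a in clusters[i]
                        for b in clusters[j]
                    )
                    if d < best[2]:
                        best = (i, j, d)
            i, j, d = best
            heights.append(d)
            clusters[i] = clusters[i] + clusters[j]
            del clusters[j]
        return heights

    def _results(self, log2_vals, significant=True):
        return [
            enrichment.EnrichmentResult(
                f"f{j}", 0, 1.0, v, 0.0, 0.5, 0.5, significant
            )
            for j, v in enumerate(log2_vals)
        ]

    def test_identical_samples_merge_at_zero(self):
        per_sample = {
            "s1": self._results([1.0, -0.5]),
            "s2": self._results([1.0, -0.5]),
        }
        _, order, Z = enrichment.enrichment_matrix(per_sample)
        assert Z[0, 2] == 0.0

    def test_equal_rows_merge_first(self):
        per_sample = {
            "s1": self._results([1.0, 0.0]),
            "s2": self._results([1.0, 0.0]),
            "s3": self._results([-2.0, 3.0]),
        }
        _, order, Z = enrichment.enrichment_matrix(per_sample)
        assert {int(Z[0, 0]), int(Z[0, 1])} == {0, 1}

    def test_merge_heights_match_naive_oracle(self, rng):
        rows = [rng.normal(size=6) for _ in range(5)]
        per_sample = {f"s{i}": self._results(rows[i]) for i in range(5)}
        _, _, Z = enrichment.enrichment_matrix(per_sample)
        expected = self._naive_complete_linkage(rows)
        assert Z[:, 2] == pytest.approx(expected)

    def test_nonsignificant_cells_masked(self):
        per_sample = {"s1": self._results([1.0, 2.0], significant=False)}
        frame, order, Z = enrichment.enrichment_matrix(per_sample)
        assert Z is None and frame.isna().all().all()
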