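"""PWM building, exact-p scanning, paired fragments, usage taxonomy."""

import itertools

import numpy as np
import pytest

from tn5prefer.core_io import Fragment, GenomeSequence, InsertionSite, shift_fragment
from tn5prefer import motif
from tn5prefer.motif import (
    PWM,
    MotifHit,
    build_pwm,
    exact_score_distribution,
    paired_fragment_sites,
    scan_pwm,
    sequence_to_indices,
    subsample_sites,
    usage_summary,
)


class TestPairedFragments:
    def test_exact_nine_bp_overlap_yields_center(self):
        left, right = Fragment("c1", 100, 200), Fragment("c1", 191, 300)
        (site,) = paired_fragment_sites([left, right])
        assert site.pos == 195
        # agrees with both shifted ends of the duplication
        assert site.pos == shift_fragment(right)[0].pos
        assert site.pos == shift_fragment(left)[1].pos

    def test_wrong_overlap_yields_nothing(self):
        assert paired_fragment_sites([Fragment("c1", 100, 200), Fragment("c1", 192, 300)]) == []
        assert paired_fragment_sites([Fragment("c1", 100, 200), Fragment("c1", 190, 300)]) == []

    def test_chained_fragments_give_one_site_per_junction(self):
        frags = [
            Fragment("c1", 0, 100),
            Fragment("c1", 91, 200),
            Fragment("c1", 191, 300),
        ]
        sites = paired_fragment_sites(frags)
        assert [s.pos for s in sites] == [95, 195]

    def test_duplicate_events_merged_to_counts(self):
        frags = [Fragment("c1", 0, 100)] * 2 + [Fragment("c1", 91, 200)]
        (site,) = paired_fragment_sites(frags)
        assert site.count == 2


class TestSubsample:
    def test_identity_when_n_is_all(self):
        sites = [InsertionSite("c1", i) for i in range(10)]
        assert subsample_sites(sites, 10, 1) == sites

    def test_deterministic(self):
        sites = [InsertionSite("c1", i) for i in range(100)]
        assert subsample_sites(sites, 10, 42) == subsample_sites(sites, 10, 42)

    def test_oversample_warns_undersample_errors(self):
        sites = [InsertionSite("c1", i) for i in range(5)]
        with pytest.warns(UserWarning):
            assert len(subsample_sites(sites, 6, 1)) == 5
        with pytest.raises(ValueError):
            subsample_sites(sites, 0, 1)


class TestBuildPwm:
    def test_unit_columns_from_identical_windows(self):
        genome = GenomeSequence({"c1": "TACGT" * 20})
        sites = [InsertionSite("c1", p) for p in range(2, 99, 5)]  # center of ACG
        pwm = build_pwm(sites, genome, window=3, pseudocount=0.0, min_windows=1)
        assert pwm.consensus == "ACG"
        assert pwm.probs.max(axis=0) == pytest.approx([1.0, 1.0, 1.0])

    def test_pseudocount_only_limit_is_uniform(self):
        genome = GenomeSequence({"c1": "ACGTACGTACGT"})
        # one window, huge pseudocount: columns approach uniform
        pwm = build_pwm(
            [InsertionSite("c1", 5)], genome, window=3, pseudocount=1e9, min_windows=1
        )
        assert pwm.probs == pytest.approx(np.full((4, 3), 0.25), abs=1e-6)

    def test_too_few_windows_raises_with_reasons(self):
        genome = GenomeSequence({"c1": "ACGTNNNNACGT"})
        with pytest.raises(ValueError, match="usable windows"):
            build_pwm([InsertionSite("c1", 5)], genome, window=5, min_windows=10)

    def test_order_invariance(self, toy_genome):
        sites = [InsertionSite("chr1", p) for p in range(100, 1100, 10)]
        p1 = build_pwm(sites, toy_genome, window=9)
        p2 = build_pwm(sites[::-1], toy_genome, window=9)
        assert p1.probs == pytest.approx(p2.probs)

    def test_minus_strand_contributes_reverse_complement(self):
        genome = GenomeSequence({"c1": "AAACGTAAA"})
        plus = build_pwm(
            [InsertionSite("c1", 4, "+")], genome, window=3, pseudocount=0, min_windows=1
        )
        minus = build_pwm(
            [InsertionSite("c1", 4, "-")], genome, window=3, pseudocount=0, min_windows=1
        )
        assert plus.consensus == "CGT"
        assert minus.consensus == "ACG"  # revcomp of CGT


class TestMemeFormat:
    def test_round_trip(self, tmp_path):
        probs = np.array([[0.7, 0.1], [0.1, 0.2], [0.1, 0.3], [0.1, 0.4]])
        pwm = PWM(probs, np.array([0.3, 0.2, 0.2, 0.3]))
        path = tmp_path / "m.meme"
        pwm.write_meme(path)
        back = PWM.read_meme(path)
        assert back.probs == pytest.approx(pwm.probs, abs=1e-5)
        assert back.background == pytest.approx(pwm.background, abs=1e-5)


class TestExactScan:
    def test_width_one_pvalue_is_letter_mass(self):
        # log-odds scores (2,1,0,0) with uniform background
        probs = np.array([[0.25 * 4], [0.25 * 2], [0.25], [0.25]])
        probs = probs / probs.sum()
        pwm = PWM(probs)
        lo = pwm.log_odds
        delta = (lo.max() - lo.min()) * 1e-4
        disc, surv = exact_score_distribution(lo, pwm.background, delta)
        top = disc[:, 0].max()
        assert surv[top] == pytest.approx(0.25, abs=1e-9)

    @pytest.mark.parametrize("width", [2, 4])
    def test_dp_matches_exhaustive_enumeration(self, rng, width):
        probs = rng.dirichlet(np.ones(4), size=width).T
        bg = rng.dirichlet(np.ones(4) * 5)
        pwm = PWM(probs, bg, pseudocount=1.0)
        lo = pwm.log_odds
        delta = max(lo.max() - lo.min(), 1e-12) * 1e-3
        disc, surv = exact_score_distribution(lo, bg, delta)
        # enumerate all 4^w sequences at the same discretization
        for letters in itertools.product(range(4), repeat=width):
            score = sum(disc[b, j] for j, b in enumerate(letters))
            mass = 0.0
            for other in itertools.product(range(4), repeat=width):
                s2 = sum(disc[b, j] for j, b in enumerate(other))
                if s2 >= score:
                    mass += np.prod([bg[b] for b in other])
            assert surv[score] == pytest.approx(mass, rel=1e-9, abs=1e-12)

    def test_distribution_sums_to_one(self, rng):
        probs = rng.dirichlet(np.ones(4), size=6).T
        pwm = PWM(probs, pseudocount=1.0)
        lo = pwm.log_odds
        delta = (lo.max() - lo.min()) * 1e-4
        _, surv = exact_score_distribution(lo, pwm.background, delta)
        assert surv[0] == pytest.approx(1.0, abs=1e-9)

    def test_pvalues_monotone_in_score(self, rng):
        probs = rng.dirichlet(np.ones(4), size=5).T
        pwm = PWM(probs, pseudocount=1.0)
        lo = pwm.log_odds
        delta = (lo.max() - lo.min()) * 1e-4
        _, surv = exact_score_distribution(lo, pwm.background, delta)
        assert (np.diff(surv) <= 1e-15).all()

    def test_consensus_attains_max_score(self):
        pwm = PWM(np.array([[0.9, 0.05], [0.05, 0.9], [0.025, 0.025], [0.025, 0.025]]))
        assert pwm.score(pwm.consensus) == pytest.approx(pwm.max_score())

    def test_width_bound_enforced(self, toy_genome):
        pwm = PWM(np.full((4, 31), 0.25))
        with pytest.raises(ValueError, match="grain"):
            scan_pwm(pwm, toy_genome)

    def test_scan_finds_planted_consensus_run(self):
        # genome: consensus repeated amid A-runs; a sharp PWM must hit it
        consensus = "CGTACG"
        seq = ("A" * 30 + consensus) * 60 + "A" * 30
        genome = GenomeSequence({"c1": seq})
        idx = sequence_to_indices(consensus)
        probs = np.full((4, 6), 0.01 / 3)
        probs[idx, np.arange(6)] = 0.99
        pwm = PWM(probs, np.array([0.7, 0.1, 0.1, 0.1]))
        hits = scan_pwm(pwm, genome, q_threshold=0.05)
        starts = {h.start for h in hits if h.strand == "+"}
        assert {30 + 36 * k for k in range(60)} <= starts


class TestUsage:
    def test_half_open_membership(self):
        hits = [MotifHit("c1", 10, 19, "+", 1.0, 1e-5, 1e-4)]
        inside = usage_summary([InsertionSite("c1", 10)], hits)
        outside = usage_summary([InsertionSite("c1", 19)], hits)
        assert inside.frac_insert_inside == 1.0 and inside.frac_motif_used == 1.0
        assert outside.frac_insert_inside == 0.0 and outside.frac_motif_used == 0.0

    def test_fractions_complementary(self):
        hits = [
            MotifHit("c1", 0, 9, "+", 1.0, 1e-5, 1e-4),
            MotifHit("c1", 100, 109, "+", 1.0, 1e-5, 1e-4),
        ]
        sites = [InsertionSite("c1", 4), InsertionSite("c1", 50)]
        s = usage_summary(sites, hits)
        assert s.frac_insert_inside + s.frac_insert_outside == pytest.approx(1.0)
        assert s.frac_motif_used + s.frac_motif_unused == pytest.approx(1.0)

    def test_empty_hits_leave_usage_undefined(self):
        s = usage_summary([InsertionSite("c1", 4)], [])
        assert s.frac_insert_inside == 0.0 and s.frac_motif_used is None
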