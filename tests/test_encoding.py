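"""Shape lookup, PWM vectors, k-mer one-hots, matrix assembly."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import random_window
from tn5prefer.core_io import GenomeSequence, InsertionSite
from tn5prefer.encoding import (
    FeatureMatrix,
    SHAPE_NAMES,
    ShapeTable,
    assemble_matrix,
    decode_kmer,
    default_shape_tables,
    encode_kmer,
    encode_pwm_vector,
    encode_shape,
    pentamer_index,
    read_shape_tables_tsv,
    sample_control_sites,
    standardize,
    synthetic_shape_table,
    write_shape_tables_tsv,
)
from tn5prefer.motif import PWM


class TestShapeTables:
    def test_fourteen_shapes_with_classes(self):
        tables = default_shape_tables()
        assert len(tables) == 14
        assert tables["MGW"].klass == "intra"
        assert tables["Roll"].klass == "inter"

    def test_single_pentamer_lookup(self):
        table = synthetic_shape_table("MGW")
        v = table.values[pentamer_index("AAAAA")]
        assert encode_shape("AAAAA", table) == pytest.approx([v])

    def test_window_gives_47_values(self):
        table = synthetic_shape_table("ProT")
        seq = "ACGT" * 12 + "ACG"  # 51 bp
        assert encode_shape(seq, table).shape == (47,)

    def test_inter_shape_averages_two_steps(self):
        table = synthetic_shape_table("HelT")
        code = pentamer_index("ACGTA")
        expected = table.values[code].mean()
        assert encode_shape("ACGTA", table)[0] == pytest.approx(expected)

    def test_matches_naive_lookup_oracle(self, rng):
        tables = default_shape_tables()
        for _ in range(50):
            seq = random_window(rng)
            for name in ("MGW", "Roll"):
                table = tables[name]
                naive = [
                    table.center_values()[pentamer_index(seq[i - 2 : i + 3])]
                    for i in range(2, 49)
                ]
                assert encode_shape(seq, table) == pytest.approx(naive)

    def test_shuffle_preserves_multiset_and_is_seeded(self):
        table = synthetic_shape_table("Opening")
        shuffled = table.shuffled(7)
        assert sorted(shuffled.values) == pytest.approx(sorted(table.values))
        assert not np.array_equal(shuffled.values, table.values)
        assert np.array_equal(shuffled.values, table.shuffled(7).values)

    def test_tsv_round_trip(self, tmp_path):
        tables = {n: synthetic_shape_table(n) for n in ("MGW", "HelT")}
        path = tmp_path / "shapes.tsv"
        write_shape_tables_tsv(tables, path)
        back = read_shape_tables_tsv(path)
        for name in tables:
            assert back[name].values == pytest.approx(tables[name].values, abs=1e-5)


class TestPwmVector:
    def test_uniform_pwm_gives_zero_vector(self):
        pwm = PWM(np.full((4, 8), 0.25))
        assert encode_pwm_vector("ACGTACGT", pwm) == pytest.approx(np.zeros(8))

    def test_vector_sum_equals_scan_score(self, rng):
        probs = rng.dirichlet(np.ones(4), size=51).T
        pwm = PWM(probs, pseudocount=1.0)
        seq = random_window(rng)
        assert encode_pwm_vector(seq, pwm).sum() == pytest.approx(pwm.score(seq))

    def test_width_mismatch_raises(self):
        pwm = PWM(np.full((4, 5), 0.25))
        with pytest.raises(ValueError):
            encode_pwm_vector("ACGT", pwm)


class TestKmerOneHot:
    def test_first_block_is_indicator(self):
        vec = encode_kmer("ACG", 1)
        assert vec[:4].tolist() == [1, 0, 0, 0]

    def test_dinucleotide_dimensions(self):
        seq = "ACGT" * 12 + "ACG"
        vec = encode_kmer(seq, 2)
        assert vec.size == 50 * 16 and vec.sum() == 50

    @given(st.integers(1, 3))
    def test_decoding_inverts_encoding(self, k):
        seq = "ACGTTGCATGCA"
        assert decode_kmer(encode_kmer(seq, k), k) == seq


class TestAssembleMatrix:
    @pytest.fixture()
    def setup(self, toy_genome):
        sites = [InsertionSite("chr1", p) for p in range(100, 600, 10)]
        controls = [InsertionSite("chr1", p) for p in range(5_000, 5_500, 10)]
        pwm = PWM(np.full((4, 51), 0.25))
        return toy_genome, sites, controls, pwm

    def test_motif_block_has_window_columns(self, setup):
        genome, sites, controls, pwm = setup
        fm = assemble_matrix(sites, controls, genome, ["motif"], pwm=pwm)
        assert fm.X.shape == (100, 51)
        assert fm.y.sum() == 50

    def test_shape_blocks_additive(self, setup):
        genome, sites, controls, pwm = setup
        fm = assemble_matrix(
            sites, controls, genome, ["motif", "shapes"],
            pwm=pwm, tables=default_shape_tables(),
        )
        assert fm.X.shape[1] == 51 + 14 * 47
        assert len(fm.blocks) == 1 + 14

    def test_standardization_bounds(self, setup, rng):
        genome, sites, controls, _ = setup
        fm = assemble_matrix(
            sites, controls, genome, ["shapes"], tables=default_shape_tables()
        )
        X01, bounds = standardize(fm.X)
        assert X01.min(axis=0) == pytest.approx(np.zeros(fm.X.shape[1]), abs=1e-12)
        assert X01.max(axis=0) == pytest.approx(np.ones(fm.X.shape[1]), abs=1e-12)
        # held-out reuse clips to [0, 1]
        X2, _ = standardize(fm.X + rng.normal(size=fm.X.shape), bounds)
        assert X2.min() >= 0.0 and X2.max() <= 1.0

    def test_zero_variance_feature_maps_to_zero(self):
        X = np.array([[1.0, 5.0], [2.0, 5.0]])
        with pytest.warns(UserWarning, match="zero-variance"):
            X01, _ = standardize(X)
        assert X01[:, 1] == pytest.approx([0.0, 0.0])

    def test_n_windows_dropped(self):
        genome = GenomeSequence({"c1": "ACGT" * 30 + "N" + "ACGT" * 30})
        sites = [InsertionSite("c1", 120), InsertionSite("c1", 60)]
        controls = [InsertionSite("c1", 180)]
        fm = assemble_matrix(sites, controls, genome, ["kmer1"], window=11)
        assert fm.X.shape[0] == 2  # the N-window site is gone

    def test_purity_same_input_same_matrix(self, setup):
        genome, sites, controls, pwm = setup
        fm1 = assemble_matrix(sites, controls, genome, ["kmer2"])
        fm2 = assemble_matrix(sites, controls, genome, ["kmer2"])
        assert np.array_equal(fm1.X, fm2.X)


class TestControls:
    def test_controls_have_valid_windows(self, toy_genome):
        controls = sample_control_sites(toy_genome, 50, seed=3)
        assert len(controls) == 50
        for c in controls:
            assert toy_genome.window(c, 51) is not None

    def test_seeded(self, toy_genome):
        a = sample_control_sites(toy_genome, 20, seed=5)
        b = sample_control_sites(toy_genome, 20, seed=5)
        assert a == b
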