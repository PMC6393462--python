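import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seforge.genomics_io import CoverageTrack, GenomeSequence, GenomicInterval, PWM
from seforge.seq_features import (
    TrapParams,
    gc_fraction,
    kmer_spectrum,
    mean_conservation,
    motif_hit_count,
    repeat_fraction,
    reverse_complement,
    sequence_feature_matrix,
    trap_affinity,
)

SEQ = st.text(alphabet="ACGTacgt", min_size=1, max_size=60)


def random_pwm(rng, length, name="rand"):
    counts = rng.dirichlet(np.ones(4) * 0.5, size=length)
    m = counts + 1e-3
    return PWM(name, m / m.sum(axis=1, keepdims=True))


class TestScalarFeatures:
    @pytest.mark.parametrize(
        "seq,expected", [("GCGC", 1.0), ("ATAT", 0.0), ("ACGTN", 0.5), ("acgt", 0.5)]
    )
    def test_gc_fraction(self, seq, expected):
        assert gc_fraction(seq) == pytest.approx(expected)

    def test_all_n_is_error(self):
        with pytest.raises(ValueError):
            gc_fraction("NNNN")

    @pytest.mark.parametrize(
        "seq,expected", [("acgtACGT", 0.5), ("ACGT", 0.0), ("acgt", 1.0)]
    )
    def test_repeat_fraction(self, seq, expected):
        assert repeat_fraction(seq) == pytest.approx(expected)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(SEQ)
    def test_gc_revcomp_invariant(self, seq):
        if set(seq.upper()) == {"N"}:
            return
        assert gc_fraction(seq) == pytest.approx(gc_fraction(reverse_complement(seq)))
        assert repeat_fraction(seq) == pytest.approx(
            repeat_fraction(reverse_complement(seq))
        )


class TestMeanConservation:
    def test_full_half_empty(self):
        region = GenomicInterval("chr1", 0, 100)
        full = CoverageTrack({"chr1": [(0, 100, 0.8)]})
        half = CoverageTrack({"chr1": [(0, 50, 1.0)]})
        empty = CoverageTrack({})
        assert mean_conservation(full, region) == pytest.approx(0.8)
        assert mean_conservation(half, region) == pytest.approx(0.5)
        assert mean_conservation(empty, region) == 0.0


class TestTrap:
    def test_uniform_pwm_zero_energy(self):
        pwm = PWM("u", np.full((6, 4), 0.25))
        params = TrapParams(both_strands=False)
        n_windows = 5
        seq = "ACGTACGTAT"  # length 10 -> 5 windows of length 6
        r0 = params.r0(6)
        assert trap_affinity(seq, pwm, params) == pytest.approx(
            n_windows * r0 / (1 + r0)
        )

    def test_consensus_single_site(self):
        m = np.full((8, 4), 0.01)
        m[:, 0] = 0.97  # strong A-consensus
        pwm = PWM("a8", m / m.sum(axis=1, keepdims=True))
        params = TrapParams(both_strands=False)
        seq = "G" * 20 + "A" * 8 + "G" * 20
        r0 = params.r0(8)
        affinity = trap_affinity(seq, pwm, params)
        assert affinity == pytest.approx(r0 / (1 + r0), rel=0.05)

    def test_brute_force_oracle(self, rng):
        params = TrapParams()
        for _ in range(20):
            pwm = random_pwm(rng, 6)
            seq = "".join(rng.choice(list("ACGT"), 30))
            expected = 0.0
            r0 = math.exp(params.ln_r0_slope * 6 + params.ln_r0_intercept)
            base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
            for s in (seq, reverse_complement(seq)):
                for i in range(len(s) - 5):
                    e = sum(
                        math.log(pwm.matrix[j].max() / pwm.matrix[j][base_index[s[i + j]]])
                        for j in range(6)
                    ) / params.lam
                    expected += r0 * math.exp(-e) / (1 + r0 * math.exp(-e))
            assert trap_affinity(seq, pwm, params) == pytest.approx(expected, abs=1e-9)

    def test_strand_symmetry(self, rng):
        pwm = random_pwm(rng, 7)
        seq = "".join(rng.choice(list("ACGT"), 40))
        assert trap_affinity(seq, pwm) == pytest.approx(
            trap_affinity(reverse_complement(seq), pwm), abs=1e-9
        )

    def test_n_windows_contribute_zero(self):
        pwm = PWM("u", np.full((4, 4), 0.25))
        params = TrapParams(both_strands=False)
        r0 = params.r0(4)
        # NNNN splits into zero valid windows + 1 valid window (last 4 bases)
        assert trap_affinity("NNNNACGT", pwm, params) == pytest.approx(r0 / (1 + r0))

    def test_short_sequence_is_error(self):
        pwm = PWM("u", np.full((6, 4), 0.25))
        with pytest.raises(ValueError):
            trap_affinity("ACG", pwm)


class TestMotifHitCount:
    def _pwm(self):
        m = np.full((6, 4), 0.02)
        for j, b in enumerate([0, 1, 2, 0, 3, 2]):  # ACGATG consensus
            m[j, b] = 0.94
        return PWM("m", m / m.sum(axis=1, keepdims=True))

    def test_consensus_counted_once(self):
        pwm = self._pwm()
        assert motif_hit_count("TTTTACGATGTTTT", pwm, score_fraction=1.0) == 1

    def test_absent_consensus_zero(self):
        pwm = self._pwm()
        assert motif_hit_count("TTTTTTTTTTTT", pwm, score_fraction=1.0) == 0

    def test_reverse_strand_counted(self):
        pwm = self._pwm()
        seq = "TTTT" + reverse_complement("ACGATG") + "TTTT"
        assert motif_hit_count(seq, pwm, score_fraction=1.0) == 1


class TestKmerSpectrum:
    def test_single_kmer(self):
        assert kmer_spectrum("AAAAA", k=5) == {"AAAAA": 1.0}

    def test_canonical_collapsing(self):
        assert kmer_spectrum("ACGTACGT", k=5) == {"ACGTA": 2.0, "CGTAC": 2.0}

    def test_window_count_conservation(self, rng):
        seq = "".join(rng.choice(list("ACGTN"), 100, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        counts = kmer_spectrum(seq, k=5)
        n_with_n = sum("N" in seq[i : i + 5].upper() for i in range(len(seq) - 4))
        assert sum(counts.values()) == len(seq) - 4 - n_with_n

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.text(alphabet="ACGT", min_size=5, max_size=40))
    def test_revcomp_invariance(self, seq):
        assert kmer_spectrum(seq, k=5) == kmer_spectrum(reverse_complement(seq), k=5)


class TestSequenceFeatureMatrix:
    def test_shape_and_columns(self, rng):
        genome = GenomeSequence({"chr1": "".join(rng.choice(list("ACGTacgt"), 2000))})
        regions = [
            GenomicInterval("chr1", 0, 500, name="a"),
            GenomicInterval("chr1", 600, 1100, name="b"),
            GenomicInterval("chr1", 1200, 1900, name="c"),
        ]
        pwms = [random_pwm(rng, 6, "m6"), random_pwm(rng, 8, "m8")]
        m = sequence_feature_matrix(regions, genome, pwms=pwms)
        assert m.shape == (3, 6)
        assert m.values.loc["a", "size_bp"] == 500
        # each cell equals the scalar op on the extracted sequence
        seq = genome.fetch(regions[1])
        assert m.values.loc["b", "gc"] == pytest.approx(gc_fraction(seq))
        assert m.values.loc["b", "repeat_fraction"] == pytest.approx(repeat_fraction(seq))
        assert m.values.loc["b", f"trap_{pwms[0].motif_id}"] == pytest.approx(
            trap_affinity(seq, pwms[0]), abs=1e-9
        )

    def test_out_of_bounds_region_is_error(self, rng):
        genome = GenomeSequence({"chr1": "ACGT" * 100})
        with pytest.raises(Exception, match="chr1:390-600"):
            sequence_feature_matrix([GenomicInterval("chr1", 390, 600)], genome)
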