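import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zcmm.models import (
    BASE_ORDER,
    ModelBundle,
    ModelError,
    Pwm,
    ZCurve,
    build_pwm,
    build_zcm,
    build_zcmm,
    compare_models,
    cumulative_frequencies,
    inverse_zcurve,
    load_model,
    save_model,
    zcurve_transform,
)
from zcmm.seqio import DnaSequence, SequenceSet
from tests.conftest import random_set

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


def seq(bases: str) -> DnaSequence:
    return DnaSequence("s", bases)


class TestCumulativeFrequencies:
    @pytest.mark.parametrize(
        "bases,expect_a,expect_c",
        [
            ("AAAA", [1, 1, 1, 1], [0, 0, 0, 0]),
            ("AC", [1, 0.5], [0, 0.5]),
        ],
    )
    def test_hand_counts(self, bases, expect_a, expect_c):
        cf = cumulative_frequencies(seq(bases))
        assert np.allclose(cf.a, expect_a)
        assert np.allclose(cf.c, expect_c)

    def test_uniform_composition(self):
        cf = cumulative_frequencies(seq("ACGT"))
        assert np.allclose(cf.freq[:, 3], 0.25)

    @given(dna)
    @settings(max_examples=100, derandomize=True)
    def test_columns_sum_to_one(self, bases):
        cf = cumulative_frequencies(seq(bases))
        assert np.allclose(cf.freq.sum(axis=0), 1.0)
        assert (cf.freq >= 0).all() and (cf.freq <= 1).all()


class TestZCurve:
    def test_pure_a_extreme(self):
        c = zcurve_transform(seq("AAAA"))
        for v in (c.x, c.y, c.z):
            assert np.allclose(v, 1.0)

    def test_ac_hand_value(self):
        c = zcurve_transform(seq("AC"))
        assert (c.x[1], c.y[1], c.z[1]) == (0.0, 1.0, 0.0)

    def test_balanced_composition_annihilates(self):
        c = zcurve_transform(seq("ACGT"))
        assert (c.x[3], c.y[3], c.z[3]) == (0.0, 0.0, 0.0)

    @given(dna)
    @settings(max_examples=200, derandomize=True)
    def test_coordinate_invariants(self, bases):
        c = zcurve_transform(seq(bases))
        cf = cumulative_frequencies(seq(bases))
        for v in (c.x, c.y, c.z):
            assert (np.abs(v) <= 1.0 + 1e-12).all()
        assert np.allclose(c.x + c.y + c.z, 4.0 * cf.a - 1.0)


class TestInverseZCurve:
    @given(dna)
    @settings(max_examples=200, derandomize=True)
    def test_round_trip_identity(self, bases):
        assert inverse_zcurve(zcurve_transform(seq(bases))).bases == bases

    def test_algebraic_inversion_of_pure_a(self):
        c = ZCurve(x=np.ones(2), y=np.ones(2), z=np.ones(2))
        assert inverse_zcurve(c).bases == "AA"

    def test_infeasible_curve_errors(self):
        c = ZCurve(x=np.array([0.5]), y=np.array([0.5]), z=np.array([0.5]))
        with pytest.raises(ModelError):
            inverse_zcurve(c)


class TestBuildZcm:
    def test_singleton_equals_own_curve(self):
        s = seq("ACGTTGCA")
        zcm = build_zcm(SequenceSet((s,)))
        own = zcurve_transform(s)
        assert np.allclose(zcm.curve.x, own.x)
        assert np.allclose(zcm.curve.z, own.z)

    def test_hand_average_aaaa_tttt(self):
        zcm = build_zcm(SequenceSet((seq("AAAA"), DnaSequence("t", "TTTT"))))
        assert np.allclose(zcm.curve.x, 0.0)
        assert np.allclose(zcm.curve.y, 0.0)
        assert np.allclose(zcm.curve.z, 1.0)

    def test_duplication_and_permutation_invariance(self, rng):
        base = random_set(rng, 10, 25)
        doubled = SequenceSet(base.sequences + base.sequences)
        perm = SequenceSet(tuple(base.sequences[i] for i in rng.permutation(10)))
        a, b, c = build_zcm(base), build_zcm(doubled), build_zcm(perm)
        assert np.allclose(a.curve.z, b.curve.z)
        assert np.allclose(a.mean_freqs.freq, c.mean_freqs.freq)


class TestBuildPwm:
    def test_uniform_columns_give_zero_logodds(self):
        s = SequenceSet((seq("ACGT"), DnaSequence("b", "CGTA"),
                         DnaSequence("c", "GTAC"), DnaSequence("d", "TACG")))
        pwm = build_pwm(s, background="uniform", pseudocount=1.0)
        assert np.allclose(pwm.M, 0.0)

    def test_all_a_column_limit(self):
        # m large, pseudocount small: M_A -> log(1/0.25) = log 4
        s = SequenceSet(tuple(DnaSequence(f"s{i}", "A") for i in range(10000)))
        pwm = build_pwm(s, background="uniform", pseudocount=1e-9)
        assert pwm.M[0, 0] == pytest.approx(np.log(4.0), abs=1e-5)

    def test_zero_pseudocount_with_absent_base_errors(self):
        s = SequenceSet((seq("AA"), DnaSequence("b", "AA")))
        with pytest.raises(ModelError, match="pseudocount"):
            build_pwm(s, pseudocount=0.0)

    def test_matched_background_gives_exact_zero(self):
        # every base once per column: q' = b = 0.25 exactly, for any pseudocount
        counts_even = SequenceSet((seq("ACGT"), DnaSequence("b", "CGTA"),
                                   DnaSequence("c", "GTAC"), DnaSequence("d", "TACG")))
        p2 = build_pwm(counts_even, background="uniform", pseudocount=2.5)
        assert (p2.M == 0.0).all()

    def test_log_base_two_rescales(self, rng):
        s = random_set(rng, 12, 8)
        pe = build_pwm(s, log_base="e")
        p2 = build_pwm(s, log_base="2")
        assert np.allclose(p2.M, pe.M / np.log(2.0))


class TestBuildZcmm:
    def _zcm(self):
        return build_zcm(SequenceSet((seq("AAAA"), DnaSequence("t", "TTTT"))))

    def _pwm(self, M):
        return Pwm(M=M, background=np.full(4, 0.25), pseudocount=1.0, log_base="e")

    def test_unit_pwm_reproduces_zcm(self, rng):
        s = random_set(rng, 15, 20)
        zcm = build_zcm(s)
        unit = self._pwm(np.ones((4, 20)))
        zcmm = build_zcmm(zcm, unit)
        assert np.allclose(zcmm.X, zcm.curve.x, atol=1e-12)
        assert np.allclose(zcmm.Y, zcm.curve.y, atol=1e-12)
        assert np.allclose(zcmm.Z, zcm.curve.z, atol=1e-12)

    def test_zero_pwm_annihilates(self):
        zcmm = build_zcmm(self._zcm(), self._pwm(np.zeros((4, 4))))
        assert np.allclose(zcmm.coords(), 0.0)

    def test_hand_weighted_example(self):
        # a=t=0.5 everywhere; M_A=2, M_T=1, M_C=M_G=0
        M = np.vstack([np.full(4, 2.0), np.zeros(4), np.zeros(4), np.ones(4)])
        zcmm = build_zcmm(self._zcm(), self._pwm(M))
        assert np.allclose(zcmm.X, 0.5)
        assert np.allclose(zcmm.Y, 0.5)
        assert np.allclose(zcmm.Z, 1.5)

    def test_length_mismatch_errors(self, rng):
        zcm = build_zcm(random_set(rng, 4, 10))
        with pytest.raises(ModelError, match="mismatch"):
            build_zcmm(zcm, self._pwm(np.ones((4, 12))))


class TestCompareModels:
    def _model(self, rng, n=150, shift=0.0):
        from zcmm.models import ZcmmModel

        base = rng.normal(size=(3, n))
        return (
            lambda arr: __import__("zcmm").models.ZcmmModel(
                X=arr[0], Y=arr[1], Z=arr[2]
            )
        )(base + shift)

    def test_identical_models_p_one(self, rng):
        a = self._model(rng)
        p = compare_models(a, a)
        assert all(v == pytest.approx(1.0) for v in p.values())

    def test_large_shift_detected(self, rng):
        from zcmm.models import ZcmmModel

        a = self._model(rng)
        b = ZcmmModel(X=a.X, Y=a.Y, Z=a.Z + 10.0)
        p = compare_models(a, b)
        assert p["z"] < 0.01 and p["pooled"] < 0.01

    def test_single_position_errors(self):
        from zcmm.models import ZcmmModel

        a = ZcmmModel(X=np.zeros(1), Y=np.zeros(1), Z=np.zeros(1))
        with pytest.raises(ModelError):
            compare_models(a, a)


class TestSerialization:
    def _bundle(self, rng, n=12):
        s = random_set(rng, 10, n)
        zcm = build_zcm(s)
        pwm = build_pwm(s)
        return ModelBundle(zcm, pwm, build_zcmm(zcm, pwm))

    def test_round_trip_bit_exact(self, tmp_path, rng):
        b = self._bundle(rng)
        f = tmp_path / "model.json"
        save_model(b, f)
        b2 = load_model(f)
        assert np.array_equal(b.zcm.mean_freqs.freq, b2.zcm.mean_freqs.freq)
        assert np.array_equal(b.pwm.M, b2.pwm.M)
        assert np.array_equal(b.zcmm.X, b2.zcmm.X)
        assert b.pwm.log_base == b2.pwm.log_base
        assert b.zcm.m == b2.zcm.m

    def test_truncated_file_errors(self, tmp_path, rng):
        f = tmp_path / "model.json"
        save_model(self._bundle(rng), f)
        f.write_text(f.read_text()[: len(f.read_text()) // 2])
        with pytest.raises(ModelError, match="corrupt"):
            load_model(f)

    def test_wrong_format_errors(self, tmp_path):
        f = tmp_path / "not.json"
        f.write_text('{"format": "something-else"}')
        with pytest.raises(ModelError):
            load_model(f)

    def test_length_mismatch_surfaces_downstream(self, tmp_path, rng):
        from zcmm.features import distance_vector
        from tests.conftest import random_seq

        b = self._bundle(rng, n=12)
        f = tmp_path / "model.json"
        save_model(b, f)
        loaded = load_model(f)
        with pytest.raises(ModelError):
            distance_vector(random_seq(rng, 15), loaded.zcmm)
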