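import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from txem import (
    Alignment,
    LengthDistribution,
    ModelParams,
    ProfileErrorModel,
    QualityErrorModel,
    ReadRecord,
    Rspd,
    Transcript,
    TranscriptSet,
    alignment_weight,
    noise_weight,
    read_emission_prob,
    rspd_start_prob,
    truncate_length_pmf,
)
from txem.model import load_params, save_params


class TestTruncation:
    def test_uniform_renormalized(self):
        d = truncate_length_pmf(LengthDistribution.uniform(1, 4), 2)
        assert np.allclose(d.pmf, [0.5, 0.5]) and d.min_len == 1

    def test_point_mass_within_limit_unchanged(self):
        d = LengthDistribution.point(3)
        assert truncate_length_pmf(d, 5) is d

    def test_partial_mass_rescaled(self):
        d = truncate_length_pmf(LengthDistribution(1, np.array([0.2, 0.3, 0.5])), 2)
        assert np.allclose(d.pmf, [0.4, 0.6])

    def test_no_mass_below_limit_is_empty(self):
        assert truncate_length_pmf(LengthDistribution.point(9), 4) is None

    @given(lo=st.integers(1, 5), width=st.integers(0, 6), limit=st.integers(1, 20))
    def test_idempotent_beyond_support(self, lo, width, limit):
        d = LengthDistribution.uniform(lo, lo + width)
        if limit >= d.max_len:
            assert truncate_length_pmf(d, limit) is d


class TestRspd:
    def test_uniform_positions(self):
        r = Rspd.uniform(20)
        assert rspd_start_prob(r, 2, 4) == pytest.approx(0.25)

    def test_one_position_per_bin(self):
        r = Rspd(np.array([0.8, 0.2]))
        assert rspd_start_prob(r, 0, 2) == pytest.approx(0.8)
        assert rspd_start_prob(r, 1, 2) == pytest.approx(0.2)

    def test_bin_mass_split_among_positions(self):
        r = Rspd(np.array([0.8, 0.2]))
        probs = [rspd_start_prob(r, s, 4) for s in range(4)]
        assert probs == pytest.approx([0.4, 0.4, 0.1, 0.1])

    @given(n=st.integers(1, 50))
    def test_positions_sum_to_one(self, n):
        r = Rspd(np.array([0.5, 0.1, 0.15, 0.25]))
        assert r.position_probs(n).sum() == pytest.approx(1.0)


class TestEmission:
    def test_perfect_match_probability_one(self, exact_profile):
        params = _params(err=exact_profile(2))
        assert read_emission_prob(params, "AC", None, "AC") == pytest.approx(1.0)

    def test_independent_positions_multiply(self):
        params = _params(err=ProfileErrorModel.flat(2, error_rate=0.1))
        assert read_emission_prob(params, "AC", None, "AC") == pytest.approx(0.81)

    def test_theoretical_phred_double_mismatch(self):
        params = _params(err=QualityErrorModel.theoretical())
        q10 = chr(10 + 33) * 2
        p = read_emission_prob(params, "CC", q10, "AA")
        assert p == pytest.approx((0.1 / 3) ** 2, rel=1e-9)

    def test_quality_and_profile_models_coincide_when_constant(self):
        rate = 0.02
        qt = np.empty((10, 4, 4))
        for c in range(4):
            qt[:, c, :] = rate / 3
            qt[:, c, c] = 1 - rate
        pq = _params(err=QualityErrorModel(qt))
        pp = _params(err=ProfileErrorModel.flat(3, rate))
        for read, ref in (("ACG", "ACG"), ("ACG", "AGG"), ("TTT", "ACG")):
            assert read_emission_prob(pq, read, "$$$", ref) == pytest.approx(
                read_emission_prob(pp, read, None, ref)
            )


def _params(err, m=1, frag=None, read=None, strand=False):
    return ModelParams(
        theta=np.full(m + 1, 1.0 / (m + 1)),
        lambda_f=frag or LengthDistribution.point(2),
        lambda_r=read or LengthDistribution.point(2),
        rspd=Rspd.uniform(),
        error=err,
        strand_specific=strand,
    )


class TestAlignmentWeight:
    def setup_method(self):
        self.ts = TranscriptSet([Transcript("t", "t", "ACG")])

    def test_se_point_mass_marginalization(self, exact_profile):
        # length-3 transcript, read length 2, fragment length 2: two possible
        # starts, uniform RSPD; P(o) = 1/2 -> 0.5 * 1 * 0.5 = 0.25
        params = _params(err=exact_profile(2))
        read = ReadRecord("r", "AC")
        w = alignment_weight(params, read, Alignment(0, 0, 0), self.ts)
        assert w == pytest.approx(0.25)

    def test_strand_specific_doubles_orientation_mass(self, exact_profile):
        params = _params(err=exact_profile(2), strand=True)
        read = ReadRecord("r", "AC")
        w = alignment_weight(params, read, Alignment(0, 0, 0), self.ts)
        assert w == pytest.approx(0.5)

    def test_start_beyond_feasible_region_is_zero(self, exact_profile):
        params = _params(err=exact_profile(2), frag=LengthDistribution.point(3))
        read = ReadRecord("r", "CG")
        # forward read at pos 1 leaves no room for a length-3 fragment
        w = alignment_weight(params, read, Alignment(0, 0, 1), self.ts)
        assert w == 0.0

    def test_total_probability_over_positions_orientations_and_sequences(self):
        # exhaustive enumeration: summing the weight over every placement and
        # every possible emitted read must give 1 (the model is a proper
        # distribution given the transcript)
        ts = TranscriptSet([Transcript("t", "t", "ACGTAC")])
        params = _params(err=ProfileErrorModel.flat(2, 0.12), frag=LengthDistribution.point(3))
        total = 0.0
        for pos in range(6):
            for rev in (False, True):
                for chars in itertools.product("ACGT", repeat=2):
                    read = ReadRecord("r", "".join(chars))
                    total += alignment_weight(params, read, Alignment(0, 0, pos, rev), ts)
        assert total == pytest.approx(1.0, rel=1e-9)

    def test_paired_weight_includes_both_mates(self, exact_profile):
        ts = TranscriptSet([Transcript("t", "t", "ACGTACGT")])
        params = _params(
            err=exact_profile(2),
            frag=LengthDistribution.point(6),
            read=LengthDistribution.point(2),
        )
        read = ReadRecord("r", "AC", None, "GT", None)  # mate2 = revcomp of "AC"...
        # fragment [0,6): mate1 fwd "AC", mate2 revcomp of seq[4:6]="AC" -> "GT"
        w = alignment_weight(params, read, Alignment(0, 0, 0, False, 6), ts)
        # P(o)=0.5, lambda_F=1, starts: 8-6+1=3 -> 1/3, emissions exact
        assert w == pytest.approx(0.5 / 3)


class TestNoiseWeight:
    def test_uniform_background(self):
        params = _params(err=ProfileErrorModel.flat(2))
        assert noise_weight(params, ReadRecord("r", "AC")) == pytest.approx(1 / 16)

    def test_read_length_mass_applies(self):
        params = _params(err=ProfileErrorModel.flat(2), read=LengthDistribution.uniform(1, 2))
        assert noise_weight(params, ReadRecord("r", "AC")) == pytest.approx(0.5 / 16)

    def test_transcript_independent(self):
        params = _params(err=ProfileErrorModel.flat(2))
        assert noise_weight(params, ReadRecord("r", "GG")) == noise_weight(
            params, ReadRecord("x", "AA")
        )


def test_params_text_round_trip(tmp_path):
    params = ModelParams(
        theta=np.array([0.1, 0.6, 0.3]),
        lambda_f=LengthDistribution(3, np.array([0.25, 0.5, 0.25])),
        lambda_r=LengthDistribution.point(4),
        rspd=Rspd(np.array([0.7, 0.3])),
        error=QualityErrorModel.theoretical(max_qual=5),
        strand_specific=True,
        noise_background=np.array([0.1, 0.2, 0.3, 0.4]),
    )
    path = tmp_path / "model.txt"
    save_params(params, path)
    back = load_params(path)
    assert np.allclose(back.theta, params.theta)
    assert back.lambda_f.min_len == 3 and np.allclose(back.lambda_f.pmf, params.lambda_f.pmf)
    assert np.allclose(back.rspd.bins, params.rspd.bins)
    assert back.strand_specific
    assert isinstance(back.error, QualityErrorModel)
    assert np.allclose(back.error.table, params.error.table)
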