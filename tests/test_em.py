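import numpy as np
import pytest

from txem import (
    AlignFilterConfig,
    Alignment,
    AlignmentSet,
    EmConfig,
    LengthDistribution,
    ModelParams,
    ProfileErrorModel,
    ReadRecord,
    Rspd,
    Transcript,
    TranscriptSet,
    e_step,
    estimate_repeat_pass_prob,
    gene_and_isopct,
    m_step,
    run_em,
    theta_to_tau,
)
from txem.em import EstimationError, _Engine


def exact_profile(read_len):
    t = np.zeros((read_len, 4, 4))
    for c in range(4):
        t[:, c, c] = 1.0
    return ProfileErrorModel(t)


def two_copy_instance():
    """Two identical transcripts; every read maps equally to both."""
    seq = "ACGTTGCAACGTTGCA"
    ts = TranscriptSet([Transcript("a", "a", seq), Transcript("b", "b", seq)])
    reads = [ReadRecord(f"r{i}", seq[i : i + 4]) for i in range(4)]
    cands = [
        [Alignment(i, 0, i), Alignment(i, 1, i)] for i in range(4)
    ]
    aset = AlignmentSet(reads=reads, candidates=cands)
    params = ModelParams(
        theta=np.full(3, 1 / 3),
        lambda_f=LengthDistribution.point(4),
        lambda_r=LengthDistribution.point(4),
        rspd=Rspd.uniform(),
        error=ProfileErrorModel.flat(4, 0.01),
    )
    return ts, aset, params


class TestEStep:
    def test_symmetric_split(self):
        ts, aset, params = two_copy_instance()
        params.theta = np.array([0.0, 0.5, 0.5])
        resp = e_step(params, aset, ts)
        noise_p, weighted = resp.per_read(0)
        assert noise_p == 0.0
        assert [p for _, p in weighted] == pytest.approx([0.5, 0.5])

    def test_theta_weights_the_split(self):
        ts, aset, params = two_copy_instance()
        params.theta = np.array([0.0, 0.8, 0.2])
        _, weighted = e_step(params, aset, ts).per_read(0)
        assert [p for _, p in weighted] == pytest.approx([0.8, 0.2])

    def test_read_without_candidates_goes_to_noise(self):
        ts, aset, params = two_copy_instance()
        aset.candidates[2] = []
        resp = e_step(params, aset, ts)
        noise_p, weighted = resp.per_read(2)
        assert noise_p == pytest.approx(1.0) and weighted == []

    def test_zero_noise_and_no_candidates_is_an_error(self):
        ts, aset, params = two_copy_instance()
        aset.candidates[2] = []
        params.theta = np.array([0.0, 0.5, 0.5])
        with pytest.raises(EstimationError, match="r2"):
            e_step(params, aset, ts)


class TestMStep:
    def test_plain_proportions(self):
        assert m_step(np.array([0.0, 1.0, 3.0])) == pytest.approx([0, 0.25, 0.75])

    def test_repeat_correction_rescales(self):
        theta = m_step(np.array([0.0, 1.0, 3.0]), m=np.array([1.0, 0.5]))
        assert theta == pytest.approx([0, 1 / 7, 6 / 7])

    def test_all_noise(self):
        assert m_step(np.array([5.0, 0.0, 0.0])) == pytest.approx([1, 0, 0])


class TestTauConversion:
    def test_equal_lengths_is_renormalization(self):
        tau = theta_to_tau(np.array([0.2, 0.4, 0.4]), np.array([100.0, 100.0]))
        assert tau == pytest.approx([0.5, 0.5])

    def test_length_normalization(self):
        tau = theta_to_tau(np.array([0.0, 0.5, 0.5]), np.array([100.0, 200.0]))
        assert tau == pytest.approx([2 / 3, 1 / 3])

    def test_single_transcript(self):
        assert theta_to_tau(np.array([0.3, 0.7]), np.array([50.0])) == pytest.approx([1.0])

    def test_all_zero_warns(self):
        with pytest.warns(UserWarning):
            tau = theta_to_tau(np.array([1.0, 0.0]), np.array([10.0]))
        assert tau == pytest.approx([0.0])


class TestGeneAggregation:
    def test_gene_sum_and_fractions(self):
        ts = TranscriptSet(
            [Transcript("i1", "g", "ACGT"), Transcript("i2", "g", "ACGT" * 2)]
        )
        gene_ids, gene_tau, isopct = gene_and_isopct(np.array([0.1, 0.3]), ts)
        assert gene_ids == ["g"]
        assert gene_tau == pytest.approx([0.4])
        assert isopct == pytest.approx([0.25, 0.75])

    def test_single_isoform_gene_fraction_one(self):
        ts = TranscriptSet([Transcript("i1", "g", "ACGT")])
        _, _, isopct = gene_and_isopct(np.array([0.2]), ts)
        assert isopct == pytest.approx([1.0])

    def test_zero_gene_gets_zero_fractions(self):
        ts = TranscriptSet(
            [Transcript("i1", "g", "ACGT"), Transcript("i2", "g", "AAGT")]
        )
        _, _, isopct = gene_and_isopct(np.array([0.0, 0.0]), ts)
        assert isopct == pytest.approx([0.0, 0.0])


class TestRepeatPassProb:
    def _params(self, read_len, frag_len):
        return ModelParams(
            theta=np.array([0.5, 0.5]),
            lambda_f=LengthDistribution.point(frag_len),
            lambda_r=LengthDistribution.point(read_len),
            rspd=Rspd.uniform(),
            error=ProfileErrorModel.flat(read_len, 0.01),
        )

    def test_unique_sequence_passes_everything(self):
        rng = np.random.default_rng(3)
        ts = TranscriptSet([Transcript("t", "t", "".join(rng.choice(list("ACGT"), 60)))])
        m = estimate_repeat_pass_prob(ts, self._params(8, 8), AlignFilterConfig(seed_length=8))
        assert m == pytest.approx([1.0])

    def test_pure_polya_transcript_floored(self):
        ts = TranscriptSet([Transcript("t", "t", "A" * 60)])
        m = estimate_repeat_pass_prob(ts, self._params(8, 8), AlignFilterConfig(seed_length=8))
        assert m[0] == pytest.approx(1e-8)

    def test_half_polya_windows_give_half(self):
        # "CGCG" + "AAAAA": 6 read windows of length 4, exactly 3 are >=75% A;
        # fragment length = read length makes every window equally likely
        ts = TranscriptSet([Transcript("t", "t", "CGCGAAAAA")])
        cfg = AlignFilterConfig(seed_length=4, polya_fraction=0.75)
        m = estimate_repeat_pass_prob(ts, self._params(4, 4), cfg)
        assert m[0] == pytest.approx(0.5)

    def test_monte_carlo_agrees_with_exact(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), 200)) + "A" * 40
        ts = TranscriptSet([Transcript("t", "t", seq)])
        params = self._params(10, 30)
        cfg = AlignFilterConfig(seed_length=10)
        exact = estimate_repeat_pass_prob(ts, params, cfg)
        mc = estimate_repeat_pass_prob(ts, params, cfg, mc_limit=1, mc_draws=20000, seed=5)
        assert mc[0] == pytest.approx(exact[0], abs=0.02)


class TestRunEm:
    def test_unique_reads_single_transcript(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACGT"), 50))
        ts = TranscriptSet([Transcript("t", "t", seq)])
        reads = [ReadRecord(f"r{i}", seq[i : i + 10]) for i in range(10)]
        cands = [[Alignment(i, 0, i)] for i in range(10)]
        aset = AlignmentSet(reads=reads, candidates=cands)
        params = ModelParams(
            theta=np.array([0.5, 0.5]),
            lambda_f=LengthDistribution.point(10),
            lambda_r=LengthDistribution.point(10),
            rspd=Rspd.uniform(),
            error=ProfileErrorModel.flat(10, 0.01),
        )
        cfg = EmConfig(apply_repeat_correction=False, aux_first=0, aux_every=10**9)
        ml = run_em(aset, ts, params=params, config=cfg)
        assert ml.theta[1] > 0.999
        assert ml.expected_counts[1] == pytest.approx(10.0, abs=1e-2)
        assert ml.tau == pytest.approx([1.0])

    def test_identical_transcripts_split_equally(self):
        ts, aset, params = two_copy_instance()
        ml = run_em(aset, ts, params=params, config=EmConfig(apply_repeat_correction=False))
        assert ml.theta[1] == pytest.approx(ml.theta[2])
        assert ml.tau == pytest.approx([0.5, 0.5])

    def test_conservation_invariants(self):
        ts, aset, params = two_copy_instance()
        ml = run_em(aset, ts, params=params, config=EmConfig(apply_repeat_correction=False))
        assert ml.theta.sum() == pytest.approx(1.0)
        assert ml.tau.sum() == pytest.approx(1.0)
        assert ml.expected_counts.sum() == pytest.approx(aset.n_unfiltered)

    def test_deterministic(self):
        ts, aset, params = two_copy_instance()
        cfg = EmConfig(apply_repeat_correction=False)
        a = run_em(aset, ts, params=params, config=cfg)
        b = run_em(aset, ts, params=params, config=cfg)
        assert np.array_equal(a.theta, b.theta) and a.iterations_run == b.iterations_run


class TestMonotoneLikelihood:
    def test_loglik_never_decreases_with_fixed_auxiliaries(self):
        rng = np.random.default_rng(7)
        seqs = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(3)]
        seqs[1] = seqs[0][:20] + seqs[1][20:]  # shared block -> multireads
        ts = TranscriptSet([Transcript(f"t{i}", f"t{i}", s) for i, s in enumerate(seqs)])
        reads, cands = [], []
        for i in range(30):
            t = int(rng.integers(0, 3))
            p = int(rng.integers(0, 30))
            reads.append(ReadRecord(f"r{i}", ts[t].sequence[p : p + 8]))
        from txem.aligner import align_reads

        aset = align_reads(reads, ts, seed_length=8, max_mismatch=0)
        params = ModelParams(
            theta=np.full(4, 0.25),
            lambda_f=LengthDistribution.uniform(8, 12),
            lambda_r=LengthDistribution.point(8),
            rspd=Rspd.uniform(),
            error=ProfileErrorModel.flat(8, 0.01),
        )
        eng = _Engine(aset, ts, params)
        theta = np.full(4, 0.25)
        last = -np.inf
        for _ in range(50):
            resp, counts, loglik = eng.responsibilities(theta)
            assert loglik >= last - 1e-12
            last = loglik
            theta = m_step(counts)


class TestAuxiliaryUpdates:
    def test_pe_fragment_lengths_reestimated(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), 120))
        ts = TranscriptSet([Transcript("t", "t", seq)])
        from txem.reference import revcomp

        reads, cands = [], []
        for i in range(12):
            s = int(rng.integers(0, 60))
            f = 50
            reads.append(
                ReadRecord(f"r{i}", seq[s : s + 10], None, revcomp(seq[s + f - 10 : s + f]), None)
            )
            cands.append([Alignment(i, 0, s, False, f)])
        aset = AlignmentSet(reads=reads, candidates=cands)
        params = ModelParams(
            theta=np.array([0.5, 0.5]),
            lambda_f=LengthDistribution.uniform(40, 60),
            lambda_r=LengthDistribution.point(10),
            rspd=Rspd.uniform(),
            error=ProfileErrorModel.flat(10, 0.01),
        )
        ml = run_em(aset, ts, params=params, config=EmConfig(apply_repeat_correction=False))
        assert ml.params.lambda_f.min_len == 50 and ml.params.lambda_f.max_len == 50

    def test_error_table_matches_counting_oracle(self):
        # with unique alignments and negligible noise mass, the learned table
        # is exactly the add-one-smoothed empirical confusion of reads vs
        # reference; verify against direct counting of the injected errors
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), 4000))
        ts = TranscriptSet([Transcript("t", "t", seq)])
        base_idx = {b: i for i, b in enumerate("ACGT")}
        L = 20
        reads, cands = [], []
        oracle = np.zeros((L, 4, 4))
        for i in range(500):
            s = int(rng.integers(0, len(seq) - L))
            ref = seq[s : s + L]
            chars = list(ref)
            for j in range(L):
                if rng.random() < 0.10:  # true mismatch, never silent
                    chars[j] = "ACGT"[(base_idx[chars[j]] + int(rng.integers(1, 4))) % 4]
                oracle[j, base_idx[ref[j]], base_idx[chars[j]]] += 1
            reads.append(ReadRecord(f"r{i}", "".join(chars)))
            cands.append([Alignment(i, 0, s)])
        oracle += 1.0
        oracle /= oracle.sum(axis=-1, keepdims=True)
        aset = AlignmentSet(reads=reads, candidates=cands)
        params = ModelParams(
            theta=np.array([0.5, 0.5]),
            lambda_f=LengthDistribution.point(L),
            lambda_r=LengthDistribution.point(L),
            rspd=Rspd.uniform(),
            error=ProfileErrorModel.flat(L, 0.01),
        )
        ml = run_em(aset, ts, params=params, config=EmConfig(apply_repeat_correction=False))
        tab = ml.params.error.table
        assert np.allclose(tab, oracle, atol=2e-3)
        off_diag = 1.0 - np.mean([tab[:, c, c].mean() for c in range(4)])
        assert off_diag == pytest.approx(0.10, abs=0.02)
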