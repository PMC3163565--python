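import numpy as np
import pytest

from txem import (
    LengthDistribution,
    ModelParams,
    QualityErrorModel,
    QualityMarkov,
    Rspd,
    Transcript,
    TranscriptSet,
    fit_quality_markov,
    revcomp,
    simulate_dataset,
    write_fastq,
)
from txem.toydata import ToySpec, make_toy_reference, tau_to_theta


def make_params(ts, theta, read_len=10, frag=(20, 30)):
    return ModelParams(
        theta=np.asarray(theta, dtype=float),
        lambda_f=LengthDistribution.uniform(*frag),
        lambda_r=LengthDistribution.point(read_len),
        rspd=Rspd.uniform(),
        error=QualityErrorModel.theoretical(),
    )


def constant_quality_chain(q=40):
    return QualityMarkov(np.array([q]), np.array([1.0]), np.array([[1.0]]))


@pytest.fixture
def small_ref():
    rng = np.random.default_rng(0)
    ts = TranscriptSet(
        [
            Transcript(f"t{i}", f"t{i}", "".join(rng.choice(list("ACGT"), 200)))
            for i in range(4)
        ]
    )
    return ts


class TestQualityMarkov:
    def test_constant_strings_regenerate_constant(self, tmp_path):
        fq = tmp_path / "r.fq"
        fq.write_text("@a\nACGT\n+\nIIII\n@b\nGGGG\n+\nIIII\n")
        qm = fit_quality_markov(fq)
        quals = qm.sample(5, 4, np.random.default_rng(0))
        assert np.all(quals == 40)  # 'I' = Phred 40

    def test_deterministic_alternation_learned(self, tmp_path):
        fq = tmp_path / "r.fq"
        fq.write_text("@a\nACGTAC\n+\nIJIJIJ\n" * 1 + "@b\nACGTAC\n+\nIJIJIJ\n")
        qm = fit_quality_markov(fq)
        i40, i41 = list(qm.states).index(40), list(qm.states).index(41)
        assert qm.transition[i40, i41] > 0.7 and qm.transition[i41, i40] > 0.7

    def test_refit_recovers_known_chain(self, tmp_path):
        states = np.array([30, 35])
        chain = QualityMarkov(states, np.array([0.5, 0.5]), np.array([[0.8, 0.2], [0.3, 0.7]]))
        rng = np.random.default_rng(1)
        quals = chain.sample(800, 30, rng)
        fq = tmp_path / "r.fq"
        with open(fq, "w") as fh:
            for i, row in enumerate(quals):
                fh.write(f"@r{i}\n{'A' * 30}\n+\n{''.join(chr(q + 33) for q in row)}\n")
        refit = fit_quality_markov(fq)
        assert np.allclose(refit.transition, chain.transition, atol=0.02)

    def test_empty_quality_data_rejected(self, tmp_path):
        fq = tmp_path / "r.fq"
        fq.write_text("")
        with pytest.raises(ValueError):
            fit_quality_markov(fq)


class TestSimulateDataset:
    def test_error_free_reads_are_exact_windows(self, small_ref):
        theta = np.array([0.0, 0.25, 0.25, 0.25, 0.25])
        params = make_params(small_ref, theta)
        reads, truth = simulate_dataset(
            params, small_ref, 300, read_len=10,
            qmodel=constant_quality_chain(90), seed=3,
        )
        for n, r in enumerate(reads):
            t = truth.transcript[n]
            s, f = truth.start[n], truth.fragment_length[n]
            seq = small_ref[int(t)].sequence
            if truth.reverse[n]:
                assert r.seq1 == revcomp(seq[s + f - 10 : s + f])
            else:
                assert r.seq1 == seq[s : s + 10]

    def test_transcript_fractions_follow_theta(self, small_ref):
        theta = np.array([0.0, 0.4, 0.3, 0.2, 0.1])
        params = make_params(small_ref, theta)
        n = 20000
        _, truth = simulate_dataset(
            params, small_ref, n, read_len=10, qmodel=constant_quality_chain(), seed=4
        )
        frac = truth.counts(4) / n
        se = np.sqrt(theta[1:] * (1 - theta[1:]) / n)
        assert np.all(np.abs(frac - theta[1:]) < 3 * se + 1e-9)

    def test_paired_mate_geometry_and_fragment_lengths(self, small_ref):
        theta = np.array([0.0, 0.25, 0.25, 0.25, 0.25])
        params = make_params(small_ref, theta)
        reads, truth = simulate_dataset(
            params, small_ref, 2000, paired=True, read_len=10,
            qmodel=constant_quality_chain(90), seed=5,
        )
        for n in (0, 7, 100):
            t, s, f = truth.transcript[n], truth.start[n], truth.fragment_length[n]
            seq = small_ref[int(t)].sequence
            if truth.reverse[n]:
                assert reads[n].seq1 == revcomp(seq[s + f - 10 : s + f])
                assert reads[n].seq2 == seq[s : s + 10]
            else:
                assert reads[n].seq1 == seq[s : s + 10]
                assert reads[n].seq2 == revcomp(seq[s + f - 10 : s + f])
        # fragment lengths reproduce the (truncated) prior: uniform 20..30
        counts = np.bincount(truth.fragment_length, minlength=31)[20:31]
        assert stats_chisq_ok(counts)

    def test_theoretical_error_rate_tracks_quality(self, small_ref):
        theta = np.array([0.0, 1.0, 0.0, 0.0, 0.0])
        params = make_params(small_ref, theta)
        q = 13  # error prob 10^-1.3 ~ 5%
        reads, truth = simulate_dataset(
            params, small_ref, 3000, read_len=10, qmodel=constant_quality_chain(q), seed=6
        )
        mm = 0
        total = 0
        for n, r in enumerate(reads):
            s, f = truth.start[n], truth.fragment_length[n]
            seq = small_ref[0].sequence
            ref = revcomp(seq[s + f - 10 : s + f]) if truth.reverse[n] else seq[s : s + 10]
            mm += sum(a != b for a, b in zip(r.seq1, ref))
            total += 10
        rate = mm / total
        expected = 10 ** (-q / 10)
        assert rate == pytest.approx(expected, rel=0.1)

    def test_truth_counts_sum_to_n_reads(self, small_ref):
        params = make_params(small_ref, np.array([0.1, 0.3, 0.3, 0.2, 0.1]))
        _, truth = simulate_dataset(params, small_ref, 500, read_len=10, seed=7)
        noise = int((truth.transcript < 0).sum())
        assert truth.counts(4).sum() + noise == 500
        assert noise > 0  # theta_0 = 0.1 emits noise reads

    def test_seeded_bit_reproducibility(self, small_ref, tmp_path):
        params = make_params(small_ref, np.array([0.0, 0.25, 0.25, 0.25, 0.25]))
        out = []
        for _ in range(2):
            reads, _ = simulate_dataset(params, small_ref, 200, read_len=10, seed=8)
            p = tmp_path / "r.fq"
            write_fastq(reads, p)
            out.append(p.read_bytes())
        assert out[0] == out[1]


def stats_chisq_ok(counts):
    from scipy import stats

    expected = counts.sum() / counts.size
    chi2 = ((counts - expected) ** 2 / expected).sum()
    return chi2 < stats.chi2.ppf(0.999, counts.size - 1)


class TestToyData:
    def test_same_seed_same_reference(self):
        a, ta = make_toy_reference(ToySpec(n_genes=10, seed=3))
        b, tb = make_toy_reference(ToySpec(n_genes=10, seed=3))
        assert [t.sequence for t in a] == [t.sequence for t in b]
        assert np.array_equal(ta, tb)

    def test_designed_tau_normalized_and_sparse(self):
        _, tau = make_toy_reference(ToySpec(n_genes=40, zero_fraction=0.3, seed=4))
        assert tau.sum() == pytest.approx(1.0)
        assert (tau == 0).mean() == pytest.approx(0.3, abs=0.12)
        nz = tau[tau > 0]
        assert nz.max() / nz.min() > 1e3  # spans >= 3 orders of magnitude

    def test_repeat_copies_are_identical_sequences(self):
        ts, _ = make_toy_reference(ToySpec(n_genes=10, repeat_copies=2, seed=5))
        by_seq = {}
        for t in ts:
            by_seq.setdefault(t.sequence, []).append(t.gene_id)
        dupes = [g for g in by_seq.values() if len(g) > 1]
        assert len(dupes) >= 2  # planted repeats live in distinct genes
        assert all(len(set(g)) > 1 for g in dupes)

    def test_tau_to_theta_weights_by_effective_length(self):
        tau = np.array([0.5, 0.5])
        theta = tau_to_theta(tau, np.array([100.0, 300.0]))
        assert theta == pytest.approx([0.0, 0.25, 0.75])
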