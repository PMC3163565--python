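# txem

Transcript-level quantification of RNA-Seq data by expectation–maximization
over a generative read model, with Bayesian credibility intervals from
collapsed Gibbs sampling and a matched read simulator.

`txem` is for researchers who have a set of reference transcript sequences —
from a genome annotation or a de novo assembly; no reference genome is
required — and single-end or paired-end RNA-Seq reads, and who want
isoform- and gene-level abundance estimates that handle multireads
(reads aligning to several isoforms or genes) statistically rather than by
discarding or naive rescue.

## The model

A sequenced fragment is generated by:

1. choosing a transcript *i* with probability θᵢ (θ₀ is a "noise" component
   for reads that align nowhere);
2. drawing a fragment length *f* from a global distribution λ_F, truncated and
   renormalized to the transcript length ℓᵢ;
3. drawing a start position from a binned read-start-position distribution
   (RSPD; uniform by default) over the ℓᵢ − f + 1 feasible positions, and an
   orientation (probability ½ each, or 1 if the protocol is strand-specific);
4. drawing read lengths from λ_R truncated to *f* (a point mass for
   fixed-length reads), and
5. emitting read characters through a sequencing-error model — either
   quality-dependent, ε(r | q, c) = P(observed base r | Phred score q,
   reference base c), or a position × reference-base "profile" model when
   qualities are absent or unreliable.

Maximum-likelihood θ is found by EM over the candidate alignments of each
read. Because reads with ≥ 200 alignments and poly(A)-dominated reads are
filtered out for speed, the M-step sets θᵢ ∝ cᵢ / (N mᵢ), where cᵢ is the
expected fragment count, N the number of unfiltered reads, and mᵢ the
probability that a fragment from transcript i survives those filters —
without this correction, transcripts containing repetitive sequence
(including the appended poly(A) tails) are systematically underestimated.

Abundances are reported as transcript fractions
τᵢ = (θᵢ/ℓ̃ᵢ) / Σⱼ (θⱼ/ℓ̃ⱼ), where ℓ̃ᵢ is the effective length (the mean
number of feasible fragment start positions), and as TPM = τ × 10⁶.

For credibility intervals, θ gets a Dirichlet(α = 1) prior. A collapsed Gibbs
sampler resamples each fragment's assignment given all others
(probability ∝ (α + c₋ₙ,ᵢ) × model weight) and records count vectors; for
each count vector, θ is drawn from Dirichlet(c + 1). The θ draws are
converted to τ and summarized as a posterior mean (PME) and an equal-tailed
95% credibility interval, at both isoform and gene level.

The same generative model drives the simulator: quality strings come from a
first-order Markov chain (fit from any FASTQ, or a built-in Illumina-like
default), and substitution errors are injected at the theoretical Phred rate
10^(−q/10) or from a learned empirical ε table.

## Worked example

A self-contained run on a 15-transcript toy reference (the package generates
it; no downloads):

```python
from txem.toydata import ToySpec, make_toy_reference
import numpy as np
ts, tau = make_toy_reference(ToySpec(n_genes=8, seed=42, repeat_copies=0))
with open("transcripts.fa", "w") as fh:
    for t in ts: fh.write(f">{t.id}\n{t.sequence}\n")
with open("genes.tsv", "w") as fh:
    for t in ts: fh.write(f"{t.gene_id}\t{t.id}\n")
np.savetxt("tau.txt", tau)
```

```
$ txem prepare-reference transcripts.fa ref --transcript-to-gene-map genes.tsv
prepared 15 transcripts -> ref.*
$ txem simulate-reads ref sim --n-reads 20000 --theta-file tau.txt --seed 11
wrote 20000 simulated reads -> sim_*.fq
$ txem calculate-expression sim_1.fq ref quant --calc-ci \
      --gibbs-count-vectors 500 --gibbs-theta-per-vector 20 --seed 11
18293 unfiltered reads, 225 EM iterations, log-likelihood -166555.288
```

20,000 reads were simulated; 18,293 survive the poly(A) and multiplicity
filters (tail-derived reads are filtered, which is exactly what the mᵢ
correction compensates for). `quant.isoforms.results` then contains, per
transcript:

```
transcript_id  gene_id  expected_count  TPM           pme_TPM       TPM_ci_lower  TPM_ci_upper
g0000.i1       g0000    317.000003      9454.596568   9489.045355   8473.492455   10540.447309
g0001.i1       g0001    651.970826     25721.190267  25666.767482  23191.562390   28204.885115
g0001.i2       g0001      0.000000          0.000001    336.958303      8.736584    1126.246533
```

`g0001.i2` shows why the Bayesian summaries matter: the ML point estimate is
0 TPM, but the posterior — which accounts for the reads it shares with its
sibling isoform — only bounds it below ~1126 TPM. Comparing against the
simulation's ground truth:

```
$ txem evaluate quant.isoforms.results sim.truth.tsv ref
               mpe     ef    fp
gene         1.357  0.000   NaN
isoform      3.887 35.714 0.000
```

i.e. at this depth the median gene-level abundance error is 1.4% and the
median global isoform error 3.9% (MPE = median percent error; EF = fraction
of transcripts with error above 10%; FP = fraction of truly sub-1-TPM
transcripts called ≥ 1 TPM).

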