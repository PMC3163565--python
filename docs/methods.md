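# Methods

## Generative model

Each sequenced fragment is modeled as: transcript G ~ Categorical(θ) over M
transcripts plus a noise component (index 0); fragment length F ~ λ_F
truncated/renormalized to the transcript length; start S ~ RSPD over the
ℓ − F + 1 feasible positions; orientation O with P(forward) = ½
(1 if strand-specific); read length(s) L ~ λ_R truncated to F; read
characters emitted through a sequencing-error model. "Forward" means mate 1
matches the transcript sense strand; in a paired fragment the other mate is
the reverse complement of the opposite fragment end (FR geometry). The
simulator and the quantifier share one scoring kernel
(`model.alignment_weight`), so a simulate-then-estimate round trip is exact
by construction up to sampling noise.

Single-end reads leave the fragment length latent; it is summed out over the
feasible range, which is orientation-dependent: a forward read fixes the
fragment start (fragment extends downstream, F ≤ ℓ − S), a reverse read
fixes the fragment *end* (F ≤ read end). The internal alignment record
therefore stores the read's leftmost coordinate; for paired and
forward-oriented alignments this equals the fragment start.

Noise reads are emitted i.i.d. from a background composition (uniform ¼ by
default, optionally re-estimated from unaligned reads) times the global λ_R
mass at the observed read length; the λ_R factor keeps the noise weight on
the same footing as transcript weights under variable read lengths.

### Error models

* Quality model: ε[q, c, r] = P(read base r | Phred q, reference base c),
  initialized at the theoretical Phred rates (error 10^(−q/10), split evenly
  over the three wrong bases) and re-estimated during EM.
* Profile model: P(r | read position, c), used when qualities are absent or
  distrusted; initialized flat at 1% error.
* `N` in read or reference emits the smallest positive mass of the relevant
  table row — never zero, so a single ambiguous base cannot veto an
  alignment.

### RSPD discretization

The RSPD has B = 20 bins (uniform by default). A transcript with n feasible
starts maps position s to bin ⌊Bs/n⌋; each bin's mass is split evenly among
its positions and the result renormalized (relevant when n < B). A uniform
RSPD yields exactly 1/n per position — the binning must not introduce
jitter, since both the simulator and the closed-form EM weights rely on the
uniform case being exact.

## Filters and the m correction

Reads with ≥ 200 candidate alignments and reads whose sequence is ≥ 90% A
(or ≥ 90% T, covering antisense) are excluded from estimation; the A/T-content
rule is this package's operational definition of "likely poly(A)-derived".
Because tailed and repetitive transcripts lose fragments to these filters
disproportionately, the M-step uses θᵢ ∝ cᵢ/(N mᵢ) with mᵢ the probability
that an error-free fragment from transcript i yields a read passing both
filters. mᵢ is computed by exact enumeration over (length, start,
orientation) — reduced to prefix sums over per-window survival flags — when
ℓᵢ · |support(λ_F)| ≤ 10⁶, and by seeded Monte Carlo (10⁴ draws) otherwise;
it is floored at 10⁻⁸ so fully repetitive transcripts stay finite. A read
and its reverse complement have identical total hit counts and A/T-symmetric
tail content, so survival is a property of the read's source window only.
For paired data, a fragment survives when both mate windows survive
individually; this slightly overstates filtering for pairs whose joint
alignment count is below the threshold even though a single mate's is not.

The same correction is applied when converting posterior θ samples to τ:
sampled counts describe *surviving* fragments, so generation-scale abundance
is proportional to θᵢ/mᵢ. Omitting this shifts the posterior of short or
heavily tailed transcripts by up to ~15% and visibly breaks interval
calibration.

mᵢ is recomputed after an auxiliary update only if λ_F or the RSPD changed;
error-model updates cannot affect it (the enumeration is error-free).

## EM

θ is initialized uniform over M + 1 components, which makes exactly
symmetric instances (identical transcripts) converge to exactly symmetric
estimates — that degeneracy is reported, not resolved, because the model is
unidentifiable there. During the first 20 iterations and every 100th
thereafter, the auxiliary distributions are re-estimated from
responsibility-weighted counts: the error table (add-one smoothed), the
fragment-length distribution for paired data (single-end λ_F stays at the
user-supplied prior, a discretized Gaussian truncated to ≥ 1), optionally the
RSPD and the noise background. Iteration stops when every θᵢ ≥ 10⁻⁷ changes
by less than 10⁻³ relative, or at 10,000 iterations. Between auxiliary
checkpoints the θ-only iterations run in a compiled kernel; the
responsibilities use per-read max-shifted linear weights, so likelihoods are
exact in double precision for reads up to hundreds of bases.

The reported `expected_count` is the final cᵢ itself (the expected number of
alignable, unfiltered fragments), not the m-corrected quantity; the
correction enters θ and τ.

## Built-in aligner

For self-contained runs an internal all-hits seed aligner reports every
placement whose first 25 bases (configurable) match with ≤ 2 mismatches,
mirroring the usual external-aligner policy. It indexes all reference 8-mers
in a sorted array; a seed with ≤ k mismatches must contain an exact 8-mer at
one of k + 1 disjoint interval starts (pigeonhole), so candidates come from
k + 1 exact lookups and are verified in a compiled loop. Seeds shorter than
8(k + 1) fall back to an exhaustive scan. Batch alignment stops enumerating
a read's placements at the filter threshold — such reads are filtered
regardless, and counts below the cap are exact, so the threshold boundary is
unaffected. Paired reads are joined per transcript in FR geometry with the
fragment capped at 1000 b by default. Gapped alignment and indels are out of
scope.

## Posterior sampling

Collapsed Gibbs over fragment assignments with θ integrated out under
Dirichlet(α = 1): each read is resampled with probability
∝ (α + c₋ₙ,ᵢ) × weight, with the noise outcome an ordinary component. The
chain starts from a draw of the ML responsibilities, burns in 200 sweeps,
and by default records one count vector per sweep (the calibration study
records every 2nd sweep; within-gene multiread blocks mix slowly and
thinning improves the tail quantiles at fixed sample count). Stage two draws
`theta_per_vector` θ vectors from Dirichlet(c + α) per count vector
(defaults 1000 × 50). Gene-level summaries are computed from per-sample
member sums — interval endpoints do not add. With α = 1 the prior is uniform
and the posterior mode coincides with the ML estimate; the test suite
verifies the sampler against exact enumeration of all assignment states on a
small instance.

## Simulator and toy data

The simulator draws fragments from the model (conditioning λ_F on fragments
long enough to hold a read), emits quality strings from a homogeneous
first-order Markov chain over Phred scores, and injects substitutions either
theoretically (10^(−q/10)) or from an ε table. The built-in default chain
emulates an Illumina-like profile: starts near q34, mean-reverting drift
toward the high 20s, and rare dips to the quality floor (≈0.05% per
transition, touching a couple percent of 35 b reads) that recover within a
few cycles. A per-position (inhomogeneous) chain is not modeled; neither are
indels, adapters, or PCR duplicates.

`toydata.make_toy_reference` builds genes from pools of 3–6 random exons of
120–500 b; isoforms are random exon subsets (so isoforms share exact
sequence blocks, creating multireads), with the per-gene isoform count drawn
from a pmf with mean 1.7 — the isoform density of a mammalian RefSeq
annotation. A configurable number of genes is duplicated verbatim to
exercise repeat handling and mappability. Designed abundances are
log-uniform over [10⁻⁶, 10⁻²] with a 20% zero fraction, normalized.

What the toy world does **not** emulate: sequence-composition bias (hexamer
priming), intron-containing pre-mRNA, positional (3′) bias unless an RSPD is
supplied, and realistic homology families beyond exact repeats. Passing the
validation studies therefore demonstrates correctness of the inference under
the model, not robustness to library-preparation biases.

## Validation studies and their scale

`txem.validation` fixes the reproducible study designs (problem sizes chosen
to run in minutes on one CPU):

* **CI calibration** — ~300-transcript toy (no duplicate transcripts: with
  identical sequences the truth is unidentifiable, and the annotation this
  emulates was de-duplicated so each gene came from a unique locus), 125 b
  poly(A) tails, 100k SE 35 b reads with λ_F = N(280, 17²), theoretical
  quality-driven errors; EM, then 1000 count vectors × 20 θ draws (burn-in
  200, thinning 2). Coverage of the 95% interval among isoforms with truth
  ≥ 1 TPM is the headline number (`scripts/acceptance.py`).
* **Parameter recovery / error-model parity** — same generator with
  duplicates retained, 200k reads; quantified once with the quality model
  and once with the profile model on the identical alignments; accuracy as
  MPE / 10% EF / FP at gene, global-isoform, and within-gene levels.

Known desk-scale limitations, visible in these studies:

* **Prior floor.** With N = 10⁵ reads and M ≈ 300, each unit of Dirichlet
  pseudo-count is worth ≈ 10 TPM after normalization, so transcripts whose
  truth lies in the low tens of TPM can fall below their own interval's
  lower bound; at 2 × 10⁷ reads the same pseudo-count is worth 0.05 TPM and
  the effect vanishes. This trims a few points from measured coverage and
  grows with M/N — the same prior-driven downward bias the method exhibits
  on large annotations.
* **Sampling floor on accuracy.** Under the log-uniform abundance design the
  median expressed transcript receives ~50 reads at 200k total, so even an
  oracle given the true read assignments has a global-isoform MPE of ≈ 7.5%;
  the multiread-allocation cost of exon-sharing isoforms at 35 b adds
  several points on top. Gene-level estimates sit within ~0.3 points of the
  oracle floor.

## Numerical choices and degenerate inputs

* Weights are computed in log space and per-read max-shifted before
  exponentiation; per-read posteriors are exact renormalizations.
* λ_F truncation to a transcript shorter than the entire support yields zero
  weight for every alignment there (and effective length 0); τ conversion
  rejects positive abundance on zero effective length.
* Convergence compares θ elementwise against the previous iteration only for
  components ≥ 10⁻⁷ (the active set).
* MAPQ in the posterior-weighted SAM is round(−10·log₁₀(1 − p)) capped at
  100 (p = 1 maps to the cap); the lossless posterior is in the `ZW` tag.
* Quantile intervals are equal-tailed with linear interpolation; levels are
  validated against closed-form Beta quantiles in the tests.
* Ties from exactly duplicated transcripts stay symmetric (uniform
  initialization); their individual estimates are not meaningful, only their
  sum is.
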