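"""High-level orchestration: align -> EM -> (optionally) posterior sampling.

These are the entry points the CLI, the test suite, and reproduction scripts
share. Everything is deterministic given the seeds in the configs.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .aligner import align_reads
from .em import AlignFilterConfig, EmConfig, MLEstimates, run_em
from .gibbs import PosteriorSummary, SamplerConfig, posterior_summary
from .model import ModelParams
from .readsio import AlignmentSet, ReadRecord
from .reference import TranscriptSet


@dataclass
class QuantifyResult:
    ml: MLEstimates
    aset: AlignmentSet
    posterior: Optional[PosteriorSummary] = None
    count_vectors: Optional[np.ndarray] = None


def quantify(
    reads: list[ReadRecord],
    ts: TranscriptSet,
    params: Optional[ModelParams] = None,
    em_config: Optional[EmConfig] = None,
    aset: Optional[AlignmentSet] = None,
    calc_ci: bool = False,
    sampler_config: Optional[SamplerConfig] = None,
    ci_level: float = 0.95,
) -> QuantifyResult:
    """Align (with the built-in aligner, unless an AlignmentSet is supplied),
    filter, run EM, and optionally sample posterior credibility intervals."""
    em_config = em_config or EmConfig()
    fc = em_config.filter_cfg
    if aset is None:
        aset = align_reads(
            reads,
            ts,
            seed_length=fc.seed_length,
            max_mismatch=fc.max_mismatch,
            max_alignments=fc.max_alignments,
            polya_fraction=fc.polya_fraction,
        )
    ml = run_em(aset, ts, params=params, config=em_config)
    post = cv = None
    if calc_ci:
        post, cv = posterior_summary(
            aset, ts, ml, sampler_config or SamplerConfig(seed=em_config.seed),
            level=ci_level,
        )
    return QuantifyResult(ml=ml, aset=aset, posterior=post, count_vectors=cv)
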