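"""The logLR clonal-relatedness statistic for a pair of tumors.

Evidence for a common clonal origin is aggregated over chromosome arms by a
likelihood ratio contrasting a shared-event model against independent
occurrence.  For a pair with arm calls (c1, c2), cohort marginal call
frequencies pi_a(c), and Jaccard breakpoint closeness s_a on concordantly
called arms, the per-arm likelihood under independence is
pi_a(c1) * pi_a(c2), while under clonality a fraction xi of events is shared:

    logLR = max_xi  sum_a log[ (xi * m_a + (1 - xi) * q_a) / q_a ]

with q_a = pi_a(c1) pi_a(c2) and m_a = pi_a(c) * s_a for concordant
gains/losses, pi_a(NORMAL) for concordant-normal arms, and 0 for discordant
arms.  A concordant change that is common in the cohort (large pi, e.g. a
1q gain) therefore contributes little evidence, while a rare matching
change with closely matching breakpoints contributes a lot.  xi is
profile-maximised on a grid; xi = 0 is always in the grid, so logLR >= 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .segmentation import ArmCall, ArmSegmentation

_CALLS = (ArmCall.GAIN, ArmCall.LOSS, ArmCall.NORMAL)
_CALL_COL = {c: k for k, c in enumerate(_CALLS)}


@dataclass
class ClonalityConfig:
    xi_grid_step: float = 0.01
    smoothing_pseudocount: float = 1.0
    leave_pair_out: bool = False  # re-estimate marginals excluding the tested pair

    def __post_init__(self):
        if not (0 < self.xi_grid_step <= 0.5):
            raise ValueError("xi_grid_step must be in (0, 0.5]")
        if self.smoothing_pseudocount <= 0:
            raise ValueError("smoothing_pseudocount must be positive")

    def xi_grid(self) -> np.ndarray:
        n = int(round(1.0 / self.xi_grid_step))
        return np.linspace(0.0, 1.0, n + 1)


class ArmMarginals:
    """Cohort marginal frequencies pi_a(GAIN/LOSS/NORMAL) per arm.

    Strictly positive by pseudo-count smoothing and summing to 1 per arm.
    """

    def __init__(self, probs: np.ndarray):
        probs = np.asarray(probs, dtype=np.float64)
        if probs.ndim != 2 or probs.shape[1] != 3:
            raise ValueError("probs must be (n_arms, 3) for GAIN/LOSS/NORMAL")
        if np.any(probs <= 0) or not np.allclose(probs.sum(axis=1), 1.0):
            raise ValueError("marginals must be strictly positive and sum to 1 per arm")
        self.probs = probs

    @property
    def n_arms(self) -> int:
        return self.probs.shape[0]

    def get(self, arm_index: int, call: ArmCall) -> float:
        return float(self.probs[arm_index, _CALL_COL[call]])


def estimate_marginals(segmentations: dict[str, list[ArmSegmentation]],
                       config: ClonalityConfig | None = None,
                       exclude: Sequence[str] = ()) -> ArmMarginals:
    """Smoothed per-arm call frequencies over a cohort.

    pi_a(c) = (count of call c on arm a + pseudo) / (n samples + 3 * pseudo).
    """
    config = config or ClonalityConfig()
    samples = [s for s in segmentations if s not in set(exclude)]
    if len(samples) < 2:
        raise ValueError("need at least 2 samples to estimate marginals")
    n_arms = len(segmentations[samples[0]])
    counts = np.zeros((n_arms, 3))
    for s in samples:
        segs = segmentations[s]
        if len(segs) != n_arms:
            raise ValueError(f"sample {s!r} has a different arm set")
        for seg in segs:
            counts[seg.arm_index, _CALL_COL[seg.call]] += 1
    pseudo = config.smoothing_pseudocount
    probs = (counts + pseudo) / (len(samples) + 3 * pseudo)
    return ArmMarginals(probs)


def segment_overlap(armseg1: ArmSegmentation, armseg2: ArmSegmentation) -> float:
    """Jaccard index of the two calling-segment footprints (marker offsets).

    Only defined for two arms carrying the same non-NORMAL call; the value
    is 1 for identical footprints and 0 for disjoint ones.
    """
    if armseg1.call is ArmCall.NORMAL or armseg1.call is not armseg2.call:
        raise ValueError("segment_overlap requires a concordant non-NORMAL call")
    if armseg1.arm_index != armseg2.arm_index:
        raise ValueError("footprints are on different arms")
    a1, b1 = armseg1.footprint
    a2, b2 = armseg2.footprint
    inter = min(b1, b2) - max(a1, a2) + 1
    if inter <= 0:
        return 0.0
    union = (b1 - a1 + 1) + (b2 - a2 + 1) - inter
    return inter / union


@dataclass
class ArmContribution:
    arm_index: int
    call1: ArmCall
    call2: ArmCall
    overlap: float  # Jaccard s, NaN where undefined
    log_term: float  # contribution to logLR at xi_hat


@dataclass
class PairResult:
    sample1: str
    sample2: str
    patient1: str = ""
    patient2: str = ""
    loglr: float = 0.0
    xi_hat: float = 0.0
    contributions: list[ArmContribution] = field(default_factory=list)
    p_value: float | None = None
    classification: str | None = None  # clonal / equivocal / independent


def pair_loglr(seg1: list[ArmSegmentation], seg2: list[ArmSegmentation],
               marginals: ArmMarginals,
               config: ClonalityConfig | None = None,
               sample1: str = "A", sample2: str = "B") -> PairResult:
    """logLR and fitted shared-event fraction xi for one tumor pair.

    Symmetric in its two arguments.  p-value and classification are filled
    in later against the empirical cross-patient null.
    """
    config = config or ClonalityConfig()
    if len(seg1) != len(seg2) or len(seg1) != marginals.n_arms:
        raise ValueError("arm sets of the two samples and the marginals must match")
    n_arms = len(seg1)
    q = np.empty(n_arms)
    m = np.empty(n_arms)
    s_vals = np.full(n_arms, np.nan)
    for a, (s1, s2) in enumerate(zip(seg1, seg2)):
        if s1.arm_index != s2.arm_index:
            raise ValueError("segmentations are not in the same arm order")
        q[a] = marginals.get(a, s1.call) * marginals.get(a, s2.call)
        if s1.call is s2.call:
            if s1.call is ArmCall.NORMAL:
                m[a] = marginals.get(a, ArmCall.NORMAL)
            else:
                s_vals[a] = segment_overlap(s1, s2)
                m[a] = marginals.get(a, s1.call) * s_vals[a]
        else:
            m[a] = 0.0

    grid = config.xi_grid()
    with np.errstate(divide="ignore"):
        # terms: (n_arms, n_grid)
        terms = np.log((np.outer(m, grid) + np.outer(q, 1.0 - grid)) / q[:, None])
    totals = terms.sum(axis=0)
    best = int(np.argmax(totals))  # first occurrence => smallest xi on ties
    loglr = float(totals[best])
    xi_hat = float(grid[best])
    contributions = [
        ArmContribution(a, seg1[a].call, seg2[a].call, float(s_vals[a]),
                        float(terms[a, best]))
        for a in range(n_arms)
    ]
    return PairResult(sample1, sample2, loglr=loglr, xi_hat=xi_hat,
                      contributions=contributions)
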