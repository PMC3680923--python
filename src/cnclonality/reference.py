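"""Empirical reference (null) distribution, p-values, three-way
classification, and cohort gain/loss frequency summaries.

Tumor pairs drawn from different patients are non-clonal by construction;
the logLR values of all such cross-patient pairs form the reference
distribution.  An observed pair is "clonal" when its logLR exceeds every
reference value, "equivocal" when it is inside the reference range but more
extreme than the upper alpha tail (p < alpha), and "independent" otherwise.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clonality import ArmMarginals, ClonalityConfig, PairResult, pair_loglr
from .segmentation import ArmCall, ArmSegmentation
from .genome_io import MarkerTrack

logger = logging.getLogger(__name__)

MIN_STABLE_NULL_PAIRS = 50


@dataclass
class ClassificationConfig:
    alpha: float = 0.05

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class NullDistribution:
    """logLR values of all (or a subsample of) cross-patient tumor pairs."""

    values: np.ndarray
    n_pairs: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.n_pairs == 0:
            self.n_pairs = self.values.size

    @property
    def max(self) -> float:
        return float(self.values.max())


def cross_patient_pairs(samples: list[str],
                        patient_of: dict[str, str]) -> list[tuple[str, str]]:
    """All unordered pairs of samples from different patients."""
    return [(a, b) for a, b in itertools.combinations(samples, 2)
            if patient_of[a] != patient_of[b]]


def build_reference(segmentations: dict[str, list[ArmSegmentation]],
                    patient_of: dict[str, str],
                    marginals: ArmMarginals,
                    config: ClonalityConfig | None = None,
                    max_pairs: int | None = None,
                    rng: np.random.Generator | None = None) -> NullDistribution:
    """logLR for every unordered cross-patient pair, under the same
    marginals and config as the real pairs.

    ``max_pairs`` subsamples the pair list (seeded ``rng`` required) when
    the full cross-patient set is larger than needed.
    """
    config = config or ClonalityConfig()
    samples = list(segmentations)
    if len(set(patient_of[s] for s in samples)) < 2:
        raise ValueError("reference distribution needs samples from >= 2 patients")
    pairs = cross_patient_pairs(samples, patient_of)
    if max_pairs is not None and len(pairs) > max_pairs:
        if rng is None:
            rng = np.random.default_rng(0)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[k] for k in sorted(idx)]
    if len(pairs) < MIN_STABLE_NULL_PAIRS:
        logger.warning("reference distribution has only %d pairs; "
                       "classifications may be unstable", len(pairs))
    values = np.array([
        pair_loglr(segmentations[a], segmentations[b], marginals, config).loglr
        for a, b in pairs
    ])
    return NullDistribution(values)


def p_value(obs_loglr: float, null: NullDistribution) -> float:
    """Add-one rank p-value against the reference: never exactly 0."""
    if null.values.size == 0:
        raise ValueError("reference distribution is empty")
    return (1 + int(np.sum(null.values >= obs_loglr))) / (1 + null.n_pairs)


def classify_pair(obs_loglr: float, p: float, null: NullDistribution,
                  config: ClassificationConfig | None = None) -> str:
    """Three-way call: clonal / equivocal / independent.

    Clonal when the observed logLR lies outside (strictly above) the whole
    reference distribution; equivocal when inside its range but with
    p < alpha; independent otherwise.
    """
    config = config or ClassificationConfig()
    if obs_loglr > null.max:
        return "clonal"
    if p < config.alpha:
        return "equivocal"
    return "independent"


def evaluate_pair(result: PairResult, null: NullDistribution,
                  config: ClassificationConfig | None = None) -> PairResult:
    result.p_value = p_value(result.loglr, null)
    result.classification = classify_pair(result.loglr, result.p_value, null, config)
    return result


@dataclass
class CohortFrequencies:
    """Marker-level gain/loss proportions and whole-arm event percentages,
    per sample group (e.g. lesion type)."""

    groups: list[str]
    marker_gain: dict[str, np.ndarray]  # proportion in [0,1] per marker
    marker_loss: dict[str, np.ndarray]
    arm_gain_pct: dict[str, np.ndarray]  # whole-arm events, percent per arm
    arm_loss_pct: dict[str, np.ndarray]
    n_samples: dict[str, int] = field(default_factory=dict)


def cohort_frequencies(segmentations_by_group: dict[str, dict[str, list[ArmSegmentation]]],
                       track: MarkerTrack) -> CohortFrequencies:
    """Gain/loss frequencies across each group of samples.

    A marker's status in a sample is the arm's call if the marker lies in
    the calling footprint, NORMAL otherwise.  Whole-arm percentages count
    samples whose calling footprint covers the entire arm.
    """
    n_arms = len(track.layout)
    n_markers = len(track)
    groups = list(segmentations_by_group)
    marker_gain, marker_loss = {}, {}
    arm_gain, arm_loss, n_samples = {}, {}, {}
    for g in groups:
        cohort = segmentations_by_group[g]
        if not cohort:
            raise ValueError(f"group {g!r} has no samples")
        n = len(cohort)
        mg = np.zeros(n_markers)
        ml = np.zeros(n_markers)
        ag = np.zeros(n_arms)
        al = np.zeros(n_arms)
        for segs in cohort.values():
            for seg in segs:
                if seg.call is ArmCall.NORMAL or seg.footprint is None:
                    continue
                sl = track.arm_slice(seg.arm_index)
                a, b = seg.footprint
                idx = slice(sl.start + a, sl.start + b + 1)
                if seg.call is ArmCall.GAIN:
                    mg[idx] += 1
                else:
                    ml[idx] += 1
                if seg.is_whole_arm():
                    (ag if seg.call is ArmCall.GAIN else al)[seg.arm_index] += 1
        marker_gain[g] = mg / n
        marker_loss[g] = ml / n
        arm_gain[g] = 100.0 * ag / n
        arm_loss[g] = 100.0 * al / n
        n_samples[g] = n
    return CohortFrequencies(groups, marker_gain, marker_loss,
                             arm_gain, arm_loss, n_samples)


def null_histogram(null: NullDistribution, n_bins: int = 30) -> pd.DataFrame:
    """Bin edges/counts of the reference distribution, for histogram plots
    of the logLR scale."""
    counts, edges = np.histogram(null.values, bins=n_bins)
    return pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:],
                         "count": counts})


def pair_table(results: list[PairResult],
               patient_of: dict[str, str] | None = None) -> pd.DataFrame:
    rows = []
    for r in results:
        p1 = r.patient1 or (patient_of or {}).get(r.sample1, "")
        p2 = r.patient2 or (patient_of or {}).get(r.sample2, "")
        rows.append(dict(sample1=r.sample1, sample2=r.sample2,
                         patient1=p1, patient2=p2, logLR=r.loglr,
                         xi=r.xi_hat, p=r.p_value,
                         classification=r.classification))
    return pd.DataFrame(rows)
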