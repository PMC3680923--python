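"""End-to-end cohort analysis: segmentation, marginals, within-patient
pair statistics, empirical null, and three-way classification."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .clonality import (ArmMarginals, ClonalityConfig, PairResult,
                        estimate_marginals, pair_loglr)
from .genome_io import MarkerTrack, SampleProfile
from .reference import (ClassificationConfig, NullDistribution,
                        build_reference, evaluate_pair)
from .segmentation import ArmSegmentation, SegmentationConfig, segment_profile


@dataclass
class CohortAnalysis:
    segmentations: dict[str, list[ArmSegmentation]]
    marginals: ArmMarginals
    null: NullDistribution
    pair_results: list[PairResult]
    patient_of: dict[str, str] = field(default_factory=dict)


def within_patient_pairs(profiles: list[SampleProfile]) -> list[tuple[str, str]]:
    """All unordered sample pairs sharing a patient id."""
    by_patient: dict[str, list[str]] = {}
    for p in profiles:
        by_patient.setdefault(p.patient_id, []).append(p.sample_id)
    pairs = []
    for ids in by_patient.values():
        pairs.extend(itertools.combinations(ids, 2))
    return pairs


def segment_cohort(profiles: list[SampleProfile], track: MarkerTrack,
                   config: SegmentationConfig | None = None,
                   ) -> dict[str, list[ArmSegmentation]]:
    config = config or SegmentationConfig()
    return {p.sample_id: segment_profile(p, track, config) for p in profiles}


def analyze_cohort(track: MarkerTrack, profiles: list[SampleProfile],
                   pairs: list[tuple[str, str]] | None = None,
                   seg_config: SegmentationConfig | None = None,
                   clon_config: ClonalityConfig | None = None,
                   class_config: ClassificationConfig | None = None,
                   null_max_pairs: int | None = None,
                   seed: int = 0) -> CohortAnalysis:
    """Run the full clonality pipeline on preprocessed, centered profiles.

    ``pairs`` defaults to all within-patient sample pairs.  The null is
    built from cross-patient pairs (optionally subsampled to
    ``null_max_pairs``) using the same marginals and configuration.
    """
    clon_config = clon_config or ClonalityConfig()
    class_config = class_config or ClassificationConfig()
    patient_of = {p.sample_id: p.patient_id for p in profiles}
    segmentations = segment_cohort(profiles, track, seg_config)
    marginals = estimate_marginals(segmentations, clon_config)
    rng = np.random.default_rng(seed)
    null = build_reference(segmentations, patient_of, marginals, clon_config,
                           max_pairs=null_max_pairs, rng=rng)
    if pairs is None:
        pairs = within_patient_pairs(profiles)
    results = []
    for a, b in pairs:
        if clon_config.leave_pair_out:
            marg = estimate_marginals(segmentations, clon_config, exclude=(a, b))
        else:
            marg = marginals
        r = pair_loglr(segmentations[a], segmentations[b], marg, clon_config,
                       sample1=a, sample2=b)
        r.patient1 = patient_of[a]
        r.patient2 = patient_of[b]
        results.append(evaluate_pair(r, null, class_config))
    return CohortAnalysis(segmentations, marginals, null, results, patient_of)
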