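"""Probe-level preprocessing: log-ratio computation against a normal-tissue
reference, germline-CNV probe exclusion, block averaging, median centering.

The pipeline mirrors standard SNP-array practice: intensities are referenced
to the average of normal samples, probes in known germline CNV regions are
removed, and resolution is reduced by averaging blocks of ``block_size``
adjacent markers (default 100) so that per-marker noise shrinks by roughly
1/sqrt(block_size).  Blocks are anchored at the start of each chromosome arm
and never span an arm boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import GenomeLayout, MarkerTrack, RegionSet, SampleProfile


@dataclass
class PreprocessConfig:
    block_size: int = 100
    min_final_block_fraction: float = 0.5  # trailing block >= this fraction keeps its own marker
    exclude_cnv_probes: bool = True

    def __post_init__(self):
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if not (0 < self.min_final_block_fraction <= 1):
            raise ValueError("min_final_block_fraction must be in (0, 1]")


def compute_log_ratios(intensities: pd.DataFrame, normal_ids: Sequence[str],
                       sample_info: dict[str, tuple[str, str]] | None = None,
                       ) -> list[SampleProfile]:
    """log2 ratio of each sample's probe intensity to the mean over normals.

    ``intensities`` is a probes x samples DataFrame of positive intensities.
    Normal samples are included in the output; their values scatter around 0.
    ``sample_info`` optionally maps sample id -> (patient id, lesion label).
    """
    normal_ids = list(normal_ids)
    if not normal_ids:
        raise ValueError("at least one normal sample id is required")
    missing = [s for s in normal_ids if s not in intensities.columns]
    if missing:
        raise ValueError(f"normal samples absent from matrix: {missing}")
    mat = intensities.to_numpy(dtype=float)
    if np.any(~np.isfinite(mat)) or np.any(mat <= 0):
        raise ValueError("intensities must be finite and strictly positive")
    ref = intensities[normal_ids].to_numpy(dtype=float).mean(axis=1)
    profiles = []
    for s in intensities.columns:
        patient, lesion = (sample_info or {}).get(s, (s, "NA"))
        vals = np.log2(intensities[s].to_numpy(dtype=float) / ref)
        profiles.append(SampleProfile(s, patient, lesion, vals))
    return profiles


def exclude_cnv_probes(track: MarkerTrack, profiles: Sequence[SampleProfile],
                       regions: RegionSet,
                       ) -> tuple[MarkerTrack, list[SampleProfile], int]:
    """Drop markers whose position falls inside any germline CNV region.

    Returns the reduced track, reduced profiles, and the number of markers
    removed.
    """
    keep = np.array([not regions.contains(c, int(p))
                     for c, p in zip(track.chrom, track.pos)])
    n_removed = int((~keep).sum())
    new_track = MarkerTrack(track.chrom[keep], track.pos[keep],
                            track.arm[keep], track.layout)
    new_profiles = [p.with_values(p.values[keep]) for p in profiles]
    return new_track, new_profiles, n_removed


def _block_edges(n: int, config: PreprocessConfig) -> list[tuple[int, int]]:
    """Block boundaries (start, stop) for one arm of n markers.

    Full blocks of ``block_size``; a trailing partial block keeps its own
    marker when it holds at least ``block_size * min_final_block_fraction``
    markers, otherwise it is merged into the previous block.  An arm smaller
    than one block is kept as a single block.
    """
    B = config.block_size
    if n == 0:
        return []
    edges = [(s, min(s + B, n)) for s in range(0, n, B)]
    if len(edges) > 1:
        last = edges[-1]
        if (last[1] - last[0]) < B * config.min_final_block_fraction:
            edges[-2] = (edges[-2][0], last[1])
            edges.pop()
    return edges


def block_average(track: MarkerTrack, profiles: Sequence[SampleProfile],
                  config: PreprocessConfig | None = None,
                  ) -> tuple[MarkerTrack, list[SampleProfile]]:
    """Collapse runs of adjacent markers within each arm to block means.

    Each output marker sits at the mean position of its block and carries
    the mean log-ratio over non-missing inputs (NaN only if every input in
    the block is missing).  Blocks never span arm boundaries.
    """
    config = config or PreprocessConfig()
    n_arms = len(track.layout)
    out_chrom, out_pos, out_arm = [], [], []
    block_index: list[np.ndarray] = []  # marker indices per output block
    for a in range(n_arms):
        sl = track.arm_slice(a)
        n = sl.stop - sl.start
        for s, e in _block_edges(n, config):
            idx = np.arange(sl.start + s, sl.start + e)
            block_index.append(idx)
            out_chrom.append(track.chrom[sl.start])
            out_pos.append(int(round(track.pos[idx].mean())))
            out_arm.append(a)
    new_track = MarkerTrack(np.array(out_chrom, dtype=object),
                            np.array(out_pos, dtype=np.int64),
                            np.array(out_arm, dtype=np.int32), track.layout)
    new_profiles = []
    for p in profiles:
        vals = np.empty(len(block_index))
        for k, idx in enumerate(block_index):
            block = p.values[idx]
            finite = block[np.isfinite(block)]
            vals[k] = finite.mean() if finite.size else np.nan
        new_profiles.append(p.with_values(vals))
    return new_track, new_profiles


def median_center(profile: SampleProfile) -> SampleProfile:
    """Subtract the genome-wide median so the diploid baseline sits at 0."""
    finite = profile.values[np.isfinite(profile.values)]
    if finite.size == 0:
        raise ValueError(f"{profile.sample_id}: all values missing")
    return profile.with_values(profile.values - np.median(finite))
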