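"""Single-change-per-arm segmentation and arm-level gain/loss calling.

Each chromosome arm receives at most one copy-number change.  The change
statistic for a candidate interval (i..j) on an arm of m markers is

    T(i, j) = (mean inside - mean outside) / (sigma * sqrt(1/n_in + 1/n_out))

maximised in absolute value over all intervals of at least
``min_segment_markers`` markers; when the interval is the whole arm the
statistic is the whole-arm z-score mean / (sigma / sqrt(m)).  The arm is
then classified from the central segment (two breakpoints) or the more
outstanding of the two segments (one breakpoint), gated by a minimum call
magnitude.  Short called segments overlapping known germline CNV regions
are reset to NORMAL.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .genome_io import MarkerTrack, RegionSet, SampleProfile

logger = logging.getLogger(__name__)

SIGMA_FLOOR = 1e-6


class ArmCall(enum.Enum):
    GAIN = "GAIN"
    LOSS = "LOSS"
    NORMAL = "NORMAL"


@dataclass
class SegmentationConfig:
    change_threshold: float = 5.0        # tau: |T| needed to declare a change
    min_call_magnitude: float = 0.10     # delta_min: |segment mean| needed for a call
    min_segment_markers: int = 3
    min_retained_segment_bp: int = 2_300_000  # shorter called segments overlapping a CNV are dropped
    cnv_regions: RegionSet | None = None

    def __post_init__(self):
        if self.change_threshold <= 0 or self.min_call_magnitude <= 0:
            raise ValueError("change_threshold and min_call_magnitude must be positive")
        if self.min_segment_markers < 1 or self.min_retained_segment_bp <= 0:
            raise ValueError("min_segment_markers and min_retained_segment_bp must be positive")


@dataclass(frozen=True)
class Segment:
    """Contiguous marker run within an arm (offsets inclusive) and its mean."""
    start: int
    end: int
    mean: float


@dataclass
class ArmSegmentation:
    """Result of one-change segmentation of a single arm.

    Offsets (breakpoints, segments, footprint) are marker offsets within the
    arm, 0-based inclusive.  ``footprint`` is the calling segment's offset
    range, or None for a NORMAL arm.  Segments tile the arm's markers.
    """

    arm_index: int
    breakpoints: tuple[int, ...]  # start offsets of second/third segment
    segments: list[Segment]
    call: ArmCall
    magnitude: float
    footprint: tuple[int, int] | None
    t_max: float
    cnv_filtered: bool = False

    @property
    def n_markers(self) -> int:
        return self.segments[-1].end + 1 if self.segments else 0

    def footprint_indices(self) -> np.ndarray:
        if self.footprint is None:
            return np.empty(0, dtype=np.int64)
        return np.arange(self.footprint[0], self.footprint[1] + 1)

    def is_whole_arm(self) -> bool:
        return (self.footprint is not None and self.footprint[0] == 0
                and self.footprint[1] == self.n_markers - 1)


def estimate_noise(profile: SampleProfile, track: MarkerTrack) -> float:
    """Robust per-marker noise scale from within-arm first differences.

    sigma_hat = 1.4826 * median(|diff|) / sqrt(2), computed within each arm
    and pooled across arms by the median, so isolated true change-points
    contribute a single outlying difference and do not inflate the estimate.
    """
    values = profile.values
    if np.isfinite(values).sum() < 10:
        raise ValueError("need at least 10 non-missing markers to estimate noise")
    per_arm = []
    for a in range(len(track.layout)):
        v = values[track.arm_slice(a)]
        v = v[np.isfinite(v)]
        if v.size >= 2:
            per_arm.append(np.median(np.abs(np.diff(v))))
    if not per_arm:
        raise ValueError("no arm has enough markers to estimate noise")
    return 1.4826 * float(np.median(per_arm)) / np.sqrt(2.0)


def _interval_geometry(m: int, min_markers: int):
    """Cached (denominator, valid-mask) matrices for arms of m markers.

    For interval (i..j): L = j - i + 1 markers inside, n_out = m - L
    outside.  The change statistic simplifies algebraically to

        T = (m * S_in - S_total * L) / (sigma * sqrt(m * L * n_out))

    and the whole-arm z-score (L = m) to S_total / (sigma * sqrt(m)), so
    the denominator geometry depends only on m and can be shared across
    samples and arms of equal length.
    """
    key = (m, min_markers)
    cached = _GEOMETRY_CACHE.get(key)
    if cached is not None:
        return cached
    j = np.arange(m)
    L = j[None, :] - j[:, None] + 1  # may be <= 0 below the diagonal
    n_out = m - L
    valid = L >= min_markers
    with np.errstate(invalid="ignore"):
        denom = np.sqrt(np.maximum(m * L * n_out, 0).astype(np.float64))
    denom[0, m - 1] = np.sqrt(m)  # whole arm: z-score scaling of m*sums - total*L
    Lf = L.astype(np.float64)
    if len(_GEOMETRY_CACHE) > 64:
        _GEOMETRY_CACHE.clear()
    _GEOMETRY_CACHE[key] = (Lf, denom, valid)
    return Lf, denom, valid


_GEOMETRY_CACHE: dict = {}


def segment_arm(values: np.ndarray, sigma: float,
                config: SegmentationConfig) -> tuple[int, int, float]:
    """Best single-change interval on one arm.

    Returns (i, j, T): 0-based inclusive offsets of the interval maximising
    |T|, and the signed statistic.  Ties resolve to the smallest i, then the
    smallest j.  The whole-arm interval competes using the whole-arm
    z-score.  ``values`` must be finite.
    """
    x = np.asarray(values, dtype=np.float64)
    if np.any(~np.isfinite(x)):
        raise ValueError("segment_arm requires finite values")
    m = x.size
    if m < config.min_segment_markers:
        raise ValueError("arm shorter than min_segment_markers")
    sigma = max(float(sigma), SIGMA_FLOOR)
    S = np.concatenate(([0.0], np.cumsum(x)))
    total = S[-1]
    if m <= 2048:
        L, denom, valid = _interval_geometry(m, config.min_segment_markers)
        sums = S[None, 1:] - S[:-1, None]  # sums[i, j] = sum x[i..j]
        with np.errstate(divide="ignore", invalid="ignore"):
            T = (m * sums - total * L) / (sigma * denom)
        # whole-arm cell uses the z-score: (m*S_m - total*m)/.. would be 0
        T[0, m - 1] = total / (sigma * np.sqrt(m))
        absT = np.where(valid, np.abs(T), -1.0)
        vmax = float(absT.max())
        # an interval and its complement are exact ties in |T|; resolve ties
        # (up to float rounding) to the smallest (i, j) in scan order
        tol = _TIE_RTOL * max(vmax, 1.0)
        flat = int(np.argmax(absT.ravel() >= vmax - tol))
        i, j = divmod(flat, m)
        return i, j, float(T[i, j])
    return _segment_arm_chunked(S, total, m, sigma, config)


_TIE_RTOL = 1e-10


def _segment_arm_chunked(S, total, m, sigma, config):
    """Row-chunked scan for very long arms, bounding memory at O(chunk*m).

    Two passes: find the global maximum, then the first (i, j) reaching it
    within the tie tolerance, matching the dense path's tie-breaking.
    """
    j_all = np.arange(m, dtype=np.float64)
    chunk = max(1, 8_000_000 // m)

    def chunk_absT(i0, i1):
        i = np.arange(i0, i1, dtype=np.float64)[:, None]
        L = j_all[None, :] - i + 1
        n_out = m - L
        valid = L >= config.min_segment_markers
        sums = S[None, 1:] - S[i0:i1, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            T = (m * sums - total * L) / (sigma * np.sqrt(np.maximum(m * L * n_out, 0)))
        if i0 == 0:
            T[0, m - 1] = total / (sigma * np.sqrt(m))
        return T, np.where(valid, np.abs(T), -1.0)

    vmax = -np.inf
    for i0 in range(0, m, chunk):
        _, absT = chunk_absT(i0, min(i0 + chunk, m))
        vmax = max(vmax, float(absT.max()))
    tol = _TIE_RTOL * max(vmax, 1.0)
    for i0 in range(0, m, chunk):
        T, absT = chunk_absT(i0, min(i0 + chunk, m))
        hits = absT.ravel() >= vmax - tol
        if hits.any():
            flat = int(np.argmax(hits))
            r, c = divmod(flat, m)
            return i0 + r, c, float(T[r, c])
    raise RuntimeError("unreachable: maximum not found on second pass")


def whole_arm_z(values: np.ndarray, sigma: float) -> float:
    x = np.asarray(values, dtype=np.float64)
    sigma = max(float(sigma), SIGMA_FLOOR)
    return float(x.mean() / (sigma / np.sqrt(x.size)))


def classify_arm(values: np.ndarray, candidate: tuple[int, int, float],
                 sigma: float, config: SegmentationConfig,
                 arm_index: int = 0) -> ArmSegmentation:
    """Turn the best single-change interval into an arm-level call.

    NORMAL if neither the interval statistic nor the whole-arm z-score
    reaches the change threshold.  Otherwise the calling segment is the
    central segment (two breakpoints), the more outstanding of the two
    segments (one breakpoint), or the whole arm (none); the call is GAIN /
    LOSS when the calling segment's mean clears the magnitude gate.
    """
    x = np.asarray(values, dtype=np.float64)
    m = x.size
    i, j, T = candidate
    z = whole_arm_z(x, sigma)

    def seg(a: int, b: int) -> Segment:
        return Segment(a, b, float(x[a:b + 1].mean()))

    if abs(T) < config.change_threshold and abs(z) < config.change_threshold:
        return ArmSegmentation(arm_index, (), [seg(0, m - 1)],
                               ArmCall.NORMAL, 0.0, None, float(T))
    if abs(T) < config.change_threshold:  # only the whole-arm shift is significant
        i, j = 0, m - 1

    parts: list[Segment] = []
    if i > 0:
        parts.append(seg(0, i - 1))
    parts.append(seg(i, j))
    if j < m - 1:
        parts.append(seg(j + 1, m - 1))
    breakpoints = tuple(s.start for s in parts[1:])

    if i > 0 and j < m - 1:          # two breakpoints: central segment calls
        calling = parts[1] if len(parts) == 3 else parts[0]
    elif i == 0 and j == m - 1:      # no breakpoint: whole arm calls
        calling = parts[0]
    else:                            # one breakpoint: most outstanding segment
        calling = max(parts, key=lambda s: (abs(s.mean), s.start == i))
    mean_call = calling.mean
    if mean_call >= config.min_call_magnitude:
        call = ArmCall.GAIN
    elif mean_call <= -config.min_call_magnitude:
        call = ArmCall.LOSS
    else:
        call = ArmCall.NORMAL
    if call is ArmCall.NORMAL:
        return ArmSegmentation(arm_index, breakpoints, parts,
                               ArmCall.NORMAL, 0.0, None, float(T))
    return ArmSegmentation(arm_index, breakpoints, parts, call,
                           float(mean_call), (calling.start, calling.end),
                           float(T))


def filter_cnv_segment(armseg: ArmSegmentation, track: MarkerTrack,
                       regions: RegionSet | None,
                       config: SegmentationConfig) -> ArmSegmentation:
    """Reset short called segments that overlap known germline CNV regions.

    A non-NORMAL arm whose calling-segment genomic span is below
    ``min_retained_segment_bp`` and overlaps any region by >= 1 bp is reset
    to NORMAL (breakpoints cleared, magnitude 0): such segments are likelier
    inherited copy-number variants than somatic events.
    """
    if regions is None or armseg.call is ArmCall.NORMAL or armseg.footprint is None:
        return armseg
    sl = track.arm_slice(armseg.arm_index)
    pos = track.pos[sl]
    chrom = track.chrom[sl.start]
    a, b = armseg.footprint
    span_start, span_end = int(pos[a]), int(pos[b])
    span_bp = span_end - span_start + 1
    if span_bp < config.min_retained_segment_bp and regions.overlaps(chrom, span_start, span_end):
        m = armseg.n_markers
        total = sum(s.mean * (s.end - s.start + 1) for s in armseg.segments)
        return ArmSegmentation(armseg.arm_index, (), [Segment(0, m - 1, total / m)],
                               ArmCall.NORMAL, 0.0, None, armseg.t_max,
                               cnv_filtered=True)
    return armseg


def segment_profile(profile: SampleProfile, track: MarkerTrack,
                    config: SegmentationConfig | None = None,
                    sigma: float | None = None) -> list[ArmSegmentation]:
    """Segment every arm of one preprocessed, median-centered profile.

    The noise scale is estimated once per sample and shared across arms;
    arms are independent, so processing order does not matter.  Arms with
    too few usable markers are returned NORMAL.
    """
    config = config or SegmentationConfig()
    if sigma is None:
        sigma = estimate_noise(profile, track)
    out: list[ArmSegmentation] = []
    for a in range(len(track.layout)):
        sl = track.arm_slice(a)
        v = profile.values[sl]
        finite = np.flatnonzero(np.isfinite(v))
        if finite.size < 2 * config.min_segment_markers:
            mean = float(np.nanmean(v)) if finite.size else 0.0
            n = max(v.size, 1)
            out.append(ArmSegmentation(a, (), [Segment(0, n - 1, mean)],
                                       ArmCall.NORMAL, 0.0, None, 0.0))
            continue
        clean = v[finite]
        ci, cj, T = segment_arm(clean, sigma, config)
        seg = classify_arm(clean, (ci, cj, T), sigma, config, arm_index=a)
        if finite.size != v.size:
            seg = _remap_to_arm_offsets(seg, finite, v.size)
        seg = filter_cnv_segment(seg, track, config.cnv_regions, config)
        out.append(seg)
    return out


def _remap_to_arm_offsets(seg: ArmSegmentation, finite_idx: np.ndarray,
                          n_arm: int) -> ArmSegmentation:
    """Map clean-value offsets back onto arm offsets when NaNs were skipped.

    Tiled segments absorb interleaved missing markers: each segment starts
    where the previous one ended (+1) and the last ends at the arm's final
    marker; means are unchanged (computed over non-missing values).
    """
    parts = []
    prev_end = -1
    for k, s in enumerate(seg.segments):
        start = prev_end + 1
        end = int(finite_idx[s.end]) if k < len(seg.segments) - 1 else n_arm - 1
        parts.append(Segment(start, end, s.mean))
        prev_end = end
    breakpoints = tuple(s.start for s in parts[1:])
    footprint = seg.footprint
    if footprint is not None:
        footprint = (int(finite_idx[footprint[0]]), int(finite_idx[footprint[1]]))
    return replace(seg, breakpoints=breakpoints, segments=parts,
                   footprint=footprint)


def call_table(segmentations: dict[str, list[ArmSegmentation]],
               track: MarkerTrack):
    """Per-arm call table: one row per (sample, arm)."""
    import pandas as pd

    rows = []
    layout = track.layout
    for sample, segs in segmentations.items():
        for seg in segs:
            arm = layout.arms[seg.arm_index]
            sl = track.arm_slice(seg.arm_index)
            pos = track.pos[sl] if sl.stop > sl.start else None
            if seg.footprint is not None and pos is not None:
                a, b = seg.footprint
                span = int(pos[b]) - int(pos[a]) + 1
                n_mark = b - a + 1
            else:
                span, n_mark = 0, 0
            rows.append(dict(sample=sample, chrom=arm.chrom, arm=arm.arm,
                             call=seg.call.value, magnitude=seg.magnitude,
                             span_bp=span, n_markers=n_mark, T=seg.t_max))
    return pd.DataFrame(rows)
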