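"""Data model and I/O for marker maps, copy-number profiles, interval sets and
segmentation output.

Coordinates are 1-based inclusive throughout the package; BED input
(0-based, half-open) is converted at the boundary.  Marker order is the total
order (chromosome rank in the layout, then position) and is shared by every
sample in an analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

MISSING_FRACTION_LIMIT = 0.20


@dataclass(frozen=True)
class Arm:
    """One chromosome arm: a contiguous 1-based inclusive span."""

    chrom: str
    arm: str  # "p" or "q"
    start: int
    end: int

    @property
    def name(self) -> str:
        return f"{self.chrom}{self.arm}"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class GenomeLayout:
    """Ordered set of chromosome arms, the unit of analysis for arm calling.

    Arms are kept in (chromosome, position) order; p precedes q.  The
    packaged default covers the 39 autosomal arms (acrocentric p-arms of
    chromosomes 13, 14, 15, 21 and 22 are omitted, the standard convention
    for SNP-array copy-number work), with hg19-scale coordinates.
    """

    def __init__(self, arms: Sequence[Arm]):
        arms = list(arms)
        if not arms:
            raise ValueError("layout must contain at least one arm")
        seen_chrom: list[str] = []
        for a in arms:
            if a.start >= a.end:
                raise ValueError(f"arm {a.name}: start must be < end")
            if a.chrom not in seen_chrom:
                seen_chrom.append(a.chrom)
        # validate ordering / non-overlap within chromosome
        by_chrom: dict[str, list[Arm]] = {}
        for a in arms:
            by_chrom.setdefault(a.chrom, []).append(a)
        for chrom, ca in by_chrom.items():
            for prev, nxt in zip(ca, ca[1:]):
                if nxt.start <= prev.end:
                    raise ValueError(f"arms overlap on {chrom}")
                if prev.arm == "q" and nxt.arm == "p":
                    raise ValueError(f"p must precede q on {chrom}")
        self.arms: tuple[Arm, ...] = tuple(arms)
        self._chrom_rank = {c: i for i, c in enumerate(seen_chrom)}
        self._by_name = {a.name: i for i, a in enumerate(arms)}

    def __len__(self) -> int:
        return len(self.arms)

    def __iter__(self):
        return iter(self.arms)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._chrom_rank, key=self._chrom_rank.get)

    def chrom_rank(self, chrom: str) -> int:
        return self._chrom_rank[chrom]

    def index_of(self, name: str) -> int:
        """Arm index by name, e.g. ``"chr1q"``."""
        return self._by_name[name]

    def arm_index(self, chrom: str, pos: int) -> int:
        """Index of the arm containing (chrom, pos), or -1 if none."""
        for i, a in enumerate(self.arms):
            if a.chrom == chrom and a.start <= pos <= a.end:
                return i
        return -1

    @classmethod
    def from_table(cls, path: str | Path) -> "GenomeLayout":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "arm": str})
        required = {"chrom", "arm", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"layout table needs columns {sorted(required)}")
        return cls([Arm(r.chrom, r.arm, int(r.start), int(r.end))
                    for r in df.itertuples()])

    @classmethod
    def default(cls) -> "GenomeLayout":
        ref = resources.files("cnclonality.data") / "arms_autosomal_hg19.tsv"
        with resources.as_file(ref) as p:
            return cls.from_table(p)


@dataclass
class MarkerTrack:
    """Ordered genome-wide marker map shared by all samples of an analysis.

    ``arm`` holds the index of each marker's arm in the layout.  Markers are
    sorted by (chromosome rank, position) and strictly increasing in
    position within a chromosome.
    """

    chrom: np.ndarray  # object array of chromosome labels
    pos: np.ndarray  # int64 positions, 1-based
    arm: np.ndarray  # int32 arm indices into layout
    layout: GenomeLayout

    def __post_init__(self):
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.arm = np.asarray(self.arm, dtype=np.int32)
        if not (len(self.chrom) == len(self.pos) == len(self.arm)):
            raise ValueError("chrom/pos/arm must have equal length")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) <= 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def n_markers(self) -> int:
        return len(self.pos)

    def arm_slice(self, arm_index: int) -> slice:
        """Contiguous slice of marker indices on one arm."""
        idx = np.flatnonzero(self.arm == arm_index)
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def arm_slices(self) -> dict[int, slice]:
        return {a: self.arm_slice(a) for a in range(len(self.layout))}

    @classmethod
    def from_positions(cls, chrom: Iterable[str], pos: Iterable[int],
                       layout: GenomeLayout) -> tuple["MarkerTrack", np.ndarray, int]:
        """Build a sorted track; returns (track, keep-order index, n dropped).

        Markers falling inside no layout arm (centromeric, off-layout
        chromosomes) are dropped with a logged count.  The returned index
        maps rows of the input onto rows of the track, so per-sample value
        vectors can be reordered consistently.
        """
        chrom = np.asarray(list(chrom), dtype=object)
        pos = np.asarray(list(pos), dtype=np.int64)
        arm = np.array([layout.arm_index(c, p) for c, p in zip(chrom, pos)],
                       dtype=np.int32)
        keep = arm >= 0
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.warning("dropped %d markers outside the arm layout", n_dropped)
        chrom, pos, arm = chrom[keep], pos[keep], arm[keep]
        rank = np.array([layout.chrom_rank(c) for c in chrom])
        order = np.lexsort((pos, rank))
        track = cls(chrom[order], pos[order], arm[order], layout)
        src = np.flatnonzero(keep)[order]
        return track, src, n_dropped


@dataclass
class SampleProfile:
    """One tumor's marker-level log2 copy-number ratios plus identifiers.

    ``values`` aligns 1:1 with a :class:`MarkerTrack`; missing values are
    NaN.  Profiles with more than 20% missing markers are rejected.
    """

    sample_id: str
    patient_id: str
    lesion: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.values.size
        if n == 0:
            raise ValueError(f"{self.sample_id}: empty profile")
        frac_missing = float(np.isnan(self.values).sum()) / n
        if frac_missing > MISSING_FRACTION_LIMIT:
            raise ValueError(
                f"{self.sample_id}: {frac_missing:.0%} missing exceeds "
                f"{MISSING_FRACTION_LIMIT:.0%} limit")

    def __len__(self) -> int:
        return len(self.values)

    def with_values(self, values: np.ndarray) -> "SampleProfile":
        return replace(self, values=np.asarray(values, dtype=np.float64))


class RegionSet:
    """Genomic intervals (germline CNV regions), 1-based inclusive,
    queryable for any-overlap."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for chrom, start, end in intervals:
            self.add(chrom, start, end)

    def add(self, chrom: str, start: int, end: int) -> None:
        if start > end:
            raise ValueError(f"interval {chrom}:{start}-{end}: start > end")
        # intervaltree is half-open; store [start, end+1)
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end + 1)
        self._n += 1

    def __len__(self) -> int:
        return self._n

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True if any stored interval overlaps [start, end] by >= 1 bp."""
        tree = self._trees.get(chrom)
        if tree is None:
            return False
        return bool(tree.overlap(start, end + 1))

    def contains(self, chrom: str, pos: int) -> bool:
        return self.overlaps(chrom, pos, pos)

    def intervals(self) -> list[tuple[str, int, int]]:
        out = []
        for chrom, tree in self._trees.items():
            for iv in sorted(tree):
                out.append((chrom, iv.begin, iv.end - 1))
        return out


# ---------------------------------------------------------------------------
# readers / writers

PROFILE_COLUMNS = ["sample", "patient", "lesion", "chrom", "pos", "logratio"]


def read_profile_table(path: str | Path, layout: GenomeLayout
                       ) -> tuple[MarkerTrack, list[SampleProfile]]:
    """Read a tab-delimited marker-level profile table.

    Expected header columns: sample, patient, lesion, chrom, pos, logratio.
    All samples must carry the identical marker set; markers outside the
    layout are dropped (with a logged count).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     na_values=["NA", "nan", ""])
    missing_cols = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    pos = pd.to_numeric(df["pos"], errors="coerce")
    bad = pos.isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
        raise ValueError(f"{path}: malformed pos field at line {line}")
    lr = pd.to_numeric(df["logratio"], errors="coerce")
    bad = lr.isna() & df["logratio"].notna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise ValueError(f"{path}: malformed logratio field at line {line}")
    df = df.assign(pos=pos.astype(np.int64), logratio=lr.astype(float))

    samples = list(dict.fromkeys(df["sample"]))
    groups = {s: g for s, g in df.groupby("sample", sort=False)}
    first = groups[samples[0]]
    key0 = list(zip(first["chrom"], first["pos"]))
    for s in samples[1:]:
        key = list(zip(groups[s]["chrom"], groups[s]["pos"]))
        if sorted(key) != sorted(key0):
            raise ValueError(f"{path}: marker set of sample {s!r} differs "
                             f"from sample {samples[0]!r}")

    track, src, _ = MarkerTrack.from_positions(first["chrom"], first["pos"], layout)
    profiles = []
    for s in samples:
        g = groups[s].sort_values(["chrom", "pos"], kind="mergesort")
        # align to the first sample's (chrom,pos) ordering, then to the track
        gmap = {(c, p): v for c, p, v in zip(g["chrom"], g["pos"], g["logratio"])}
        vals = np.array([gmap[k] for k in key0], dtype=float)
        profiles.append(SampleProfile(
            sample_id=s,
            patient_id=str(groups[s]["patient"].iloc[0]),
            lesion=str(groups[s]["lesion"].iloc[0]),
            values=vals[src]))
    return track, profiles


def write_profile_table(path: str | Path, track: MarkerTrack,
                        profiles: Sequence[SampleProfile]) -> None:
    """Write profiles in the tab-delimited format read_profile_table expects."""
    with open(path, "w") as fh:
        fh.write("\t".join(PROFILE_COLUMNS) + "\n")
        for p in profiles:
            for c, pos, v in zip(track.chrom, track.pos, p.values):
                sval = "NA" if np.isnan(v) else f"{v:.6f}"
                fh.write(f"{p.sample_id}\t{p.patient_id}\t{p.lesion}\t"
                         f"{c}\t{pos}\t{sval}\n")


def read_region_bed(path: str | Path,
                    layout: GenomeLayout | None = None) -> RegionSet:
    """Read a BED file (0-based half-open) into a 1-based inclusive RegionSet.

    Only the first three columns are used.  If a layout is given, intervals
    on chromosomes absent from it are skipped with a warning.
    """
    known = set(layout.chromosomes) if layout is not None else None
    regions = RegionSet()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}: line {lineno}: start >= end")
            if known is not None and chrom not in known:
                logger.warning("%s: line %d: unknown chromosome %r skipped",
                               path, lineno, chrom)
                continue
            regions.add(chrom, start + 1, end)  # BED -> 1-based inclusive
    return regions


def write_seg(path: str | Path, track: MarkerTrack,
              segmentations: dict[str, list]) -> None:
    """Write per-arm segmentations as a SEG table (IGV dialect).

    One row per segment, including unchanged flanks; rows tile each arm's
    markers exactly.  ``segmentations`` maps sample id to a list of
    ArmSegmentation (one per arm, layout order).
    """
    with open(path, "w") as fh:
        fh.write("ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n")
        for sample, segs in segmentations.items():
            for seg in segs:
                sl = track.arm_slice(seg.arm_index)
                if sl.stop == sl.start:
                    continue
                pos = track.pos[sl]
                chrom = track.chrom[sl.start]
                for s in seg.segments:
                    fh.write(f"{sample}\t{chrom}\t{pos[s.start]}\t{pos[s.end]}"
                             f"\t{s.end - s.start + 1}\t{s.mean:.6f}\n")


def read_seg(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
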