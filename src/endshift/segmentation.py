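"""Annotation-agnostic expressed-region detection and differential
segmentation of per-base coverage within loci.

Replicate coverage profiles of a locus are first area-normalised (each
profile scaled so its area equals the mean area over all profiles).
Expressed regions are maximal runs where mean normalised coverage is at
least 1.  Expressed regions are then split wherever the treatment/
control log-ratio changes by at least two-fold within a trailing 25-nt
window, and segments shorter than 50 nt are merged away.  The resulting
segment x sample fragment-count table is exported for downstream
differential-usage tools.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .read_io import ValidationError


class AllZeroCoverage(ValueError):
    """All profiles of a locus have zero area; the locus is skipped."""


@dataclass
class CoverageProfile:
    locus_id: str
    sample_id: str
    condition: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValidationError(f"profile {self.sample_id}: negative coverage")

    @property
    def area(self) -> float:
        return float(self.values.sum())


@dataclass(frozen=True)
class CoverageSegment:
    locus_id: str
    chrom: str
    start: int
    end: int
    kind: str  # "expressed" or "differential-boundary-delimited"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValidationError("empty coverage segment")


def normalize_profiles(profiles: Sequence[CoverageProfile]) -> list[CoverageProfile]:
    """Scale each profile so its area equals the mean area of all
    profiles of the locus.  Zero-area profiles are left as zeros."""
    if not profiles:
        raise ValidationError("no profiles supplied")
    lengths = {p.values.size for p in profiles}
    if len(lengths) != 1:
        raise ValidationError("profiles of one locus must share a length")
    areas = np.array([p.area for p in profiles])
    if np.all(areas == 0):
        raise AllZeroCoverage(profiles[0].locus_id)
    mean_area = areas.mean()
    out = []
    for p, area in zip(profiles, areas):
        scaled = p.values * (mean_area / area) if area > 0 else p.values.copy()
        out.append(CoverageProfile(p.locus_id, p.sample_id, p.condition, scaled))
    return out


def detect_expressed_regions(
    profiles: Sequence[CoverageProfile], threshold: float = 1.0
) -> list[tuple[int, int]]:
    """Maximal runs where the mean normalised coverage across all
    samples is at least ``threshold``; intervals are locus-relative,
    0-based half-open."""
    if not profiles:
        return []
    mean_cov = np.mean([p.values for p in profiles], axis=0)
    above = mean_cov >= threshold
    edges = np.diff(above.astype(np.int8))
    starts = list(np.nonzero(edges == 1)[0] + 1)
    ends = list(np.nonzero(edges == -1)[0] + 1)
    if above.size and above[0]:
        starts.insert(0, 0)
    if above.size and above[-1]:
        ends.append(above.size)
    return list(zip(starts, ends))


def _boundaries_in_interval(r: np.ndarray, window: int, log2_fold: float) -> list[int]:
    """Candidate differential boundaries inside one expressed interval.

    A position is a candidate when the range (max - min) of the
    log-ratio over the trailing ``window`` nt reaches ``log2_fold``.
    Candidate runs closer than ``window`` are merged and each merged run
    is represented by its steepest position (largest one-step log-ratio
    change), which for a clean step is the step itself.
    """
    n = r.size
    if n <= window:
        return []
    candidates = []
    for p in range(1, n):
        w = r[max(0, p - window + 1): p + 1]
        if w.max() - w.min() >= log2_fold:
            candidates.append(p)
    if not candidates:
        return []
    clusters: list[list[int]] = [[candidates[0]]]
    for p in candidates[1:]:
        if p - clusters[-1][-1] < window:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    boundaries = []
    step = np.abs(np.diff(r))
    for cluster in clusters:
        lo = max(1, cluster[0] - window + 1)
        hi = cluster[-1]
        span = step[lo - 1: hi]
        b = lo + int(np.argmax(span))
        if 0 < b < n:
            boundaries.append(b)
    return boundaries


def segment_differential(
    expressed: Sequence[tuple[int, int]],
    mean_treatment: np.ndarray,
    mean_control: np.ndarray,
    locus_id: str = "",
    chrom: str = "",
    window: int = 25,
    fold: float = 2.0,
    min_len: int = 50,
    pseudocount: float = 1.0,
) -> list[CoverageSegment]:
    """Split expressed intervals at treatment/control fold-change
    boundaries and drop sub-``min_len`` pieces by merging them into the
    neighbour with the closer mean log-ratio."""
    if window <= 0 or fold <= 0 or min_len <= 0:
        raise ValidationError("window, fold and min_len must be positive")
    trt = np.asarray(mean_treatment, float)
    ctl = np.asarray(mean_control, float)
    log2_fold = np.log2(fold)
    ratio = np.log2((trt + pseudocount) / (ctl + pseudocount))
    segments: list[CoverageSegment] = []
    for start, end in expressed:
        r = ratio[start:end]
        bounds = _boundaries_in_interval(r, window, log2_fold)
        pieces = []
        edges = [0] + bounds + [end - start]
        for lo, hi in zip(edges[:-1], edges[1:]):
            pieces.append([lo, hi])
        # merge sub-minimum pieces into the log-ratio-closer neighbour
        while len(pieces) > 1 and min(hi - lo for lo, hi in pieces) < min_len:
            i = min(range(len(pieces)), key=lambda j: pieces[j][1] - pieces[j][0])
            if pieces[i][1] - pieces[i][0] >= min_len:
                break
            own = r[pieces[i][0]:pieces[i][1]].mean()
            left = i - 1 if i > 0 else None
            right = i + 1 if i < len(pieces) - 1 else None

            def dist(j):
                return abs(r[pieces[j][0]:pieces[j][1]].mean() - own)

            if left is not None and (right is None or dist(left) <= dist(right)):
                pieces[left][1] = pieces[i][1]
            else:
                pieces[right][0] = pieces[i][0]
            del pieces[i]
        kind = "expressed" if not bounds else "differential-boundary-delimited"
        for lo, hi in pieces:
            if hi - lo >= min_len:
                segments.append(CoverageSegment(locus_id, chrom, start + lo, start + hi, kind))
    return segments


@dataclass(frozen=True)
class Fragment:
    """Outer span of a read pair, with the flags fragment counting needs."""

    fragment_id: str
    chrom: str
    start: int
    end: int
    sample_id: str
    is_proper_pair: bool = True
    is_primary: bool = True


def count_fragments(
    segments: Sequence[CoverageSegment],
    fragments: Sequence[Fragment],
    mode: str = "multi",
) -> pd.DataFrame:
    """Count eligible fragments per segment and sample.

    Only properly paired, primary fragments are counted; each read pair
    counts once.  In ``multi`` mode a fragment overlapping k segments
    increments each; ``largest`` assigns it only to the segment with the
    greatest overlap (ties: first segment in sorted order).
    """
    if mode not in ("multi", "largest"):
        raise ValidationError(f"unknown counting mode {mode!r}")
    samples = sorted({f.sample_id for f in fragments})
    seg_order = sorted(range(len(segments)), key=lambda i: (segments[i].chrom, segments[i].start))
    counts = np.zeros((len(segments), len(samples)), dtype=int)
    sample_idx = {s: j for j, s in enumerate(samples)}
    for frag in fragments:
        if not (frag.is_proper_pair and frag.is_primary):
            continue
        overlaps = []
        for i in seg_order:
            seg = segments[i]
            if seg.chrom != frag.chrom:
                continue
            ov = min(seg.end, frag.end) - max(seg.start, frag.start)
            if ov > 0:
                overlaps.append((i, ov))
        if not overlaps:
            continue
        j = sample_idx[frag.sample_id]
        if mode == "multi":
            for i, _ in overlaps:
                counts[i, j] += 1
        else:
            best = max(overlaps, key=lambda t: t[1])[0]
            counts[best, j] += 1
    rows = []
    for i in seg_order:
        seg = segments[i]
        rows.append({
            "segment_id": f"{seg.locus_id}:{seg.start}-{seg.end}",
            "chrom": seg.chrom, "start": seg.start, "end": seg.end,
            "length": seg.end - seg.start,
            **{s: counts[i, sample_idx[s]] for s in samples},
        })
    return pd.DataFrame(rows)
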