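"""Variational-signature scanning: alignment file -> eight meta-features.

The scanner does not call SVs. It estimates, quickly and approximately, the
dataset-level descriptors that separate SV callers from each other:

* file level — average read length and average sequencing depth;
* signature level — the size-class mix of candidate SVs (short 50-200 bp,
  middle 200-1,000 bp, large >1,000 bp), the fraction falling in tandem
  repeat regions, the read variant burden (mean number of candidate SVs a
  read-length span traverses) and the fraction of such spans with high
  burden.

Candidate SVs are found by collecting soft-clipped read ends, clustering
their breakpoints per chromosome and clip side with single linkage, and
greedily pairing END-side clusters with downstream START-side clusters.
Paired clusters model deletion-like signals; the scanner does not
distinguish SV types, which is deliberate — only the aggregate feature
vector matters downstream.
"""

from __future__ import annotations

import os
from bisect import bisect_left
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .errors import EmptyInputError, ValidationError
from .formats import (
    AlignmentRecord,
    CIGAR_S,
    GenomicInterval,
    ScanReport,
    merge_intervals,
    read_alignments,
    read_repeat_intervals,
)

SIDE_START = "START"
SIDE_END = "END"

#: canonical ordering of the eight meta-features, used everywhere a vector is built
FEATURE_ORDER = (
    "avg_read_length",
    "avg_depth",
    "prop_sv_tr",
    "prop_short",
    "prop_middle",
    "prop_large",
    "rvb",
    "prop_high_rvb",
)

# size-class boundaries: short [50,200), middle [200,1000], large >1000
SV_FLOOR = 50
SHORT_MAX = 200
MIDDLE_MAX = 1000


@dataclass(frozen=True)
class SoftclipSignature:
    """One soft-clipped read end with its implied breakpoint."""

    read_id: str
    chrom: str
    side: str  # SIDE_START if the clip is the first CIGAR operation
    clip_length: int
    breakpoint: int  # 0-based reference coordinate


@dataclass(frozen=True)
class BreakpointCluster:
    """A single-linkage group of same-side breakpoints on one chromosome."""

    chrom: str
    side: str
    representative: int  # median member breakpoint (lower middle on ties)
    support: int


@dataclass(frozen=True)
class EstimatedSV:
    """A paired END/START breakpoint event; the gap estimates the SV size."""

    chrom: str
    left: int
    right: int

    def __post_init__(self) -> None:
        if self.right <= self.left:
            raise ValidationError("EstimatedSV requires right > left")

    @property
    def size(self) -> int:
        return self.right - self.left


@dataclass(frozen=True)
class MetaFeatureVector:
    """The eight dataset-level meta-features."""

    avg_read_length: float
    avg_depth: float
    prop_sv_tr: float
    prop_short: float
    prop_middle: float
    prop_large: float
    rvb: float
    prop_high_rvb: float

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, name) for name in FEATURE_ORDER)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_ORDER}


@dataclass
class ScanConfig:
    """Tunables of the scanning algorithm.

    min_clip: soft clips shorter than this are treated as sequencing-noise
        artifacts and ignored (bp).
    cluster_window: maximum gap between successive breakpoints in one
        single-linkage cluster (bp), absorbing long-read breakpoint jitter.
    min_sv / max_sv: admissible estimated SV sizes when pairing clusters (bp);
        the floor is the conventional 50 bp SV definition.
    rvb_high_threshold: a window counts as high-burden when at least this
        many estimated SVs intersect it.
    """

    min_clip: int = 20
    cluster_window: int = 100
    min_sv: int = SV_FLOOR
    max_sv: int = 100_000
    rvb_high_threshold: int = 2


def extract_softclip_signatures(
    records: Iterable[AlignmentRecord], min_clip: int = 20
) -> list[SoftclipSignature]:
    """Collect soft-clip signatures of at least ``min_clip`` bases.

    A START-side clip (first CIGAR operation) breaks at the record's mapped
    position; an END-side clip breaks at the end of the aligned span. A read
    clipped on both ends yields two signatures.
    """
    if min_clip < 1:
        raise ValidationError("min_clip must be >= 1")
    out: list[SoftclipSignature] = []
    for rec in records:
        if rec.is_unmapped or not rec.cigar:
            continue
        first_op, first_len = rec.cigar[0]
        if first_op == CIGAR_S and first_len >= min_clip:
            out.append(
                SoftclipSignature(rec.read_id, rec.chrom, SIDE_START, first_len, rec.pos)
            )
        last_op, last_len = rec.cigar[-1]
        if len(rec.cigar) > 1 and last_op == CIGAR_S and last_len >= min_clip:
            out.append(
                SoftclipSignature(
                    rec.read_id, rec.chrom, SIDE_END, last_len, rec.reference_end
                )
            )
    return out


def _median_lower(sorted_vals: Sequence[int]) -> int:
    # lower of the two middles for even counts
    return sorted_vals[(len(sorted_vals) - 1) // 2]


def cluster_breakpoints(
    signatures: Iterable[SoftclipSignature], window: int = 100
) -> list[BreakpointCluster]:
    """Single-linkage clustering of breakpoints per (chromosome, clip side).

    Two same-side signatures share a cluster iff a chain of members with
    successive gaps <= ``window`` connects them. The representative is the
    median member breakpoint.
    """
    if window < 1:
        raise ValidationError("cluster window must be >= 1")
    groups: dict[tuple[str, str], list[int]] = {}
    for sig in signatures:
        groups.setdefault((sig.chrom, sig.side), []).append(sig.breakpoint)
    clusters: list[BreakpointCluster] = []
    for (chrom, side), points in sorted(groups.items()):
        points.sort()
        run: list[int] = [points[0]]
        for p in points[1:]:
            if p - run[-1] <= window:
                run.append(p)
            else:
                clusters.append(
                    BreakpointCluster(chrom, side, _median_lower(run), len(run))
                )
                run = [p]
        clusters.append(BreakpointCluster(chrom, side, _median_lower(run), len(run)))
    return clusters


def pair_breakpoint_clusters(
    end_clusters: Iterable[BreakpointCluster],
    start_clusters: Iterable[BreakpointCluster],
    min_sv: int = SV_FLOOR,
    max_sv: int = 100_000,
) -> list[EstimatedSV]:
    """Pair END-side clusters with downstream START-side clusters.

    Candidate pairs are same-chromosome (END, START) cluster pairs with the
    START representative strictly to the right and a gap within
    [min_sv, max_sv]. Pairs are accepted greedily in order of increasing gap
    (ties by left coordinate); each cluster joins at most one event.
    """
    if min_sv < SV_FLOOR:
        raise ValidationError(f"min_sv must be >= {SV_FLOOR}")
    if max_sv <= min_sv:
        raise ValidationError("max_sv must exceed min_sv")
    ends = [c for c in end_clusters if c.side == SIDE_END]
    starts = [c for c in start_clusters if c.side == SIDE_START]
    candidates: list[tuple[int, int, int, int]] = []  # (gap, left, ei, si)
    for ei, e in enumerate(ends):
        for si, s in enumerate(starts):
            if s.chrom != e.chrom:
                continue
            gap = s.representative - e.representative
            if min_sv <= gap <= max_sv:
                candidates.append((gap, e.representative, ei, si))
    candidates.sort()
    used_e: set[int] = set()
    used_s: set[int] = set()
    events: list[EstimatedSV] = []
    for gap, left, ei, si in candidates:
        if ei in used_e or si in used_s:
            continue
        used_e.add(ei)
        used_s.add(si)
        events.append(EstimatedSV(ends[ei].chrom, left, left + gap))
    events.sort(key=lambda ev: (ev.chrom, ev.left, ev.right))
    return events


def compute_file_level_features(
    records: Sequence[AlignmentRecord],
) -> tuple[float, float, list[GenomicInterval]]:
    """Average read length, average depth and the covered reference span.

    Depth is aligned bases divided by the length of the merged union of
    aligned intervals, so sparsely covered toy genomes are not diluted by
    uncovered sequence.
    """
    mapped = [r for r in records if not r.is_unmapped]
    if not mapped:
        raise EmptyInputError("no mapped records: cannot compute file-level features")
    avg_read_length = sum(r.read_length for r in mapped) / len(mapped)
    span = merge_intervals(
        GenomicInterval(r.chrom, r.pos, r.reference_end)
        for r in mapped
        if r.reference_consumed() > 0
    )
    total_span = sum(iv.length for iv in span)
    aligned_bases = sum(r.reference_consumed() for r in mapped)
    avg_depth = aligned_bases / total_span if total_span else 0.0
    return avg_read_length, avg_depth, span


def compute_size_proportions(
    svs: Iterable[EstimatedSV],
) -> tuple[float, float, float]:
    """Proportions of short [50,200), middle [200,1000] and large (>1000) SVs."""
    short = middle = large = 0
    for sv in svs:
        if sv.size < SV_FLOOR:
            raise ValidationError(f"estimated SV of size {sv.size} below {SV_FLOOR} bp")
        if sv.size < SHORT_MAX:
            short += 1
        elif sv.size <= MIDDLE_MAX:
            middle += 1
        else:
            large += 1
    total = short + middle + large
    if total == 0:
        return 0.0, 0.0, 0.0
    return short / total, middle / total, large / total


def compute_tandem_repeat_proportion(
    svs: Sequence[EstimatedSV], tr: Sequence[GenomicInterval]
) -> float:
    """Fraction of estimated SVs intersecting a tandem-repeat interval >= 1 bp."""
    if not svs:
        return 0.0
    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for iv in tr:
        starts, ends = by_chrom.setdefault(iv.chrom, ([], []))
        starts.append(iv.start)
        ends.append(iv.end)
    hits = 0
    for sv in svs:
        if sv.chrom not in by_chrom:
            continue
        starts, ends = by_chrom[sv.chrom]
        # first interval with end > sv.left could overlap
        i = bisect_left(ends, sv.left + 1)
        if i < len(starts) and starts[i] < sv.right:
            hits += 1
    return hits / len(svs)


def _windows(
    span: Sequence[GenomicInterval], width: int
) -> list[GenomicInterval]:
    """Half-overlapping windows tiling each covered interval.

    Windows start at the interval start and advance by width/2; the first
    window reaching or passing the interval end is the last one (kept even
    when partial).
    """
    step = max(width // 2, 1)
    out: list[GenomicInterval] = []
    for iv in span:
        start = iv.start
        while True:
            out.append(GenomicInterval(iv.chrom, start, min(start + width, iv.end)))
            if start + width >= iv.end:
                break
            start += step
    return out


def compute_rvb_features(
    svs: Sequence[EstimatedSV],
    avg_read_length: float,
    covered_span: Sequence[GenomicInterval],
    high_threshold: int = 2,
) -> tuple[float, float]:
    """Read variant burden and the fraction of high-burden windows.

    Windows of width round(avg_read_length) step by half a width over the
    covered span; a window's burden is the number of estimated SVs it
    intersects. RVB is the mean burden; a window is high-burden when its
    burden reaches ``high_threshold``.
    """
    if avg_read_length < 1:
        raise ValidationError("avg_read_length must be >= 1")
    if high_threshold < 1:
        raise ValidationError("high_threshold must be >= 1")
    if not svs or not covered_span:
        return 0.0, 0.0
    width = max(int(round(avg_read_length)), 1)
    windows = _windows(covered_span, width)
    if not windows:
        return 0.0, 0.0
    by_chrom: dict[str, list[EstimatedSV]] = {}
    for sv in svs:
        by_chrom.setdefault(sv.chrom, []).append(sv)
    total_burden = 0
    high = 0
    for w in windows:
        burden = 0
        for sv in by_chrom.get(w.chrom, ()):
            if sv.left < w.end and sv.right > w.start:
                burden += 1
        total_burden += burden
        if burden >= high_threshold:
            high += 1
    return total_burden / len(windows), high / len(windows)


def compute_metafeatures(
    records: Sequence[AlignmentRecord],
    tr: Sequence[GenomicInterval] = (),
    config: Optional[ScanConfig] = None,
    report: Optional[ScanReport] = None,
) -> MetaFeatureVector:
    """Run the full scanning pipeline on in-memory alignment records."""
    cfg = config or ScanConfig()
    avg_read_length, avg_depth, span = compute_file_level_features(records)
    signatures = extract_softclip_signatures(records, cfg.min_clip)
    clusters = cluster_breakpoints(signatures, cfg.cluster_window)
    events = pair_breakpoint_clusters(clusters, clusters, cfg.min_sv, cfg.max_sv)
    if report is not None:
        report.n_clips = len(signatures)
        report.n_clusters = len(clusters)
        report.n_events = len(events)
    prop_short, prop_middle, prop_large = compute_size_proportions(events)
    prop_sv_tr = compute_tandem_repeat_proportion(events, tr)
    rvb, prop_high = compute_rvb_features(
        events, avg_read_length, span, cfg.rvb_high_threshold
    )
    return MetaFeatureVector(
        avg_read_length=avg_read_length,
        avg_depth=avg_depth,
        prop_sv_tr=prop_sv_tr,
        prop_short=prop_short,
        prop_middle=prop_middle,
        prop_large=prop_large,
        rvb=rvb,
        prop_high_rvb=prop_high,
    )


def extract_metafeatures(
    path: str | os.PathLike,
    tr_path: Optional[str | os.PathLike] = None,
    tr_dialect: str = "bed",
    config: Optional[ScanConfig] = None,
) -> tuple[MetaFeatureVector, ScanReport]:
    """Scan an alignment file (plus optional repeat track) into meta-features.

    Returns the eight-feature vector and a scan report with record, clip,
    cluster and event counts.
    """
    report = ScanReport()
    records = list(read_alignments(path, report=report))
    if not records:
        raise EmptyInputError(f"{path}: no mapped records to scan")
    tr = read_repeat_intervals(tr_path, tr_dialect) if tr_path else []
    mf = compute_metafeatures(records, tr, config, report)
    return mf, report
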