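"""Independent brute-force oracles the test suite checks the package against.

Everything here is written with direct loops and no shared code paths with
the package implementation: union-find clustering over all pairs, repeated
global-minimum pairing, per-base coverage counting, exhaustive window
enumeration, and exact maximum-cardinality bipartite matching via scipy.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from svrec.formats import AlignmentRecord, GenomicInterval, SVRecord


def naive_metafeatures(records, tr, min_clip=20, window=100, min_sv=50,
                       max_sv=100_000, high_threshold=2):
    """Recompute the eight meta-features with direct loops."""
    mapped = [r for r in records if not r.is_unmapped]
    assert mapped, "oracle needs mapped records"
    # file level: per-base coverage over an explicit position set
    avg_read_length = sum(r.read_length for r in mapped) / len(mapped)
    covered: dict[str, set[int]] = {}
    aligned_bases = 0
    for r in mapped:
        ref_len = sum(n for op, n in r.cigar if op in (0, 2, 3, 7, 8))
        aligned_bases += ref_len
        covered.setdefault(r.chrom, set()).update(range(r.pos, r.pos + ref_len))
    span_len = sum(len(s) for s in covered.values())
    avg_depth = aligned_bases / span_len if span_len else 0.0

    # signatures
    sigs = []  # (chrom, side, breakpoint)
    for r in mapped:
        if not r.cigar:
            continue
        op0, n0 = r.cigar[0]
        if op0 == 4 and n0 >= min_clip:
            sigs.append((r.chrom, "START", r.pos))
        if len(r.cigar) > 1:
            opL, nL = r.cigar[-1]
            if opL == 4 and nL >= min_clip:
                ref_len = sum(n for op, n in r.cigar if op in (0, 2, 3, 7, 8))
                sigs.append((r.chrom, "END", r.pos + ref_len))

    # union-find single-linkage clustering over all same-group pairs
    parent = list(range(len(sigs)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(sigs)):
        for j in range(i + 1, len(sigs)):
            if sigs[i][0] == sigs[j][0] and sigs[i][1] == sigs[j][1]:
                if abs(sigs[i][2] - sigs[j][2]) <= window:
                    parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(len(sigs)):
        groups.setdefault(find(i), []).append(i)
    clusters = []  # (chrom, side, representative)
    for members in groups.values():
        pts = sorted(sigs[i][2] for i in members)
        rep = pts[(len(pts) - 1) // 2]
        clusters.append((sigs[members[0]][0], sigs[members[0]][1], rep))

    # pairing: repeatedly take the globally smallest admissible gap
    ends = [c for c in clusters if c[1] == "END"]
    starts = [c for c in clusters if c[1] == "START"]
    used_e, used_s = set(), set()
    events = []  # (chrom, left, right)
    while True:
        best = None
        for ei, e in enumerate(ends):
            if ei in used_e:
                continue
            for si, s in enumerate(starts):
                if si in used_s or s[0] != e[0]:
                    continue
                gap = s[2] - e[2]
                if min_sv <= gap <= max_sv:
                    key = (gap, e[2], ei, si)
                    if best is None or key < best:
                        best = key
        if best is None:
            break
        gap, left, ei, si = best
        used_e.add(ei)
        used_s.add(si)
        events.append((ends[ei][0], left, left + gap))

    # size classes
    short = sum(1 for _, l, r in events if 50 <= r - l < 200)
    middle = sum(1 for _, l, r in events if 200 <= r - l <= 1000)
    large = sum(1 for _, l, r in events if r - l > 1000)
    n = len(events)
    props = (short / n, middle / n, large / n) if n else (0.0, 0.0, 0.0)

    # TR overlap by explicit pairwise check
    if n:
        hits = sum(
            1
            for chrom, l, r in events
            if any(iv.chrom == chrom and iv.start < r and iv.end > l for iv in tr)
        )
        prop_sv_tr = hits / n
    else:
        prop_sv_tr = 0.0

    # RVB: enumerate windows per covered run of positions
    if n == 0 or span_len == 0:
        rvb, prop_high = 0.0, 0.0
    else:
        width = max(int(round(avg_read_length)), 1)
        step = max(width // 2, 1)
        windows = []
        for chrom, positions in sorted(covered.items()):
            pts = sorted(positions)
            runs = []
            run_start = pts[0]
            prev = pts[0]
            for p in pts[1:]:
                if p != prev + 1:
                    runs.append((run_start, prev + 1))
                    run_start = p
                prev = p
            runs.append((run_start, prev + 1))
            for lo, hi in runs:
                start = lo
                while True:
                    windows.append((chrom, start, min(start + width, hi)))
                    if start + width >= hi:
                        break
                    start += step
        burdens = [
            sum(1 for c, l, r in events if c == chrom and l < we and r > ws)
            for chrom, ws, we in windows
        ]
        rvb = sum(burdens) / len(burdens)
        prop_high = sum(1 for b in burdens if b >= high_threshold) / len(burdens)

    return {
        "avg_read_length": avg_read_length,
        "avg_depth": avg_depth,
        "prop_sv_tr": prop_sv_tr,
        "prop_short": props[0],
        "prop_middle": props[1],
        "prop_large": props[2],
        "rvb": rvb,
        "prop_high_rvb": prop_high,
    }


def admissible(call: SVRecord, ref: SVRecord, min_overlap: float) -> bool:
    """The matching admissibility rule, restated independently."""
    if call.chrom != ref.chrom:
        return False
    if (call.svtype == "INS") != (ref.svtype == "INS"):
        return False
    if call.svtype == "INS":
        return (
            abs(call.start - ref.start) <= 100
            and min(call.size, ref.size) / max(call.size, ref.size) >= min_overlap
        )
    inter = min(call.end, ref.end) - max(call.start, ref.start)
    if inter <= 0:
        return False
    return (
        inter >= min_overlap * (call.end - call.start)
        and inter >= min_overlap * (ref.end - ref.start)
    )


def max_matching_tp(called, reference, min_overlap=0.8) -> int:
    """Exact maximum-cardinality matching size on the admissibility graph."""
    rows, cols = [], []
    for ci, call in enumerate(called):
        for ri, ref in enumerate(reference):
            if admissible(call, ref, min_overlap):
                rows.append(ci)
                cols.append(ri)
    if not rows:
        return 0
    graph = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(called), len(reference))
    )
    match = maximum_bipartite_matching(graph, perm_type="column")
    return int((match >= 0).sum())
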