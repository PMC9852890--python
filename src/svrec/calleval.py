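"""Caller evaluation: truth matching, precision/recall/f-measure, meta-target
ranking, recommendation accuracy and win/draw/loss counting.

A called SV is a true positive when it matches a benchmark SV under the
reciprocal-overlap rule: the intersection must cover at least ``min_overlap``
(default 0.8) of BOTH intervals. Insertions, which have no meaningful span,
match when their breakpoints are within 100 bp and the smaller/larger size
ratio reaches the same threshold. Matching is one-to-one and greedy by
descending overlap quality.

Recommendation accuracy (RA) places the recommended caller's performance on
a 0-1 scale between the worst (0) and best (1) caller on that dataset:

    RA = (p_recommended - p_worst) / (p_optimal - p_worst)

with RA defined as 1 when all callers tie (any choice is optimal).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .errors import ValidationError
from .formats import SVRecord

METRICS = ("f_measure", "precision", "recall")

#: breakpoint distance within which two insertions are considered co-located
INS_BREAKPOINT_TOL = 100


@dataclass(frozen=True)
class CallerPerformance:
    """Precision/recall/f-measure of one caller on one dataset.

    The raw counts (tp, n_call, n_ref) are optional: entries of a synthetic
    corpus carry metric values only.
    """

    dataset_id: str
    caller: str
    precision: float
    recall: float
    f_measure: float
    tp: Optional[int] = None
    n_call: Optional[int] = None
    n_ref: Optional[int] = None

    def __post_init__(self) -> None:
        for name in METRICS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(
                    f"{self.dataset_id}/{self.caller}: {name}={v} outside [0,1]"
                )
        if self.tp is not None and self.n_call is not None and self.n_ref is not None:
            if self.tp > min(self.n_call, self.n_ref):
                raise ValidationError(
                    f"{self.dataset_id}/{self.caller}: tp exceeds min(call, ref)"
                )

    def metric(self, name: str) -> float:
        if name not in METRICS:
            raise ValidationError(f"unknown metric {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class MetaTargetLabel:
    """The best caller (and full ranking) for one dataset under one metric."""

    dataset_id: str
    metric: str
    best_caller: str
    ranking: tuple[str, ...]


@dataclass(frozen=True)
class WinDrawLossCount:
    wins: int
    draws: int
    losses: int

    @property
    def total(self) -> int:
        return self.wins + self.draws + self.losses


def _overlap_quality(call: SVRecord, ref: SVRecord, min_overlap: float) -> float:
    """Admissibility score of a (call, ref) pair; <= 0 means no match.

    For interval SVs this is the smaller of the two reciprocal overlap
    fractions; for insertion pairs it is the size ratio, gated on breakpoint
    proximity. Mixed INS/interval pairs never match.
    """
    if call.chrom != ref.chrom:
        return 0.0
    call_ins = call.svtype == "INS"
    ref_ins = ref.svtype == "INS"
    if call_ins != ref_ins:
        return 0.0
    if call_ins:
        if abs(call.start - ref.start) > INS_BREAKPOINT_TOL:
            return 0.0
        ratio = min(call.size, ref.size) / max(call.size, ref.size)
        return ratio if ratio >= min_overlap else 0.0
    inter = min(call.end, ref.end) - max(call.start, ref.start)
    if inter <= 0:
        return 0.0
    frac = min(inter / (call.end - call.start), inter / (ref.end - ref.start))
    return frac if frac >= min_overlap else 0.0


def match_sv_calls(
    called: Sequence[SVRecord],
    reference: Sequence[SVRecord],
    min_overlap: float = 0.8,
) -> tuple[int, list[tuple[int, int]]]:
    """One-to-one matching of called against benchmark SVs.

    Returns the true-positive count and the matched (call index, ref index)
    pairs. Admissible pairs are taken greedily by descending overlap quality,
    ties broken by left coordinate.
    """
    if not 0.0 < min_overlap <= 1.0:
        raise ValidationError("min_overlap must lie in (0, 1]")
    admissible: list[tuple[float, int, int, int]] = []
    for ci, call in enumerate(called):
        for ri, ref in enumerate(reference):
            q = _overlap_quality(call, ref, min_overlap)
            if q > 0.0:
                admissible.append((-q, min(call.start, ref.start), ci, ri))
    admissible.sort()
    used_c: set[int] = set()
    used_r: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, _, ci, ri in admissible:
        if ci in used_c or ri in used_r:
            continue
        used_c.add(ci)
        used_r.add(ri)
        pairs.append((ci, ri))
    pairs.sort()
    return len(pairs), pairs


def compute_prf(tp: int, n_call: int, n_ref: int) -> tuple[float, float, float]:
    """Precision, recall and f-measure from the matching counts.

    Precision is defined as 0 when no calls were made, keeping the f-measure
    defined; a benchmark with zero reference SVs is an error.
    """
    if n_ref < 1:
        raise ValidationError("a non-empty benchmark (n_ref >= 1) is required")
    if tp > min(n_call, n_ref) or tp < 0:
        raise ValidationError(f"tp={tp} inconsistent with call={n_call}, ref={n_ref}")
    precision = tp / n_call if n_call else 0.0
    recall = tp / n_ref
    denom = precision + recall
    f_measure = 2 * precision * recall / denom if denom else 0.0
    return precision, recall, f_measure


def identify_meta_target(
    performances: Iterable[CallerPerformance], metric: str = "f_measure"
) -> MetaTargetLabel:
    """Rank callers on one dataset by a metric; the best is the meta-target.

    Ties are broken by lexicographically smaller caller name.
    """
    perfs = list(performances)
    if not perfs:
        raise ValidationError("no caller performances supplied")
    dataset_ids = {p.dataset_id for p in perfs}
    if len(dataset_ids) != 1:
        raise ValidationError(f"performances span several datasets: {dataset_ids}")
    callers = [p.caller for p in perfs]
    if len(set(callers)) != len(callers):
        raise ValidationError("duplicate (dataset, caller) rows")
    if len(callers) < 2:
        raise ValidationError("meta-target needs at least 2 distinct callers")
    ranked = sorted(perfs, key=lambda p: (-p.metric(metric), p.caller))
    return MetaTargetLabel(
        dataset_id=perfs[0].dataset_id,
        metric=metric,
        best_caller=ranked[0].caller,
        ranking=tuple(p.caller for p in ranked),
    )


def recommendation_accuracy(
    p_recommended: float, p_optimal: float, p_worst: float
) -> float:
    """RA of a recommendation given the optimal and worst performances.

    Returns 1 when optimal equals worst (all callers tie, any choice is
    optimal); otherwise the linear position of the recommendation between
    worst (0) and optimal (1).
    """
    if not (p_worst <= p_recommended <= p_optimal):
        raise ValidationError(
            f"require p_worst <= p_recommended <= p_optimal, got "
            f"({p_worst}, {p_recommended}, {p_optimal})"
        )
    spread = p_optimal - p_worst
    if spread == 0:
        return 1.0
    return (p_recommended - p_worst) / spread


def win_draw_loss(
    perf_a: Sequence[float], perf_b: Sequence[float], tol: float = 1e-9
) -> WinDrawLossCount:
    """Count per-dataset wins, draws and losses of strategy A against B."""
    if len(perf_a) != len(perf_b):
        raise ValidationError(
            f"strategy vectors differ in length: {len(perf_a)} vs {len(perf_b)}"
        )
    if not perf_a:
        raise ValidationError("empty performance vectors")
    wins = draws = losses = 0
    for a, b in zip(perf_a, perf_b):
        if a - b > tol:
            wins += 1
        elif b - a > tol:
            losses += 1
        else:
            draws += 1
    return WinDrawLossCount(wins, draws, losses)
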