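"""Synthetic fixtures: toy alignment files with planted deletions and
synthetic meta-learning corpora with known feature-to-caller rules.

The alignment simulator emulates, at toy scale, a long-read sequencing run
over a single-chromosome genome carrying planted deletions: reads tile the
deleted (sample) genome at a target depth, and any read crossing a deletion
junction is emitted as split alignment records soft-clipped toward the two
breakpoints, with Gaussian jitter on the clip boundaries mimicking alignment
ambiguity. Reads are error-free away from the junctions — every implemented
statistic reads only CIGAR geometry and positions, so base-level errors
would be dead weight.

The corpus simulator draws meta-feature vectors from realistic long-read
ranges (read length 1,000-25,000 bp, depth 10-150x), assigns the optimal
caller by a declarative threshold rule, and constructs per-caller metric
tables where the rule's caller leads by a configurable spread before metric
noise is added. The meta-targets are then re-derived from the noisy table,
so a noisy corpus is deliberately imperfectly separable.
"""

from __future__ import annotations

import json
import os
import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pysam

from .calleval import METRICS, CallerPerformance
from .errors import ConfigError, ValidationError
from .formats import GenomicInterval, SVRecord, merge_intervals, write_sv_set_vcf
from .recommender import CorpusEntry, HistoricalCorpus
from .sigscan import MetaFeatureVector

_SEED_MASK = 0x7FFFFFFF

# size-class sampling ranges for planted deletions (bp)
CLASS_RANGES = {"short": (60, 190), "middle": (220, 980), "large": (1100, 5000)}


@dataclass
class PlantingConfig:
    """Parameters of the toy alignment simulation.

    The defaults describe a 500 kb single-chromosome genome sequenced at
    20-fold coverage with 8 kb reads — large enough for stable feature
    recovery, small enough that a full simulate-and-scan cycle takes
    seconds.
    """

    genome_length: int = 500_000
    read_length_mean: int = 8_000
    read_length_sd: int = 400
    depth: float = 20.0
    sv_counts: dict = field(
        default_factory=lambda: {"short": 0, "middle": 20, "large": 0}
    )
    tr_fraction: float = 0.10
    clip_jitter_sd: float = 8.0
    seed: int = 1
    chrom: str = "chr1"

    def validate(self) -> None:
        if self.genome_length < 10 * self.read_length_mean:
            raise ConfigError(
                "genome_length must be at least 10 x read_length_mean"
            )
        for cls in self.sv_counts:
            if cls not in CLASS_RANGES:
                raise ConfigError(f"unknown SV size class {cls!r}")


@dataclass
class SimulatedDataset:
    """Paths and ground truth of one simulated dataset."""

    sam_path: str
    truth_vcf_path: str
    tr_bed_path: str
    log_path: str
    truth: list[SVRecord]
    tr: list[GenomicInterval]
    config: PlantingConfig


def _draw_sv_sizes(config: PlantingConfig, rng: np.random.Generator) -> list[tuple[str, int]]:
    sizes: list[tuple[str, int]] = []
    for cls in ("short", "middle", "large"):
        lo, hi = CLASS_RANGES[cls]
        for _ in range(int(config.sv_counts.get(cls, 0))):
            sizes.append((cls, int(rng.integers(lo, hi + 1))))
    rng.shuffle(sizes)
    return sizes


def _place_deletions(
    config: PlantingConfig, rng: np.random.Generator
) -> list[tuple[str, int, int]]:
    """Place non-overlapping deletions separated by >= read_length_mean.

    Returns (size class, ref start, ref end) triples sorted by position.
    Placement distributes the slack after reserving the mandatory spacing
    uniformly among the gaps; impossible configurations raise ConfigError.
    """
    sizes = _draw_sv_sizes(config, rng)
    n = len(sizes)
    spacing = config.read_length_mean
    margin = config.read_length_mean  # keep events away from genome edges
    needed = sum(s for _, s in sizes) + spacing * (n - 1 if n else 0) + 2 * margin
    if needed > config.genome_length:
        raise ConfigError(
            f"cannot place {n} SVs with {spacing} bp spacing in a "
            f"{config.genome_length} bp genome"
        )
    slack = config.genome_length - needed
    # n+1 gaps (before first, between, after last); uniform random split
    cuts = np.sort(rng.integers(0, slack + 1, size=n)) if n else np.array([], int)
    extras = np.diff(np.concatenate(([0], cuts)))  # first n gaps' extra slack
    placements: list[tuple[str, int, int]] = []
    pos = margin
    for i, (cls, size) in enumerate(sizes):
        pos += int(extras[i]) + (spacing if i > 0 else 0)
        placements.append((cls, pos, pos + size))
        pos += size
    return placements


def _ref_coord(alt_pos: int, junctions: Sequence[int], shifts: Sequence[int]) -> int:
    """Map a coordinate on the deleted genome back to the reference."""
    d = bisect_right(junctions, alt_pos)
    return alt_pos + (shifts[d - 1] if d else 0)


def simulate_dataset(
    config: PlantingConfig, outdir: str | os.PathLike
) -> SimulatedDataset:
    """Simulate an alignment file with planted deletions plus its truth sets.

    Writes a SAM file, a truth VCF, a tandem-repeat BED track and a JSON
    planting log into ``outdir``; byte-identical across runs with the same
    configuration and seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed & _SEED_MASK)
    os.makedirs(outdir, exist_ok=True)
    chrom, G = config.chrom, config.genome_length

    placements = _place_deletions(config, rng)
    truth = [
        SVRecord(chrom, start, end, "DEL", end - start)
        for _, start, end in placements
    ]

    # ALT (sample) genome coordinates: junction positions and cumulative shifts
    junctions: list[int] = []
    shifts: list[int] = []
    removed = 0
    for _, start, end in placements:
        junctions.append(start - removed)
        removed += end - start
        shifts.append(removed)
    alt_length = G - removed

    # tandem-repeat track: random ~2 kb intervals until tr_fraction is covered
    tr: list[GenomicInterval] = []
    target_tr = config.tr_fraction * G
    covered = 0.0
    while covered < target_tr:
        width = int(rng.integers(1_000, 3_000))
        start = int(rng.integers(0, G - width))
        tr.append(GenomicInterval(chrom, start, start + width))
        covered += width
    tr = merge_intervals(tr)

    # reads tile the ALT genome at the target depth
    n_reads = int(round(config.depth * alt_length / config.read_length_mean))
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": chrom, "LN": G}],
    }
    sam_path = os.path.join(outdir, "reads.sam")
    min_aligned = 50  # an aligner would not report a shorter split
    with pysam.AlignmentFile(sam_path, "w", header=header) as out:
        for ridx in range(n_reads):
            rlen = int(
                np.clip(
                    rng.normal(config.read_length_mean, config.read_length_sd),
                    200,
                    None,
                )
            )
            rlen = min(rlen, alt_length)
            a = int(rng.integers(0, alt_length - rlen + 1))
            # junctions strictly inside the read split it into segments
            inside = [j for j in junctions if a < j < a + rlen]
            cuts = [0] + [j - a for j in inside] + [rlen]
            for seg in range(len(cuts) - 1):
                lo, hi = cuts[seg], cuts[seg + 1]
                jitter = 0
                if seg > 0:  # START-side boundary sits at a junction
                    jitter = int(round(rng.normal(0.0, config.clip_jitter_sd)))
                lo_j = int(np.clip(lo + jitter, 0, rlen - 1))
                jitter = 0
                if seg < len(cuts) - 2:  # END-side boundary at a junction
                    jitter = int(round(rng.normal(0.0, config.clip_jitter_sd)))
                hi_j = int(np.clip(hi + jitter, lo_j + 1, rlen))
                aligned = hi_j - lo_j
                if aligned < min_aligned:
                    continue
                ref_pos = _ref_coord(a + cuts[seg], junctions, shifts) + (lo_j - lo)
                cig = []
                if lo_j:
                    cig.append((4, lo_j))  # leading softclip
                cig.append((0, aligned))
                if rlen - hi_j:
                    cig.append((4, rlen - hi_j))  # trailing softclip
                seg_rec = pysam.AlignedSegment(out.header)
                seg_rec.query_name = f"read{ridx:06d}" + (
                    f"_p{seg}" if len(cuts) > 2 else ""
                )
                seg_rec.flag = 0
                seg_rec.reference_id = 0
                seg_rec.reference_start = ref_pos
                seg_rec.mapping_quality = 60
                seg_rec.cigartuples = cig
                out.write(seg_rec)

    truth_vcf_path = os.path.join(outdir, "truth.vcf")
    write_sv_set_vcf(truth, truth_vcf_path, contigs={chrom: G})
    tr_bed_path = os.path.join(outdir, "repeats.bed")
    with open(tr_bed_path, "w") as fh:
        for iv in tr:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    log_path = os.path.join(outdir, "planting_log.json")
    tr_sorted = tr
    with open(log_path, "w") as fh:
        json.dump(
            {
                "config": {
                    **{k: v for k, v in config.__dict__.items() if k != "sv_counts"},
                    "sv_counts": dict(config.sv_counts),
                },
                "n_reads": n_reads,
                "events": [
                    {
                        "class": cls,
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "size": end - start,
                        "in_tr": any(
                            iv.start < end and iv.end > start for iv in tr_sorted
                        ),
                    }
                    for cls, start, end in placements
                ],
            },
            fh,
            indent=1,
        )
    return SimulatedDataset(
        sam_path, truth_vcf_path, tr_bed_path, log_path, truth, tr, config
    )


# ---- synthetic meta-learning corpora ---------------------------------------


@dataclass(frozen=True)
class RuleClause:
    """One clause of a label rule: a conjunction of threshold conditions.

    Each condition is (feature, op, threshold) with op ``>`` or ``<=``.
    """

    conditions: tuple[tuple[str, str, float], ...]
    caller: str

    def matches(self, mf: MetaFeatureVector) -> bool:
        for feature, op, threshold in self.conditions:
            value = getattr(mf, feature)
            ok = value > threshold if op == ">" else value <= threshold
            if not ok:
                return False
        return True


@dataclass(frozen=True)
class LabelRule:
    """A decision list over meta-features: first matching clause wins."""

    clauses: tuple[RuleClause, ...]
    default: str

    def label(self, mf: MetaFeatureVector) -> str:
        for clause in self.clauses:
            if clause.matches(mf):
                return clause.caller
        return self.default

    @property
    def callers(self) -> tuple[str, ...]:
        return tuple(sorted({c.caller for c in self.clauses} | {self.default}))

    @classmethod
    def from_dict(cls, spec: dict) -> "LabelRule":
        clauses = tuple(
            RuleClause(
                conditions=tuple(
                    (c["feature"], c["op"], float(c["threshold"]))
                    for c in clause["conditions"]
                ),
                caller=clause["caller"],
            )
            for clause in spec.get("clauses", ())
        )
        return cls(clauses=clauses, default=spec["default"])


def standard_label_rule(callers: Sequence[str]) -> LabelRule:
    """The default two-feature rule over depth and large-SV proportion.

    Splits the (avg_depth, prop_large) plane into up to five regions, one
    per caller, echoing how real callers separate on coverage and SV size.
    """
    c = list(callers)
    if len(c) < 2:
        raise ValidationError("a label rule needs >= 2 callers")
    clauses = [
        RuleClause((("avg_depth", ">", 80.0), ("prop_large", ">", 0.4)), c[0]),
        RuleClause((("avg_depth", ">", 80.0),), c[1 % len(c)]),
        RuleClause((("prop_large", ">", 0.4),), c[2 % len(c)]),
        RuleClause((("avg_depth", ">", 40.0),), c[3 % len(c)]),
    ]
    return LabelRule(tuple(clauses), default=c[4 % len(c)])


DEFAULT_CALLERS = ("cutesv", "nanosv", "pbsv", "picky", "sniffles")


@dataclass
class CorpusConfig:
    """Parameters of the synthetic meta-learning corpus.

    ``performance_spread`` is the constructed gap between the rule-optimal
    caller's metric and the runner-up band before noise; ``noise_sd`` is the
    per-metric Gaussian noise. Feature ranges follow typical long-read runs
    (read length 1,000-25,000 bp, depth 10-150x).
    """

    n_datasets: int = 200
    caller_names: tuple[str, ...] = DEFAULT_CALLERS
    label_rule: Optional[LabelRule] = None
    performance_spread: float = 0.4
    noise_sd: float = 0.05
    base_level: float = 0.5
    seed: int = 1


def simulate_corpus(config: CorpusConfig) -> HistoricalCorpus:
    """Draw a synthetic historical corpus with a known feature-to-caller rule.

    The rule's caller receives metric ``base_level + performance_spread``;
    the others fall in a band just below ``base_level``. Gaussian noise is
    added and clipped to [0,1], and the stored meta-target is re-derived
    from the noisy table — with enough noise relative to the spread, some
    datasets' targets flip, which is intended.
    """
    if config.n_datasets < 3:
        raise ValidationError("a corpus needs >= 3 datasets")
    callers = tuple(config.caller_names)
    if len(callers) < 2:
        raise ValidationError("a corpus needs >= 2 callers")
    rule = config.label_rule or standard_label_rule(callers)
    unknown = set(rule.callers) - set(callers)
    if unknown:
        raise ValidationError(f"label rule names unknown callers: {unknown}")
    rng = np.random.default_rng(config.seed & _SEED_MASK)
    entries: list[CorpusEntry] = []
    labels_seen: set[str] = set()
    for i in range(config.n_datasets):
        triple = rng.dirichlet((1.0, 1.0, 1.0))
        mf = MetaFeatureVector(
            avg_read_length=float(rng.uniform(1_000, 25_000)),
            avg_depth=float(rng.uniform(10, 150)),
            prop_sv_tr=float(rng.uniform(0, 1)),
            prop_short=float(triple[0]),
            prop_middle=float(triple[1]),
            prop_large=float(triple[2]),
            rvb=float(rng.uniform(0, 4)),
            prop_high_rvb=float(rng.uniform(0, 1)),
        )
        best = rule.label(mf)
        labels_seen.add(best)
        dataset_id = f"ds{i:04d}"
        perfs: dict[str, CallerPerformance] = {}
        values: dict[str, dict[str, float]] = {c: {} for c in callers}
        for metric in METRICS:
            base = config.base_level
            for c in callers:
                if c == best:
                    v = base + config.performance_spread
                else:
                    v = float(rng.uniform(base - config.performance_spread / 4, base))
                v += float(rng.normal(0.0, config.noise_sd)) if config.noise_sd else 0.0
                values[c][metric] = float(np.clip(v, 0.0, 1.0))
        for c in callers:
            perfs[c] = CallerPerformance(
                dataset_id=dataset_id,
                caller=c,
                precision=values[c]["precision"],
                recall=values[c]["recall"],
                f_measure=values[c]["f_measure"],
            )
        entries.append(CorpusEntry(dataset_id, mf, perfs))
    if len(labels_seen) < 2:
        warnings.warn(
            "label rule produced a single class on this corpus; the "
            "recommendation task is degenerate",
            stacklevel=2,
        )
    return HistoricalCorpus(entries)
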