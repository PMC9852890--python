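"""Readers and writers for every external representation the tool touches.

Alignments come in as SAM/BAM through pysam, repeat annotations as BED3+ or
the UCSC rmsk.txt table dialect, SV sets as VCF (SVTYPE/END/SVLEN) with a
BED fallback, per-caller performance tables as TSV, and trained
recommendation models as version-tagged joblib archives.

All internal coordinates are 0-based half-open; the 1-based SAM/VCF
conventions are converted at this boundary and nowhere else.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

import joblib
import pandas as pd
import pysam

from .errors import (
    FormatError,
    InputError,
    ModelLoadError,
    ValidationError,
)

# CIGAR operation codes as encoded by pysam/htslib.
CIGAR_M, CIGAR_I, CIGAR_D, CIGAR_N, CIGAR_S = 0, 1, 2, 3, 4
CIGAR_EQ, CIGAR_X = 7, 8
#: operations that consume query bases (M, I, S, =, X)
QUERY_OPS = frozenset({CIGAR_M, CIGAR_I, CIGAR_S, CIGAR_EQ, CIGAR_X})
#: operations that consume reference bases (M, D, N, =, X)
REF_OPS = frozenset({CIGAR_M, CIGAR_D, CIGAR_N, CIGAR_EQ, CIGAR_X})

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class AlignmentRecord:
    """One mapped long read: position, CIGAR geometry and length."""

    read_id: str
    chrom: str
    pos: int  # 0-based leftmost mapped reference coordinate
    cigar: tuple[tuple[int, int], ...]  # (op code, length) pairs
    read_length: int  # query bases including soft clips
    mapq: int = 60
    is_unmapped: bool = False

    def query_consumed(self) -> int:
        return sum(n for op, n in self.cigar if op in QUERY_OPS)

    def reference_consumed(self) -> int:
        return sum(n for op, n in self.cigar if op in REF_OPS)

    @property
    def reference_end(self) -> int:
        """0-based exclusive end of the aligned span."""
        return self.pos + self.reference_consumed()

    def validate(self) -> None:
        if not self.is_unmapped and self.pos < 0:
            raise ValidationError(f"read {self.read_id}: negative mapped position")
        if self.query_consumed() != self.read_length:
            raise FormatError(
                f"read {self.read_id}: CIGAR query length "
                f"{self.query_consumed()} != read length {self.read_length}"
            )


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open interval on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"interval {self.chrom}:{self.start}-{self.end} has non-positive length"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SVRecord:
    """One structural variant as a typed interval.

    DEL and OTHER records span [start, end) with size = end - start;
    insertions are anchored at a single breakpoint (end = start + 1) and
    carry their inserted length in ``size``.
    """

    chrom: str
    start: int
    end: int
    svtype: str  # DEL, INS or OTHER
    size: int

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValidationError(f"SV at {self.chrom}:{self.start}: size < 1")
        if self.svtype == "INS":
            if self.end != self.start + 1:
                raise ValidationError("INS records must have end = start + 1")
        elif self.size != self.end - self.start:
            raise ValidationError(
                f"SV at {self.chrom}:{self.start}: size {self.size} != span "
                f"{self.end - self.start}"
            )


@dataclass
class ScanReport:
    """Bookkeeping counts accumulated while scanning an alignment file."""

    n_records: int = 0
    n_mapped: int = 0
    n_unmapped: int = 0
    n_secondary: int = 0
    n_clips: int = 0
    n_clusters: int = 0
    n_events: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _record_from_pysam(seg: pysam.AlignedSegment) -> AlignmentRecord:
    cigar = tuple(seg.cigartuples or ())
    read_length = sum(n for op, n in cigar if op in QUERY_OPS)
    if seg.query_sequence is not None and len(seg.query_sequence) != read_length:
        raise FormatError(
            f"read {seg.query_name}: CIGAR query length {read_length} "
            f"contradicts sequence length {len(seg.query_sequence)}"
        )
    rec = AlignmentRecord(
        read_id=seg.query_name or "?",
        chrom=seg.reference_name or "?",
        pos=seg.reference_start,
        cigar=cigar,
        read_length=read_length,
        mapq=seg.mapping_quality,
    )
    return rec


def read_alignments(
    path: str | os.PathLike,
    region: Optional[GenomicInterval] = None,
    report: Optional[ScanReport] = None,
) -> Iterator[AlignmentRecord]:
    """Yield mapped primary alignment records from a SAM/BAM file in file order.

    Unmapped, secondary and supplementary records are skipped (and counted in
    ``report`` when given) so each sequenced read contributes once. When
    ``region`` is given, only records overlapping it are yielded; an index is
    used when present, otherwise the file is streamed and filtered.
    """
    if not os.path.exists(path):
        raise InputError(f"alignment file not found: {path}")
    try:
        afile = pysam.AlignmentFile(str(path), check_sq=False)
    except ValueError as exc:
        raise FormatError(f"cannot open {path}: {exc}") from exc

    def _overlaps(seg: pysam.AlignedSegment) -> bool:
        return (
            not seg.is_unmapped
            and seg.reference_name == region.chrom
            and seg.reference_start < region.end
            and (seg.reference_end or seg.reference_start) > region.start
        )

    def _iter() -> Iterator[pysam.AlignedSegment]:
        if region is not None:
            try:
                yield from afile.fetch(region.chrom, region.start, region.end)
                return
            except ValueError:
                # no index: stream the whole file and filter by overlap
                yield from (seg for seg in afile if _overlaps(seg))
                return
        yield from afile

    with afile:
        try:
            for seg in _iter():
                if report is not None:
                    report.n_records += 1
                if seg.is_unmapped:
                    if report is not None:
                        report.n_unmapped += 1
                    continue
                if seg.is_secondary or seg.is_supplementary:
                    if report is not None:
                        report.n_secondary += 1
                    continue
                if report is not None:
                    report.n_mapped += 1
                yield _record_from_pysam(seg)
        except (ValueError, OSError) as exc:
            # htslib reports parse failures (bad CIGAR, SEQ/CIGAR length
            # mismatch) as truncated-file errors mid-iteration
            raise FormatError(f"malformed record in {path}: {exc}") from exc


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping or adjacent intervals, sorted by (chrom, start).

    Idempotent: merging an already-merged collection changes nothing.
    """
    out: list[GenomicInterval] = []
    for iv in sorted(intervals):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            if iv.end > out[-1].end:
                out[-1] = GenomicInterval(iv.chrom, out[-1].start, iv.end)
        else:
            out.append(iv)
    return out


def read_repeat_intervals(
    path: str | os.PathLike, dialect: str = "bed"
) -> list[GenomicInterval]:
    """Read a repeat annotation as merged, sorted genomic intervals.

    ``dialect`` selects the column mapping: ``bed`` takes columns 1-3,
    ``rmsk`` the genoName/genoStart/genoEnd columns of the UCSC rmsk table.
    """
    if not os.path.exists(path):
        raise InputError(f"repeat annotation not found: {path}")
    if dialect not in ("bed", "rmsk"):
        raise ValidationError(f"unknown repeat dialect: {dialect!r}")
    cols = (0, 1, 2) if dialect == "bed" else (5, 6, 7)
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) <= max(cols):
                raise FormatError(f"{path}:{lineno}: expected at least "
                                  f"{max(cols) + 1} columns")
            chrom, s, e = (fields[c] for c in cols)
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric coordinates {s!r}, {e!r}"
                ) from exc
            intervals.append(GenomicInterval(chrom, start, end))
    return merge_intervals(intervals)


_END_RE = re.compile(r"(?:^|;)END=(-?\d+)")


def _sv_from_vcf_record(rec: pysam.VariantRecord, path: str) -> SVRecord:
    info = rec.info
    svtype = str(info.get("SVTYPE", "OTHER")).upper()
    if svtype not in ("DEL", "INS"):
        svtype = "OTHER"
    svlen = info.get("SVLEN")
    if isinstance(svlen, (tuple, list)):
        svlen = svlen[0]
    start = rec.start  # pysam is already 0-based
    # htslib reinterprets END/SVLEN when setting rec.stop (and the rules
    # changed across VCF versions), so take END verbatim from the line
    raw_info = str(rec).rstrip("\n").split("\t")[7]
    end_match = _END_RE.search(raw_info)
    if svtype == "INS":
        if svlen is None:
            raise FormatError(
                f"{path}: INS at {rec.chrom}:{rec.pos} lacks SVLEN"
            )
        return SVRecord(rec.chrom, start, start + 1, "INS", abs(int(svlen)))
    if end_match:
        end = int(end_match.group(1))  # 1-based inclusive == 0-based exclusive
    elif svlen is not None:
        end = start + abs(int(svlen))
    else:
        raise FormatError(
            f"{path}: SV at {rec.chrom}:{rec.pos} has neither END nor SVLEN"
        )
    return SVRecord(rec.chrom, start, end, svtype, end - start)


def read_sv_set(path: str | os.PathLike) -> list[SVRecord]:
    """Read an SV set from VCF (SVTYPE/END/SVLEN) or 3+-column BED.

    BED intervals are treated as DEL-like events spanning their interval.
    """
    if not os.path.exists(path):
        raise InputError(f"SV set not found: {path}")
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz")):
        try:
            vcf = pysam.VariantFile(path)
        except (ValueError, OSError) as exc:
            raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
        with vcf:
            return [_sv_from_vcf_record(rec, path) for rec in vcf]
    records: list[SVRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3+ BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric coordinates"
                ) from exc
            records.append(SVRecord(fields[0], start, end, "DEL", end - start))
    return records


def write_sv_set_vcf(
    records: Sequence[SVRecord],
    path: str | os.PathLike,
    contigs: Optional[dict[str, int]] = None,
) -> None:
    """Write SV records as a minimal VCF 4.2 file."""
    if contigs is None:
        contigs = {}
        for r in records:
            contigs[r.chrom] = max(contigs.get(r.chrom, 0), r.end + 1000)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in contigs.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        fh.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        fh.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        fh.write("##ALT=<ID=DEL,Description=\"Deletion\">\n")
        fh.write("##ALT=<ID=INS,Description=\"Insertion\">\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, r in enumerate(records, start=1):
            if r.svtype == "INS":
                info = f"SVTYPE=INS;SVLEN={r.size}"
            else:
                sign = "-" if r.svtype == "DEL" else ""
                info = f"SVTYPE={r.svtype};END={r.end};SVLEN={sign}{r.size}"
            fh.write(
                f"{r.chrom}\t{r.start + 1}\tsv{i}\tN\t<{r.svtype}>\t.\tPASS\t{info}\n"
            )


PERFORMANCE_COLUMNS = ["dataset_id", "caller", "precision", "recall", "f_measure"]


def read_performance_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read a per-caller performance TSV with validated metric columns."""
    if not os.path.exists(path):
        raise InputError(f"performance table not found: {path}")
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in PERFORMANCE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in ("precision", "recall", "f_measure"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise FormatError(f"{path}: non-numeric values in column {col}")
        if ((vals < 0) | (vals > 1)).any():
            bad = df.loc[(vals < 0) | (vals > 1)].iloc[0]
            raise ValidationError(
                f"{path}: metric {col}={bad[col]} outside [0,1] "
                f"(dataset {bad['dataset_id']}, caller {bad['caller']})"
            )
        df[col] = vals
    return df


def write_performance_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_model(payload: dict, path: str | os.PathLike) -> None:
    """Persist a trained recommendation model with a format-version tag."""
    envelope = {"format": "svrec-model", "version": MODEL_FORMAT_VERSION}
    envelope.update(payload)
    joblib.dump(envelope, path)


def read_model(path: str | os.PathLike) -> dict:
    """Load a model envelope written by :func:`write_model`."""
    if not os.path.exists(path):
        raise InputError(f"model file not found: {path}")
    try:
        envelope = joblib.load(path)
    except Exception as exc:  # joblib raises a zoo of unpickling errors
        raise ModelLoadError(f"cannot load model {path}: {exc}") from exc
    if not isinstance(envelope, dict) or envelope.get("format") != "svrec-model":
        raise ModelLoadError(f"{path} is not an svrec model file")
    if envelope.get("version") != MODEL_FORMAT_VERSION:
        raise ModelLoadError(
            f"{path}: model format version {envelope.get('version')} "
            f"!= supported {MODEL_FORMAT_VERSION}"
        )
    return envelope
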