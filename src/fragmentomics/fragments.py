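"""Fragment ingestion and read qualification.

A sequenced cfDNA molecule is represented as a genomic interval (0-based,
half-open). Paired-end alignments are qualified with five rules, applied in a
fixed order, before any featurization:

  (1) aligned to an autosome,
  (2) mapping quality strictly greater than the threshold (min of the pair),
  (3) insert size within the configured window (inclusive),
  (4) properly paired,
  (5) reference region free of degenerate (non-ACGT) bases.

The insert size is recomputed from mate coordinates (outer distance), not
taken from TLEN, because TLEN conventions vary by aligner. The qualification
report tallies the *first* failing rule for each pair.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeBundle, is_autosome

QC_RULES = ("autosome", "mapq", "insert", "proper_pair", "degenerate_reference")

FRAGMENT_COLUMNS = ["chrom", "start", "end", "mapq"]


@dataclass(frozen=True)
class FragmentRecord:
    """One cfDNA fragment: chrom, [start, end) in bp, pair-minimum MAPQ."""

    chrom: str
    start: int
    end: int
    mapq: int = 60

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"fragment start {self.start} >= end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class QCConfig:
    """Read-qualification thresholds.

    ``min_mapq`` is a strict lower bound ("greater than 20"); the insert
    window is inclusive on both sides. ``feature_insert_bounds`` carries the
    per-feature insert windows used downstream of global qualification: the
    size-distribution diagnostic looks below the 150-bp floor, and the
    short/long profile only uses 130-237 bp fragments.
    """

    min_mapq: int = 20
    min_insert: int = 150
    max_insert: int = 600
    autosomes_only: bool = True
    require_proper_pair: bool = True
    exclude_degenerate_reference: bool = True
    drop_flagged_duplicates: bool = True
    feature_insert_bounds: dict = field(
        default_factory=lambda: {
            "size_distribution": (90, 600),
            "fragment_size": (130, 237),
            "end_motif": (150, 600),
            "nucleosome_footprint": (150, 600),
        }
    )

    def __post_init__(self):
        if not (0 < self.min_insert <= self.max_insert):
            raise ValueError("require 0 < min_insert <= max_insert")
        if self.min_mapq < 0:
            raise ValueError("min_mapq must be >= 0")


@dataclass
class QCReport:
    total_in: int = 0
    kept: int = 0
    failures: dict = field(default_factory=lambda: {rule: 0 for rule in QC_RULES})

    def check(self) -> bool:
        return self.kept + sum(self.failures.values()) == self.total_in

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _first_failure(
    chrom: str, start: int, end: int, mapq: int, proper: bool, qc: QCConfig,
    genome: GenomeBundle | None,
) -> str | None:
    """Return the first failing rule name in the fixed (1)-(5) order, or None."""
    if qc.autosomes_only and not is_autosome(chrom):
        return "autosome"
    if not mapq > qc.min_mapq:
        return "mapq"
    if not (qc.min_insert <= end - start <= qc.max_insert):
        return "insert"
    if qc.require_proper_pair and not proper:
        return "proper_pair"
    if qc.exclude_degenerate_reference and genome is not None:
        arr = genome.base_array(chrom)
        if (arr[start:end] > 3).any():
            return "degenerate_reference"
    return None


def read_fragments(
    bam_path: str | Path,
    qc: QCConfig | None = None,
    genome: GenomeBundle | None = None,
) -> tuple[list[FragmentRecord], QCReport]:
    """Read a coordinate-sorted paired-end BAM/SAM and emit qualified fragments.

    Mates are paired by query name; each pair yields at most one record,
    anchored at the leftmost mate. Secondary/supplementary alignments are
    ignored; flagged PCR duplicates are dropped (deduplication is assumed to
    have happened upstream). Rule (5) requires ``genome``; without it the
    degenerate-reference check is skipped.
    """
    import pysam

    qc = qc or QCConfig()
    path = Path(bam_path)
    if not path.exists():
        raise FileNotFoundError(path)
    report = QCReport()
    records: list[FragmentRecord] = []
    pending: dict[str, "pysam.AlignedSegment"] = {}
    with pysam.AlignmentFile(str(path), check_sq=False) as bam:
        for read in bam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if qc.drop_flagged_duplicates and read.is_duplicate:
                continue
            if not read.is_paired:
                raise ValueError("single-end data: read qualification needs read pairs")
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            report.total_in += 1
            chrom = read.reference_name
            if mate.reference_name != chrom:
                report.failures["proper_pair"] += 1  # inter-chromosomal pair
                continue
            start = min(read.reference_start, mate.reference_start)
            end = max(read.reference_end, mate.reference_end)
            mapq = min(read.mapping_quality, mate.mapping_quality)
            proper = read.is_proper_pair and mate.is_proper_pair
            rule = _first_failure(chrom, start, end, mapq, proper, qc, genome)
            if rule is None:
                records.append(FragmentRecord(chrom, start, end, mapq))
                report.kept += 1
            else:
                report.failures[rule] += 1
    return records, report


def read_fragment_table(
    tsv_path: str | Path,
    qc: QCConfig | None = None,
    genome: GenomeBundle | None = None,
) -> tuple[list[FragmentRecord], QCReport]:
    """Qualify a plain fragment table (chrom, start, end[, mapq]).

    Same semantics as :func:`read_fragments` minus the rules that need BAM
    flags: every row is treated as properly paired, and a missing mapq column
    defaults to passing.
    """
    qc = qc or QCConfig()
    df = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str})
    if not {"chrom", "start", "end"}.issubset(df.columns):
        raise ValueError("fragment table needs columns chrom, start, end")
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].iloc[0]
        raise ValueError(f"malformed row: start {bad['start']} >= end {bad['end']}")
    if "mapq" not in df.columns:
        df = df.assign(mapq=qc.min_mapq + 1)
    report = QCReport(total_in=len(df))
    records = []
    for chrom, start, end, mapq in df[FRAGMENT_COLUMNS].itertuples(index=False):
        rule = _first_failure(chrom, int(start), int(end), int(mapq), True, qc, genome)
        if rule is None:
            records.append(FragmentRecord(chrom, int(start), int(end), int(mapq)))
            report.kept += 1
        else:
            report.failures[rule] += 1
    return records, report


def fragments_to_frame(fragments: Iterable[FragmentRecord]) -> pd.DataFrame:
    """Columnar view of a fragment collection (the featurizers' native input)."""
    rows = [(f.chrom, f.start, f.end, f.mapq) for f in fragments]
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


def as_fragment_frame(fragments) -> pd.DataFrame:
    if isinstance(fragments, pd.DataFrame):
        return fragments
    return fragments_to_frame(fragments)


def downsample(fragments, keep_fraction: float, seed: int):
    """Keep each fragment independently with probability ``keep_fraction``.

    Deterministic given the seed; ``keep_fraction == 1.0`` returns the input
    unchanged. Accepts and returns either a fragment DataFrame or a list of
    :class:`FragmentRecord`.
    """
    if not (0 < keep_fraction <= 1):
        raise ValueError("keep_fraction must be in (0, 1]")
    if keep_fraction == 1.0:
        return fragments
    rng = np.random.default_rng(seed)
    if isinstance(fragments, pd.DataFrame):
        mask = rng.random(len(fragments)) < keep_fraction
        return fragments[mask].reset_index(drop=True)
    fragments = list(fragments)
    mask = rng.random(len(fragments)) < keep_fraction
    return [f for f, m in zip(fragments, mask) if m]
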