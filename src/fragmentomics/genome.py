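"""Coordinate scaffolds: reference genome access, genomic bins, TSS annotation.

All coordinates are 0-based, half-open internally. BED input is consumed
natively; 1-based annotation formats must be converted at the reader boundary.
Chromosome-name dialects ("chr1" vs "1") are reconciled through a small
normalisation helper so BAMs aligned to hg19 or g1k_v37-style references both
work against the same bin and gene files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AUTOSOME_NAMES = frozenset(str(i) for i in range(1, 23))

# uint8 code per base: A=0 C=1 G=2 T=3, anything else (incl. N) = 4
_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def normalize_chrom(name: str) -> str:
    """Strip a leading 'chr' so 'chr1' and '1' compare equal."""
    return name[3:] if name.lower().startswith("chr") else name


def is_autosome(name: str) -> bool:
    return normalize_chrom(name) in AUTOSOME_NAMES


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeBundle:
    """Reference sequences plus chromosome sizes.

    Backed either by an in-memory dict of sequences (synthetic genomes) or a
    pyfaidx.Fasta handle (on-disk FASTA). ``fetch`` uses half-open coordinates
    and raises on out-of-bounds queries; ``base_array`` exposes a cached uint8
    encoding (A=0..T=3, other=4) used by the vectorised featurizers.
    """

    def __init__(self, sequences: Mapping[str, str] | "pyfaidx.Fasta"):
        self._backend = sequences
        self._arrays: dict[str, np.ndarray] = {}
        if isinstance(sequences, dict):
            self.chromosomes: list[tuple[str, int]] = [
                (name, len(seq)) for name, seq in sequences.items()
            ]
        else:  # pyfaidx-like
            self.chromosomes = [(name, len(sequences[name])) for name in sequences.keys()]
        names = [c[0] for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        self.lengths: dict[str, int] = dict(self.chromosomes)
        self._norm = {normalize_chrom(n): n for n in names}

    def resolve(self, chrom: str) -> str:
        """Map a possibly differently-dialected name onto this genome's names."""
        if chrom in self.lengths:
            return chrom
        key = normalize_chrom(chrom)
        if key in self._norm:
            return self._norm[key]
        raise KeyError(f"unknown chromosome {chrom!r}")

    def fetch(self, chrom: str, start: int, end: int) -> str:
        chrom = self.resolve(chrom)
        if start < 0 or end > self.lengths[chrom] or start > end:
            raise ValueError(
                f"query {chrom}:{start}-{end} outside chromosome of length {self.lengths[chrom]}"
            )
        if isinstance(self._backend, dict):
            return self._backend[chrom][start:end].upper()
        return str(self._backend[chrom][start:end]).upper()

    def base_array(self, chrom: str) -> np.ndarray:
        """Whole-chromosome uint8 base codes, cached after first use."""
        chrom = self.resolve(chrom)
        if chrom not in self._arrays:
            seq = self.fetch(chrom, 0, self.lengths[chrom])
            self._arrays[chrom] = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        return self._arrays[chrom]


def load_genome(fasta_path: str | Path) -> GenomeBundle:
    """Open a (faidx-indexable) FASTA as a :class:`GenomeBundle`."""
    import pyfaidx

    path = Path(fasta_path)
    if not path.exists():
        raise FileNotFoundError(path)
    return GenomeBundle(pyfaidx.Fasta(str(path)))


@dataclass(frozen=True)
class BinSet:
    """Ordered, non-overlapping genomic bins with contiguous indices 0..B-1."""

    frame: pd.DataFrame  # columns: chrom, start, end, index
    width: int

    def __post_init__(self):
        df = self.frame
        if not (df["index"].values == np.arange(len(df))).all():
            raise ValueError("bin indices must be contiguous 0..B-1")
        for _, grp in df.groupby("chrom", sort=False):
            s, e = grp["start"].values, grp["end"].values
            if not ((s[1:] >= e[:-1]).all() and (s < e).all()):
                raise ValueError("bins must be ordered and non-overlapping per chromosome")

    def __len__(self) -> int:
        return len(self.frame)

    def lookup_tables(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends, indices) arrays for midpoint assignment."""
        out = {}
        for chrom, grp in self.frame.groupby("chrom", sort=False):
            out[normalize_chrom(chrom)] = (
                grp["start"].values.astype(np.int64),
                grp["end"].values.astype(np.int64),
                grp["index"].values.astype(np.int64),
            )
        return out

    def to_bed(self, path: str | Path) -> None:
        self.frame[["chrom", "start", "end", "index"]].to_csv(
            path, sep="\t", header=False, index=False
        )

    @classmethod
    def from_bed(cls, path: str | Path, width: int | None = None) -> "BinSet":
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"]
        )
        df["index"] = np.arange(len(df))
        if width is None:
            width = int((df["end"] - df["start"]).mode().iloc[0])
        return cls(df, width)


def tile_bins(
    genome: GenomeBundle, width_bp: int, include_chroms: Sequence[str] | None = None
) -> BinSet:
    """Tile chromosomes into consecutive fixed-width windows.

    A trailing window shorter than ``width_bp`` is dropped so every bin has
    identical width and coverage stays comparable across bins.
    """
    if width_bp <= 0:
        raise ValueError("width_bp must be positive")
    chroms = [c for c, _ in genome.chromosomes] if include_chroms is None else [
        genome.resolve(c) for c in include_chroms
    ]
    rows = []
    for chrom in chroms:
        length = genome.lengths[chrom]
        for start in range(0, length - width_bp + 1, width_bp):
            rows.append((chrom, start, start + width_bp))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["index"] = np.arange(len(df))
    return BinSet(df, width_bp)


def load_builtin_bins() -> BinSet:
    """Load the shipped 504-bin, 5-Mb hg19 autosome scaffold.

    The file is a synthetic stand-in for the DELFI filtered tiling: a naive
    5-Mb tiling of the hg19 autosomes with the first and last bin of each
    chromosome and the centromere-containing bin of the 19 largest
    chromosomes removed, which leaves 504 bins. Bin *count and width* match
    the published scaffold; the exact excluded regions do not.
    """
    with resources.as_file(
        resources.files("fragmentomics.data") / "hg19_autosome_5mb_bins.synthetic.bed"
    ) as p:
        return BinSet.from_bed(p, width=5_000_000)


@dataclass
class GeneAnnotation:
    """Gene TSSs with strand, plus the windows the NF statistic needs.

    For minus-strand genes orientation is strand-aware: "upstream" means
    larger genomic coordinates. The central window at the default half-width
    of 250 spans 501 positions regardless of strand.
    """

    frame: pd.DataFrame  # columns: gene_id, chrom, tss, strand
    central_halfwidth: int = 250
    reference_offsets: tuple[tuple[int, int], tuple[int, int]] = ((-2000, -1000), (1000, 2000))

    def __post_init__(self):
        if self.frame["gene_id"].duplicated().any():
            raise ValueError("gene ids must be unique")
        bad = ~self.frame["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError(f"invalid strand values: {self.frame.loc[bad, 'strand'].unique()}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def max_extent(self) -> int:
        """Largest |offset| any per-gene window reaches from the TSS."""
        return max(
            self.central_halfwidth,
            max(abs(b) for pair in self.reference_offsets for b in pair),
        )

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def load_gene_annotation(
    path: str | Path,
    genome: GenomeBundle,
    central_halfwidth: int = 250,
    reference_offsets: tuple[tuple[int, int], tuple[int, int]] = ((-2000, -1000), (1000, 2000)),
) -> GeneAnnotation:
    """Read a TSV (gene_id, chrom, tss, strand); drop genes whose windows
    would extend beyond chromosome bounds, logging the dropped count."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    required = {"gene_id", "chrom", "tss", "strand"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    ann = GeneAnnotation(df, central_halfwidth, reference_offsets)
    extent = ann.max_extent
    keep = []
    for _, row in df.iterrows():
        chrom = genome.resolve(row["chrom"])
        tss = int(row["tss"])
        keep.append(tss - extent >= 0 and tss + extent < genome.lengths[chrom])
    kept = df[np.array(keep)].reset_index(drop=True)
    dropped = len(df) - len(kept)
    if dropped:
        logger.info("dropped %d genes with out-of-bounds windows", dropped)
    return GeneAnnotation(kept, central_halfwidth, reference_offsets)
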