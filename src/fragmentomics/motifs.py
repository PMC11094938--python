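"""Fragment 5'-end motif features and end-composition diagnostics.

The main feature is the 9-bp "codon" end motif: three separate 3-bp motifs
read at offsets 1, 4 and 7 within the informative part of each fragment end,
64 motifs per position, 192 features in total. With UMI-attached library
chemistry the first bases of the read are perturbed, so position 1 is taken
to be the (umi_offset+1)-th base of the end; umi_offset defaults to 5 (the
6th base is position 1) and should be 0 for UMI-free data.

Motifs are read from the REFERENCE sequence at the fragment's coordinates,
not from read bases, which removes sequencing-error noise. Both 5' ends of
every fragment contribute: the left end as-is and the right end as the
reverse complement of the reference, so both are read 5'->3' on their own
strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np

from .fragments import as_fragment_frame
from .genome import GenomeBundle, reverse_complement

BASES = "ACGT"


def motif_names(width: int) -> list[str]:
    """All 4^width motifs in the lexicographic order used by the count vectors."""
    return ["".join(p) for p in product(BASES, repeat=width)]


@dataclass(frozen=True)
class MotifConfig:
    umi_offset: int = 5
    positions: tuple[int, ...] = (1, 4, 7)  # 1-based starts within the end window
    width: int = 3

    def __post_init__(self):
        if self.umi_offset < 0 or self.width < 1 or min(self.positions) < 1:
            raise ValueError("umi_offset >= 0, width >= 1, positions >= 1 required")

    @property
    def window(self) -> int:
        """Bases of reference needed beyond each fragment end."""
        return self.umi_offset + max(self.positions) + self.width - 1

    @property
    def n_features(self) -> int:
        return len(self.positions) * 4 ** self.width


@dataclass
class MotifProfile:
    """Per-position motif frequency blocks; each block is its own simplex."""

    positions: tuple[int, ...]
    width: int
    counts: dict  # position -> int64 array of length 4**width
    skipped_ends: int = 0

    def frequencies(self, position: int) -> np.ndarray:
        c = self.counts[position].astype(float)
        total = c.sum()
        return c / total if total > 0 else c

    def vector(self) -> np.ndarray:
        return np.concatenate([self.frequencies(p) for p in self.positions])


def fragment_end_sequences(frag, genome: GenomeBundle, window_bp: int) -> tuple[str, str]:
    """The two 5'-end sequences of a fragment, each read 5'->3'.

    Left = reference[start, start+window); right = reverse complement of
    reference[end-window, end). Raises if the window leaves the chromosome.
    """
    left = genome.fetch(frag.chrom, frag.start, frag.start + window_bp)
    right = reverse_complement(genome.fetch(frag.chrom, frag.end - window_bp, frag.end))
    return left, right


def _end_code_matrix(
    frame, genome: GenomeBundle, offsets: np.ndarray
) -> tuple[np.ndarray, int]:
    """Base codes at the given offsets from each 5' end (both ends stacked).

    Offset j of the left end is reference position start+j; offset j of the
    right end is the complement of reference position end-1-j. Ends whose
    offsets would leave the chromosome are skipped and tallied. Returns a
    (2 * n_kept_ends, len(offsets)) uint8 matrix (codes 0..3, 4 = non-ACGT).
    """
    blocks, skipped = [], 0
    lo, hi = int(offsets.min()), int(offsets.max())
    for chrom, sub in frame.groupby("chrom", sort=False):
        arr = genome.base_array(chrom)
        L = len(arr)
        starts = sub["start"].values.astype(np.int64)
        ends = sub["end"].values.astype(np.int64)
        ok_left = (starts + lo >= 0) & (starts + hi < L)
        ok_right = (ends - 1 - hi >= 0) & (ends - 1 - lo < L)
        skipped += int((~ok_left).sum() + (~ok_right).sum())
        if ok_left.any():
            blocks.append(arr[starts[ok_left, None] + offsets[None, :]])
        if ok_right.any():
            codes = arr[(ends[ok_right, None] - 1) - offsets[None, :]]
            comp = np.where(codes < 4, 3 - codes, 4).astype(np.uint8)
            blocks.append(comp)
    if not blocks:
        return np.empty((0, len(offsets)), dtype=np.uint8), skipped
    return np.vstack(blocks), skipped


def count_codon_motifs(
    fragments, genome: GenomeBundle, cfg: MotifConfig | None = None
) -> MotifProfile:
    """Count the per-position 3-bp motifs over both 5' ends of every fragment.

    The motif at (1-based) position p occupies bases
    [umi_offset + p, umi_offset + p + width) of the end sequence. Motifs
    containing a non-ACGT base are skipped for that position only; each
    position's counts are normalized independently.
    """
    cfg = cfg or MotifConfig()
    frame = as_fragment_frame(fragments)
    offsets = np.arange(cfg.window, dtype=np.int64)
    codes, skipped = _end_code_matrix(frame, genome, offsets)
    weights = 4 ** np.arange(cfg.width - 1, -1, -1)
    counts = {}
    for p in cfg.positions:
        block = codes[:, cfg.umi_offset + p - 1 : cfg.umi_offset + p - 1 + cfg.width]
        valid = (block < 4).all(axis=1)
        idx = (block[valid].astype(np.int64) * weights).sum(axis=1)
        counts[p] = np.bincount(idx, minlength=4 ** cfg.width).astype(np.int64)
    return MotifProfile(tuple(cfg.positions), cfg.width, counts, skipped)


def count_kmer_end_motifs(
    fragments, genome: GenomeBundle, k: int, umi_offset: int = 0
) -> np.ndarray:
    """Plain k-mer end-motif frequencies (4^k vector), both ends counted."""
    if not 1 <= k <= 8:
        raise ValueError("k must be in 1..8")
    profile = count_codon_motifs(
        fragments, genome, MotifConfig(umi_offset=umi_offset, positions=(1,), width=k)
    )
    return profile.frequencies(1)


def end_gc_content(fragments, genome: GenomeBundle, max_pos: int = 140) -> np.ndarray:
    """Fraction of fragment ends carrying G or C at each of positions 1..max_pos."""
    if max_pos < 1:
        raise ValueError("max_pos must be >= 1")
    frame = as_fragment_frame(fragments)
    codes, _ = _end_code_matrix(frame, genome, np.arange(max_pos, dtype=np.int64))
    valid = codes < 4
    gc = (codes == 1) | (codes == 2)
    with np.errstate(invalid="ignore"):
        return gc.sum(axis=0) / valid.sum(axis=0)


def base_occurrence_correlation(
    sample_fragment_sets: Sequence, genome: GenomeBundle, flank: int = 10
) -> dict:
    """Across-sample Pearson correlation of base frequencies between positions.

    For each sample, the frequency of each base is computed at reference
    positions -flank..+flank relative to the fragment 5' end (position 0 is
    the first fragment base; negative offsets lie outside the fragment). The
    returned dict maps each base, plus "pooled" (mean over bases), to a
    (2*flank+1) x (2*flank+1) correlation matrix; zero-variance positions
    yield NaN entries.
    """
    if len(sample_fragment_sets) < 2:
        raise ValueError("need at least 2 samples to correlate across samples")
    offsets = np.arange(-flank, flank + 1, dtype=np.int64)
    freqs = np.empty((len(sample_fragment_sets), 4, len(offsets)))
    for s, frags in enumerate(sample_fragment_sets):
        codes, _ = _end_code_matrix(as_fragment_frame(frags), genome, offsets)
        valid = (codes < 4).sum(axis=0).astype(float)
        for b in range(4):
            with np.errstate(invalid="ignore"):
                freqs[s, b] = (codes == b).sum(axis=0) / valid
    out = {}
    mats = []
    for b, base in enumerate(BASES):
        with np.errstate(invalid="ignore", divide="ignore"):
            mat = np.corrcoef(freqs[:, b, :], rowvar=False)
        out[base] = mat
        mats.append(mat)
    out["pooled"] = np.nanmean(np.stack(mats), axis=0)
    out["offsets"] = offsets
    return out
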