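"""Nucleosome footprint (NF) at transcription start sites.

Nucleosome-bound DNA is protected from nuclease digestion, so cfDNA coverage
dips over the nucleosome-depleted region of actively transcribed promoters.
The NF statistic for a gene is the mean fragment coverage of the central
window (TSS +/- 250 bp, 501 strand-oriented positions) divided by the mean
coverage of the flanking reference windows ([-2000,-1000] and [1000,2000]
relative to the TSS, closed intervals). Low NF indicates depletion and hence
active transcription. Coverage counts whole fragments (the protected
molecule), not individual reads, and the ratio is invariant to uniform
sequencing-depth scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragments import as_fragment_frame
from .genome import GeneAnnotation, normalize_chrom

TSS_FLANK = 2000  # coverage arrays span [-TSS_FLANK, +TSS_FLANK]


def coverage_around_tss(
    fragments,
    genes: GeneAnnotation,
    flank: int = TSS_FLANK,
    max_fragment_length: int = 1000,
) -> np.ndarray:
    """Strand-oriented per-position fragment coverage around every TSS.

    Returns an (n_genes, 2*flank+1) array where column j is the number of
    fragments covering strand-oriented offset j-flank from the TSS (offsets
    increase downstream; minus-strand genes are mirrored).
    ``max_fragment_length`` bounds the candidate search window and must be at
    least the longest fragment present.
    """
    if len(genes) == 0:
        raise ValueError("empty gene annotation")
    frame = as_fragment_frame(fragments)
    width = 2 * flank + 1
    cov = np.zeros((len(genes), width), dtype=np.int64)

    by_chrom = {}
    if len(frame):
        chrom_keys = frame["chrom"].map(normalize_chrom)
        for chrom, idx in frame.groupby(chrom_keys).groups.items():
            sub = frame.loc[idx].sort_values("start")
            by_chrom[chrom] = (
                sub["start"].values.astype(np.int64),
                sub["end"].values.astype(np.int64),
            )

    for g, row in enumerate(genes.frame.itertuples(index=False)):
        key = normalize_chrom(row.chrom)
        if key not in by_chrom:
            continue
        starts, ends = by_chrom[key]
        tss = int(row.tss)
        win_lo, win_hi = tss - flank, tss + flank + 1
        lo = np.searchsorted(starts, win_lo - max_fragment_length, side="left")
        hi = np.searchsorted(starts, win_hi, side="left")
        s, e = starts[lo:hi], ends[lo:hi]
        overlap = e > win_lo
        s, e = s[overlap], e[overlap]
        diff = np.zeros(width + 1, dtype=np.int64)
        np.add.at(diff, np.clip(s - win_lo, 0, width), 1)
        np.add.at(diff, np.clip(e - win_lo, 0, width), -1)
        profile = np.cumsum(diff[:-1])
        cov[g] = profile[::-1] if row.strand == "-" else profile
    return cov


def nucleosome_footprint(
    coverage: np.ndarray, genes: GeneAnnotation, flank: int = TSS_FLANK
) -> pd.DataFrame:
    """Per-gene NF table: central mean, reference mean, and their ratio.

    NF is NaN (missing) when the reference windows have zero coverage.
    """
    if coverage.shape[1] < 2 * flank + 1:
        raise ValueError("coverage arrays narrower than the NF windows")
    hw = genes.central_halfwidth
    center = slice(flank - hw, flank + hw + 1)
    ref_cols = np.concatenate(
        [np.arange(flank + a, flank + b + 1) for a, b in genes.reference_offsets]
    )
    central_mean = coverage[:, center].mean(axis=1)
    reference_mean = coverage[:, ref_cols].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        nf = np.where(reference_mean > 0, central_mean / reference_mean, np.nan)
    return pd.DataFrame(
        {
            "gene_id": genes.frame["gene_id"].values,
            "central_mean": central_mean,
            "reference_mean": reference_mean,
            "nf": nf,
        }
    )


@dataclass
class NFAssembly:
    """Frozen gene panel + imputation means, reusable on new samples."""

    gene_ids: list
    impute_means: np.ndarray

    def transform(self, profiles: dict) -> np.ndarray:
        """Build the (samples x genes) NF matrix for ``profiles`` using the
        panel and imputation means fit at assembly time."""
        mat = np.empty((len(profiles), len(self.gene_ids)))
        for i, prof in enumerate(profiles.values()):
            nf = prof.set_index("gene_id")["nf"].reindex(self.gene_ids).values
            missing = np.isnan(nf)
            nf[missing] = self.impute_means[missing]
            mat[i] = nf
        return mat


def assemble_nf_features(
    profiles: dict, min_presence: float = 1.0
) -> tuple[NFAssembly, np.ndarray]:
    """Select the gene panel and build the NF feature matrix.

    ``profiles`` maps sample id -> the DataFrame from
    :func:`nucleosome_footprint`. Genes with a non-missing NF in at least
    ``min_presence`` of samples are kept (deterministic annotation order);
    remaining missing values are imputed with the gene's cross-sample mean.
    The returned :class:`NFAssembly` carries the panel and imputation means so
    held-out samples are transformed with training-fit parameters only.
    """
    if not profiles:
        raise ValueError("no samples")
    ids0 = list(next(iter(profiles.values()))["gene_id"])
    wide = pd.DataFrame(
        {sid: prof.set_index("gene_id")["nf"].reindex(ids0) for sid, prof in profiles.items()}
    ).T  # samples x genes
    presence = wide.notna().mean(axis=0)
    keep = presence[presence >= min_presence].index.tolist()
    if not keep:
        raise ValueError("no gene passes the presence filter")
    sub = wide[keep]
    means = sub.mean(axis=0, skipna=True).values
    assembly = NFAssembly(keep, means)
    return assembly, assembly.transform(profiles)
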