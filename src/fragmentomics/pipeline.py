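"""Per-sample featurization and cohort feature-matrix assembly.

Each qualified fragment set yields three feature vectors:

* fragment-size profile — z-scored short and total per-bin coverage (2B dims);
* codon end motifs — 3 x 64 motif frequencies (192 dims at defaults);
* nucleosome footprint — one NF ratio per annotated gene.

The global insert filter keeps 150-600 bp fragments, but the short-fragment
class of the size profile starts at 130 bp, so featurization applies
per-family insert windows (from ``QCConfig.feature_insert_bounds``) within
the otherwise-qualified fragments: 130-237 bp for the size profile and
150-600 bp for motifs and NF. NF panel selection and imputation are fit on
the training cohort only and applied frozen to held-out samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fragments import QCConfig, as_fragment_frame
from .genome import BinSet, GeneAnnotation, GenomeBundle
from .motifs import MotifConfig, count_codon_motifs
from .nucleosome import NFAssembly, assemble_nf_features, coverage_around_tss, nucleosome_footprint
from .size_profile import SizeClassBounds, count_size_classes, zscore_profile

FAMILIES = ("fragment", "motif", "nf")


@dataclass
class SampleFeatures:
    size_vector: np.ndarray
    motif_vector: np.ndarray
    nf_profile: pd.DataFrame  # gene_id, central_mean, reference_mean, nf


def _length_mask(frame: pd.DataFrame, bounds: tuple[int, int]) -> pd.DataFrame:
    lengths = frame["end"] - frame["start"]
    return frame[(lengths >= bounds[0]) & (lengths <= bounds[1])]


def extract_sample_features(
    fragments,
    genome: GenomeBundle,
    bins: BinSet,
    genes: GeneAnnotation,
    qc: QCConfig | None = None,
    motif_cfg: MotifConfig | None = None,
    size_bounds: SizeClassBounds | None = None,
) -> SampleFeatures:
    qc = qc or QCConfig()
    frame = as_fragment_frame(fragments)
    size_vec = zscore_profile(count_size_classes(frame, bins, size_bounds))
    motif_frame = _length_mask(frame, qc.feature_insert_bounds["end_motif"])
    motif_vec = count_codon_motifs(motif_frame, genome, motif_cfg).vector()
    nf_frame = _length_mask(frame, qc.feature_insert_bounds["nucleosome_footprint"])
    cov = coverage_around_tss(nf_frame, genes)
    nf_profile = nucleosome_footprint(cov, genes)
    return SampleFeatures(size_vec, motif_vec, nf_profile)


@dataclass
class CohortFeatureMatrix:
    """Aligned per-family feature blocks plus labels and optional CA19-9."""

    sample_ids: list
    labels: np.ndarray
    blocks: dict  # family -> (n_samples, n_features) array
    ca19_9: np.ndarray | None = None
    nf_assembly: NFAssembly | None = None

    def __post_init__(self):
        n = len(self.sample_ids)
        for fam, block in self.blocks.items():
            if block.shape[0] != n:
                raise ValueError(f"block {fam!r} has {block.shape[0]} rows, expected {n}")
            if np.isnan(block).any():
                raise ValueError(f"block {fam!r} contains missing values")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def binary_labels(self, positive: set | frozenset) -> np.ndarray:
        return np.array([1 if l in positive else 0 for l in self.labels])

    def subset(self, mask: np.ndarray) -> "CohortFeatureMatrix":
        return CohortFeatureMatrix(
            [s for s, m in zip(self.sample_ids, mask) if m],
            self.labels[mask],
            {f: b[mask] for f, b in self.blocks.items()},
            None if self.ca19_9 is None else self.ca19_9[mask],
            self.nf_assembly,
        )

    def to_tsv(self, path) -> None:
        cols, names = [], []
        for fam in FAMILIES:
            block = self.blocks[fam]
            cols.append(block)
            names += [f"{fam}_{i}" for i in range(block.shape[1])]
        df = pd.DataFrame(np.hstack(cols), index=self.sample_ids, columns=names)
        df.insert(0, "label", self.labels)
        if self.ca19_9 is not None:
            df.insert(1, "ca19_9", self.ca19_9)
        df.to_csv(path, sep="\t", index_label="sample_id")


def build_feature_matrix(
    samples: dict,
    metadata: pd.DataFrame,
    genome: GenomeBundle,
    bins: BinSet,
    genes: GeneAnnotation,
    qc: QCConfig | None = None,
    motif_cfg: MotifConfig | None = None,
    nf_assembly: NFAssembly | None = None,
    min_presence: float = 1.0,
) -> CohortFeatureMatrix:
    """Featurize every sample and assemble aligned feature blocks.

    Pass the training cohort's ``nf_assembly`` when featurizing a held-out
    cohort so its gene panel and imputation means are reused; otherwise the
    panel is fit here.
    """
    meta = metadata.set_index("sample_id")
    feats = {
        sid: extract_sample_features(frame, genome, bins, genes, qc, motif_cfg)
        for sid, frame in samples.items()
    }
    sample_ids = list(feats)
    profiles = {sid: feats[sid].nf_profile for sid in sample_ids}
    if nf_assembly is None:
        nf_assembly, nf_block = assemble_nf_features(profiles, min_presence)
    else:
        nf_block = nf_assembly.transform(profiles)
    blocks = {
        "fragment": np.vstack([feats[s].size_vector for s in sample_ids]),
        "motif": np.vstack([feats[s].motif_vector for s in sample_ids]),
        "nf": nf_block,
    }
    labels = meta.loc[sample_ids, "label"].values
    ca = meta.loc[sample_ids, "ca19_9"].values.astype(float) if "ca19_9" in meta else None
    return CohortFeatureMatrix(sample_ids, labels, blocks, ca, nf_assembly)
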