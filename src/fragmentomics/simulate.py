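"""Synthetic cfDNA cohort generator.

Generates a small random genome plus labeled per-sample fragment sets and
CA19-9 values, with controllable class effects in each of the three feature
families the pipeline measures:

* fragment size — every class draws lengths from a mononucleosome Gaussian
  (mode ~166 bp) plus a sub-nucleosomal component with an ~10-bp comb below
  160 bp and a small dinucleosome shoulder; cancer classes add extra short
  fragments confined to a fixed subset of genomic regions, producing both the
  global leftward size shift and the regional short/long imbalance that the
  binned profile detects (a purely global shift would vanish under
  within-sample z-scoring);
* end motifs — fragment start positions are resampled toward sites whose
  REFERENCE context matches class-specific base weights and planted motif
  log-fold-changes, so reference-based motif extraction sees the effect
  without any sequence rewriting;
* nucleosome footprint — fragments whose midpoint falls in the central
  window of an expressed gene are rejection-thinned in proportion to
  (depletion depth x expression); cancer classes additionally deplete
  designated differential genes.

CA19-9 is log-normal per class, with a Lewis-negative subset of cancer
patients forced low regardless of tumour burden. All randomness flows from
one root seed through per-sample derived seeds, so any sample is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import BinSet, GeneAnnotation, GenomeBundle, tile_bins

CLASSES = ("non_cancer", "CCA", "GBC", "PAC")
CANCER_CLASSES = ("CCA", "GBC", "PAC")

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SizeModel:
    """Per-class fragment-length mixture."""

    mono_mean: float = 166.0
    mono_sd: float = 10.0
    di_mean: float = 320.0
    di_sd: float = 25.0
    di_weight: float = 0.05
    comb_lo: int = 98
    comb_hi: int = 158
    comb_period: int = 10
    comb_jitter_sd: float = 1.2
    comb_weight: float = 0.12
    short_boost: float = 0.0  # extra short-fragment mass confined to effect regions


@dataclass
class MotifModel:
    """Per-class 5'-end composition: multiplicative base weights over the 9
    informative end positions plus planted codon-motif log-fold-changes."""

    base_bias: list = field(default_factory=lambda: np.ones((9, 4)).tolist())
    motif_lfc: dict = field(default_factory=dict)  # (position, motif) -> lfc


@dataclass
class CA199Model:
    """Log-normal serum CA19-9 (U/mL) on the natural-log scale."""

    log_mean: float = 2.3
    log_sd: float = 0.8
    lewis_negative_prob: float = 0.0
    lewis_log_mean: float = 1.6
    lewis_log_sd: float = 0.8


@dataclass
class ClassModel:
    size: SizeModel = field(default_factory=SizeModel)
    motif: MotifModel = field(default_factory=MotifModel)
    ca19_9: CA199Model = field(default_factory=CA199Model)
    n_diff_genes: int = 0  # class-specific differential NF genes
    diff_depletion: float = 0.0


@dataclass
class SyntheticCohortConfig:
    seed: int = 0
    # training cohort shape: 31 non-cancer + 16 CCA + 14 GBC + 28 PAC = 89
    n_per_class: dict = field(
        default_factory=lambda: {"non_cancer": 31, "CCA": 16, "GBC": 14, "PAC": 28}
    )
    # validation cohort shape: 40 + 39 + 16 + 34 = 129
    n_per_class_validation: dict = field(
        default_factory=lambda: {"non_cancer": 40, "CCA": 39, "GBC": 16, "PAC": 34}
    )
    n_chromosomes: int = 2
    chromosome_length: int = 750_000
    gc_content: float = 0.41
    markov_strength: float = 0.10  # P(copy previous base) -> adjacent-base correlation
    fragments_per_sample: int = 25_000
    bin_width: int = 50_000
    n_genes: int = 150
    expressed_fraction: float = 0.5
    depletion_depth: float = 0.7
    shared_diff_genes: int = 10  # depleted in every cancer class
    shared_diff_depletion: float = 0.6
    size_effect_fraction: float = 0.3  # fraction of bins carrying the cancer short excess
    motif_offset: int = 5  # informative end positions start after this many bases
    edge_margin: int = 700
    classes: dict = field(default_factory=dict)

    def class_model(self, label: str) -> ClassModel:
        if label not in self.classes:
            raise ValueError(f"unknown class {label!r}")
        return self.classes[label]


def _baseline_bias() -> np.ndarray:
    """Mild C/G enrichment at the first informative end positions, decaying
    over 9 bp (the shape real cfDNA end composition shows)."""
    decay = np.linspace(1.0, 0.0, 9)
    bias = np.ones((9, 4))
    bias[:, 1] += 0.30 * decay  # C
    bias[:, 2] += 0.18 * decay  # G
    return bias


def _cancer_bias(shift: float) -> np.ndarray:
    bias = _baseline_bias()
    decay = np.linspace(1.0, 0.0, 9)
    bias[:, 0] += shift * decay  # toward A
    bias[:, 1] -= 0.5 * shift * decay
    return bias


_CANCER_MOTIF_LFC = {
    (1, "AAG"): 0.6,
    (4, "ATG"): 0.6,
    (7, "ACA"): 0.6,
    (1, "GTT"): -0.6,
    (7, "GTC"): -0.6,
    (1, "GTC"): -0.6,
}


def default_config(**overrides) -> SyntheticCohortConfig:
    """Strong-effect study conditions: every cancer class carries size, motif,
    NF and CA19-9 contrasts against non-cancer; PAC carries the largest
    class-specific NF effect (so NF is the most informative family for
    PAC-vs-other contrasts)."""
    cfg = SyntheticCohortConfig(**overrides)
    if not cfg.classes:
        non_cancer = ClassModel(
            motif=MotifModel(base_bias=_baseline_bias().tolist()),
            ca19_9=CA199Model(log_mean=np.log(10.0), log_sd=0.8),
        )
        cancer_ca = CA199Model(
            log_mean=np.log(200.0), log_sd=1.5, lewis_negative_prob=0.08
        )
        cfg.classes = {"non_cancer": non_cancer}
        for label, n_diff in (("CCA", 4), ("GBC", 4), ("PAC", 10)):
            cfg.classes[label] = ClassModel(
                size=SizeModel(short_boost=0.08),
                motif=MotifModel(
                    base_bias=_cancer_bias(0.15).tolist(),
                    motif_lfc=dict(_CANCER_MOTIF_LFC),
                ),
                ca19_9=CA199Model(**asdict(cancer_ca)),
                n_diff_genes=n_diff,
                diff_depletion=0.6,
            )
    return cfg


def null_config(**overrides) -> SyntheticCohortConfig:
    """All class effects zero: every label generates from the non-cancer
    model, including CA19-9. Downstream models must not find signal."""
    overrides.setdefault("shared_diff_genes", 0)
    overrides.setdefault("shared_diff_depletion", 0.0)
    overrides.setdefault("size_effect_fraction", 0.0)
    cfg = SyntheticCohortConfig(**overrides)
    cfg.classes = {
        label: ClassModel(
            motif=MotifModel(base_bias=_baseline_bias().tolist()),
            ca19_9=CA199Model(log_mean=np.log(10.0), log_sd=0.8),
        )
        for label in CLASSES
    }
    return cfg


def _plain(obj):
    """Recursively convert numpy scalars/arrays and tuple motif keys to plain
    YAML-safe types."""
    if isinstance(obj, dict):
        return {
            (f"{k[0]}:{k[1]}" if isinstance(k, tuple) else k): _plain(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return _plain(obj.tolist())
    return obj


def config_to_yaml(cfg: SyntheticCohortConfig, path: str | Path) -> None:
    import yaml

    Path(path).write_text(yaml.safe_dump(_plain(asdict(cfg)), sort_keys=False))


def config_from_yaml(path: str | Path) -> SyntheticCohortConfig:
    import yaml

    raw = yaml.safe_load(Path(path).read_text())
    classes = {}
    for label, cm in raw.pop("classes", {}).items():
        lfc = {
            (int(k.split(":")[0]), k.split(":")[1]): v
            for k, v in cm["motif"].pop("motif_lfc", {}).items()
        }
        classes[label] = ClassModel(
            size=SizeModel(**cm["size"]),
            motif=MotifModel(motif_lfc=lfc, **cm["motif"]),
            ca19_9=CA199Model(**cm["ca19_9"]),
            n_diff_genes=cm["n_diff_genes"],
            diff_depletion=cm["diff_depletion"],
        )
    cfg = SyntheticCohortConfig(**raw)
    cfg.classes = classes
    return cfg


# ---------------------------------------------------------------------------
# genome


@dataclass
class GenomeArtifacts:
    genome: GenomeBundle
    bins: BinSet
    genes: GeneAnnotation
    expression: np.ndarray  # per-gene baseline expression in [0, 1]
    diff_gene_idx: dict  # class label -> indices of genes depleted in that class
    effect_bins: np.ndarray  # bin indices carrying the cancer short excess
    _thinning_cache: dict = field(default_factory=dict, repr=False)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        self.bins.to_bed(outdir / "bins.bed")
        self.genes.to_tsv(outdir / "genes.tsv")
        truth = self.genes.frame.copy()
        truth["expression"] = self.expression
        for label, idx in self.diff_gene_idx.items():
            col = np.zeros(len(truth), dtype=bool)
            col[idx] = True
            truth[f"diff_{label}"] = col
        truth.to_csv(outdir / "gene_truth.tsv", sep="\t", index=False)


def write_fasta(genome: GenomeBundle, path: str | Path, line_width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.chromosomes:
            fh.write(f">{chrom}\n")
            seq = genome.fetch(chrom, 0, length)
            for i in range(0, length, line_width):
                fh.write(seq[i : i + line_width] + "\n")


def _markov_sequence(rng, length: int, gc: float, markov: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draw = rng.choice(4, size=length, p=p)
    if markov > 0:
        copy = rng.random(length) < markov
        copy[0] = False
        anchors = np.where(~copy, np.arange(length), 0)
        draw = draw[np.maximum.accumulate(anchors)]
    return "".join(_BASES[i] for i in draw)


def simulate_genome(cfg: SyntheticCohortConfig) -> GenomeArtifacts:
    """Build the shared genome, bins, annotation, expression truth, per-class
    differential gene sets and the cancer size-effect regions."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    L = cfg.chromosome_length
    sequences = {
        f"chr{c + 1}": _markov_sequence(rng, L, cfg.gc_content, cfg.markov_strength)
        for c in range(cfg.n_chromosomes)
    }
    genome = GenomeBundle(sequences)
    bins = tile_bins(genome, cfg.bin_width)

    extent = 2000
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chromosomes))
    usable = L - 2 * (extent + cfg.edge_margin)
    spacing = usable // per_chrom
    if spacing < 2 * extent + 200:
        raise ValueError("genome too small for the requested gene count")
    rows = []
    for c in range(cfg.n_chromosomes):
        for i in range(per_chrom):
            if len(rows) >= cfg.n_genes:
                break
            tss = extent + cfg.edge_margin + i * spacing + spacing // 2
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"gene{len(rows):04d}", f"chr{c + 1}", tss, strand))
    genes = GeneAnnotation(pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"]))

    n = len(genes)
    expression = np.zeros(n)
    expressed = rng.choice(n, size=int(round(cfg.expressed_fraction * n)), replace=False)
    expression[expressed] = rng.uniform(0.3, 1.0, size=len(expressed))

    silent = np.setdiff1d(np.arange(n), expressed)
    rng.shuffle(silent)
    needed = cfg.shared_diff_genes + sum(
        m.n_diff_genes for m in cfg.classes.values() if m.n_diff_genes
    )
    if needed > len(silent):
        raise ValueError("not enough silent genes for the differential sets")
    shared = silent[: cfg.shared_diff_genes]
    cursor = cfg.shared_diff_genes
    diff_gene_idx = {}
    for label in CANCER_CLASSES:
        model = cfg.class_model(label) if label in cfg.classes else ClassModel()
        own = silent[cursor : cursor + model.n_diff_genes]
        cursor += model.n_diff_genes
        diff_gene_idx[label] = np.sort(np.concatenate([shared, own]))
    diff_gene_idx["shared"] = np.sort(shared)

    n_effect = int(round(cfg.size_effect_fraction * len(bins)))
    effect_bins = np.sort(rng.choice(len(bins), size=n_effect, replace=False))
    return GenomeArtifacts(genome, bins, genes, expression, diff_gene_idx, effect_bins)


# ---------------------------------------------------------------------------
# fragments


def _sample_lengths(rng, n: int, sm: SizeModel, comb_only: bool = False) -> np.ndarray:
    if n == 0:
        return np.empty(0, dtype=np.int64)
    centers = np.arange(sm.comb_lo, sm.comb_hi + 1, sm.comb_period)
    comb_w = np.linspace(0.35, 1.0, len(centers))
    comb_w /= comb_w.sum()

    def comb(k):
        c = rng.choice(centers, size=k, p=comb_w)
        return c + rng.normal(0, sm.comb_jitter_sd, size=k)

    if comb_only:
        lengths = comb(n)
    else:
        u = rng.random(n)
        lengths = rng.normal(sm.mono_mean, sm.mono_sd, size=n)
        di = u < sm.di_weight
        lengths[di] = rng.normal(sm.di_mean, sm.di_sd, size=int(di.sum()))
        sub = (u >= sm.di_weight) & (u < sm.di_weight + sm.comb_weight)
        lengths[sub] = comb(int(sub.sum()))
    return np.clip(np.rint(lengths), 60, 600).astype(np.int64)


def _thinning_keep_prob(cfg, art: GenomeArtifacts, label: str) -> dict:
    """Per-chromosome array of midpoint keep-probabilities for TSS depletion."""
    key = label
    if key in art._thinning_cache:
        return art._thinning_cache[key]
    model = cfg.class_model(label)
    depletion = cfg.depletion_depth * art.expression.copy()
    if label in CANCER_CLASSES:
        extra = np.zeros_like(depletion)
        extra[art.diff_gene_idx[label]] = np.maximum(
            cfg.shared_diff_depletion, model.diff_depletion
        )
        depletion = np.clip(depletion + extra, 0, 1)
    hw = art.genes.central_halfwidth
    keep = {c: np.ones(l, dtype=np.float32) for c, l in art.genome.chromosomes}
    for (gi, row) in enumerate(art.genes.frame.itertuples(index=False)):
        d = depletion[gi]
        if d <= 0:
            continue
        lo, hi = row.tss - hw, row.tss + hw + 1
        keep[row.chrom][lo:hi] = 1.0 - d
    art._thinning_cache[key] = keep
    return keep


def _motif_log_weight(cfg, model: MotifModel, art, chroms, starts, ends) -> np.ndarray:
    """Log selection weight from the reference context of both 5' ends."""
    log_bias = np.log(np.asarray(model.base_bias, dtype=float))
    n_pos = log_bias.shape[0]
    lfc_tables = {}
    for (pos, motif), lfc in model.motif_lfc.items():
        idx = 0
        for ch in motif:
            idx = idx * 4 + _BASES.index(ch)
        lfc_tables.setdefault(pos, np.zeros(64))[idx] += lfc
    offsets = cfg.motif_offset + np.arange(n_pos)
    logw = np.zeros(len(starts))
    for chrom in np.unique(chroms):
        arr = art.genome.base_array(chrom)
        sel = chroms == chrom
        s, e = starts[sel], ends[sel]
        left = arr[s[:, None] + offsets[None, :]].astype(np.int64)
        right = (3 - arr[(e[:, None] - 1) - offsets[None, :]].astype(np.int64)) % 4
        w = np.zeros(sel.sum())
        for codes in (left, right):
            w += log_bias[np.arange(n_pos)[None, :], codes].sum(axis=1)
            for pos, table in lfc_tables.items():
                j = pos - 1
                codon = codes[:, j] * 16 + codes[:, j + 1] * 4 + codes[:, j + 2]
                w += table[codon]
        logw[sel] = w
    return logw


def simulate_sample(
    cfg: SyntheticCohortConfig, label: str, art: GenomeArtifacts, seed
) -> pd.DataFrame:
    """Generate one sample's fragment frame (chrom, start, end, mapq).

    Proposal positions are uniform (the cancer short-excess pool is confined
    to the effect regions); TSS depletion is applied by Bernoulli thinning of
    central-window midpoints, then the class motif model selects the required
    number of fragments by weighted sampling without replacement (Gumbel
    top-k), which resamples starts toward matching reference contexts.
    """
    model = cfg.class_model(label)
    rng = np.random.default_rng(seed)
    n_total = cfg.fragments_per_sample
    n_boost = rng.binomial(n_total, model.size.short_boost)
    keep_prob = _thinning_keep_prob(cfg, art, label)

    chrom_names = [c for c, _ in art.genome.chromosomes]
    chrom_len = np.array([l for _, l in art.genome.chromosomes], dtype=np.int64)
    chrom_p = chrom_len / chrom_len.sum()
    eff = art.bins.frame.iloc[art.effect_bins]
    eff_chroms = eff["chrom"].values
    eff_starts = eff["start"].values.astype(np.int64)
    eff_width = art.bins.width

    def propose(k: int, boost: bool):
        lengths = _sample_lengths(rng, k, model.size, comb_only=boost)
        if boost:
            which = rng.integers(0, len(eff_starts), size=k)
            chroms = eff_chroms[which]
            starts = eff_starts[which] + rng.integers(0, eff_width, size=k)
            starts = np.minimum(
                starts, chrom_len[[chrom_names.index(c) for c in chroms]] - lengths - cfg.edge_margin
            )
        else:
            ci = rng.choice(len(chrom_names), size=k, p=chrom_p)
            chroms = np.array(chrom_names, dtype=object)[ci]
            span = chrom_len[ci] - lengths - 2 * cfg.edge_margin
            starts = cfg.edge_margin + (rng.random(k) * span).astype(np.int64)
        return chroms, starts, starts + lengths

    def build_pool(target: int, boost: bool):
        got_c, got_s, got_e, got_w = [], [], [], []
        have, rounds = 0, 0
        while have < target and rounds < 30:
            rounds += 1
            k = int((target - have) * 1.35) + 64
            chroms, starts, ends = propose(k, boost)
            mid = (starts + ends) // 2
            p = np.empty(k, dtype=np.float32)
            for chrom in np.unique(chroms):
                sel = chroms == chrom
                p[sel] = keep_prob[chrom][mid[sel]]
            survive = rng.random(k) < p
            chroms, starts, ends = chroms[survive], starts[survive], ends[survive]
            logw = _motif_log_weight(cfg, model.motif, art, chroms, starts, ends)
            got_c.append(chroms), got_s.append(starts), got_e.append(ends), got_w.append(logw)
            have += len(starts)
        chroms = np.concatenate(got_c)
        starts, ends = np.concatenate(got_s), np.concatenate(got_e)
        logw = np.concatenate(got_w)
        if len(starts) > target:  # weighted sampling without replacement
            keys = logw + rng.gumbel(size=len(logw))
            top = np.argpartition(-keys, target)[:target]
            chroms, starts, ends = chroms[top], starts[top], ends[top]
        return chroms, starts, ends

    parts = [build_pool(n_total - n_boost, boost=False)]
    if n_boost:
        parts.append(build_pool(n_boost, boost=True))
    frame = pd.DataFrame(
        {
            "chrom": np.concatenate([p[0] for p in parts]),
            "start": np.concatenate([p[1] for p in parts]),
            "end": np.concatenate([p[2] for p in parts]),
            "mapq": 60,
        }
    )
    return frame.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# cohorts


_ABBREV = {"non_cancer": "NC", "CCA": "CCA", "GBC": "GBC", "PAC": "PAC"}


@dataclass
class Cohort:
    artifacts: GenomeArtifacts
    samples: dict  # sample id -> fragment frame
    metadata: pd.DataFrame  # sample_id, label, ca19_9, lewis_negative
    truth: pd.DataFrame

    def write(self, outdir: str | Path, include_genome: bool = True) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if include_genome:
            self.artifacts.write(outdir)
        self.metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        frag_dir = outdir / "fragments"
        frag_dir.mkdir(exist_ok=True)
        for sid, frame in self.samples.items():
            frame.to_csv(frag_dir / f"{sid}.tsv", sep="\t", index=False)


def _draw_ca19_9(rng, model: CA199Model, cancer: bool) -> tuple[float, bool]:
    lewis = bool(cancer and rng.random() < model.lewis_negative_prob)
    if lewis:
        value = float(np.exp(rng.normal(model.lewis_log_mean, model.lewis_log_sd)))
    else:
        value = float(np.exp(rng.normal(model.log_mean, model.log_sd)))
    return round(value, 1), lewis


def simulate_cohort(
    cfg: SyntheticCohortConfig,
    art: GenomeArtifacts | None = None,
    n_per_class: dict | None = None,
    branch: int = 1,
    id_prefix: str = "",
) -> Cohort:
    """Generate ``n_per_class`` samples per label against a shared genome.

    ``branch`` separates the randomness of independently generated cohorts
    (e.g. training vs validation) that share one root seed and genome.
    """
    art = art or simulate_genome(cfg)
    n_per_class = n_per_class or cfg.n_per_class
    samples, meta_rows = {}, []
    for label in CLASSES:
        count = n_per_class.get(label, 0)
        model = cfg.class_model(label)
        for i in range(count):
            ss = np.random.SeedSequence([cfg.seed, branch, CLASSES.index(label), i])
            sid = f"{id_prefix}{_ABBREV[label]}{i + 1:03d}"
            samples[sid] = simulate_sample(cfg, label, art, ss)
            ca_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, branch, 99, CLASSES.index(label), i]))
            ca, lewis = _draw_ca19_9(ca_rng, model.ca19_9, label in CANCER_CLASSES)
            meta_rows.append((sid, label, ca, lewis))
    metadata = pd.DataFrame(meta_rows, columns=["sample_id", "label", "ca19_9", "lewis_negative"])
    truth = metadata.copy()
    truth["short_boost"] = [cfg.class_model(l).size.short_boost for l in truth["label"]]
    truth["diff_depletion"] = [cfg.class_model(l).diff_depletion for l in truth["label"]]
    return Cohort(art, samples, metadata, truth)


def simulate_study(cfg: SyntheticCohortConfig) -> tuple[GenomeArtifacts, Cohort, Cohort]:
    """One shared genome, a training cohort and a validation cohort with the
    configured class counts (defaults mirror an 89/129 two-cohort design)."""
    art = simulate_genome(cfg)
    train = simulate_cohort(cfg, art, cfg.n_per_class, branch=1, id_prefix="T")
    val = simulate_cohort(cfg, art, cfg.n_per_class_validation, branch=2, id_prefix="V")
    return art, train, val


# ---------------------------------------------------------------------------
# optional BAM rendering


def write_sample_bam(frame: pd.DataFrame, genome: GenomeBundle, path: str | Path,
                     read_length: int = 100) -> None:
    """Render a fragment frame as a coordinate-sorted, indexed paired-end BAM.

    Reads are perfect copies of the reference (proper-pair flags, MAPQ 60),
    which lets the BAM qualification path be exercised end-to-end on
    synthetic data.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": l} for c, l in genome.chromosomes],
    }
    tids = {c: i for i, (c, _) in enumerate(genome.chromosomes)}
    frame = frame.sort_values(["chrom", "start"], kind="stable")
    path = str(path)
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        records = []
        for i, row in enumerate(frame.itertuples(index=False)):
            rl = min(read_length, row.end - row.start)
            length = row.end - row.start
            for first in (True, False):
                a = pysam.AlignedSegment()
                a.query_name = f"frag{i:08d}"
                a.reference_id = tids[row.chrom]
                a.reference_start = row.start if first else row.end - rl
                a.mapping_quality = row.mapq
                a.cigarstring = f"{rl}M"
                a.query_sequence = genome.fetch(
                    row.chrom, a.reference_start, a.reference_start + rl
                )
                a.flag = (0x1 | 0x2 | 0x20 | 0x40) if first else (0x1 | 0x2 | 0x10 | 0x80)
                a.next_reference_id = a.reference_id
                a.next_reference_start = row.end - rl if first else row.start
                a.template_length = length if first else -length
                records.append(a)
        for a in sorted(records, key=lambda r: (r.reference_id, r.reference_start)):
            bam.write(a)
    pysam.index(path)
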