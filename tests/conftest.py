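import numpy as np
import pandas as pd
import pytest

from fragmentomics.genome import GenomeBundle
from fragmentomics.models import CANCER_LABELS, train_cf, train_stacked
from fragmentomics.pipeline import build_feature_matrix
from fragmentomics.simulate import default_config, simulate_study


def _random_sequence(rng, length, gc=0.45):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join("ACGT"[i] for i in rng.choice(4, size=length, p=p))


@pytest.fixture(scope="session")
def toy_genome():
    """Two small chromosomes plus an allosome; chr1 carries an N-run."""
    rng = np.random.default_rng(2024)
    chr1 = list(_random_sequence(rng, 10_000))
    chr1[4000:4050] = "N" * 50
    return GenomeBundle(
        {
            "chr1": "".join(chr1),
            "chr2": _random_sequence(rng, 8_000),
            "chrX": _random_sequence(rng, 5_000),
        }
    )


def make_pairs(rng, n=50):
    """Deterministic mixed-quality read pairs for the qualification oracle.

    Each tuple: (chrom, start, end, mapq1, mapq2, proper_pair).
    """
    pairs = []
    chroms = ["chr1"] * 30 + ["chr2"] * 15 + ["chrX"] * 5
    rng.shuffle(chroms)
    for chrom in chroms:
        insert = int(rng.choice([100, 140, 150, 166, 300, 600, 601, 700]))
        start = int(rng.integers(100, 4000))  # keeps every pair inside chrX too
        mapq1 = int(rng.choice([15, 20, 21, 40, 60]))
        mapq2 = int(rng.choice([20, 21, 60]))
        proper = bool(rng.random() > 0.15)
        pairs.append((chrom, start, start + insert, mapq1, mapq2, proper))
    return pairs


def write_pairs_bam(pairs, genome, path, read_length=50):
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": l} for c, l in genome.chromosomes],
    }
    tids = {c: i for i, (c, _) in enumerate(genome.chromosomes)}
    records = []
    for i, (chrom, start, end, mapq1, mapq2, proper) in enumerate(pairs):
        for first in (True, False):
            a = pysam.AlignedSegment()
            a.query_name = f"pair{i:04d}"
            a.reference_id = tids[chrom]
            a.reference_start = start if first else end - read_length
            a.mapping_quality = mapq1 if first else mapq2
            a.cigarstring = f"{read_length}M"
            a.query_sequence = "A" * read_length
            flag = 0x1 | 0x40 if first else 0x1 | 0x80 | 0x10
            if proper:
                flag |= 0x2
            a.flag = flag
            a.next_reference_id = a.reference_id
            a.next_reference_start = end - read_length if first else start
            a.template_length = (end - start) if first else -(end - start)
            records.append(a)
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for a in sorted(records, key=lambda r: (r.reference_id, r.reference_start)):
            bam.write(a)
    pysam.index(str(path))


@pytest.fixture(scope="session")
def pair_fixture(toy_genome, tmp_path_factory):
    rng = np.random.default_rng(7)
    pairs = make_pairs(rng, 50)
    path = tmp_path_factory.mktemp("bam") / "pairs.bam"
    write_pairs_bam(pairs, toy_genome, path)
    return pairs, path


@pytest.fixture(scope="session")
def strong_study():
    """Default strong-effect two-cohort study, featurized and fitted once."""
    cfg = default_config(seed=1)
    art, train, val = simulate_study(cfg)
    tr = build_feature_matrix(train.samples, train.metadata, art.genome, art.bins, art.genes)
    va = build_feature_matrix(
        val.samples, val.metadata, art.genome, art.bins, art.genes, nf_assembly=tr.nf_assembly
    )
    stacked = train_stacked(tr, seed=1)
    cf = train_cf(tr, stacked, seed=1)
    return {
        "cfg": cfg,
        "art": art,
        "train": train,
        "val": val,
        "tr": tr,
        "va": va,
        "stacked": stacked,
        "cf": cf,
    }
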