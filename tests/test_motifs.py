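import numpy as np
import pytest

from fragmentomics.fragments import FragmentRecord, fragments_to_frame
from fragmentomics.genome import GenomeBundle, reverse_complement
from fragmentomics.motifs import (
    MotifConfig,
    base_occurrence_correlation,
    count_codon_motifs,
    count_kmer_end_motifs,
    end_gc_content,
    fragment_end_sequences,
    motif_names,
)

NAMES3 = motif_names(3)


def symmetric_genome(core="GTTACAGGC", pad=0):
    """A chromosome whose single fragment reads the same 9-mer from both ends."""
    seq = "A" * pad + core + "TTTT" + reverse_complement(core) + "A" * pad
    return GenomeBundle({"chr1": seq}), pad, len(seq) - pad


class TestEndSequences:
    def test_left_right_readout(self):
        g = GenomeBundle({"chr1": "GTTACAGGCT"})
        frag = FragmentRecord("chr1", 0, 10)
        left, right = fragment_end_sequences(frag, g, 3)
        assert left == "GTT"
        assert right == "AGC"  # revcomp of GCT

    def test_palindromic_ends_agree(self):
        g = GenomeBundle({"chr1": "GAATTCAAAAGAATTC"})
        left, right = fragment_end_sequences(FragmentRecord("chr1", 0, 16), g, 6)
        assert left == right == "GAATTC"

    def test_window_beyond_chromosome_raises(self):
        g = GenomeBundle({"chr1": "ACGTACGT"})
        with pytest.raises(ValueError):
            fragment_end_sequences(FragmentRecord("chr1", 0, 8), g, 9)


class TestCodonMotifs:
    def test_single_fragment_bookkeeping(self):
        g, s, e = symmetric_genome("GTTACAGGC")
        prof = count_codon_motifs(
            fragments_to_frame([FragmentRecord("chr1", s, e)]),
            g,
            MotifConfig(umi_offset=0),
        )
        assert prof.frequencies(1)[NAMES3.index("GTT")] == 1.0
        assert prof.frequencies(4)[NAMES3.index("ACA")] == 1.0
        assert prof.frequencies(7)[NAMES3.index("GGC")] == 1.0

    def test_umi_offset_shifts_position_one(self):
        # same 9-mer preceded by 5 throwaway bases on each end
        core = "GTTACAGGC"
        seq = "CCCCC" + core + "TTTT" + reverse_complement("CCCCC" + core)
        g = GenomeBundle({"chr1": seq})
        prof = count_codon_motifs(
            fragments_to_frame([FragmentRecord("chr1", 0, len(seq))]),
            g,
            MotifConfig(umi_offset=5),
        )
        assert prof.frequencies(1)[NAMES3.index("GTT")] == 1.0
        assert prof.frequencies(7)[NAMES3.index("GGC")] == 1.0

    def test_default_config_emits_192_features(self):
        g, s, e = symmetric_genome("GTTACAGGC", pad=20)
        vec = count_codon_motifs(
            fragments_to_frame([FragmentRecord("chr1", s, e)]), g
        ).vector()
        assert vec.shape == (192,)

    def test_brute_force_oracle_on_random_fragments(self):
        """Vectorised counting equals naive per-fragment string counting."""
        rng = np.random.default_rng(21)
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        g = GenomeBundle({"chr1": seq})
        frags = []
        for _ in range(20):
            start = int(rng.integers(20, 2700))
            frags.append(FragmentRecord("chr1", start, start + int(rng.integers(120, 250))))
        cfg = MotifConfig(umi_offset=5)
        prof = count_codon_motifs(fragments_to_frame(frags), g, cfg)

        expected = {p: np.zeros(64) for p in cfg.positions}
        for f in frags:
            for end_seq in fragment_end_sequences(f, g, cfg.window):
                for p in cfg.positions:
                    motif = end_seq[cfg.umi_offset + p - 1 : cfg.umi_offset + p + 2]
                    expected[p][NAMES3.index(motif)] += 1
        for p in cfg.positions:
            np.testing.assert_array_equal(prof.counts[p], expected[p])

    def test_concatenation_is_count_weighted_average(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        g = GenomeBundle({"chr1": seq})
        mk = lambda n, off: [
            FragmentRecord("chr1", off + i * 7, off + i * 7 + 166) for i in range(n)
        ]
        a, b = mk(30, 50), mk(50, 1500)
        pa = count_codon_motifs(fragments_to_frame(a), g)
        pb = count_codon_motifs(fragments_to_frame(b), g)
        pab = count_codon_motifs(fragments_to_frame(a + b), g)
        for p in (1, 4, 7):
            weighted = (
                pa.frequencies(p) * pa.counts[p].sum() + pb.frequencies(p) * pb.counts[p].sum()
            ) / (pa.counts[p].sum() + pb.counts[p].sum())
            np.testing.assert_allclose(pab.frequencies(p), weighted, atol=1e-12)

    def test_block_frequencies_sum_to_one(self):
        g, s, e = symmetric_genome("GTTACAGGC", pad=30)
        prof = count_codon_motifs(fragments_to_frame([FragmentRecord("chr1", s, e)]), g)
        for p in (1, 4, 7):
            assert prof.frequencies(p).sum() == pytest.approx(1.0, abs=1e-9)


class TestKmerMotifs:
    def test_k4_yields_256_simplex(self):
        rng = np.random.default_rng(9)
        seq = "".join(rng.choice(list("ACGT"), size=4000))
        g = GenomeBundle({"chr1": seq})
        frags = fragments_to_frame(
            [FragmentRecord("chr1", i * 11 + 20, i * 11 + 186) for i in range(50)]
        )
        vec = count_kmer_end_motifs(frags, g, k=4)
        assert vec.shape == (256,)
        assert vec.sum() == pytest.approx(1.0)

    def test_k3_matches_position_one_block(self):
        rng = np.random.default_rng(13)
        seq = "".join(rng.choice(list("ACGT"), size=4000))
        g = GenomeBundle({"chr1": seq})
        frags = fragments_to_frame(
            [FragmentRecord("chr1", i * 13 + 20, i * 13 + 170) for i in range(40)]
        )
        vec = count_kmer_end_motifs(frags, g, k=3, umi_offset=0)
        block = count_codon_motifs(frags, g, MotifConfig(umi_offset=0)).frequencies(1)
        np.testing.assert_allclose(vec, block)

    def test_k1_on_all_a_ends(self):
        g = GenomeBundle({"chr1": "AAA" + "C" * 200 + "TTT"})
        frags = fragments_to_frame([FragmentRecord("chr1", 0, 206)])
        vec = count_kmer_end_motifs(frags, g, k=1)
        assert vec[0] == 1.0  # A

    def test_k_range_validated(self):
        with pytest.raises(ValueError):
            count_kmer_end_motifs(fragments_to_frame([]), GenomeBundle({"c": "A"}), k=9)


class TestDiagnostics:
    def test_gc_content_all_gc_genome(self):
        g = GenomeBundle({"chr1": "G" * 500})
        frags = fragments_to_frame([FragmentRecord("chr1", 10, 200)])
        np.testing.assert_allclose(end_gc_content(frags, g, max_pos=20), 1.0)

    def test_biased_end_composition_confined_to_first_9_positions(self):
        """With the end bias planted at offsets 0..8, GC deviation beyond
        position 9 stays at background level."""
        from fragmentomics.simulate import default_config, simulate_genome, simulate_sample

        cfg = default_config(seed=5, motif_offset=0, markov_strength=0.0,
                             fragments_per_sample=8000)
        art = simulate_genome(cfg)
        frame = simulate_sample(cfg, "non_cancer", art, np.random.SeedSequence(5))
        gc = end_gc_content(frame, art.genome, max_pos=40)
        baseline = cfg.gc_content
        early_dev = np.abs(gc[:9] - baseline)
        late_dev = np.abs(gc[12:] - baseline)
        assert early_dev.max() > 0.02
        assert late_dev.max() < 0.02

    def test_correlation_matrix_structure(self):
        from fragmentomics.simulate import default_config, simulate_genome, simulate_sample

        cfg = default_config(seed=6, markov_strength=0.35, fragments_per_sample=4000)
        art = simulate_genome(cfg)
        samples = [
            simulate_sample(cfg, "non_cancer", art, np.random.SeedSequence([6, i]))
            for i in range(6)
        ]
        out = base_occurrence_correlation(samples, art.genome, flank=6)
        mat = out["pooled"]
        assert np.allclose(np.diag(mat), 1.0)
        assert np.allclose(mat, mat.T, equal_nan=True)
        off1 = np.nanmean(np.diagonal(mat, offset=1))
        off4 = np.nanmean(np.diagonal(mat, offset=4))
        assert off1 > off4  # adjacent positions more correlated than distant

    def test_correlation_needs_two_samples(self):
        with pytest.raises(ValueError):
            base_occurrence_correlation([None], GenomeBundle({"c": "A"}), flank=3)
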