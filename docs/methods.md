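# Methods

## Fragment model and qualification

A cfDNA fragment is the outer interval spanned by an aligned read pair,
0-based half-open; the insert size is recomputed from mate coordinates
rather than taken from TLEN, whose sign/offset conventions vary by aligner.
Qualification applies five rules in a fixed order (autosome; pair-minimum
MAPQ strictly > 20; insert in the inclusive window [150, 600] bp; properly
paired; reference region containing only A/C/G/T), and the QC report tallies
the first failing rule so the counts partition the input. PCR deduplication
is assumed upstream; flagged duplicates are additionally dropped.

The 150-bp global floor conflicts with the 130-bp lower edge of the
short-fragment class and with the 90–160 bp sub-nucleosomal structure the
size diagnostic displays. Resolution: qualification is configurable per
feature (`QCConfig.feature_insert_bounds`); the pipeline qualifies broadly
and then applies 130–237 bp to the size profile, 150–600 bp to motifs and
NF, and 90–600 bp to the size-distribution diagnostic.

## Feature families

**Size profile.** Short = [130, 177), long = [177, 237]: the nominal class
definitions overlap at 177, resolved here half-open so the classes
partition and no fragment is double-counted (boundary mass is negligible).
Fragments map to at most one bin by midpoint. "Coverage" is implemented as
fragment counts, not base-pair coverage; at fixed length classes the two are
proportional and the within-sample z-score removes the difference. The
z-score uses the population SD across bins and maps constant vectors to
zero. Normalizing within sample (not across samples) keeps the transform
applicable to a single sample at predict time and makes the feature
invariant to uniform depth scaling. No GC correction is applied (an optional
extension point; the base pipeline does not model GC amplification bias).

**Codon end motifs.** Motifs are read from the reference at the fragment's
coordinates, not from read bases, which removes sequencing error and makes
UMI contamination a pure offset problem. Both 5′ ends contribute (left end
as-is, right end reverse-complemented), doubling counts symmetrically. Each
of the three position blocks is normalized to its own simplex so blocks are
comparable. Motifs containing a non-ACGT base are skipped per position.
`umi_offset` defaults to 5 (position 1 = 6th base) matching UMI-attached
chemistry; UMI-free data should use 0.

**Nucleosome footprint.** Coverage counts whole fragments — the protected
molecule — rather than reads, since the footprint is a fragment-level
phenomenon. Windows are closed and strand-oriented: central ±250 bp
(501 positions), reference [−2000, −1000] ∪ [1000, 2000]. NF is missing when
the reference windows have zero coverage. Panel assembly keeps genes with
non-missing NF in at least `min_presence` of training samples (default 1.0,
i.e. present everywhere), imputes the remainder with cross-sample means, and
freezes both the panel and the means for held-out cohorts. The gene-selection
rule behind published panel sizes is not derivable, so the annotation is
fully user-supplied and the presence filter is the explicit, logged
criterion.

## Models

Base learners: LinearSVC (C = 1) for the fragment and NF blocks, a 500-tree
random forest for the motif block; neither hyperparameter set is tuned.
Folds are stratified (class imbalance makes unstratified folds unstable at
n ≈ 89) and seeded; all three families share one fold assignment.
Standardization and calibration are fit inside training folds only. SVC
margins become [0, 1] scores through a logistic calibration fit on
training-fold margins — the standard bridge that makes margins commensurate
with forest vote fractions. The meta-learner is logistic regression on the
three out-of-fold score columns, effectively unpenalized (C = 1e6; a truly
penalty-free fit does not converge on separable score columns). Out-of-fold
*stacked* scores come from per-fold meta-learners, so the Gini cutoff and
the CF model train on scores that never saw their own sample.

The decision cutoff minimizes n_L/n·Gini(L) + n_R/n·Gini(R) over midpoints
of consecutive sorted unique scores, ties broken toward the larger cutoff
(higher specificity). The CF model standardizes (out-of-fold stacked score,
log2(CA19-9 + 1)) and fits a LinearSVC; its boundary is exportable as a line
in the raw 2-D plane. Validation cohorts are scored by the refit-on-all-
training models, not a fold ensemble.

Sensitivity "at 95% specificity" means: the threshold maximizing sensitivity
subject to specificity ≥ 0.95 on controls. Group comparisons use two-sided
Mann–Whitney U (exact for combined n ≤ 20 without ties). Cross-validated AUC
intervals are fold-wise percentiles and are labelled as such.

## Synthetic cohorts

The generator's defaults are the study conditions for all shipped tests:
89 training samples (31 non-cancer, 16 CCA, 14 GBC, 28 PAC) and 129
validation samples (40/39/16/34), 25,000 fragments per sample on a
2 × 750 kb genome with 150 genes — about 2.8× coverage, matching the
low-coverage regime the pipeline targets while keeping a full study under a
minute of compute. Bins are 50 kb (30 bins; bin width scales with the
genome, the feature is 2B-dimensional throughout).

Per class it emulates:

* **sizes** — mononucleosome Gaussian (mean 166, SD 10 bp), a 5%
  dinucleosome shoulder (320 ± 25 bp), and a 12% sub-nucleosomal component
  with a 10-bp comb over 98–158 bp, weights rising toward the mode. Cancer
  classes add 8% extra comb-only fragments confined to a fixed 30% subset of
  bins: a purely global shift would be erased by within-sample z-scoring, so
  the cancer signal is regional, as in real tumour-derived profiles, while
  still shifting the mean length left.
* **end motifs** — proposals are re-selected (Gumbel top-k weighted sampling
  without replacement) toward reference contexts matching per-class base
  weights over the 9 informative end positions plus log-fold-changes on six
  planted codon motifs (three up, three down in cancer). Selection moves
  start positions, never rewrites sequence, so reference-based extraction
  stays honest.
* **NF** — fragments whose midpoint lands in an expressed gene's central
  window are thinned with probability depletion × expression (default depth
  0.7); cancer classes additionally deplete 10 shared differential genes
  (plus 4/4/10 class-specific ones for CCA/GBC/PAC, giving PAC the largest
  class-specific NF signature) chosen among baseline-silent genes.
* **CA19-9** — log-normal per class (median 10 U/mL non-cancer, 200 U/mL
  cancer, σ_ln = 1.5), with an 8% Lewis-negative cancer subset forced low
  regardless of class, so the fragmentomic score has something real to
  rescue below the 39 U/mL clinical cutoff.

All randomness flows from one root seed through per-sample `SeedSequence`
derivations; any sample is reproducible in isolation. `null_config` zeroes
every class effect including the cohort-level shared differential genes and
the regional size effect.

What the generator does **not** model: sequencing error, base qualities,
duplicates/UMIs at read level, GC amplification bias, copy-number structure,
mappability, or a true nucleosome-positioning map. Passing tests therefore
demonstrate that the pipeline measures what it claims and does not
manufacture signal — not that real-cohort AUCs are reproduced.

## Numerical and testing choices

* Under the all-null cohort the stacked out-of-fold AUC is noisy around
  chance: the meta-learner weights whichever base column shows the largest
  chance correlation, so single-run null AUCs concentrate slightly above
  0.5. The null guard therefore checks the mean over three fixed seeds
  against [0.35, 0.65] rather than a single draw.
* Downsampling re-extracts features and retrains from scratch per fraction;
  its NF presence filter is relaxed to 0.5 because aggressive thinning
  empties reference windows in some samples.
* The shipped 504-bin hg19 scaffold is a constructed stand-in for the
  filtered DELFI tiling (naive 5-Mb autosome tiling minus terminal and
  centromeric bins); bin count and width match the published scaffold, the
  excluded regions do not. Synthetic genomes use naive tiling.
* Chromosome-name dialects ("chr1" vs "1") are normalized at every reader
  boundary.
* Degenerate inputs: constant score vectors yield cutoff = the constant;
  zero-variance features get zero exported coefficient; zero-reference NF is
  missing, never infinite.

## Known limitations

Single-sample prediction requires the frozen NF assembly from training.
The BAM reader pairs mates by name in memory, which is fine at the intended
low-coverage scale but not for deep WGS. The motif featurizer assumes the
reference fits in memory per chromosome. Whether published pipelines count
one or both fragment ends, or used read rather than reference sequence for
the motif feature proper, is not stated anywhere authoritative; both-ends
reference readout is this package's documented choice.
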