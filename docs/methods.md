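# Methods

## Overview

`wcms` implements a Biotyper-independent workflow for typing bacterial
strains from whole-cell MALDI-TOF mass spectra (WC-MS), in which the peaks
are dominated by ribosomal proteins and therefore carry phylogenetic
signal. The workflow has two largely independent arms:

1. **Fingerprint clustering.** Profile spectra are smoothed, baseline
   subtracted and normalised; peaks are picked, matched across spectra,
   and binarized; strains are compared by the Pearson correlation of their
   presence/absence vectors (the phi coefficient) and clustered by
   group-average (UPGMA) linkage. A query whose best similarity against
   every reference type strain falls below a threshold (default 0.5) is
   flagged as a candidate novel species. Concordance with an independent
   measure (e.g. pairwise 16S rRNA identity) is assessed by a one-sided
   Mantel permutation test.
2. **Peak annotation.** Theoretical average molecular masses of proteins
   are predicted from sequence (or taken from a curated table), the
   N-terminal Met-excision rule and protein-specific modification
   hypotheses are applied, and observed peaks are assigned to the nearest
   hypothesis within a mass tolerance.

All m/z values are treated as singly protonated species from linear-mode
positive spectra; no charge deconvolution or isotope modelling is done.

## Preprocessing

- **Smoothing**: Savitzky–Golay, applied `sg_cycles` times (default 3).
  The method itself does not pin the window or order; we default to a
  gentle window of 7 points, polynomial order 2, both exposed in
  `PreprocessConfig`. Repeated application of a gentle filter is
  preferred over one aggressive pass because it suppresses detector noise
  while moving Gaussian peak apexes by less than one grid step (tested).
- **Baseline**: a morphological top-hat — a rolling minimum followed by a
  rolling maximum (grey opening) with a structuring element spanning
  2 × `baseline_halfwidth` (default 50 Da). Chosen for determinism and
  because it is exact on features broader than the element: a monotone
  drift is returned unchanged by the opening and therefore subtracts to
  zero. The signal is padded by linear edge extrapolation before the
  opening; a bare opening leaves a `slope × halfwidth` artifact inside one
  half-window of each boundary. Output intensities are clipped at zero.
  `baseline_method="none"` supports pre-corrected or centroided data.
- **Normalisation**: intensities are scaled so the base peak is 100
  (percent of base peak). An all-zero spectrum is passed through and
  flagged `empty` rather than raising, so one blank replicate cannot abort
  a batch; downstream correlation rejects it explicitly instead.
- **Averaging**: replicate spectra are averaged pointwise after linear
  resampling to the coarsest common uniform grid (step = the largest
  median raw spacing). The mean is deliberately *not* re-normalised, so
  `mean([0,100],[100,0]) = [50,50]`; callers re-normalise when they need
  the relative-stage contract.

## Peak matrix

- **Picking**: local maxima by height and prominence (defaults 1 % each)
  on the relative-intensity profile; apex m/z and height are kept.
- **Matching** (`align_peaks`): pooled peaks sorted by m/z are grouped
  greedily — a peak joins the open consensus position if it is within
  `max_shift` of the group's running-mean m/z, otherwise it opens a new
  position; a spectrum never contributes twice to one position (the
  nearer peak wins, the other opens its own position). The published
  procedure used "maximum shift 20" in an external tool whose native unit
  is data points; we interpret it as 20 working-grid steps, which at the
  default 1 Da grid is a ±20 Da matching radius, and expose it as
  `max_shift` in Da. The greedy running-mean grouping is declared as this
  package's reference matching algorithm; it is order-stable to within
  the matching radius (property-tested against an order-independent
  fixed-radius oracle).
- **Binarization**: presence iff relative intensity is strictly greater
  than the threshold (default 5 %), restricted to the m/z 3,500–20,000
  window (inclusive bounds). Thresholding is applied *after* alignment,
  on the aligned relative intensities. Binarization is terminal by type:
  a `BinaryPeakMatrix` cannot be re-binarized.

## Clustering and identification

- **Similarity**: Pearson correlation of 0/1 columns. Constant columns
  (empty or saturated fingerprints) make the coefficient undefined and
  raise with the offending label; they must be filtered upstream.
- **Distance**: `d = 1 − r`, held fixed throughout; dendrogram node
  heights are `d/2` at each merge, giving an ultrametric tree whose leaf
  depth is half the merge distance. UPGMA is computed by average linkage
  (SciPy); ties are broken by SciPy's deterministic scan order, so trees
  are bit-reproducible. Correctness is checked against a brute-force
  O(n³) re-averaging oracle.
- **Novelty threshold**: default 0.5 — near-identical type-strain pairs
  correlate at roughly 0.5 in a realistic library, so a query scoring
  below that against *every* reference is a candidate novel species. The
  verdict uses strict `best_similarity < threshold`; the threshold is
  config-exposed because the operational cut is approximate by nature.
- **Mantel test**: r over the n(n−1)/2 upper-triangle entries; one-sided
  (positive association); rows and columns of the second matrix permuted
  jointly; `p = (1 + #{r_perm ≥ r_obs}) / (n_permutations + 1)` with
  default 9,999 permutations and an explicit seed. p resolution is
  therefore 1/(m+1) and p can never be 0.

## Protein masses and annotation

- **Masses**: average residue masses (standard IUPAC table), water
  18.0153 Da, proton 1.00728 Da; a protein's mass is the residue sum plus
  one water. Constants live in one versioned table
  (`wcms.protein_mass.CONSTANTS_VERSION`).
- **N-terminal rule**: the initiator Met is excised iff the second
  residue is small — G, A, S, C, T, P, V — the canonical methionine
  aminopeptidase specificity. The packaged AM1 table contains three
  proteins (S19, L28, S14) annotated as retaining Met despite a small
  second residue; such exceptions are real (downstream residues modulate
  the enzyme) but cannot be predicted from the second residue alone, so
  the rule is applied canonically and the curated flag wins when a table
  provides one.
- **Modifications**: methylation +14.0266, acetylation +42.0367,
  β-methylthiolation +46.0916 Da (average deltas). Hypotheses are
  *protein-specific*: each `ProteinRecord` lists the modifications it may
  carry (for the ribosomal set: methylation on L33, acetylation on S18,
  β-methylthiolation on S12, as conserved in E. coli). A global
  hypothesis space would mis-assign peaks — e.g. an acetylated-S12
  hypothesis would capture the peak that belongs to unmodified S13.
- **Matching**: each observed peak goes to the hypothesis minimising the
  absolute mass difference, reported when within tolerance (default
  ±5 Da, covering the largest credible unmodified error). Errors are
  signed (observed − hypothesis) and additionally reported against the
  unmodified mass, the convention used when modified detections are
  tabulated against gene-derived masses.
- **Detection report**: distinct proteins matched per channel plus the
  in-range-but-undetected list. The in-range criterion is
  `2,000 ≤ theoretical mass ≤ 20,000` Da; on the packaged table this
  counts 42 proteins (the table's curators counted 41 without stating
  their exact criterion, so the count is reported, not asserted).

## Synthetic libraries

The generator emulates the empirical behaviour of whole-cell spectra:
peak *positions* are stable across media and cultivation time while
*intensities* vary strongly. Each species is a latent set of masses
(default 30 peaks) drawn from a separation-guaranteed lattice within
m/z 3,600–19,500, with heights log-uniform on [5, 100] % so that some
peaks sit near the 5 % binarization threshold. A replicate is a sum of
Gaussians (σ = 3 Da) at jittered positions (σ = 2 Da) with lognormal
intensity noise (CV 0.25), 3 % peak dropout and a small sloped baseline,
sampled on a 1 Da grid over m/z 2,000–20,000 (18,001 points). Sibling
species share a configurable fraction of latent masses. A companion
16S-like similarity table maps latent Jaccard overlap affinely into the
97–100 % identity range typical of congeneric type strains.

What the generator does **not** emulate: ion-suppression of high-mass
peaks, detector saturation, isotope envelopes, doubly charged ions, mass
miscalibration drift beyond white jitter, and peak-shape asymmetry.
Passing recovery tests on this generator therefore demonstrates the
correctness and robustness of the pipeline's logic under realistic
position/intensity noise, not instrument-level performance on real data.

A note on the ~0.5 sibling similarity: the phi coefficient between two
species sharing half their peaks depends on the size of the whole peak
universe (it approaches 0.5 only as the library grows; in a 5-species
universe its expectation is ≈0.36). The sibling-similarity check
therefore uses a 12-species library — the realistic size of a type-strain
panel — where the expectation sits near 0.45.

## Problem sizes used in the test suite

Recovery checks run 40 seeded replicates of a 5-species × 4-replicate
library (ARI of the 5-cluster cut), 40 seeds of the 12-species sibling
library, and 40 novelty queries against 5-strain libraries; the Mantel
null calibration uses 100 independent 10×10 matrix pairs at 199
permutations. These sizes give stable pass/fail behaviour at
desk-scale while exercising every pipeline stage end-to-end.

## Known limitations

- The peak matcher is greedy and single-pass; pathological peak ladders
  spaced just under `max_shift` can chain into one consensus position.
- Binary-Pearson similarity is sensitive to the total number of aligned
  positions (see the sibling note above); libraries of very different
  sizes are not directly comparable at a fixed novelty threshold.
- The Met-excision rule is second-residue-only; proteins with
  context-dependent Met retention need a curated flag.
- Average-mass annotation at ±5 Da cannot discriminate hypotheses closer
  than the tolerance; ambiguous assignments go to the nearest mass.
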