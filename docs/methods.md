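# Methods

## Pipeline

`exocall` implements single-sample exome variant calling as four stages.

1. **Read streaming and filtering.** Coordinate-sorted SAM/BAM is streamed
   through pysam one record at a time; unmapped and duplicate-flagged
   reads are dropped, and out-of-order records abort with an explicit
   error.  Effective reads must satisfy a mapping-quality rule
   (`exact255` for aligners that reserve MAPQ 255 for unique mappings, or
   `min:N` for conventional aligners) and carry at most 3 variant events
   (mismatched bases plus gap events; a multi-base gap counts once).
   Internally all coordinates are 0-based half-open; SAM/VCF/BED
   conversion happens at the I/O boundary.

2. **Pileup and features.** A sliding-window pileup retains only reads
   overlapping the active column, so memory is bounded by depth × read
   length regardless of input size (the `PileupStream.max_retained`
   counter makes the contract assertable).  Per observation we record the
   base and quality, the distance to the 3' end in sequencing orientation
   (soft clips excluded — clipped bases carry no alignment evidence), the
   strand, the read's variation rate, and the pooled NBQ window.  SNP NBQ
   pools the qualities of the variant base and up to five flanking bases
   per variant read and divides by the actual (truncated) window size; no
   padding value at read edges is defensible.  Deletion NBQ uses the
   flanking read bases only (deleted bases have no sequenced quality);
   insertion NBQ additionally includes the inserted bases.

3. **Candidates and scoring.** Every non-reference base observation makes
   a SNP candidate (one per alternate base; multi-allelic sites become
   separate records).  INDEL candidates come from I/D CIGAR operations,
   left-normalized against the reference so every aligner placement of
   the same event in a repeat maps to one canonical (chrom, pos, ref,
   alt) key; normalization is idempotent and shifts the event left while
   its last base equals the current anchor base.  Candidates are scored
   to p by the logistic model and filtered at the operating points listed
   in the README; the INDEL total depth is the number of passing reads
   spanning the anchor (base and gap observations alike), while the SNP
   site depth is the effective depth (reads carrying a reference or
   variant base; gaps and Ns excluded).

4. **Genotyping and output.** Passing calls are genotyped from the
   adjusted variant ratio t with inclusive thresholds 0.1 (het) and 0.8
   (hom); a passing call with t below 0.1 is demoted with filter reason
   `low_t` rather than emitted as reference.  INDELs reuse the SNP t
   thresholds, which the source method leaves unstated for INDELs.  The
   color-corrected count in t's denominator defaults to 0 and can be
   supplied per site via a tab-delimited sidecar for colorspace data.
   QUAL is −10·log10(1−p) capped at 99.99.  The VCF writer is a
   deterministic text emitter (INFO `P`, FORMAT GT/DP/VR/TR, floats at
   %.6g) so write → read → write round-trips byte-identically through
   pysam's parser.

### Population merge and evaluation

`merge_population` takes the union of sites across single-sample VCFs and
fills every cell: called sites keep their fields verbatim; a sample
without a call is filled 0/0 with its observed depth when its depth track
covers the site (depth ≥ 1), else ./. with depth 0.  The fill source is
explicit because "missing coverage" is meaningless without one.
`split_by_target` partitions records by BED membership of the 1-based
POS.  Metrics: Ts/Tv (transitions A↔G/C↔T over transversions, `inf`
flagged when no transversions exist), known-site rediscovery
(|calls ∩ known| / |calls|, matching on chrom+pos+alt by default with a
position-only mode), SNP density per kbp of callable sequence, INDEL
in-frame rate (fraction of |len(ref)−len(alt)| divisible by 3), pairwise
concordance restricted to a shared region (rediscovery(A,B) ≡
confirmation(B,A) by construction), and precision/sensitivity/ROC curves.

## Model fitting machinery

The logistic MLE is computed by IRLS (log-likelihood tolerance 1e-8,
at most 100 iterations, step-halving on non-improving steps).  Perfect
separation — all fitted probabilities within 1e-8 of the labels — raises
an error by default because the MLE does not exist; cross-validation
refits disable the check, since a saturated refit still yields usable
held-out scores (mirroring how R's glm warns but proceeds).  Singular
designs are rejected with the offending columns named via pivoted QR.
Wald z and two-sided p per coefficient come from the observed information
matrix; p below 2e-16 prints as "< 2e-16".

* **Stepwise selection** is AIC-guided and bidirectional from the full
  model, matching R `step` defaults; ties keep the earliest move, so the
  search is deterministic given variable order.  On pure-noise data a
  spurious variable survives with probability ≈ P(χ²₁ > 2) ≈ 0.16 per
  variable — that is AIC's designed behavior, not a defect.
* **drop1-style pruning** repeatedly removes the term with the largest
  single-term likelihood-ratio p while it exceeds α (default 0.05),
  refitting after each removal; it is idempotent at its fixed point.
* **Bootstrap CIs** are case-resampling percentile intervals (the
  simplest "standard bootstrap"; BCa adds nothing at these n).
  Non-converged or separated replicates are discarded; more than 10%
  failures aborts with a diagnostic, since that is the overfitting
  signature, and interval/point inconsistencies are reported rather than
  clamped.
* **Cross-validation** repeats (default 100×) a 50/50 split: refit on one
  half, score the other, record precision TP/(TP+FP) and sensitivity
  TP/(TP+FN) over a cutoff grid of 0.00–1.00 in steps of 0.01 ("all
  possible cutoffs" discretized reproducibly).  Splits missing a class on
  either side are redrawn.  Precision is NaN at cutoffs where nothing is
  called and NaN-aware means are used.  A well-specified model's mean
  replicate curve sits on the full-data curve (gap < 0.02 at cutoff 0.5);
  an overfit one (e.g. n=60 with 12 covariates) disperses several-fold
  more across replicates.

All stochastic operations take an explicit seed; there is no hidden
global RNG state.

## Synthetic data generator

The generator emulates the discriminative structure the classifiers
exploit, not any particular instrument.  A uniform-random reference is
drawn from the seed.  `n_sites` candidate loci are spaced ≥ 2 read
lengths apart; `tp_fraction` of them are true variants (het/hom 60/40,
alternate alleles uniform; `indel_fraction` of them 1–3 bp insertions or
deletions), the rest systematic error sites.  The two components differ
the way true and false candidates differ in capture data:

* true sites: balanced strands, normal qualities, uniform read position;
  het sites carry the allele on ~50% of covering reads (a configurable
  minority, default 15%, are weakly supported at ~25% to keep the classes
  honestly overlapped); hom sites on all reads that fully span the event;
* error sites: recruit a small fraction of reads (3–15% for base errors,
  5–20% for false gaps, minimum 2) chosen preferentially where the site
  falls near the read's 3' end, single-strand with probability 0.85 (with
  an occasional stray opposite-strand read), base and flank qualities
  depressed in ~80% of sites, and false gaps co-occur with extra
  mismatches (the mismapping signature that makes variation rate
  informative).

Phred qualities are integers in [2, 40] with a linear decay (default 12)
toward the 3' end plus Gaussian jitter; baseline per-bp miscalls are
3'-weighted.  Capture depth is heterogeneous: read starts follow
per-window Gamma multipliers with a configurable coefficient of variation
(default 0.35); `depth_cv=0` gives uniform coverage.  Setting the error
rates to zero disables both the baseline noise and the systematic error
component, which is the "clean signal" configuration used by the
end-to-end recovery tests.  Labeled training tables for the model
machinery are generated separately: features from per-variable
distribution specs, labels drawn Bernoulli(logistic(β·x)), optionally
resampled within class to a target TP fraction (e.g. the 10%/90% mix used
for INDEL training sets).

What the generator does **not** emulate: colorspace chemistry, capture
GC/reference bias, alignment artifacts beyond gap-placement ambiguity,
correlated errors across sites, and real allele-frequency spectra.
Passing tests therefore demonstrate the pipeline's internal correctness
and the statistical behavior of the training machinery, not calling
accuracy on real instrument data.

## Packaged default models

`scripts/train_default_models.py` regenerates
`src/exocall/models/default_{snp,indel}.json` by simulating labeled
mixtures (SNP: 2000 sites at 12% true, depth 30; INDEL: 2000 sites at 10%
true, depth 20 — the lower depth supplies the moderate-support true
examples that pin the decision boundary), extracting candidate feature
tables, and fitting the full models.  Their provenance strings mark them
as synthetic-trained.  At saturating depth a het variant lands on both
strands with probability ≈ 1−2^{1−v}, so the strand indicator is nearly
constant among true sites and its coefficient is weakly identified —
the same quasi-separation R's glm reports on such data; depth
heterogeneity in the training fixture is what keeps all seven SNP terms
finite and modest.

## Numerical and edge-case choices

* ref/var ratio with zero variant reads is undefined (such sites are not
  candidates); with zero reference reads it is 0, the homozygous-alt
  limit.
* Each insertion or deletion counts as one variant event in both the
  read filter and the variation rate, matching per-event phrasing over
  per-base counting.
* `near_read_end` is inclusive at 5 bp and uses the event edge closest
  to a read end in (clip-adjusted) read coordinates.
* Callable regions are maximal merged runs of positions with effective
  depth ≥ 6 (inclusive); calls outside them are demoted with reason
  `callable`.
* Genotype and filter boundaries are all inclusive (p ≥ 0.5, p ≥ 0.88,
  ratio ≥ 0.05, t ≥ 0.1/0.8, depth ≥ 2/6).
* In-frame rate uses |len(ref) − len(alt)| as the INDEL length;
  multi-allelic records are split before metrics.

## Problem sizes and limitations

Tests and the acceptance script run at desk scale: fixtures of 10–150
candidate sites at depth 20–30 (103–180 k reads at the largest), training
sets of 2 000–50 000 rows, 100 cross-validation replicates, 1000
bootstrap replicates, and CI coverage over 100 simulated datasets — sizes
chosen so the statistical checks are sharp while the whole suite remains
quick to run.  Known limitations: the genotyper reuses SNP t-thresholds
for INDELs; hom indels near t = 0.8 can genotype het because reads that
do not fully span the event dilute the ratio; binomial sampling of het
support means a small fraction of true sites in any finite fixture carry
genuinely ambiguous evidence (the ~97% recall operating point of the
classifier, visible in the cross-validation curves); and the in-frame
metric requires a user-supplied coding BED to be interpreted as a coding
QC statistic.
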