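# Methods

## Study design being modeled

The pipeline analyzes a 2 × 2 small-RNA design: two maize inbred lines with
contrasting senescence behaviour — an early leaf-senescence line (ELS-1) and
a stay-green line (Yu87-1) — sampled at 20 and 30 days after pollination
(DAP), one pooled sequencing library per genotype × timepoint (biological
replicates are pooled before library construction, so there is no replicate
structure and no count-model differential test; the contrast is a plain
fold-change rule). A senescence-associated miRNA (SA-miRNA) is defined
operationally: |log2 fold change| of RPM between 20 and 30 DAP strictly
greater than 1.5 in ELS-1, and not greater than 1.5 in Yu87-1.

## Synthetic data generator

`senmir.simulate` produces every input from one seed:

* **Genome** (default 200 kb, one reference): planted hairpin precursors for
  40 known + 10 novel miRNAs, 20 ncRNA loci (rRNA/tRNA/snRNA/snoRNA/cis-reg,
  100–150 nt), random filler between features. A precursor is
  mature + loop (12 nt) + star, where the star is the reverse complement of
  the mature with 1–2 substitutions; arm (5p/3p) and strand are random. The
  star carries at least one substitution because a perfect inverted repeat
  would make the mature sequence occur at two genomic positions (its own arm
  and the reverse complement of the star), breaking the unique-locus
  invariant that mapping-based annotation relies on.
* **Expression truth**: per-library relative weights, normalized per library
  to expected RPM. The first `n_sa_mirnas` miRNAs are senescence-associated
  with a 4-fold within-ELS-1 change (|log2| = 2.0, comfortably above the 1.5
  threshold) and a mild same-direction 2-fold trend in Yu87-1 (|log2| = 1.0,
  below the removal threshold — the shared families move in the same
  direction in both lines but only pass the threshold in ELS-1). Directions
  alternate up/down so library compositions stay balanced and RPM
  denominators do not drift between timepoints. Non-SA weights are uniform
  in [1.5, 3], keeping every planted miRNA well above the 5-RPM floor; the
  floor's boundary behaviour is unit-tested directly.
* **Count noise**: per-miRNA library counts are negative-binomial with
  var = m + α·m², default α = 0.002. Each library is a single sequencing run
  of one pooled RNA sample, so the appropriate noise is technical
  (near-Poisson with mild overdispersion from pooling and amplification),
  not the α ≈ 0.1 typical of biological replicates — with α = 0.1 the log2
  fold-change noise SD (~0.68) would swamp the 0.5-log2 margin between the
  planted effect and the selection threshold, and no fold-change rule could
  recover the planted set reliably; at α = 0.002 and the default depths the
  margin is ≈ 4 SD. α = 0 switches to deterministic rounding for exactness
  tests.
* **Libraries** (50,000 reads each, exactly): miRNA reads are exact mature
  copies (~70% of reads in expectation); the remaining depth is filled with
  ncRNA-locus fragments (24-nt-heavy length mixture, so >half of all reads
  fall in the 20–24 nt window, with a 24-nt mode), Phred-2 low-quality
  reads, and unmappable random reads. 70% of emitted reads carry the full 3′
  adapter (TruSeq small-RNA sequence by default) to exercise trimming.
* **Degradome** (12,000 tags): per planted cleavage site, tags start at the
  site with probability 0.7 (`degradome_peak_fraction`), else at a uniform
  background position; tags are the first 36 nt of the 3′ cleavage fragment,
  truncated (and flagged) at transcript ends. Cleavage positions sit
  opposite miRNA positions 10–11 of a perfect-complement site embedded in a
  400–600 nt transcript.
* **Phenotype tables**: absorbance tables are the exact inverse of the
  chlorophyll equations at planted trajectories (ELS-1 chlorophyll a
  25.58 mg/L at 25 DAP collapsing to 0.35 mg/L at 30 DAP; stay-green
  27.41 → 23.01 mg/L; chlorophyll b dropping early in ELS-1, 13.45 → 2.30 by
  20 DAP), three replicates, Gaussian noise optional (default 0). Ct tables
  encode planted relative expression through the ΔΔCt model (reference gene
  fixed at Ct 15, calibrator target at Ct 25) with Gaussian noise,
  σ = 0.15 cycles by default, three replicates per sample.

**What the generator does not emulate**: ligation and PCR biases, sequencing
substitution errors, isomiR production (reads are exact mature copies),
multi-mapping miRNA families sharing a sequence, expression heterogeneity
over orders of magnitude, and the replicate-mixing step (one pooled library
is drawn directly per sample). Passing recovery tests therefore demonstrates
that the selection logic, coordinate conventions and scoring rules are
implemented correctly — not that the pipeline is robust to real-library
artifacts.

## Read processing

Adapter trimming removes the longest read suffix that exactly matches an
adapter prefix (≥ 6 nt). Quality filtering discards reads with mean Phred
< 20 or any N, before trimming; reasons are counted and reported. Length
selection keeps 18–32 nt. Mapping is exact full-length matching on both
strands via an 18-mer seed index with verification; all hit positions are
reported, multi-mapping tags count once per library in expression totals
(not once per hit), and unmapped tags are excluded from candidate counts.
ncRNA screening removes tags that occur as exact substrings of any reference
entry, attributing each to the first matching entry's class. The stage
accounting satisfies raw = quality discards + length discards + unmapped +
ncRNA-removed + candidate reads, checked per library in every run report.

## miRNA annotation

Known annotation: a tag matches a reference mature if identical up to a
≤ 2 nt shift at either end with the overlapping stretch exact (isomiR
convention); among multiple matches the smallest total shift wins, ties by
id. Counts of all tags assigned to a mature id are summed.

Novel prediction evaluates each unannotated mapped tag (18–26 nt) in two
flank windows (tag ± 150 nt, strand-corrected, covering both arm
hypotheses). The star is located by direct complementarity: the
best-pairing region on either side of the tag (G:U counts as paired, at most
one bulge of ≤ 2 nt on either strand, star not overlapping the tag,
separated by ≥ 3 nt). Criteria: ≤ 4 mismatched tag positions, bulge ≤ 2 nt,
loop 3–60 nt, and a folding score ≤ −18 for the trimmed [tag..star] stem.
The stem is scored by the package's folding DP — pseudoknot-free base-pair
maximization weighted by pair identity (GC −3, AU −2, GU −1), −0.5 per
stacked pair, minimum loop 3 — on the trimmed stem rather than the whole
window, so flanking sequence cannot subsidize a weak hairpin. The star is
found by complementarity rather than read off the window-wide fold because
base-pair maximization over a 170-nt window frequently trades mature:star
pairs for incidental flank structure, misreporting mismatch counts for
genuine hairpins. The criteria are statistical, not absolute: random
200-nt windows contain miRNA-like foldbacks at a measurable rate (~20% per
window at these thresholds), which is why prediction is restricted to
genome-mapped, annotation-negative tags. The folding backend is pluggable
behind the `fold_hairpin(sequence) -> (pairs, score)` contract; an external
thermodynamic folder can be swapped in without touching the criteria.

## Expression contrast

RPM = count / (mapped candidate reads in the library) × 10⁶. The floor
keeps rows with max-over-libraries ≥ 5 RPM (the rule is stated once as RPKM
in the source protocol; RPM is used throughout since length normalization is
meaningless for collapsed ~21-nt tags). Fold changes use
log2((x₂ + c)/(x₁ + c)) with pseudocount c = 1 RPM so zero entries stay
finite; the run report carries a sensitivity sweep over c ∈ {0.5, 1, 2}
because the zero-handling convention is not uniquely determined. The
threshold comparison is strict (> 1.5, not ≥). Note that the composed
candidate rule is not monotone in the threshold: raising it shrinks the
ELS-1 DE set but also shrinks the Yu87-1 removal set, so candidates can
appear as the threshold rises; the per-genotype exceedance sets individually
are monotone.

## Degradome analysis

Duplex scoring: the site pairs the miRNA antiparallel (miRNA position k
against the k-th base from the site's 3′ end); penalties are mismatch 1.0,
G:U 0.5, gap 1.0, doubled at miRNA positions 2–13, at most one gap of one
nucleotide. For a bulged miRNA base the gap is charged at that position; for
an unpaired site base, at the miRNA position 3′ of the insertion. Sites with
S ≤ 4 are reported; overlapping gap/no-gap representations reduce to the
best alignment per (transcript, cleavage position), gapless preferred on
ties. The cleavage position is the transcript base pairing miRNA position 10
(1-based in reports; when position 10 itself is bulged, the start of the 3′
fragment adjacent to the position-9 pairing is used). Tag profiles count
exact-match 5′ ends per transcript position, multi-transcript tags counting
everywhere they match. Categories: 4 if the site count is exactly 1;
otherwise 0 if it equals a unique transcript-wide maximum, 1 if a shared
maximum, 2 if above the median of positions with ≥ 1 read, else 3.

## Wet-lab arithmetic

Chlorophyll uses Arnon-type coefficients for 80% organic-solvent extracts
(in config, swappable for other solvent calibrations); concentrations are
mg/L of extract, also reported per gram fresh mass (× 20 mL / 0.2 g /
1000) since the assay records both and the source protocol reports only
mg/L. The equations are linear and invertible; negative computed
concentrations (extreme absorbance ratios outside the calibration's domain)
are clipped to zero. The early-senescence flag marks the genotype whose
maximum per-interval decline rate exceeds every other genotype's by a
configurable factor (default 2×). ΔΔCt averages replicate Ct values before
differencing; RQ = 2^−ΔΔCt with the calibrator at exactly 1. Direction
concordance compares sign(log2 RQ₃₀/RQ₂₀) against the sequencing log2 fold
change, zeros agreeing with either sign.

## Numerical and convention choices

* Coordinates are 0-based half-open internally; 1-based only in
  human-readable outputs (degradome cleavage positions, stated explicitly).
* All scores are sums of multiples of 0.5, so exact float comparisons in the
  folding traceback are safe.
* Deterministic orderings everywhere: tags sorted lexicographically, target
  sites by (transcript, position), novel calls by locus; repeat runs of any
  stage at the same seed are byte-identical.
* Randomness derives from a single seed through named child streams
  (genome/reads/degradome/phenotype), so regenerating one artifact does not
  perturb the others.

## Problem sizes

Default study conditions: 200 kb genome, 4 × 50,000 reads, 50 miRNA loci
(8 SA), 20 ncRNA loci, 18 target transcripts, 12,000 degradome tags. A full
pipeline run takes ~10 s on one CPU. The test suite exercises the same
design at reduced scale (30 kb genome, 4 × 3,000 reads) for per-module
tests, plus one full-scale run for end-to-end recovery; brute-force oracle
comparisons use ≥ 1,000 randomized instances per operation, with exhaustive
structure enumeration for folding at 8–16 nt and spot checks at 25 nt.

## Known limitations

* Exact-match mapping only; real genomes need a seed-and-extend aligner and
  a mismatch policy.
* The folding model is a weighted base-pair maximization, not a
  thermodynamic model; the −18 threshold is calibrated to this scoring and
  would need recalibration for a free-energy backend.
* Degradome categories carry no significance statistics (no p-values); a
  category-0 call on a lowly covered transcript is weaker evidence than the
  category alone suggests.
* The two-genotype selection has no error control — it is a deterministic
  fold-change rule, faithful to the design it implements.
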