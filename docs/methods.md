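# Methods

## Coordinate and identity conventions

Genomic coordinates are 0-based half-open (BED convention); exon indices are
1-based in transcript order, so "exon 2" is the second exon read 5′→3′ along
the mRNA regardless of strand. A backsplice junction is identified as
`gene:acceptor-donor@chrom:start-end`, with acceptor ≤ donor (the acceptor is
the earlier exon in transcript order); display names follow the field's
donor-first style (`circSMAD2-6,2`). One canonical transcript represents each
gene — the transcript with the most exons, ties broken by total exon length
and then transcript id — because exon-position statistics are reported per
gene, not per isoform. Junction boundaries must coincide with canonical exon
boundaries (configurable slack, default 0 nt to match the synthetic data;
real callers may need ±1 for dialect differences); non-matching junctions are
flagged unannotated and kept in expression matrices but excluded from
exon-position analyses.

## Quantification

Raw backsplice counts are normalized per sample to reads per million
(`counts × 10⁶ / library size`), then replicate columns are averaged into one
column per cell line, then junction rows are pooled into genes by summation.
Normalizing before averaging keeps replicates equally weighted regardless of
depth; pooling last is equivalent to pooling first (linearity) but keeps the
two levels consistent by construction. Gene aggregation accumulates
sequentially in row order (unbuffered `np.add.at`), so the gene value is
bitwise-identical to an in-order `+=` over its junction rows; the
conservation tests hold it to exact equality, not a tolerance. "Expressed"
means strictly positive normalized reads; the occurrence filter (default: at
least 30 of 60 cell lines) is inclusive at the boundary.

The upstream caller's fragment-length normalization could not be pinned down
to a formula, so reads-per-million is the primary unit throughout; this does
not affect correlations or fold changes, only the absolute scale of the
circ/total ratio.

## Landscape statistics

Acceptor usage is counted per absolute exon index; donor usage both per
absolute index and per distance from the transcript end (last exon = 1),
because donor depletion is a property of the transcript end. Decile binning
maps exon i of n to `ceil(10·i/n)`, so the last exon of every transcript
lands in bin 10 and single-exon genes contribute to bin 10 only. The
positional filter variant (total reads ≥ 2, transcript ≥ 10 exons) mirrors
the robust subset commonly reported.

Circ–linear correlation is Pearson, computed per feature across cell lines
against the FPKM of the co-derived gene (a junction inherits its host gene's
linear value; per-junction linear quantification is not attempted).
Zero-variance features and features below the occurrence cut are excluded
and counted. Pearson (not Spearman) because the coupling of interest is
between expression magnitudes, and the implementation is verified against a
textbook computation to 1e-12.

The circ/total ratio is a relative quantity, not a molar one: the numerator
counts only junction-spanning reads per million, the denominator is
length-normalized FPKM. The across-line average ratio is the ratio of means
over the cell lines with FPKM > 0 (per-line ratios are also emitted; the
ratio-of-means is less volatile when single lines have near-zero FPKM).
Features with circular signal but zero linear signal everywhere are tallied
separately rather than scored.

The polyA scan asks for ≥ `min_run` (default 5) consecutive As on the
*circle*: the scan window extends `min_run − 1` bases past the origin so
junction-spanning runs are found; it is equivalent to scanning the doubled
sequence.

## Association tests

Per-row testing follows the classic spreadsheet/Prism procedure: a two-sided
*F*-test of variance equality at α = 0.05 routes each feature to the
pooled-variance or Welch two-sided *t*-test; features whose mean is exactly
zero in either group are excluded *before* testing (they are reported as
group-exclusive instead), and the Bonferroni threshold is α divided by the
number of features actually tested. The *F*-test level is a fixed design
choice; rows where the F statistic is degenerate (zero variance on one side)
route to Welch. Fold-change bands ([0.5, 2.0], inclusive) partition the
expressed features into only-slow / only-fast / in-band / other.
Proliferation classes use inclusive cutoffs: fold ≥ 5 is fast, ≤ 3 is slow,
lines in between join correlations but not the two-group contrast. Genotype
contrasts compare mutant vs wild-type lines; lines with unknown status sit
out.

One calibration note: with a strong multiplicative group effect, group
variances differ by the squared fold, the *F*-test essentially always
selects Welch, and Welch's reduced degrees of freedom cost detection power
relative to a pooled test at stringent Bonferroni thresholds. The test-suite
power simulation (4-fold effects, 20 vs 20, lognormal sd 0.5, 5000 features)
measures this directly; the family-wise error under the null is controlled
well below α.

Cancer-gene enrichment reports the CGC fraction among detected genes and
among individual junctions, the fold difference in mean normalized counts
(CGC vs rest, same F-routed *t*-test), and CGC frequency across log10 bins
of the circ/total ratio.

## Synthetic-data generator

The generator emulates the study conditions of a 60-line panel and is the
package's test bed; its defaults are fixed once:

- **Panel**: 60 cell lines (histology 50 : 7 : 3 LUAD : other NSCLC :
  non-transformed), 2–3 replicates (P(3) = 0.9, matching ~175 samples per
  60 lines), library sizes uniform in 20–40 M reads; genotype flags with
  field-typical mutation frequencies (TP53 0.5, KRAS 0.3, EGFR 0.15, BRAF
  0.05, 5% unknown); proliferation folds drawn so that exactly 11 lines are
  fast (folds in [5, 8]) and 21 slow ([1.5, 3]), the rest intermediate
  ([3.2, 4.8]).
- **Structures**: exon counts per gene are rounded lognormal (median 9,
  log-sd 0.6, clipped to 1–50); circRNAs per gene are rounded lognormal with
  median 5 and log-sd 1.32 (mean ≈ 12, heavy-tailed). Acceptor exons are
  drawn with weight 1/78 for exon 1 and geometric decay 0.85 from exon 2
  onward; donors with weight 1/62 for the last exon and decay 0.85 toward
  the start, conditioned donor ≥ acceptor. Repeated draws of the same
  (acceptor, donor) pair collapse into one junction, so measured positional
  folds at the unique-junction level sit below the planted draw-level
  weights; recovery experiments that need iid draws use one circRNA per
  gene.
- **Expression**: linear FPKM is lognormal (gene-level log-mean ~N(1, 1),
  between-line log-sd 0.7, replicate log-sd 0.1). Circular abundance shares
  the line-level latent factor with linear expression; the latent (log-scale)
  correlation is set by inverting the bivariate-lognormal identity
  corr = (e^{ρ_log σ²} − 1)/(e^{σ²} − 1) so the *value-scale* Pearson hits
  the target ρ (default 0.4). Counts are negative binomial (gamma-mixed
  Poisson, dispersion 0.3) with mean = rate × library/10⁶; counting noise
  attenuates the realized correlation a few hundredths below target, which
  the recovery band accommodates. 45% of junctions are restricted to a
  single randomly chosen home line (high cell-line specificity); a 2.8%
  gene subset ("cancer genes") carries a 2.1-fold rate multiplier; group
  effects and per-feature proliferation effects multiply the latent rate.
- **Determinism**: one `numpy` generator seeded from the config drives every
  draw in fixed order; identical configs produce byte-identical output
  files.

What the generator does *not* emulate: sequence-level splice-site realism,
read-level data (no FASTQ), batch effects, linear-expression group effects,
or the correlation structure between neighboring genes. Passing recovery
tests therefore demonstrates that the analyses measure what they claim on
data matching their assumptions — not that the assumptions hold for any
particular real dataset.

Recovery experiments are designed experiments with their own configs: the
acceptor-weight check uses 3000 twenty-exon genes with one circRNA each (so
exon-1 counts are iid Binomial(n, 1/79) and a closed-form CI applies); the
coupling check uses 230 genes × 60 lines at default noise; the cancer-gene
fold check enlarges the planted subset to 25% of 400 genes and tames rate
dispersion so the fold estimate is tight. Test problem sizes are chosen to
give stable statistics at interactive runtimes.

## Rolling-circle ORF finder

Position 0 of a circular sequence is the first base downstream of the
backsplice junction. For every ATG on the circle, codons are read over
consecutive copies of the sequence until the first in-frame stop (TAA, TAG,
TGA; standard code, ATG-only starts) or until the ORF would exceed
`max_wraps × L` nt. Three wraps suffice: if L is not a multiple of 3 every
pass shifts the codon phase, so all three frames are exhausted within three
passes and a stop-free circle is provably stop-free forever; if L is a
multiple of 3 the frame never changes and a stop-free first pass repeats
forever (flagged `unbounded`).

Junction crossings are `floor((start + length)/L) − floor(start/L)`: an ORF
whose stop ends exactly on the junction counts that terminal pass (the
ribosome reads its final codon up to the junction). Frames visited counts
distinct codon phases `(start + k·L) mod 3` over wraps k whose segment
inside the ORF is non-empty — an ORF ending exactly on the junction
contributes no frame for the empty final segment, which is how an ORF can
cross twice yet visit only two frames. Peptide mass uses average (not
monoisotopic) residue masses plus one water, in kDa.

The planted-circle constructor (`simulate_circle_with_orf`) places the ATG
and the TAA stop at the prescribed geometry and fills the remaining
positions from {A, C, G}: with no other T on the circle, no unplanned start
or stop can form; in-frame re-reads of the planted Ts on later passes are
repaired (the base after the ATG's G is forced away from A to avoid TGA) or,
if the geometry makes a premature stop unavoidable, the constructor refuses.
The construction is verified post hoc (unique ATG, no premature in-frame
stop), and only the filler bases depend on the seed.

## Numerical choices and degenerate inputs

- Exact (bitwise) equality is promised only for the gene/backsplice
  conservation contract; everything else uses explicit tolerances.
- Ties in top-expressed ranking break lexicographically by feature id, so
  rankings are deterministic across runs.
- Zero-variance features are excluded (and counted) from correlations;
  zero-mean groups are excluded (and counted) from differential tests;
  FPKM = 0 cells yield undefined per-line ratios.
- Single-replicate cell lines get an undefined (NaN) concordance score
  rather than an error; metadata with replicate counts outside 2–3 warns
  but loads.
- Empty gene lists warn and disable gene-set analyses.

## Known limitations

- Backsplice detection itself (alignment, junction calling) is out of scope;
  the pipeline starts from call tables and trusts their coordinates.
- Exon annotation against one canonical transcript per gene will mis-index
  junctions that use exons absent from that transcript; such junctions are
  flagged unannotated rather than guessed.
- The circ/total ratio's absolute scale depends on the upstream
  normalization of both inputs; only relative comparisons across features
  or lines are meaningful.
- The ORF finder predicts coding potential only; it says nothing about
  translation initiation (IRES, m6A) or protein stability.
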