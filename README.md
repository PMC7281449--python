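# circlandscape

Analysis of circular RNA (circRNA) landscapes from backsplice-junction call
tables, for transcriptomics work on cell-line panels (the motivating setting
is a panel of ~60 lung cancer and non-transformed cell lines sequenced after
rRNA depletion, with 2–3 replicates per line).

circRNAs arise from backsplicing: the 3′ end of a downstream (donor) exon is
joined back to the 5′ end of an upstream (acceptor) exon, producing a
covalently closed circle detected by junction-spanning reads. This package
takes per-sample backsplice call tables (CIRCexplorer2-style BED-like TSV), a
GTF annotation, a linear FPKM matrix and sample metadata, and computes:

- **Dual-level quantification** — reads per million per backsplice junction,
  replicate-averaged per cell line, and pooled per gene, with the exact
  conservation guarantee `gene value = Σ junction values`;
- **Occurrence and filtering** — in how many cell lines each circRNA is
  expressed, distinct backsplice sites per gene, top-expressed features,
  replicate concordance;
- **Exon-position statistics** — which exon of the transcript serves as
  acceptor or donor (absolute index, distance from the transcript end, and
  decile bins `ceil(10·i/n)`), with fold ratios such as exon-2 vs exon-1
  acceptor usage;
- **Circ–linear coupling** — per-feature Pearson correlation of circular vs
  linear (total) expression across cell lines, and the relative circ/total
  ratio (normalized backsplice reads / FPKM);
- **Association tests** — Pearson correlation with 72-h proliferation folds,
  fast (fold ≥ 5) vs slow (fold ≤ 3) contrasts, fold-change band
  classification, and per-row two-sided *t*-tests (an *F*-test of variance
  equality routes each row to the pooled or Welch form) with Bonferroni
  correction, excluding features whose mean is exactly zero in either group;
- **Cancer-gene enrichment** — the fraction of circRNA output attributable
  to a cancer-gene list (CGC style), with a fold and significance test;
- **Rolling-circle ORF prediction** — ORFs on the circular sequence that
  read through the backsplice junction; when the circle length L is not a
  multiple of 3, each pass shifts the codon phase, so one ORF can traverse
  up to three reading frames. Reported per ORF: length, junction crossings,
  distinct frames visited, peptide, and average-mass estimate;
- **A seeded synthetic-data generator** producing GTF + junction tables +
  FPKM + metadata with planted, recoverable structure (coupling ρ,
  exon-position weights, sparsity, group effects, proliferation classes).

## Worked example

```python
from circlandscape import (SimulationConfig, build_dataset, simulate_landscape,
                           simulate_circle_with_orf)
from circlandscape.circorf import rolling_circle_orfs
from circlandscape.landscape import circ_linear_correlation
from circlandscape.association import classify_fast_slow

# a 1147-nt circle whose only start codon sits 23 nt upstream of the
# junction and whose first in-frame stop ends exactly on the junction
# during the second pass
circ = simulate_circle_with_orf(L=1147, orf_start=1124, peptide_len=389, seed=1)
orf = rolling_circle_orfs(circ, max_wraps=3)[0]
print(f"ORF: {orf.length_nt} nt, {len(orf.peptide)} aa, "
      f"{orf.crossings} junction crossings, {orf.frames_visited} reading frames, "
      f"~{orf.mass_kda:.1f} kDa")

sim = simulate_landscape(SimulationConfig(seed=1, n_genes=150))
ds = build_dataset(sim.junctions_by_sample, sim.meta, sim.linear_fpkm)
res = circ_linear_correlation(ds.gene_cell_line, ds.linear_fpkm)
classes = classify_fast_slow(ds.meta)
print(f"{len(ds.junctions)} circRNAs from {ds.gene_cell_line.values.shape[0]} genes "
      f"across {ds.gene_cell_line.values.shape[1]} cell lines")
print(f"median circ-linear correlation (gene level): {res.median:.2f}")
print(f"proliferation classes: {len(classes.fast)} fast, {len(classes.slow)} slow")
```

prints:

```
ORF: 1170 nt, 389 aa, 2 junction crossings, 2 reading frames, ~42.4 kDa
1041 circRNAs from 150 genes across 60 cell lines
median circ-linear correlation (gene level): 0.34
proliferation classes: 11 fast, 21 slow
```

The ORF is longer than the circle (1170 nt on a 1147-nt template): the
ribosome crosses the backsplice junction twice and finishes in a different
reading frame than it started, encoding a 389-residue protein of roughly
42 kDa. The simulated panel recovers its planted structure: the circ–linear
coupling (planted Pearson ρ = 0.4; counting noise attenuates the measured
median slightly) and the planted proliferation classes (11 fast, 21 slow of
60).

## Command line

```sh
circlandscape simulate  --config config.yaml --out data/
circlandscape quantify  --dataset data/ --out quant/
circlandscape landscape --dataset data/ --out land/ --min-reads 2 --min-exons 10
circlandscape associate --dataset data/ --contrast TP53 --out assoc/
circlandscape orf       --fasta circles.fa --out orfs/ --max-wraps 3
circlandscape report    --dataset data/ --out report/
```

A dataset directory holds `annotation.gtf`, `junctions/<sample>.tsv`,
`metadata.tsv`, `fpkm.tsv` and optionally `cgc_genes.txt`. Every run writes
a `manifest.json` with input checksums and the output inventory.

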