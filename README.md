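# exomir

Small-RNA sequencing analysis of exosomal versus cellular miRNA cargo, built
as a reusable, fully testable Python library. It targets the question of how
cells sort specific miRNAs into exosomes (40–130 nm extracellular vesicles),
for example in isogenic colorectal-cancer lines differing only in *KRAS*
status: which miRNAs are enriched in exosomes relative to their parent
cells, whether 3′ isomiR modifications (trimming, templated tailing,
non-templated addition) differ between compartments, and whether candidate
sorting motifs such as GGAG sit in exported sequences.

Because raw sequencing data for such studies are often undeposited, the
package ships a synthetic-data generator as a first-class module: it builds
a toy reference world (hairpins with mature windows embedded verbatim in a
mini-genome alongside tRNA/rRNA/snRNA/repeat loci) and simulates libraries
with known per-read ground truth, so every analysis stage is verifiable
end-to-end.

## What it implements

- **`simulate` / `reference`** — deterministic reference construction and
  FASTQ library simulation with per-read truth tables (source locus, 5′
  offset, 3′ trim length, tail sequence and templated/NTA status, ligated
  3′ adapter).
- **`readprep`** — 3′ adapter trimming by unit-cost edit distance with the
  error budget ⌊0.1 × matched adapter length⌋, then exclusion of reads
  shorter than 15 nt.
- **`mapanno`** — exact (optionally ≤2-mismatch, indel-free) alignment to
  hairpins and genome, 1/k weighting of multi-mappers, hierarchical ncRNA
  annotation with mature windows extended ±2 nt, and the composition /
  length × 5′-base summaries.
- **`isomir`** — iterative trim-and-remap 3′ classification: unmapped reads
  are trimmed 1 nt at a time (up to 10 rounds) and remapped to hairpins;
  removed suffixes are split into templated tails and non-templated
  additions (NTA ≤ 3 nt, analysed for reads ≥ 18 nt and miRNAs with ≥ 500
  weighted reads per compartment).
- **`diffexpr`** — weighted count matrices, RPM and TMM normalization
  (trimmed mean of M-values, matching the reference implementation to
  ~1e-6), method-of-moments NB dispersion with a lowess mean trend, a
  sum-conditioned exact NB test (Wald fallback for large totals),
  enrichment calls at |log2FC| ≥ 1 and BH-FDR ≤ 0.001, the seven-way
  three-line set partition, Spearman matrices and PCA.
- **`qpcr` / reporter** — ΔΔCt fold changes (FC = 2^−ΔΔCt with
  Δ = Ct_miRNA − Ct_U6), dilution-series standard curves (OLS of mean Ct on
  log10 copies/µl), curve inversion to absolute copies, percent increase of
  transferred miRNA, and Luc/β-Gal reporter normalization.
- **`motifs`** — deterministic IUPAC motif scanning (GGAG, U/CC, …) with 3′
  windowing and hypergeometric set-enrichment counts.

Packaged fixtures transcribe the published three-line enrichment category
tables (cells and exosomes) and the absolute miR-100 copy numbers used by
the transfer experiment.

## Worked example

```bash
python examples/03_differential_enrichment.py
```

```
count matrix: 80 miRNAs x 12 samples
WT: 19 exosome-enriched calls, recall 0.95, false fraction 0.0000
MUT: 19 exosome-enriched calls, recall 0.95, false fraction 0.0000
...
PC1 explains 0.65 of variance; cell and exosome samples separate along it:
       WT-cell-1: -4.2
    WT-exosome-1: +3.1
```

The script simulates a 4-condition experiment (WT/MUT line × cell/exosome,
3 replicates) in which 20 of 80 miRNAs carry a 4-fold export bias, rebuilds
counts from the raw reads, and tests exosome vs cell per line: 19 of the 20
truly exported miRNAs are recovered at |log2FC| ≥ 1 and FDR ≤ 0.001 with no
false calls, and PC1 of the count matrix separates compartments. The other
examples cover isomiR classification (`01`), composition profiling (`02`),
qPCR quantification (`04` — prints the 34.3%/8.4% miR-100 transfer increases
from the packaged copy numbers), and motif scanning (`05`).

A thin CLI mirrors the modules: `exomir simulate|prep|map-annotate|isomir|
diffexpr|qpcr|motif|fixtures` (see `exomir --help`).

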