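# silencerkit

Analysis toolkit for **breadth-defined repressive chromatin domains**
(broad H3K27me3 "silencer" domains): call domains from ChIP-seq peak
intervals, characterize them against gene constraint, expression and
3D-genome annotations, and classify two-condition domain loss/gain
integrated with expression and DNA methylation. A synthetic-epigenome
generator with planted ground truth makes every stage testable offline.

## What it does

1. **Domain calling** — merge repressive-mark peaks within 2 kb, quantify
   input-subtracted RPKM per domain, and classify by breadth: *grand* (top
   5 % broadest **and** > 50 kb), *narrow* (bottom 5 %), *control* (seeded
   random 5 % of the remainder) and *typical*.
2. **Gene association** — mark genes by domain overlap (body ± 2 kb),
   test constraint metrics (missense Z, dN/dS) of grand-marked vs other
   marked genes, and compute the breadth-vs-expression trend (bin-level
   Spearman over 20 equal-count breadth bins).
3. **3D-genome integration** — TAD overlap census (including whole-TAD
   spanning at a ≥ 90 % coverage threshold), normalized TAD position
   profile, same-class loop connectivity and multiplexity (1 / 2 / ≥3
   partner anchors), a length-preserving permutation null for grand-domain
   connectivity, loop-partner target-gene assignment (≤ 3 kb), and
   enrichment-significance correlation between gene sets (cumulative
   hypergeometric, p < 0.01, enrichment factor > 1.5).
4. **Differential activation** — per-gene H3K27me3 change
   (log2 fold-change with pseudocount, |log2FC| > 1 ⇒ loss/gain), crossed
   with expression calls (log2FC > 1, FDR < 0.05 ⇒ activated) into an
   activation catalog with summary percentages, cumulative-shift test and
   per-mark/methylation profiles (promoter vs gene-body deltas).
5. **Synthetic data** — a paired normal/tumor epigenome with a
   heavy-tailed peak-breadth law, breadth-linked signal, breadth-repressed
   expression, TAD-aligned grand domains, loop enrichment and planted
   tumor loss/gain with expression/methylation responses, all keyed to a
   seed and recorded in a truth JSON.

All coordinates are 0-based half-open; bedGraph gaps mean value 0; output
tables are TSV with `#` provenance headers.

## CLI

```sh
silencerkit demo --out runs/demo --seed 7            # simulate + full pipeline
silencerkit simulate --out runs/d1 --seed 3          # synthetic data only
silencerkit call-domains --run-dir runs/d1 --out runs/d1/analysis \
    --merge-gap 2000 --grand-quantile 0.95 --min-breadth 50000
silencerkit annotate-genes --run-dir runs/d1 --out runs/d1/analysis
silencerkit tad --run-dir runs/d1 --out runs/d1/analysis --n-perm 1000
silencerkit differential --run-dir runs/d1 --out runs/d1/analysis
silencerkit report --out runs/d1/analysis
```

`demo` derives per-stage seeds from the single master seed (simulation =
seed, control sample = seed + 1000, permutation = seed + 2000), writes a
markdown report and a MANIFEST with a sha256 checksum for every output;
re-running with the same seed reproduces all checksums byte-for-byte.

An external differential-expression table (`--de-table`, columns gene_id /
log2fc / fdr) replaces the built-in replicate-count rank-sum mode.

## Layout

```
src/silencerkit/
  core.py         interval / gene / loop / coverage-track types
  io.py           BED, BEDPE, bedGraph, gene/expression/constraint TSV, GMT
  stats.py        rank-sum (exact + approx), correlations, hypergeometric,
                  BH-FDR, empirical p
  domains.py      peak merging, RPKM quantification, breadth classification,
                  metagene matrix
  genes.py        domain->gene marking, constraint association, expression trend
  tads.py         TAD census/profile, connectivity, permutation null, targets,
                  enrichment correlation
  differential.py loss/gain classification, activation catalog, profiles
  simulate.py     synthetic epigenome generator with planted truth
  pipeline.py     stage orchestration over run directories
  cli.py          click CLI
```
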