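# tadakit

Analysis toolkit for a multi-omics workflow that nominates transcriptional
targets of a receptor-tyrosine-kinase signal in the *Drosophila* larval CNS,
and characterises a candidate neuropeptide precursor and the behavioural
phenotypes of its loss. The package covers five analysis stages plus a
fully seeded synthetic-data module, so the entire chain is testable without
any external downloads.

## What it does

1. **GATC fragment map** (`tadakit.gatc`) — Targeted DamID (TaDa) reports
   RNA Pol II occupancy through methylation of GATC sites; the unit of
   quantification is the DpnI fragment between consecutive cut sites
   (cut at `GA^TC`, coordinates 0-based half-open).

2. **Differential occupancy** (`tadakit.damid`) — reads are counted onto
   fragments by midpoint, normalised to log2-CPM, and tested with a
   moderated two-sample *t* (per-fragment variance shrunk toward the
   across-fragment mean with prior weight `prior_df = 4`; the `prior_df = 0`
   limit is the ordinary *t*-test). Fragments with `p < 1e-5` are chained
   into peaks (gap tolerance 195 bp, maximum width 5000 bp), combined with
   the Simes rule `p = min_i (n·p_(i)/i)`, and filtered across peaks with
   Benjamini–Hochberg at FDR ≤ 0.05 and |mean log2FC| ≥ 2, direction
   "down" (occupancy lost under the perturbation). Peaks are assigned to
   overlapping genes and annotated onto promoter/UTR/exon/intron features.

3. **Signature enrichment** (`tadakit.signature`) — AUCell-style scoring:
   each cell's genes are ranked by decreasing expression and the score is
   the area under the recovery curve of signature genes within the top
   5% of the ranking, normalised to [0, 1]; cells with AUC strictly above
   the threshold (0.196 in the modelled analysis) are "enriched".

4. **Context-dependent filter** (`tadakit.integration`) — a candidate must
   simultaneously (i) be in the DamID down set, (ii) be up in the bulk
   gain-of-function contrast (log2FC > 1.5, p ≤ 0.05), (iii) be down in the
   loss-of-function contrast (log2FC < −1.5, p ≤ 0.05), and (iv) be
   expressed in receptor-positive cells (≥ 10% co-expression fraction).
   Every criterion leaves an audit flag per gene.

5. **Precursor processing** (`tadakit.propeptide`) — prohormone convertase
   cleavage at maximal poly-/dibasic K/R runs (KR, KK, RR, RK, …),
   carboxypeptidase trimming of C-terminal basics, C-terminal amidation of
   an exposed glycine, monoisotopic masses (pyteomics) matched to observed
   peptidomics masses within an inclusive 8 ppm tolerance, plus composition
   metrics (glutamine runs, Bjellqvist-pKa isoelectric point, net charge).

6. **Activity-monitor analysis** (`tadakit.phenotype`) — Trikinetics DAM
   parsing, sleep (≥ 5 consecutive zero-count minutes), death censoring
   (terminal immobility > 24 h), daily activity/sleep summaries,
   morning/evening anticipation ratios (3 h / 6 h pre-transition activity),
   actograms, and the chi-square periodogram
   `Qp = K · Σ_h (M_h − M̄)² / ((1/N′) Σ_i (X_i − M̄)²)` with
   `power = Qp − χ²_{1−α, P−1}`, plus the corrected-total-cell-fluorescence
   formula `CTCF = integrated density − area × mean background`.

`tadakit.synthetic` generates genomes with planted GATC spacing,
negative-binomial DamID reads with planted occupancy loss, single-cell
matrices with one signature-enriched cluster, bulk DE tables, Poisson
activity series with known period/sleep/death structure, and prepropeptides
with planted cleavage sites — each returning a `TruthRecord` for recovery
tests.

## Worked example

```python
from tadakit import (gen_genome, gen_tada_reads, count_reads_per_fragment,
                     differential_occupancy_genes, median_fragment_length,
                     build_fragments, find_gatc_sites)

genome, genes, truth = gen_genome(length=505_000, seed=42)
frag_map = build_fragments(find_gatc_sites(genome))
print(f"genes: {len(genes)}, GATC fragments: {frag_map.n_fragments()}, "
      f"median fragment: {median_fragment_length(frag_map):.0f} bp")

targets = [g.gene_id for g in genes[:3]]
samples, conditions, frag_map, _ = gen_tada_reads(genome, genes, targets, seed=42)
matrix = count_reads_per_fragment(samples, frag_map, conditions)
result = differential_occupancy_genes(matrix, genes)
print(f"retained peaks: {len(result['retained_peaks'])}")
print(f"down genes: {result['genes']}")
```

prints

```
genes: 50, GATC fragments: 1477, median fragment: 242 bp
retained peaks: 3
down genes: ['contig1_g1', 'contig1_g3']
```

Three genes carried a planted 4-fold occupancy loss; on this deliberately
small 505 kb demo two of them survive the strict default gates
(fragment p < 1e-5, peak FDR ≤ 0.05, |log2FC| ≥ 2, direction down). At the
full study scale (500 genes over 5 Mb) the same pipeline recovers the 20
planted targets with precision and recall ≥ 0.9 — that is what the
acceptance suite verifies.

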