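# sumoscape

Analysis toolkit for heat-shock-induced chromatin SUMOylation, for
epigenomics groups working with SUMO2/3 (or other factor) ChIP-seq together
with GRO-seq nascent transcription. The package covers the downstream
computational arc of such a study: replicate-consistent peak sets and their
genomic classification, promoter-proximal pausing, divergent eRNA enhancer
detection, differential transcription, and the stratified peak-to-gene
association analysis that connects chromatin SUMOylation to transcription
and pausing — plus a synthetic-data generator with planted ground truth so
the whole pipeline can be validated end to end without external data.

## Core quantities

* **Peaks**: sliding-window Poisson enrichment against an input sample;
  a region counts only if a peak was defined in **both** biological
  replicates (base-pair intersection), and sparse peaks are removed with
  strict raw-read cutoffs (control < 9 reads, heat shock < 10 reads).
  Condition classes: C-unique / shared / HS-unique by ≥ 1 bp overlap;
  HS-enriched / HS-depleted by a four-fold normalized tag ratio
  (all tags depth-normalized to 10⁷ reads).
* **Transcription**: per gene, sense-strand GRO-seq RPKM over the promoter
  (TSS..+250 bp) and gene body (+250 bp..TTS). A gene is *transcribed* if
  body RPKM > 0.5 in control or heat shock. The promoter-proximal pausing
  index is `PPI = promoter RPKM / body RPKM`; the transcriptional response
  is `log2(body RPKM_HS / body RPKM_C)`. Pol II activity uses promoter
  RPKM > 0.2 and gene-level counting over TSS..TTS+3 kb.
* **eRNA enhancers**: intergenic loci (> 10 kb from any TTS) where two
  opposing-strand de novo transcripts lie ≤ 1 kb apart in divergent
  orientation, with ≤ 2-fold difference between strand read counts in
  ± 500 bp of the center; transcription and ChIP signal are measured in the
  1-kb locus window.
* **Differential transcription**: a negative-binomial exact count test
  (conditional on the per-gene total; exact binomial at dispersion 0) with
  Benjamini–Hochberg FDR, calling genes at FDR < 0.01 and fold change > 2.
* **Association**: genes are flagged by a SUMO peak overlapping their
  promoter window, or by an intergenic SUMO peak center within 100 kb of
  the TSS; transcription metrics are then compared between flagged and
  unflagged genes with rank-based tests (Kruskal–Wallis/Dunn,
  Mann–Whitney, t).

## Worked example

Simulate a small scenario and run the pipeline from the shell:

```bash
sumoscape simulate --seed 3 --preset small -o sim/
sumoscape peaks --sample sim/sumo_HS_r1.bed --control sim/input.bed \
    --chrom-sizes sim/chrom.sizes --min-reads 10 -o peaks_HS_r1.tsv
sumoscape transcribe --genes sim/genes.gtf --chrom-sizes sim/chrom.sizes \
    --groseq-c sim/groseq_C_r1.bed --groseq-hs sim/groseq_HS_r1.bed -o tx.tsv
```

which prints

```
wrote scenario to sim
32 peaks -> peaks_HS_r1.tsv
50 genes -> tx.tsv
```

The 32 peaks are the planted heat-shock SUMO sites recovered from one
replicate at 10-read stringency; `tx.tsv` holds the per-gene promoter/body
RPKM, pausing indices for both conditions, the transcribed flag, and the
log2(HS/C) response for the 50 simulated genes.

The same analysis from Python, end to end:

```python
from sumoscape.synthetic_data import SimConfig
from sumoscape.workflows import hs_scenario_analysis, directional_summary

summary = directional_summary(hs_scenario_analysis(SimConfig(seed=5)))
print(summary["ppi_by_promoter"])
```

```
{'median_associated': 8.15, 'median_unassociated': 3.47,
 'mannwhitney_p': 2.5e-22}
```

i.e. genes with a promoter SUMO peak pause roughly 2.3× more strongly than
genes without one — the planted regulatory structure, recovered by the
measurement pipeline.

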