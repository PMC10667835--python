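# srps

Genome-wide inference of **selective RNA processing and stabilization
(SRPS)** targetomes in bacteria, from strand-specific transcript 5′/3′
end-count profiles.

In a polycistronic operon, one primary transcript can yield very different
per-gene transcript abundances: ribonucleases cut the primary mRNA into
segments, and the segments decay at different rates. Four enzyme activities
drive this in *E. coli*:

* **RppH** removes the 5′ pyrophosphate, converting primary (5′-PPP)
  transcript ends into processed (5′-P) ends — the licensing step for decay;
* **RNase E** (endonuclease) cleaves preferentially after `RN↓WUU`
  (R = G/A, W = A/U), creating new 5′ and, indirectly, new 3′ ends;
* **PNPase, RNase II, RNase R** (3′→5′ exonucleases) trim the exposed 3′
  ends and halt at stable stem-loops.

`srps` calls each enzyme's targetome from sequencing libraries that report
both termini of each RNA fragment (SEnd-seq-style data), relates the site
classes to one another, and computes the quantitative statistics that link
sequence and structure to processing:

* per-position **5′/3′ end counts and coverage** from paired alignments,
  with adapter-based partitioning of the 5′-monophosphate ("processed")
  fraction and gene-level FPKM,
  `FPKM_g = reads_g × 10⁹ / (total × L_g)`;
* **RppH sites**: reproducible processed-fraction 5′-end pile-ups within
  5 nt of a TSS (with transcription-initiation wobble handled by ±2 nt
  bins); processed 5′ ends far from TSSs are "other enzyme" monophosphate
  ends;
* **differential end calling** (WT vs. mutant strains): TMM normalization,
  an exact negative-binomial test, BH FDR < 0.05, |log2FC| ≥ 1, an end
  proportion (ends/coverage) ≥ 2% and ≥ 3× the other strain, 5-nt window
  clustering — yielding RNase E 5′/3′ ends and exonuclease trimming
  stop/start sites;
* **site matching**: rne3 ↔ exo stop/start within ±5 nt, stop/start pairs
  within the enzyme's reach (300 nt for PNPase/RNase R, 10 nt for
  RNase II), processing fragments, and the RNase II offset histogram;
* the **processing ratio** (Eq. on processed/total 5′ ends in a ±4 nt
  window), its correlation with the **TSS trinucleotide score**
  (CCT = 3 … AAT/AGT = 14), the **end ratio** at trimming stops and its
  negative correlation with the upstream stem-loop folding energy ΔG
  (ViennaRNA MFE), positional base frequencies, and sliding-window MFE
  profiles;
* **operon analysis**: complex-operon classification from adjacent-gene
  FPKM skew, the site-distribution table, and operons with multiple RNase E
  cleavages in a 5′-UTR/IGR (alternative 5′-UTR isoforms);
* a **generative simulator** that implants all of the above with known
  ground truth, enabling parameter-recovery benchmarking of the entire
  pipeline.

## Worked example

Simulate a 50-operon genome with known processing parameters, run the full
calling pipeline, and check the two structure/sequence relationships:

```python
import srps

cfg = srps.SimConfig(seed=7, n_operons=50)
genome, annotation, truth, profiles = srps.simulate(cfg)
calls = srps.call_all_sites(profiles, annotation)
quant = srps.quantify(calls, profiles, genome)

print(f"RppH sites:            {len(calls.rpph)}")
print(f"RNase E ends:          {len(calls.rne5)} five-prime, {len(calls.rne3)} three-prime")
print(f"score vs ratio r:      {quant.score_ratio_r:.3f}")
print(f"end ratio vs dG r:     {quant.endratio_mfe_r:.3f}")
print(quant.score_table)
```

prints

```
RppH sites:            50
RNase E ends:          35 five-prime, 51 three-prime
score vs ratio r:      0.998
end ratio vs dG r:     -0.679
   tri  score   n  mean_ratio
0  CCT      3  11    0.234588
1  CAT      7   4    0.458795
2  GAT      8   3    0.555753
3  ACT     10   8    0.646241
4  TAT     10   4    0.645235
5  ATT     13   3    0.811278
6  AGT     14   7    0.897682
7  AAT     14   8    0.895244
```

All 50 implanted RppH positions are recovered; the group-mean processing
ratio is almost perfectly linear in the TSS trinucleotide score (r ≈ 1.0,
the implanted link is linear), and the end ratio at PNPase trimming stops
falls with the stability of the upstream stem-loop (r ≈ −0.68; more
negative ΔG → the enzyme halts more reliably → a larger share of 3′ ends
concentrates at the stop).

The same stages are exposed on the command line for file-based use:

```bash
srps simulate --seed 1 --out sim/          # FASTA + GFF3 + bedGraphs + truth
srps call --sim-dir sim/ --out calls/      # BED per class + summary.json
srps partition --fastq reads.fastq --out-prefix run1
srps endcounts --bam aligned.bam --out-prefix wt_total_1
```

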