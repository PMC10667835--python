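# Methods

## The inference problem

Selective RNA processing and stabilization (SRPS) shapes the per-gene
transcript abundance of a polycistronic operon after transcription: RppH
converts the primary 5′-triphosphate end to a monophosphate, RNase E cleaves
the licensed transcript endonucleolytically, and the 3′→5′ exonucleases
(PNPase, RNase II, RNase R) trim the exposed 3′ ends until a stable
stem-loop stops them. Every one of these events leaves a footprint in
strand-specific per-base counts of fragment 5′ ends (`n5`), 3′ ends (`n3`)
and coverage (`cov`): a new 5′ end appears, a 3′ end appears or moves, and
coverage steps up or down. The package infers the enzyme targetomes from
those footprints by comparing libraries — the adapter-selected
monophosphate ("processed") fraction against the total library for RppH,
and wild type against enzyme-deficient strains for the nucleases.

Coordinates are 0-based half-open internally; bedGraph output is 0-based,
GFF3 and report TSVs 1-based. "Upstream/downstream" is always transcript
orientation. The 3′ terminus of a plus-strand fragment `[s, e)` is `e−1`.

## Calling rules and their parameters

**Processed-fraction (RppH) caller.** A candidate position needs
`n5 > candidate_min_reads` (default 3) and a coverage step
`cov[p] ≥ 1.3 × cov[p−1]` (strand-aware). Transcription-initiation wobble is
handled by ±2 nt bins: a bin passes when its summed read starts reach
`bin_min_reads` (default 10; applied to the bin total — a per-position
requirement of 10 would contradict the >3-read candidate rule) and the
coverage at the single base 3′ of the bin is ≥ 1.3 × the bin's coverage.
The bin-coverage summary is the **minimum** inside the bin (config
`bin_cov_mode`, alternative `mean`): the bin straddles the coverage step, so
its 3′ half already carries post-processing coverage; summarizing by the
mean would systematically fail internal processed sites that sit on top of
substantial upstream coverage, which the same rule is also used for. The
representative is the max-`n5` position (ties 5′-most). Sites reproduced
within 5 nt in ≥ 2 libraries are kept; within 5 nt of a TSS → class `rpph`,
otherwise `other_processed`.

**Differential end caller.** Positions with CPM ≥ 3 in every replicate of
at least one strain are tested. Normalization is the trimmed mean of
M-values (30% M-trim, 5% A-trim, precision weights, reference = library
whose upper-quartile rate is closest to the mean). The test is an exact
negative-binomial double-tail test on library-size-equalized counts,
conditioning on the row total (a binomial test in the dispersion-0/Poisson
limit); replicated designs use a moment estimate of the common dispersion,
single-replicate knockouts a fixed dispersion of BCV² = 0.2² = 0.04, the
standard conservative choice without replication. Benjamini–Hochberg FDR is
taken across tested rows. Called rows additionally need an end proportion
(ends/coverage at the position, pooled per strain, capped at 1) ≥ 2% in the
enriched strain and ≥ 3× the other strain's proportion. 5′ RNase E ends
must coincide exactly (configurable tolerance, default 0) with an
`other_processed` monophosphate site — the cleavage product is a
monophosphate end and must be visible in the processed fraction. Finally,
called positions within a 5-nt window are collapsed to the one with the
highest end proportion in the reference strain (greedy 5′→3′ sweep, ties
5′-most).

**Site matching.** All matching is per strand and deterministic. A 3′
RNase E end is classified against exo trimming stops first, then starts
(±5 nt; nearest, ties upstream): the stop comparison runs first, so an end
matching both counts as a stop match, and the three fractions partition the
rne3 set. Stop/start pairing is nearest-downstream-start within the
enzyme's reach (300 nt PNPase/RNase R, 10 nt RNase II), each start usable
once, conflicts resolved in ascending distance. Processing fragments are
(rne5, rne3) pairs < 300 nt apart and same-enzyme (start5, start3) pairs
50–300 nt apart.

**Quantitative layer.** The processing ratio of a site is the processed/total
`n5` sum over the ±4 nt window, computed per replicate pair and averaged,
capped at 1. The end ratio of a stop/start pair is the 3′-end sum over the
11 nt centered on the stop divided by the sum from 5 nt upstream of the
stop to 5 nt downstream of the start, pooled over WT totals. `upstream_mfe`
folds the single 50-nt window immediately upstream of the stop
(`mode="window"`, the default): that window holds the stem-loop that
blocked the enzyme. A sliding-window mean over the 100-nt flank
(`mode="sliding"`) is retained for profile-style summaries, but note its
geometry: only one of the 51 windows fully contains a stop-adjacent
stem-loop, so the mean dilutes exactly the signal the end-ratio correlation
depends on. Folding is ViennaRNA's MFE with default parameters throughout.
The TSS trinucleotide score table ships with the eight validated entries
(CCT 3, CAT 7, GAT 8, ACT 10, TAT 10, ATT 13, AAT 14, AGT 14) and is
immutable; unknown trinucleotides raise an explicit error unless a user
table is supplied (2-column TSV).

**Operon layer.** An operon is complex when any adjacent gene pair has both
FPKM ≥ 2 and a ≥ 3-fold ratio in either direction, or one FPKM < 2 and an
absolute difference ≥ 10. (The in-either-direction reading — ≥ 3 or ≤ 1/3 —
is the only self-consistent one; "≥ 1/3" taken literally would flag every
pair.) Operon genomic extent is [TSS, 3′ end of last gene), half-open,
same-strand. Alternative-UTR cases need ≥ 1 rne5 end in a 5′-UTR < 200 nt
from the TSS, or ≥ 2 rne5 ends in one IGR spaced < 200 nt, and every
implied isoform 5′ end must have pooled WT-total `n5` evidence (≥ 1,
configurable).

## The synthetic-data generator

The simulator is the generative inverse of the pipeline and defines the
study conditions for all recovery benchmarks. Defaults: 200 operons
(1–4 genes of 200–500 nt, IGRs 30–120 nt, 5′-UTRs 60–250 nt), depth 200
expected end-reads per implanted event, mutant residual activity ε = 0.02
(activity ablation, matching a temperature-sensitive allele rather than a
clean null), negative-binomial count dispersion 0.05, library-size factors
lognormal (σ = 0.15), and a low uniform background of stray fragments
(0.05/kb per library). The emitted design mirrors the study: WT total ×3,
WT processed ×3, RNase E-ts total ×2, and one total library per exonuclease
knockout.

Per operon:

* the TSS trinucleotide is drawn from the eight scored entries (90%) or at
  random; the processed fraction follows the clamped linear link
  `p = 0.05 + 0.06 × score` (scores 3–14 span p ≈ 0.23–0.89 — the linear
  form mirrors the observed relationship without asserting its unprinted
  slope), and TSS 5′ ends wobble over ±2 nt (weights .08/.14/.56/.14/.08);
* with probability 0.7 the operon carries one RNase E cleavage: the `RN↓WUU`
  motif is implanted, a fraction `q = 0.8 p` of molecules is cleaved
  (cleavage requires the monophosphate end, so intensity follows p; ×ε in
  the rne-ts strain), the downstream fragment keeps a monophosphate 5′ end
  at the cleavage site, and the upstream fragment's exposed 3′ end is
  trimmed by the operon's exonuclease (pnp/rnb/rnr weighted 0.5/0.35/0.15);
* otherwise the operon carries one endonuclease-generated internal fragment
  (50–300 nt) fully degraded in WT, whose 5′/3′ ends accumulate only in the
  cognate knockout (`start5`/`start3` signal);
* trimming: PNPase/RNase R start at the exposure point and halt at a
  designed stem-loop with probability
  `P(stop) = 1/(1 + exp(k (ΔG − ΔG₀)))`, ΔG₀ = −10 kcal·mol⁻¹, k = 0.4 (a
  logistic keeps probabilities in (0,1) while matching the observed
  monotone negative association); a fraction u = 0.08 of cleaved molecules
  is caught before trimming and retains the exposure-point 3′ end, giving
  the end ratio its denominator. RNase II is modeled as a distributive
  nibbler: it always halts at the stem, 3–10 nt (mode 3–5) downstream of
  which its trimming start sits.

Three generator choices deserve emphasis because naive alternatives break
the method's own rules:

* **u = 0.08.** The untrimmed residual must be > 0 (otherwise every end
  ratio is 1 and the ΔG correlation is undefined) but small: at u ≈ 0.15
  the WT residual at the exposure point pushes the mutant/WT proportion
  ratio below the 3× filter for strongly cleaved operons, i.e. the
  generator would contradict the caller it feeds.
* **Background GC = 0.30.** Random 50-nt windows at GC 0.5 fold to
  ΔG ≈ −9 ± 2 kcal·mol⁻¹, burying the implanted stem-loop signal; an
  AT-rich background lets the designed stem-loops, not incidental
  background structure, carry the folding signal.
* **Stop probability uses the contextual ΔG** — the folding energy of the
  50-nt window immediately upstream of the stop, with the stem-loop
  implanted in place (the enzyme encounters the folded 3′ end in context,
  not an isolated hairpin), and the processive enzymes stall a 3-nt
  footprint short of the stem. The truth table records both the isolated
  hairpin ΔG (`dg_hairpin`, which equals `fold_mfe` of the recorded
  sequence by construction) and the contextual ΔG (`dg`, which drives the
  stop link). Stem-loop design targets ΔG bands of [−14, −6] (pnp/rnr; the
  logistic transition region) and [−20, −8] (rnb) by rejection sampling of
  inverted repeats, verified by the folding engine.

The WT processed libraries are binomial thinnings of their matched total
replicate — in the protocol the processed reads are extracted from the
total library by adapter search, so the two share a sequencing depth;
modeling them as independent libraries would inject spurious library-size
noise into the processing ratio.

What the simulator does **not** emulate: raw reads and alignment artifacts
(simulation is at the fragment/end-count level; the adapter and alignment
filters are tested on separately constructed FASTQ/SAM fixtures),
overlapping transcription units, rho-dependent or premature termination,
multi-TSS operons, RNase E's degradosome context, and cross-enzyme
redundancy (each operon is trimmed by exactly one exonuclease; the other
knockouts behave as WT there). Passing recovery benchmarks therefore shows
that the calling rules invert this generative model at realistic depth and
noise — not that the thresholds are optimal for any particular real
dataset, where the unmodeled features above add calling errors.

## Numerical and degenerate-case choices

* Ties everywhere break toward the 5′-most position (determinism).
* Proportions are capped at 1; zero coverage gives proportion 0.
* The exact test conditions on the observed row total with a `1 + 1e−10`
  relative tolerance when summing outcome probabilities no more likely than
  the observed one; `t = 0` gives p = 1.
* TMM falls back to factor 1 for degenerate pairs (no common nonzero rows);
  an all-zero library is an error.
* A zero total-window sum skips the processing-ratio record with a warning;
  a zero denominator skips the end-ratio record; a trimming start inside
  the 11-nt numerator window yields ratio 1 with a degenerate-geometry
  warning.
* Sites too close to contig edges are skipped with warnings in MFE and
  base-frequency analyses; an empty usable set is an error.
* Score lookups never silently return 0 — unknown trinucleotides raise.
* `score_vs_ratio`/`endratio_mfe_correlation` require ≥ 3 groups/records
  and refuse zero-variance inputs rather than report an undefined r.

## Problem sizes

The shipped benchmark (200 operons, ~0.3 Mb genome, 9 libraries, depth 200)
runs the full pipeline in well under a minute on one CPU; the test suite
adds exhaustive small-total oracle checks (all two-library splits with
totals ≤ 200) and a 30-operon simulation shared across unit tests. These
sizes were chosen as the smallest at which every site class appears with
double-digit counts per enzyme and the correlation estimates stabilize.

## Known limitations

* The exact-test stand-in reproduces the TMM + exact-NB methodology but
  not any specific external implementation's pseudo-count rounding or
  dispersion shrinkage; genome-scale site counts from real data will
  therefore differ in detail from analyses run with other toolchains.
* Single-replicate knockout comparisons inherit the fixed-dispersion
  assumption; the BCV default (0.2) is a convention, not an estimate.
* `other_processed` overlap for 5′ RNase E ends is exact-position by
  default; real data with imperfect end precision may need the tolerance
  raised.
* The complex-operon rule and the score table are taken as given;
  the full 64-entry trinucleotide score table is not public, so unknown
  trinucleotides require a user-supplied extension.
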