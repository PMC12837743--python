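# Methods

`enhancerlink` implements the computational chain used to connect a
noncoding risk-SNP enhancer to the genes it regulates through chromatin
looping: viewpoint 4C-seq processing and interaction calling, integration
with differential expression to nominate target genes, efficiency-corrected
3C-qPCR quantification, and allele-specific transcription-factor motif
scoring at the SNP. This note records the models, the parameters that
matter, and the design choices made where the design was genuinely open.

## Coordinates and conventions

All coordinates are 0-based, half-open (BED convention). Restriction
enzymes are described by a recognition motif and a cut offset from the
motif start: DpnII cuts `^GATC` (offset 0), CviQI cuts `G^TAC` (offset 1).
Overlapping motif occurrences each produce a cut; `N` never matches a
motif position; zero-length fragments (a cut at a chromosome end) are
dropped, so fragments always tile each chromosome exactly. Degenerate
IUPAC motifs and methylation sensitivity are out of scope.

The default fragment map is the first-cutter (DpnII) map; the second
cutter (CviQI) participates only in read-level in-silico digestion. Both
are plain `EnzymeSpec` values, so a DpnII x CviQI joint map is one
argument away (`digest_genome(refs, [DPNII, CVIQI])`).

## 4C read model and processing

The assay circularizes the bait (viewpoint) restriction fragment with its
contact partner; inverse PCR with a bait-anchored reading primer reads
across the ligation junction into the partner fragment. Processing
follows that structure:

1. **Demultiplex/trim.** A pair is kept iff exactly one mate begins with
   the reading primer (anchored Hamming distance <= `max_mismatch`,
   default 0); the primer prefix is removed and the remainder of that mate
   is the capture. Pairs where neither or both mates match are discarded
   and counted.
2. **In-silico digestion.** The capture is split at every DpnII/CviQI cut
   position; pieces shorter than `min_fragment_len` (default 20 bp, the
   shortest length that is effectively unique in the toy genomes) are
   dropped. This separates the bait-side remnant from the partner piece at
   the ligation junction.
3. **Placement.** The bundled matcher places a piece iff it occurs exactly
   once in the genome over both strands (reverse complement searched);
   ambiguous and absent pieces are discarded and counted. It is an exact,
   toy-scale matcher by design — externally aligned data enters through
   SAM (`load_placements_sam`; primary mapped records above a MAPQ
   threshold only).
4. **Coverage.** Each placement is assigned to the restriction fragment
   containing its 5'-most aligned base; counts are scaled to reads per
   million (RPM), so RPM sums to 10^6 per library by construction.
5. **Calling.** A fragment is called iff its RPM exceeds the threshold
   (default 50) in *every* biological replicate — the strictest reading of
   "reproducible in two replicates" — and lies outside the bait exclusion
   zone (bait fragment +/- 2 fragments, standard practice for
   self-ligation and undigested signal). Calls carry a cis/trans flag and,
   for cis, the signed distance from the call midpoint to the SNP. The
   calling unit is a single restriction fragment; adjacent called
   fragments are not merged.

No statistical background model (z-scores, domainograms), PCR-duplicate
collapsing or quality trimming is attempted: the thresholded-RPM rule is
the method being implemented, not approximated.

## Target-gene nomination

The two-step filter: a gene is a candidate iff (i) it is significantly
down-regulated after enhancer deletion — log2FC < -1.3 and adjusted
p < 0.05, strict inequalities — and (ii) at least one interaction call
whose minimum across-replicate RPM exceeds 50 overlaps the gene body
extended by a window. The assignment window is genuinely open (the
interacting region need not touch the gene body); the default is 50 kb
around the gene, configuration-exposed, and every candidate reports its
supporting fragments and distances so the assignment can be audited.
Trans-supported genes are nominated identically to cis-supported ones.
Gene-set overlap comparisons reuse the same thresholded-set semantics,
with an optional magnitude-free variant (padj and sign only) for set
definitions that do not impose a fold-change cut. Benjamini–Hochberg
adjustment is the standard step-up procedure (delegated to statsmodels and
cross-checked in the tests against an independent reference
implementation).

## 3C-qPCR with efficiency correction

Primer-pair efficiency E is estimated from a genomic-DNA standard curve:
ordinary least squares of Ct on log10(dilution), then
E = 10^(-1/slope) - 1. At least three distinct dilutions are required and
a non-negative slope is an error ("non-amplifying curve"). The QC window
is 90% <= E <= 110%, bounds inclusive (the natural reading of "between");
both bounds are parameters. Relative quantity is RQ = (1+E)^(-Ct);
normalizing to the anchor self-ligation RQ gives interaction frequencies
(anchor = 1). Order of operations where the protocol is ambiguous:
technical replicates are averaged on the Ct scale (an `'rq'` alternative
is exposed), and anchor normalization happens within each biological
replicate *before* cross-replicate summarization, preserving
within-replicate pairing. Summaries are mean +/- SEM with the n-1 sample
standard deviation; SEM is reported as missing when n = 1.
Promoter-vs-flank comparisons report mean ratios with first-order
(delta-method) SEM propagation, validated against Monte-Carlo propagation
in the tests; hypothesis testing of frequency differences is out of scope.

## Allele-specific motif scoring

JASPAR PFMs (bracketed or plain four-row dialect) become probabilities via
an equally split pseudocount: p(b, j) = (count + pc/4) / (colsum + pc),
with pc = 0.8 by default and a uniform 0.25 background (both exposed).
Scores are log2 odds (bits). For a SNP, each allele is substituted into
the context and every motif-length window overlapping the SNP is scored on
both strands; the report keeps the best window per allele and their
difference (positive delta = alternate allele preferred). Max-over-windows
rather than sum-occupancy matches the single-site interpretation of a SNP
inside one motif hit. Windows containing `N` are skipped. The ChIP-qPCR
arithmetic (percent input with input-dilution correction, fold enrichment
between alleles) and SNP-in-peak interval overlap are included as thin,
exactly specified utilities.

## Synthetic data model

The generators produce every input with known ground truth, seeded and
byte-reproducible:

- **Genome.** Uniform random sequence (two chromosomes, 1 Mb and 0.5 Mb
  by default) with a GATC injected every ~400 bp so the fragment map is
  dense (~160 bp median fragment).
- **Contacts.** Partner fragments are drawn i.i.d. from a profile:
  planted peaks with explicit weights, cis background
  (1 + |d|/d0)^(-alpha), and a uniform per-fragment trans background
  epsilon. Defaults alpha = 3, d0 = 2.5 kb, epsilon = 1e-5. These were
  chosen so that, at the default depth of 10^5 pairs per replicate, the
  cis background falls below the RPM-50 calling threshold beyond ~35 kb
  from the bait while planted peaks (weight 50x the cis background level
  at 50 kb, i.e. >= 50x their local background) sit severalfold above it
  in every replicate; a shallower decay (e.g. alpha = 1 with d0 = 10 kb)
  keeps hundreds of kilobases of ordinary cis background above threshold
  and makes clean peak recovery impossible by construction.
- **Reads.** Read 1 = reading primer + 10 bp bait remnant + partner
  fragment sequence across the ligation junction (150 bp total); read 2 =
  partner fragment prefix. Reads are error-free by default so that
  placement ambiguity, not sequencing noise, is the tested difficulty.
- **DE tables.** Null genes: log2FC ~ N(0, 0.2), p ~ U(0,1). Targets:
  log2FC ~ N(-2.0, 0.3) rejection-sampled below -1.4 (so the planted
  effect always clears the -1.3 cut), p ~ U(0, 1e-5); BH adjustment over
  the whole table. Targets sit exactly on peak fragments; null genes
  avoid them.
- **Ct tables.** Ct = intercept - log10(template)/log10(1+E) + N(0, sd).
  The default scenario's four primer pairs have true E of 0.95, 1.00,
  1.05 and 0.85 — the last must fail QC.
- **Motif.** A synthetic SOX-family-like PFM (consensus AACAAT, strongly
  informative columns) whose consensus is completed by the alternate
  allele.

What the generator does **not** emulate: sequencing errors and quality
structure, PCR duplicates, mappability variation, genome-scale repeat
content, and realistic cis/trans contact proportions (trans background is
deliberately sparse). Passing recovery tests therefore demonstrates the
correctness of the pipeline's logic under its stated model, not its
robustness to real-data artifacts.

## Problem sizes and numerical choices

The default scenario uses 10^5 read pairs per replicate x 2 replicates on
a 1.5 Mb genome (~9,600 fragments), 200 genes with 3 planted targets, and
200 simulated standard curves for efficiency-recovery statistics; the
twenty-seed nomination-sensitivity check uses the depth-matched
multinomial contact sampler rather than read-level simulation, with
read-level equivalence asserted once end-to-end. RPM conservation is
checked to 1e-9 relative; the efficiency formula identity to 1e-12;
PWM/digestion/BH implementations agree exactly (1e-12) with brute-force
oracles. Ties in best-window motif scoring resolve to the first window
encountered (leftmost, forward strand first), making reports
deterministic.

## Known limitations

- The exact matcher is quadratic in genome size per lookup and intended
  for toy genomes only; real libraries should arrive as SAM.
- Interaction calling is threshold-based; no FDR is attached to calls.
- The gene-assignment window is a blunt instrument; candidates report
  distances precisely so users can apply stricter locus logic.
- `summarize_cis_trans` percentages are rounded to two decimals and can
  sum to 99.99/100.01 for pathological counts; counts are always exact.
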