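# Methods

This note documents the models, conventions, parameter choices and known
limitations of `circscreen`. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and junction conventions

All genomic intervals are 0-based half-open. A backsplice junction is
stored as `(chrom, strand, acceptor_pos, donor_pos)` with
`acceptor_pos < donor_pos`: the circle occupies the genomic span
`[acceptor_pos, donor_pos)` regardless of strand, and the spliced
circular sequence begins at the acceptor-side base, so the junction sits
at offset 0 of the circle. On the forward genome strand a + circle is
bracketed by `AG` immediately upstream of the acceptor and `GT`
immediately downstream of the donor; a − circle by the reverse
complement pattern (`AC` … `CT`). "Junction-spanning" for an ORF means
translation proceeds past the offset-0 boundary after its first codon.

## Synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions of the demo screen.

**Genome and genes.** Chromosomes are i.i.d. draws with P(G)=P(C)=gc/2
(default gc 0.45), so realised GC content is binomial around the target.
Genes (default 210, 3–5 exons of 90–260 nt, introns 60–160 nt) are placed
without overlap; every exon receives an `AG` written immediately 5' and a
`GT` immediately 3' (in gene-strand orientation). Writing flanks at
*every* exon boundary — not only across internal introns — is a
deliberate superset of the canonical GT..AG intron rule: planted circles
may begin or end at a gene's terminal exons, and the screen's flank
invariant (100 % of planted junctions satisfy the detector's GT/AG rule)
must hold for any contiguous exon block.

**Circles.** A planted circle is a contiguous exon block spliced in
transcript order; the junction joins the end of the last block exon back
to the start of the first. Per-sample abundances are free parameters.

**Reads.** Single-end 150-nt reads (read length is configurable, not
inferred from any dataset; libraries here are idealised) are allocated
multinomially across linear transcripts and circles in proportion to
abundance. Circular templates are rolling: start positions are uniform
on [0, L) and the template is the circle unrolled as often as needed, so
reads may cross the junction; names encode sample, origin, start offset
and serial, which lets tests recompute the simulator's junction-read
bookkeeping independently. The error model is i.i.d. per-base
substitution only — anchors are fixed-length exact-match units, and
indels would change the detection contract. No quality model, paired
ends, or rRNA are simulated.

**Expression.** Samples form tumour/normal pairs (T*k*/N*k*). Background
genes follow a log-normal baseline (log2 mean 7, sd 1.2) with a
within-pair shared effect (sd 0.3) and per-sample noise (sd 0.25);
planted DE features add their log2 fold change to tumour columns. Genes
in a correlated set are generated as `a·circ + ε`, with `a = r/√(1−r²) ·
σ_noise/σ_circ`, which makes the expected sample Pearson r equal the
target at any noise level; the degenerate cases (noise 0 or |r| = 1)
return exact ±1. A per-gene additive shift enforces nonnegativity
without changing Pearson r.

## Junction detection

Detection follows the split-anchor scheme: reads failing a contiguous
end-to-end alignment (≤ m = 2 substitutions; pigeonhole with m+1 spread
seeds guarantees no qualifying placement is missed) against the genome
*and* the spliced transcripts are split into terminal k = 20-mers.
Anchor placement uses an exhaustive exact-match k-mer index;
"unique" means exactly one perfect placement genome-wide, and ambiguous
anchors discard the read. A head-to-tail pair (right anchor genomically
upstream of the left on +, mirrored on −, within a 100 kb span cap)
nominates a breakpoint, which is resolved by scanning every split point
i ∈ [k, n−k]: the read must align as genome-suffix (ending at the donor)
plus genome-prefix (starting at the acceptor) with ≤ m substitutions
total, and the breakpoint must be bracketed by splice flanks. The
junction strand is called from the flank orientation, not from the read
orientation, so a read and its reverse complement carry identical
evidence (unstranded-library behaviour). Ties between flank-consistent
breakpoints go to the leftmost acceptor and are logged.

Candidate calling collapses reads with identical nucleotide sequence
(the working definition of "unique back-spliced reads": PCR-duplicate
collapse) and keeps a junction iff some single sample contributes ≥ 2
distinct junction reads. An optional junction catalogue (BED) annotates
candidates known/novel; no remote lookup is performed.

Limitations: no paired-end evidence, no indels at the breakpoint, no
trans-chromosomal fusions. Reads whose junction arms extend beyond the
donor/acceptor exon into an adjacent intron-spliced region cannot be
extended (the arms are modelled as genomically contiguous); with
multi-exon circles this only reduces the number of usable junction
reads, not correctness.

## Quantification and differential expression

circRNAs are quantified as distinct junction reads per sample scaled to
RPM with the per-sample linearly-mapped read count as denominator; genes
as FPKM (counts / kb / million mapped, with column totals as the mapped
totals when genes come from a simulated count matrix). The differential
test is an explicit stand-in for negative-binomial count machinery (out
of scope here and flagged in output metadata): log2FC = log2(mean_T+pc) −
log2(mean_N+pc) and a two-sided paired (default) or Welch t-test on
log2(x+pc), pseudocount pc = 0.5 RPM for fold-change stability on sparse
junction counts. BH adjustment is applied when requested; the screen's
circRNA rule uses raw p < 0.05 with |log2FC| ≥ 1, the gene-level variant
FDR < 0.05. Degenerate-variance features get p = 1 with a warning. The
t-test on logs is exact under the generator's log-normal noise, which is
what the calibration property (null p < 0.05 fraction ≈ 0.05) verifies;
on real overdispersed counts a count model would be preferred.

## Rolling translation

For every ATG at offset s the translator reads codons around the circle
until the first in-frame stop or 3L nt. Three passes are provably
sufficient: when L is not a multiple of 3 the L codon starts of three
passes visit every circle position exactly once (asserted on random
circles in the tests), and when L ≡ 0 (mod 3) one pass already covers
the start's frame. ORFs with no stop in three passes are flagged
infinite and truncated at 3L nt (never silently). `passes` counts
strictly interior crossings of offset 0, so an ORF ending exactly at the
junction has not crossed it; `exceeds_360` means nt_length + 3 > L and
implies junction spanning. Start codons are ATG only; stops TAA/TAG/TGA.

The *unique C-terminus* is defined as the peptide suffix from the first
codon whose start offset lies in sequence already traversed by an
earlier pass — i.e. codon index ⌈L/3⌉ — which is frameshifted whenever
L % 3 ≠ 0 and empty otherwise. The literature counts such frameshift
tails in slightly different ways (e.g. from the junction re-entry rather
than from frame divergence); this oracle-backed definition was chosen
because it is exact, testable, and rotation-covariant. Under it, a 92-aa
ORF on a 253-nt circle has ⌈253/3⌉ = 85 shared codons and a 7-residue
unique tail.

The screen filter keeps circles whose best (longest; ties to smallest
start offset) junction-spanning ORF is shorter than 100 aa (strict).
Linear mORFs for the length comparison are standard ATG→stop ORFs in the
three forward frames, longest per stop.

## Correlation-ranked GSEA

Genes are ranked by signed sample Pearson correlation with the circRNA
profile (constant genes get r = 0 and are flagged; ties break
lexicographically for determinism). The enrichment score is the classic
weighted KS running sum — hit increments |r|^w (w = 1 default, 0
available) normalised over set hits, miss decrements 1/(N−n); ES is the
extremum by absolute value (positive extremum wins an exact tie), and
the leading edge is the member set up to (ES > 0) or after (ES < 0) the
extremum. The null is *gene-set permutation*: random same-size sets
drawn from the ranked universe, p = (1 + #{|ES₀| ≥ |ES|})/(n_perm + 1)
(never zero), NES = ES / mean |same-sign null ES|. Sample permutation is
deliberately not used: with 6 tumour/normal pairs it has too few
distinct relabellings to resolve p below ~0.03. The permutation loop
uses an O(n) extremum formula over sorted hit positions, verified
against the full running sum in the tests and cross-checked against an
independent implementation (gseapy) on identical inputs.

Prioritisation intersects DE "up" calls with the ORF screen, ranks by
fold change, and annotates each candidate with the configured pathway's
ES sign and permutation p; a *hit* requires negative enrichment with p
below the cut (default 0.05).

## Demo screen: study conditions and power

The default `screen` configuration simulates 3 × 120 kb chromosomes, 210
genes, 6 tumour/normal pairs, 28 000 reads per sample, substitution rate
0.002, and 203 circles: one positive (log2FC +2, a junction-spanning
< 100 aa ORF found by rejection sampling over exon blocks of 180–450 nt,
and a 27-gene set anti-correlated with its abundance at target r = −0.6,
relative noise 0.3), two upregulated decoys rejection-sampled to *lack*
any junction-spanning ORF under 100 aa (they exercise the ORF-filter
path), and 200 background decoys with no planted differential
expression.

Decoy abundances (log-normal around parity with genes) and depth were
chosen so per-sample junction support lands at roughly 10–20 distinct
reads. This is a statistical requirement, not a tuning knob: with
support λ, the estimator sd of log2FC across 6 pairs is approximately
√(2(2.08/λ + 0.0625)/6), and the screen's |log2FC| ≥ 1 gate over 200
null decoys only stays clean (expected false "up" ≪ 1 per run) for
λ ≳ 15; the positive's normal-side support must likewise stay ≳ 10 so a
zero count (which the 0.5-RPM pseudocount maps to an extreme log outlier)
is negligible. These counts emulate the per-circRNA junction coverage of
deep real libraries while keeping the simulated genome small.

One confound is inherent to the design and documented rather than
patched: the planted NK-like set anti-correlates with a tumour-high
circRNA and is therefore itself tumour-low, so *any* decoy that passes
DE by chance tends to show negative enrichment too. The screen's
specificity thus rests on the DE stage's false-positive control — true
of the paired tumour/normal design in general, not only of this
simulation.

What passing tests show — and what they do not: the generator produces
idealised data (uniform coverage, substitution-only errors, log-normal
expression, exact GT/AG flanks, no repeats beyond chance). Success here
demonstrates the algorithms' correctness and calibration under their
stated assumptions, not performance on real libraries with fragment
bias, indels, repetitive genomes or overdispersed counts.

## Reproducibility

Every stochastic component takes an explicit integer seed. The pipeline
fans a single global seed out to stages via
`numpy.random.SeedSequence([seed, stage_index, extra])`, keeping stages
independently reproducible; identical config + seed yields byte-identical
candidate tables. The orchestrator refuses to write into a non-empty
output directory unless forced, so runs never mix. All artefacts are
plain text (FASTA, GFF3, FASTQ, BED6, TSV, GMT, JSON).

## Scale choices

Test and acceptance runs use deliberately small problem sizes chosen to
make their statistical assertions sharp yet quick on one CPU: 1000
random circles for the ORF oracle, 20 planted junctions at ~50× linear
background for recovery, 1000 features for DE calibration, 500
replicates for GSEA null uniformity, 40 replicates for GSEA power, and
10 seeds of the full demo for the end-to-end unique-hit rate.
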