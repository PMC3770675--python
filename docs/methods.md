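# Methods

`polymine` mines DNA polymorphisms from multiple alignments of expressed
sequence tags (ESTs) pooled across crop varieties. Its model of the data
is the one used for EST-based marker discovery in cassava: reads are
single-pass transcript sequences grouped by variety (or library), an
overlap assembler has already aligned them into contigs, and one member
of each contig is an annotated transcript predicted from the draft
genome, which ties alignment columns to genome coordinates. This note
records the model assumptions, the tunable parameters, what the
synthetic-data generator does and does not emulate, and the numerical
and design choices that were genuinely open.

## Discovery model

A polymorphism is a column (SNP) or a short maximal gap run (InDel) of a
contig alignment that segregates *between* varieties while being
consistent *within* each variety. The caller applies six filters, whose
rationale is artifact rejection rather than population-genetic modelling:

1. **Genome anchoring** — the contig must place on the draft genome
   through its reference-member transcript. Applied after calling
   (`require_genome_anchor`, default on) so the caller itself needs no
   genome; unanchored calls are reported in a sidecar when kept.
2. **No N** — any ambiguous base among the reads covering the site vetoes
   it.
3. **Exactly two allele types** — a third base type at a column is read
   as cross-contamination between paralogous loci and kills the site
   outright, even if the third type is a singleton.
4. **Per-variety support ≥ 2** — each of the two alleles must be carried
   by at least `min_support` (default 2) reads *within a single variety*.
   Singleton observations are treated as sequencing error. The support
   requirement is enforced per allele; the two alleles may draw support
   from different varieties. Reads with the sentinel variety `unknown`
   contribute observations (and can veto via filters 2, 3, 5) but cannot
   supply support, because support is defined per named variety.
5. **Within-variety monomorphism** — every variety covering the site must
   be internally uniform. Heterozygosity is deliberately not modelled:
   for marker development a site that is not fixed within a variety is
   not usable, and within-variety disagreement at EST coverage depths is
   more often error than heterozygosity.
6. **Flanking-window cleanliness** — fewer than `max_flank_polys`
   (default 3) *discontinuous* other polymorphic columns within
   `window_halfwidth` (default 5) columns of the site. "Polymorphic"
   here is any column with ≥ 2 symbol types among covering reads, gaps
   and N included; runs of adjacent polymorphic columns collapse to one
   cluster, and a run interrupted by the candidate column itself counts
   as two. Dense local polymorphism marks a low-quality alignment region.

InDels are maximal runs of columns where gap and base symbols co-occur,
subject to the same support/monomorphism/no-N filters applied run-wise,
with run length capped at `max_indel_len` (default 3 bp, matching the
observed 1–3 bp length range of transcribed-region InDels). A column
containing any gap is never evaluated as a SNP, so one event cannot be
reported under both classes. All based reads across a run must agree on
the spanned bases — a run that also varies in its base form has more than
two alleles and is dropped.

Degenerate inputs: contigs with < 2 reads return empty call lists;
columns covered by no read are skipped; ties in consensus rendering for
ACE output break by symbol-count then alphabet, making serialization
deterministic.

## Coordinates, anchoring and effects

Internally all columns and offsets are 0-based half-open; everything
serialized (VCF, GFF3, reports) is 1-based inclusive. Anchoring walks
the reference member's ungapped bases along its gene model's spliced
exon structure, strand-aware; the member may itself have been placed
reverse-complemented by the assembler, in which case contig symbols are
complemented en route to the coding strand. Columns where the reference
member is gapped (insertions relative to the genome) are unanchored and
are represented in VCF, when kept, by left-anchoring to the nearest
mapped column.

Region classification (CDS / 5′-UTR / 3′-UTR / intron / intergenic) uses
explicit UTR features when the GFF3 provides them and otherwise derives
the UTR side from the position relative to the CDS and the strand. A SNP
under overlapping gene models yields one annotation per model, flagged
`multi_gene`; no tie-break is imposed because emitting all is lossless.

Codon effects use the standard nuclear genetic code. The reference
allele is the one matching the genome base; if neither matches, the
lexicographically smaller allele is chosen for determinism. Effects are
`synonymous`, `nonsynonymous`, `premature_stop` (coding codon → stop)
and `read_through` (stop codon → coding codon); the last two are special
cases of nonsynonymous change and are counted as nonsynonymous in the
nonsynonymous-fraction statistic. A CDS whose length is not divisible by
3 is annotated on its in-frame prefix with a warning flag rather than
rejected.

GO-term transfer takes tabular protein-alignment hits and keeps, per
query gene, the single best hit (lowest E-value, ties by higher coverage
then subject id) with coverage > 70% of the *subject* protein length and
E-value < 1e-5. Coverage is normalized by the subject because the
transfer direction is from the annotated proteome to the query gene set;
the opposite normalization is not implemented.

## Summary statistics

* **Ts/Tv spectrum** — SNPs are tallied by unordered allele pair
  (C/T, G/A, A/C, A/T, C/G, T/G); transitions are C/T + G/A. The ratio is
  reported to 2 decimals; an all-transition input reports a
  transversions=0 sentinel instead of a ratio.
* **Codon positions and nonsynonymous fraction** — counts at codon
  positions 1–3 plus nonsyn/(nonsyn+syn) as a percentage, 1 decimal.
* **Per-family nonsyn:syn ratios** — families (e.g. protein-domain
  labels, supplied externally) with fewer than 30 classified SNPs are
  excluded; a family with zero synonymous SNPs keeps its row with a NaN
  sentinel.
* **Pairwise variety ratios** — for a pair of varieties, the fraction of
  genes, among those containing at least one SNP at which *both*
  varieties have observed alleles, where the two varieties differ at
  some SNP. This co-covered-polymorphic-genes denominator is an
  interpretation fixed in code; it guarantees ratios in [0, 1].
  Varieties with little sequencing should be excluded upstream by the
  caller of the matrix function.
* **Chi-square with adjusted standardized residuals** — for an r×c table,
  E_ij = n_i·n_j/N and d_ij = (O_ij − E_ij)/√(E_ij(1 − n_i/N)(1 − n_j/N)).
  Under independence d_ij is approximately standard normal; per-cell
  flags use |d| > 1.96 (α = 0.05) and |d| > 2.575 (α = 0.01). The 2.575
  cutoff is kept as configured rather than silently replaced by the
  conventional 2.576. The group-comparison wrapper reports per-term
  flags only when the global chi-square passes α = 0.05 and applies no
  multiple-testing correction by default (an optional Bonferroni switch
  adjusts both cutoffs). Zero margins raise, naming the empty
  row/column.

## Primer design

Primer pairs flank each anchored site under hard constraints: primer
length 18–25 bp, product 150–200 bp, GC 45–65% per primer, Tm 58–72 °C
per primer, pair Tm difference ≤ 5 °C, and ≥ `min_flank` (default 10)
bases between each primer's 3′ end and the site. The 10 bp flank default
is this package's choice — marker assays need clean sequence next to the
variant, and no published value was available to adopt. Product-size
bounds include the primers; GC/Tm bounds apply per primer. Windows
containing ambiguous or soft-masked bases are disqualified individually,
not the whole template.

Melting temperatures are nearest-neighbor: unified dinucleotide ΔH/ΔS
(Allawi & SantaLucia 1997) with terminal A/T vs G/C initiation terms,
the SantaLucia 1998 entropic salt correction 0.368·(N−1)·ln[mon⁺], and
Tm = 1000·ΔH/(ΔS + R·ln(C_T/4)) − 273.15 at 50 mM monovalent cation and
50 nM total strand concentration (non-self-complementary assumption).
The same parameter set is available in Biopython, which the test suite
uses as an independent oracle.

Among valid pairs the ranking is: smallest pair Tm difference, then
product length closest to 175 bp (the product-range midpoint), then
leftmost placement, then shortest product. This ordering is a design
choice of this package — any deterministic preference would do, and Tm
balance matters most for PCR multiplexing. Boulder-IO records
(tag=value, records closed by `=`) can be emitted for cross-checking
with external primer tools.

## Synthetic-data generator

`polymine.simulate` builds the whole test substrate: scaffolds of random
sequence; genes with 50–90 bp UTRs, 80–140 codon CDSs (ATG start, no
internal stops, one terminal stop), canonical GT..AG introns, and
alternating strands; and per-gene contig alignments containing the
reference transcript (variety AM560-2, one copy) plus full-length
transcript copies per variety at configured depth (default: six
varieties at depth 3, one at depth 1, plus an `unknown` class at
depth 2 — depth 3 being a typical per-variety EST coverage for
well-sampled varieties, and the depth-1 and unknown classes exercising
the support rule's edge cases).

Planted events per gene (defaults): 3 detectable SNPs (carriers a random
proper subset of the depth-≥2 varieties), 1 SNP carried only by the
depth-1 variety (undetectable by construction), 1 three-allele site
emulating paralog cross-contamination (vetoed by the two-allele filter),
and 1 deletion of 1–3 bp with lengths drawn 612:42:20 — the empirical
length distribution of transcribed-region InDels. Events are spaced
≥ 13 columns apart so the flanking-window filter cannot couple them.
Sequencing errors and N bases are injected per read at configured rates,
with columns never reused within a variety, so artifacts are guaranteed
singletons — the exact class the support criterion exists to reject.
A configurable fraction of contigs is stored reverse-complemented
relative to the transcript to exercise orientation handling end to end.

Every event carries a detectability flag decidable from the config
alone, which is what makes exact recall/precision assertions possible.

What the generator does *not* emulate — and hence what passing recovery
tests do not establish about real EST data: reads are full-length
transcript copies, not length- and quality-variable fragments, so
partial-coverage support loss never occurs; insertions relative to the
reference genome are not planted (only deletions), keeping alignment
columns in bijection with transcript positions; errors are independent
substitutions, not chromatogram-correlated miscalls; there are no
chimeric reads, no paralog families, and no assembler mistakes — the
alignment is correct by construction. Real pipelines inherit the
assembler's errors; this package treats the alignment as given.

## Problem sizes

The bundled end-to-end runs use 2–3 scaffolds × 3 genes (≈ 18–54 planted
events per cohort), 200 random alignments of up to 50 reads × 500
columns for caller–oracle equivalence, 10,000 multinomial tables for
residual calibration, and 1 kb templates for primer enumeration. These
sizes were chosen so the complete verification cycle runs in minutes on
one core while every code path (strands, orientations, InDel lengths,
undetectable plants, contamination sites) is still exercised.

## Known limitations

* Diploid heterozygosity, genotype likelihoods and multi-allelic sites
  are out of scope by design; the within-variety monomorphism filter
  discards heterozygous sites deliberately.
* Base qualities (ACE QA/BQ) are parsed but ignored; the filters are
  sequence-level.
* The window filter's "discontinuous cluster" reading and the per-allele
  support reading are documented interpretations; both are configurable.
* GO analysis consumes a term map; it does not propagate the GO DAG or
  build slims.
* Primer design does no secondary-structure or genome-wide specificity
  screening.
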