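# Methods

This note documents the models, defaults and numerical choices behind
`psvkit`, and what its synthetic-data tests do and do not demonstrate.

## Paralog alignment and diagnostic positions

Gene and pseudogene segments are aligned globally with affine gaps
(Biopython's `PairwiseAligner`). Defaults: match +1, mismatch −2, gap open
−6, gap extend −1, where a gap of length L costs `open + L·extend`. The
penalties are chosen for recently diverged paralogs (~85–97% identity): a
mismatch is much cheaper than any gap pair, so point substitutions stay
aligned as substitutions rather than being split around spurious gaps —
which is what makes the substitution columns directly usable as paralogous
sequence variants (PSVs). Sequences that are more than 50% N are refused.
Alignments are deterministic for fixed parameters (the aligner's canonical
traceback is used).

Windowed identity is measured in *alignment columns* around the column
holding the focal variant (a 60-column flank gives 121 columns when
gap-free); with gaps the genomic span may exceed the column count. Regional
identity is `100 · matches / columns` with gap columns counted as
non-matches; this matches the usual matches-over-alignment-length
definition of percent identity for gap-free regions. BLAST itself is not
re-implemented.

In-silico PCR requires the three 3′-terminal bases of each primer to match
exactly and allows up to 2 mismatches elsewhere per primer (a standard
specificity heuristic); primers must be ≥ 15 nt. Product size is measured
outer-edge to outer-edge, inclusive of both primer footprints. A primer
pair is flagged non-specific on a gene/pseudogene pair when it yields a
product on both sequences.

## Read-origin classification and variant adjudication

At each PSV a read covers, its base votes *gene* (equals the gene base),
*pseudogene* (equals the pseudogene base) or abstains (anything else —
sequencing error or a third allele). Abstaining sites still count as
informative coverage, but never against either origin. A read is labelled
by strict majority provided it covers at least `min_informative = 2` PSVs;
ties are ambiguous. Single-PSV calls are too fragile to one sequencing
error, so a threshold of 2 replaces the visual inspection a human analyst
would perform in a genome browser.

Variant adjudication distinguishes two locus configurations:

1. **Pseudogene homolog ≠ alt.** Mis-mapped pseudogene reads deposit the
   pseudogene (= reference) base, so alt reads cannot be bleed-through.
   Verdict *gene_derived* when ≥ `min_alt_reads = 5` alt reads exist and
   the alt fraction among gene-labelled reads lies in the heterozygous
   band [0.2, 0.8] (the standard germline-het expectation).
2. **Pseudogene homolog = alt.** Mis-mapped pseudogene reads mimic the
   variant exactly. Verdict *gene_derived_confirmed* only when ≥ 5
   gene-labelled reads carry the alt allele; otherwise
   *pseudogene_artefact_possible*.

The variant site itself is excluded from PSV voting: in configuration 2 an
alt-carrying gene read would otherwise cast a pseudogene vote at its own
variant position. Depth below `min_depth = 20` yields *indeterminate* with
a reason, never an exception. The defaults are trivially met by ~30×
whole-genome short reads and by deep amplicon data; they are not calibrated
to any particular study's observed depths.

## Allele-split haplotyping and founder analysis

Long amplicon reads are partitioned by the base at the anchor variant
(third alleles and non-covering reads are left unassigned); partitions can
be down-sampled to a depth cap with a seeded generator for reproducibility.
Consensus calling at a site requires depth ≥ 20 and a modal-base fraction
≥ 0.8; exact ties are no-calls. Haplotype sites are discovered from the
data — positions where the two allele partitions have confidently different
consensus bases — rather than taken from a fixed panel; PSV positions can
be excluded so paralog differences are never mistaken for haplotype SNPs.

Carriers are founder-consistent when every pair of variant-anchored
haplotypes agrees at every jointly-called site *and* each differs from its
own sample's non-variant background haplotype at ≥ 1 site (ruling out the
degenerate case of no informative sites at all). With zero jointly-called
sites the report flags founder status as undefined rather than guessing.
The package reports concordance; whether a given concordance suffices to
declare a population founder allele is left to the analyst, since
short-read genotypes of additional carriers cannot be phased from the
amplicon. Meiotic distance between relatives is the sum of generation
counts down both sides of the pedigree path through the common ancestor.

## Locus filtering

Linked-locus triage keeps variants inside the region, heterozygous in every
named affected individual, and with MAF strictly below 0.001. A missing MAF
is treated as absence from population databases — evidence of rarity — and
kept. Indels are triaged separately because microsatellite slippage
produces abundant artefactual indel calls: an indel is excluded when it
lies inside a perfect tandem repeat of unit length 1–6 with ≥ 3 copies and
tract ≥ 8 bases (a common short-tandem-repeat convention). Every exclusion
is logged with the rule that removed it.

Score classification labels a variant *deleterious* iff CADD > 15, or
SpliceAI > 0.4, or both FATHMM-MKL scores (coding and non-coding) > 0.5;
missing scores never satisfy a clause. ReMM has no published cut-off
matching its service's labels, so it is reported but not thresholded.

## Enrichment statistics

Fisher's exact test is computed from hypergeometric point probabilities
evaluated in log space via log-gamma — naive factorials overflow at
population-database margins (~10⁶ alleles). One-sided p is the upper tail
P(a ≥ observed); two-sided p sums point probabilities ≤ the observed
table's, admitting ties within relative tolerance 1e-7 (the conventional
definition). The test is applied to allele-level tables (2N alleles per N
diploid probands) because population databases report allele counts.

Printed-style frequencies use round-half-even at 2 significant figures.
The carrier-versus-prevalence check compares the expected affected-carrier
frequency of a dominant allele, `2q(1−q)·penetrance`, against the disease
prevalence, flagging incompatibility with a fully penetrant dominant cause
when carriers would outnumber all affected individuals.

## ACMG evidence combination

Evidence items carry a default strength from their code family (PVS very
strong, PS strong, PM moderate, PP supporting; BA stand-alone, BS strong
benign, BP supporting benign) and may be re-weighted within their
direction, as clinical interpretation platforms allow. Combination follows
the published rule table; when both a pathogenic and a benign rule fire the
result is uncertain significance. One addition: two very-strong items are
classified pathogenic. The original combining table leaves that
combination unclassifiable, which breaks the natural monotonicity of
upgrading an item's strength (strong → very strong could demote a
pathogenic call to uncertain); the addition is consistent with later
sequence-variant-interpretation guidance.

## Synthetic-data generator

The generator emulates the structure of a gene/pseudogene locus, not any
real sequence. Defaults are the study conditions the package targets: a
10 kb gene, 87.5% gene–pseudogene identity (substitution-only divergence,
so the planted PSV count is exactly `round((1−identity)·L)` and fully
deterministic), 150 bp short reads at 30× per locus, a 9 kb amplicon read
end-to-end, 1% uniform substitution error, four carriers sharing a
12-SNP founder haplotype with six private background SNPs each.

Two variant configurations can be planted heterozygously on one gene
haplotype: one at a site where the pseudogene matches the gene reference
(bleed-through cannot mimic the alt), and one at a PSV site with the alt
equal to the pseudogene base (bleed-through mimics the alt exactly — the
artefact-prone case). Pseudogene reads are emitted at their source
coordinates *on the gene coordinate system*, modelling mis-mapping directly
instead of simulating an aligner; this isolates the adjudication logic
from aligner behaviour, which is exactly the failure mode under test.

What the generator does **not** emulate: indel divergence between the
copies (optional alignment stress is out of scope by default to keep PSV
counts deterministic), quality scores, coverage waviness, GC bias,
platform-specific error profiles (in particular nanopore indel errors —
long reads reuse the uniform substitution model), chimeric/PCR-duplicate
reads, and copy-number variation. Passing the recovery tests therefore
demonstrates the correctness of the inference logic under controlled
mis-mapping, not robustness to every artefact of real instruments.

## Problem sizes and determinism

All randomness flows through seeded NumPy generators; identical
configurations produce byte-identical outputs (including SAM text). The
test suite and the acceptance script use: 200 random reference pairs for
PSV recovery; 10,000 labelled reads for origin-accuracy estimates; 20
seeded replicates per locus configuration for verdict recovery (the full
10 kb / 30× conditions); 20 replicates of 4-carrier founder cohorts at
200 reads per allele over the 9 kb amplicon (deep amplicon data carries no
extra information for a consensus caller beyond a few hundred reads, so
the replicate count is spent on seeds rather than depth); and 300 random
tables with N ≤ 60 for exact-enumeration cross-checks of the Fisher test,
which is also validated against an exact-rational binomial-coefficient
oracle and an independent statistics library.

## Known limitations

- The aligner reports one optimal alignment; for pathological low-identity
  inputs PSV coordinates may depend on tie-breaking among co-optimal
  alignments (not an issue at paralog-scale identity).
- Read-origin voting assumes the PSV list is correct; PSVs inside
  polymorphic sites of the gene itself would miscount votes.
- Founder consistency is a yes/no identity test over jointly-called sites;
  it does not estimate allele age or detect recombination within the
  amplicon.
- The microsatellite detector requires *perfect* tandem repeats;
  interrupted repeats are not flagged.
- The ACMG engine combines evidence; it does not decide which evidence
  codes apply (except PS4 from a computed enrichment p-value).
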