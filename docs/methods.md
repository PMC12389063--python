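# Methods

## Biological model

Higher-plant genomes carry hundreds of tandem nrDNA repeat units (18S–
ITS1–5.8S–ITS2–26S).  Concerted evolution homogenises the copies, but the
homogenisation is incomplete in *Morus*: deep short-read coverage of the
unit reveals sites where an accession's copies carry the reference base,
the alternative base, or both.  The package models one nrDNA unit as a
5814 bp linear coordinate system (18S 1..1808, ITS1 1809..2023, 5.8S
2024..2186, ITS2 2187..2419, 26S 2420..5814; ITS span 611 bp) and each
variant call as a biallelic (position, ref, alt) locus with a per-accession
zygosity observation:

- homogeneous — only the alternative allele observed (alt/alt);
- heterogeneous — reference and alternative co-occur (ref/alt);
- absent — reference only (not a variant of that accession).

At species level a locus is labelled heterogeneous when it is
heterogeneous in at least one member accession, otherwise homogeneous.
This aggregation rule is a genuine design choice (per-accession labels are
not themselves species labels); it is what lets a locus that is fixed
(alt/alt) in one sub-lineage and mixed in another still register the
intra-individual polymorphism that motivates the analysis.

## Variant filtering

Hard filters follow the standard GATK expressions.  SNPs fail on
QD < 2.0, MQ < 40.0, FS > 60.0, SOR > 3.0, QUAL < 30.0, MQRankSum < −12.5
or ReadPosRankSum < −8.0; InDels use the same expressions with the
strand-bias bounds relaxed to FS > 200.0 and SOR > 10.0.  Missing
annotations never trigger their criterion (the caller convention of
skipping unevaluable expressions).  Filter evaluation is monotone: making
any single annotation worse can only move a record toward failing, a
property the test suite checks by perturbation.  Multi-allelic records are
decomposed into biallelic ref/alt pairs before classification; InDels are
assigned to the region containing their leftmost (anchor) position.

## Haplotype coding and collapsing

The cohort SNP panel is the union of all filtered SNP loci, sorted by
position (158 loci for the packaged cohort).  Each accession maps to a
string over that panel: ref base when absent, alt base when homogeneous,
two-base IUPAC code (R, Y, K, M, S, W) when heterogeneous.  Strings are
deduplicated by exact match — no mismatch tolerance, no realignment (the
panel is positional).  Groups are ordered by size, ties by first
occurrence, making the collapse deterministic and idempotent.

## Neighbor joining and species clusters

Distances between haplotype strings are ambiguity-aware p-distances: a
column counts 1 only when the two IUPAC base sets are disjoint, so R vs A
is 0 and R vs C is 1.  This metric deliberately treats a heterogeneous
observation as compatible with either allele; it satisfies symmetry and
identity but not the triangle inequality, which NJ does not require.
The NJ implementation is the standard Saitou–Nei agglomeration with the
Studier–Keppler Q-criterion, first-minimum tie-breaking (deterministic for
a fixed input order) and exact recovery of additive matrices (verified
against randomly generated 5–8 leaf trees and cross-checked against an
independent NJ implementation).  Negative branch lengths, which arise only
on non-additive inputs, are clamped to zero with the deficit transferred
to the sibling branch.  Species clusters are counted on the
midpoint-rooted tree as maximal clades whose leaves share one species
label; the clusters partition the leaf set.  A distance-based tree is a
deliberate desk-scale choice: the quantity of interest here is clade
composition, not branch support, so likelihood inference and bootstrap
resampling are out of scope.

## Insertion read counting

The 13 bp (`CGTGCGCAATGCG`) or 16 bp (`CGACGTACACAATGCG`) ITS1 insertion
after position 1862 is detected directly in reads by fixed flank
patterns: `TCGAAACC.+AATGCGCCCCAACCCC` (insertion, plus strand),
`GGGGTTGGGGCGCATT.+GGTTTCGA` (insertion, reverse orientation), and the
flank-only pair `TCGAAACC.+CCCCAACCCC` / `GGGGTTGGGG.+GGTTTCGA` for the
reference allele.  Both insertion alleles end in `AATGCG`, so one
insertion pattern serves both.  Every insertion-matching read also
matches the looser reference pattern; classification therefore tests the
insertion patterns first.  An accession is called `mixed` when both
classes reach `min_reads` supporting reads (default 1 — a single read per
allele is evidence at the locus, and the threshold is configurable),
`ins_only`/`ref_only` when one side does, `nocall` otherwise.  Reads are
taken as given: no deduplication, no base-quality weighting, no
requirement that flanks anchor at read ends.

## In-silico ITS-CAPS

The assay amplifies the ITS plus 41 bp of 18S and 37 bp of 26S with the
mulberry ITS primer pair, then digests with BstEII (GGTNACC, cutting
after the first base) and MstI (TGCGCA, blunt, cutting after the third).
Both recognition motifs are palindromic under IUPAC complement, so
plus-strand scanning finds every double-strand cut.  Primer matching is
exact by default (`max_mismatch` configurable); the amplicon must be
unique.  Fragment lengths are the gaps between consecutive cut positions
and always sum to the amplicon length.

The classifier keys only on gel-robust bands, with a ±5 bp default
tolerance (length differences below that are not separable on a 1.5 %
agarose gel): a single band equal to the amplicon for both enzymes →
*M. notabilis*; a ~449 bp BstEII band without a ~602–604 bp MstI band →
*M. alba*; the converse → the nigra group (*M. nigra*, *M. serrata*,
*M. celtidifolia*, *M. rubra*); both → an accession heterozygous for the
13 bp insertion, digested as the union of both allele templates (the
mixed-lane pattern).  The small 91/100 bp fragments are often too faint
to score and are never used as evidence.

## The synthetic study generator

The generator produces the full study from one seed.  Design constraints,
all audited at build time:

- **Reference geometry.**  The amplicon spans nrDNA 1768–2456 (689 bp).
  Fixed segments stamped into the reference: the forward primer at
  1768–1788, the read-pattern flank `TCGAAACC` at 1847–1854, `GGTAA` at
  1858–1862 which together with the downstream flank `CCCCAACCCC`
  (1863–1872) forms the first BstEII site (cut after amplicon position
  91), a second BstEII site `GGTCACC` at 2307–2313 (cut after amplicon
  position 540), and the reverse-primer binding site at 2439–2456.  The
  insertion point (after 1862) interrupts the first BstEII site, which is
  how the insertion allele loses the 91 bp cut; the 13 bp insertion
  carries the assay's only MstI site, the 16 bp insertion carries none.
- **Background.**  Everything else is uniform-random over ACGT with
  bounded repair: any unintended occurrence of a primer, enzyme motif or
  read-flank literal — in the reference or under any single planned
  allele substitution — is mutated away.  Variable positions are kept at
  least 7 bp apart so no 7 bp motif window spans two edits; the final
  audit re-runs PCR and digestion on every species template and fails
  generation rather than emit an inconsistent study.
- **Species profiles.**  158 SNP loci in three shared pools (20 in 18S,
  66 in ITS, 72 in 26S); each species draws a fixed subset (M. notabilis
  77, M. rubra 47, M. serrata 44, M. nigra 43, M. celtidifolia 42,
  M. alba 23) with fixed heterogeneous subsets, and 15 InDel loci
  (anchored small insertions/deletions plus the two-allele position-1862
  locus) whose per-species nets give the amplicon lengths 689/702/703/
  703/704/702/709.  One *M. notabilis*-private SNP sits inside the second
  BstEII site (position 2311, the invariant A of GGTNACC) and disables
  it, leaving that species' amplicon uncut; the same species' InDel set
  stretches its ITS to 631 bp, versus 611 bp in *M. alba*.
- **Cohort.**  31 distinct haplotypes: nine repeated groups of sizes
  457, 21, 13, 13, 6, 4, 2, 2, 2 (seven in the *M. alba* clade, the
  13-accession and 2-accession groups of the *M. notabilis* clade) plus
  22 singletons (9 alba-clade, 1 notabilis, 5 celtidifolia, 3 nigra,
  3 rubra, 1 serrata).  Wild-species singletons share their species
  locus set and differ in per-accession zygosity patterns.  One
  *M. rubra* and one *M. serrata* accession are placed inside the
  457-member reference-identical group, mirroring accessions whose nrDNA
  is indistinguishable from *M. alba*.  Fine species labels (16 names)
  and six-clade taxon labels are both emitted; tallies and clustering
  use the taxon.
- **Reads.**  Insertion-locus reads are windows of the appropriate allele
  template guaranteed to contain the diagnostic span, half reverse
  complemented.  Defaults: 60 reads of 150 bp per accession.  539
  accessions are mixed and three (the *M. nigra* accessions — an
  arbitrary but fixed choice, since the census only constrains the
  count) are pure-insertion.  Allele fractions in mixed accessions are
  an even split, not a model of copy-number ratios.

Determinism: one `numpy` Generator seeded from (seed, attempt) drives
background sampling and repair; read simulation derives per-accession
subseeds.  Identical seeds give byte-identical FASTA/VCF/FASTQ output.

### What the generator does and does not emulate

It emulates the *structure* of the study — locus counts per region and
zygosity class, haplotype-group multiplicities, assay fragment lengths,
read-level allele mixtures — not its sequence content: the background is
random, SNP positions are evenly spaced pool slots rather than real
coordinates, there is no sequencing error, no coverage variation, no
quality modelling, and the species-sharing structure of loci is a
constructed overlap, not an inference.  Tests passing on this cohort
therefore demonstrate that the pipeline's operations are correct and
internally consistent at study scale; they say nothing about variant
calling from real alignments, which is upstream of this package's scope
(alignment, duplicate marking and the caller itself are external tools).

## Numerical and interface choices

- Coordinates are 1-based inclusive throughout the API; BED export is
  0-based half-open.  Seeds are reduced modulo 2^31.
- VCF is read through cyvcf2; the cohort writer emits minimal well-formed
  VCF 4.2 text (multi-allelic rows merged per position) that round-trips
  through the reader.
- Trees are scikit-bio `TreeNode`s (newick IO, midpoint rooting); the NJ
  agglomeration itself is implemented here for deterministic tie-breaking
  and the clamp-and-transfer treatment of negative branches.
- Degenerate-motif scanning uses an overlap-tolerant compiled regex; the
  test suite checks it against a brute-force windowed scan.
- Problem sizes used in tests and in `scripts/acceptance.py` — 542
  accessions, 60× read depth, 1000 random 2 kb digestion sequences,
  5–8 taxon tree-recovery trials — keep the whole suite in seconds while
  exercising every cohort-scale property.

## Known limitations

- The banding classifier assumes the two-enzyme assay as packaged;
  additional enzymes or partial digestion are not modelled.
- `species_clusters` labels each haplotype leaf with one species; cohorts
  where a haplotype is genuinely shared across species must resolve the
  label (the pipeline uses majority membership) before counting.
- The p-distance treats any base-set overlap as identity, so a fully
  heterozygous haplotype is distance 0 from its homozygous parents;
  cluster separation relies on homogeneous between-species differences,
  which is the regime the cohort is in.
- The insertion counter trusts its flank patterns; reads with errors
  inside a flank are `neither` and simply do not count.
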