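# Methods

`minkmap` implements the computational core of a pedigree-free recessive
gene-mapping study: given multi-sample genotype calls for a handful of
affected and unaffected animals, find genes whose genotype pattern
segregates with a recessive Mendelian trait, predict the coding
consequences of the surviving variants, and resolve the cis/trans
configuration of compound-heterozygous candidates. A synthetic-cohort
generator reproduces the statistical structure of such a study so the whole
chain can be exercised and tested without the (non-redistributable) animal
genomes.

## The discovery model

A recessive trait requires two mutant alleles of the causal gene in every
affected individual. The filter therefore selects genes `G` such that

* **(A)** every case is homozygous for the alternate allele at some variant
  in `G`, or heterozygous at two or more variants of `G` (a putative
  compound heterozygote), each such genotype supported by read depth
  `DP > 2` (i.e. at least 3 reads); and
* **(B)** no control is homozygous-alternate at any of the variants
  implicated by the cases, nor heterozygous at two or more of them.

Two deliberate asymmetries:

* **Exclusion needs affirmative evidence.** A control genotype only rules a
  gene out when it is called and depth-passing. Missing or shallow control
  calls are common at 5–8× coverage; treating them as exculpatory would
  randomly rescue genes, treating them as damning would randomly kill them.
  A consequence worth knowing: the candidate set is *not* monotone in the
  depth threshold — raising it can silence a control's excluding genotype.
  The monotone quantity, which the property tests pin down, is the per-case
  supporting evidence.
* **Compound heterozygosity is unphased at discovery.** Any two
  heterozygous variants in a gene qualify; two variants on the same
  chromosome copy (cis) leave one intact allele and cannot cause a
  recessive phenotype, but short-read genotype calls cannot distinguish the
  configurations. Phase is resolved afterwards (below); the filter's job is
  only not to lose candidates.

Gene membership of a variant is positional: anywhere within the union span
of the gene's transcripts, introns included, since the filter runs before
annotation and splice-disrupting intronic variants would otherwise be
silently dropped.

`require_called_in_all_cases` (default on) demands that every case carry
supporting genotypes. The relaxed mode exists for cohorts where only a
subset of cases was sequenced deeply: a case without supporting evidence is
skipped unless it has a usable (called, depth-passing) genotype at one of
the variants implicated by the other cases — being callable at a candidate
site and failing to fit the model still refutes the gene. At mean depth 1
the relaxed mode recovers the planted gene in strictly more simulated
cohorts than the strict mode (tested over 50 seeds).

## Coding-consequence engine

The annotator is self-contained: HGVS `c.` parsing/formatting, strand-aware
projection of VCF-style variants through the exon structure into CDS
coordinates, and frameshift translation.

* **Coordinates.** Genomic intervals are 0-based half-open internally;
  VCF/GFF3 convert at the boundary; CDS and protein positions are 1-based.
* **Normalization.** The shared VCF anchor base is stripped (suffix then
  prefix trimming); minus-strand alleles are reverse-complemented; indels
  are then 3'-shifted within the CDS to the most-3' equivalent position, as
  HGVS requires — note VCF left-aligns, so the same edit has different
  canonical homes in the two coordinate systems, and both the genomic
  variant and the CDS edit are kept on the record. An insertion whose
  sequence equals the immediately preceding CDS segment after shifting is a
  duplication.
* **Translation.** The edit is applied to the CDS string and the mutant is
  translated from the original start codon with the standard table,
  scanning codon-by-codon for the first stop. A frameshift (net indel
  length not a multiple of 3) that reads through the reference stop
  continues into the supplied 3' UTR; running out of sequence yields the
  explicit `no_stop_found` outcome. Destroying the ATG short-circuits to
  `start_loss` with no downstream arithmetic. The parser accepts the
  hyphenated range dialect (`c.574-589del`) seen in print but always emits
  the standard underscore form; intron-offset positions are out of dialect
  and rejected rather than misparsed.
* **Impact tiers.** frameshift / stop gain / stop loss / start loss /
  splice region / no-stop-found → HIGH; missense and in-frame indels →
  MODERATE; synonymous → LOW; non-coding → MODIFIER. `first_affected_codon`
  reports the codon of the first edited nucleotide even when that residue
  happens to be preserved, matching how frameshift positions are
  conventionally quoted.

The engine is verified against an independent brute-force translator (its
own codon table, its own edit splicing, its own stop scan) on 500 random
CDS × edit combinations, and for strand symmetry on mirrored plus/minus
fixtures.

### The surrogate transcript

The committed 636-nt surrogate CDS (633 coding nt + TAA; 211 residues,
stop at codon 212) stands in for the real RAB38 transcript, which is not
redistributable here; it is synthetic and engineered so the two published
mutations reproduce the published arithmetic chain exactly:

* `c.574_589del` (16 nt): frameshift at codon 192, loss of the reference
  stop at codon 212, first mutant-frame stop at codon 277 in former 3'-UTR
  territory — a 276-residue product, 30.8 % longer than wild type;
* `c.20_21dupCT` (2 nt): frameshift at codon 8, premature stop at codon 15.

Only the positional arithmetic is meaningful; the intervening amino acids
are arbitrary. The packaged gene model embeds this CDS as a minus-strand
three-exon gene (duplication in exon 1, deletion in exon 3, exon 1 at the
higher genomic coordinate) so that projection, strand handling and UTR
scanning are all exercised on the way to those numbers.

## Phase inference

Models the allele-specific RT-PCR design: a primer whose 3' end sits on one
allele of an anchor variant amplifies only that haplotype, and the amplicon
reveals the partner variant's allele on the same chromosome. An
ALT-anchored amplicon showing REF at the partner site implies trans; a
REF-anchored amplicon's implication flips. The qualitative Sanger readout
is generalized to counted observations: within each (anchor site, anchor
allele) class the majority allele votes, a class whose minority fraction
exceeds `noise_fraction` (default 5 %) makes the call `ambiguous`, as do
disagreeing classes; a call supported by a single anchor class is returned
but flagged low-confidence. Trans therefore requires evidence, not absence
of evidence.

## Synthetic cohorts

`simulate_reference` draws a single contig carrying `n_genes` one- to
three-exon genes on mixed strands, each with a valid CDS (150–300 nt) and a
3' UTR long enough (150–220 nt) for read-through stop scans.
`simulate_cohort` plants two causal mutations in one gene — a 2-nt
duplication early in the CDS and a 16-nt deletion about two-thirds in,
each expressed as an anchored VCF indel — and assigns genotypes:

* cases per `causal_config`: homozygous deletion, homozygous duplication,
  or compound heterozygous (always trans); `mixed_per_case` cycles the
  three mechanisms, so the default two cases mirror the study design of one
  animal homozygous for each mutation;
* controls carry at most one causal allele, at
  `carrier_rate_in_controls = 0.04` (≈ 1 carrier in 27 unaffected animals);
* background SNVs (default 70 over the ~7 kb contig, matching a ~1 variant
  / 100–200 bp density) get genotypes drawn independently of case/control
  status from per-site allele frequencies.

Defaults are the emulated study's conditions: 2 cases vs 6 controls, and
Poisson read depth with mean 11 — the mean coverage of the eight genomes
being emulated (9×/40× cases, three 8× and three 5× controls). Default
`missing_rate` is 0 because independent no-calls are rare at such depths
(a DP of 0–2 already fails the filter); the rate is a dial for stress
tests, and masking provably never alters alleles, only blanks calls.
Background allele frequencies default to a rare spectrum, uniform on
(0.001, 0.01): with only two cases, the unphased compound-het rule fires on
any gene where both cases happen to carry two heterozygous background
variants, so the default spectrum is calibrated so that the planted gene is
by design the expected unique survivor; commoner variation can be dialled
in via `background_af_range` (and then candidate lists legitimately grow,
as they do in real small-cohort studies). Amplicon observations are
simulated for every double-het sample at 200 reads per anchor class with a
1 % allele-dropout/misprime rate, comfortably below the 5 % calling
threshold. `n_cis_decoys` plants genes in which every case is double-het in
cis: these survive the discovery filter and must be rejected by phase
inference, which the pipeline's confirmation step does.

The master seed is split into named substreams (reference, variants,
genotypes, depth, missingness, amplicons), so changing one knob leaves
unrelated draws untouched; identical (params, seed) produce byte-identical
FASTA/GFF3/VCF outputs.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: linkage disequilibrium and haplotype
structure (background genotypes are independent across sites), relatedness
and population stratification within the cohort, sequencing error in the
genotype calls themselves (genotypes are correct unless masked), realistic
site-frequency spectra beyond the uniform band, multi-gene overlapping loci,
and structural variation beyond short indels.

## Genotype table fixture

The packaged genotyping table transcribes the published two-site results
for 35 minks across eight coat-colour phenotypes (the published text
mentions a 31-animal subtotal in one place, but the table's N column and
the animal roster both sum to 35, and the fixture follows the table). Two
published inconsistencies are resolved in the table's favour and noted
here rather than silently patched: the single carrier among the
non-dilute animals is recorded as royal pastel `+/del` (the deletion
allele, although the text says the carrier was heterozygous for the
duplication), and the Moyle rows are `del/del` or double-het (the text
swaps the two mutation names for this group). Genotyped calls carry a
nominal DP of 30 — they represent targeted resequencing confirmations, not
shallow WGS — so the fixture passes depth filtering as the published
genotypes did. With the three brown-dilute phenotypes (Moyle, Lavender,
Violet) as cases, the surrogate gene is the unique filter candidate, the
single `+/del` carrier does not exclude it, and the concordance summary is
8 biallelic cases / 26 wild-type controls / 1 carrier / 0 discordant.

## Numerical and procedural choices

* Depth bound is exclusive (`DP > 2`), read literally from the design it
  reproduces; `passes_depth` treats absent DP as failing.
* Multi-allelic VCF records are decomposed (other ALTs map to REF in each
  biallelic copy), conserving per-sample non-REF allele counts; symbolic
  ALTs are skipped with a warning.
* Candidate output is sorted by gene id, variants by (chrom, pos); all
  tabulations have deterministic row order.
* The genotype-independence sanity property of the generator is tested as a
  Fisher-combined chi-square over 20 seeds at overall α = 0.01.
* Problem sizes in the test suite — exhaustive 4^6 genotype matrices plus
  several hundred random ≤5-sample × ≤8-variant cohorts for the filter
  oracle, 500 random CDS × edit trials for the translator oracle, 20 seeds
  for cohort recovery, 50 for phase — were chosen as the smallest sets that
  exercise every rule branch while keeping the default suite fast.

## Known limitations

* Only diploid, biallelic genotypes; allele indices above 1 are removed by
  decomposition, ploidy ≠ 2 is rejected.
* HGVS support covers plain CDS coordinates only — no intron offsets
  (`c.88+2`), no UTR positions (`c.-14`, `c.*6`), no inversions/repeats.
* One transcript per gene is assumed by the simulator (the filter and
  annotator accept many; candidate annotation reports all).
* The phase model treats reads as independent; systematic mispriming that
  exceeds the noise threshold yields `ambiguous`, never a forced call.
* Genotype-quality (GQ) filtering is not implemented — the reproduced
  design filtered on depth only — and no statistical association or
  kinship machinery is included; with cohorts this small the filter is a
  logical sieve, not a test.

## Appendix: truth.json schema

`simulate` / `run` write the ground truth of each simulated cohort as JSON:

```
{
  "causal_gene_id":  str | null,        # gene carrying the planted pair
  "causal_variants": [str, ...],        # "chrom:pos:REF>ALT" descriptors
  "genotypes":       {sample_id: {variant: [allele_a, allele_b]}},
                                        # pre-masking planted genotypes
  "phase":           {sample_id: {gene_id: "cis" | "trans"}},
                                        # for double-het variant pairs
  "decoy_gene_ids":  [str, ...],
  "decoy_variants":  {gene_id: [str, str]}
}
```
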