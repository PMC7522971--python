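# minkmap

Pedigree-free mapping of recessive Mendelian traits from small case/control
cohorts of genotype calls — built around the study design that identified
loss-of-function *RAB38* mutations behind a dilute brown (Moyle) coat
colour in American mink, and reusable for any analysis with the same shape.

When a recessive phenotype segregates in a handful of sequenced animals,
the causal gene can be found without a pedigree: every affected individual
must carry **two** mutant alleles of it — homozygous (`a/a`) or compound
heterozygous (`a1/a2`, one mutant allele per chromosome copy, *in trans*) —
while no unaffected individual may. `minkmap` implements that discovery
filter and the two analyses that come after it:

* **Segregation filter** — select genes with homozygous or
  compound-heterozygous genotypes (read depth > 2) in all cases that are
  not homozygous or compound-heterozygous in any control. Heterozygous
  carrier controls are fine; exclusion needs affirmative, depth-supported
  evidence.
* **Coding-consequence engine** — project VCF variants through the
  transcript structure into HGVS `c.` coordinates (strand-aware, indels
  3'-shifted), apply the edit to the CDS, translate from the original ATG
  and scan codon-by-codon for the first stop, continuing into the 3' UTR
  when a frameshift reads through the reference stop. For a frameshift at
  codon *c* with new stop at codon *s* it reports `p.{c}fs*{s−c+1}` and an
  impact tier (HIGH/MODERATE/LOW/MODIFIER).
* **Phase inference** — decide cis vs trans for double heterozygotes from
  allele-specific amplicon observations (the RT-PCR design: an
  allele-anchored primer amplifies one haplotype; the amplicon shows which
  partner allele rides with it), with a noise threshold and an explicit
  `ambiguous` outcome.
* **Synthetic cohorts** — a deterministic generator planting a recessive
  causal gene (16-nt deletion + 2-nt duplication) in a random multi-exon
  genome, with configurable case mechanisms, control carrier rates,
  Poisson read depth, missingness, and cis decoy genes; ground truth is
  emitted alongside the VCF.

Standard formats throughout: multi-sample VCF 4.x (pysam), FASTA
(Biopython), GFF3 (gffutils), TSV sample sheets.

## Worked example

The package ships a surrogate RAB38 transcript — a committed 636-nt CDS
(211 codons + stop) engineered to reproduce the published frameshift
arithmetic of the two mink mutations:

```python
from minkmap import parse_hgvs_c, predict_consequence, rab38_surrogate_fixture

cds, utr3, sites = rab38_surrogate_fixture()
for text in ("RAB38:c.574-589del", "RAB38:c.20-21dup"):
    rec = predict_consequence(parse_hgvs_c(text), cds, utr3)
    print(f"{text}: {rec.type} ({rec.impact}), {rec.protein_summary}, "
          f"wt stop {rec.wt_stop_codon_index}, mutant stop {rec.mut_stop_codon_index}, "
          f"protein {rec.wt_protein_len} -> {rec.mut_protein_len} residues")
```

prints

```
RAB38:c.574-589del: frameshift (HIGH), p.192fs*86, wt stop 212, mutant stop 277, protein 211 -> 276 residues
RAB38:c.20-21dup: frameshift (HIGH), p.8fs*8, wt stop 212, mutant stop 15, protein 211 -> 14 residues
```

The 16-nt deletion shifts the frame at protein position 192, reads through
the wild-type stop at codon 212 and terminates only at codon 277 — a ~31 %
longer protein with a rewritten C-terminus; the 2-nt duplication shifts the
frame at position 8 and truncates at codon 15. Both are HIGH-impact losses
of function, which is exactly the genotype–phenotype logic the segregation
filter screens for.

The whole pipeline on a synthetic cohort:

```
minkmap -v run --seed 7 --outdir run7
```

simulates a reference, gene models and an 8-sample cohort (2 cases, 6
controls), writes them as FASTA/GFF3/VCF/TSV, re-reads them, and runs
filter → annotate → phase → report, logging the funnel (variants in,
depth-passing calls, genes tested, candidates out). The report names the
single candidate gene, its mode (homozygous / compound het), the HIGH
impact frameshift annotations of its two variants, any cis/trans calls,
and a genotype table with a recessive-model concordance summary. Each
stage is also available separately (`minkmap simulate / filter / annotate /
phase`); `python -m minkmap.cli --help` or the `minkmap` entry point shows
the options.

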