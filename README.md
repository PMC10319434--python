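# triocascade

Family-based prioritization of recessive variants in trio whole-exome data,
built for the study design where a handful of unrelated families share a
rare Mendelian phenotype (here: primary infertility with oocyte metaphase-I
arrest) and the causal gene is expected to be hit biallelically in every
affected proband.

The package implements the complete filter cascade as a tested, reusable
library plus CLI:

1. **Population frequency** — keep variants with minor allele frequency
   (MAF) < 1% in every reference database scanned (dbSNP, 1000 Genomes,
   EVS, ExAC, gnomAD, supplied as frequency tables); absence from all
   databases counts as a pass.
2. **Functional class** — keep nonsynonymous exonic, splice-site, and
   coding-indel variants (stopgain, missense, frameshift, in-frame indel,
   splicing); drop synonymous/intronic/UTR/intergenic.
3. **Deep-intronic rescue** — re-include a dropped intronic variant when the
   same gene in the same proband carries a surviving rare heterozygous
   loss-of-function allele and the two can sit in trans (this reproduces the
   manual reconsideration that recovers a pathogenic intronic allele such as
   *MAD2L1BP* c.21-94G>A as the partner of a frameshift).
4. **Recessive inheritance on autosomes** — homozygous-alternate proband
   with both parents heterozygous carriers, or a compound heterozygote with
   one allele from each parent (trans-confirmed by trio phasing; ambiguous
   pairs are kept but downranked).
5. **Autozygosity** — in consanguineous families, homozygous candidates
   inside runs of homozygosity (ROH) longer than 2 Mb are prioritized.
6. **Cross-family recurrence and oocyte expression** — intersect candidate
   genes across ≥ `min_families` unrelated families and require expression
   in oocytes (TPM ≥ 1 in at least one maturation stage: GV, MI, MII).

Alongside the cascade, the `gene_model` module performs the coordinate and
consequence arithmetic used to characterize candidates: genomic ↔ coding-DNA
(c.) mapping with HGVS-style intronic offsets, codon index
⌈cds_pos / 3⌉, stopgain/missense/synonymous calls from the CDS, frameshift
read-through to the new stop (`p.X###Yfs*N`), and truncated-tail lengths
(a stop at codon 285 of a 306-residue protein removes the C-terminal 22
residues; at codon 181 it removes 126).

Because patient-level WES data for this design are generally not shareable,
the package ships a deterministic synthetic-cohort simulator
(`synthetic_cohort`) that generates everything a run needs — per-family
multi-sample VCFs with Mendelian trio genotypes, a PED file with a
consanguinity flag, five frequency tables, intron-containing gene models
with CDS sequences, an oocyte expression table, and a truth file — with
planted causal configurations (homozygous nonsense inside an autozygosity
block, homozygous nonsense without one, and a frameshift + deep-intronic
compound heterozygote sharing one causal gene across families).

## Worked example

Simulate a three-family cohort (one scenario per family, shared causal
gene) and run the cascade:

```sh
triocascade simulate --seed 1 --out-dir demo/cohort --n-background 2000
triocascade run --cohort-dir demo/cohort --out-dir demo/out --min-families 3
```

which prints

```
shared candidate genes (expressed): ['GENE0012']
top candidate: GENE0012 (F1, hom_recessive, trans_confirmed)
```

`demo/out/report.trace.tsv` holds the per-family stage counts (surviving
variants down the cascade; F1 is the consanguineous family):

```
family_id  stage                        surviving
F1         total_variants               2001
F1         after_maf                    137
F1         after_functional             43
F1         after_inheritance_autosomal  1
F1         homozygous_only              1
F1         in_roh_gt2mb                 1
F1         rescued                      0
```

and `demo/out/report.candidates.tsv` the ranked candidates — the planted
homozygous stopgains in families 1 and 3 and the rescued intronic allele
completing the trans compound heterozygote in family 2:

```
family_id  gene      cdna_change            protein_change      mutation_type                 inheritance_model  phase_status     in_roh  rescued
F1         GENE0012  c.56C>A                p.S19*              stopgain                      hom_recessive      trans_confirmed  1       0
F3         GENE0012  c.770T>A               p.L257*             stopgain                      hom_recessive      trans_confirmed  0       0
F2         GENE0012  c.253-38G>A;c.549delC  -;p.R183Rfs*7       intronic;frameshift_deletion  compound_het       trans_confirmed  0       1
```

One-off consequence annotation and clinical summarization also have
subcommands; summing a per-cycle oocyte outcome table gives per-family
totals and the (artifact-added) MI-arrest fraction:

```
$ triocascade summarize-clinical table1.csv
F1  cycles=3  retrieved=30  gv=1  mi=29  pb1=0  fertilized=0  cleaved=0  mi_arrest_fraction=0.967
F2  cycles=1  retrieved=9   gv=0  mi=9   pb1=0  fertilized=0  cleaved=0  mi_arrest_fraction=1.000
F3  cycles=2  retrieved=5   gv=0  mi=5   pb1=0  fertilized=0  cleaved=0  mi_arrest_fraction=1.000
```

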