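# Methods

## The prioritization model

The cascade assumes a fully penetrant autosomal-recessive architecture: each
affected proband carries two inactivated copies of the causal gene, either
as a homozygous genotype (expected under consanguinity, where the variant
sits in a long autozygous segment) or as a compound heterozygote with one
allele transmitted from each parent. Three consequences of that assumption
shape the stages:

- **Carrier parents.** A homozygous candidate requires every genotyped
  parent to be heterozygous; a hom-ref or hom-alt parent is treated as
  incompatible with the recessive carrier model and rejects the variant
  (de novo and dominant models are out of scope). A missing parental
  genotype relaxes the check and marks the candidate `parents_unverified`.
- **Trans configuration.** A compound-het pair needs its two alleles on
  different parental haplotypes. With both parents genotyped, father-only +
  mother-only origins confirm trans; both-alleles-in-one-parent is cis and
  rejected; anything ambiguous (a parent carrying both alleles, or an
  ungenotyped parent) is retained as `phase_unknown` and ranked below
  confirmed pairs.
- **Strict unaffected relatives.** Only genotyped *unaffected* full
  siblings can veto a homozygous candidate (they must not share the
  homozygous genotype); affected relatives are never used as exclusion
  evidence, because in small families an affected sibling legitimately
  shares the causal genotype.

## Parameters

| Parameter | Default | Units | Role |
|---|---|---|---|
| `maf_threshold` | 0.01 | fraction | strict `<` comparison of the max AF over databases; absence from all databases passes. 0 is allowed and keeps only database-absent variants |
| `splice_window` | 2 | bp | intronic positions within this distance of an exon boundary are class `splicing` (the common exome-annotator convention) |
| `roh_min_length_bp` | 2,000,000 | bp | strictly-greater span threshold for reported ROH segments |
| `roh_min_sites` | 25 | sites | minimum informative sites supporting a segment |
| `roh_het_tolerance` / `roh_window_sites` | 1 / 50 | — | at most `het_tolerance` heterozygous calls per `window_sites`-site trailing window inside a run |
| `roh_max_gap_bp` | 500,000 | bp | maximum physical gap bridged when merging adjacent runs (see below) |
| `tpm_min` | 1.0 | TPM | a gene is "expressed" when any oocyte stage (GV/MI/MII) reaches this |
| `min_families` | 2 | families | recurrence threshold for the shared-gene stage; set to the cohort size for a strict intersection |
| `strict_siblings` | true | — | hom-alt unaffected sibling rejects (strict) or only warns (lenient) |

The frequency rule is deliberately "max over databases < threshold, absence
passes": absence is weaker evidence of commonness than a catalogued
frequency, and documented pathogenic alleles are often absent from every
reference panel. Whether the original analyses used per-database thresholds
or a combined max is not knowable from published summaries; the combined
max is the stricter and simpler reading.

## Coordinate and consequence arithmetic

Genomic coordinates are 1-based inclusive throughout; BED output converts
to 0-based half-open at the writer and nowhere else. Coding positions count
along the coding strand from the A of the start codon. Intronic positions
take HGVS-style offsets: positive past a donor, negative before an
acceptor, anchored at the nearest exonic base (ties go to the donor side).
Indel alleles are canonicalized by shared suffix-then-prefix trimming;
full left-alignment across repeat tracts would additionally require the
flanking reference sequence, which the data model does not carry, so inputs
are expected in (and the simulator emits) left-aligned form.

Consequence precedence: splice-window intronic > coding SNV translation
(stopgain / missense / synonymous) > coding indel length arithmetic
(frameshift iff |Δlen| mod 3 ≠ 0) > UTR > intronic > intergenic. Frameshift
protein naming translates the shifted frame from the first altered codon
until a stop, extending into a 3'UTR read-through sequence when provided;
`p.X###Yfs*N` counts the first altered codon as position 1, and a stop at
position 1 collapses to nonsense-style `p.X###*`. A missing CDS sequence
degrades the call to class-only with a warning rather than failing.

The committed MAD2L1BP transcript fixture is a constrained synthetic
reconstruction, not downloaded annotation: its exon boundaries and CDS are
chosen to satisfy every published anchor (the four genomic↔cDNA coordinate
pairs of the exon-4 variants, a 306-residue protein, c.21 as the first base
of exon 2, arginine codons at 181 and 285, phenylalanine at 173 with
downstream context yielding fs*4 on a 1-bp deletion), and tests verify
those anchors rather than trusting the construction. Sequence between the
constrained codons is filler and carries no biological meaning.

## ROH detection

A deterministic streak/window scan rather than a likelihood (LOD) model: a
run opens at a homozygous call, extends through heterozygous calls while no
trailing window of `window_sites` sites exceeds `het_tolerance` hets, and
closes (trimmed back to its last homozygous site) at the het that would
break the bound. Missing calls are transparent — they neither support nor
interrupt a run. ROH is computed on the full genotyped site set, not the
rare subset, because rare-only sites are far too sparse to define
megabase-scale runs.

Merging adjacent runs needs care at exome site density: a plain
"merge if the gap is under 0.5 Mb" rule would chain-merge across every
het-broken run (the breaking het is almost always closer than 0.5 Mb) and
flag whole chromosomes. The merge therefore additionally requires the
joined run's overall het count to stay within `het_tolerance` per
`window_sites` sites. With `het_tolerance = 0` no merge ever crosses a het,
which makes the scan exactly equivalent to maximal-run brute force — a
property the suite tests on random genotype strings.

The `> 2 Mb` span comparison is strictly greater. All ROH parameters other
than the length threshold are conventional exome settings and remain
configurable.

## The synthetic cohort generator

The generator defines the study conditions under which the cascade is
exercised:

- **Scale.** 20,000 background variants per family by default (desk scale);
  the full-scale check runs 130,000, matching the order of magnitude of a
  real exome callset. Sites live on three synthetic 20-Mb chromosomes
  carrying 120 intron-containing genes (~⅓ on the reverse strand) with
  random non-stop CDS content.
- **Allele-frequency spectrum.** A mixture per site: 93% common
  (AF ~ Uniform(0.01, 0.5)), 5% rare (AF ~ Exponential, mean 0.001,
  truncated below 0.01), 2% absent from every database. Catalogued sites
  appear in gnomAD always and in each other database with probability 0.8,
  with ±15% multiplicative jitter. Under this spectrum the MAF stage
  removes roughly 93% of sites (a ~14× reduction), qualitatively matching
  the order-of-magnitude collapse seen in real cascades.
- **Functional-class mix.** Placement-realized proportions: 25% missense,
  18% synonymous, 2% stopgain, 2% frameshift, 1% in-frame indel, 2%
  splice-region, 20% intronic, 10% UTR, 20% intergenic. Classes are
  realized by construction (e.g. a stopgain is drawn from the gene's
  enumerated nonsense substitutions), so the pipeline's own consequence
  caller is exercised on realistic inputs. Indels are planted on
  forward-strand genes, where the anchor-base arithmetic is unambiguous.
- **Transmission.** Founder alleles i.i.d. Bernoulli(AF); children inherit
  one random allele per parent, so emitted genotypes are Mendelian-clean at
  zero missingness (tested exhaustively). Inside an autozygosity block the
  proband's two alleles are copies of a single founder allele carried by
  both parents — consanguinity by descent, still Mendelian-consistent.
- **Planted scenarios.** Homozygous nonsense inside a 2.5–10 Mb autozygous
  block (consanguineous family), homozygous nonsense without a block, and a
  compound heterozygote: a maternal frameshift plus a paternal deep-intronic
  allele 10–200 bp inside an intron of the causal gene. Planted coding
  alleles are database-absent by construction; the intronic partner is
  catalogued in gnomAD at 111/31250 ≈ 0.36% — rare enough to pass the MAF
  stage, intronic enough to need the rescue.

What the generator does **not** emulate: linkage disequilibrium between
sites, genotyping error beyond uniform missingness, sequencing reads,
multi-nucleotide or clustered variants, population structure. Passing tests
therefore demonstrate the correctness of the cascade's logic under clean
genotypes, not robustness to caller artifacts or LD-driven phasing
shortcuts.

## Pipeline order and the trace

Stages run in fixed order: load → MAF → functional → rescue → autosomal +
inheritance → ROH annotation → per-family gene sets → shared genes →
expression filter → rank → report. The rescue sits between the functional
and inheritance stages so a rescued intronic allele can pair into a
compound heterozygote. The per-family trace
(`total_variants, after_maf, after_functional, after_inheritance_autosomal,
homozygous_only, in_roh_gt2mb`) is nonincreasing by construction; rescued
variants are tallied separately and excluded from the inheritance-stage
count so the monotonicity invariant is never violated by re-inclusion.

Ranking is a deterministic total order: shared-gene membership first, then
homozygous-in-ROH (consanguineous families), homozygous, trans-confirmed
compound het, phase-unknown compound het, with (gene, chromosome, position)
tie-breaks — any permutation of the input yields the same list. Genes
absent from the expression table are dropped, not kept: the expression
criterion demands positive evidence. The MI-arrest fraction in the clinical
summary is derived reporting added by this artifact, not a published
statistic, and is labelled as such.

## Numerical and degenerate-input choices

- Frequency 0 in a database is distinct from absence; report cells render
  absence as `not found`.
- Multi-allelic VCF rows decompose into one record per ALT; a genotype
  allele pointing at a different ALT maps to REF in the decomposed record,
  conserving summed ALT dosage. Half-missing calls contribute their known
  allele to dosage but have zygosity `missing`.
- `maf_threshold = 0` keeps only database-absent variants;
  `roh_min_length_bp = 0` disables the span threshold (the comparison is
  strict).
- An empty candidate list produces a trace-only report; a family absent
  from the clinical table logs a warning rather than failing the run.
- Problem sizes in the test suite are chosen for a desk-scale run: the
  full-exome check uses one 130k-site family, the recovery sweep 20 seeds
  of three 1,500-site families, and the ROH oracle 500 random strings.

## Known limitations

- HGVS support is deliberately "lite": `c.N`, `c.N±offset`, `c.NdelX`,
  `p.X###*`, `p.X###Yfs*N`; no dup/ins/ext/delins naming, no multi-transcript
  aggregation (one canonical transcript per gene).
- X-linked recessive models are excluded by design (the cascade drops
  chrX/chrY), as are statistical phasing and population-haplotype inference.
- The oocyte expression table is user-supplied; no reference database ships
  with the package (tests use the simulator's synthetic table).
- Cross-species coordinate lifting (e.g. mapping a human truncation onto a
  mouse construct) is out of scope.
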