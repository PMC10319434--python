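"""Self-contained synthetic trio-exome cohorts with planted causal alleles.

Everything a cascade run needs — per-family multi-sample VCFs, a PED file,
five population-frequency tables, gene models with CDS sequences, an oocyte
expression table, and a truth file — is generated deterministically from one
seed, on a small synthetic genome (no reference download).

What the generator emulates: exome-scale per-family variant counts with a
configurable allele-frequency spectrum (a common component, a rare tail, and
a fraction absent from every database), a realistic functional-class mix,
clean Mendelian trio transmission, contiguous autozygosity blocks in
consanguineous probands, and the three planted causal configurations the
cascade is designed to recover — a homozygous nonsense allele inside an
autozygosity block, a homozygous nonsense allele without one, and a
compound heterozygote pairing a frameshift with a deep-intronic allele in
trans.  What it does not emulate: linkage disequilibrium, genotyping error
beyond simple missingness, sequencing reads.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .gene_model import (
    GENETIC_CODE,
    NON_STOP_CODONS,
    TranscriptModel,
    codon_index,
    write_gene_models,
)
from .io_formats import (
    ALT,
    DEFAULT_DATABASES,
    MISSING,
    REF,
    Pedigree,
    PedSample,
    VariantRecord,
    genotype_call,
    write_vcf,
)

BASES = ("A", "C", "G", "T")

# Planted scenarios
HOM_NONSENSE_IN_ROH = "HOM_NONSENSE_IN_ROH"
COMPHET_FRAMESHIFT_PLUS_INTRONIC = "COMPHET_FRAMESHIFT_PLUS_INTRONIC"
HOM_NONSENSE = "HOM_NONSENSE"
NONE = "NONE"
SCENARIOS = (HOM_NONSENSE_IN_ROH, COMPHET_FRAMESHIFT_PLUS_INTRONIC, HOM_NONSENSE, NONE)

#: gnomAD frequency given to the planted deep-intronic allele (a catalogued
#: but rare variant: 111 alleles / 31250).
INTRONIC_PARTNER_AF = 111 / 31250


class ConfigError(ValueError):
    """Contradictory simulation configuration."""


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults describe a desk-scale exome: 20,000 background variants per
    family (``full_scale`` runs use 130,000), an AF spectrum that is mostly
    common with a rare tail and a small database-absent fraction, and a
    functional-class mix dominated by missense/synonymous coding changes with
    intronic/UTR/intergenic background.
    """

    n_families: int = 3
    scenarios: tuple[str, ...] = (
        HOM_NONSENSE_IN_ROH,
        COMPHET_FRAMESHIFT_PLUS_INTRONIC,
        HOM_NONSENSE,
    )
    shared_causal_gene: bool = True
    n_background_variants: int = 20_000
    af_fraction_common: float = 0.93
    af_fraction_rare: float = 0.05
    af_fraction_absent: float = 0.02
    rare_af_mean: float = 0.001
    functional_class_mix: dict[str, float] = field(
        default_factory=lambda: {
            "missense": 0.25,
            "synonymous": 0.18,
            "stopgain": 0.02,
            "frameshift_deletion": 0.02,
            "inframe_indel": 0.01,
            "splicing": 0.02,
            "intronic": 0.20,
            "UTR": 0.10,
            "intergenic": 0.20,
        }
    )
    roh_block_length_bp: tuple[int, int] = (2_500_000, 10_000_000)
    genotype_missingness: float = 0.0
    seed: int = 0
    n_genes: int = 120
    chromosomes: dict[str, int] = field(
        default_factory=lambda: {"chrS1": 20_000_000, "chrS2": 20_000_000, "chrS3": 20_000_000}
    )
    databases: tuple[str, ...] = DEFAULT_DATABASES

    def __post_init__(self) -> None:
        if len(self.scenarios) != self.n_families:
            raise ConfigError(
                f"{self.n_families} families but {len(self.scenarios)} scenarios"
            )
        for s in self.scenarios:
            if s not in SCENARIOS:
                raise ConfigError(f"unknown scenario {s!r}")
        if self.shared_causal_gene and sum(s != NONE for s in self.scenarios) < 2:
            raise ConfigError("shared_causal_gene needs >= 2 families with planted scenarios")
        af_sum = self.af_fraction_common + self.af_fraction_rare + self.af_fraction_absent
        if abs(af_sum - 1.0) > 1e-9:
            raise ConfigError(f"AF-spectrum fractions sum to {af_sum}, not 1")
        mix_sum = sum(self.functional_class_mix.values())
        if abs(mix_sum - 1.0) > 1e-9:
            raise ConfigError(f"functional-class mix sums to {mix_sum}, not 1")
        if not 0.0 <= self.genotype_missingness < 1.0:
            raise ConfigError("genotype_missingness must be in [0, 1)")


@dataclass(frozen=True)
class TruthRecord:
    """What was planted in one family and what the cascade should recover."""

    family_id: str
    scenario: str
    variant_keys: tuple[str, ...]  # "chrom:pos:ref:alt"
    expected_model: str            # hom_recessive | compound_het | none
    expected_in_roh: bool
    causal_gene: str


@dataclass
class CohortBundle:
    """Paths and in-memory truth for one simulated cohort."""

    out_dir: Path
    ped_path: Path
    vcf_paths: dict[str, Path]
    frequency_paths: dict[str, Path]
    gene_model_tsv: Path
    cds_fasta: Path
    expression_path: Path
    truth_path: Path
    truth: list[TruthRecord]
    pedigrees: list[Pedigree]


# ---------------------------------------------------------------------------
# Gene panel
# ---------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = [NON_STOP_CODONS[i] for i in rng.integers(0, len(NON_STOP_CODONS), n_codons)]
    codons[0] = "ATG"
    stop = ("TAA", "TAG", "TGA")[rng.integers(0, 3)]
    return "".join(codons) + stop


def build_gene_panel(config: SimulationConfig, rng: np.random.Generator) -> list[TranscriptModel]:
    """Deterministic panel of intron-containing genes spread over the
    synthetic chromosomes; roughly a third on the reverse strand."""
    chroms = list(config.chromosomes)
    per_chrom = [config.n_genes // len(chroms)] * len(chroms)
    for i in range(config.n_genes - sum(per_chrom)):
        per_chrom[i] += 1

    models = []
    gid = 0
    for chrom, n_here in zip(chroms, per_chrom):
        length = config.chromosomes[chrom]
        spacing = length // (n_here + 1)
        for j in range(n_here):
            gid += 1
            start = spacing * (j + 1) + int(rng.integers(-spacing // 4, spacing // 4))
            n_codons = int(rng.integers(150, 400))
            cds_len = 3 * (n_codons + 1)  # + stop codon
            n_exons = int(rng.integers(3, 6))
            # split CDS length into n_exons positive chunks
            cuts = sorted(rng.choice(np.arange(1, cds_len), size=n_exons - 1, replace=False))
            chunks = np.diff([0, *cuts, cds_len]).tolist()
            strand = "-" if rng.random() < 0.3 else "+"
            utr5, utr3 = 60, 120
            exons = []
            g = start
            for k, chunk in enumerate(chunks):
                exon_len = chunk
                if k == 0:
                    exon_len += utr5
                if k == n_exons - 1:
                    exon_len += utr3
                exons.append((g, g + exon_len - 1))
                g += exon_len + int(rng.integers(300, 3000))
            cds_start = exons[0][0] + utr5
            cds_end = exons[-1][1] - utr3
            cds = _random_cds(rng, n_codons)
            # 3'UTR read-through with stops reachable in every frame
            utr3_seq = "".join(BASES[i] for i in rng.integers(0, 4, 30)) + "TTAATTAATTAA"
            models.append(
                TranscriptModel(
                    transcript_id=f"TX{gid:04d}",
                    gene=f"GENE{gid:04d}",
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    cds_start=cds_start,
                    cds_end=cds_end,
                    cds_sequence=cds,
                    utr3_sequence=utr3_seq,
                )
            )
    return models


def pick_causal_gene(models: Sequence[TranscriptModel], rng: np.random.Generator) -> TranscriptModel:
    """A forward-strand gene whose first intron is deep enough to host the
    planted deep-intronic allele (>= 250 bp)."""
    eligible = [
        m for m in models
        if m.strand == "+"
        and len(m.exons) >= 3
        and (m.exons[1][0] - m.exons[0][1] - 1) >= 250
    ]
    if not eligible:
        raise ConfigError("gene panel has no eligible causal gene")
    return eligible[int(rng.integers(0, len(eligible)))]


# ---------------------------------------------------------------------------
# Background variant panel
# ---------------------------------------------------------------------------

@dataclass
class _Site:
    chrom: str
    pos: int
    ref: str
    alt: str
    af: float                      # generating AF used for genotype draws
    db_afs: dict[str, float]       # catalogued per-database frequencies
    planted_for: str | None = None  # family_id when not a background site
    planted_gt: dict[str, tuple[str, str]] | None = None


class _SubstitutionIndex:
    """Per-gene cache of coding substitutions grouped by consequence class."""

    def __init__(self) -> None:
        self._cache: dict[str, dict[str, list[tuple[int, str]]]] = {}

    def get(self, model: TranscriptModel, cls: str) -> list[tuple[int, str]]:
        table = self._cache.get(model.transcript_id)
        if table is None:
            table = {"missense": [], "synonymous": [], "stopgain": []}
            seq = model.cds_sequence
            for cds_pos in range(4, len(seq) - 2):  # skip start + stop codons
                cn = codon_index(cds_pos)
                within = (cds_pos - 1) % 3
                ref_codon = seq[(cn - 1) * 3:(cn - 1) * 3 + 3]
                ref_aa = GENETIC_CODE[ref_codon]
                if ref_aa == "*":
                    continue
                for alt_base in BASES:
                    if alt_base == seq[cds_pos - 1]:
                        continue
                    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1:]
                    alt_aa = GENETIC_CODE[alt_codon]
                    if alt_aa == "*":
                        table["stopgain"].append((cds_pos, alt_base))
                    elif alt_aa == ref_aa:
                        table["synonymous"].append((cds_pos, alt_base))
                    else:
                        table["missense"].append((cds_pos, alt_base))
            self._cache[model.transcript_id] = table
        return table[cls]


def _revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(seq))


def _coding_snv_site(
    model: TranscriptModel, cds_pos: int, alt_base: str
) -> tuple[str, int, str, str]:
    from .gene_model import CdnaCoordinate

    gpos = model.cdna_to_genomic(CdnaCoordinate(cds_pos, 0, "coding"))
    ref_cs = model.cds_base(cds_pos)
    if model.strand == "+":
        return model.chrom, gpos, ref_cs, alt_base
    return model.chrom, gpos, _revcomp(ref_cs), _revcomp(alt_base)


def _frameshift_site(model: TranscriptModel, rng: np.random.Generator) -> tuple[str, int, str, str] | None:
    """A 1-bp coding deletion on a forward-strand gene, VCF anchor style."""
    if model.strand != "+" or model.cds_sequence is None:
        return None
    from .gene_model import CdnaCoordinate

    intervals = model.coding_intervals()
    for _ in range(30):
        cds_pos = int(rng.integers(5, model.cds_length - 10))
        g_anchor = model.cdna_to_genomic(CdnaCoordinate(cds_pos - 1, 0, "coding"))
        g_del = model.cdna_to_genomic(CdnaCoordinate(cds_pos, 0, "coding"))
        if g_del != g_anchor + 1:  # anchor and deleted base must be adjacent
            continue
        if not any(lo <= g_anchor and g_del <= hi for lo, hi in intervals):
            continue
        ref = model.cds_base(cds_pos - 1) + model.cds_base(cds_pos)
        alt = ref[0]
        if ref[0] == ref[1]:  # avoid alleles that suffix-trim to a different key
            continue
        return model.chrom, g_anchor, ref, alt
    return None


def _inframe_site(model: TranscriptModel, rng: np.random.Generator) -> tuple[str, int, str, str] | None:
    """A 3-bp coding deletion on a forward-strand gene."""
    if model.strand != "+" or model.cds_sequence is None:
        return None
    from .gene_model import CdnaCoordinate

    intervals = model.coding_intervals()
    for _ in range(30):
        cds_pos = int(rng.integers(5, model.cds_length - 12))
        g_anchor = model.cdna_to_genomic(CdnaCoordinate(cds_pos - 1, 0, "coding"))
        g_last = model.cdna_to_genomic(CdnaCoordinate(cds_pos + 2, 0, "coding"))
        if g_last != g_anchor + 3:
            continue
        if not any(lo <= g_anchor and g_last <= hi for lo, hi in intervals):
            continue
        ref = "".join(model.cds_base(cds_pos - 1 + k) for k in range(4))
        alt = ref[0]
        if ref[-1] == ref[0]:
            continue
        return model.chrom, g_anchor, ref, alt
    return None


def _intron_of(model: TranscriptModel, rng: np.random.Generator, min_len: int = 30) -> tuple[int, int] | None:
    introns = [
        (e1 + 1, s2 - 1)
        for (_, e1), (s2, _) in zip(model.exons, model.exons[1:])
        if s2 - e1 - 1 >= min_len
    ]
    if not introns:
        return None
    return introns[int(rng.integers(0, len(introns)))]


def _random_snv_alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref = BASES[int(rng.integers(0, 4))]
    alt = BASES[int(rng.integers(0, 3))]
    if alt >= ref:
        alt = BASES[(BASES.index(alt) + 1) % 4]
    if alt == ref:
        alt = BASES[(BASES.index(ref) + 1) % 4]
    return ref, alt


def _draw_background_site(
    cls: str,
    models: Sequence[TranscriptModel],
    models_by_chrom: dict[str, list[TranscriptModel]],
    chrom_lengths: dict[str, int],
    subst: _SubstitutionIndex,
    rng: np.random.Generator,
) -> tuple[str, int, str, str] | None:
    """Realize one background variant of the requested functional class."""
    model = models[int(rng.integers(0, len(models)))]
    if cls in ("missense", "synonymous", "stopgain"):
        choices = subst.get(model, cls)
        if not choices:
            return None
        cds_pos, alt_base = choices[int(rng.integers(0, len(choices)))]
        return _coding_snv_site(model, cds_pos, alt_base)
    if cls == "frameshift_deletion":
        return _frameshift_site(model, rng)
    if cls == "inframe_indel":
        return _inframe_site(model, rng)
    if cls == "splicing":
        intron = _intron_of(model, rng, min_len=10)
        if intron is None:
            return None
        lo, hi = intron
        pos = lo + int(rng.integers(0, 2)) if rng.random() < 0.5 else hi - int(rng.integers(0, 2))
        ref, alt = _random_snv_alleles(rng)
        return model.chrom, pos, ref, alt
    if cls == "intronic":
        intron = _intron_of(model, rng)
        if intron is None:
            return None
        lo, hi = intron
        pos = int(rng.integers(lo + 10, hi - 9))
        ref, alt = _random_snv_alleles(rng)
        return model.chrom, pos, ref, alt
    if cls == "UTR":
        if rng.random() < 0.5:
            lo, hi = (model.exons[0][0], model.cds_start - 1)
        else:
            lo, hi = (model.cds_end + 1, model.exons[-1][1])
        if hi < lo:
            return None
        pos = int(rng.integers(lo, hi + 1))
        ref, alt = _random_snv_alleles(rng)
        return model.chrom, pos, ref, alt
    if cls == "intergenic":
        chrom = list(chrom_lengths)[int(rng.integers(0, len(chrom_lengths)))]
        spans = sorted((m.span for m in models_by_chrom.get(chrom, [])))
        starts = [s for s, _ in spans]
        for _ in range(20):
            pos = int(rng.integers(1, chrom_lengths[chrom]))
            i = bisect.bisect_right(starts, pos) - 1
            if i >= 0 and spans[i][0] <= pos <= spans[i][1]:
                continue
            ref, alt = _random_snv_alleles(rng)
            return chrom, pos, ref, alt
        return None
    raise ConfigError(f"unknown functional class in mix: {cls}")


def _draw_af(config: SimulationConfig, rng: np.random.Generator) -> tuple[float, bool]:
    """Draw (generating AF, catalogued?) from the three-component spectrum."""
    u = rng.random()
    if u < config.af_fraction_common:
        return float(rng.uniform(0.01, 0.5)), True
    rare = float(min(rng.exponential(config.rare_af_mean), 0.0099))
    rare = max(rare, 1e-6)
    if u < config.af_fraction_common + config.af_fraction_rare:
        return rare, True
    return rare, False


def _db_afs(
    af: float, catalogued: bool, databases: Sequence[str], rng: np.random.Generator
) -> dict[str, float]:
    if not catalogued:
        return {}
    out = {}
    for db in databases:
        if db == "gnomAD" or rng.random() < 0.8:
            out[db] = float(np.clip(af * rng.uniform(0.85, 1.15), 1e-7, 1.0))
    return out


def build_variant_panel(
    config: SimulationConfig,
    models: Sequence[TranscriptModel],
    rng: np.random.Generator,
) -> list[_Site]:
    """The background site panel shared by every family in the cohort."""
    models_by_chrom: dict[str, list[TranscriptModel]] = {}
    for m in models:
        models_by_chrom.setdefault(m.chrom, []).append(m)
    subst = _SubstitutionIndex()

    classes = list(config.functional_class_mix)
    probs = np.array([config.functional_class_mix[c] for c in classes])
    draws = rng.choice(len(classes), size=config.n_background_variants, p=probs)

    used: set[tuple[str, int]] = set()
    sites: list[_Site] = []
    for class_i in draws:
        cls = classes[class_i]
        for _ in range(50):
            drawn = _draw_background_site(
                cls, models, models_by_chrom, config.chromosomes, subst, rng
            )
            if drawn is None:
                continue
            chrom, pos, ref, alt = drawn
            if (chrom, pos) in used:
                continue
            used.add((chrom, pos))
            af, catalogued = _draw_af(config, rng)
            sites.append(
                _Site(chrom, pos, ref, alt, af, _db_afs(af, catalogued, config.databases, rng))
            )
            break
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return sites


# ---------------------------------------------------------------------------
# Trio genotypes
# ---------------------------------------------------------------------------

def simulate_trio_genotypes(
    afs: np.ndarray,
    rng: np.random.Generator,
    autozygous: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Vectorized trio transmission: founder alleles i.i.d. Bernoulli(af),
    the child inheriting one random allele per parent.

    ``autozygous`` is a boolean mask of sites where the proband's two alleles
    are copies of a single founder allele shared identically by descent
    through both parents (each parent carries that allele plus one free
    draw), so transmission stays Mendelian-consistent inside the block.
    Returns allele arrays of shape (n, 2) keyed by role.
    """
    n = len(afs)
    father = (rng.random((n, 2)) < afs[:, None]).astype(np.int8)
    mother = (rng.random((n, 2)) < afs[:, None]).astype(np.int8)
    pick_f = rng.integers(0, 2, n)
    pick_m = rng.integers(0, 2, n)
    child = np.stack(
        [father[np.arange(n), pick_f], mother[np.arange(n), pick_m]], axis=1
    )
    if autozygous is not None and autozygous.any():
        shared = (rng.random(n) < afs).astype(np.int8)
        idx = np.where(autozygous)[0]
        father[idx, 0] = shared[idx]
        mother[idx, 0] = shared[idx]
        child[idx, 0] = shared[idx]
        child[idx, 1] = shared[idx]
    return {"father": father, "mother": mother, "child": child}


_ALLELE = (REF, ALT)


def _calls_from_alleles(alleles: np.ndarray, missing_mask: np.ndarray):
    return [
        genotype_call(MISSING, MISSING)
        if missing_mask[i]
        else genotype_call(_ALLELE[alleles[i, 0]], _ALLELE[alleles[i, 1]])
        for i in range(len(alleles))
    ]


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _plant_for_family(
    family_id: str,
    scenario: str,
    causal: TranscriptModel,
    config: SimulationConfig,
    rng: np.random.Generator,
    sample_ids: dict[str, str],
) -> tuple[list[_Site], TruthRecord | None, tuple[int, int] | None]:
    """Planted causal sites, the truth record, and the autozygosity block."""
    father, mother, child = sample_ids["father"], sample_ids["mother"], sample_ids["child"]
    subst = _SubstitutionIndex()
    if scenario == NONE:
        return [], None, None

    if scenario in (HOM_NONSENSE_IN_ROH, HOM_NONSENSE):
        stopgains = subst.get(causal, "stopgain")
        cds_pos, alt_base = stopgains[int(rng.integers(0, len(stopgains)))]
        chrom, pos, ref, alt = _coding_snv_site(causal, cds_pos, alt_base)
        site = _Site(
            chrom, pos, ref, alt,
            af=1e-5, db_afs={},  # absent from every database
            planted_for=family_id,
            planted_gt={father: (REF, ALT), mother: (REF, ALT), child: (ALT, ALT)},
        )
        block = None
        if scenario == HOM_NONSENSE_IN_ROH:
            lo, hi = config.roh_block_length_bp
            length = int(rng.integers(lo, hi))
            lead = int(rng.integers(length // 5, length // 2))
            start = max(1, pos - lead)
            block = (start, start + length - 1)
        truth = TruthRecord(
            family_id=family_id,
            scenario=scenario,
            variant_keys=(f"{chrom}:{pos}:{ref}:{alt}",),
            expected_model="hom_recessive",
            expected_in_roh=scenario == HOM_NONSENSE_IN_ROH,
            causal_gene=causal.gene,
        )
        return [site], truth, block

    # COMPHET_FRAMESHIFT_PLUS_INTRONIC
    fs = _frameshift_site(causal, rng)
    if fs is None:
        raise ConfigError(f"causal gene {causal.gene} cannot host a frameshift")
    chrom, pos, ref, alt = fs
    fs_site = _Site(
        chrom, pos, ref, alt, af=1e-5, db_afs={},
        planted_for=family_id,
        planted_gt={father: (REF, REF), mother: (REF, ALT), child: (REF, ALT)},
    )
    # deep-intronic partner: 10-200 bp inside an intron, opposite origin
    intron_lo, intron_hi = causal.exons[0][1] + 1, causal.exons[1][0] - 1
    offset = int(rng.integers(10, min(200, intron_hi - intron_lo - 9) + 1))
    ipos = causal.exons[1][0] - offset  # upstream of the acceptor, c.X-offset
    iref, ialt = "G", "A"
    intronic_site = _Site(
        chrom, ipos, iref, ialt,
        af=INTRONIC_PARTNER_AF,
        db_afs={"gnomAD": INTRONIC_PARTNER_AF},
        planted_for=family_id,
        planted_gt={father: (REF, ALT), mother: (REF, REF), child: (REF, ALT)},
    )
    truth = TruthRecord(
        family_id=family_id,
        scenario=scenario,
        variant_keys=(
            f"{chrom}:{pos}:{ref}:{alt}",
            f"{chrom}:{ipos}:{iref}:{ialt}",
        ),
        expected_model="compound_het",
        expected_in_roh=False,
        causal_gene=causal.gene,
    )
    return [fs_site, intronic_site], truth, None


def simulate_cohort(config: SimulationConfig, out_dir: str | Path) -> CohortBundle:
    """Generate a complete cohort bundle under ``out_dir``.

    Deterministic for a fixed config (including the seed): one RNG stream
    drives the whole generation and every container is ordered.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    models = build_gene_panel(config, rng)
    shared_causal = pick_causal_gene(models, rng)
    panel = build_variant_panel(config, models, rng)

    # choose distinct causal genes when not shared
    causal_by_family: dict[str, TranscriptModel] = {}
    taken = {shared_causal.transcript_id}
    pedigrees: list[Pedigree] = []
    ped_lines: list[str] = []
    truth_records: list[TruthRecord] = []
    vcf_paths: dict[str, Path] = {}

    extra_db_rows: list[tuple[str, str, int, str, str, float]] = []

    for fam_i, scenario in enumerate(config.scenarios, start=1):
        family_id = f"F{fam_i}"
        father_id, mother_id, child_id = f"{family_id}-f", f"{family_id}-m", f"{family_id}-p"
        consanguineous = scenario == HOM_NONSENSE_IN_ROH
        if config.shared_causal_gene or scenario == NONE:
            causal = shared_causal
        else:
            candidates = [
                m for m in models
                if m.transcript_id not in taken and m.strand == "+" and len(m.exons) >= 3
                and (m.exons[1][0] - m.exons[0][1] - 1) >= 250
            ]
            causal = candidates[int(rng.integers(0, len(candidates)))]
            taken.add(causal.transcript_id)
        causal_by_family[family_id] = causal

        planted, truth, block = _plant_for_family(
            family_id, scenario, causal, config, rng,
            {"father": father_id, "mother": mother_id, "child": child_id},
        )
        if truth is not None:
            truth_records.append(truth)

        # genotypes over the shared background panel
        afs = np.array([s.af for s in panel])
        autozygous = None
        if block is not None:
            start, end = block
            autozygous = np.array(
                [s.chrom == causal.chrom and start <= s.pos <= end for s in panel]
            )
        alleles = simulate_trio_genotypes(afs, rng, autozygous)
        n = len(panel)
        if config.genotype_missingness > 0:
            missing = {
                role: rng.random(n) < config.genotype_missingness
                for role in ("father", "mother", "child")
            }
        else:
            zeros = np.zeros(n, dtype=bool)
            missing = {role: zeros for role in ("father", "mother", "child")}
        calls = {
            father_id: _calls_from_alleles(alleles["father"], missing["father"]),
            mother_id: _calls_from_alleles(alleles["mother"], missing["mother"]),
            child_id: _calls_from_alleles(alleles["child"], missing["child"]),
        }

        records = []
        for i, s in enumerate(panel):
            records.append(
                VariantRecord(
                    chrom=s.chrom, pos=s.pos, ref=s.ref, alt=s.alt,
                    genotypes={
                        father_id: calls[father_id][i],
                        mother_id: calls[mother_id][i],
                        child_id: calls[child_id][i],
                    },
                )
            )
        for s in planted:
            records.append(
                VariantRecord(
                    chrom=s.chrom, pos=s.pos, ref=s.ref, alt=s.alt,
                    genotypes={
                        sid: genotype_call(a, b) for sid, (a, b) in s.planted_gt.items()
                    },
                )
            )
            for db, af in s.db_afs.items():
                extra_db_rows.append((db, s.chrom, s.pos, s.ref, s.alt, af))

        vcf_path = out_dir / f"{family_id}.vcf"
        write_vcf(records, [father_id, mother_id, child_id], vcf_path)
        vcf_paths[family_id] = vcf_path

        consang_col = "1" if consanguineous else "0"
        ped_lines += [
            f"{family_id}\t{father_id}\t0\t0\t1\t1\t{consang_col}",
            f"{family_id}\t{mother_id}\t0\t0\t2\t1\t{consang_col}",
            f"{family_id}\t{child_id}\t{father_id}\t{mother_id}\t2\t2\t{consang_col}",
        ]
        pedigrees.append(
            Pedigree(
                family_id=family_id,
                samples=[
                    PedSample(father_id, None, None, "1", False),
                    PedSample(mother_id, None, None, "2", False),
                    PedSample(child_id, father_id, mother_id, "2", True),
                ],
                consanguineous=consanguineous,
            )
        )

    ped_path = out_dir / "cohort.ped"
    ped_path.write_text("\n".join(ped_lines) + "\n")

    # frequency tables
    frequency_paths: dict[str, Path] = {}
    for db in config.databases:
        rows = ["chrom\tpos\tref\talt\taf"]
        for s in panel:
            if db in s.db_afs:
                rows.append(f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t{s.db_afs[db]:.8g}")
        for edb, chrom, pos, ref, alt, af in extra_db_rows:
            if edb == db:
                rows.append(f"{chrom}\t{pos}\t{ref}\t{alt}\t{af:.8g}")
        path = out_dir / f"freq_{db}.tsv"
        path.write_text("\n".join(rows) + "\n")
        frequency_paths[db] = path

    # gene models
    gene_model_tsv = out_dir / "gene_models.tsv"
    cds_fasta = out_dir / "cds.fa"
    write_gene_models(models, gene_model_tsv, cds_fasta)

    # expression table: causal genes strongly expressed, ~1/4 of background
    # genes below the TPM >= 1 cutoff
    causal_ids = {m.gene for m in causal_by_family.values()}
    expr_rows = ["gene\tstage\ttpm"]
    for m in models:
        for stage in ("GV", "MI", "MII"):
            if m.gene in causal_ids:
                tpm = float(rng.uniform(30, 90))
            elif rng.random() < 0.25:
                tpm = float(rng.uniform(0.0, 0.9))
            else:
                tpm = float(rng.lognormal(1.5, 1.0))
            expr_rows.append(f"{m.gene}\t{stage}\t{tpm:.4f}")
    expression_path = out_dir / "expression.tsv"
    expression_path.write_text("\n".join(expr_rows) + "\n")

    truth_path = out_dir / "truth.tsv"
    write_truth(truth_records, truth_path)

    return CohortBundle(
        out_dir=out_dir,
        ped_path=ped_path,
        vcf_paths=vcf_paths,
        frequency_paths=frequency_paths,
        gene_model_tsv=gene_model_tsv,
        cds_fasta=cds_fasta,
        expression_path=expression_path,
        truth_path=truth_path,
        truth=truth_records,
        pedigrees=pedigrees,
    )


# ---------------------------------------------------------------------------
# Truth file round-trip
# ---------------------------------------------------------------------------

_TRUTH_HEADER = "family_id\tscenario\tvariant_keys\texpected_model\texpected_in_roh\tcausal_gene"


class TruthParseError(ValueError):
    pass


def write_truth(records: Sequence[TruthRecord], path: str | Path) -> None:
    lines = [_TRUTH_HEADER]
    for r in records:
        lines.append(
            "\t".join(
                [
                    r.family_id,
                    r.scenario,
                    ";".join(r.variant_keys),
                    r.expected_model,
                    "1" if r.expected_in_roh else "0",
                    r.causal_gene,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_truth(path: str | Path) -> list[TruthRecord]:
    lines = Path(path).read_text().splitlines()
    out = []
    for line in lines[1:]:
        if not line.strip():
            continue
        fam, scenario, keys, model, in_roh, gene = line.split("\t")
        for key in keys.split(";") if keys else []:
            if key.count(":") != 3:
                raise TruthParseError(f"malformed variant key {key!r}")
        out.append(
            TruthRecord(
                family_id=fam,
                scenario=scenario,
                variant_keys=tuple(keys.split(";")) if keys else (),
                expected_model=model,
                expected_in_roh=in_roh == "1",
                causal_gene=gene,
            )
        )
    return out
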