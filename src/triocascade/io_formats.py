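"""Readers and writers for the file formats the cascade touches.

Everything downstream works on the small data model defined here:
:class:`VariantRecord` (one site, one ALT, per-sample genotype calls),
:class:`Pedigree`, and :class:`FrequencyTable`.  VCF parsing is backed by
cyvcf2; multi-allelic rows are decomposed into one record per ALT allele so
that frequency-table joins and genotype logic are always biallelic.

Coordinates are 1-based inclusive throughout (the VCF convention); BED output
converts to 0-based half-open at the boundary and nowhere else.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from cyvcf2 import VCF

logger = logging.getLogger("triocascade")

REF = "REF"
ALT = "ALT"
MISSING = "MISSING"

#: Database names scanned by default for the population-frequency filter.
DEFAULT_DATABASES = ("dbSNP", "1000g", "EVS", "ExAC", "gnomAD")


class VcfFormatError(ValueError):
    """The input is not a usable VCF (missing header or GT FORMAT)."""


class PedStructureError(ValueError):
    """A pedigree row references a parent that does not exist in the family."""


class FrequencyTableError(ValueError):
    """A frequency table row is malformed (bad AF or duplicate key)."""


# ---------------------------------------------------------------------------
# Genotypes and variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class GenotypeCall:
    """One diploid genotype for one sample, allele slots in {REF, ALT, MISSING}."""

    allele_a: str = MISSING
    allele_b: str = MISSING
    phased: bool = False

    @property
    def is_missing(self) -> bool:
        return MISSING in (self.allele_a, self.allele_b)

    @property
    def zygosity(self) -> str:
        """One of ``hom_ref`` / ``het`` / ``hom_alt`` / ``missing``."""
        if self.is_missing:
            return "missing"
        n_alt = (self.allele_a == ALT) + (self.allele_b == ALT)
        return ("hom_ref", "het", "hom_alt")[n_alt]

    @property
    def alt_dosage(self) -> int | None:
        """Count of ALT alleles among the *known* slots; None if fully missing."""
        known = [a for a in (self.allele_a, self.allele_b) if a != MISSING]
        if not known:
            return None
        return sum(a == ALT for a in known)

    def has_alt(self) -> bool:
        return ALT in (self.allele_a, self.allele_b)


MISSING_CALL = GenotypeCall()

_CALL_CACHE: dict[tuple[str, str, bool], GenotypeCall] = {}


def genotype_call(allele_a: str, allele_b: str, phased: bool = False) -> GenotypeCall:
    """Interned :class:`GenotypeCall` constructor (only 18 distinct values exist,
    so cohort-scale record sets share instances)."""
    key = (allele_a, allele_b, phased)
    call = _CALL_CACHE.get(key)
    if call is None:
        call = _CALL_CACHE[key] = GenotypeCall(allele_a, allele_b, phased)
    return call


@dataclass
class VariantRecord:
    """One biallelic variant site with per-sample genotype calls.

    ``annotations`` is an open bag: the pipeline attaches ``max_maf``,
    ``db_afs``, ``gene``, ``consequence``, ``rescued`` ... as stages run.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    ids: tuple[str, ...] = ()
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def key_str(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    def genotype(self, sample: str) -> GenotypeCall:
        return self.genotypes.get(sample, MISSING_CALL)

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


def normalize_alleles(pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Trim shared suffix then shared prefix, keeping at least one base each.

    Produces the canonical (pos, ref, alt) key used for database joins.  Full
    left-alignment across repeat tracts would additionally need the flanking
    reference sequence, which records do not carry; trimming is sufficient for
    alleles emitted in normalized form.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


_CHROM_RE = re.compile(r"^(chr)?(.+)$", re.IGNORECASE)


def normalize_chrom(chrom: str) -> str:
    """Strip an optional ``chr`` prefix and upper-case; '6' and 'chr6' agree."""
    return _CHROM_RE.match(chrom).group(2).upper()


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    core = normalize_chrom(chrom)
    if core.isdigit():
        return (int(core), "")
    return (10**6, core)


# ---------------------------------------------------------------------------
# Pedigrees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PedSample:
    sample_id: str
    father_id: str | None
    mother_id: str | None
    sex: str  # "1" male, "2" female, other = unknown
    affected: bool | None  # True / False / None (unknown)


@dataclass
class Pedigree:
    family_id: str
    samples: list[PedSample]
    consanguineous: bool = False

    def __post_init__(self) -> None:
        ids = {s.sample_id for s in self.samples}
        for s in self.samples:
            for parent in (s.father_id, s.mother_id):
                if parent is not None and parent not in ids:
                    raise PedStructureError(
                        f"family {self.family_id}: sample {s.sample_id} references "
                        f"unknown parent {parent}"
                    )

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def affected(self) -> list[PedSample]:
        return [s for s in self.samples if s.affected is True]

    @property
    def proband(self) -> PedSample:
        """The first affected sample with both parents in the family, else the
        first affected sample."""
        aff = self.affected
        if not aff:
            raise ValueError(f"family {self.family_id} has no affected sample")
        for s in aff:
            if s.father_id and s.mother_id:
                return s
        return aff[0]

    def parents_of(self, sample_id: str) -> tuple[str | None, str | None]:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s.father_id, s.mother_id
        raise KeyError(sample_id)

    def unaffected_siblings(self, sample_id: str) -> list[PedSample]:
        father, mother = self.parents_of(sample_id)
        return [
            s
            for s in self.samples
            if s.sample_id != sample_id
            and s.affected is False
            and (s.father_id, s.mother_id) == (father, mother)
            and (father is not None or mother is not None)
        ]


def read_ped(path: str | Path) -> list[Pedigree]:
    """Parse a 6-column PED file with an optional 7th consanguinity column.

    Affected status: 2 -> True, 1 -> False, 0/-9 -> unknown.  One
    :class:`Pedigree` per family id, in file order.
    """
    families: dict[str, list[PedSample]] = {}
    consang: dict[str, bool] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < 6:
            raise PedStructureError(f"PED row has {len(cols)} columns, need >= 6: {line!r}")
        fam, sid, father, mother, sex, pheno = cols[:6]
        affected = {"2": True, "1": False}.get(pheno)
        families.setdefault(fam, []).append(
            PedSample(
                sample_id=sid,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                sex=sex,
                affected=affected,
            )
        )
        if len(cols) >= 7 and cols[6] == "1":
            consang[fam] = True
    return [
        Pedigree(family_id=fam, samples=members, consanguineous=consang.get(fam, False))
        for fam, members in families.items()
    ]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, family: Pedigree | None = None) -> list[VariantRecord]:
    """Read a VCF v4.x into decomposed, sorted :class:`VariantRecord` objects.

    Multi-allelic rows become one record per ALT; a genotype allele pointing
    at a *different* ALT of the same row is mapped to REF in the decomposed
    record, so summed ALT dosages are conserved across the decomposition.
    Pedigree samples absent from the VCF get all-MISSING calls (with a
    warning); extraneous VCF samples are kept and flagged.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.startswith("##fileformat=VCF"):
        raise VcfFormatError(f"{path}: missing ##fileformat=VCFv4.x header line")

    vcf = VCF(str(path))
    try:
        vcf.get_header_type("GT")
    except KeyError:
        raise VcfFormatError(f"{path}: no GT FORMAT field declared in header")

    vcf_samples = list(vcf.samples)
    ped_samples = set(family.sample_ids) if family is not None else None
    if ped_samples is not None:
        absent = sorted(ped_samples - set(vcf_samples))
        if absent:
            warnings.warn(
                f"{path}: pedigree samples missing from VCF, genotypes set MISSING: "
                + ", ".join(absent)
            )
        extraneous = sorted(set(vcf_samples) - ped_samples)
        if extraneous:
            logger.info("%s: %d extraneous VCF samples ignored by pedigree logic", path, len(extraneous))

    records: list[VariantRecord] = []
    for v in vcf:
        alts = v.ALT
        if not alts:
            continue
        gts = v.genotypes  # [[a, b, phased], ...] aligned with vcf_samples
        for alt_index, alt in enumerate(alts, start=1):
            genotypes: dict[str, GenotypeCall] = {}
            for sample, gt in zip(vcf_samples, gts):
                a, b = gt[0], gt[1]
                genotypes[sample] = genotype_call(
                    MISSING if a < 0 else (ALT if a == alt_index else REF),
                    MISSING if b < 0 else (ALT if b == alt_index else REF),
                    bool(gt[-1]),
                )
            if ped_samples is not None:
                for sid in ped_samples - set(vcf_samples):
                    genotypes[sid] = MISSING_CALL
            pos, ref, nalt = normalize_alleles(v.POS, v.REF, alt)
            ids = tuple(v.ID.split(";")) if v.ID else ()
            records.append(
                VariantRecord(chrom=v.CHROM, pos=pos, ref=ref, alt=nalt, ids=ids, genotypes=genotypes)
            )
    records.sort(key=lambda r: (chrom_sort_key(r.chrom), r.pos, r.ref, r.alt))
    return records


def write_vcf(
    records: Sequence[VariantRecord],
    samples: Sequence[str],
    path: str | Path,
    reference_note: str = "synthetic",
) -> None:
    """Write records as a minimal VCF v4.2 (GT only), sorted, one ALT per row."""
    gt_code = {REF: "0", ALT: "1", MISSING: "."}
    chroms = sorted({r.chrom for r in records}, key=chrom_sort_key)
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=triocascade ({reference_note})",
        *[f"##contig=<ID={c}>" for c in chroms],
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for rec in sorted(records, key=lambda r: (chrom_sort_key(r.chrom), r.pos, r.ref, r.alt)):
        cells = [rec.chrom, str(rec.pos), ";".join(rec.ids) or ".", rec.ref, rec.alt, ".", "PASS", ".", "GT"]
        for s in samples:
            g = rec.genotype(s)
            sep = "|" if g.phased else "/"
            cells.append(gt_code[g.allele_a] + sep + gt_code[g.allele_b])
        lines.append("\t".join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Frequency tables
# ---------------------------------------------------------------------------

@dataclass
class FrequencyTable:
    """Allele frequencies from one population database.

    An absent key means "not observed in this database" — deliberately distinct
    from an entry with frequency 0.
    """

    db_name: str
    entries: dict[tuple[str, int, str, str], float] = field(default_factory=dict)

    def lookup(self, variant: VariantRecord) -> float | None:
        return self.entries.get((normalize_chrom(variant.chrom), variant.pos, variant.ref, variant.alt))


def read_frequency_table(path: str | Path, db_name: str) -> FrequencyTable:
    """Read a TSV with columns chrom, pos, ref, alt and af (or allele_count +
    allele_number, from which af is computed)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    required = {"chrom", "pos", "ref", "alt"}
    if not required.issubset(df.columns):
        raise FrequencyTableError(f"{path}: need columns {sorted(required)}, got {list(df.columns)}")
    if "af" in df.columns:
        afs = df["af"].astype(float)
    elif {"allele_count", "allele_number"}.issubset(df.columns):
        afs = df["allele_count"].astype(float) / df["allele_number"].astype(float)
    else:
        raise FrequencyTableError(f"{path}: need 'af' or 'allele_count'+'allele_number' columns")
    entries: dict[tuple[str, int, str, str], float] = {}
    for chrom, pos, ref, alt, af in zip(df["chrom"], df["pos"], df["ref"], df["alt"], afs):
        af = float(af)
        if not 0.0 <= af <= 1.0:
            raise FrequencyTableError(f"{path}: AF {af} outside [0,1] at {chrom}:{pos}")
        key = (normalize_chrom(str(chrom)), int(pos), str(ref).upper(), str(alt).upper())
        if key in entries:
            raise FrequencyTableError(f"{path}: duplicate key {key}")
        entries[key] = af
    return FrequencyTable(db_name=db_name, entries=entries)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

CANDIDATE_COLUMNS = [
    "family_id", "gene", "chrom", "pos", "ref", "alt", "cdna_change",
    "protein_change", "mutation_type", "inheritance_model", "phase_status",
    "in_roh", "rescued",
]

NOT_FOUND = "not found"


def write_candidate_report(
    candidates: Sequence,  # CandidateRow-like, see pipeline
    trace_rows: Sequence[tuple[str, str, int]],  # (family, stage, count)
    out_prefix: str | Path,
    databases: Sequence[str] = DEFAULT_DATABASES,
) -> tuple[Path, Path]:
    """Write the per-stage count table and the per-candidate TSV.

    Returns (trace_path, candidates_path).  AF cells for databases with no
    entry render as ``not found`` to distinguish absence from frequency 0.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)

    trace_path = out_prefix.with_name(out_prefix.name + ".trace.tsv")
    with open(trace_path, "w") as fh:
        fh.write("family_id\tstage\tsurviving\n")
        for fam, stage, count in trace_rows:
            fh.write(f"{fam}\t{stage}\t{count}\n")

    cand_path = out_prefix.with_name(out_prefix.name + ".candidates.tsv")
    columns = CANDIDATE_COLUMNS + [f"af_{db}" for db in databases]
    with open(cand_path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in candidates:
            cells = [str(row.get(c, "")) for c in CANDIDATE_COLUMNS]
            db_afs: Mapping[str, float] = row.get("db_afs", {})
            for db in databases:
                af = db_afs.get(db)
                cells.append(NOT_FOUND if af is None else f"{af:.6g}")
            fh.write("\t".join(cells) + "\n")
    return trace_path, cand_path


def write_roh_bed(segments: Iterable, path: str | Path) -> None:
    """Write ROH segments as BED: 0-based half-open, converted here only."""
    with open(path, "w") as fh:
        for seg in segments:
            fh.write(f"{seg.chrom}\t{seg.start - 1}\t{seg.end}\troh_n{seg.n_sites}_het{seg.n_het}\n")
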