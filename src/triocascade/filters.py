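"""Population-frequency and functional-class filters, plus the deep-intronic
rescue path.

The rarity rule is "MAF below 1% in every database scanned", implemented as
max-over-databases < threshold with absence from all databases counting as a
pass (absence is weaker evidence of commonness than an entry of 0.009, and
several causal alleles in this design space are simply not catalogued).

The rescue path reproduces a manual re-evaluation step: an intronic variant
discarded by the functional filter is reconsidered when the same gene in the
same affected sample already carries a surviving rare heterozygous
loss-of-function allele and the two could sit in trans.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .io_formats import DEFAULT_DATABASES, FrequencyTable, Pedigree, VariantRecord

#: Classes kept by the functional filter.
FUNCTIONAL_KEEP = {
    "stopgain", "missense", "frameshift_deletion", "frameshift_insertion",
    "inframe_indel", "splicing",
}
#: Classes dropped by the functional filter.
FUNCTIONAL_DROP = {"synonymous", "intronic", "UTR5", "UTR3", "intergenic"}

#: Loss-of-function classes eligible as rescue anchors.
LOF_CLASSES = {"stopgain", "frameshift_deletion", "frameshift_insertion", "splicing"}


class UnclassifiedVariantError(ValueError):
    """A variant reached the functional filter without a consequence call."""


@dataclass
class FilterParams:
    """Thresholds for the first two cascade stages."""

    maf_threshold: float = 0.01
    databases: tuple[str, ...] = DEFAULT_DATABASES
    splice_window: int = 2
    rescue_enabled: bool = True

    def __post_init__(self) -> None:
        # 0 is permitted and means "database-absent variants only"
        if not 0.0 <= self.maf_threshold < 1.0:
            raise ValueError(f"maf_threshold must be in [0, 1), got {self.maf_threshold}")


def max_observed_maf(
    variant: VariantRecord, tables: Sequence[FrequencyTable]
) -> float | None:
    """Maximum allele frequency over the databases that have seen the variant,
    or None ("not observed") when absent from all of them.

    Also stashes the per-database AFs on ``annotations['db_afs']`` for the
    report (absent databases omitted there, rendered "not found")."""
    afs = {}
    for table in tables:
        af = table.lookup(variant)
        if af is not None:
            afs[table.db_name] = af
    variant.annotations["db_afs"] = afs
    if not afs:
        return None
    return max(afs.values())


def filter_rare(
    variants: Sequence[VariantRecord],
    tables: Sequence[FrequencyTable],
    params: FilterParams,
) -> tuple[list[VariantRecord], int]:
    """Keep variants with max observed MAF < threshold or absent everywhere."""
    kept = []
    for v in variants:
        maf = max_observed_maf(v, tables)
        v.annotations["max_maf"] = maf
        if maf is None or maf < params.maf_threshold:
            kept.append(v)
    return kept, len(kept)


def filter_functional(
    variants: Sequence[VariantRecord], params: FilterParams
) -> tuple[list[VariantRecord], int, list[VariantRecord]]:
    """Keep protein-affecting / splice classes; returns (kept, count, dropped).

    The dropped list feeds :func:`apply_rescue_list`."""
    kept, dropped = [], []
    for v in variants:
        call = v.annotations.get("consequence")
        if call is None:
            raise UnclassifiedVariantError(
                f"variant {v.key_str} has no consequence annotation"
            )
        cls = call.functional_class
        if cls in FUNCTIONAL_KEEP:
            kept.append(v)
        elif cls in FUNCTIONAL_DROP:
            dropped.append(v)
        else:  # pragma: no cover - ConsequenceCall validates classes
            raise UnclassifiedVariantError(f"variant {v.key_str}: unknown class {cls}")
    return kept, len(kept), dropped


def parental_origin(variant: VariantRecord, pedigree: Pedigree, proband_id: str) -> str:
    """Which genotyped parent carries the ALT allele.

    Returns ``father`` / ``mother`` / ``both`` / ``neither`` / ``unknown``
    (unknown = a parent link absent or a parental genotype missing)."""
    father_id, mother_id = pedigree.parents_of(proband_id)
    if father_id is None or mother_id is None:
        return "unknown"
    f = variant.genotype(father_id)
    m = variant.genotype(mother_id)
    if f.is_missing or m.is_missing:
        return "unknown"
    if f.has_alt() and m.has_alt():
        return "both"
    if f.has_alt():
        return "father"
    if m.has_alt():
        return "mother"
    return "neither"


def could_be_trans(origin_a: str, origin_b: str) -> bool:
    """True when two alleles may lie on different parental haplotypes."""
    if "unknown" in (origin_a, origin_b) or "both" in (origin_a, origin_b):
        return True
    return origin_a != origin_b and "neither" not in (origin_a, origin_b)


def apply_rescue_list(
    dropped: Sequence[VariantRecord],
    surviving: Sequence[VariantRecord],
    pedigree: Pedigree,
) -> list[VariantRecord]:
    """Re-include dropped intronic variants that are candidate trans-partners
    of a surviving heterozygous loss-of-function allele in the same gene.

    Only variants that already passed the MAF stage are eligible (the dropped
    list comes from the functional stage, downstream of the MAF stage), so the
    rescue can never resurrect a common variant.  Re-included records are
    flagged ``annotations['rescued'] = True``.
    """
    proband = pedigree.proband.sample_id
    anchors: dict[str, list[str]] = {}  # gene -> origins of surviving het LoF
    for v in surviving:
        call = v.annotations.get("consequence")
        gene = v.annotations.get("gene")
        if call is None or gene is None:
            continue
        if call.functional_class in LOF_CLASSES and v.genotype(proband).zygosity == "het":
            anchors.setdefault(gene, []).append(parental_origin(v, pedigree, proband))

    rescued = []
    for v in dropped:
        call = v.annotations.get("consequence")
        gene = v.annotations.get("gene")
        if call is None or gene is None or gene not in anchors:
            continue
        if call.functional_class != "intronic":
            continue
        if v.genotype(proband).zygosity != "het":
            continue
        origin_v = parental_origin(v, pedigree, proband)
        if any(could_be_trans(origin_v, origin_a) for origin_a in anchors[gene]):
            v.annotations["rescued"] = True
            rescued.append(v)
    return rescued
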