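"""Recessive inheritance-model detection on autosomes.

Two recessive configurations are recognised in each family: a homozygous
alternate genotype in the affected proband with both genotyped parents
heterozygous carriers, and a compound heterozygote — two different variants
of one gene, one inherited from each parent (in trans).  Sex chromosomes are
excluded; dominant and de novo models are out of scope (the carrier-parent
assumption is what makes the cascade recessive).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

from .filters import parental_origin
from .io_formats import Pedigree, VariantRecord, normalize_chrom

logger = logging.getLogger("triocascade")

SEX_CHROMOSOMES = {"X", "Y"}


@dataclass
class InheritanceCandidate:
    model: str  # "hom_recessive" | "compound_het"
    variants: tuple[VariantRecord, ...]
    gene: str
    family_id: str
    phase_status: str = "trans_confirmed"  # or "phase_unknown"
    parents_unverified: bool = False
    in_roh: bool = False

    def __post_init__(self) -> None:
        if self.model == "hom_recessive" and len(self.variants) != 1:
            raise ValueError("hom_recessive candidate carries exactly one variant")
        if self.model == "compound_het" and len(self.variants) != 2:
            raise ValueError("compound_het candidate carries exactly two variants")

    @property
    def sort_pos(self) -> tuple[str, int]:
        v = min(self.variants, key=lambda r: (r.chrom, r.pos))
        return (v.chrom, v.pos)


def filter_autosomal(variants: Sequence[VariantRecord]) -> list[VariantRecord]:
    """Drop chrX/chrY records; 'X' and 'chrX' spellings are both recognised."""
    return [v for v in variants if normalize_chrom(v.chrom) not in SEX_CHROMOSOMES]


def find_homozygous_recessive(
    variants: Sequence[VariantRecord],
    pedigree: Pedigree,
    strict_siblings: bool = True,
) -> list[InheritanceCandidate]:
    """Homozygous-recessive candidates for the family's proband.

    A variant qualifies when the affected proband is hom-alt, every genotyped
    parent is a heterozygous carrier (a hom-ref or hom-alt parent is a
    Mendelian inconsistency with the recessive carrier model and rejects the
    variant; a missing parental genotype relaxes the check and sets
    ``parents_unverified``), and no genotyped *unaffected* full sibling is
    hom-alt.  Affected relatives are never used as exclusion evidence.  In
    lenient mode a hom-alt unaffected sibling only logs a warning.
    """
    proband = pedigree.proband
    father_id, mother_id = proband.father_id, proband.mother_id
    siblings = pedigree.unaffected_siblings(proband.sample_id)

    out = []
    for v in variants:
        if v.genotype(proband.sample_id).zygosity != "hom_alt":
            continue
        unverified = False
        consistent = True
        for parent_id in (father_id, mother_id):
            if parent_id is None:
                unverified = True
                continue
            g = v.genotype(parent_id)
            if g.is_missing:
                unverified = True
            elif g.zygosity != "het":
                consistent = False
                break
        if not consistent:
            continue
        sibling_conflict = any(
            v.genotype(s.sample_id).zygosity == "hom_alt" for s in siblings
        )
        if sibling_conflict:
            if strict_siblings:
                continue
            logger.warning(
                "family %s: unaffected sibling homozygous for %s kept in lenient mode",
                pedigree.family_id, v.key_str,
            )
        gene = v.annotations.get("gene") or ""
        out.append(
            InheritanceCandidate(
                model="hom_recessive",
                variants=(v,),
                gene=gene,
                family_id=pedigree.family_id,
                phase_status="trans_confirmed",
                parents_unverified=unverified,
            )
        )
    return out


def find_compound_het(
    variants_by_gene: dict[str, Sequence[VariantRecord]],
    pedigree: Pedigree,
) -> list[InheritanceCandidate]:
    """Compound-heterozygote candidates from proband-het variants per gene.

    For each unordered pair: one allele carried by the father only and the
    other by the mother only → ``trans_confirmed``; both alleles traceable to
    the same single parent → rejected (cis); a de-novo allele (genotyped
    parents, neither carries) → rejected (outside the carrier-parent model);
    anything ambiguous (ungenotyped parent, allele present in both parents)
    → retained as ``phase_unknown``, ranked below confirmed pairs.
    """
    proband = pedigree.proband.sample_id
    out = []
    for gene in sorted(variants_by_gene):
        hets = [
            v for v in variants_by_gene[gene]
            if v.genotype(proband).zygosity == "het"
        ]
        hets.sort(key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
        for va, vb in combinations(hets, 2):
            oa = parental_origin(va, pedigree, proband)
            ob = parental_origin(vb, pedigree, proband)
            if "neither" in (oa, ob):
                continue  # de novo allele: not a carrier-transmitted pair
            if {oa, ob} == {"father", "mother"}:
                status = "trans_confirmed"
            elif oa == ob and oa in ("father", "mother"):
                continue  # cis: both on one parental haplotype
            else:
                status = "phase_unknown"
            out.append(
                InheritanceCandidate(
                    model="compound_het",
                    variants=(va, vb),
                    gene=gene,
                    family_id=pedigree.family_id,
                    phase_status=status,
                )
            )
    return out


def group_by_gene(variants: Sequence[VariantRecord]) -> dict[str, list[VariantRecord]]:
    """Group variants by their ``gene`` annotation, skipping unassigned ones."""
    grouped: dict[str, list[VariantRecord]] = {}
    for v in variants:
        gene = v.annotations.get("gene")
        if gene:
            grouped.setdefault(gene, []).append(v)
    return grouped
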