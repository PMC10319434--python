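"""End-to-end orchestration of the filter cascade over a cohort directory.

Stage order is fixed: load → population-frequency filter → functional-class
filter → deep-intronic rescue → autosomal restriction + inheritance models →
ROH annotation → per-family gene sets → cross-family shared genes → oocyte
expression filter → ranking → report.  The rescue runs between the
functional and inheritance stages so a rescued intronic allele can pair into
a compound heterozygote.

Each family accumulates a :class:`FilterTrace` of surviving counts whose
rows are nonincreasing; rescued variants are tallied in a separate
annotation, never added back to earlier stages, and are excluded from the
inheritance-stage count so monotonicity is preserved by construction.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence

import yaml

from . import cohort_report as cr
from . import filters as flt
from . import inheritance as inh
from . import roh as roh_mod
from .gene_model import TranscriptModel, load_gene_models
from .io_formats import (
    Pedigree,
    VariantRecord,
    read_frequency_table,
    read_ped,
    read_vcf,
    write_candidate_report,
    write_roh_bed,
)

logger = logging.getLogger("triocascade")

TRACE_STAGES = (
    "total_variants",
    "after_maf",
    "after_functional",
    "after_inheritance_autosomal",
    "homozygous_only",
    "in_roh_gt2mb",
)


@dataclass
class FilterTrace:
    """Per-family surviving counts down the cascade, plus the rescue tally."""

    family_id: str
    counts: dict[str, int] = field(default_factory=dict)
    rescued: int = 0

    def record(self, stage: str, count: int) -> None:
        if stage not in TRACE_STAGES:
            raise ValueError(f"unknown trace stage {stage!r}")
        if count < 0:
            raise ValueError("stage counts must be nonnegative")
        self.counts[stage] = count
        logger.info("family %s: %s = %d", self.family_id, stage, count)

    def as_rows(self) -> list[tuple[str, str, int]]:
        rows = [
            (self.family_id, stage, self.counts[stage])
            for stage in TRACE_STAGES
            if stage in self.counts
        ]
        rows.append((self.family_id, "rescued", self.rescued))
        return rows

    def is_monotone(self) -> bool:
        seq = [self.counts[s] for s in TRACE_STAGES if s in self.counts]
        return all(a >= b for a, b in zip(seq, seq[1:]))


@dataclass
class PipelineParams:
    """All thresholds of the cascade, by name, with their defaults."""

    maf_threshold: float = 0.01
    roh_min_length_bp: int = 2_000_000
    roh_min_sites: int = 25
    roh_het_tolerance: int = 1
    roh_window_sites: int = 50
    roh_max_gap_bp: int = 500_000
    tpm_min: float = 1.0
    min_families: int = 2
    splice_window: int = 2
    rescue_enabled: bool = True
    strict_siblings: bool = True
    databases: tuple[str, ...] = flt.DEFAULT_DATABASES

    @property
    def filter_params(self) -> flt.FilterParams:
        return flt.FilterParams(
            maf_threshold=self.maf_threshold,
            databases=tuple(self.databases),
            splice_window=self.splice_window,
            rescue_enabled=self.rescue_enabled,
        )

    @property
    def roh_params(self) -> roh_mod.ROHParams:
        return roh_mod.ROHParams(
            min_length_bp=self.roh_min_length_bp,
            min_sites=self.roh_min_sites,
            het_tolerance=self.roh_het_tolerance,
            window_sites=self.roh_window_sites,
            max_gap_bp=self.roh_max_gap_bp,
        )


def load_config(path: str | Path) -> PipelineParams:
    """Read a flat key-value YAML config; keys mirror PipelineParams fields."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in fields(PipelineParams)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "databases" in raw:
        raw["databases"] = tuple(raw["databases"])
    return PipelineParams(**raw)


def write_config(params: PipelineParams, path: str | Path) -> None:
    doc = {f.name: getattr(params, f.name) for f in fields(PipelineParams)}
    doc["databases"] = list(doc["databases"])
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


# ---------------------------------------------------------------------------
# Gene / consequence annotation
# ---------------------------------------------------------------------------

class _GeneIndex:
    """Overlap lookup: genomic position -> canonical transcript (one per gene)."""

    def __init__(self, models: Sequence[TranscriptModel], flank: int = 0) -> None:
        self._by_chrom: dict[str, tuple[list[int], list[tuple[int, int, TranscriptModel]]]] = {}
        per_chrom: dict[str, list[tuple[int, int, TranscriptModel]]] = {}
        for m in models:
            lo, hi = m.span
            per_chrom.setdefault(m.chrom, []).append((lo - flank, hi + flank, m))
        for chrom, spans in per_chrom.items():
            spans.sort(key=lambda t: t[0])
            self._by_chrom[chrom] = ([s for s, _, _ in spans], spans)

    def lookup(self, chrom: str, pos: int) -> TranscriptModel | None:
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        starts, spans = entry
        i = bisect.bisect_right(starts, pos) - 1
        # walk left while intervals may still cover pos (panels are near-disjoint)
        while i >= 0:
            lo, hi, m = spans[i]
            if lo <= pos <= hi:
                return m
            if hi < pos and i < len(spans) - 1 and spans[i][1] < spans[i + 1][0]:
                break
            i -= 1
        return None


def annotate_gene_and_consequence(
    variants: Sequence[VariantRecord],
    models: Sequence[TranscriptModel],
    splice_window: int = 2,
) -> None:
    """Attach ``gene`` and ``consequence`` annotations in place.

    Variants overlapping no transcript get class ``intergenic`` and no gene.
    """
    from .gene_model import ConsequenceCall, call_consequence

    index = _GeneIndex(models)
    for v in variants:
        model = index.lookup(v.chrom, v.pos)
        if model is None:
            v.annotations["gene"] = None
            v.annotations["consequence"] = ConsequenceCall("intergenic")
            continue
        v.annotations["gene"] = model.gene
        v.annotations["consequence"] = call_consequence(v, model, splice_window)


# ---------------------------------------------------------------------------
# Per-family cascade
# ---------------------------------------------------------------------------

@dataclass
class FamilyResult:
    pedigree: Pedigree
    trace: FilterTrace
    candidates: list[inh.InheritanceCandidate]
    roh_segments: list[roh_mod.ROHSegment]


def run_family(
    records: list[VariantRecord],
    pedigree: Pedigree,
    tables,
    models: Sequence[TranscriptModel],
    params: PipelineParams,
) -> FamilyResult:
    """Run the per-family stages of the cascade and return its candidates."""
    trace = FilterTrace(family_id=pedigree.family_id)
    trace.record("total_variants", len(records))

    rare, n_rare = flt.filter_rare(records, tables, params.filter_params)
    trace.record("after_maf", n_rare)

    annotate_gene_and_consequence(rare, models, params.splice_window)
    functional, n_func, dropped = flt.filter_functional(rare, params.filter_params)
    trace.record("after_functional", n_func)

    rescued: list[VariantRecord] = []
    if params.rescue_enabled:
        rescued = flt.apply_rescue_list(dropped, functional, pedigree)
        trace.rescued = len(rescued)

    pool = inh.filter_autosomal(functional + rescued)
    hom = inh.find_homozygous_recessive(pool, pedigree, params.strict_siblings)
    comp = inh.find_compound_het(inh.group_by_gene(pool), pedigree)
    candidates = hom + comp

    candidate_variants = {
        v.key for c in candidates for v in c.variants if not v.annotations.get("rescued")
    }
    trace.record("after_inheritance_autosomal", len(candidate_variants))
    trace.record("homozygous_only", len(hom))

    segments = roh_mod.detect_roh(roh_mod.proband_sites(records, pedigree), params.roh_params)
    candidates = roh_mod.annotate_in_roh(candidates, segments)
    trace.record("in_roh_gt2mb", sum(1 for c in hom if c.in_roh))

    return FamilyResult(pedigree=pedigree, trace=trace, candidates=candidates, roh_segments=segments)


# ---------------------------------------------------------------------------
# Cohort run
# ---------------------------------------------------------------------------

def run_pipeline(
    cohort_dir: str | Path,
    params: PipelineParams | None = None,
    out_dir: str | Path | None = None,
    clinical_path: str | Path | None = None,
) -> cr.CohortReport:
    """Execute the full cascade on a cohort directory.

    Expects the bundle layout the simulator writes: ``cohort.ped``, one
    ``<family_id>.vcf`` per family, ``freq_<db>.tsv`` tables,
    ``gene_models.tsv`` + ``cds.fa``, and ``expression.tsv``.  Identical
    inputs and params produce identical reports (no randomness anywhere in
    the analysis path).
    """
    cohort_dir = Path(cohort_dir)
    params = params or PipelineParams()

    pedigrees = read_ped(cohort_dir / "cohort.ped")
    if not pedigrees:
        raise ValueError(f"{cohort_dir}: empty pedigree file")
    tables = []
    for db in params.databases:
        path = cohort_dir / f"freq_{db}.tsv"
        if path.exists():
            tables.append(read_frequency_table(path, db))
        else:
            logger.warning("frequency table for %s not found at %s", db, path)
    models = load_gene_models(cohort_dir / "gene_models.tsv", cohort_dir / "cds.fa")
    expr = cr.read_expression_table(cohort_dir / "expression.tsv", tpm_min=params.tpm_min)

    report = cr.CohortReport()
    family_results: dict[str, FamilyResult] = {}
    for ped in pedigrees:
        vcf_path = cohort_dir / f"{ped.family_id}.vcf"
        records = read_vcf(vcf_path, family=ped)
        result = run_family(records, ped, tables, models, params)
        family_results[ped.family_id] = result
        report.family_traces[ped.family_id] = result.trace
        report.family_candidates[ped.family_id] = result.candidates
        report.family_genes[ped.family_id] = cr.candidate_genes(result.candidates)

    min_fams = min(params.min_families, len(pedigrees))
    if params.min_families > len(pedigrees):
        logger.warning(
            "min_families=%d exceeds cohort size %d; using %d",
            params.min_families, len(pedigrees), min_fams,
        )
    report.shared = cr.shared_genes(list(report.family_genes.values()), min_fams)
    report.expressed_shared = cr.expression_filter(report.shared, expr)

    all_candidates = [c for r in family_results.values() for c in r.candidates]
    expressed_any = cr.expression_filter(
        {c.gene for c in all_candidates if c.gene}, expr
    )
    ranked_pool = [c for c in all_candidates if c.gene in expressed_any]
    consang = {p.family_id for p in pedigrees if p.consanguineous}
    report.ranked = cr.rank_candidates(ranked_pool, report.expressed_shared, consang)

    if clinical_path is not None:
        clinical = cr.read_clinical_table(clinical_path)
        for ped in pedigrees:
            try:
                report.clinical_summaries.append(
                    cr.summarize_oocyte_outcomes(clinical, ped.family_id)
                )
            except KeyError:
                logger.warning("no clinical rows for family %s", ped.family_id)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        trace_rows = [row for ped in pedigrees for row in report.family_traces[ped.family_id].as_rows()]
        candidate_rows = [_candidate_row(c) for c in report.ranked]
        write_candidate_report(
            candidate_rows, trace_rows, out_dir / "report", databases=params.databases
        )
        for fam, result in family_results.items():
            write_roh_bed(result.roh_segments, out_dir / f"{fam}.roh.bed")
        _write_cohort_summary(report, out_dir / "cohort_summary.tsv")

    return report


def _candidate_row(c: inh.InheritanceCandidate) -> dict:
    v = c.variants[0]
    call = v.annotations.get("consequence")
    row = {
        "family_id": c.family_id,
        "gene": c.gene,
        "chrom": v.chrom,
        "pos": v.pos,
        "ref": v.ref,
        "alt": v.alt,
        "cdna_change": (call.cdna_change or "") if call else "",
        "protein_change": (call.protein_change or "") if call else "",
        "mutation_type": call.functional_class if call else "",
        "inheritance_model": c.model,
        "phase_status": c.phase_status,
        "in_roh": int(c.in_roh),
        "rescued": int(any(x.annotations.get("rescued", False) for x in c.variants)),
        "db_afs": v.annotations.get("db_afs", {}),
    }
    if c.model == "compound_het":
        def joined(attr):
            parts = []
            for x in c.variants:
                call2 = x.annotations.get("consequence")
                parts.append((getattr(call2, attr, None) or "-") if call2 else "-")
            return ";".join(parts)

        row["cdna_change"] = joined("cdna_change")
        row["protein_change"] = joined("protein_change")
        row["mutation_type"] = joined("functional_class")
    return row


def _write_cohort_summary(report: cr.CohortReport, path: Path) -> None:
    lines = ["section\tkey\tvalue"]
    for fam, genes in report.family_genes.items():
        lines.append(f"candidate_genes\t{fam}\t{','.join(sorted(genes))}")
    lines.append(f"shared_genes\tall\t{','.join(sorted(report.shared))}")
    lines.append(f"expressed_shared_genes\tall\t{','.join(sorted(report.expressed_shared))}")
    for i, c in enumerate(report.ranked, 1):
        lines.append(f"ranked\t{i}\t{c.gene}:{c.family_id}:{c.model}:{c.phase_status}")
    for summary in report.clinical_summaries:
        for k, v in summary.items():
            if k != "family_id":
                lines.append(f"clinical:{summary['family_id']}\t{k}\t{v}")
    path.write_text("\n".join(lines) + "\n")
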