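"""Cross-family stages: candidate-gene intersection, oocyte-expression
filtering, deterministic ranking, and clinical-outcome summarization."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .inheritance import InheritanceCandidate
from .io_formats import Pedigree, chrom_sort_key

logger = logging.getLogger("triocascade")


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

@dataclass
class ExpressionTable:
    """Gene x oocyte-stage TPM values; a gene is "expressed" when any stage
    reaches ``tpm_min`` (TPM >= 1 by default)."""

    entries: dict[str, dict[str, float]]
    tpm_min: float = 1.0

    def is_expressed(self, gene: str) -> bool | None:
        """True/False for genes in the table, None for unknown genes."""
        stages = self.entries.get(gene)
        if stages is None:
            return None
        return any(tpm >= self.tpm_min for tpm in stages.values())


def read_expression_table(path: str | Path, tpm_min: float = 1.0) -> ExpressionTable:
    """Read a long-format TSV with columns gene, stage, tpm."""
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "stage": str})
    entries: dict[str, dict[str, float]] = {}
    for gene, stage, tpm in zip(df["gene"], df["stage"], df["tpm"]):
        tpm = float(tpm)
        if tpm < 0:
            raise ValueError(f"{path}: negative TPM {tpm} for {gene}/{stage}")
        entries.setdefault(gene, {})[stage] = tpm
    return ExpressionTable(entries=entries, tpm_min=tpm_min)


def expression_filter(genes: set[str], expr: ExpressionTable) -> set[str]:
    """Keep genes expressed (TPM >= tpm_min in at least one stage).

    Genes absent from the table are dropped with a warning: the criterion
    demands positive evidence of oocyte expression, not merely no evidence
    against it."""
    kept = set()
    for gene in sorted(genes):
        status = expr.is_expressed(gene)
        if status is None:
            logger.warning("gene %s absent from expression table; dropped", gene)
        elif status:
            kept.add(gene)
    return kept


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def candidate_genes(candidates: Sequence[InheritanceCandidate]) -> set[str]:
    """Union of genes over homozygous-recessive and compound-het candidates."""
    return {c.gene for c in candidates if c.gene}


def shared_genes(family_gene_sets: Sequence[set[str]], min_families: int = 2) -> set[str]:
    """Genes recurring in at least ``min_families`` of the per-family sets.

    min_families=1 gives the union; min_families = number of families gives
    the intersection."""
    if min_families > len(family_gene_sets):
        raise ValueError(
            f"min_families={min_families} exceeds number of families {len(family_gene_sets)}"
        )
    counts: dict[str, int] = {}
    for genes in family_gene_sets:
        for g in genes:
            counts[g] = counts.get(g, 0) + 1
    return {g for g, n in counts.items() if n >= min_families}


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def rank_candidates(
    candidates: Sequence[InheritanceCandidate],
    shared: set[str],
    consanguineous_families: set[str],
) -> list[InheritanceCandidate]:
    """Deterministic total order over all families' candidates.

    Tiers: (1) shared-gene membership, then (2) homozygous-in-ROH in a
    consanguineous family, (3) homozygous, (4) trans-confirmed compound het,
    (5) phase-unknown compound het; ties broken by (gene, chrom, pos) so any
    permutation of the input yields the same list.
    """
    def tier(c: InheritanceCandidate) -> int:
        if c.model == "hom_recessive":
            if c.in_roh and c.family_id in consanguineous_families:
                return 0
            return 1
        return 2 if c.phase_status == "trans_confirmed" else 3

    def key(c: InheritanceCandidate):
        chrom, pos = c.sort_pos
        return (c.gene not in shared, tier(c), c.gene, chrom_sort_key(chrom), pos, c.family_id)

    return sorted(candidates, key=key)


# ---------------------------------------------------------------------------
# Clinical summarization
# ---------------------------------------------------------------------------

CLINICAL_COLUMNS = [
    "family_id", "cycle", "protocol", "total_retrieved", "gv", "mi", "pb1",
    "fertilized", "cleaved",
]
_COUNT_COLUMNS = ["total_retrieved", "gv", "mi", "pb1", "fertilized", "cleaved"]


@dataclass
class ClinicalOocyteTable:
    """Per-IVF-cycle oocyte outcome counts for each family."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(CLINICAL_COLUMNS) - set(self.rows.columns)
        if missing:
            raise ValueError(f"clinical table missing columns {sorted(missing)}")
        for col in _COUNT_COLUMNS:
            if (self.rows[col] < 0).any():
                raise ValueError(f"negative counts in column {col}")
        staged = self.rows["gv"] + self.rows["mi"] + self.rows["pb1"]
        if (staged > self.rows["total_retrieved"]).any():
            raise ValueError("gv + mi + pb1 exceeds total_retrieved in some row")


def read_clinical_table(path: str | Path) -> ClinicalOocyteTable:
    df = pd.read_csv(path, dtype={"family_id": str, "cycle": str, "protocol": str})
    return ClinicalOocyteTable(rows=df)


def summarize_oocyte_outcomes(table: ClinicalOocyteTable, family_id: str) -> dict:
    """Sum each count column over the family's cycles.

    ``mi_arrest_fraction`` (sum MI / sum retrieved) is derived reporting added
    by this artifact, not a published statistic; it is None when no oocytes
    were retrieved."""
    rows = table.rows[table.rows["family_id"] == family_id]
    if rows.empty:
        raise KeyError(f"no clinical rows for family {family_id}")
    totals = {col: int(rows[col].sum()) for col in _COUNT_COLUMNS}
    total = totals["total_retrieved"]
    return {
        "family_id": family_id,
        "n_cycles": len(rows),
        **totals,
        "mi_arrest_fraction": (totals["mi"] / total) if total > 0 else None,
    }


# ---------------------------------------------------------------------------
# Cohort report container
# ---------------------------------------------------------------------------

@dataclass
class CohortReport:
    """Everything the cascade produces for one cohort run."""

    family_traces: dict[str, "object"] = field(default_factory=dict)  # family -> FilterTrace
    family_candidates: dict[str, list[InheritanceCandidate]] = field(default_factory=dict)
    family_genes: dict[str, set[str]] = field(default_factory=dict)
    shared: set[str] = field(default_factory=set)
    expressed_shared: set[str] = field(default_factory=set)
    ranked: list[InheritanceCandidate] = field(default_factory=list)
    clinical_summaries: list[dict] = field(default_factory=list)
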