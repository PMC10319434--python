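"""Shared fixtures: toy transcript models, a clinical outcomes table, and a
small simulated cohort bundle reused across pipeline-level tests."""

from __future__ import annotations

import pytest

from triocascade import (
    PipelineParams,
    SimulationConfig,
    TranscriptModel,
    simulate_cohort,
)

CLINICAL_CSV = """\
family_id,cycle,protocol,total_retrieved,gv,mi,pb1,fertilized,cleaved
F1,1,IVF modified ultra-long,11,0,11,0,0,0
F1,2,IVF mild stimulation,6,1,5,0,0,0
F1,3,IVF PPOS,13,0,13,0,0,0
F2,1,IVF PPOS,9,0,9,0,0,0
F3,1,IVF natural,1,0,1,0,0,0
F3,2,IVF short,4,0,4,0,0,0
"""


@pytest.fixture
def clinical_csv(tmp_path):
    path = tmp_path / "clinical.csv"
    path.write_text(CLINICAL_CSV)
    return path


@pytest.fixture
def toy_plus_model():
    """Two-exon forward-strand transcript: coding 1..30 at genomic 101..130,
    intron 131..200, coding 31..60 at genomic 201..230."""
    cds = "ATG" + "GCT" * 18 + "TAA"
    return TranscriptModel(
        transcript_id="TOY+",
        gene="TOYGENE",
        chrom="chrT",
        strand="+",
        exons=[(101, 130), (201, 230)],
        cds_start=101,
        cds_end=230,
        cds_sequence=cds,
        utr3_sequence="TTAATTAATTAA",
    )


@pytest.fixture
def toy_minus_model():
    """Mirror-image reverse-strand transcript with the same genomic layout."""
    cds = "ATG" + "GGT" * 18 + "TGA"
    return TranscriptModel(
        transcript_id="TOY-",
        gene="TOYGENE2",
        chrom="chrT",
        strand="-",
        exons=[(101, 130), (201, 230)],
        cds_start=101,
        cds_end=230,
        cds_sequence=cds,
        utr3_sequence="TTAATTAATTAA",
    )


@pytest.fixture
def tiny_cds_model():
    """Single-exon 4-codon transcript with CDS ATG CGA TGG TAA."""
    return TranscriptModel(
        transcript_id="TINY",
        gene="TINYGENE",
        chrom="chrT",
        strand="+",
        exons=[(101, 112)],
        cds_start=101,
        cds_end=112,
        cds_sequence="ATGCGATGGTAA",
        utr3_sequence="TTAATTAATTAA",
    )


@pytest.fixture(scope="session")
def cohort_bundle(tmp_path_factory):
    """A three-family cohort (hom-in-ROH, comp-het, hom) with a shared
    planted causal gene, at reduced background scale."""
    out = tmp_path_factory.mktemp("cohort")
    config = SimulationConfig(seed=1, n_background_variants=2000)
    return simulate_cohort(config, out)


@pytest.fixture
def pipeline_params():
    return PipelineParams(min_families=3)
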