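"""Population-frequency and functional filters, and the intronic rescue."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from triocascade import (
    FilterParams,
    Pedigree,
    PedSample,
    VariantRecord,
    apply_rescue_list,
    filter_functional,
    filter_rare,
    genotype_call,
    max_observed_maf,
    parental_origin,
)
from triocascade.filters import UnclassifiedVariantError, could_be_trans
from triocascade.gene_model import ConsequenceCall
from triocascade.io_formats import ALT, MISSING, REF, FrequencyTable


def _table(db, entries):
    return FrequencyTable(db_name=db, entries=entries)


def _variant(pos=100, **annotations):
    v = VariantRecord(chrom="chr1", pos=pos, ref="A", alt="G")
    v.annotations.update(annotations)
    return v


KEY = ("1", 100, "A", "G")


class TestMaxObservedMaf:
    def test_single_database(self):
        v = _variant()
        maf = max_observed_maf(v, [_table("gnomAD", {KEY: 1.2e-5})])
        assert maf == pytest.approx(1.2e-5)

    def test_absent_everywhere_is_not_observed(self):
        v = _variant()
        tables = [_table(db, {}) for db in ("dbSNP", "1000g", "EVS", "ExAC", "gnomAD")]
        assert max_observed_maf(v, tables) is None

    def test_max_over_databases(self):
        v = _variant()
        tables = [_table("gnomAD", {KEY: 0.00355}), _table("dbSNP", {KEY: 0.002})]
        assert max_observed_maf(v, tables) == pytest.approx(0.00355)


class TestFilterRare:
    def test_matches_brute_force_on_simulated_afs(self):
        rng = np.random.default_rng(3)
        variants, entries = [], {}
        for i in range(1000):
            v = VariantRecord(chrom="chr1", pos=i + 1, ref="A", alt="G")
            variants.append(v)
            if rng.random() < 0.8:
                entries[("1", i + 1, "A", "G")] = float(rng.uniform(0, 0.05))
        tables = [_table("gnomAD", entries)]
        params = FilterParams(maf_threshold=0.01)
        kept, n = filter_rare(variants, tables, params)
        expected = {
            v.key for v in variants
            if ("1", v.pos, "A", "G") not in entries
            or entries[("1", v.pos, "A", "G")] < 0.01
        }
        assert {v.key for v in kept} == expected
        assert n == len(expected)

    def test_threshold_is_strict(self):
        v = _variant()
        kept, _ = filter_rare([v], [_table("g", {KEY: 0.01})], FilterParams())
        assert kept == []
        kept, _ = filter_rare([v], [_table("g", {KEY: 0.00999})], FilterParams())
        assert kept == [v]

    def test_commutes_with_functional_filter(self):
        rng = np.random.default_rng(4)
        classes = ["stopgain", "missense", "synonymous", "intronic", "UTR5"]
        variants, entries = [], {}
        for i in range(200):
            v = VariantRecord(chrom="chr1", pos=i + 1, ref="A", alt="G")
            v.annotations["consequence"] = ConsequenceCall(classes[rng.integers(0, 5)])
            variants.append(v)
            if rng.random() < 0.5:
                entries[("1", i + 1, "A", "G")] = float(rng.uniform(0, 0.05))
        tables = [_table("gnomAD", entries)]
        params = FilterParams()
        rare_first, _ = filter_rare(list(variants), tables, params)
        rare_then_func, _, _ = filter_functional(rare_first, params)
        func_first, _, _ = filter_functional(list(variants), params)
        func_then_rare, _ = filter_rare(func_first, tables, params)
        assert {v.key for v in rare_then_func} == {v.key for v in func_then_rare}


class TestFilterFunctional:
    @pytest.mark.parametrize(
        "cls,kept",
        [
            ("stopgain", True), ("missense", True), ("frameshift_deletion", True),
            ("frameshift_insertion", True), ("inframe_indel", True), ("splicing", True),
            ("synonymous", False), ("intronic", False), ("UTR5", False),
            ("UTR3", False), ("intergenic", False),
        ],
    )
    def test_class_membership(self, cls, kept):
        v = _variant(consequence=ConsequenceCall(cls))
        surviving, n, dropped = filter_functional([v], FilterParams())
        assert (v in surviving) is kept
        assert (v in dropped) is (not kept)

    def test_unclassified_variant_is_an_error(self):
        with pytest.raises(UnclassifiedVariantError, match="chr1:100"):
            filter_functional([_variant()], FilterParams())


def _trio(child_gt, father_gt, mother_gt, pos=100, gene="GENEX", cls="intronic"):
    v = VariantRecord(
        chrom="chr1", pos=pos, ref="A", alt="G",
        genotypes={
            "kid": genotype_call(*child_gt),
            "dad": genotype_call(*father_gt),
            "mom": genotype_call(*mother_gt),
        },
    )
    v.annotations["gene"] = gene
    v.annotations["consequence"] = ConsequenceCall(cls)
    return v


@pytest.fixture
def trio_ped():
    return Pedigree(
        family_id="FAM",
        samples=[
            PedSample("dad", None, None, "1", False),
            PedSample("mom", None, None, "2", False),
            PedSample("kid", "dad", "mom", "2", True),
        ],
    )


HET = (REF, ALT)
HOMREF = (REF, REF)
MISS = (MISSING, MISSING)


class TestRescue:
    def test_trans_partner_of_frameshift_is_rescued(self, trio_ped):
        fs = _trio(HET, HOMREF, HET, pos=50, cls="frameshift_deletion")
        intronic = _trio(HET, HET, HOMREF, pos=60, cls="intronic")
        rescued = apply_rescue_list([intronic], [fs], trio_ped)
        assert rescued == [intronic]
        assert intronic.annotations["rescued"] is True

    def test_gene_with_only_intronic_variants_rescues_nothing(self, trio_ped):
        a = _trio(HET, HET, HOMREF, pos=50, cls="intronic")
        b = _trio(HET, HOMREF, HET, pos=60, cls="intronic")
        assert apply_rescue_list([a, b], [], trio_ped) == []

    def test_origin_combination_enumeration(self, trio_ped):
        """Rescue decisions match direct enumeration over parental-origin
        combinations of the anchor and the dropped intronic variant."""
        origin_gts = {
            "father": (HET, HOMREF),
            "mother": (HOMREF, HET),
            "both": (HET, HET),
            "unknown": (MISS, HET),
        }
        for o_anchor, o_drop in itertools.product(origin_gts, repeat=2):
            fgt, mgt = origin_gts[o_anchor]
            anchor = _trio(HET, fgt, mgt, pos=50, cls="stopgain")
            fgt, mgt = origin_gts[o_drop]
            dropped = _trio(HET, fgt, mgt, pos=60, cls="intronic")
            rescued = apply_rescue_list([dropped], [anchor], trio_ped)
            oa = parental_origin(anchor, trio_ped, "kid")
            ob = parental_origin(dropped, trio_ped, "kid")
            assert (dropped in rescued) == could_be_trans(ob, oa), (o_anchor, o_drop)
        # same single parental origin is explicitly not a trans pair
        assert not could_be_trans("father", "father")
        assert could_be_trans("father", "mother")
        assert could_be_trans("unknown", "father")

    def test_missense_anchor_does_not_rescue(self, trio_ped):
        miss = _trio(HET, HOMREF, HET, pos=50, cls="missense")
        intronic = _trio(HET, HET, HOMREF, pos=60, cls="intronic")
        assert apply_rescue_list([intronic], [miss], trio_ped) == []

    def test_rescue_cannot_resurrect_maf_failures(self, trio_ped):
        """A common intronic variant is removed at the frequency stage and
        never reaches the functional-stage dropped list the rescue scans."""
        fs = _trio(HET, HOMREF, HET, pos=50, cls="frameshift_deletion")
        common = _trio(HET, HET, HOMREF, pos=60, cls="intronic")
        tables = [_table("gnomAD", {("1", 60, "A", "G"): 0.2})]
        params = FilterParams()
        rare, _ = filter_rare([fs, common], tables, params)
        surviving, _, dropped = filter_functional(rare, params)
        rescued = apply_rescue_list(dropped, surviving, trio_ped)
        assert common not in rescued
        assert dropped == []
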