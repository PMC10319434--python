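"""The cohort simulator: determinism, Mendelian consistency, the AF
spectrum, planted-scenario construction, and the truth-file round trip."""

from __future__ import annotations

import hashlib

import numpy as np
import pytest

from triocascade import (
    SimulationConfig,
    TruthRecord,
    load_truth,
    read_vcf,
    simulate_cohort,
    simulate_trio_genotypes,
    write_truth,
)
from triocascade.synthetic_cohort import (
    COMPHET_FRAMESHIFT_PLUS_INTRONIC,
    HOM_NONSENSE,
    HOM_NONSENSE_IN_ROH,
    NONE,
    ConfigError,
    TruthParseError,
)


def _dir_hashes(d):
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(d.iterdir()) if p.is_file()
    }


class TestDeterminism:
    def test_same_seed_byte_identical(self, tmp_path):
        config = SimulationConfig(seed=42, n_background_variants=500)
        b1 = simulate_cohort(config, tmp_path / "a")
        b2 = simulate_cohort(config, tmp_path / "b")
        assert _dir_hashes(b1.out_dir) == _dir_hashes(b2.out_dir)

    def test_different_seed_differs(self, tmp_path):
        a = simulate_cohort(SimulationConfig(seed=1, n_background_variants=500), tmp_path / "a")
        b = simulate_cohort(SimulationConfig(seed=2, n_background_variants=500), tmp_path / "b")
        assert _dir_hashes(a.out_dir) != _dir_hashes(b.out_dir)


class TestConfigValidation:
    def test_shared_gene_needs_two_planted_families(self):
        with pytest.raises(ConfigError):
            SimulationConfig(
                n_families=1, scenarios=(HOM_NONSENSE,), shared_causal_gene=True
            )

    def test_scenario_count_must_match(self):
        with pytest.raises(ConfigError):
            SimulationConfig(n_families=2, scenarios=(HOM_NONSENSE,))

    def test_af_fractions_must_sum_to_one(self):
        with pytest.raises(ConfigError):
            SimulationConfig(af_fraction_common=0.5, af_fraction_rare=0.1,
                             af_fraction_absent=0.1)


class TestTrioTransmission:
    def test_af_zero_all_hom_ref(self):
        rng = np.random.default_rng(0)
        out = simulate_trio_genotypes(np.zeros(100), rng)
        assert all(arr.sum() == 0 for arr in out.values())

    def test_af_one_all_hom_alt(self):
        rng = np.random.default_rng(0)
        out = simulate_trio_genotypes(np.ones(100), rng)
        assert all((arr == 1).all() for arr in out.values())

    def test_offspring_het_fraction_matches_mendelian_expectation(self):
        """Observed child het count sits within 3 SE of the closed-form
        expectation given the realized parental genotypes."""
        rng = np.random.default_rng(8)
        n = 10_000
        out = simulate_trio_genotypes(np.full(n, 0.3), rng)
        father, mother, child = out["father"], out["mother"], out["child"]
        # P(child het | parents) averaged over the four transmissions
        p_het = np.zeros(n)
        for i in range(2):
            for j in range(2):
                p_het += (father[:, i] != mother[:, j]) / 4
        expected = p_het.sum()
        se = np.sqrt((p_het * (1 - p_het)).sum())
        observed = (child.sum(axis=1) == 1).sum()
        assert abs(observed - expected) <= 3 * se

    def test_autozygous_sites_are_hom_and_consistent(self):
        rng = np.random.default_rng(9)
        n = 2000
        mask = np.zeros(n, dtype=bool)
        mask[500:1500] = True
        out = simulate_trio_genotypes(np.full(n, 0.3), rng, autozygous=mask)
        child = out["child"]
        assert (child[mask, 0] == child[mask, 1]).all()
        # the shared allele is carried by both parents
        assert (out["father"][mask, 0] == child[mask, 0]).all()
        assert (out["mother"][mask, 0] == child[mask, 0]).all()


def _mendelian_consistent(child, father, mother):
    ca = {child.allele_a, child.allele_b}
    fa = {father.allele_a, father.allele_b}
    ma = {mother.allele_a, mother.allele_b}
    if "MISSING" in ca | fa | ma:
        return True
    return (child.allele_a in fa and child.allele_b in ma) or (
        child.allele_a in ma and child.allele_b in fa
    )


class TestCohortBundle:
    def test_zero_mendelian_errors_at_full_missingness_zero(self, cohort_bundle):
        for ped in cohort_bundle.pedigrees:
            records = read_vcf(cohort_bundle.vcf_paths[ped.family_id], family=ped)
            child = ped.proband.sample_id
            father, mother = ped.parents_of(child)
            for v in records:
                assert _mendelian_consistent(
                    v.genotype(child), v.genotype(father), v.genotype(mother)
                ), v.key_str

    def test_hom_in_roh_scenario_construction(self, cohort_bundle):
        truth = {t.scenario: t for t in cohort_bundle.truth}
        t = truth[HOM_NONSENSE_IN_ROH]
        ped = next(p for p in cohort_bundle.pedigrees if p.family_id == t.family_id)
        assert ped.consanguineous
        records = read_vcf(cohort_bundle.vcf_paths[t.family_id], family=ped)
        by_key = {r.key_str: r for r in records}
        (key,) = t.variant_keys
        planted = by_key[key]
        child = ped.proband.sample_id
        father, mother = ped.parents_of(child)
        assert planted.genotype(child).zygosity == "hom_alt"
        assert planted.genotype(father).zygosity == "het"
        assert planted.genotype(mother).zygosity == "het"
        # the planted allele sits inside a long all-hom stretch
        chrom, pos = planted.chrom, planted.pos
        span_hom = [
            r.pos for r in records
            if r.chrom == chrom and abs(r.pos - pos) <= 1_000_000
            and r.genotype(child).zygosity in ("hom_ref", "hom_alt")
        ]
        span_het = [
            r.pos for r in records
            if r.chrom == chrom and abs(r.pos - pos) <= 1_000_000
            and r.genotype(child).zygosity == "het"
        ]
        assert len(span_hom) > 20
        assert span_het == []

    def test_comphet_scenario_construction(self, cohort_bundle):
        truth = {t.scenario: t for t in cohort_bundle.truth}
        t = truth[COMPHET_FRAMESHIFT_PLUS_INTRONIC]
        ped = next(p for p in cohort_bundle.pedigrees if p.family_id == t.family_id)
        records = {r.key_str: r for r in read_vcf(cohort_bundle.vcf_paths[t.family_id], family=ped)}
        fs_key, intr_key = t.variant_keys
        child = ped.proband.sample_id
        father, mother = ped.parents_of(child)
        fs, intr = records[fs_key], records[intr_key]
        assert fs.genotype(child).zygosity == intr.genotype(child).zygosity == "het"
        # opposite parental origins (in trans)
        assert fs.genotype(mother).has_alt() and not fs.genotype(father).has_alt()
        assert intr.genotype(father).has_alt() and not intr.genotype(mother).has_alt()
        assert len(fs.ref) - len(fs.alt) == 1  # 1-bp frameshift deletion

    def test_planted_variants_absent_or_rare_in_databases(self, cohort_bundle):
        import pandas as pd

        keys = {
            k for t in cohort_bundle.truth for k in t.variant_keys
        }
        for db, path in cohort_bundle.frequency_paths.items():
            df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
            db_keys = {
                f"{c}:{p}:{r}:{a}": af
                for c, p, r, a, af in zip(df.chrom, df.pos, df.ref, df.alt, df.af)
            }
            for key in keys:
                if key in db_keys:
                    assert db_keys[key] < 0.01  # catalogued planted alleles stay rare

    def test_causal_gene_expressed(self, cohort_bundle):
        from triocascade import read_expression_table

        expr = read_expression_table(cohort_bundle.expression_path)
        for t in cohort_bundle.truth:
            assert expr.is_expressed(t.causal_gene)


class TestTruthIO:
    RECORDS = [
        TruthRecord("F1", HOM_NONSENSE_IN_ROH, ("chr1:5:A:G",), "hom_recessive", True, "G1"),
        TruthRecord("F2", COMPHET_FRAMESHIFT_PLUS_INTRONIC,
                    ("chr1:9:CT:C", "chr1:20:G:A"), "compound_het", False, "G1"),
        TruthRecord("F3", NONE, (), "none", False, ""),
    ]

    def test_round_trip(self, tmp_path):
        path = tmp_path / "truth.tsv"
        write_truth(self.RECORDS, path)
        assert load_truth(path) == self.RECORDS

    def test_empty_truth_has_header(self, tmp_path):
        path = tmp_path / "truth.tsv"
        write_truth([], path)
        assert path.read_text().startswith("family_id\t")
        assert load_truth(path) == []

    def test_novel_chrom_preserved(self, tmp_path):
        rec = TruthRecord("F1", HOM_NONSENSE, ("weird_contig_7:12:A:T",), "hom_recessive", False, "G")
        path = tmp_path / "truth.tsv"
        write_truth([rec], path)
        assert load_truth(path)[0].variant_keys == ("weird_contig_7:12:A:T",)

    def test_malformed_key_rejected(self, tmp_path):
        path = tmp_path / "truth.tsv"
        path.write_text(
            "family_id\tscenario\tvariant_keys\texpected_model\texpected_in_roh\tcausal_gene\n"
            "F1\tHOM_NONSENSE\tchr1-5-A-G\thom_recessive\t0\tG\n"
        )
        with pytest.raises(TruthParseError):
            load_truth(path)
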