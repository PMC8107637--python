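from __future__ import annotations

import random

import pytest

from conftest import make_call, make_site
from founderhap.candidate_filter import (
    CIS_EXCLUDED,
    COMPOUND_HET_TRANS,
    COMPOUND_HET_UNRESOLVED,
    HET_PLUS_DELETION_HEMIZYGOUS,
    HOM_ALT,
    FilterConfig,
    assemble_biallelic,
    filter_rare,
)
from founderhap.io import DeletionCall, GenomicInterval, Individual, Pedigree


class TestFilterConfig:
    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            FilterConfig(maf_rare=0.01, maf_rare_exome=0.003)
        cfg = FilterConfig()
        assert cfg.maf_rare == 0.001 and cfg.maf_rare_exome == 0.003


class TestFilterRare:
    def test_threshold_and_class_semantics(self):
        cfg = FilterConfig()
        novel = make_site(10, af=0.0, consequence="missense")
        common = make_site(20, af=0.05, consequence="missense")
        unknown = make_site(30, af=None, consequence="stop_gain")
        silent = make_site(40, af=0.0, consequence="synonymous")
        kept = filter_rare([novel, common, unknown, silent], cfg)
        assert kept == [novel, unknown]

    def test_panel_gene_excluded(self):
        cfg = FilterConfig(panel_genes=frozenset({"OPA1"}))
        known = make_site(10, af=0.0, consequence="missense", gene="OPA1")
        target = make_site(20, af=0.0, consequence="missense", gene="FDXR")
        assert filter_rare([known, target], cfg) == [target]

    def test_matches_bruteforce_refilter_and_preserves_order(self):
        """filter_rare agrees with an independent per-site recheck on a
        random panel and keeps input order."""
        rng = random.Random(42)
        cfg = FilterConfig(panel_genes=frozenset({"PANEL"}))
        consequences = ["missense", "stop_gain", "synonymous", "intergenic"]
        sites = [
            make_site(
                100 + i,
                af=rng.choice([None, 0.0, 1e-5, 5e-4, 2e-3, 0.05]),
                consequence=rng.choice(consequences),
                gene=rng.choice(["FDXR", "PANEL", None]),
            )
            for i in range(20)
        ]
        kept = filter_rare(sites, cfg)
        expected = [
            s
            for s in sites
            if s.consequence in ("missense", "stop_gain")
            and (s.population_af is None or s.population_af < 0.001)
            and s.gene != "PANEL"
        ]
        assert kept == expected

    def test_idempotent(self):
        rng = random.Random(7)
        cfg = FilterConfig()
        sites = [
            make_site(
                100 + i,
                af=rng.choice([None, 0.0, 5e-4, 0.01]),
                consequence=rng.choice(["missense", "synonymous"]),
            )
            for i in range(30)
        ]
        once = filter_rare(sites, cfg)
        assert filter_rare(once, cfg) == once


def _trio_pedigree():
    return Pedigree(
        [
            Individual("dad", "F", sex=1),
            Individual("mum", "F", sex=2),
            Individual("kid", "F", father="dad", mother="mum", sex=1, affected=True),
        ]
    )


SITE_A = make_site(1000, af=0.0, consequence="missense", gene="FDXR")
SITE_B = make_site(2000, af=0.0, consequence="missense", gene="FDXR")


class TestAssembleBiallelic:
    def test_trans_forced_by_both_parents(self):
        ped = _trio_pedigree()
        calls = [
            make_call("kid", SITE_A, 0, 1),
            make_call("kid", SITE_B, 0, 1),
            make_call("dad", SITE_A, 0, 1),
            make_call("dad", SITE_B, 0, 0),
            make_call("mum", SITE_A, 0, 0),
            make_call("mum", SITE_B, 0, 1),
        ]
        result = assemble_biallelic(ped["kid"], calls, [], ped)
        assert [g.configuration for g in result.candidates] == [COMPOUND_HET_TRANS]
        assert result.candidates[0].evidence_grade == "parental"

    def test_cis_excluded_when_single_parent_carries_both(self):
        ped = Pedigree(
            [
                Individual("mum", "F", sex=2),
                Individual("kid", "F", mother="mum", sex=1, affected=True),
            ]
        )
        calls = [
            make_call("kid", SITE_A, 0, 1),
            make_call("kid", SITE_B, 0, 1),
            make_call("mum", SITE_A, 0, 1),
            make_call("mum", SITE_B, 0, 1),
        ]
        result = assemble_biallelic(ped["kid"], calls, [], ped)
        assert result.candidates == []
        assert [g.configuration for g in result.excluded] == [CIS_EXCLUDED]
        assert "single_parent_carries_both" in result.excluded[0].flags

    def test_hom_alt_emitted(self):
        ped = _trio_pedigree()
        calls = [
            make_call("kid", SITE_A, 1, 1),
            make_call("dad", SITE_A, 0, 1),
            make_call("mum", SITE_A, 0, 1),
        ]
        result = assemble_biallelic(ped["kid"], calls, [], ped)
        assert [g.configuration for g in result.candidates] == [HOM_ALT]

    def test_hemizygous_requires_overlap(self):
        ped = Pedigree([Individual("kid", "F", sex=1, affected=True)])
        inside = make_site(1500, af=0.0, consequence="missense", gene="FDXR")
        outside = make_site(5000, af=0.0, consequence="missense", gene="FDXR")
        deletion = DeletionCall("kid", GenomicInterval("chr17", 1000, 2000))
        calls = [make_call("kid", inside, 1, 1), make_call("kid", outside, 0, 1)]
        result = assemble_biallelic(ped["kid"], calls, [deletion], ped)
        configs = {g.configuration for g in result.candidates}
        assert HET_PLUS_DELETION_HEMIZYGOUS in configs
        hemi = next(
            g for g in result.candidates if g.configuration == HET_PLUS_DELETION_HEMIZYGOUS
        )
        assert hemi.allele_a.pos == 1500

    def test_depth_contradiction_warns(self):
        ped = Pedigree([Individual("kid", "F", sex=1, affected=True)])
        inside = make_site(1500, af=0.0, consequence="missense")
        deletion = DeletionCall("kid", GenomicInterval("chr17", 1000, 2000))
        calls = [make_call("kid", inside, 0, 1, depth=30, alt_depth=14)]
        with pytest.warns(UserWarning, match="copy loss"):
            assemble_biallelic(ped["kid"], calls, [deletion], ped)

    def test_sibling_carrying_one_allele_proves_trans(self):
        ped = Pedigree(
            [
                Individual("dad", "F", sex=1),
                Individual("mum", "F", sex=2),
                Individual("kid", "F", father="dad", mother="mum", affected=True),
                Individual("sib", "F", father="dad", mother="mum"),
            ]
        )
        calls = [
            make_call("kid", SITE_A, 0, 1),
            make_call("kid", SITE_B, 0, 1),
            make_call("sib", SITE_A, 0, 1),
            make_call("sib", SITE_B, 0, 0),
        ]
        result = assemble_biallelic(ped["kid"], calls, [], ped)
        assert [g.configuration for g in result.candidates] == [COMPOUND_HET_TRANS]
        assert result.candidates[0].evidence_grade == "sibling"

    def test_no_relatives_yields_unresolved_with_unavailable_grade(self):
        ped = Pedigree([Individual("kid", "F", sex=2, affected=True)])
        calls = [make_call("kid", SITE_A, 0, 1), make_call("kid", SITE_B, 0, 1)]
        result = assemble_biallelic(ped["kid"], calls, [], ped)
        assert [g.configuration for g in result.candidates] == [COMPOUND_HET_UNRESOLVED]
        assert result.candidates[0].evidence_grade == "unavailable"


class TestCohortTableConfigurations:
    def test_all_families_reproduce_reported_configurations(self, cohort):
        """The assembled genotypes match the cohort table: every family is
        biallelic-trans except the hemizygous-deletion family and the one
        where segregation was impossible."""
        configs: dict[str, set[str]] = {}
        grades: dict[str, set[str]] = {}
        for family, probands in cohort.probands.items():
            for pid in probands:
                result = assemble_biallelic(
                    cohort.pedigree[pid], cohort.calls, cohort.deletions, cohort.pedigree
                )
                assert result.excluded == []
                for g in result.candidates:
                    configs.setdefault(family, set()).add(g.configuration)
                    grades.setdefault(family, set()).add(g.evidence_grade)
        trans_families = {f for f, c in configs.items() if c == {COMPOUND_HET_TRANS}}
        assert trans_families == {
            "family_1",
            "family_2",
            "family_3",
            "family_4",
            "family_5",
            "family_7",
        }
        assert configs["family_6"] == {HET_PLUS_DELETION_HEMIZYGOUS}
        assert configs["family_8"] == {COMPOUND_HET_UNRESOLVED}
        assert grades["family_8"] == {"unavailable"}
        assert grades["family_5"] == {"sibling"}

    def test_trans_pairs_never_contradict_phase_oracle(self, cohort):
        """Every emitted trans pair admits a Mendelian-consistent assignment
        placing the two alleles on different parental chromosomes."""
        from _oracles import enumerate_trio_phase

        calls_by = {(c.sample, c.site.key): c for c in cohort.calls}
        for family, probands in cohort.probands.items():
            for pid in probands:
                result = assemble_biallelic(
                    cohort.pedigree[pid], cohort.calls, cohort.deletions, cohort.pedigree
                )
                for g in result.candidates:
                    if g.configuration != "compound_het_trans":
                        continue
                    father = cohort.pedigree.father_of(pid)
                    mother = cohort.pedigree.mother_of(pid)

                    def geno(person, site):
                        if person is None:
                            return None
                        call = calls_by.get((person.id, site.key))
                        return call.alleles if call else None

                    sols_a = enumerate_trio_phase(
                        (0, 1), geno(father, g.allele_a), geno(mother, g.allele_a)
                    )
                    sols_b = enumerate_trio_phase(
                        (0, 1), geno(father, g.allele_b), geno(mother, g.allele_b)
                    )
                    # some assignment puts alt of a and alt of b on opposite sides
                    assert any(
                        (1, 0) == sa and (0, 1) == sb or (0, 1) == sa and (1, 0) == sb
                        for sa in sols_a
                        for sb in sols_b
                    )
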