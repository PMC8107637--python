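from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import enumerate_trio_phase
from conftest import make_call, make_site
from founderhap.io import DeletionCall, GenomicInterval
from founderhap.phasing import (
    HEMIZYGOUS_ANCHOR,
    HOMOZYGOUS,
    MENDEL_CONFLICT,
    UNRESOLVED,
    AnchorError,
    PhaseConfig,
    anchor_hemizygous,
    build_carrier_haplotypes,
    resolve_trio_site,
    select_informative,
)


class TestPhaseConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            PhaseConfig(window_bp=0)
        with pytest.raises(ValueError):
            PhaseConfig(maf_informative=1.0)


GENE = GenomicInterval("chr17", 500_000, 520_000)
INDEX = make_site(510_000, af=1e-5, ref="C", alt="A")


def _freq(sites):
    return {s.key: s.population_af for s in sites if s.population_af is not None}


class TestSelectInformative:
    def test_window_boundary_is_inclusive(self):
        cfg = PhaseConfig(window_bp=1000)
        at_edge = make_site(GENE.end + 1000, af=0.01)
        beyond = make_site(GENE.end + 1001, af=0.01)
        sites = [INDEX, at_edge, beyond]
        kept = select_informative(sites, _freq(sites), cfg, GENE, INDEX)
        assert at_edge in kept and beyond not in kept

    def test_af_threshold_is_strict(self):
        cfg = PhaseConfig()
        rare = make_site(505_000, af=0.09)
        common = make_site(506_000, af=0.11)
        sites = [INDEX, rare, common]
        kept = select_informative(sites, _freq(sites), cfg, GENE, INDEX)
        assert rare in kept and common not in kept

    def test_index_always_included_and_unknown_af_excluded(self):
        cfg = PhaseConfig()
        unknown = make_site(505_000)
        index_common = make_site(
            510_000, af=0.5, ref="C", alt="A"
        )  # index retained regardless of af
        sites = [index_common, unknown]
        kept = select_informative(sites, {}, cfg, GENE, index_common)
        assert kept == [index_common]

    def test_bruteforce_refilter_sorted(self):
        rng = random.Random(3)
        cfg = PhaseConfig()
        sites = [
            make_site(
                GENE.start - 140_000 + 7000 * i,
                af=rng.choice([0.01, 0.05, 0.2, 0.4]),
            )
            for i in range(40)
        ]
        sites = [s for s in sites if s.pos != INDEX.pos]
        kept = select_informative(sites + [INDEX], _freq(sites + [INDEX]), cfg, GENE, INDEX)
        expected = sorted(
            [s for s in sites if s.population_af < 0.1] + [INDEX], key=lambda s: s.pos
        )
        assert kept == expected

    def test_warns_when_only_index_survives(self):
        cfg = PhaseConfig()
        with pytest.warns(UserWarning, match="informative"):
            select_informative([INDEX], {}, cfg, GENE, INDEX)


SITE = make_site(1000)


def _phase(child, father, mother):
    return resolve_trio_site(
        make_call("c", SITE, *child) if child else None,
        make_call("f", SITE, *father) if father else None,
        make_call("m", SITE, *mother) if mother else None,
    )


class TestResolveTrioSite:
    def test_forced_maternal(self):
        p = _phase((0, 1), (0, 0), (0, 1))
        assert p.status == "resolved" and (p.paternal, p.maternal) == (0, 1)

    def test_all_het_unresolved(self):
        assert _phase((0, 1), (0, 1), (0, 1)).status == UNRESOLVED

    def test_missing_parent_leaves_het_unresolved(self):
        assert _phase((0, 1), None, (0, 1)).status == UNRESOLVED

    def test_single_parent_can_force(self):
        # mother cannot transmit alt, so alt must be paternal
        p = _phase((0, 1), None, (0, 0))
        assert p.status == "resolved" and p.paternal == 1

    def test_homozygous_always_resolved(self):
        p = _phase((1, 1), None, None)
        assert p.status == HOMOZYGOUS and (p.paternal, p.maternal) == (1, 1)

    def test_mendel_conflict_flagged(self):
        assert _phase((1, 1), (0, 0), (0, 1)).status == MENDEL_CONFLICT

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_transmission_enumeration_oracle(self, data):
        """On error-free trios the assignment equals exhaustive enumeration
        of Mendelian-consistent transmissions at every site."""
        genotype = st.tuples(st.integers(0, 1), st.integers(0, 1))
        father = data.draw(st.one_of(st.none(), genotype))
        mother = data.draw(st.one_of(st.none(), genotype))
        # child inherits one allele from each (unavailable parent: free draw)
        pat = data.draw(st.sampled_from(father)) if father else data.draw(st.integers(0, 1))
        mat = data.draw(st.sampled_from(mother)) if mother else data.draw(st.integers(0, 1))
        child = (pat, mat) if data.draw(st.booleans()) else (mat, pat)

        result = _phase(child, father, mother)
        sols = enumerate_trio_phase(child, father, mother)
        assert sols, "construction guarantees consistency"
        if child[0] == child[1]:
            assert result.status == HOMOZYGOUS
        elif len(sols) == 1:
            assert result.status == "resolved"
            assert (result.paternal, result.maternal) == next(iter(sols))
        else:
            assert result.status == UNRESOLVED


DELETION = DeletionCall("kid", GenomicInterval("chr17", 74_818_633, 74_888_183))
DEL_INDEX = make_site(74_864_337, ref="C", alt="A")


class TestAnchorHemizygous:
    def test_sites_inside_deletion_are_anchored(self):
        inside = make_site(74_820_000)
        edge = make_site(74_888_183)
        beyond = make_site(74_888_184)
        sites = sorted([inside, edge, beyond, DEL_INDEX], key=lambda s: s.pos)
        calls = [
            make_call("kid", DEL_INDEX, 1, 1),
            make_call("kid", inside, 1, 1),
            make_call("kid", edge, 0, 0),
            make_call("kid", beyond, 0, 1),
        ]
        hap = anchor_hemizygous(calls, DELETION, sites, DEL_INDEX, individual="kid")
        by_pos = dict(zip(hap.sites, zip(hap.alleles, hap.origin)))
        assert by_pos[74_820_000] == (1, HEMIZYGOUS_ANCHOR)
        assert by_pos[74_888_183] == (0, HEMIZYGOUS_ANCHOR)  # interval end inclusive
        assert by_pos[74_888_184] == (None, UNRESOLVED)  # 1 bp beyond: not anchored

    def test_refuses_index_outside_deletion(self):
        index_outside = make_site(74_900_000, ref="C", alt="A")
        calls = [make_call("kid", index_outside, 0, 1)]
        with pytest.raises(AnchorError, match="outside the deletion"):
            anchor_hemizygous(calls, DELETION, [index_outside], index_outside)

    def test_refuses_non_carrier(self):
        calls = [make_call("kid", DEL_INDEX, 0, 0)]
        with pytest.raises(AnchorError, match="does not carry"):
            anchor_hemizygous(calls, DELETION, [DEL_INDEX], DEL_INDEX)

    def test_anchored_haplotype_matches_planted_founder(self, sim_paper):
        """In the simulated deletion family, every anchored site reproduces
        the generator's founder allele."""
        cfg, res = sim_paper
        informative = select_informative(
            res.sites, res.frequencies, PhaseConfig(), cfg.gene, res.index_site
        )
        haps = build_carrier_haplotypes(
            informative, res.calls, res.pedigree, res.deletions, res.index_site
        )
        hap = next(h for h in haps if h.family == "FAM4")
        founder = dict(zip(res.truth.positions, res.truth.founder_alleles))
        anchored = [
            (pos, allele)
            for pos, allele, origin in zip(hap.sites, hap.alleles, hap.origin)
            if origin == HEMIZYGOUS_ANCHOR
        ]
        assert len(anchored) >= 5
        assert all(founder[pos] == allele for pos, allele in anchored)

    def test_anchoring_resolves_superset_of_segregation(self, sim_paper):
        """Inside the deletion, anchoring resolves at least the sites plain
        segregation would (the deletion family is a singleton: segregation
        alone resolves only homozygous sites)."""
        cfg, res = sim_paper
        informative = select_informative(
            res.sites, res.frequencies, PhaseConfig(), cfg.gene, res.index_site
        )
        sample_calls = [c for c in res.calls if c.sample == "FAM4_II1"]
        hap = anchor_hemizygous(
            sample_calls, res.deletions[0], informative, res.index_site, individual="FAM4_II1"
        )
        by_key = {c.site.key: c for c in sample_calls}
        for site, allele in zip(informative, hap.alleles):
            if not res.deletions[0].interval.contains(site.chrom, site.pos):
                continue
            call = by_key.get(site.key)
            if call is not None and not call.is_missing:
                seg_resolves = call.alleles[0] == call.alleles[1]
                if seg_resolves:
                    assert allele == call.alleles[0]
                assert allele is not None  # anchored even where segregation fails


class TestBuildCarrierHaplotypes:
    def test_sibs_sharing_transmission_merge_to_one_haplotype(self, sim_paper):
        cfg, res = sim_paper
        informative = select_informative(
            res.sites, res.frequencies, PhaseConfig(), cfg.gene, res.index_site
        )
        haps = build_carrier_haplotypes(
            informative, res.calls, res.pedigree, res.deletions, res.index_site
        )
        fam1 = [h for h in haps if h.family == "FAM1"]
        assert len(fam1) == 1  # two affected sibs, one transmitted chromosome
        assert "FAM1_II1" in fam1[0].individual and "FAM1_II2" in fam1[0].individual

    def test_one_haplotype_per_carrier_family(self, sim_paper):
        cfg, res = sim_paper
        informative = select_informative(
            res.sites, res.frequencies, PhaseConfig(), cfg.gene, res.index_site
        )
        haps = build_carrier_haplotypes(
            informative, res.calls, res.pedigree, res.deletions, res.index_site
        )
        assert sorted(h.family for h in haps) == ["FAM1", "FAM2", "FAM3", "FAM4", "FAM5"]

    def test_resolved_sites_match_truth_inside_segments(self, sim_paper):
        """At error rate 0, every resolved allele inside a family's
        transmitted founder segment equals the founder allele."""
        cfg, res = sim_paper
        informative = select_informative(
            res.sites, res.frequencies, PhaseConfig(), cfg.gene, res.index_site
        )
        haps = build_carrier_haplotypes(
            informative, res.calls, res.pedigree, res.deletions, res.index_site
        )
        founder = dict(zip(res.truth.positions, res.truth.founder_alleles))
        for hap in haps:
            seg = res.truth.families[hap.family].segment
            for pos, allele in zip(hap.sites, hap.alleles):
                if allele is None or not (seg[0] <= pos <= seg[1]):
                    continue
                assert allele == founder[pos], (hap.family, pos)

    def test_singleton_resolves_only_hom_sites_plus_index(self, sim_paper):
        cfg, res = sim_paper
        informative = select_informative(
            res.sites, res.frequencies, PhaseConfig(), cfg.gene, res.index_site
        )
        haps = build_carrier_haplotypes(
            informative, res.calls, res.pedigree, res.deletions, res.index_site
        )
        solo = next(h for h in haps if h.family == "FAM5")
        calls = {c.site.pos: c for c in res.calls if c.sample == "FAM5_II1"}
        for pos, allele, origin in zip(solo.sites, solo.alleles, solo.origin):
            if pos == res.index_site.pos:
                assert allele == 1
            elif calls[pos].alleles[0] == calls[pos].alleles[1]:
                assert origin == HOMOZYGOUS and allele == calls[pos].alleles[0]
            else:
                assert allele is None

    def test_index_site_carries_alt_on_every_haplotype(self, sim_paper):
        cfg, res = sim_paper
        informative = select_informative(
            res.sites, res.frequencies, PhaseConfig(), cfg.gene, res.index_site
        )
        haps = build_carrier_haplotypes(
            informative, res.calls, res.pedigree, res.deletions, res.index_site
        )
        idx = [s.pos for s in informative].index(res.index_site.pos)
        assert all(h.alleles[idx] == 1 for h in haps)
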