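"""Inheritance searches against enumeration oracles and rule examples."""

import itertools

import numpy as np
import pytest

from crevar.inheritance import (
    apply_cohort_exclusion,
    call_de_novo,
    find_compound_het,
    find_de_novo,
    find_dominant,
    find_homozygous_recessive,
)
from crevar.intervals import GenomicInterval
from crevar.pedigree import Individual, Pedigree, read_ped, write_ped
from crevar.variants import Genotype

from conftest import make_variant

CALLS = ("hom_ref", "het", "hom_alt", "missing")


def G(call, gq=60.0, ad=None):
    if ad is None:
        ad = {"hom_ref": (30, 0), "het": (15, 15), "hom_alt": (0, 30),
              "missing": (0, 0)}[call]
    return Genotype(call, gq, ad)


class TestDeNovoCaller:
    def test_clean_de_novo(self):
        assert call_de_novo(G("het", 50.0, (16, 14)), G("hom_ref", 60.0),
                            G("hom_ref", 60.0))

    def test_carrier_parent_blocks(self):
        assert not call_de_novo(G("het"), G("het"), G("hom_ref"))

    def test_missing_parent_blocks(self):
        assert not call_de_novo(G("het"), G("hom_ref"), G("missing"))

    def test_rule_table_over_all_trio_configurations(self):
        """Enumerate all 4^3 genotype-call combinations against the rule."""
        for c, f, m in itertools.product(CALLS, repeat=3):
            got = call_de_novo(G(c), G(f), G(m))
            expected = (c == "het" and f == "hom_ref" and m == "hom_ref")
            assert got == expected, (c, f, m)

    def test_quality_gates(self):
        assert not call_de_novo(G("het", 10.0), G("hom_ref"), G("hom_ref"))
        assert not call_de_novo(G("het"), G("hom_ref", 10.0), G("hom_ref"))
        # child allele balance below the het gate
        assert not call_de_novo(G("het", 60.0, (29, 1)), G("hom_ref"),
                                G("hom_ref"))


def quartet(affected_ids, fam="Q1"):
    """Parents + two children; affected per the id list."""
    inds = [
        Individual("fa", None, None, 1, "fa" in affected_ids),
        Individual("mo", None, None, 2, "mo" in affected_ids),
        Individual("c1", "fa", "mo", 1, "c1" in affected_ids),
        Individual("c2", "fa", "mo", 2, "c2" in affected_ids),
    ]
    return Pedigree(fam, {i.individual_id: i for i in inds})


class TestDominant:
    def test_segregating_dominant_nominated(self):
        ped = quartet({"fa", "c1"})
        v = make_variant(gts={"fa": "het", "mo": "hom_ref", "c1": "het",
                              "c2": "hom_ref"})
        assert len(find_dominant(ped, [v])) == 1

    def test_unaffected_carrier_blocks_unless_incomplete_penetrance(self):
        ped = quartet({"fa", "c1"})
        v = make_variant(gts={"fa": "het", "mo": "hom_ref", "c1": "het",
                              "c2": "het"})
        assert find_dominant(ped, [v]) == []
        calls = find_dominant(ped, [v], incomplete_penetrance=True)
        assert len(calls) == 1
        assert calls[0].mode == "dominant_incomplete_penetrance"

    def test_noncarrier_affected_blocks(self):
        ped = quartet({"fa", "c1"})
        v = make_variant(gts={"fa": "het", "mo": "hom_ref", "c1": "hom_ref",
                              "c2": "hom_ref"})
        assert find_dominant(ped, [v]) == []


class TestRecessive:
    def test_classic_trio_pattern(self, trio):
        v = make_variant(gts={"fa": "het", "mo": "het", "ch": "hom_alt"})
        assert len(find_homozygous_recessive(trio, [v])) == 1

    def test_homref_parent_inconsistent(self, trio):
        v = make_variant(gts={"fa": "hom_ref", "mo": "het", "ch": "hom_alt"})
        assert find_homozygous_recessive(trio, [v]) == []

    def test_unaffected_homozygote_blocks(self):
        ped = quartet({"c1"})
        v = make_variant(gts={"fa": "het", "mo": "het", "c1": "hom_alt",
                              "c2": "hom_alt"})
        assert find_homozygous_recessive(ped, [v]) == []


class TestCompoundHet:
    PEAK_A = GenomicInterval("chr1", 100, 600)
    PEAK_B = GenomicInterval("chr1", 5000, 5500)

    def test_trans_pair_in_same_peak(self, trio):
        v1 = make_variant(pos=150, gts={"fa": "het", "mo": "hom_ref", "ch": "het"})
        v2 = make_variant(pos=300, ref="G", alt="C",
                          gts={"fa": "hom_ref", "mo": "het", "ch": "het"})
        peaks = {v1.key: self.PEAK_A, v2.key: self.PEAK_A}
        calls = find_compound_het(trio, [v1, v2], peaks)
        assert len(calls) == 1
        assert calls[0].variant.key == v1.key
        assert calls[0].partner_variant.key == v2.key
        assert calls[0].supporting_peak == self.PEAK_A

    def test_different_peaks_do_not_pair(self, trio):
        v1 = make_variant(pos=150, gts={"fa": "het", "mo": "hom_ref", "ch": "het"})
        v2 = make_variant(pos=5100, ref="G", alt="C",
                          gts={"fa": "hom_ref", "mo": "het", "ch": "het"})
        peaks = {v1.key: self.PEAK_A, v2.key: self.PEAK_B}
        assert find_compound_het(trio, [v1, v2], peaks) == []

    def test_both_from_one_parent_do_not_pair(self, trio):
        v1 = make_variant(pos=150, gts={"fa": "het", "mo": "hom_ref", "ch": "het"})
        v2 = make_variant(pos=300, ref="G", alt="C",
                          gts={"fa": "het", "mo": "hom_ref", "ch": "het"})
        peaks = {v1.key: self.PEAK_A, v2.key: self.PEAK_A}
        assert find_compound_het(trio, [v1, v2], peaks) == []

    def test_ambiguous_origin_skipped_with_warning(self, trio):
        v1 = make_variant(pos=150, gts={"fa": "het", "mo": "het", "ch": "het"})
        v2 = make_variant(pos=300, ref="G", alt="C",
                          gts={"fa": "hom_ref", "mo": "het", "ch": "het"})
        peaks = {v1.key: self.PEAK_A, v2.key: self.PEAK_A}
        with pytest.warns(UserWarning, match="ambiguous"):
            assert find_compound_het(trio, [v1, v2], peaks) == []

    def test_affected_parent_disqualifies_trio(self):
        inds = [Individual("fa", None, None, 1, True),
                Individual("mo", None, None, 2, False),
                Individual("ch", "fa", "mo", 1, True)]
        ped = Pedigree("F", {i.individual_id: i for i in inds})
        v1 = make_variant(pos=150, gts={"fa": "het", "mo": "hom_ref", "ch": "het"})
        v2 = make_variant(pos=300, ref="G", alt="C",
                          gts={"fa": "hom_ref", "mo": "het", "ch": "het"})
        peaks = {v1.key: self.PEAK_A, v2.key: self.PEAK_A}
        assert find_compound_het(ped, [v1, v2], peaks) == []


class TestCohortExclusion:
    def _dominant_call(self, trio, carrier_gts):
        v = make_variant(gts=carrier_gts)
        calls = find_de_novo(trio, [v])
        assert calls
        return calls, {v.key: v}

    def test_unrelated_het_carrier_excludes_dominant(self, trio):
        gts = {"fa": "hom_ref", "mo": "hom_ref", "ch": "het", "x1": "het"}
        calls, vmap = self._dominant_call(trio, gts)
        kept = apply_cohort_exclusion(calls, vmap, {"FAM1": ["fa", "mo"],
                                                    "OTHER": ["x1"]})
        assert kept == []

    def test_het_carrier_does_not_exclude_recessive(self, trio):
        v = make_variant(gts={"fa": "het", "mo": "het", "ch": "hom_alt",
                              "x1": "het"})
        calls = find_homozygous_recessive(trio, [v])
        kept = apply_cohort_exclusion(calls, {v.key: v},
                                      {"FAM1": ["fa", "mo"], "OTHER": ["x1"]})
        assert len(kept) == 1

    def test_homozygous_carrier_excludes_recessive(self, trio):
        v = make_variant(gts={"fa": "het", "mo": "het", "ch": "hom_alt",
                              "x1": "hom_alt"})
        calls = find_homozygous_recessive(trio, [v])
        kept = apply_cohort_exclusion(calls, {v.key: v},
                                      {"FAM1": ["fa", "mo"], "OTHER": ["x1"]})
        assert kept == []

    def test_incomplete_penetrance_family_exempt_from_own_carriers(self):
        ped = quartet({"fa", "c1"})
        v = make_variant(gts={"fa": "het", "mo": "hom_ref", "c1": "het",
                              "c2": "het"})
        calls = find_dominant(ped, [v], incomplete_penetrance=True)
        kept = apply_cohort_exclusion(calls, {v.key: v}, {"Q1": ["mo", "c2"]},
                                      incomplete_penetrance_families={"Q1"})
        assert len(kept) == 1
        # but an unrelated carrier still excludes
        v2 = make_variant(ref="G", alt="C",
                          gts={"fa": "het", "mo": "hom_ref", "c1": "het",
                               "c2": "hom_ref", "x1": "het"})
        calls2 = find_dominant(ped, [v2], incomplete_penetrance=True)
        kept2 = apply_cohort_exclusion(calls2, {v2.key: v2},
                                       {"Q1": ["mo", "c2"], "O": ["x1"]},
                                       incomplete_penetrance_families={"Q1"})
        assert kept2 == []


# ---------------------------------------------------------------------------
# brute-force oracle on random pedigrees


def _oracle_modes(ped, v):
    """Definition-level re-derivation of the nomination rules."""
    gt = {s: v.genotypes.get(s, Genotype("missing")) for s in ped.members}
    aff = [i.individual_id for i in ped.affected]
    unaff = [i.individual_id for i in ped.unaffected]

    def ok(s):
        g = gt[s]
        if g.call == "missing" or g.gq <= 20:
            return False
        if g.call == "het":
            tot = sum(g.ad)
            if tot == 0 or g.ad[1] / tot <= 0.15:
                return False
        return True

    modes = set()
    # de novo: any affected child of a full trio
    for ind in ped.members.values():
        if not ind.affected or not (ind.father_id and ind.mother_id):
            continue
        c, f, m = ind.individual_id, ind.father_id, ind.mother_id
        if (gt[c].call == "het" and ok(c) and gt[f].call == "hom_ref" and ok(f)
                and gt[m].call == "hom_ref" and ok(m)):
            modes.add("de_novo")
    carriers_ok = all(gt[s].call in ("het", "hom_alt") and ok(s) for s in aff)
    if carriers_ok and not any(gt[s].call in ("het", "hom_alt") for s in unaff):
        modes.add("dominant")
    if all(gt[s].call == "hom_alt" and ok(s) for s in aff):
        if not any(gt[s].call == "hom_alt" for s in unaff):
            consistent = True
            for s in aff:
                ind = ped.members[s]
                for pid in (ind.father_id, ind.mother_id):
                    if pid is None:
                        continue
                    if gt[pid].call == "hom_ref":
                        consistent = False
                    elif gt[pid].call != "missing" and not ok(pid):
                        consistent = False
            if consistent:
                modes.add("homozygous_recessive")
    return modes


def _random_pedigree(rng, idx):
    """Random <=6-member two-generation family with >=1 affected."""
    n_children = int(rng.integers(1, 5))
    aff = set()
    ids = ["fa", "mo"] + [f"c{i}" for i in range(n_children)]
    while not aff:
        aff = {s for s in ids if rng.random() < 0.4}
    inds = [Individual("fa", None, None, 1, "fa" in aff),
            Individual("mo", None, None, 2, "mo" in aff)]
    for i in range(n_children):
        inds.append(Individual(f"c{i}", "fa", "mo", 1, f"c{i}" in aff))
    return Pedigree(f"R{idx}", {i.individual_id: i for i in inds})


def test_engine_matches_oracle_on_random_pedigrees(rng):
    """1000 random <=6-member pedigrees x random genotypes vs the oracle."""
    for i in range(1000):
        ped = _random_pedigree(rng, i)
        gts = {s: G(CALLS[int(rng.integers(4))]) for s in ped.members}
        v = make_variant(gts=gts)
        got = set()
        if find_de_novo(ped, [v]):
            got.add("de_novo")
        if find_dominant(ped, [v]):
            got.add("dominant")
        if find_homozygous_recessive(ped, [v]):
            got.add("homozygous_recessive")
        assert got == _oracle_modes(ped, v), (i, gts)


def test_de_novo_and_recessive_outputs_disjoint(rng):
    """A de novo call (affected child het) is incompatible with a
    homozygous-recessive call (every affected hom_alt) on one variant."""
    for i in range(300):
        ped = _random_pedigree(rng, i)
        gts = {s: G(CALLS[int(rng.integers(3))]) for s in ped.members}
        v = make_variant(gts=gts)
        dn = bool(find_de_novo(ped, [v]))
        rec = bool(find_homozygous_recessive(ped, [v]))
        assert not (dn and rec)


def test_ped_roundtrip(tmp_path, trio):
    write_ped([trio], tmp_path / "f.ped", tmp_path / "fams.tsv")
    back = read_ped(tmp_path / "f.ped", tmp_path / "fams.tsv")
    assert len(back) == 1
    ped = back[0]
    assert ped.disease_group == "DRS"
    assert ped.members["ch"].father_id == "fa"
    assert ped.members["ch"].affected
    assert not ped.members["mo"].affected
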