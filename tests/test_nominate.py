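"""Candidate nomination pipeline, multi-hit aggregation, and effect scores."""

import itertools

import numpy as np
import pytest
from scipy.special import comb

from crevar.inheritance import CandidateCall
from crevar.intervals import DiseaseMap, GenomicInterval, PeakAtlas
from crevar.links import PeakGeneLink
from crevar.nominate import (
    EffectScore,
    NominationConfig,
    find_multihit_genes,
    find_multihit_peaks,
    fisher_exact_2x2,
    nominate_candidates,
    sad_zscores,
    summarize_validation,
)
from crevar.simulate import DEFAULT_DISEASE_MAP, SimConfig, simulate_cohort, simulate_peak_atlas

from conftest import make_variant


def I(s, e, c="chr1"):
    return GenomicInterval(c, s, e)


def _cohort(seed, **kw):
    cfg = SimConfig(seed=seed, n_background_variants=kw.pop("n_background", 80),
                    **kw)
    atlas = simulate_peak_atlas(cfg)
    cohort = simulate_cohort(cfg, atlas=atlas)
    return cfg, atlas, cohort


def _nominate(atlas, cohort, config=NominationConfig()):
    fam_variants = {p.family_id: cohort.variants for p in cohort.pedigrees}
    return nominate_candidates(
        cohort.pedigrees, fam_variants, atlas, DEFAULT_DISEASE_MAP, config,
        sv_variants_by_family={p.family_id: cohort.sv_variants
                               for p in cohort.pedigrees},
        te_variants_by_family={p.family_id: cohort.te_variants
                               for p in cohort.pedigrees},
        cohort_variants=cohort.variants_by_key(),
        unaffected_by_family=cohort.unaffected_by_family(),
    )


class TestNomination:
    def test_planted_recovery_noise_free(self):
        """Precision = recall = 1 on a noise-free synthetic cohort."""
        _, atlas, cohort = _cohort(seed=21, n_planted_sv=2, n_planted_te=2)
        calls = _nominate(atlas, cohort)
        truth = {(c["family"], tuple(c["variant"]))
                 for c in cohort.truth.candidates}
        found = {(c.family_id, c.variant.key) for c in calls}
        assert found == truth

    def test_candidate_outside_disease_peaks_not_nominated(self, trio):
        atlas = PeakAtlas(peaks={"cMN6": [I(1000, 1500)], "cMN7": [I(9000, 9500)]})
        dmap = DiseaseMap({"DRS": ["cMN6"]})
        # de novo variant inside a cMN7 (wrong cell type) peak only
        v = make_variant(pos=9100, gts={"fa": "hom_ref", "mo": "hom_ref",
                                        "ch": "het"})
        calls = nominate_candidates([trio], {"FAM1": [v]}, atlas, dmap)
        assert calls == []
        v2 = make_variant(pos=1100, gts={"fa": "hom_ref", "mo": "hom_ref",
                                         "ch": "het"})
        calls2 = nominate_candidates([trio], {"FAM1": [v2]}, atlas, dmap)
        assert len(calls2) == 1 and calls2[0].mode == "de_novo"

    def test_te_de_novo_af_gate_is_zero(self, trio):
        atlas = PeakAtlas(peaks={"cMN6": [I(1000, 1500)]})
        dmap = DiseaseMap({"DRS": ["cMN6"]})
        te = make_variant(pos=1100, ref="N", alt="<INS:ME>",
                          gnomad_af=0.001, gerp=5.0,
                          gts={"fa": "hom_ref", "mo": "hom_ref", "ch": "het"})
        te.var_class = "TE"
        te.te_confidence = "two_side_tprt_both"
        calls = nominate_candidates([trio], {"FAM1": []}, atlas, dmap,
                                    te_variants_by_family={"FAM1": [te]})
        assert calls == []  # de novo TE gate is AF = 0
        te.gnomad_af = 0.0
        calls = nominate_candidates([trio], {"FAM1": []}, atlas, dmap,
                                    te_variants_by_family={"FAM1": [te]})
        assert len(calls) == 1

    def test_te_low_confidence_label_excluded(self, trio):
        atlas = PeakAtlas(peaks={"cMN6": [I(1000, 1500)]})
        dmap = DiseaseMap({"DRS": ["cMN6"]})
        te = make_variant(pos=1100, ref="N", alt="<INS:ME>", gnomad_af=0.0,
                          gts={"fa": "hom_ref", "mo": "hom_ref", "ch": "het"})
        te.var_class = "TE"
        te.te_confidence = "one_side"
        calls = nominate_candidates([trio], {"FAM1": []}, atlas, dmap,
                                    te_variants_by_family={"FAM1": [te]})
        assert calls == []

    def test_sv_cohort_af_gate(self, trio):
        atlas = PeakAtlas(peaks={"cMN6": [I(1000, 1500)]})
        dmap = DiseaseMap({"DRS": ["cMN6"]})
        sv = make_variant(pos=900, ref="N", alt="<DEL>", cohort_af=0.006,
                          gts={"fa": "hom_ref", "mo": "hom_ref", "ch": "het"})
        sv.var_class = "SV"
        sv.sv_span = (899, 1200)
        calls = nominate_candidates([trio], {"FAM1": []}, atlas, dmap,
                                    sv_variants_by_family={"FAM1": [sv]})
        assert calls == []  # cohort AF >= 0.005
        sv.cohort_af = 0.004
        calls = nominate_candidates([trio], {"FAM1": []}, atlas, dmap,
                                    sv_variants_by_family={"FAM1": [sv]})
        assert len(calls) == 1

    def test_blocklisted_family_skipped(self):
        _, atlas, cohort = _cohort(seed=22)
        blocked = cohort.pedigrees[0].family_id
        cfg = NominationConfig(family_blocklist=frozenset({blocked}))
        calls = _nominate(atlas, cohort, cfg)
        assert all(c.family_id != blocked for c in calls)

    def test_search_space_reduction_monotone(self):
        """Candidates are a subset of hard-filter survivors, themselves a
        subset of all variants."""
        from crevar.variants import apply_hard_filters

        _, atlas, cohort = _cohort(seed=23)
        calls = _nominate(atlas, cohort)
        survivors = {
            v.key for v in cohort.variants
            if apply_hard_filters(v, "monoallelic").passed
            or apply_hard_filters(v, "biallelic").passed
        }
        candidate_keys = {c.variant.key for c in calls
                          if c.variant.var_class in ("SNV", "indel")}
        assert candidate_keys <= survivors
        assert survivors <= {v.key for v in cohort.variants}


class TestMultiHit:
    def _call(self, fam, peak, mode="dominant", pos=None, var=None):
        v = var or make_variant(pos=pos or (peak.start + 10),
                                gts={f"{fam}_a": "het"})
        return CandidateCall(v, fam, mode, supporting_peak=peak)

    def test_two_families_same_mode(self):
        peak = I(1000, 1500)
        calls = [self._call("F1", peak, pos=1010),
                 self._call("F2", peak, pos=1020)]
        out = find_multihit_peaks(calls)
        assert len(out) == 1
        assert out[0].families == {"F1", "F2"}

    def test_mode_mismatch_not_aggregated(self):
        peak = I(1000, 1500)
        v2 = make_variant(pos=1020, gts={"F2_a": "hom_alt"})
        calls = [self._call("F1", peak, pos=1010),
                 CandidateCall(v2, "F2", "homozygous_recessive",
                               supporting_peak=peak)]
        assert find_multihit_peaks(calls) == []

    def test_single_family_never_reported(self):
        peak = I(1000, 1500)
        calls = [self._call("F1", peak, pos=1010),
                 self._call("F1", peak, pos=1020)]
        assert find_multihit_peaks(calls) == []

    def test_oversized_sv_dropped_before_counting(self):
        peak = I(1000, 1500)
        big = make_variant(pos=1001, ref="N", alt="<DEL>")
        big.var_class = "SV"
        big.sv_span = (1000, 251_000)  # 250 kb
        calls = [self._call("F1", peak, pos=1010),
                 CandidateCall(big, "F2", "dominant", supporting_peak=peak)]
        assert find_multihit_peaks(calls) == []
        calls.append(self._call("F3", peak, pos=1030))
        out = find_multihit_peaks(calls)
        assert out and out[0].families == {"F1", "F3"}

    def test_planted_multihit_recovery_many_cohorts(self):
        """50 random cohorts: every planted multi-hit peak recovered, no
        single-family peaks reported."""
        for seed in range(50):
            cfg = SimConfig(seed=seed, n_background_variants=20,
                            n_multihit_peaks=2)
            atlas = simulate_peak_atlas(cfg)
            cohort = simulate_cohort(cfg, atlas=atlas)
            calls = _nominate(atlas, cohort)
            out = find_multihit_peaks(calls)
            got = {(m.peak.key, m.broad_mode) for m in out}
            want = {(tuple(t["peak"]), t["broad_mode"])
                    for t in cohort.truth.multihit_peaks}
            assert got == want, seed
            for m in out:
                assert len(m.families) >= 2

    def test_multihit_genes_require_two_connected_peaks(self):
        p1, p2 = I(1000, 1500), I(3000, 3500)
        calls = [self._call("F1", p1, pos=1010), self._call("F2", p2, pos=3010)]
        links = [PeakGeneLink(p1, "GENE", 0.5, 1e-9, 1e-8, 100),
                 PeakGeneLink(p2, "GENE", 0.4, 1e-8, 1e-7, 200)]
        out = find_multihit_genes(calls, links)
        assert len(out) == 1
        assert out[0].gene == "GENE" and len(out[0].variants) == 2
        # one peak with several candidates is not a multi-hit gene
        calls_one_peak = [self._call("F1", p1, pos=1010),
                          self._call("F2", p1, pos=1020),
                          self._call("F3", p1, pos=1030)]
        assert find_multihit_genes(calls_one_peak, links[:1]) == []

    def test_multihit_genes_dominant_only(self):
        p1, p2 = I(1000, 1500), I(3000, 3500)
        v2 = make_variant(pos=3010, gts={"F2_a": "hom_alt"})
        calls = [self._call("F1", p1, pos=1010),
                 CandidateCall(v2, "F2", "homozygous_recessive",
                               supporting_peak=p2)]
        links = [PeakGeneLink(p1, "GENE", 0.5, 1e-9, 1e-8, 100),
                 PeakGeneLink(p2, "GENE", 0.4, 1e-8, 1e-7, 200)]
        assert find_multihit_genes(calls, links) == []


def _fisher_oracle(a, b, c, d):
    """Exhaustive conditional-hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = comb(n, c1, exact=True)
    probs = {}
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        probs[x] = comb(r1, x, exact=True) * comb(r2, c1 - x, exact=True) / denom
    obs = probs[a]
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-9))


class TestFisher:
    def test_odds_ratio_arithmetic(self):
        orr, _ = fisher_exact_2x2([[10, 2], [4, 8]])
        assert orr == pytest.approx(10.0)

    def test_symmetric_table(self):
        orr, p = fisher_exact_2x2([[5, 5], [5, 5]])
        assert orr == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_zero_cell_infinite_or(self):
        orr, _ = fisher_exact_2x2([[5, 0], [2, 8]])
        assert orr == float("inf")

    def test_all_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[0, 0], [3, 4]])

    def test_matches_enumeration_for_small_tables(self, rng):
        """Conditional two-sided p equals exhaustive enumeration, n <= 40."""
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(0, 11, 4))
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            _, p = fisher_exact_2x2([[a, b], [c, d]])
            assert p == pytest.approx(_fisher_oracle(a, b, c, d), abs=1e-9)


class TestEffectScores:
    def test_snv_z_against_own_null(self):
        scores = [EffectScore(f"v{i}", s) for i, s in enumerate((-1.0, 0.0, 1.0))]
        out = sad_zscores(scores)
        assert out[1].sad_z == pytest.approx(0.0)

    def test_indel_scored_against_snv_null(self, rng):
        snv = [EffectScore(f"v{i}", float(x))
               for i, x in enumerate(rng.standard_normal(2000))]
        indel = EffectScore("ind", 3.0, var_class="indel")
        out = sad_zscores(snv + [indel])
        # null mean ~0, sd ~1, so the indel z is close to its raw score
        assert out[-1].sad_z == pytest.approx(3.0, abs=0.25)

    def test_tail_fraction_matches_normal_mass(self, rng):
        snv = [EffectScore(f"v{i}", float(x))
               for i, x in enumerate(rng.standard_normal(1000))]
        out = sad_zscores(snv)
        frac = np.mean([abs(s.sad_z) > 2 for s in out])
        assert frac == pytest.approx(0.0455, abs=0.02)

    def test_affine_invariance(self, rng):
        raw = rng.standard_normal(50)
        a = sad_zscores([EffectScore(f"v{i}", float(x))
                         for i, x in enumerate(raw)])
        b = sad_zscores([EffectScore(f"v{i}", float(3.0 * x + 7.0))
                         for i, x in enumerate(raw)])
        np.testing.assert_allclose([s.sad_z for s in a], [s.sad_z for s in b],
                                   atol=1e-12)

    def test_degenerate_null_rejected(self):
        with pytest.raises(ValueError):
            sad_zscores([EffectScore("a", 1.0), EffectScore("b", 1.0)])


class TestValidationSummary:
    def test_reported_fractions(self):
        got = summarize_validation({
            "overall": (44, 59), "screen1": (17, 26), "screen2": (27, 33),
            "abc_overlap": (4925, 6072), "none": (0, 10),
        })
        assert got == {"overall": 75, "screen1": 65, "screen2": 82,
                       "abc_overlap": 81, "none": 0}

    def test_invalid_tallies(self):
        with pytest.raises(ValueError):
            summarize_validation({"x": (1, 0)})
        with pytest.raises(ValueError):
            summarize_validation({"x": (5, 4)})
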