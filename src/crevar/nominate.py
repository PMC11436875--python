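"""Cell type-aware candidate nomination and allelic aggregation.

The pipeline composes: hard filters -> per-family inheritance searches ->
restriction to the disease group's accessible-chromatin peaks (SNV/indel
positional containment; SVs by any-overlap with cohort AF < 0.005; mobile
element insertions by padded-point overlap with class-specific AF gates and
a confidence-label filter) -> cohort-level exclusion, with solved pedigrees
removed by a config blocklist.

Aggregation is peak-centric (multi-hit peaks: candidates from >= 2 families
sharing a broad inheritance mode in one peak) and gene-centric (multi-hit
genes: >= 2 distinct linked peaks each carrying a dominant candidate).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats as _stats

from .inheritance import (
    BROAD_MODE,
    CandidateCall,
    apply_cohort_exclusion,
    find_compound_het,
    find_de_novo,
    find_dominant,
    find_homozygous_recessive,
)
from .intervals import (
    DiseaseMap,
    GenomicInterval,
    PeakAtlas,
    build_disease_peakset,
    overlap_variants,
)
from .pedigree import Pedigree
from .variants import FilterThresholds, Variant, apply_hard_filters

__all__ = [
    "NominationConfig",
    "MultiHitPeak",
    "MultiHitGene",
    "EffectScore",
    "nominate_candidates",
    "find_multihit_peaks",
    "find_multihit_genes",
    "fisher_exact_2x2",
    "sad_zscores",
    "summarize_validation",
]


@dataclass
class NominationConfig:
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    sv_cohort_af_max: float = 0.005
    te_af_dominant_max: float = 0.01
    te_af_de_novo_max: float = 0.0
    te_padding: int = 15
    te_confidence_inherited: tuple[str, ...] = ("two_side_tprt_both", "two_side_tprt")
    te_confidence_de_novo: tuple[str, ...] = ("two_side_tprt_both",)
    sv_multihit_max_span: int = 100_000
    family_blocklist: frozenset = frozenset()  # solved / QC-failed pedigrees
    known_genes: tuple[str, ...] = ()


@dataclass
class MultiHitPeak:
    peak: GenomicInterval
    broad_mode: str
    families: frozenset
    variants: tuple

    def __post_init__(self) -> None:
        assert len(self.families) >= 2


@dataclass
class MultiHitGene:
    gene: str
    peaks: frozenset  # interval keys of connected candidate-bearing peaks
    variants: tuple

    def __post_init__(self) -> None:
        assert len(self.peaks) >= 2


@dataclass
class EffectScore:
    variant_id: str
    raw_sad: float
    var_class: str = "SNV"  # SNV or indel
    sad_z: float | None = None


def _mode_class(mode: str) -> str:
    return "monoallelic" if BROAD_MODE[mode] == "dominant" else "biallelic"


def _search_family(
    ped: Pedigree,
    variants: Sequence[Variant],
    peaks: Sequence[GenomicInterval],
    config: NominationConfig,
) -> list[CandidateCall]:
    th = config.thresholds
    fam_samples = ped.sample_ids()

    def survivors(mode_class: str) -> list[Variant]:
        return [
            v for v in variants
            if apply_hard_filters(v, mode_class, th, samples=[
                s for s in fam_samples if s in v.genotypes
            ]).passed
        ]

    mono = survivors("monoallelic")
    bi = survivors("biallelic")

    calls: list[CandidateCall] = []
    calls += find_de_novo(ped, mono, th)
    nominated = {(c.variant.key, c.mode) for c in calls}
    for c in find_dominant(ped, mono, ped.incomplete_penetrance, th):
        if (c.variant.key, "de_novo") not in nominated:
            calls.append(c)
    calls += find_homozygous_recessive(ped, bi, th)

    # compound hets: both members gated at the biallelic AF threshold and
    # restricted to the same disease-relevant peak up front
    hit_peaks = {v.key: iv for v, iv in overlap_variants(bi, peaks)}
    calls += find_compound_het(ped, bi, hit_peaks, th)
    return calls


def _attach_peaks(
    calls: Sequence[CandidateCall],
    peaks: Sequence[GenomicInterval],
    config: NominationConfig,
) -> list[CandidateCall]:
    """Keep calls whose variant overlaps a disease-relevant peak."""
    from dataclasses import replace

    out = []
    for call in calls:
        if call.supporting_peak is not None:  # compound hets pre-assigned
            out.append(call)
            continue
        v = call.variant
        pad = config.te_padding if v.var_class == "TE" else 0
        hits = overlap_variants([v], peaks, padding=pad)
        if hits:
            out.append(replace(call, supporting_peak=hits[0][1]))
    return out


def _class_gates(call: CandidateCall, config: NominationConfig) -> bool:
    """SV and mobile-element class-specific gates."""
    v = call.variant
    if v.var_class == "SV":
        return (v.cohort_af or 0.0) < config.sv_cohort_af_max
    if v.var_class == "TE":
        if call.mode == "de_novo":
            ok_conf = v.te_confidence in config.te_confidence_de_novo
            ok_af = (v.gnomad_af or 0.0) <= config.te_af_de_novo_max
        else:
            ok_conf = v.te_confidence in config.te_confidence_inherited
            ok_af = (v.gnomad_af or 0.0) < config.te_af_dominant_max
        return ok_conf and ok_af
    return True


def nominate_candidates(
    pedigrees: Sequence[Pedigree],
    variants_by_family: Mapping[str, Sequence[Variant]],
    atlas: PeakAtlas,
    dmap: DiseaseMap,
    config: NominationConfig = NominationConfig(),
    sv_variants_by_family: Mapping[str, Sequence[Variant]] | None = None,
    te_variants_by_family: Mapping[str, Sequence[Variant]] | None = None,
    cohort_variants: Mapping[tuple, Variant] | None = None,
    unaffected_by_family: Mapping[str, Sequence[str]] | None = None,
) -> list[CandidateCall]:
    """End-to-end per-family nomination across SNV/indel, SV, and TE calls.

    ``variants_by_family`` may share one cohort-wide list across families.
    ``cohort_variants``/``unaffected_by_family`` enable cohort-level
    exclusion; when omitted, only within-family rules apply.
    """
    all_calls: list[CandidateCall] = []
    incomplete = set()
    for ped in pedigrees:
        if ped.family_id in config.family_blocklist:
            continue
        if ped.incomplete_penetrance:
            incomplete.add(ped.family_id)
        if ped.disease_group is None:
            continue
        peaks = build_disease_peakset(atlas, dmap, ped.disease_group)
        fam_variants = variants_by_family.get(ped.family_id, ())
        calls = _search_family(ped, list(fam_variants), peaks, config)
        calls = _attach_peaks(calls, peaks, config)
        for source in (sv_variants_by_family, te_variants_by_family):
            if source is None:
                continue
            extra = list(source.get(ped.family_id, ()))
            sv_calls: list[CandidateCall] = []
            sv_calls += find_de_novo(ped, extra, config.thresholds)
            seen = {(c.variant.key, "de_novo") for c in sv_calls}
            for c in find_dominant(ped, extra, ped.incomplete_penetrance,
                                   config.thresholds):
                if (c.variant.key, "de_novo") not in seen:
                    sv_calls.append(c)
            sv_calls = [c for c in sv_calls if _class_gates(c, config)]
            calls += _attach_peaks(sv_calls, peaks, config)
        all_calls += calls
    if cohort_variants is not None and unaffected_by_family is not None:
        all_calls = apply_cohort_exclusion(
            all_calls, cohort_variants, unaffected_by_family,
            incomplete_penetrance_families=incomplete,
        )
    return all_calls


def find_multihit_peaks(
    candidates: Sequence[CandidateCall],
    config: NominationConfig = NominationConfig(),
    sv_coding_etiology: Mapping[tuple, bool] | None = None,
) -> list[MultiHitPeak]:
    """Peaks hit by candidates from >= 2 families under one broad mode.

    SVs longer than the span cap (100 kb) or flagged with clear coding
    etiology are excluded from the tabulation before counting families.
    """
    usable = []
    for c in candidates:
        if c.supporting_peak is None:
            continue
        v = c.variant
        if v.var_class == "SV":
            span = v.sv_span[1] - v.sv_span[0] if v.sv_span else 0
            if span > config.sv_multihit_max_span:
                continue
            if sv_coding_etiology and sv_coding_etiology.get(v.key, False):
                continue
        usable.append(c)
    grouped: dict[tuple, list[CandidateCall]] = {}
    for c in usable:
        grouped.setdefault((c.supporting_peak.key, c.broad_mode), []).append(c)
    out = []
    for (peak_key, broad), calls in sorted(grouped.items()):
        fams = frozenset(c.family_id for c in calls)
        if len(fams) >= 2:
            out.append(MultiHitPeak(
                peak=calls[0].supporting_peak, broad_mode=broad,
                families=fams,
                variants=tuple(sorted({c.variant.key for c in calls})),
            ))
    return out


def find_multihit_genes(
    candidates: Sequence[CandidateCall],
    links: Sequence,  # PeakGeneLink list
) -> list[MultiHitGene]:
    """Genes with >= 2 distinct linked peaks each holding a dominant candidate."""
    dom_peaks: dict[tuple, list[CandidateCall]] = {}
    for c in candidates:
        if c.broad_mode == "dominant" and c.supporting_peak is not None:
            dom_peaks.setdefault(c.supporting_peak.key, []).append(c)
    gene_peaks: dict[str, set[tuple]] = {}
    for lk in links:
        if lk.peak.key in dom_peaks:
            gene_peaks.setdefault(lk.gene, set()).add(lk.peak.key)
    out = []
    for gene, peaks in sorted(gene_peaks.items()):
        if len(peaks) >= 2:
            variants = tuple(sorted({
                c.variant.key for pk in peaks for c in dom_peaks[pk]
            }))
            out.append(MultiHitGene(gene, frozenset(peaks), variants))
    return out


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Returns (sample odds ratio a*d / b*c, with inf for zero b*c, and the
    conditional-hypergeometric two-sided p-value).
    """
    a, b = int(table[0][0]), int(table[0][1])
    c, d = int(table[1][0]), int(table[1][1])
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if 0 in (a + b, c + d, a + c, b + d):
        raise ValueError("all-zero margin")
    res = _stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if b * c == 0:
        oddsratio = float("inf") if a * d > 0 else float("nan")
    else:
        oddsratio = (a * d) / (b * c)
    return oddsratio, float(res.pvalue)


def sad_zscores(
    scores: Sequence[EffectScore], z_threshold: float = 2.0,
) -> list[EffectScore]:
    """Z-normalize predicted accessibility-difference (SAD) scores.

    SNV scores define the null distribution; indels are scored against the
    SNV mean/sd (an indel-only null is not well defined). Scores with
    |z| > ``z_threshold`` are the significant predicted effects.
    """
    snv = np.array([s.raw_sad for s in scores if s.var_class == "SNV"])
    if snv.size < 2:
        raise ValueError("need >= 2 SNV scores to define the null")
    mu, sd = float(snv.mean()), float(snv.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate SNV null (sd = 0)")
    return [
        EffectScore(s.variant_id, s.raw_sad, s.var_class,
                    sad_z=(s.raw_sad - mu) / sd)
        for s in scores
    ]


def summarize_validation(tallies: Mapping[str, tuple[int, int]]) -> dict[str, int]:
    """Integer percentages from (positive, total) tallies.

    Matches the reporting precision used for validation and concordance
    rates (e.g. 17/26 -> 65).
    """
    out = {}
    for label, (k, n) in tallies.items():
        if n == 0:
            raise ValueError(f"{label}: zero denominator")
        if k > n:
            raise ValueError(f"{label}: positives exceed total")
        out[label] = round(100 * k / n)
    return out
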