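"""Per-pedigree inheritance-mode searches and cohort-level exclusion.

Five configurations are searched per family: de novo, dominant, dominant
with incomplete penetrance, homozygous recessive, and compound heterozygous.
For compound heterozygotes the accessible-chromatin peak — not the gene — is
the unit of heredity: the two variants must lie in the same disease-relevant
peak, one transmitted by the unaffected father and the other by the
unaffected mother.

Genotype-quality and allele-balance gates apply to every genotype a decision
consumes. De novo calling is a genotype-rule caller (child het, both parents
confidently homozygous reference) rather than a likelihood model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .intervals import GenomicInterval
from .pedigree import Individual, Pedigree
from .variants import FilterThresholds, Genotype, Variant, genotype_passes

__all__ = [
    "CandidateCall",
    "call_de_novo",
    "find_de_novo",
    "find_dominant",
    "find_homozygous_recessive",
    "find_compound_het",
    "apply_cohort_exclusion",
    "BROAD_MODE",
]

MODES = ("de_novo", "dominant", "dominant_incomplete_penetrance",
         "homozygous_recessive", "compound_het")

#: broad mode of inheritance used for multi-hit aggregation
BROAD_MODE = {
    "de_novo": "dominant",
    "dominant": "dominant",
    "dominant_incomplete_penetrance": "dominant",
    "homozygous_recessive": "recessive",
    "compound_het": "recessive",
}


@dataclass(frozen=True)
class CandidateCall:
    variant: Variant
    family_id: str
    mode: str
    partner_variant: Variant | None = None
    supporting_peak: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.mode == "compound_het":
            assert self.partner_variant is not None
            assert self.partner_variant.key != self.variant.key

    @property
    def broad_mode(self) -> str:
        return BROAD_MODE[self.mode]


def _gt(v: Variant, ind: Individual) -> Genotype:
    return v.genotypes.get(ind.individual_id, Genotype("missing"))


def call_de_novo(
    child: Genotype, father: Genotype, mother: Genotype,
    thresholds: FilterThresholds = FilterThresholds(),
) -> bool:
    """True iff the trio genotypes support a de novo heterozygote.

    Child het passing GQ/AB, both parents hom_ref passing GQ. A missing
    parental genotype never yields a call.
    """
    if child.call != "het" or not genotype_passes(child, thresholds):
        return False
    for parent in (father, mother):
        if parent.call != "hom_ref" or not genotype_passes(parent, thresholds):
            return False
    return True


def find_de_novo(
    ped: Pedigree, variants: Iterable[Variant],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[CandidateCall]:
    """De novo candidates in affected children with both parents genotyped."""
    out = []
    for v in variants:
        for child, father, mother in ped.trios():
            if not child.affected:
                continue
            if call_de_novo(_gt(v, child), _gt(v, father), _gt(v, mother),
                            thresholds):
                out.append(CandidateCall(v, ped.family_id, "de_novo"))
                break
    return out


def find_dominant(
    ped: Pedigree, variants: Iterable[Variant],
    incomplete_penetrance: bool = False,
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[CandidateCall]:
    """Dominant segregation: every affected member carries the allele.

    In the standard mode no unaffected family member may carry it; the
    incomplete-penetrance search drops that within-family exclusion.
    """
    mode = "dominant_incomplete_penetrance" if incomplete_penetrance else "dominant"
    out = []
    for v in variants:
        gts = {i.individual_id: _gt(v, i) for i in ped.members.values()}
        if not all(
            gts[a.individual_id].carries_alt
            and genotype_passes(gts[a.individual_id], thresholds)
            for a in ped.affected
        ):
            continue
        if not incomplete_penetrance and any(
            gts[u.individual_id].carries_alt for u in ped.unaffected
        ):
            continue
        out.append(CandidateCall(v, ped.family_id, mode))
    return out


def find_homozygous_recessive(
    ped: Pedigree, variants: Iterable[Variant],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[CandidateCall]:
    """All affecteds homozygous alt; no unaffected member homozygous alt;
    genotyped parents of affecteds must carry at least one alt allele."""
    out = []
    for v in variants:
        ok = all(
            _gt(v, a).call == "hom_alt" and genotype_passes(_gt(v, a), thresholds)
            for a in ped.affected
        )
        if not ok:
            continue
        if any(_gt(v, u).call == "hom_alt" for u in ped.unaffected):
            continue
        consistent = True
        for a in ped.affected:
            for pid in (a.father_id, a.mother_id):
                if pid is None:
                    continue
                pgt = _gt(v, ped.members[pid])
                if pgt.call == "hom_ref":
                    consistent = False  # transmission impossible
                elif pgt.call != "missing" and not genotype_passes(pgt, thresholds):
                    consistent = False
        if consistent:
            out.append(CandidateCall(v, ped.family_id, "homozygous_recessive"))
    return out


def _parental_origin(
    child: Genotype, father: Genotype, mother: Genotype,
) -> str | None:
    """Infer which unaffected parent transmitted a het child allele.

    Returns "father", "mother", or None when ambiguous/inconsistent
    (e.g. both parents het at the site, or neither carries the allele).
    """
    if child.call != "het":
        return None
    f, m = father.carries_alt, mother.carries_alt
    if f and not m:
        return "father"
    if m and not f:
        return "mother"
    return None


def find_compound_het(
    ped: Pedigree,
    variants: Sequence[Variant],
    peak_of: Mapping[tuple, GenomicInterval],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[CandidateCall]:
    """Compound heterozygotes with the peak as the unit of heredity.

    ``peak_of`` maps variant key -> containing disease-relevant peak;
    variants without a peak assignment are not considered. For each peak,
    nominate pairs (v1, v2) where the affected child is het at both, v1 was
    transmitted by the unaffected father and v2 by the unaffected mother.
    Pairs whose parental origin cannot be resolved from trio genotypes are
    skipped with a warning rather than guessed.
    """
    out: list[CandidateCall] = []
    for child, father, mother in ped.trios():
        if not child.affected or father.affected or mother.affected:
            continue
        by_peak: dict[tuple, list[tuple[Variant, str]]] = {}
        for v in variants:
            peak = peak_of.get(v.key)
            if peak is None:
                continue
            cg, fg, mg = _gt(v, child), _gt(v, father), _gt(v, mother)
            if cg.call != "het" or not genotype_passes(cg, thresholds):
                continue
            if not (genotype_passes(fg, thresholds) and
                    genotype_passes(mg, thresholds)):
                continue
            origin = _parental_origin(cg, fg, mg)
            if origin is None:
                if fg.carries_alt and mg.carries_alt:
                    warnings.warn(
                        f"{ped.family_id}: parental origin ambiguous at "
                        f"{v.chrom}:{v.pos}; variant skipped"
                    )
                continue
            by_peak.setdefault(peak.key, []).append((v, origin))
        for key, items in by_peak.items():
            paternal = [v for v, o in items if o == "father"]
            maternal = [v for v, o in items if o == "mother"]
            for v1 in paternal:
                for v2 in maternal:
                    if v1.key == v2.key:
                        continue
                    peak = peak_of[v1.key]
                    out.append(CandidateCall(v1, ped.family_id, "compound_het",
                                             partner_variant=v2,
                                             supporting_peak=peak))
    return out


def apply_cohort_exclusion(
    calls: Iterable[CandidateCall],
    variants_by_key: Mapping[tuple, Variant],
    unaffected_by_family: Mapping[str, Sequence[str]],
    incomplete_penetrance_families: frozenset[str] | set[str] = frozenset(),
) -> list[CandidateCall]:
    """Drop candidates carried by unaffected individuals cohort-wide.

    Dominant/de novo calls are excluded when any unaffected individual in
    the whole cohort carries the allele; recessive-class calls only when an
    unaffected individual is homozygous alt. Unaffected carriers inside a
    family flagged for incomplete penetrance do not trigger exclusion of
    that family's own dominant call.
    """
    kept = []
    for call in calls:
        v = variants_by_key.get(call.variant.key, call.variant)
        excluded = False
        for fam, samples in unaffected_by_family.items():
            if (call.broad_mode == "dominant" and fam == call.family_id
                    and fam in incomplete_penetrance_families):
                continue
            for s in samples:
                gt = v.genotypes.get(s)
                if gt is None:
                    continue
                if call.broad_mode == "dominant" and gt.carries_alt:
                    excluded = True
                elif call.broad_mode == "recessive" and gt.call == "hom_alt":
                    excluded = True
            if excluded:
                break
        if not excluded:
            kept.append(call)
    return kept
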