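"""Variant records, biallelic splitting, hard filters, and genomic context.

Variants are held biallelic: one record per alternate allele, with per-sample
genotypes recoded against that single alternate. Hard filters implement the
cohort's rarity/conservation/quality gates:

- gnomAD and TOPMed AF below 1e-3 for monoallelic (dominant/de novo) searches
  or 1e-2 for biallelic (recessive) searches; a missing AF counts as 0
  (absent from the reference panels means rare);
- GERP > 2;
- the record passes all upstream VCF quality filters;
- genotype quality > 20 and heterozygous allele balance > 0.15 for every
  genotype an inheritance decision consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Genotype",
    "Variant",
    "FilterDecision",
    "FilterThresholds",
    "split_multiallelic",
    "apply_hard_filters",
    "genotype_passes",
    "GeneModel",
    "classify_context",
    "tabulate_context_fractions",
    "read_vcf",
    "write_vcf",
]

Call = Literal["hom_ref", "het", "hom_alt", "missing"]


@dataclass(frozen=True)
class Genotype:
    call: Call
    gq: float = 99.0
    ad: tuple[int, int] = (0, 0)  # (ref_depth, alt_depth)

    @property
    def allele_balance(self) -> float:
        """Alt-fraction of reads; NaN when no reads are informative."""
        tot = self.ad[0] + self.ad[1]
        return self.ad[1] / tot if tot > 0 else float("nan")

    @property
    def carries_alt(self) -> bool:
        return self.call in ("het", "hom_alt")


@dataclass
class Variant:
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    var_class: Literal["SNV", "indel", "SV", "TE"] = "SNV"
    sv_span: tuple[int, int] | None = None  # 0-based half-open, SVs only
    cohort_af: float | None = None
    gnomad_af: float | None = None
    topmed_af: float | None = None
    gerp: float | None = None
    filter_status: str = "PASS"
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    sv_type: str | None = None
    te_family: str | None = None
    te_confidence: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"1-based position must be >= 1, got {self.pos}")
        for af in (self.cohort_af, self.gnomad_af, self.topmed_af):
            if af is not None and not 0 <= af <= 1:
                raise ValueError(f"allele frequency out of [0,1]: {af}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterDecision:
    passed: bool
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        assert self.passed == (len(self.reasons) == 0)


@dataclass(frozen=True)
class FilterThresholds:
    """Hard-filter thresholds; defaults are the framework's stated values."""

    af_monoallelic: float = 1e-3
    af_biallelic: float = 1e-2
    gerp_min: float = 2.0
    gq_min: float = 20.0
    ab_min: float = 0.15
    symmetric_ab: bool = False  # optionally gate min(AB, 1-AB)


_SPANNING_DELETION = "*"


def split_multiallelic(
    chrom: str,
    pos: int,
    ref: str,
    alts: Sequence[str],
    genotypes: Mapping[str, tuple[int | None, int | None, float, tuple[int, ...]]],
    **annotations,
) -> list[Variant]:
    """Split a multi-allelic site into biallelic :class:`Variant` records.

    ``genotypes`` maps sample -> (allele1, allele2, GQ, per-allele AD) with
    allele indices into [ref, *alts] and None for missing calls. Spanning
    deletion alleles (``*``) are dropped. For each retained alternate, each
    sample's genotype is recoded against that alternate alone: alleles equal
    to the alternate count as alt, any other allele counts as ref.
    """
    if not alts:
        raise ValueError("record has no alternate alleles")
    per_alt_ann = annotations.pop("per_alt", None)
    out: list[Variant] = []
    for ai, alt in enumerate(alts, start=1):
        if alt == _SPANNING_DELETION:
            continue
        gts: dict[str, Genotype] = {}
        for sample, (a1, a2, gq, ad) in genotypes.items():
            if a1 is None or a2 is None:
                gts[sample] = Genotype("missing", gq, (0, 0))
                continue
            n_alt = (a1 == ai) + (a2 == ai)
            call: Call = ("hom_ref", "het", "hom_alt")[n_alt]
            alt_depth = ad[ai] if len(ad) > ai else 0
            ref_depth = sum(d for j, d in enumerate(ad) if j != ai)
            gts[sample] = Genotype(call, gq, (ref_depth, alt_depth))
        ann = dict(annotations)
        if per_alt_ann is not None:
            ann.update(per_alt_ann[ai - 1])
        var_class = "indel" if len(ref) != len(alt) else "SNV"
        out.append(
            Variant(chrom, pos, ref, alt, var_class=var_class, genotypes=gts, **ann)
        )
    return out


def genotype_passes(gt: Genotype, thresholds: FilterThresholds) -> bool:
    """GQ/AB gate for a single genotype consumed by an inheritance decision."""
    if gt.call == "missing":
        return False
    if not gt.gq > thresholds.gq_min:
        return False
    if gt.call == "het":
        ab = gt.allele_balance
        if np.isnan(ab):
            return False
        if thresholds.symmetric_ab:
            ab = min(ab, 1.0 - ab)
        if not ab > thresholds.ab_min:
            return False
    return True


def apply_hard_filters(
    v: Variant,
    mode_class: Literal["monoallelic", "biallelic"],
    thresholds: FilterThresholds = FilterThresholds(),
    samples: Sequence[str] | None = None,
) -> FilterDecision:
    """Evaluate the site-level hard filters plus per-genotype gates.

    ``samples`` limits the GQ/AB check to the genotypes an inheritance
    decision will consume; by default every non-missing genotype is gated.
    Missing population AFs are treated as 0. Returns a decision whose
    ``reasons`` list every failed rule.
    """
    if mode_class not in ("monoallelic", "biallelic"):
        raise ValueError(f"unknown mode class {mode_class!r}")
    af_max = (
        thresholds.af_monoallelic
        if mode_class == "monoallelic"
        else thresholds.af_biallelic
    )
    reasons: list[str] = []
    if (v.gnomad_af or 0.0) >= af_max:
        reasons.append("gnomad_af")
    if (v.topmed_af or 0.0) >= af_max:
        reasons.append("topmed_af")
    if v.gerp is None or not v.gerp > thresholds.gerp_min:
        reasons.append("gerp")
    if v.filter_status not in ("PASS", "."):
        reasons.append("vcf_filter")
    check = samples if samples is not None else [
        s for s, g in v.genotypes.items() if g.call != "missing"
    ]
    for s in check:
        gt = v.genotypes.get(s)
        if gt is None or not genotype_passes(gt, thresholds):
            reasons.append(f"genotype:{s}")
    return FilterDecision(not reasons, tuple(reasons))


def filter_report(
    variants: Sequence[Variant],
    mode_class: Literal["monoallelic", "biallelic"],
    path,
    thresholds: FilterThresholds = FilterThresholds(),
) -> pd.DataFrame:
    """Write a per-variant hard-filter report TSV (one reasons column)."""
    rows = []
    for v in variants:
        d = apply_hard_filters(v, mode_class, thresholds)
        rows.append({"chrom": v.chrom, "pos": v.pos, "ref": v.ref,
                     "alt": v.alt, "passed": d.passed,
                     "reasons": ";".join(d.reasons)})
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df


# ---------------------------------------------------------------------------
# genomic context


@dataclass
class GeneModel:
    """Minimal gene annotation: per-gene TSS/strand plus exon intervals.

    ``genes`` rows: gene_id, chrom, start, end, strand (start/end 0-based
    half-open transcript span). ``exons`` rows: gene_id, chrom, start, end.
    """

    genes: pd.DataFrame
    exons: pd.DataFrame

    @classmethod
    def from_bed12(cls, path) -> "GeneModel":
        cols = pd.read_csv(path, sep="\t", header=None, comment="#")
        genes, exons = [], []
        for row in cols.itertuples(index=False):
            chrom, start, end, name, strand = (
                str(row[0]), int(row[1]), int(row[2]), str(row[3]), str(row[5]),
            )
            genes.append((name, chrom, start, end, strand))
            sizes = [int(x) for x in str(row[10]).rstrip(",").split(",")]
            offs = [int(x) for x in str(row[11]).rstrip(",").split(",")]
            for sz, off in zip(sizes, offs):
                exons.append((name, chrom, start + off, start + off + sz))
        return cls(
            pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end", "strand"]),
            pd.DataFrame(exons, columns=["gene_id", "chrom", "start", "end"]),
        )

    def tss(self) -> pd.DataFrame:
        """Per-gene transcription start site (strand-aware), 0-based."""
        g = self.genes
        pos = np.where(g["strand"] == "-", g["end"] - 1, g["start"])
        return pd.DataFrame({"gene_id": g["gene_id"], "chrom": g["chrom"], "tss": pos,
                             "strand": g["strand"]})


def classify_context(
    v: Variant,
    gene_model: GeneModel,
    promoter_upstream: int = 2000,
    promoter_downstream: int = 200,
) -> str:
    """Label a variant exonic / promoter / intronic / intergenic.

    Precedence when annotations overlap: exonic > promoter > intronic >
    intergenic. The promoter window spans ``promoter_upstream`` bases
    upstream to ``promoter_downstream`` bases downstream of the TSS,
    strand-aware. A chromosome absent from the gene model yields intergenic
    with a warning.
    """
    pos0 = v.pos - 1
    genes = gene_model.genes
    if v.chrom not in set(genes["chrom"]):
        warnings.warn(f"chromosome {v.chrom} absent from gene model")
        return "intergenic"
    ex = gene_model.exons
    ex = ex[(ex["chrom"] == v.chrom) & (ex["start"] <= pos0) & (pos0 < ex["end"])]
    if len(ex):
        return "exonic"
    for row in gene_model.tss().itertuples(index=False):
        if row.chrom != v.chrom:
            continue
        if row.strand == "-":
            lo, hi = row.tss - promoter_downstream, row.tss + promoter_upstream
        else:
            lo, hi = row.tss - promoter_upstream, row.tss + promoter_downstream
        if lo <= pos0 <= hi:
            return "promoter"
    g = genes[(genes["chrom"] == v.chrom) & (genes["start"] <= pos0)
              & (pos0 < genes["end"])]
    if len(g):
        return "intronic"
    return "intergenic"


_CONTEXT_LABELS = ("exonic", "promoter", "intronic", "intergenic")


def tabulate_context_fractions(labels: Sequence[str]) -> dict[str, float]:
    """Fractions per context label; they sum to 1."""
    if len(labels) == 0:
        raise ValueError("no variants")
    n = len(labels)
    counts = pd.Series(labels).value_counts()
    return {lab: counts.get(lab, 0) / n for lab in _CONTEXT_LABELS}


# ---------------------------------------------------------------------------
# VCF I/O (pysam)

_INFO_KEYS = ("COHORT_AF", "GNOMAD_AF", "TOPMED_AF", "GERP")


def _vcf_header(samples: Sequence[str], contigs: Mapping[str, int]):
    import pysam

    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.add_meta("INFO", items=[("ID", "COHORT_AF"), ("Number", "1"),
                                   ("Type", "Float"), ("Description", "Cohort allele frequency")])
    header.add_meta("INFO", items=[("ID", "GNOMAD_AF"), ("Number", "1"),
                                   ("Type", "Float"), ("Description", "gnomAD allele frequency")])
    header.add_meta("INFO", items=[("ID", "TOPMED_AF"), ("Number", "1"),
                                   ("Type", "Float"), ("Description", "TOPMed allele frequency")])
    header.add_meta("INFO", items=[("ID", "GERP"), ("Number", "1"),
                                   ("Type", "Float"), ("Description", "GERP conservation score")])
    header.add_meta("FILTER", items=[("ID", "FAIL"), ("Description", "Failed upstream QC")])
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    header.formats.add("AD", "R", "Integer", "Allelic depths")
    for s in samples:
        header.add_sample(s)
    return header


_CALL_TO_GT = {"hom_ref": (0, 0), "het": (0, 1), "hom_alt": (1, 1),
               "missing": (None, None)}


def write_vcf(variants: Sequence[Variant], samples: Sequence[str],
              contigs: Mapping[str, int], path) -> None:
    """Write biallelic variants as uncompressed VCF v4.2 with GT:GQ:AD."""
    import pysam

    header = _vcf_header(samples, contigs)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for v in sorted(variants, key=lambda x: (x.chrom, x.pos, x.ref, x.alt)):
            rec = vf.new_record(
                contig=v.chrom, start=v.pos - 1, alleles=(v.ref, v.alt),
                filter="PASS" if v.filter_status == "PASS" else "FAIL",
            )
            for key, val in zip(_INFO_KEYS,
                                (v.cohort_af, v.gnomad_af, v.topmed_af, v.gerp)):
                if val is not None:
                    rec.info[key] = float(val)
            for s in samples:
                gt = v.genotypes.get(s, Genotype("missing"))
                rec.samples[s]["GT"] = _CALL_TO_GT[gt.call]
                rec.samples[s]["GQ"] = int(gt.gq)
                rec.samples[s]["AD"] = (int(gt.ad[0]), int(gt.ad[1]))
            vf.write(rec)


def read_vcf(path) -> list[Variant]:
    """Read a VCF into biallelic :class:`Variant` records.

    Multi-allelic records are split via :func:`split_multiallelic` (spanning
    deletions dropped).
    """
    import pysam

    out: list[Variant] = []
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            filt = list(rec.filter)
            status = "PASS" if (not filt or filt == ["PASS"]) else filt[0]
            gts = {}
            for s in samples:
                sm = rec.samples[s]
                alleles = sm.get("GT", (None, None))
                a1 = alleles[0] if len(alleles) > 0 else None
                a2 = alleles[1] if len(alleles) > 1 else a1
                gq = float(sm.get("GQ") or 0)
                ad = tuple(int(x or 0) for x in (sm.get("AD") or ()))
                if not ad:
                    ad = (0,) * (1 + len(rec.alts or ()))
                gts[s] = (a1, a2, gq, ad)

            def _info(key):
                val = rec.info.get(key)
                return float(val) if val is not None else None

            out.extend(
                split_multiallelic(
                    rec.contig, rec.pos, rec.ref, list(rec.alts or ()), gts,
                    cohort_af=_info("COHORT_AF"), gnomad_af=_info("GNOMAD_AF"),
                    topmed_af=_info("TOPMED_AF"), gerp=_info("GERP"),
                    filter_status=status,
                )
            )
    return out
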