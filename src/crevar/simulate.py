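"""Synthetic cohorts with planted, recoverable signals.

Every input the nomination framework consumes can be generated here on a
small synthetic assembly (default three 10 Mb chromosomes with a masked
fraction at each chromosome start): pedigrees over the seven disease
categories and four inheritance/phenotype subgroups, jointly-genotyped
biallelic variants with population-frequency and conservation annotations,
SV and mobile-element call tables, per-cell-type peak atlases, and
cell x peak / cell x gene count matrices with planted peak-gene
correlations. A :class:`TruthSet` records exactly what was planted so every
downstream stage can be scored for recovery.

Planted candidate variants satisfy all hard filters by construction;
every background variant is given at least one disqualifying annotation
(common population frequency, low conservation, or a failed upstream QC
filter), so in the noise-free limit the nomination pipeline should achieve
precision = recall = 1 on the planted truth.

Population allele frequencies follow a three-component mixture — a point
mass at 0 (private), a Beta-distributed rare component, and a common
component — parameterized so the filtering thresholds (1e-3, 5e-3, 1e-2)
fall inside the spectrum. Count matrices are negative binomial with a
per-cell depth factor; planted peak-gene correlation enters through a
shared latent Gaussian (Gaussian copula), which preserves the target
correlation up to mild attenuation by the count noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .imbalance import AlleleCountSet
from .intervals import DiseaseMap, GenomicInterval, PeakAtlas
from .pedigree import DISEASE_GROUPS, SUBGROUPS, Individual, Pedigree
from .variants import Genotype, Variant

__all__ = [
    "SimConfig",
    "TruthSet",
    "SyntheticCohort",
    "CellData",
    "DEFAULT_DISEASE_MAP",
    "simulate_cohort",
    "simulate_peak_atlas",
    "simulate_cell_matrices",
    "simulate_allele_counts",
]

#: phenotype -> disease-relevant cranial motor neuron cell types
DEFAULT_DISEASE_MAP = DiseaseMap({
    "CFEOM": ["cMN3", "cMN4"],
    "FNP": ["cMN4"],
    "DRS": ["cMN6"],
    "CFP": ["cMN7"],
    "Moebius": ["cMN6", "cMN7"],
    "Ptosis": ["cMN3"],
    "Ptosis/MGJWS": ["cMN3"],
})

_PLANT_MODES = ("de_novo", "dominant", "homozygous_recessive", "compound_het")


@dataclass
class AFSpectrum:
    """Mixture for population allele frequencies.

    ``private_weight`` point mass at 0; ``rare_weight`` Beta(a, b) scaled to
    (0, rare_max); remainder uniform on (common_min, common_max). Defaults
    straddle the filtering thresholds.
    """

    private_weight: float = 0.3
    rare_weight: float = 0.4
    rare_a: float = 0.5
    rare_b: float = 5.0
    rare_max: float = 5e-3
    common_min: float = 1e-2
    common_max: float = 0.5

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        u = rng.random(size)
        out = np.zeros(size)
        rare = (u >= self.private_weight) & (
            u < self.private_weight + self.rare_weight)
        common = u >= self.private_weight + self.rare_weight
        out[rare] = rng.beta(self.rare_a, self.rare_b, rare.sum()) * self.rare_max
        out[common] = rng.uniform(self.common_min, self.common_max, common.sum())
        return out


@dataclass
class SimConfig:
    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000,
                                 "chr3": 10_000_000})
    mask_fraction: float = 0.1
    n_families_per_group: int = 1  # per disease group x subgroup
    disease_groups: tuple[str, ...] = DISEASE_GROUPS
    subgroups: tuple[str, ...] = SUBGROUPS
    n_background_variants: int = 200
    planted_candidates: list[tuple[str, str]] | None = None  # (family_id, mode)
    n_multihit_peaks: int = 0  # planted dominant multi-hit peaks (2 families each)
    n_planted_sv: int = 0
    n_planted_te: int = 0
    af_spectrum: AFSpectrum = field(default_factory=AFSpectrum)
    genotype_error_rate: float = 0.0
    # peak atlas
    peaks_per_cell_type: int = 30
    peak_length: int = 500
    shared_peaks: int = 3  # intervals copied between consecutive cell types
    # cell matrices
    n_cells: int = 1000
    n_peaks: int = 50
    n_genes: int = 20
    n_replicates: int = 2
    base_mean_count: float = 5.0
    nb_dispersion: float = 0.1
    depth_log_sd: float = 0.1
    planted_links: list[tuple[int, int, float]] = field(default_factory=list)
    # (peak index, gene index, target correlation)

    def __post_init__(self) -> None:
        for c, L in self.chrom_lengths.items():
            if L <= 0:
                raise ValueError(f"chromosome {c} has non-positive length")
        for _, _, r in self.planted_links:
            if not -1 <= r <= 1:
                raise ValueError(f"target correlation {r} outside [-1, 1]")
        if not 0 <= self.mask_fraction < 1:
            raise ValueError("mask_fraction must lie in [0, 1)")


@dataclass
class TruthSet:
    """Everything that was planted, keyed to the emitted entities."""

    candidates: list[dict] = field(default_factory=list)
    # each: {family, mode, variant: [chrom,pos,ref,alt], partner, peak}
    multihit_peaks: list[dict] = field(default_factory=list)
    # each: {peak: [chrom,start,end], families, broad_mode}
    links: list[dict] = field(default_factory=list)
    # each: {peak, gene, r}
    true_ref_prob: float | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=list)


@dataclass
class SyntheticCohort:
    pedigrees: list[Pedigree]
    variants: list[Variant]
    sv_variants: list[Variant]
    te_variants: list[Variant]
    truth: TruthSet
    mask: list[GenomicInterval]

    def sample_ids(self) -> list[str]:
        return [s for p in self.pedigrees for s in p.sample_ids()]

    def unaffected_by_family(self) -> dict[str, list[str]]:
        return {p.family_id: [i.individual_id for i in p.unaffected]
                for p in self.pedigrees}

    def variants_by_key(self) -> dict[tuple, Variant]:
        return {v.key: v for v in self.variants + self.sv_variants
                + self.te_variants}


def _genome_mask(config: SimConfig) -> list[GenomicInterval]:
    out = []
    for chrom, length in config.chrom_lengths.items():
        m = int(length * config.mask_fraction)
        if m > 0:
            out.append(GenomicInterval(chrom, 0, m))
    return out


def simulate_peak_atlas(
    config: SimConfig, rng: np.random.Generator | None = None,
) -> PeakAtlas:
    """Per-cell-type peak sets placed uniformly over the unmasked genome.

    Consecutive cell types share ``shared_peaks`` intervals to exercise
    cross-cell-type merging downstream.
    """
    from .permutation import randomize_regions

    rng = np.random.default_rng(config.seed if rng is None else rng)
    mask = _genome_mask(config)
    cell_types = sorted({ct for cts in DEFAULT_DISEASE_MAP.groups.values()
                         for ct in cts})
    template = [GenomicInterval("chr1", 0, config.peak_length)
                for _ in range(config.peaks_per_cell_type)]
    peaks: dict[str, list[GenomicInterval]] = {}
    prev: list[GenomicInterval] = []
    for ct in cell_types:
        placed = randomize_regions(template, config.chrom_lengths, mask, rng)
        if prev and config.shared_peaks:
            placed = placed[:-config.shared_peaks] + prev[:config.shared_peaks]
        peaks[ct] = placed
        prev = sorted(placed)
    return PeakAtlas(peaks=peaks, provenance={ct: "synthetic" for ct in peaks})


def _make_families(config: SimConfig) -> list[Pedigree]:
    peds = []
    idx = 0
    for group in config.disease_groups:
        for sub in config.subgroups:
            for _ in range(config.n_families_per_group):
                fam = f"F{idx:04d}"
                idx += 1
                familial = sub.startswith("familial")
                father = Individual(f"{fam}_fa", None, None, 1,
                                    affected=familial)
                mother = Individual(f"{fam}_mo", None, None, 2, affected=False)
                child = Individual(f"{fam}_ch", father.individual_id,
                                   mother.individual_id, 1, affected=True)
                peds.append(Pedigree(
                    family_id=fam,
                    members={m.individual_id: m for m in (father, mother, child)},
                    disease_group=group, subgroup=sub,
                ))
    return peds


def _good_gt(call: str, rng: np.random.Generator, depth: int = 30) -> Genotype:
    gq = float(rng.integers(40, 90))
    if call == "het":
        alt = int(rng.binomial(depth, 0.5))
        alt = min(max(alt, int(0.25 * depth)), int(0.75 * depth))
        return Genotype("het", gq, (depth - alt, alt))
    if call == "hom_alt":
        return Genotype("hom_alt", gq, (0, depth))
    return Genotype("hom_ref", gq, (depth, 0))


def _rand_pos(config: SimConfig, rng: np.random.Generator) -> tuple[str, int]:
    chroms = list(config.chrom_lengths)
    chrom = chroms[int(rng.integers(len(chroms)))]
    length = config.chrom_lengths[chrom]
    lo = int(length * config.mask_fraction)
    return chrom, int(rng.integers(lo + 1, length))  # 1-based

_BASES = np.array(list("ACGT"))


def _alleles(rng: np.random.Generator) -> tuple[str, str]:
    i, j = rng.choice(4, size=2, replace=False)
    return str(_BASES[i]), str(_BASES[j])


def _default_mode(ped: Pedigree, counter: int) -> str:
    if ped.subgroup and ped.subgroup.startswith("familial"):
        return "dominant"
    return ("de_novo", "homozygous_recessive", "compound_het")[counter % 3]


def _family_peak(ped: Pedigree, atlas: PeakAtlas, dmap: DiseaseMap,
                 which: int = 0, used: set | None = None) -> GenomicInterval:
    """Pick a disease-relevant peak; with ``used`` supplied, the first free
    one at or after index ``which``, so plantings never share a peak by
    accident (deliberate sharing registers the peak once)."""
    from .intervals import build_disease_peakset

    peaks = build_disease_peakset(atlas, dmap, ped.disease_group)
    if not peaks:
        raise ValueError(f"no peaks for group {ped.disease_group}")
    if used is None:
        return peaks[which % len(peaks)]
    for i in range(len(peaks)):
        peak = peaks[(which + i) % len(peaks)]
        if peak.key not in used:
            used.add(peak.key)
            return peak
    raise ValueError(f"no free peak left for group {ped.disease_group}")


def _plant_variant(
    ped: Pedigree, mode: str, peak: GenomicInterval,
    rng: np.random.Generator, all_samples: Sequence[str],
    offset: int | None = None,
) -> list[tuple[Variant, Variant | None]]:
    """Build planted variant(s) for one family; compound hets return a pair."""
    child, father, mother = ped.trios()[0]
    if offset is None:
        offset = int(rng.integers(0, len(peak)))
    pos = peak.start + 1 + offset  # 1-based, inside the peak
    ref, alt = _alleles(rng)
    base_gt = {s: _good_gt("hom_ref", rng) for s in all_samples}
    monoallelic = mode in ("de_novo", "dominant")
    af = 0.0 if mode == "de_novo" else (
        float(rng.uniform(0, 8e-4)) if monoallelic
        else float(rng.uniform(1e-3, 8e-3)))  # biallelic band
    ann = dict(gnomad_af=af, topmed_af=af, cohort_af=af,
               gerp=float(rng.uniform(3.0, 6.0)), filter_status="PASS")
    if mode == "de_novo":
        gts = dict(base_gt)
        gts[child.individual_id] = _good_gt("het", rng)
        v = Variant(peak.chrom, pos, ref, alt, genotypes=gts, **ann)
        return [(v, None)]
    if mode == "dominant":
        gts = dict(base_gt)
        for ind in ped.affected:
            gts[ind.individual_id] = _good_gt("het", rng)
        v = Variant(peak.chrom, pos, ref, alt, genotypes=gts, **ann)
        return [(v, None)]
    if mode == "homozygous_recessive":
        gts = dict(base_gt)
        gts[child.individual_id] = _good_gt("hom_alt", rng)
        gts[father.individual_id] = _good_gt("het", rng)
        gts[mother.individual_id] = _good_gt("het", rng)
        v = Variant(peak.chrom, pos, ref, alt, genotypes=gts, **ann)
        return [(v, None)]
    if mode == "compound_het":
        off2 = (offset + 1 + int(rng.integers(0, len(peak) - 1))) % len(peak)
        pos2 = peak.start + 1 + off2
        ref2, alt2 = _alleles(rng)
        g1 = dict(base_gt)
        g1[child.individual_id] = _good_gt("het", rng)
        g1[father.individual_id] = _good_gt("het", rng)
        g2 = dict(base_gt)
        g2[child.individual_id] = _good_gt("het", rng)
        g2[mother.individual_id] = _good_gt("het", rng)
        v1 = Variant(peak.chrom, pos, ref, alt, genotypes=g1, **ann)
        ann2 = dict(ann)
        ann2["gerp"] = float(rng.uniform(3.0, 6.0))
        v2 = Variant(peak.chrom, pos2, ref2, alt2, genotypes=g2, **ann2)
        return [(v1, v2)]
    raise ValueError(f"unknown planted mode {mode!r}")


def _background_variant(
    config: SimConfig, rng: np.random.Generator,
    pedigrees: Sequence[Pedigree],
) -> Variant:
    chrom, pos = _rand_pos(config, rng)
    ref, alt = _alleles(rng)
    af = float(config.af_spectrum.sample(rng, 1)[0])
    violation = ("common_af", "low_gerp", "vcf_fail")[int(rng.integers(3))]
    gnomad = af
    gerp = float(rng.uniform(2.5, 6.0))
    status = "PASS"
    if violation == "common_af":
        gnomad = float(rng.uniform(1e-2, 0.5))
    elif violation == "low_gerp":
        gerp = float(rng.uniform(-3.0, 2.0))
    else:
        status = "FAIL"
    # Mendelian transmission of the allele within each family
    sim_af = max(gnomad, 0.05)  # genotype-sampling frequency; keeps carriers present
    gts: dict[str, Genotype] = {}
    for ped in pedigrees:
        for child, father, mother in ped.trios():
            fa = int(rng.binomial(2, sim_af))
            mo = int(rng.binomial(2, sim_af))
            ch = int(rng.binomial(1, fa / 2)) + int(rng.binomial(1, mo / 2))
            for ind, dose in ((father, fa), (mother, mo), (child, ch)):
                call = ("hom_ref", "het", "hom_alt")[dose]
                if config.genotype_error_rate and rng.random() < config.genotype_error_rate:
                    call = ("hom_ref", "het", "hom_alt")[int(rng.integers(3))]
                gts[ind.individual_id] = _good_gt(call, rng)
    return Variant(chrom, pos, ref, alt, cohort_af=min(gnomad, 1.0),
                   gnomad_af=min(gnomad, 1.0), topmed_af=min(gnomad, 1.0),
                   gerp=gerp, filter_status=status, genotypes=gts)


def simulate_cohort(
    config: SimConfig,
    atlas: PeakAtlas | None = None,
    dmap: DiseaseMap = DEFAULT_DISEASE_MAP,
) -> SyntheticCohort:
    """Generate pedigrees, variants, SV/TE tables, and the planted truth."""
    rng = np.random.default_rng(config.seed)
    if atlas is None:
        atlas = simulate_peak_atlas(config, rng)
    pedigrees = _make_families(config)
    ped_by_id = {p.family_id: p for p in pedigrees}
    all_samples = [s for p in pedigrees for s in p.sample_ids()]
    truth = TruthSet()
    variants: list[Variant] = []

    planted = config.planted_candidates
    if planted is None:
        planted = [(p.family_id, _default_mode(p, i))
                   for i, p in enumerate(pedigrees)]
    used_peaks: set[tuple] = set()

    # reserve the multi-hit peaks first so single plantings avoid them
    group_fams: dict[str, list[Pedigree]] = {}
    for p in pedigrees:
        group_fams.setdefault(p.disease_group, []).append(p)
    eligible = [g for g, fs in group_fams.items() if len(fs) >= 2]
    multihit_assignments = []
    for m in range(config.n_multihit_peaks):
        group = eligible[m % len(eligible)]
        fams = group_fams[group][:2]
        peak = _family_peak(fams[0], atlas, dmap, which=m, used=used_peaks)
        multihit_assignments.append((fams, peak))

    for j, (fam_id, mode) in enumerate(planted):
        ped = ped_by_id[fam_id]
        peak = _family_peak(ped, atlas, dmap, which=j, used=used_peaks)
        for v, partner in _plant_variant(ped, mode, peak, rng, all_samples):
            variants.append(v)
            entry = {"family": fam_id, "mode": mode,
                     "variant": list(v.key), "peak": list(peak.key),
                     "partner": None}
            if partner is not None:
                variants.append(partner)
                entry["partner"] = list(partner.key)
            truth.candidates.append(entry)

    # planted dominant multi-hit peaks: two families of the same disease group
    for m, (fams, peak) in enumerate(multihit_assignments):
        hit_fams = []
        for j, ped in enumerate(fams):
            for v, _ in _plant_variant(ped, "dominant", peak, rng, all_samples,
                                       offset=(7 * m + 3 * j) % len(peak)):
                variants.append(v)
                hit_fams.append(ped.family_id)
                truth.candidates.append({
                    "family": ped.family_id, "mode": "dominant",
                    "variant": list(v.key), "peak": list(peak.key),
                    "partner": None})
        truth.multihit_peaks.append({
            "peak": list(peak.key), "families": hit_fams,
            "broad_mode": "dominant"})

    for _ in range(config.n_background_variants):
        variants.append(_background_variant(config, rng, pedigrees))

    # SVs / TEs: planted candidates only (background SV/TE noise adds little)
    sv_variants: list[Variant] = []
    for i in range(config.n_planted_sv):
        ped = pedigrees[i % len(pedigrees)]
        peak = _family_peak(ped, atlas, dmap, which=2 + i, used=used_peaks)
        start0 = max(0, peak.start - 100)
        span = (start0, peak.start + 50)
        gts = {s: _good_gt("hom_ref", rng) for s in all_samples}
        gts[ped.trios()[0][0].individual_id] = _good_gt("het", rng)
        v = Variant(peak.chrom, start0 + 1, "N", "<DEL>", var_class="SV",
                    sv_span=span, sv_type="DEL", cohort_af=0.001,
                    gnomad_af=0.0, topmed_af=0.0, gerp=5.0, genotypes=gts)
        sv_variants.append(v)
        truth.candidates.append({
            "family": ped.family_id, "mode": "de_novo",
            "variant": list(v.key), "peak": list(peak.key), "partner": None})
    te_variants: list[Variant] = []
    for i in range(config.n_planted_te):
        ped = pedigrees[(i + 1) % len(pedigrees)]
        peak = _family_peak(ped, atlas, dmap, which=3 + i, used=used_peaks)
        pos = peak.start + 1  # 0-based insertion point = peak.start, inside
        gts = {s: _good_gt("hom_ref", rng) for s in all_samples}
        gts[ped.trios()[0][0].individual_id] = _good_gt("het", rng)
        v = Variant(peak.chrom, pos, "N", "<INS:ME>", var_class="TE",
                    te_family=("L1", "Alu", "SVA")[i % 3],
                    te_confidence="two_side_tprt_both",
                    cohort_af=0.0, gnomad_af=0.0, topmed_af=0.0, gerp=5.0,
                    genotypes=gts)
        te_variants.append(v)
        truth.candidates.append({
            "family": ped.family_id, "mode": "de_novo",
            "variant": list(v.key), "peak": list(peak.key), "partner": None})

    return SyntheticCohort(pedigrees, variants, sv_variants, te_variants,
                           truth, _genome_mask(config))


@dataclass
class CellData:
    peak_counts: pd.DataFrame  # cells x peaks
    gene_counts: pd.DataFrame  # cells x genes
    metadata: pd.DataFrame  # cell_id, cell_class, cluster, replicate, fragments
    peak_coords: dict[str, GenomicInterval]
    tss: pd.DataFrame  # gene_id, chrom, tss, strand
    truth_links: list[dict]


def _nb_from_gaussian(z: np.ndarray, mean: np.ndarray, dispersion: float
                      ) -> np.ndarray:
    """Gaussian copula -> negative binomial marginals (elementwise)."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    u = stats.norm.cdf(z)
    u = np.clip(u, 1e-12, 1 - 1e-12)
    return stats.nbinom.ppf(u, size, p)


def simulate_cell_matrices(config: SimConfig) -> CellData:
    """Cell x peak and cell x gene count matrices with planted correlations.

    Cells carry a class label (their cell type of origin), a cluster label
    (equal to the class by default, so a perfect clustering is available as
    ground truth), a replicate label, and a fragment-count depth. Planted
    (peak, gene) pairs share a latent Gaussian with the target correlation;
    all other features are independent.
    """
    rng = np.random.default_rng(config.seed + 1)
    n, n_peaks, n_genes = config.n_cells, config.n_peaks, config.n_genes
    for pi, gi, r in config.planted_links:
        if pi >= n_peaks or gi >= n_genes:
            raise ValueError("planted link references a missing feature")
        if abs(r) > 0.999:
            raise ValueError("target correlation infeasible under count noise")
    depth = np.exp(rng.normal(0.0, config.depth_log_sd, n))
    z_peaks = rng.standard_normal((n, n_peaks))
    z_genes = rng.standard_normal((n, n_genes))
    for pi, gi, r in config.planted_links:
        shared = rng.standard_normal(n)
        z_peaks[:, pi] = shared
        z_genes[:, gi] = r * shared + np.sqrt(1 - r * r) * rng.standard_normal(n)
    mean = config.base_mean_count * depth[:, None]
    peak_counts = _nb_from_gaussian(z_peaks, np.broadcast_to(mean, (n, n_peaks)),
                                    config.nb_dispersion)
    gene_counts = _nb_from_gaussian(z_genes, np.broadcast_to(mean, (n, n_genes)),
                                    config.nb_dispersion)

    # coordinates: peaks spread along chr1, each gene's TSS near peak i
    chrom = next(iter(config.chrom_lengths))
    length = config.chrom_lengths[chrom]
    spacing = max(config.peak_length * 4, length // (n_peaks + 1))
    peak_coords = {}
    for i in range(n_peaks):
        start = min((i + 1) * spacing, length - config.peak_length - 1)
        peak_coords[f"peak_{i:04d}"] = GenomicInterval(
            chrom, start, start + config.peak_length)
    tss_rows = []
    for g in range(n_genes):
        anchor = peak_coords[f"peak_{g % n_peaks:04d}"]
        tss_rows.append((f"gene_{g:03d}", chrom,
                         (anchor.start + anchor.end) // 2 + 1000, "+"))
    tss = pd.DataFrame(tss_rows, columns=["gene_id", "chrom", "tss", "strand"])

    cell_ids = [f"cell_{i:05d}" for i in range(n)]
    classes = [f"class_{i % 5}" for i in range(n)]
    replicates = [f"rep{1 + (i % config.n_replicates)}" for i in range(n)]
    peak_df = pd.DataFrame(peak_counts, index=cell_ids,
                           columns=list(peak_coords))
    gene_df = pd.DataFrame(gene_counts, index=cell_ids,
                           columns=[f"gene_{g:03d}" for g in range(n_genes)])
    fragments = peak_df.sum(axis=1) + 1  # strictly positive depth proxy
    metadata = pd.DataFrame({
        "cell_id": cell_ids, "cell_class": classes, "cluster": classes,
        "replicate": replicates, "fragments": fragments.to_numpy(),
    }).set_index("cell_id")
    truth_links = [
        {"peak": f"peak_{pi:04d}", "gene": f"gene_{gi:03d}", "r": r}
        for pi, gi, r in config.planted_links
    ]
    return CellData(peak_df, gene_df, metadata, peak_coords, tss, truth_links)


def simulate_allele_counts(
    true_ref_prob: float, n_total: int, n_replicates: int, seed: int,
) -> list[AlleleCountSet]:
    """Binomial reference-allele counts for replicate allelic-imbalance assays."""
    if not 0 < true_ref_prob < 1:
        raise ValueError("true_ref_prob must lie strictly in (0, 1)")
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    return [
        AlleleCountSet(k=int(rng.binomial(n_total, true_ref_prob)), n=n_total,
                       replicate=f"rep{i + 1}")
        for i in range(n_replicates)
    ]
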