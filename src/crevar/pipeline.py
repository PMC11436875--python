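"""End-to-end orchestration on a synthetic cohort.

``run_pipeline`` executes the stages in dependency order — simulate,
hard-filter + inheritance + peak restriction (nomination), peak-centric
aggregation, permutation enrichment, peak-to-gene linking, DORC scoring,
cluster metrics, allelic imbalance — writing each stage's outputs plus a
provenance manifest into a run directory. Reruns with the same
configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import contingency, purity, v_measure
from .config import RunConfig
from .imbalance import binomial_atac
from .intervals import write_bed
from .links import compute_links, dorc_scores, make_cell_aggregates, rank_genes_by_links
from .nominate import find_multihit_peaks, nominate_candidates
from .pedigree import write_ped
from .permutation import permutation_test
from .simulate import (
    DEFAULT_DISEASE_MAP,
    SimConfig,
    simulate_allele_counts,
    simulate_cell_matrices,
    simulate_cohort,
    simulate_peak_atlas,
)
from .variants import write_vcf

__all__ = ["run_pipeline"]


def _candidates_frame(calls) -> pd.DataFrame:
    rows = []
    for c in sorted(calls, key=lambda c: (c.family_id, c.variant.key, c.mode)):
        rows.append({
            "family": c.family_id, "mode": c.mode,
            "chrom": c.variant.chrom, "pos": c.variant.pos,
            "ref": c.variant.ref, "alt": c.variant.alt,
            "partner": "" if c.partner_variant is None
            else f"{c.partner_variant.chrom}:{c.partner_variant.pos}",
            "peak": "" if c.supporting_peak is None
            else f"{c.supporting_peak.chrom}:{c.supporting_peak.start}"
                 f"-{c.supporting_peak.end}",
        })
    return pd.DataFrame(rows, columns=["family", "mode", "chrom", "pos", "ref",
                                       "alt", "partner", "peak"])


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(
    config: RunConfig,
    sim_config: SimConfig | None = None,
    out_dir: str | Path = "crevar_run",
) -> dict:
    """Run every stage on a simulated cohort; returns the summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if sim_config is None:
        sim_config = SimConfig(seed=config.seed, n_multihit_peaks=2,
                               planted_links=[(0, 0, 0.8), (1, 1, 0.7)])

    # --- stage 1: synthetic cohort ---------------------------------------
    atlas = simulate_peak_atlas(sim_config)
    cohort = simulate_cohort(sim_config, atlas=atlas)
    write_ped(cohort.pedigrees, out / "cohort.ped", out / "families.tsv")
    write_vcf(cohort.variants, cohort.sample_ids(), sim_config.chrom_lengths,
              out / "cohort.vcf")
    for ct, ivs in atlas.peaks.items():
        write_bed(ivs, out / f"peaks_{ct.replace('/', '_')}.bed")
    cohort.truth.to_json(out / "truth.json")

    # --- stage 2: nomination ----------------------------------------------
    nom_cfg = config.nomination_config()
    fam_variants = {p.family_id: cohort.variants for p in cohort.pedigrees}
    candidates = nominate_candidates(
        cohort.pedigrees, fam_variants, atlas, DEFAULT_DISEASE_MAP, nom_cfg,
        cohort_variants=cohort.variants_by_key(),
        unaffected_by_family=cohort.unaffected_by_family(),
    )
    _candidates_frame(candidates).to_csv(out / "candidates.tsv", sep="\t",
                                         index=False)

    # --- stage 3: peak-centric aggregation --------------------------------
    multihit = find_multihit_peaks(candidates, nom_cfg)
    pd.DataFrame([
        {"chrom": m.peak.chrom, "start": m.peak.start, "end": m.peak.end,
         "broad_mode": m.broad_mode, "n_families": len(m.families),
         "families": ",".join(sorted(m.families))}
        for m in multihit
    ]).to_csv(out / "multihit_peaks.tsv", sep="\t", index=False)

    # --- stage 4: permutation enrichment ----------------------------------
    dn_positions: dict[str, list[int]] = {}
    for c in candidates:
        if c.broad_mode == "dominant":
            dn_positions.setdefault(c.variant.chrom, []).append(c.variant.pos - 1)
    positions = {ch: np.sort(np.array(p)) for ch, p in dn_positions.items()}
    peakset = atlas.union()
    perm = permutation_test(
        positions, peakset, sim_config.chrom_lengths, cohort.mask,
        n_iter=min(config.permutation_iterations, 500), seed=config.seed,
    )
    with open(out / "permutation.json", "w") as fh:
        json.dump({"observed": perm.observed_count, "z": perm.z,
                   "p_empirical": perm.p_empirical,
                   "n_iterations": perm.n_iterations}, fh, indent=1)

    # --- stage 5: peak-to-gene links, DORC, cluster metrics ---------------
    cells = simulate_cell_matrices(sim_config)
    agg_p, agg_g, _ = make_cell_aggregates(
        cells.peak_counts, cells.gene_counts,
        k_groups=min(100, sim_config.n_cells), rng=config.seed)
    links = compute_links(agg_p, agg_g, cells.peak_coords, cells.tss,
                          window=config.link_window, r_min=config.link_r_min,
                          fdr_max=config.link_fdr_max)
    pd.DataFrame([
        {"peak": f"{lk.peak.chrom}:{lk.peak.start}-{lk.peak.end}",
         "gene": lk.gene, "r": lk.r, "p": lk.p_raw, "fdr": lk.fdr,
         "distance": lk.distance}
        for lk in links
    ]).to_csv(out / "links.tsv", sep="\t", index=False)
    peak_ids = {iv.key: pid for pid, iv in cells.peak_coords.items()}
    dorc = dorc_scores(cells.peak_counts, cells.metadata["fragments"], links,
                       peak_ids, cells.tss, window=config.link_window)
    dorc.to_csv(out / "dorc.tsv", sep="\t")
    ranks = rank_genes_by_links(links, window=config.gene_rank_window)
    ranks.to_csv(out / "gene_ranks.tsv", sep="\t", index=False)

    cl = contingency(cells.metadata["cell_class"], cells.metadata["cluster"])
    vm = v_measure(cl)
    pur = purity(cl)

    # --- stage 6: allelic imbalance ---------------------------------------
    reps = simulate_allele_counts(0.81, 75, 2, seed=config.seed + 7)
    pooled, _ = binomial_atac(reps)

    summary = {
        "version": __version__,
        "seed": config.seed,
        "n_families": len(cohort.pedigrees),
        "n_variants": len(cohort.variants),
        "n_candidates": len(candidates),
        "n_multihit_peaks": len(multihit),
        "permutation_z": perm.z,
        "permutation_p": perm.p_empirical,
        "n_links": len(links),
        "homogeneity": vm.h,
        "completeness": vm.c,
        "v_measure": vm.v_beta,
        "min_purity": min(pur.p_k.values()),
        "binomial_estimate": pooled.estimate,
        "binomial_p": pooled.p_two_sided,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    manifest = {
        "version": __version__, "seed": config.seed,
        "inputs": {p.name: _hash_file(p)
                   for p in sorted(out.glob("*.tsv")) + sorted(out.glob("*.vcf"))},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return summary
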