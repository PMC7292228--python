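"""Orchestration: wire the per-pool screen stages and the TF-integration
stages into end-to-end runs with provenance."""

from __future__ import annotations

import logging

import pandas as pd

from . import __version__
from .config import RunConfig
from .library import LibraryManifest
from .screen import (
    CountMatrix,
    call_enriched,
    candidate_genes,
    gene_filters,
    hairpin_scores,
    normalize_counts,
    riger_rank,
    zero_fill,
)
from .tf import rank_tf_table

__all__ = ["run_screen_pipeline", "run_tf_pipeline"]

log = logging.getLogger("plscreen")


def run_screen_pipeline(
    manifest: LibraryManifest,
    pools: dict[int, CountMatrix],
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full hit-calling pass over per-pool raw count matrices.

    Per pool: normalize to the configured scale, zero-fill non-scoring
    tumors, compute hairpin log2 enrichment scores and per-tumor
    enrichment calls.  Library-wide: KS gene ranking with a permutation
    null, reproducibility filters (phi over all xenografted tumors
    including zero-filled ones, h = independent enriched hairpins), and the
    three-filter candidate report.  Returns (report, provenance).
    """
    config = config or RunConfig()
    if not pools:
        raise ValueError("no pools given")

    scores_parts: list[pd.Series] = []
    filter_parts: list[pd.DataFrame] = []
    total_tumors = 0
    for pool_id in sorted(pools):
        raw = pools[pool_id]
        norm = normalize_counts(raw, scale=config.scale)
        scored = set(norm.samples.index[(norm.samples["class_"] == "tumor")
                                        & norm.samples["scored"]])
        norm = zero_fill(norm, scored)
        scores_parts.append(hairpin_scores(norm, pseudocount=config.pseudocount,
                                           reference=config.reference))
        calls = call_enriched(norm, fold=config.fold, floor=config.floor,
                              pseudocount=config.pseudocount)
        # phi denominator: every injection of this pool, zero-filled included
        pool_filters = gene_filters(
            calls, manifest,
            min_tumors_per_hairpin=config.min_tumors_per_hairpin,
            total_tumors=len(norm.tumor_columns))
        pool_genes = set(norm.counts.index.map(manifest.gene_of_hairpin()))
        filter_parts.append(pool_filters.loc[sorted(pool_genes)])
        total_tumors += len(norm.tumor_columns)
        log.info("pool %s: %d hairpins, %d tumors (%d scored)", pool_id,
                 len(norm.counts), len(norm.tumor_columns), len(scored))

    all_scores = pd.concat(scores_parts)
    ranking = riger_rank(all_scores, manifest,
                         permutations=config.permutations,
                         weight_exponent=config.weight_exponent,
                         seed=config.seed)
    filters = pd.concat(filter_parts)
    filters = filters[~filters.index.duplicated()]
    report = candidate_genes(ranking, filters, p_cut=config.p_cut,
                             phi_cut=config.phi_cut, h_cut=config.h_cut)
    log.info("filters: %d pass p, %d pass phi, %d pass h, %d candidates",
             int(report["pass_p"].sum()), int(report["pass_phi"].sum()),
             int(report["pass_h"].sum()), int(report["candidate"].sum()))
    provenance = {
        "stage": "screen",
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "version": __version__,
        "n_pools": len(pools),
        "n_hairpins": int(len(all_scores)),
        "n_tumors": int(total_tumors),
        "n_candidates": int(report["candidate"].sum()),
    }
    return report, provenance


def run_tf_pipeline(
    table: pd.DataFrame,
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Driver-TF prediction pass over a per-TF four-line score table."""
    config = config or RunConfig()
    ranked = rank_tf_table(table, weight_group=config.weight_group,
                           top_rna=config.top_rna, top_atac=config.top_atac,
                           n_combined=config.n_combined, n_atac=config.n_atac)
    log.info("ranked %d TFs, selected %d", len(ranked),
             int(ranked["selected"].sum()))
    provenance = {
        "stage": "tf",
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "version": __version__,
        "gamma_rna": ranked.attrs.get("gamma_rna"),
        "gamma_atac": ranked.attrs.get("gamma_atac"),
        "n_tfs": int(len(ranked)),
        "n_selected": int(ranked["selected"].sum()),
    }
    return ranked, provenance
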