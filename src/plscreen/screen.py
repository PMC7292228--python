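"""Hit-calling for the pooled in vivo shRNA screen.

Stages: per-pool read-count normalization to a fixed sequencing scale,
zero-filling of tumors that never scored, per-hairpin log2 enrichment
scores, KS-based gene enrichment ranking with a permutation null
(RIGER-style), per-hairpin/per-tumor enrichment calls, reproducibility
filters (fraction of tumors, number of independent hairpins), triangle
thresholding for the hairpin-support cutoff, and the final candidate-gene
report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .library import LibraryManifest

__all__ = [
    "CountMatrix",
    "GeneRanking",
    "EnrichmentCalls",
    "normalize_counts",
    "zero_fill",
    "hairpin_scores",
    "riger_rank",
    "call_enriched",
    "gene_filters",
    "triangle_threshold",
    "candidate_genes",
]

SAMPLE_CLASSES = ("plasmid", "pregraft", "tumor")


@dataclass
class CountMatrix:
    """Hairpin x sample read counts plus per-sample metadata.

    ``counts``: DataFrame indexed by hairpin_id, one column per sample.
    ``samples``: DataFrame indexed by sample_id with columns ``class_``
    (plasmid/pregraft/tumor), ``pool_id`` and ``scored`` (bool).
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    normalized: bool = False
    scale: float = 1e7

    def __post_init__(self) -> None:
        if not set(self.counts.columns) == set(self.samples.index):
            raise ValueError("count columns and sample sheet disagree")
        bad = set(self.samples["class_"]) - set(SAMPLE_CLASSES)
        if bad:
            raise ValueError(f"unknown sample classes: {sorted(bad)}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative read counts")

    def columns_of(self, class_: str) -> list[str]:
        return list(self.samples.index[self.samples["class_"] == class_])

    @property
    def tumor_columns(self) -> list[str]:
        return self.columns_of("tumor")

    @property
    def plasmid_columns(self) -> list[str]:
        return self.columns_of("plasmid")


@dataclass
class GeneRanking:
    """Per-gene enrichment score, permutation p-value and rank (1 = most
    enriched)."""

    table: pd.DataFrame  # index gene_id: es, p_value, rank, n_hairpins
    permutations: int = 0

    def __post_init__(self) -> None:
        ranks = np.sort(self.table["rank"].to_numpy())
        if not np.array_equal(ranks, np.arange(1, len(self.table) + 1)):
            raise ValueError("ranks are not a permutation of 1..G")


@dataclass
class EnrichmentCalls:
    """Boolean hairpin x tumor enrichment call matrix with thresholds."""

    calls: pd.DataFrame
    fold: float
    floor: float


def normalize_counts(raw: CountMatrix, scale: float = 1e7) -> CountMatrix:
    """Rescale every sample column to sum to ``scale`` reads (the screen's
    sequencing depth unit: 10 million reads per pool).

    All-zero columns are left as zeros with a warning.
    """
    if raw.normalized:
        raise ValueError("matrix already normalized")
    values = raw.counts.astype(float)
    sums = values.sum(axis=0)
    zero_cols = sums[sums == 0].index
    if len(zero_cols):
        warnings.warn(
            f"{len(zero_cols)} all-zero sample column(s) left unnormalized: "
            f"{list(zero_cols[:5])}",
            stacklevel=2,
        )
    factors = pd.Series(np.where(sums > 0, scale / sums.replace(0, np.nan), 0.0),
                        index=sums.index).fillna(0.0)
    normed = values * factors
    return CountMatrix(normed, raw.samples.copy(), normalized=True, scale=scale)


def zero_fill(counts: CountMatrix, scored_tumors: set[str] | list[str]) -> CountMatrix:
    """Set tumor columns outside ``scored_tumors`` to zero and flag them
    unscored.

    Tumors that never produced a scorable mass by the harvest week failed to
    out-grow stochastically enriched clones; their hairpin reads are
    recorded as zero so the matrix stays complete for the ranking model.
    """
    scored = set(scored_tumors)
    tumors = set(counts.tumor_columns)
    unknown = scored - tumors
    if unknown:
        raise KeyError(f"unknown tumor sample ids: {sorted(unknown)}")
    out = counts.counts.copy()
    samples = counts.samples.copy()
    for col in tumors - scored:
        out[col] = 0.0
        samples.loc[col, "scored"] = False
    for col in scored:
        samples.loc[col, "scored"] = True
    return replace(counts, counts=out, samples=samples)


def hairpin_scores(
    norm: CountMatrix,
    pseudocount: float = 1.0,
    reference: str = "plasmid",
) -> pd.Series:
    """Per-hairpin log2 enrichment of mean tumor reads over mean reference
    (plasmid by default) reads, with a pseudocount on both means."""
    if not norm.normalized:
        raise ValueError("hairpin_scores requires a normalized matrix")
    ref_cols = norm.columns_of(reference)
    tum_cols = norm.tumor_columns
    if not ref_cols:
        raise ValueError(f"no {reference} column in matrix")
    if not tum_cols:
        raise ValueError("no tumor column in matrix")
    ref_mean = norm.counts[ref_cols].mean(axis=1)
    tum_mean = norm.counts[tum_cols].mean(axis=1)
    return np.log2((tum_mean + pseudocount) / (ref_mean + pseudocount)).rename("score")


# --- RIGER-style KS gene ranking -------------------------------------------


def _es_from_positions(
    positions: np.ndarray, weights: np.ndarray, n_total: int
) -> np.ndarray:
    """Signed KS enrichment score for hit-position sets.

    ``positions``: (P, n) sorted 0-based ranks of each gene's hairpins in
    the score-sorted list; ``weights``: per-rank |score|^exponent over the
    whole list (length n_total).  Returns (P,) signed ES: the running-sum
    extremum of largest magnitude (positive on ties), where the sum steps
    up by the hit's weight share and down by 1/(misses) between hits.
    """
    positions = np.atleast_2d(positions)
    p, n = positions.shape
    if n >= n_total:
        raise ValueError("gene cannot own every hairpin in the list")
    w = weights[positions]
    cumw = np.cumsum(w, axis=1)
    total = cumw[:, -1].copy()
    uniform = total <= 0
    if uniform.any():
        # all-zero weights: fall back to the unweighted (classic KS) step
        cumw[uniform] = np.arange(1, n + 1)
        total[uniform] = n
    miss_cdf = (positions - np.arange(n)) / (n_total - n)
    dev_after = cumw / total[:, None] - miss_cdf
    dev_before = (cumw - w) / total[:, None] - miss_cdf
    if uniform.any():
        dev_before[uniform] = np.arange(n) / n - miss_cdf[uniform]
    hi = dev_after.max(axis=1)
    lo = dev_before.min(axis=1)
    # positive extremum wins magnitude ties (tolerance absorbs fp noise)
    return np.where(hi >= -lo - 1e-12, hi, lo)


def _null_positions(
    rng: np.random.Generator, permutations: int, n: int, n_total: int
) -> np.ndarray:
    """(permutations, n) sorted random hit-position sets."""
    u = rng.random((permutations, n_total))
    part = np.argpartition(u, n - 1, axis=1)[:, :n]
    return np.sort(part, axis=1)


def _exact_positions(n: int, n_total: int) -> np.ndarray:
    return np.array(list(combinations(range(n_total), n)), dtype=np.int64)


def riger_rank(
    scores: pd.Series,
    manifest: LibraryManifest,
    permutations: int = 10000,
    weight_exponent: float = 0.0,
    seed: int = 0,
    exact_p: bool = False,
    max_exact: int = 200_000,
    stratify_by_pool: bool = True,
) -> GeneRanking:
    """Rank genes by KS enrichment of their hairpins in the score-sorted
    list (RIGER-style, enrichment direction).

    Hairpins are sorted by score descending; each gene's ES is the maximal
    running-sum deviation of its hairpin positions against the rest,
    weighted by |score|^``weight_exponent`` (0 = classic KS).  The p-value
    is (1 + #{permuted ES >= observed}) / (1 + P) under random
    reassignment of hairpin positions preserving the gene's hairpin count;
    the null is shared across genes of equal size (and pool).  With
    ``stratify_by_pool`` (default) and a pooled manifest, null positions
    are drawn from the gene's own pool — pooled screens have pool-level
    batch structure (each pool sees its own tumors), and an unstratified
    null is anti-conservative for gene-blocked pools.  ``exact_p``
    enumerates all position sets instead of sampling when the count is at
    most ``max_exact``.  Rank 1 = most enriched; ES ties break by gene_id.
    """
    gene_of = manifest.gene_of_hairpin()
    unknown = set(scores.index) - set(gene_of.index)
    if unknown:
        raise ValueError(f"hairpins without gene mapping: {sorted(unknown)[:5]}")
    genes_all = sorted(manifest.hairpins_per_gene.index)
    n_total = len(scores)

    vals = scores.to_numpy(dtype=float)
    ids = scores.index.to_numpy(dtype=str)
    order_idx = np.lexsort((ids, -vals))  # score desc, hairpin id tie-break
    order = scores.iloc[order_idx]
    ranked_genes = gene_of.loc[order.index].to_numpy()
    weights = np.abs(order.to_numpy()) ** weight_exponent if weight_exponent else np.ones(n_total)

    pos_of_gene: dict[str, np.ndarray] = {}
    for g in genes_all:
        pos = np.flatnonzero(ranked_genes == g)
        if pos.size == 0:
            warnings.warn(f"gene {g} has no hairpin in the score vector; excluded",
                          stacklevel=2)
            continue
        pos_of_gene[g] = pos
    if len(pos_of_gene) < 2:
        raise ValueError("need at least 2 genes with scored hairpins")

    es_obs = {
        g: float(_es_from_positions(pos[None, :], weights, n_total)[0])
        for g, pos in pos_of_gene.items()
    }

    # permutation stratum per gene: its pool's positions in the ranked list
    if stratify_by_pool and manifest.pooled and manifest.n_pools > 1:
        pool_of_gene = (manifest.entries.drop_duplicates("gene_id")
                        .set_index("gene_id")["pool_id"])
        pool_of_ranked = pool_of_gene.loc[ranked_genes].to_numpy()
        stratum_of = {g: int(pool_of_gene[g]) for g in pos_of_gene}
        stratum_positions = {
            int(q): np.flatnonzero(pool_of_ranked == q)
            for q in pool_of_gene.loc[list(pos_of_gene)].unique()
        }
    else:
        stratum_of = {g: 0 for g in pos_of_gene}
        stratum_positions = {0: np.arange(n_total)}

    rng = np.random.default_rng(seed)
    null_es: dict[tuple[int, int], np.ndarray] = {}
    null_n: dict[tuple[int, int], int] = {}
    for g, pos in pos_of_gene.items():
        key = (stratum_of[g], pos.size)
        if key in null_es:
            continue
        stratum = stratum_positions[stratum_of[g]]
        n, m = pos.size, stratum.size
        if exact_p and comb(m, n) <= max_exact:
            idx_sets = _exact_positions(n, m)
        else:
            idx_sets = _null_positions(rng, permutations, n, m)
        null_es[key] = _es_from_positions(stratum[idx_sets], weights, n_total)
        null_n[key] = idx_sets.shape[0]

    rows = []
    for g, pos in pos_of_gene.items():
        key = (stratum_of[g], pos.size)
        null = null_es[key]
        p = (1 + int((null >= es_obs[g] - 1e-12).sum())) / (1 + null_n[key])
        rows.append((g, es_obs[g], p, pos.size))
    table = pd.DataFrame(rows, columns=["gene_id", "es", "p_value", "n_hairpins"])
    table = table.sort_values(["es", "gene_id"], ascending=[False, True],
                              kind="mergesort").set_index("gene_id")
    table["rank"] = np.arange(1, len(table) + 1)
    return GeneRanking(table, permutations=permutations)


# --- enrichment calls and reproducibility filters ---------------------------


def call_enriched(
    norm: CountMatrix,
    fold: float = 4.0,
    floor: float = 100.0,
    pseudocount: float = 1.0,
) -> EnrichmentCalls:
    """Call a hairpin enriched in a tumor when its normalized reads are at
    least ``fold`` times the plasmid mean (plus pseudocount) and at least
    ``floor`` reads (suppresses ratio blow-ups at low counts)."""
    if fold <= 0:
        raise ValueError("fold must be positive")
    if not norm.normalized:
        raise ValueError("call_enriched requires a normalized matrix")
    plasmid_cols = norm.plasmid_columns
    if not plasmid_cols:
        raise ValueError("no plasmid column in matrix")
    tum_cols = norm.tumor_columns
    plasmid_mean = norm.counts[plasmid_cols].mean(axis=1)
    threshold = np.maximum(fold * (plasmid_mean + pseudocount), floor)
    calls = norm.counts[tum_cols].ge(threshold, axis=0)
    return EnrichmentCalls(calls, fold=fold, floor=floor)


def gene_filters(
    calls: EnrichmentCalls,
    manifest: LibraryManifest,
    min_tumors_per_hairpin: int = 1,
    total_tumors: int | None = None,
) -> pd.DataFrame:
    """Per-gene reproducibility statistics.

    phi(g): fraction of tumors (over ``total_tumors``, default the number
    of tumor columns — zero-filled tumors included in the denominator)
    with at least one enriched hairpin of g.  h(g): number of distinct
    hairpins of g enriched in at least ``min_tumors_per_hairpin`` tumors.
    """
    if total_tumors is None:
        total_tumors = calls.calls.shape[1]
    if total_tumors <= 0:
        raise ValueError("total_tumors must be positive")
    gene_of = manifest.gene_of_hairpin()
    common = calls.calls.index.intersection(gene_of.index)
    calls_df = calls.calls.loc[common]
    genes = gene_of.loc[common]

    per_gene_tumor = calls_df.groupby(genes).any()  # gene x tumor: any hairpin
    phi = per_gene_tumor.sum(axis=1) / total_tumors
    per_hairpin = calls_df.sum(axis=1) >= min_tumors_per_hairpin
    h = per_hairpin.groupby(genes).sum()

    out = pd.DataFrame({"phi": phi, "h": h.astype(int)})
    missing = sorted(set(manifest.hairpins_per_gene.index) - set(out.index))
    if missing:
        pad = pd.DataFrame({"phi": 0.0, "h": 0}, index=pd.Index(missing, name="gene_id"))
        out = pd.concat([out, pad]).sort_index()
    out.index.name = "gene_id"
    return out


def triangle_threshold(histogram: np.ndarray | list[float]) -> int:
    """Triangle (Zack) threshold on a histogram of support values.

    Draws the line from the histogram peak (leftmost maximum) to the last
    nonzero bin and returns the index of the interior bin at maximal
    perpendicular distance from that line, plus one (the threshold excludes
    the distribution bulk).
    """
    h = np.asarray(histogram, dtype=float)
    if h.ndim != 1 or h.size < 3:
        raise ValueError("histogram needs at least 3 bins")
    if (h < 0).any():
        raise ValueError("histogram counts must be non-negative")
    if not h.any():
        raise ValueError("all-zero histogram")
    b_peak = int(np.argmax(h))  # leftmost maximum
    b_tail = int(np.flatnonzero(h)[-1])
    if b_tail <= b_peak:
        raise ValueError("histogram has no tail to the right of its peak")
    # perpendicular distance from (i, h_i) to the peak->tail line
    x0, y0 = b_peak, h[b_peak]
    x1, y1 = b_tail, h[b_tail]
    i = np.arange(b_peak + 1, b_tail + 1)
    dist = np.abs((x1 - x0) * (h[i] - y0) - (y1 - y0) * (i - x0))
    best = int(i[np.argmax(dist)])
    return best + 1


def candidate_genes(
    ranking: GeneRanking,
    filters: pd.DataFrame,
    p_cut: float = 1e-4,
    phi_cut: float = 0.08,
    h_cut: int = 4,
) -> pd.DataFrame:
    """Combine the enrichment ranking with the reproducibility filters into
    the candidate-gene report.

    candidate <=> p < p_cut  AND  phi > phi_cut  AND  h >= h_cut.
    """
    table = ranking.table.join(filters, how="left")
    if table[["phi", "h"]].isna().any().any():
        missing = table.index[table["phi"].isna()]
        raise ValueError(f"genes missing filter stats: {list(missing[:5])}")
    table["pass_p"] = table["p_value"] < p_cut
    table["pass_phi"] = table["phi"] > phi_cut
    table["pass_h"] = table["h"] >= h_cut
    table["candidate"] = table["pass_p"] & table["pass_phi"] & table["pass_h"]
    return table.sort_values("rank")
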