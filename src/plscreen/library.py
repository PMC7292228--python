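"""Screen library manifest construction and injection-pool partitioning.

An in vivo pooled shRNA screen must keep per-hairpin representation high
enough that every hairpin contributes cells to every engrafted tumor.  The
standard remedy is to split the library into small injection pools (~100
hairpins each) and screen each pool through multiple independent
injections.  This module builds the gene/hairpin manifest for such a
library (5 or 6 hairpins per gene) and partitions it into balanced,
gene-blocked pools.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LibraryManifest", "build_manifest", "partition_pools"]


@dataclass
class LibraryManifest:
    """Gene <-> hairpin <-> pool mapping for a pooled screen.

    ``entries`` is a DataFrame with columns ``gene_id``, ``hairpin_id`` and
    ``pool_id`` (nullable integer; NA until pools are assigned).
    """

    entries: pd.DataFrame
    hairpins_per_gene: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        required = {"gene_id", "hairpin_id", "pool_id"}
        missing = required - set(self.entries.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        if self.entries["hairpin_id"].duplicated().any():
            dups = self.entries.loc[self.entries["hairpin_id"].duplicated(), "hairpin_id"]
            raise ValueError(f"duplicate hairpin ids: {list(dups.head())}")
        counts = self.entries.groupby("gene_id").size()
        if ((counts < 1) | (counts > 8)).any():
            raise ValueError("every gene must carry between 1 and 8 hairpins")
        self.hairpins_per_gene = counts

    @property
    def n_hairpins(self) -> int:
        return len(self.entries)

    @property
    def n_genes(self) -> int:
        return self.entries["gene_id"].nunique()

    @property
    def pooled(self) -> bool:
        return self.entries["pool_id"].notna().all()

    @property
    def n_pools(self) -> int:
        return int(self.entries["pool_id"].nunique(dropna=True))

    def genes_of_pool(self, pool_id: int) -> list[str]:
        sub = self.entries[self.entries["pool_id"] == pool_id]
        return sorted(sub["gene_id"].unique())

    def hairpins_of_gene(self, gene_id: str) -> list[str]:
        return list(self.entries.loc[self.entries["gene_id"] == gene_id, "hairpin_id"])

    def gene_of_hairpin(self) -> pd.Series:
        """hairpin_id -> gene_id mapping."""
        return self.entries.set_index("hairpin_id")["gene_id"]


def build_manifest(gene_count: int, six_hairpin_gene_count: int) -> LibraryManifest:
    """Build a manifest with 5 hairpins per gene, 6 for the first
    ``six_hairpin_gene_count`` genes.

    Identifiers are deterministic: genes ``GENE0001..``, hairpins
    ``GENE0001_sh1..``.
    """
    if gene_count <= 0:
        raise ValueError("gene_count must be positive")
    if six_hairpin_gene_count < 0:
        raise ValueError("six_hairpin_gene_count must be non-negative")
    if six_hairpin_gene_count > gene_count:
        raise ValueError("six_hairpin_gene_count cannot exceed gene_count")

    width = max(4, len(str(gene_count)))
    genes, hairpins = [], []
    for g in range(1, gene_count + 1):
        gene_id = f"GENE{g:0{width}d}"
        n_hp = 6 if g <= six_hairpin_gene_count else 5
        for h in range(1, n_hp + 1):
            genes.append(gene_id)
            hairpins.append(f"{gene_id}_sh{h}")
    entries = pd.DataFrame(
        {
            "gene_id": genes,
            "hairpin_id": hairpins,
            "pool_id": pd.array([pd.NA] * len(genes), dtype="Int64"),
        }
    )
    return LibraryManifest(entries)


def partition_pools(
    manifest: LibraryManifest,
    target_size: int = 100,
    seed: int = 0,
    gene_blocked: bool = True,
) -> LibraryManifest:
    """Partition the manifest into K = ceil(N / target_size) injection pools.

    With ``gene_blocked`` (default) all hairpins of a gene share one pool:
    genes are assigned largest-first to the currently least-full pool, after
    a seeded shuffle that breaks ties between equal-sized genes.  Pool sizes
    then differ by at most one gene's hairpin count.  Without gene blocking,
    hairpins are shuffled and dealt round-robin.
    """
    n = manifest.n_hairpins
    if n < 1:
        raise ValueError("manifest has no hairpins")
    if target_size <= 0:
        raise ValueError("target_size must be positive")
    max_per_gene = int(manifest.hairpins_per_gene.max())
    if gene_blocked and target_size < max_per_gene:
        raise ValueError(
            f"target_size {target_size} smaller than the largest gene "
            f"({max_per_gene} hairpins); gene-blocked pooling impossible"
        )

    k = -(-n // target_size)  # ceil
    rng = np.random.default_rng(seed)
    entries = manifest.entries.copy()

    if gene_blocked:
        sizes = manifest.hairpins_per_gene
        gene_ids = np.array(sorted(sizes.index))
        rng.shuffle(gene_ids)
        # stable sort: largest genes first, seeded order breaks ties
        order = sorted(gene_ids, key=lambda g: -sizes[g])
        # min-heap of (pool load, pool id)
        heap = [(0, pid) for pid in range(1, k + 1)]
        heapq.heapify(heap)
        assignment: dict[str, int] = {}
        for g in order:
            load, pid = heapq.heappop(heap)
            assignment[g] = pid
            heapq.heappush(heap, (load + int(sizes[g]), pid))
        entries["pool_id"] = entries["gene_id"].map(assignment).astype("Int64")
    else:
        idx = rng.permutation(n)
        pools = np.empty(n, dtype=int)
        pools[idx] = np.arange(n) % k + 1
        entries["pool_id"] = pd.array(pools, dtype="Int64")

    return LibraryManifest(entries)
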