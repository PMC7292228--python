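"""Synthetic-data generators with ground truth for every pipeline stage.

The screen generator reproduces the statistical shape the hit-calling
stages assume: a tightly distributed plasmid library, a hard engraftment
bottleneck per tumor, broad lognormal clonal expansion (so most hairpins
dilute while a few expand), planted resistant hairpins amplified in a
penetrance-chosen subset of tumors, per-tumor jackpot clones, a negative
control gene with a fixed stochastic enrichment rate, and a fraction of
injections that never score.  The TF-table and ATAC generators plant
driver TFs and motif-proximity enrichment on noise backgrounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .library import LibraryManifest
from .screen import CountMatrix

__all__ = [
    "ScreenTruth",
    "TFTruth",
    "simulate_screen",
    "simulate_tf_tables",
    "simulate_atac",
]


@dataclass
class ScreenTruth:
    """Generator parameters and planted ground truth for a screen run.

    ``planted``: gene_id -> (n_active_hairpins, tumor_penetrance) for
    resistant genes; per pool, each planted gene's active hairpins expand
    clonally in a randomly chosen subset of round(penetrance x tumors)
    tumors (at least one when penetrance > 0) — the penetrance is the
    fraction of injection sites in which the resistant clone establishes.
    ``negative_control_gene`` enriches one random hairpin per tumor at
    ``negative_control_rate`` (stochastic, never reproducible across
    hairpins).  ``jackpot_rate`` is the per-tumor probability that one
    random bystander hairpin expands clonally.  A tumor scores by harvest
    whenever it harbors any expanded clone; tumors carrying only diluting
    background clones fail to score with probability ``nonscoring_rate``.
    """

    planted: dict[str, tuple[int, float]] = field(default_factory=dict)
    negative_control_gene: str | None = None
    negative_control_rate: float = 0.08
    jackpot_rate: float = 0.1
    bottleneck: int = 10000
    representation_sigma: float = 0.25
    growth_sigma: float = 0.5
    resistant_advantage: float = 150.0
    jackpot_advantage: float = 300.0
    nonscoring_rate: float = 0.2
    plasmid_depth: int = 2_000_000
    tumor_depth: int = 2_000_000

    def __post_init__(self) -> None:
        for rate in (self.negative_control_rate, self.jackpot_rate,
                     self.nonscoring_rate):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")
        for gene, (n_active, pen) in self.planted.items():
            if n_active < 1 or not 0 <= pen <= 1:
                raise ValueError(f"invalid planted spec for {gene}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TFTruth:
    """Planted drivers and effect sizes for synthetic TF score tables.

    Effects are positive shifts added to every line's background noise;
    XE lines get the larger shifts, with per-line lognormal multipliers
    emulating the divergence of independently derived resistant sublines.
    """

    planted_driver_tfs: tuple[str, ...] = ()
    rna_effect_xe: float = 3.0
    rna_effect_sh: float = 1.5
    atac_effect_xe: float = 0.25
    atac_effect_sh: float = 0.12
    rna_noise: float = 0.7
    atac_noise: float = 0.06
    line_sigma: float = 0.25

    def __post_init__(self) -> None:
        if self.planted_driver_tfs and (
                min(self.rna_effect_xe, self.rna_effect_sh) <= 0
                or min(self.atac_effect_xe, self.atac_effect_sh) <= 0):
            raise ValueError("driver effects must be positive in both modalities")

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_screen(
    manifest: LibraryManifest,
    truth: ScreenTruth,
    tumors_per_pool: int = 10,
    seed: int = 0,
) -> tuple[dict[int, CountMatrix], ScreenTruth]:
    """Simulate raw per-pool count matrices for a pooled in vivo screen.

    Returns one raw CountMatrix per pool (1 plasmid sample + 10 tumors by
    default, a configurable fraction flagged non-scoring) plus the truth.
    """
    if not manifest.pooled:
        raise ValueError("manifest must be pooled first")
    unknown = set(truth.planted) - set(manifest.hairpins_per_gene.index)
    if unknown:
        raise ValueError(f"planted genes not in manifest: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    matrices: dict[int, CountMatrix] = {}

    for pool_id in sorted(manifest.entries["pool_id"].dropna().unique()):
        sub = manifest.entries[manifest.entries["pool_id"] == pool_id]
        hairpins = sub["hairpin_id"].to_numpy()
        genes = sub["gene_id"].to_numpy()
        n = len(hairpins)
        if truth.bottleneck < n:
            raise ValueError("engraftment bottleneck smaller than pool size")

        # plasmid: near-uniform with lognormal representation noise
        rep = rng.lognormal(0.0, truth.representation_sigma, n)
        rep /= rep.sum()
        plasmid = rng.multinomial(truth.plasmid_depth, rep)

        # active hairpins and penetrant-tumor subset per planted gene
        active_idx: dict[str, np.ndarray] = {}
        penetrant_tumors: dict[str, set[int]] = {}
        for gene, (n_active, pen) in truth.planted.items():
            gene_idx = np.flatnonzero(genes == gene)
            if not gene_idx.size:
                continue
            active_idx[gene] = gene_idx[: min(n_active, gene_idx.size)]
            n_pen = max(1, round(pen * tumors_per_pool)) if pen > 0 else 0
            n_pen = min(n_pen, tumors_per_pool)
            penetrant_tumors[gene] = set(
                rng.choice(tumors_per_pool, size=n_pen, replace=False))

        nc_idx = (np.flatnonzero(genes == truth.negative_control_gene)
                  if truth.negative_control_gene else np.array([], dtype=int))

        columns = {}
        sample_rows = []
        p_id = f"pool{pool_id}_plasmid"
        columns[p_id] = plasmid
        sample_rows.append((p_id, "plasmid", pool_id, True))

        for t in range(tumors_per_pool):
            cells = rng.multinomial(truth.bottleneck, rep).astype(float)
            growth = rng.lognormal(0.0, truth.growth_sigma, n)
            mass = cells * growth
            expanded = False
            for gene, act in active_idx.items():
                if t in penetrant_tumors[gene]:
                    mass[act] *= truth.resistant_advantage
                    expanded = True
            if nc_idx.size and rng.random() < truth.negative_control_rate:
                mass[rng.choice(nc_idx)] *= truth.jackpot_advantage
                expanded = True
            if rng.random() < truth.jackpot_rate:
                mass[rng.integers(n)] *= truth.jackpot_advantage
                expanded = True
            if mass.sum() == 0:
                mass[:] = 1.0
            reads = rng.multinomial(truth.tumor_depth, mass / mass.sum())
            t_id = f"pool{pool_id}_tumor{t + 1}"
            # tumors score when an expanded clone drives growth; background-
            # only tumors fail at the configured rate
            scored = expanded or bool(rng.random() >= truth.nonscoring_rate)
            columns[t_id] = reads
            sample_rows.append((t_id, "tumor", pool_id, scored))

        counts = pd.DataFrame(columns, index=pd.Index(hairpins, name="hairpin_id"))
        samples = pd.DataFrame(
            sample_rows, columns=["sample_id", "class_", "pool_id", "scored"]
        ).set_index("sample_id")
        matrices[int(pool_id)] = CountMatrix(counts, samples, normalized=False)

    return matrices, truth


def simulate_tf_tables(
    n_tfs: int = 200,
    truth: TFTruth | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, TFTruth]:
    """Simulate the per-TF four-line score table the driver-prediction
    workflow consumes.

    Background TFs draw zero-mean noise per line; planted drivers add
    positive RNA and motif-differential shifts in every line, larger in the
    XE lines and modulated by per-line lognormal multipliers.
    """
    if truth is None:
        truth = TFTruth(planted_driver_tfs=())
    rng = np.random.default_rng(seed)
    width = max(3, len(str(n_tfs)))
    tf_ids = [f"TF{i:0{width}d}" for i in range(1, n_tfs + 1)]
    unknown = set(truth.planted_driver_tfs) - set(tf_ids)
    if unknown:
        raise ValueError(f"planted drivers outside the TF universe: {sorted(unknown)}")

    rna = rng.normal(0.0, truth.rna_noise, (n_tfs, 4))
    atac = rng.normal(0.0, truth.atac_noise, (n_tfs, 4))
    driver_idx = [tf_ids.index(t) for t in truth.planted_driver_tfs]
    for i in driver_idx:
        mult = rng.lognormal(0.0, truth.line_sigma, 4)
        rna[i] += mult * np.array([truth.rna_effect_xe, truth.rna_effect_xe,
                                   truth.rna_effect_sh, truth.rna_effect_sh])
        mult = rng.lognormal(0.0, truth.line_sigma, 4)
        atac[i] += mult * np.array([truth.atac_effect_xe, truth.atac_effect_xe,
                                    truth.atac_effect_sh, truth.atac_effect_sh])

    table = pd.DataFrame(
        np.hstack([rna, atac]),
        index=pd.Index(tf_ids, name="tf_id"),
        columns=["rna_lfc_xe1", "rna_lfc_xe2", "rna_lfc_sh1", "rna_lfc_sh2",
                 "atac_d_xe1", "atac_d_xe2", "atac_d_sh1", "atac_d_sh2"],
    )
    return table, truth


def simulate_atac(
    n_peaks: int = 400,
    n_motifs: int = 10,
    planted: dict[str, float] | None = None,
    genome_length: int = 10_000_000,
    seed: int = 0,
    n_replicates: int = 2,
    n_pseudoreplicates: int = 2,
    peak_width: int = 500,
    jitter: int = 20,
    hits_per_motif: int = 2000,
    background_near_fraction: float = 0.2,
    r_small: int = 150,
    n_gained: int = 0,
    n_lost: int = 0,
) -> dict:
    """Simulate peak sets (condition + control, each with replicates and
    pseudoreplicates) and motif hit sets with planted proximity enrichment.

    Latent condition/control peak sets share a common core; ``n_gained``
    latent peaks are condition-only and ``n_lost`` control-only.  Replicates
    are jittered copies of the latent set (edges shifted by up to
    ``jitter`` bp inward/outward).  Background motifs place a
    ``background_near_fraction`` of their hits within +-``r_small`` of
    shared peak centers (visible in both conditions, so their MD
    differential is null); a motif listed in ``planted`` instead places
    that fraction of its hits near condition-only (gained) peak centers,
    emulating a TF whose binding sites open specifically in the condition.
    Remaining hits are uniform on the genome.  Returns a dict with keys
    ``condition``, ``control`` (lists of replicate DataFrames),
    ``latent_condition``, ``latent_control``, ``motif_hits`` and ``truth``.
    """
    planted = dict(planted or {})
    rng = np.random.default_rng(seed)
    span = peak_width + 2 * jitter + 10
    n_latent = n_peaks + n_gained + n_lost
    if n_latent * 4 * span > genome_length:
        raise ValueError("peaks do not fit in genome_length at this density")

    # non-overlapping latent peak starts on one chromosome
    slots = rng.choice(genome_length // (4 * span), size=n_latent, replace=False)
    starts = np.sort(slots) * 4 * span + span
    latent = pd.DataFrame({"chrom": "chr1", "start": starts,
                           "end": starts + peak_width})
    shared = latent.iloc[: n_peaks]
    gained = latent.iloc[n_peaks: n_peaks + n_gained]
    lost = latent.iloc[n_peaks + n_gained:]
    latent_cond = pd.concat([shared, gained]).sort_values("start").reset_index(drop=True)
    latent_ctrl = pd.concat([shared, lost]).sort_values("start").reset_index(drop=True)

    def jittered(base: pd.DataFrame) -> pd.DataFrame:
        if jitter == 0:
            return base.copy()
        ds = rng.integers(-jitter, jitter + 1, len(base))
        de = rng.integers(-jitter, jitter + 1, len(base))
        out = base.copy()
        out["start"] = np.maximum(0, base["start"] + ds)
        out["end"] = np.maximum(out["start"] + 1, base["end"] + de)
        return out

    condition = [jittered(latent_cond) for _ in range(n_replicates + n_pseudoreplicates)]
    control = [jittered(latent_ctrl) for _ in range(n_replicates + n_pseudoreplicates)]

    if planted and n_gained == 0:
        raise ValueError("planted motifs need n_gained > 0 condition-only peaks")
    shared_centers = ((shared["start"] + shared["end"]) // 2).to_numpy()
    gained_centers = ((gained["start"] + gained["end"]) // 2).to_numpy()
    width_m = max(3, len(str(n_motifs)))
    rows = []
    for m in range(1, n_motifs + 1):
        motif = f"MOTIF{m:0{width_m}d}"
        if motif in planted:
            near_frac, anchors = planted[motif], gained_centers
        else:
            near_frac, anchors = background_near_fraction, shared_centers
        near = rng.random(hits_per_motif) < near_frac
        pos = rng.integers(0, genome_length, hits_per_motif)
        offsets = rng.integers(-int(r_small * 0.8), int(r_small * 0.8) + 1,
                               hits_per_motif)
        anchor = anchors[rng.integers(0, len(anchors), hits_per_motif)]
        pos = np.where(near, np.clip(anchor + offsets, 0, genome_length - 10), pos)
        for p in pos:
            rows.append((motif, "chr1", int(p), int(p) + 10))
    motif_hits = pd.DataFrame(rows, columns=["motif_id", "chrom", "start", "end"])

    truth = {
        "planted": planted,
        "background_near_fraction": background_near_fraction,
        "n_gained": n_gained,
        "n_lost": n_lost,
        "jitter": jitter,
        "seed": seed,
    }
    return {
        "condition": condition[:n_replicates],
        "condition_pseudoreplicates": condition[n_replicates:],
        "control": control[:n_replicates],
        "control_pseudoreplicates": control[n_replicates:],
        "latent_condition": latent_cond,
        "latent_control": latent_ctrl,
        "motif_hits": motif_hits,
        "truth": truth,
    }
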